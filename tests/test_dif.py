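"""Anchored iterative DIF detection: calibration, contracts, invariants."""

import numpy as np
import pytest

from audcheck import (DIFDetector, ItemBank, MultigroupTwoPL, bonferroni_alpha,
                      detect_dif, lr_test_item, simulate_responses, study)
from audcheck.errors import ValidationError

from conftest import NULL_BANK, null_draw as _null_draw


class TestBonferroni:
    @pytest.mark.parametrize(
        "familywise,m,expected",
        [(0.05, 11, 0.05 / 11), (0.05, 1, 0.05), (0.10, 10, 0.01)],
    )
    def test_split(self, familywise, m, expected):
        assert bonferroni_alpha(familywise, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bonferroni_alpha(1.5, 11)
        with pytest.raises(ValidationError):
            bonferroni_alpha(0.05, 0)


class TestLRTest:
    def test_statistic_nonnegative_and_type_one_error_calibrated(self, null_joint_tests):
        stats_ = np.array([t.stat for t in null_joint_tests])
        ps = np.array([t.p for t in null_joint_tests])
        assert (stats_ >= 0).all()  # nested models: freeing can never hurt
        rate = (ps <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(ps))
        assert abs(rate - 0.05) <= 3 * se

    def test_anchor_item_cannot_be_tested(self):
        data = _null_draw(60, seed=1)
        with pytest.raises(ValidationError, match="anchor"):
            lr_test_item(data, "i1", anchors=("i1", "i2"), reference_group="clinic")

    def test_localisation_statistics_present(self):
        data = _null_draw(120, seed=9)
        t = lr_test_item(data, "i4", anchors=("i1", "i2"), reference_group="clinic")
        assert t.df == 2 and t.stat_a is not None and t.stat_b is not None
        assert 0 <= t.p_a <= 1 and 0 <= t.p_b <= 1


class TestDetectDIF:
    def test_null_bank_rarely_flags(self):
        """With no DIF anywhere, the full procedure at the .0045 per-item level
        leaves the flag set empty in at least 11 of 12 replicates."""
        bank = ItemBank.from_reference(
            list(study.ITEM_IDS), study.A_REFERENCE, study.B_REFERENCE,
            anchors=study.ANCHOR_ITEMS,
            reference_group=study.REFERENCE_GROUP, focal_group=study.FOCAL_GROUP,
        )
        empty = 0
        for seed in range(100, 112):
            rng = np.random.default_rng(seed)
            n = 600
            theta = rng.normal(0, 1, 2 * n)
            groups = np.array(
                [study.REFERENCE_GROUP] * n + [study.FOCAL_GROUP] * n, object
            )
            data = simulate_responses(theta, groups, bank, seed + 1)
            det = DIFDetector(
                anchors=study.ANCHOR_ITEMS, reference_group=study.REFERENCE_GROUP
            ).fit(data)
            empty += not det.flagged_items_
        assert empty >= 11

    def test_known_dif_free_item_rarely_flagged(self, detection_replicates):
        """'Hazardous use' is pooled in the published solution; re-simulated
        data should leave it unflagged in >= 9 of 12 replicates."""
        unflagged = sum(
            "hazardous_use" not in rep["report"].flagged_items
            for rep in detection_replicates
        )
        assert unflagged >= 9

    def test_strong_dif_item_reliably_flagged(self, detection_replicates):
        flagged = sum(
            "social_interpersonal" in rep["report"].flagged_items
            for rep in detection_replicates
        )
        assert flagged >= 10

    def test_anchors_never_flagged(self, detection_replicates):
        for rep in detection_replicates:
            assert not set(rep["report"].flagged_items) & set(study.ANCHOR_ITEMS)

    def test_final_fit_dominates_baseline(self, detection_replicates):
        for rep in detection_replicates:
            assert rep["report"].fit.loglik >= rep["report"].baseline_loglik - 1e-6

    def test_reported_pattern_reproduces_reported_loglik(self, detection_replicates):
        rep = detection_replicates[0]
        report = rep["report"]
        data = None
        # refit from the reported constraint pattern alone
        from conftest import simulate_clean_study
        data, _ = simulate_clean_study(rep["seed"])
        refit = MultigroupTwoPL(
            reference_group=study.REFERENCE_GROUP,
            anchors=report.anchors,
            free_a=list(report.free_a),
            free_b=list(report.free_b),
            compute_se=False,
        ).fit(data)
        assert refit.loglik_ == pytest.approx(report.fit.loglik, abs=1e-4)

    def test_detection_is_deterministic(self):
        bank = ItemBank.from_reference(
            ["i1", "i2", "i3", "i4", "i5"],
            [1.5, 2.2, 1.8, 2.6, 1.2],
            [-0.8, 0.0, 0.5, 1.0, 1.5],
            focal_b={"i4": 0.5},
            reference_group="clinic", focal_group="online",
        )
        data = _null_draw(250, seed=77, bank=bank)
        d1 = DIFDetector(anchors=("i1", "i2"), reference_group="clinic").fit(data)
        d2 = DIFDetector(anchors=("i1", "i2"), reference_group="clinic").fit(data)
        assert d1.flags_ == d2.flags_
        assert d1.report_.fit.loglik == d2.report_.fit.loglik

    def test_all_items_anchored_gives_empty_report(self):
        data = _null_draw(150, seed=31)
        report = detect_dif(data, anchors=tuple(NULL_BANK.item_ids),
                            reference_group="clinic")
        assert report.flagged_items == ()
        assert report.table["tested"].sum() == 0
        assert report.fit.converged

    def test_auto_anchor_selection(self):
        bank = ItemBank.from_reference(
            ["i1", "i2", "i3", "i4", "i5"],
            [1.5, 2.2, 1.8, 2.6, 1.2],
            [-0.8, 0.0, 0.5, 1.0, 1.5],
            focal_b={"i4": 0.4},
            reference_group="clinic", focal_group="online",
        )
        data = _null_draw(400, seed=55, bank=bank)
        det = DIFDetector(anchors="auto", n_anchors=2, reference_group="clinic").fit(data)
        assert len(det.anchors_) == 2
        assert "i4" not in det.anchors_  # the DIF item has the largest LR statistic
        assert not set(det.flagged_items_) & set(det.anchors_)
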