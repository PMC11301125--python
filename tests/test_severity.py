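"""Criteria counting, DSM-5 severity grading and unadjusted tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audcheck import (DSM5_RULE, SeverityRule, criteria_count,
                      severity_category, study, tabulate)
from audcheck.errors import ValidationError

from conftest import toy_matrix


class TestCriteriaCount:
    def test_extremes(self):
        assert criteria_count([0] * 11) == 0
        assert criteria_count([1] * 11) == 11

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([0, 1]), min_size=11, max_size=11),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, row, rnd):
        shuffled = list(row)
        rnd.shuffle(shuffled)
        assert criteria_count(shuffled) == criteria_count(row)

    def test_missing_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            criteria_count([1, None, 0])


class TestSeverityCategory:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "no AUD"), (1, "no AUD"), (2, "mild"), (3, "mild"),
         (4, "moderate"), (5, "moderate"), (6, "severe"), (11, "severe")],
    )
    def test_dsm5_mapping(self, count, expected):
        assert severity_category(count) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            severity_category(12)
        with pytest.raises(ValidationError):
            severity_category(-1)

    def test_rule_must_partition_range(self):
        with pytest.raises(ValidationError, match="partition"):
            SeverityRule(cuts=((0, 1, "none"), (3, 11, "rest")))

    def test_total_deterministic_map(self):
        cats = [severity_category(c) for c in range(12)]
        assert cats == [severity_category(c) for c in range(12)]
        assert set(cats) == set(DSM5_RULE.categories)


class TestTabulate:
    def _toy(self):
        rows = [
            tuple([1] * 11),                 # severe (11)
            tuple([1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0]),   # mild (2)
            tuple([0] * 11),                 # no AUD
            tuple([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]),   # moderate (4)
        ]
        return toy_matrix(
            rows, item_ids=study.ITEM_IDS,
            groups=["clinic", "clinic", "online", "online"],
        )

    def test_counts_recomputable_by_hand(self):
        s = tabulate(self._toy())
        sev = s.severity_table
        assert sev.loc[("clinic", "severe"), "count"] == 1
        assert sev.loc[("clinic", "mild"), "proportion"] == 0.5
        assert sev.loc[("online", "no AUD"), "count"] == 1
        assert s.mean_criteria["clinic"] == pytest.approx((11 + 2) / 2)
        item = s.item_table
        assert item.loc[("clinic", "tolerance"), "count"] == 2
        assert item.loc[("online", "craving"), "proportion"] == 0.0
        lo, hi = item.loc[("clinic", "tolerance"), ["ci_low", "ci_high"]]
        assert 0.0 <= lo < hi <= 1.0

    def test_single_group_omits_comparison(self):
        rows = [tuple([0] * 11), tuple([1] * 11)]
        data = toy_matrix(rows, item_ids=study.ITEM_IDS, groups=["clinic", "clinic"])
        s = tabulate(data)
        assert s.chi2_severity is None
        assert list(s.n_per_group) == ["clinic"]

    def test_row_permutation_invariant(self):
        data = self._toy()
        perm = data.subset(np.array([3, 1, 0, 2]))
        a, b = tabulate(data), tabulate(perm)
        assert a.severity_table.sort_index().equals(b.severity_table.sort_index())

    def test_category_counts_sum_to_group_n(self):
        s = tabulate(self._toy())
        for g, n in s.n_per_group.items():
            sub = s.severity_table.xs(g, level="group")
            assert sub["count"].sum() == n
            assert sub["proportion"].sum() == pytest.approx(1.0)

    def test_simulated_prevalence_matches_model_implied_rate(self, study_draw):
        """The simulated fraction with >= 2 criteria agrees with the rate
        implied by integrating the response model over the latent density."""
        data, _ = study_draw
        s = tabulate(data)
        bank = study.checklist_item_bank()
        latent = study.checklist_latent()
        x, w = np.polynomial.hermite_e.hermegauss(80)
        w = w / w.sum()
        for g in (study.REFERENCE_GROUP, study.FOCAL_GROUP):
            mean, var = latent.moments(g)
            theta = mean + np.sqrt(var) * x
            a, b = bank.resolve(g)
            p = 1.0 / (1.0 + np.exp(-a[None, :] * (theta[:, None] - b[None, :])))
            p0 = np.prod(1 - p, axis=1)
            J = p.shape[1]
            p1 = sum(
                p[:, j] * np.prod(1 - p[:, [k for k in range(J) if k != j]], axis=1)
                for j in range(J)
            )
            implied = float(w @ (1.0 - p0 - p1))  # P(count >= 2)
            sub = s.severity_table.xs(g, level="group")
            observed = sub.loc[["mild", "moderate", "severe"], "proportion"].sum()
            n = s.n_per_group[g]
            se = np.sqrt(implied * (1 - implied) / n)
            assert abs(observed - implied) < 3 * se
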