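"""2PL core: response function, marginal likelihood, EM estimation, SEs."""

import numpy as np
import pytest
from scipy import optimize

from audcheck import (ItemBank, LatentDistribution, MultigroupTwoPL,
                      QuadratureGrid, TwoParameterLogistic, irf,
                      marginal_loglik, simulate_responses, study)
from audcheck.errors import (BoundaryError, IdentificationError,
                             ValidationError)

from conftest import toy_matrix


def _simulate_single(bank, n, seed, group="reference"):
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 1, n)
    return simulate_responses(theta, np.full(n, group, object), bank, seed + 1)


class TestIRF:
    def test_half_probability_at_theta_equal_b(self):
        assert irf(1.46, 0.99, 0.99) == pytest.approx(0.5)

    def test_logistic_formula_value(self):
        # direct scalar evaluation: 1 / (1 + exp(1.46 * 0.99))
        assert irf(1.46, 0.99, 0.0) == pytest.approx(
            1.0 / (1.0 + np.exp(1.46 * 0.99)), abs=1e-12
        )
        assert irf(1.46, 0.99, 0.0) == pytest.approx(0.191, abs=5e-4)

    def test_limits_and_monotonicity(self):
        assert irf(2.0, 0.0, 60.0) == pytest.approx(1.0)
        theta = np.linspace(-5, 5, 101)
        assert (np.diff(irf(2.0, 0.3, theta)) > 0).all()

    def test_nonpositive_a_rejected(self):
        with pytest.raises(ValidationError):
            irf(0.0, 0.0, 0.0)


class TestMarginalLoglik:
    def test_degenerate_grid_closed_form(self):
        # one respondent, one item, y=1, grid collapsed onto theta = b
        data = toy_matrix([(1,)], item_ids=("i1",), groups=["reference"])
        bank = ItemBank.from_reference(["i1"], [1.7], [0.4])
        latent = LatentDistribution(reference_group="reference")
        grid = QuadratureGrid(np.array([0.4]), {"reference": np.array([1.0])})
        assert marginal_loglik(data, bank, latent, grid) == pytest.approx(np.log(0.5))

    def test_additivity_under_duplication(self):
        bank = ItemBank.from_reference(["i1", "i2", "i3"], [1.2, 2.0, 2.8], [-0.5, 0.3, 1.1])
        data = _simulate_single(bank, 40, seed=5)
        latent = LatentDistribution(reference_group="reference")
        doubled = toy_matrix(
            [tuple(r) for r in np.vstack([data.complete_values()] * 2)],
            item_ids=("i1", "i2", "i3"),
            patients=[f"q{i}" for i in range(80)],
            groups=["reference"] * 80,
        )
        assert marginal_loglik(doubled, bank, latent) == pytest.approx(
            2 * marginal_loglik(data, bank, latent), rel=1e-12
        )

    def test_matches_fine_grid_integration(self):
        # 2 items, 3 respondents: the 61-node approximation agrees with a
        # 10x-resolution exhaustive integration to 1e-6
        data = toy_matrix(
            [(1, 0), (0, 0), (1, 1)], item_ids=("i1", "i2"),
            groups=["reference"] * 3,
        )
        bank = ItemBank.from_reference(["i1", "i2"], [1.4, 2.2], [0.2, -0.6])
        latent = LatentDistribution(reference_group="reference")
        coarse = marginal_loglik(
            data, bank, latent, QuadratureGrid.for_latent(latent, n_nodes=61)
        )
        fine = marginal_loglik(
            data, bank, latent, QuadratureGrid.for_latent(latent, n_nodes=610)
        )
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_missing_data_directs_to_filter(self):
        data = toy_matrix([(1, None, 0)], groups=["reference"])
        bank = ItemBank.from_reference(["i1", "i2", "i3"], [1, 1, 1], [0, 0, 0])
        latent = LatentDistribution(reference_group="reference")
        with pytest.raises(ValidationError, match="filter_complete"):
            marginal_loglik(data, bank, latent)


class TestSingleGroupFit:
    def test_em_loglik_monotone(self):
        bank = ItemBank.from_reference(["i1", "i2", "i3"], [1.5, 2.0, 1.0], [0.0, 0.5, -0.5])
        data = _simulate_single(bank, 400, seed=2)
        model = TwoParameterLogistic(compute_se=False).fit(data)
        trace = np.array(model.result_.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_parameter_recovery_with_helpers(self):
        bank = ItemBank.from_reference(
            ["target", "h1", "h2", "h3", "h4"],
            [2.0, 1.5, 2.5, 1.8, 2.2],
            [0.5, -0.5, 0.0, 1.0, -1.0],
        )
        data = _simulate_single(bank, 5000, seed=11)
        model = TwoParameterLogistic().fit(data)
        se_a = model.standard_errors_["a[target]"]
        se_b = model.standard_errors_["b[target]"]
        assert abs(model.discrimination_[0] - 2.0) < 3 * se_a
        assert abs(model.severity_[0] - 0.5) < 3 * se_b

    def test_matches_direct_likelihood_maximisation(self):
        """EM finds the same optimum as brute-force maximisation of the
        marginal likelihood over all six parameters of a 3-item instance."""
        gen = ItemBank.from_reference(["i1", "i2", "i3"], [1.3, 2.1, 1.7], [-0.3, 0.4, 0.9])
        data = _simulate_single(gen, 200, seed=7)
        model = TwoParameterLogistic(compute_se=False).fit(data)
        latent = LatentDistribution(reference_group="reference")
        grid = QuadratureGrid.for_latent(latent, n_nodes=61)

        def negll(psi):
            a, b = psi[:3], psi[3:]
            if (a <= 0).any():
                return 1e9
            bank = ItemBank.from_reference(["i1", "i2", "i3"], a, b)
            return -marginal_loglik(data, bank, latent, grid)

        best = np.inf
        for start in ([1, 1, 1, 0, 0, 0], [2, 2, 2, 0.5, 0.5, 0.5], [0.8, 1.5, 1.2, -1, 0, 1]):
            res = optimize.minimize(negll, np.array(start, float), method="Nelder-Mead",
                                    options={"maxiter": 6000, "xatol": 1e-6, "fatol": 1e-10})
            best = min(best, res.fun)
        # generating parameters can never beat the MLE
        assert model.loglik_ >= -negll(np.array([1.3, 2.1, 1.7, -0.3, 0.4, 0.9]))
        assert model.loglik_ == pytest.approx(-best, abs=1e-3)

    def test_constant_item_raises_boundary_error(self):
        data = toy_matrix(
            [(1, 1, 0), (1, 0, 1), (1, 1, 1), (1, 0, 0)], groups=["reference"] * 4
        )
        with pytest.raises(BoundaryError, match="i1"):
            TwoParameterLogistic().fit(data)

    def test_invariance_to_item_and_row_order(self):
        bank = ItemBank.from_reference(["i1", "i2", "i3"], [1.5, 2.0, 1.0], [0.0, 0.5, -0.5])
        data = _simulate_single(bank, 300, seed=13)
        m1 = TwoParameterLogistic(compute_se=False).fit(data)
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(data.n_respondents)
        shuffled = data.subset(perm_rows).reorder_items(["i3", "i1", "i2"])
        m2 = TwoParameterLogistic(compute_se=False).fit(shuffled)
        back = [m2.item_ids_.index(it) for it in m1.item_ids_]
        assert np.allclose(m1.discrimination_, m2.discrimination_[back], atol=1e-6)
        assert np.allclose(m1.severity_, m2.severity_[back], atol=1e-6)


class TestStandardErrors:
    def test_matches_numerical_hessian_of_marginal_loglik(self):
        gen = ItemBank.from_reference(["i1", "i2", "i3"], [1.5, 2.0, 1.2], [0.2, -0.4, 0.8])
        data = _simulate_single(gen, 250, seed=3)
        model = TwoParameterLogistic().fit(data)
        latent = LatentDistribution(reference_group="reference")
        grid = QuadratureGrid.for_latent(latent, n_nodes=61)

        order = ["a[i1]", "b[i1]", "a[i2]", "b[i2]", "a[i3]", "b[i3]"]
        psi0 = np.array([
            model.discrimination_[0], model.severity_[0],
            model.discrimination_[1], model.severity_[1],
            model.discrimination_[2], model.severity_[2],
        ])

        def ll(psi):
            bank = ItemBank.from_reference(["i1", "i2", "i3"], psi[[0, 2, 4]], psi[[1, 3, 5]])
            return marginal_loglik(data, bank, latent, grid)

        h = 1e-4
        H = np.zeros((6, 6))
        for i in range(6):
            for j in range(i, 6):
                ei = np.eye(6)[i] * h * (1 + abs(psi0[i]))
                ej = np.eye(6)[j] * h * (1 + abs(psi0[j]))
                H[i, j] = H[j, i] = (
                    ll(psi0 + ei + ej) - ll(psi0 + ei - ej)
                    - ll(psi0 - ei + ej) + ll(psi0 - ei - ej)
                ) / (4 * ei[i] * ej[j])
        se_brute = np.sqrt(np.diag(np.linalg.inv(-H)))
        se_pkg = model.standard_errors_[order].to_numpy()
        assert np.allclose(se_pkg, se_brute, atol=1e-4)

    def test_se_shrinks_like_root_n(self):
        bank = ItemBank.from_reference(
            ["i1", "i2", "i3", "i4"], [1.5, 2.0, 1.2, 2.4], [0.2, -0.4, 0.8, 0.0]
        )
        m_small = TwoParameterLogistic().fit(_simulate_single(bank, 1500, seed=21))
        m_big = TwoParameterLogistic().fit(_simulate_single(bank, 3000, seed=22))
        ratio = np.median(m_small.standard_errors_ / m_big.standard_errors_)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.2)

    def test_fixed_parameters_have_no_se_entry(self, multigroup_replicates):
        se = multigroup_replicates[0]["fit"].standard_errors
        ref = study.REFERENCE_GROUP
        assert f"mean[{ref}]" not in se.index and f"var[{ref}]" not in se.index
        # pooled parameters appear once, without group suffixes
        assert "a[withdrawal]" in se.index
        assert f"a[withdrawal]@{ref}" not in se.index


class TestMultigroupFit:
    def test_null_dif_recovers_identical_latent_moments(self):
        bank = ItemBank.from_reference(
            ["i1", "i2", "i3", "i4", "i5"],
            [1.5, 2.0, 1.2, 2.4, 1.8],
            [0.2, -0.4, 0.8, 0.0, 1.2],
            reference_group="clinic", focal_group="online",
        )
        rng = np.random.default_rng(17)
        n = 900
        theta = rng.normal(0, 1, 2 * n)
        groups = np.array(["clinic"] * n + ["online"] * n, object)
        data = simulate_responses(theta, groups, bank, seed=18)
        fit = MultigroupTwoPL(
            reference_group="clinic", anchors=["i1", "i2", "i3", "i4", "i5"]
        ).fit(data).result_
        se_m = fit.standard_errors["mean[online]"]
        se_v = fit.standard_errors["var[online]"]
        assert abs(fit.latent.means["online"] - 0.0) < 3 * se_m
        assert abs(fit.latent.variances["online"] - 1.0) < 3 * se_v

    def test_generating_parameters_inside_wald_intervals(self, multigroup_replicates):
        """At the published study size, every generating parameter lies in its
        99.7% Wald interval in at least 10 of 12 replicates."""
        truth_bank = study.checklist_item_bank()
        hits = {}
        for rep in multigroup_replicates:
            fit = rep["fit"]
            for name, se in fit.standard_errors.items():
                if name.startswith(("mean", "var")):
                    continue
                est = fit.to_frame().loc[name, "estimate"]
                true = _true_value(truth_bank, name)
                hits.setdefault(name, 0)
                hits[name] += int(abs(est - true) <= 3 * se)
        assert all(v >= 10 for v in hits.values()), hits

    def test_all_free_without_anchors_is_unidentified(self, study_draw):
        data, _ = study_draw
        with pytest.raises(IdentificationError):
            MultigroupTwoPL(
                reference_group=study.REFERENCE_GROUP,
                anchors=(),
                free_a=list(study.ITEM_IDS),
                free_b=list(study.ITEM_IDS),
            ).fit(data)

    def test_single_group_data_rejected(self):
        data = toy_matrix([(0, 1, 0), (1, 0, 1)], groups=["clinic", "clinic"])
        with pytest.raises(ValidationError, match="TwoParameterLogistic"):
            MultigroupTwoPL(anchors=["i1"]).fit(data)


def _true_value(bank, name):
    kind, rest = name.split("[", 1)
    if "]@" in rest:
        item, group = rest.split("]@", 1)
        g = bank.group_index(group)
    else:
        item, g = rest[:-1], 0
    j = bank.item_ids.index(item)
    return (bank.a if kind == "a" else bank.b)[j, g]
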