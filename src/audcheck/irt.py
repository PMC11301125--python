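"""Two-parameter logistic IRT estimators (scikit-learn style).

The model: respondent p in group g endorses item j with probability

    P(y = 1 | theta) = 1 / (1 + exp(-a_jg * (theta - b_jg)))

(logistic metric, no 1.7 scaling constant), with theta ~ N(0, 1) in the
reference group and theta ~ N(mu_F, sigma2_F) in the focal group.  Item
parameters are estimated by marginal maximum likelihood: the latent trait is
integrated out on an equally spaced quadrature grid and the marginal
likelihood is climbed by Bock-Aitkin EM.

Two estimators are exposed:

* :class:`TwoParameterLogistic` — single-group fit; ``fit(X)`` on a complete
  binary ``(n, J)`` array or one-group :class:`~audcheck.io.ResponseMatrix`.
* :class:`MultigroupTwoPL` — two-group fit with per-parameter equality
  constraints, anchor items, and free focal latent moments.

Both follow scikit-learn conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling; the
module-level :func:`fit_single_group` / :func:`fit_multigroup` functions are
thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _em
from .errors import IdentificationError, ValidationError
from .io import ItemBank, LatentDistribution, ResponseMatrix


def irf(a: float | np.ndarray, b: float | np.ndarray, theta: float | np.ndarray):
    """Item response function: endorsement probability at latent severity theta.

    Strictly increasing in theta; requires positive discrimination ``a``.
    """
    a = np.asarray(a, dtype=float)
    if (a <= 0).any():
        raise ValidationError("discrimination a must be positive")
    out = 1.0 / (1.0 + np.exp(-a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))))
    return out if out.ndim else float(out)


@dataclass
class QuadratureGrid:
    """Latent-trait grid with per-group normalised density weights."""

    nodes: np.ndarray
    weights: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if len(self.nodes) > 1 and not (np.diff(self.nodes) > 0).all():
            raise ValidationError("quadrature nodes must be strictly increasing")
        for g, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
                raise ValidationError(f"weights for group {g!r} must be a probability vector")
            self.weights[g] = w

    @classmethod
    def for_latent(
        cls,
        latent: LatentDistribution,
        n_nodes: int = 61,
        bounds: tuple[float, float] = (-6.0, 6.0),
    ) -> "QuadratureGrid":
        nodes = _em.make_nodes(n_nodes, bounds)
        return cls(
            nodes,
            {g: _em.normal_weights(nodes, *latent.moments(g)) for g in latent.groups},
        )


def marginal_loglik(
    data: ResponseMatrix,
    bank: ItemBank,
    latent: LatentDistribution,
    grid: QuadratureGrid | None = None,
) -> float:
    """Marginal log-likelihood of complete data under a fixed bank and latent moments.

    Integrates each respondent's response-pattern likelihood over their
    group's latent density on the grid.
    """
    Y = data.complete_values()
    if data.item_ids != bank.item_ids:
        data = data.reorder_items(bank.item_ids)
        Y = data.complete_values()
    if grid is None:
        grid = QuadratureGrid.for_latent(latent)
    total = 0.0
    for g in data.groups:
        gi = bank.group_index(g)
        mask = data.group == g
        L = _em.group_loglik_matrix(Y[mask], bank.a[:, gi], bank.b[:, gi], grid.nodes)
        L = L + np.log(grid.weights[g])[None, :]
        m = L.max(axis=1)
        total += float((m + np.log(np.exp(L - m[:, None]).sum(axis=1))).sum())
    return total


@dataclass
class FitResult:
    """Converged (or flagged non-converged) marginal maximum likelihood fit."""

    bank: ItemBank
    latent: LatentDistribution
    loglik: float
    n_iterations: int
    converged: bool
    standard_errors: pd.Series
    loglik_trace: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Parameter table with one row per freely estimated parameter."""
        return pd.DataFrame(
            {"estimate": self._estimates(), "se": self.standard_errors}
        )

    def _estimates(self) -> pd.Series:
        vals = {}
        for name in self.standard_errors.index:
            vals[name] = _parameter_value(self.bank, self.latent, name)
        return pd.Series(vals)


def _parameter_name(bank: ItemBank, kind: str, j, g) -> str:
    if kind in ("a", "b"):
        item = bank.item_ids[j]
        if g is None:
            return f"{kind}[{item}]"
        return f"{kind}[{item}]@{bank.groups[g]}"
    return f"{kind}[{bank.focal_group}]"


def _parameter_value(bank: ItemBank, latent: LatentDistribution, name: str) -> float:
    kind, rest = name.split("[", 1)
    if "]@" in rest:
        inner, group = rest.split("]@", 1)
    else:
        inner, group = rest[:-1], ""
    if kind in ("a", "b"):
        j = bank.item_ids.index(inner)
        g = bank.group_index(group) if group else 0
        return float((bank.a if kind == "a" else bank.b)[j, g])
    mean, var = latent.moments(inner)
    return mean if kind == "mean" else var


def _se_series(bank, se, names) -> pd.Series:
    labels = [_parameter_name(bank, kind, j, g) for kind, j, g in names]
    return pd.Series(se, index=labels, dtype=float)


# ---------------------------------------------------------------------------
# Estimators


def _as_binary_array(X) -> tuple[np.ndarray, list[str] | None, np.ndarray | None]:
    """Accept an array, DataFrame or ResponseMatrix; return (Y, item_ids, groups)."""
    if isinstance(X, ResponseMatrix):
        return X.complete_values(), X.item_ids, X.group
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy()
        item_ids = [str(c) for c in X.columns]
    else:
        arr = np.asarray(X)
        item_ids = None
    if np.issubdtype(arr.dtype, np.floating) and np.isnan(arr.astype(float)).any():
        raise ValidationError("responses contain missing values; run filter_complete first")
    arr = arr.astype("uint8")
    if arr.ndim != 2 or not np.isin(arr, (0, 1)).all():
        raise ValidationError("X must be a 2-D array of 0/1 responses")
    return arr, item_ids, None


class TwoParameterLogistic(BaseEstimator):
    """Single-group 2PL estimated by marginal maximum likelihood (Bock-Aitkin EM).

    Parameters
    ----------
    n_quadrature : number of equally spaced latent nodes (default 61).
    theta_bounds : grid endpoints on the latent scale (default (-6, 6)).
    tol_loglik, tol_param, max_iter : EM stopping rule — stop when the
        log-likelihood improves by less than ``tol_loglik`` and no parameter
        moves more than ``tol_param``, or after ``max_iter`` cycles (the fit
        is then flagged ``converged_ = False``, never silently accepted).
    compute_se : whether to compute observed-information standard errors.

    Attributes (after ``fit``)
    --------------------------
    item_ids_, discrimination_, severity_ : per-item estimates.
    loglik_, n_iter_, converged_, standard_errors_, result_.
    """

    def __init__(
        self,
        *,
        n_quadrature: int = 61,
        theta_bounds: tuple[float, float] = (-6.0, 6.0),
        tol_loglik: float = 1e-5,
        tol_param: float = 1e-4,
        max_iter: int = 500,
        compute_se: bool = True,
        start_a: Sequence[float] | None = None,
        start_b: Sequence[float] | None = None,
    ):
        self.n_quadrature = n_quadrature
        self.theta_bounds = theta_bounds
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.max_iter = max_iter
        self.compute_se = compute_se
        self.start_a = start_a
        self.start_b = start_b

    def fit(self, X, y=None):
        Y, item_ids, groups = _as_binary_array(X)
        if groups is not None and len(set(groups)) > 1:
            raise ValidationError(
                "more than one group present; use MultigroupTwoPL for joint fits"
            )
        J = Y.shape[1]
        self.item_ids_ = item_ids or [f"item{j + 1}" for j in range(J)]
        nodes = _em.make_nodes(self.n_quadrature, self.theta_bounds)
        a0 = None if self.start_a is None else np.column_stack([self.start_a, self.start_a])
        b0 = None if self.start_b is None else np.column_stack([self.start_b, self.start_b])
        fit = _em.fit_em(
            [Y],
            np.ones(J, bool),
            np.ones(J, bool),
            nodes,
            estimate_moments=False,
            item_ids=self.item_ids_,
            a0=a0,
            b0=b0,
            tol_loglik=self.tol_loglik,
            tol_param=self.tol_param,
            max_iter=self.max_iter,
        )
        self.discrimination_ = fit.a[:, 0].copy()
        self.severity_ = fit.b[:, 0].copy()
        self.loglik_ = fit.loglik
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged
        bank = ItemBank(
            self.item_ids_, fit.a, fit.b, np.ones(J, bool), np.ones(J, bool)
        )
        latent = LatentDistribution(reference_group="reference")
        if self.compute_se:
            se, names = _em.observed_information_se(
                fit, [Y], nodes, np.ones(J, bool), np.ones(J, bool), False
            )
            self.standard_errors_ = _se_series(bank, se, names)
        else:
            self.standard_errors_ = pd.Series(dtype=float)
        self.result_ = FitResult(
            bank, latent, fit.loglik, fit.n_iterations, fit.converged,
            self.standard_errors_, fit.trace,
        )
        return self

    def predict_proba(self, theta) -> np.ndarray:
        """Per-item endorsement probabilities at the given latent severities."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return 1.0 / (
            1.0 + np.exp(-self.discrimination_[None, :] * (theta[:, None] - self.severity_[None, :]))
        )


class MultigroupTwoPL(BaseEstimator):
    """Two-group 2PL with equality constraints, anchors and free focal moments.

    ``free_a`` / ``free_b`` name the items whose discrimination / severity
    is group-specific; everything else is pooled.  Anchor items must stay
    fully pooled — they pin the shared latent metric, which is what lets the
    focal group's latent mean and variance be estimated (reference fixed at
    N(0, 1)).

    ``fit(X, groups)`` takes a complete binary matrix plus a group label per
    row, or a two-group :class:`~audcheck.io.ResponseMatrix` alone.
    """

    def __init__(
        self,
        *,
        reference_group: str | None = None,
        anchors: Sequence[str] = (),
        free_a: Sequence[str] = (),
        free_b: Sequence[str] = (),
        estimate_latent: bool = True,
        n_quadrature: int = 61,
        theta_bounds: tuple[float, float] = (-6.0, 6.0),
        tol_loglik: float = 1e-5,
        tol_param: float = 1e-4,
        max_iter: int = 500,
        compute_se: bool = True,
        start: "FitResult | None" = None,
    ):
        self.reference_group = reference_group
        self.anchors = anchors
        self.free_a = free_a
        self.free_b = free_b
        self.estimate_latent = estimate_latent
        self.n_quadrature = n_quadrature
        self.theta_bounds = theta_bounds
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.max_iter = max_iter
        self.compute_se = compute_se
        self.start = start

    # -- helpers ------------------------------------------------------------
    def _resolve_groups(self, groups: np.ndarray) -> tuple[str, str]:
        labels = list(dict.fromkeys(groups))
        if len(labels) < 2:
            raise ValidationError(
                "only one group present; use TwoParameterLogistic for single-group fits"
            )
        if len(labels) > 2:
            raise ValidationError(f"more than two groups: {labels}")
        ref = self.reference_group if self.reference_group is not None else labels[0]
        if ref not in labels:
            raise ValidationError(f"reference group {ref!r} not present in data")
        focal = next(g for g in labels if g != ref)
        return ref, focal

    def fit(self, X, groups=None):
        if isinstance(X, ResponseMatrix):
            Y, item_ids, groups = X.complete_values(), X.item_ids, X.group
        else:
            Y, item_ids, _ = _as_binary_array(X)
            if groups is None:
                raise ValidationError("groups must be provided with an array X")
            groups = np.asarray(groups, dtype=object)
        J = Y.shape[1]
        self.item_ids_ = item_ids or [f"item{j + 1}" for j in range(J)]
        ref, focal = self._resolve_groups(groups)
        self.reference_group_, self.focal_group_ = ref, focal

        anchors = tuple(self.anchors)
        if self.estimate_latent and not anchors:
            raise IdentificationError(
                "at least one anchor item is required to identify the focal latent moments"
            )
        unknown = (set(anchors) | set(self.free_a) | set(self.free_b)) - set(self.item_ids_)
        if unknown:
            raise ValidationError(f"unknown item ids in constraints: {sorted(unknown)}")
        overlap = set(anchors) & (set(self.free_a) | set(self.free_b))
        if overlap:
            raise ValidationError(f"anchor items cannot be freed: {sorted(overlap)}")

        share_a = np.array([it not in set(self.free_a) for it in self.item_ids_])
        share_b = np.array([it not in set(self.free_b) for it in self.item_ids_])
        if not (share_a & share_b).any():
            raise IdentificationError(
                "every item is freed; no shared item remains to link the groups"
            )

        Ys = [Y[groups == ref], Y[groups == focal]]
        nodes = _em.make_nodes(self.n_quadrature, self.theta_bounds)
        kw: dict = {}
        if self.start is not None:
            sb = self.start.bank
            kw.update(a0=sb.a, b0=sb.b)
            if self.start.latent is not None and focal in self.start.latent.means:
                kw.update(
                    mean0=self.start.latent.means[focal],
                    var0=self.start.latent.variances[focal],
                )
        fit = _em.fit_em(
            Ys,
            share_a,
            share_b,
            nodes,
            estimate_moments=self.estimate_latent,
            item_ids=self.item_ids_,
            group_names=(ref, focal),
            tol_loglik=self.tol_loglik,
            tol_param=self.tol_param,
            max_iter=self.max_iter,
            **kw,
        )
        bank = ItemBank(
            self.item_ids_, fit.a, fit.b, share_a, share_b,
            reference_group=ref, focal_group=focal, anchors=anchors,
        )
        latent = LatentDistribution(
            means={ref: 0.0, focal: fit.mean_focal},
            variances={ref: 1.0, focal: fit.var_focal},
            reference_group=ref,
        )
        self.bank_ = bank
        self.latent_ = latent
        self.loglik_ = fit.loglik
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged
        if self.compute_se:
            se, names = _em.observed_information_se(
                fit, Ys, nodes, share_a, share_b, self.estimate_latent
            )
            self.standard_errors_ = _se_series(bank, se, names)
        else:
            self.standard_errors_ = pd.Series(dtype=float)
        self.result_ = FitResult(
            bank, latent, fit.loglik, fit.n_iterations, fit.converged,
            self.standard_errors_, fit.trace,
        )
        return self


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_single_group(X, **params) -> FitResult:
    """Fit a single-group 2PL; see :class:`TwoParameterLogistic`."""
    return TwoParameterLogistic(**params).fit(X).result_


def fit_multigroup(X, groups=None, **params) -> FitResult:
    """Fit the two-group constrained 2PL; see :class:`MultigroupTwoPL`."""
    return MultigroupTwoPL(**params).fit(X, groups).result_
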