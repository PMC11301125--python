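"""Bock-Aitkin EM engine for single- and multiple-group 2PL models.

Array-level workhorse behind the estimator classes in :mod:`audcheck.irt`.
The latent trait is integrated out on a fixed grid of equally spaced nodes
whose weights are the (renormalised) normal density of each group; the focal
group's mean and variance may be re-estimated every cycle from the pooled
posterior moments of theta, with the reference group pinned at N(0, 1).

The M step solves each item's weighted Bernoulli likelihood by Newton's
method with step halving, in whichever parametrisation keeps the problem
concave where possible: slope/intercept ``(a, c)`` with ``b = -c/a`` for
fully pooled or fully free items, common slope with per-group intercepts
when only the discrimination is pooled, and a direct ``(a_ref, a_focal, b)``
Newton when only the severity is pooled.

Standard errors come from the observed information of the marginal
likelihood: analytic score, Hessian by central finite differences of the
score, inverted and square-rooted on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import BoundaryError, IdentificationError, ValidationError

_MIN_A = 1e-4
_MAX_A = 100.0
_MIN_VAR = 1e-4


def make_nodes(n_nodes: int = 61, bounds: tuple[float, float] = (-6.0, 6.0)) -> np.ndarray:
    if n_nodes < 1:
        raise ValidationError("need at least one quadrature node")
    lo, hi = bounds
    if n_nodes > 1 and not hi > lo:
        raise ValidationError("quadrature bounds must be increasing")
    return np.linspace(lo, hi, n_nodes)


def normal_weights(nodes: np.ndarray, mean: float = 0.0, var: float = 1.0) -> np.ndarray:
    """Normal density at the nodes, renormalised to sum to one."""
    if var <= 0:
        raise ValidationError("latent variance must be positive")
    z = (nodes - mean) ** 2 / (2.0 * var)
    w = np.exp(-(z - z.min()))
    return w / w.sum()


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def item_logprobs(a_g: np.ndarray, b_g: np.ndarray, nodes: np.ndarray):
    """(log P, log(1-P)) arrays of shape (J, Q) for one group."""
    z = a_g[:, None] * (nodes[None, :] - b_g[:, None])
    return -_softplus(-z), -_softplus(z)


def group_loglik_matrix(Yg: np.ndarray, a_g, b_g, nodes) -> np.ndarray:
    """log f(y_p | theta_q) for every respondent of one group, shape (n_g, Q)."""
    logP, log1mP = item_logprobs(np.asarray(a_g, float), np.asarray(b_g, float), nodes)
    return Yg @ (logP - log1mP) + log1mP.sum(axis=0)[None, :]


def e_step(Ys, a, b, weights, nodes):
    """Marginal log-likelihood plus expected counts at the quadrature nodes.

    Returns ``(loglik, nq, r)`` where ``nq[g]`` is the expected number of
    focal/reference respondents at each node and ``r[g]`` the expected
    endorsements per item and node, shape (J, Q).
    """
    loglik = 0.0
    nq, r = [], []
    for g, Yg in enumerate(Ys):
        L = group_loglik_matrix(Yg, a[:, g], b[:, g], nodes) + np.log(weights[g])[None, :]
        m = L.max(axis=1)
        ll_p = m + np.log(np.exp(L - m[:, None]).sum(axis=1))
        loglik += float(ll_p.sum())
        post = np.exp(L - ll_p[:, None])
        nq.append(post.sum(axis=0))
        r.append(Yg.T @ post)
    return loglik, nq, r


# ---------------------------------------------------------------------------
# M-step Newton solvers (expected Bernoulli likelihoods on the grid)


def _bern_ll(eta, r, n) -> float:
    return float(np.sum(r * eta - n * _softplus(eta)))


def _newton_ac(x, r, n, a0, c0, max_steps=50):
    """Maximise sum r*eta - n*softplus(eta), eta = a*x + c, keeping a > 0."""
    a, c = float(a0), float(c0)
    ll = _bern_ll(a * x + c, r, n)
    for _ in range(max_steps):
        p = expit(a * x + c)
        s = r - n * p
        w = n * p * (1.0 - p)
        g = np.array([s @ x, s.sum()])
        H = np.array([[w @ (x * x), w @ x], [w @ x, w.sum()]])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(step).all():
            break
        t, ok = 1.0, False
        for _ in range(40):
            a1, c1 = a + t * step[0], c + t * step[1]
            if _MIN_A < a1 < _MAX_A:
                ll1 = _bern_ll(a1 * x + c1, r, n)
                if ll1 >= ll - 1e-12:
                    ok = True
                    break
            t *= 0.5
        if not ok:
            break
        moved = max(abs(a1 - a), abs(c1 - c))
        a, c, ll = a1, c1, ll1
        if moved < 1e-10:
            break
    return a, c


def _newton_a_c2(x, r2, n2, a0, c2_0, max_steps=50):
    """Common slope, per-group intercepts: eta_g = a*x + c_g."""
    th = np.array([a0, c2_0[0], c2_0[1]], dtype=float)

    def _ll(v):
        return _bern_ll(v[0] * x + v[1], r2[0], n2[0]) + _bern_ll(v[0] * x + v[2], r2[1], n2[1])

    ll = _ll(th)
    for _ in range(max_steps):
        g = np.zeros(3)
        H = np.zeros((3, 3))
        for gi in range(2):
            p = expit(th[0] * x + th[1 + gi])
            s = r2[gi] - n2[gi] * p
            w = n2[gi] * p * (1.0 - p)
            g[0] += s @ x
            g[1 + gi] = s.sum()
            H[0, 0] += w @ (x * x)
            H[0, 1 + gi] = H[1 + gi, 0] = w @ x
            H[1 + gi, 1 + gi] = w.sum()
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(step).all():
            break
        t, ok = 1.0, False
        for _ in range(40):
            v = th + t * step
            if _MIN_A < v[0] < _MAX_A:
                ll1 = _ll(v)
                if ll1 >= ll - 1e-12:
                    ok = True
                    break
            t *= 0.5
        if not ok:
            break
        moved = np.abs(v - th).max()
        th, ll = v, ll1
        if moved < 1e-10:
            break
    return th[0], (th[1], th[2])


def _newton_a2_b(x, r2, n2, a2_0, b0, max_steps=50):
    """Per-group slopes with a common severity: eta_g = a_g * (x - b)."""
    th = np.array([a2_0[0], a2_0[1], b0], dtype=float)

    def _ll(v):
        return (_bern_ll(v[0] * (x - v[2]), r2[0], n2[0])
                + _bern_ll(v[1] * (x - v[2]), r2[1], n2[1]))

    ll = _ll(th)
    for _ in range(max_steps):
        g = np.zeros(3)
        H = np.zeros((3, 3))
        xb = x - th[2]
        for gi in range(2):
            a_g = th[gi]
            p = expit(a_g * xb)
            s = r2[gi] - n2[gi] * p
            w = n2[gi] * p * (1.0 - p)
            ssum = s.sum()
            g[gi] += s @ xb
            g[2] += -a_g * ssum
            # full Hessian of the expected loglik (eta nonlinear in (a_g, b))
            H[gi, gi] += w @ (xb * xb)
            cross = -a_g * (w @ xb) + ssum  # -d2l/da_g db
            H[gi, 2] += cross
            H[2, gi] += cross
            H[2, 2] += a_g * a_g * w.sum()
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(step).all():
            break
        t, ok = 1.0, False
        for _ in range(40):
            v = th + t * step
            if _MIN_A < v[0] < _MAX_A and _MIN_A < v[1] < _MAX_A:
                ll1 = _ll(v)
                if ll1 >= ll - 1e-12:
                    ok = True
                    break
            t *= 0.5
        if not ok:
            break
        moved = np.abs(v - th).max()
        th, ll = v, ll1
        if moved < 1e-10:
            break
    return (th[0], th[1]), th[2]


def m_step(a, b, share_a, share_b, nq, r, nodes, two_groups):
    a = a.copy()
    b = b.copy()
    for j in range(a.shape[0]):
        if not two_groups:
            aj, cj = _newton_ac(nodes, r[0][j], nq[0], a[j, 0], -a[j, 0] * b[j, 0])
            a[j, :], b[j, :] = aj, -cj / aj
        elif share_a[j] and share_b[j]:
            x2 = np.concatenate([nodes, nodes])
            rr = np.concatenate([r[0][j], r[1][j]])
            nn = np.concatenate([nq[0], nq[1]])
            aj, cj = _newton_ac(x2, rr, nn, a[j, 0], -a[j, 0] * b[j, 0])
            a[j, :], b[j, :] = aj, -cj / aj
        elif share_a[j]:
            aj, (c0, c1) = _newton_a_c2(
                nodes, (r[0][j], r[1][j]), (nq[0], nq[1]),
                a[j, 0], (-a[j, 0] * b[j, 0], -a[j, 1] * b[j, 1]),
            )
            a[j, :] = aj
            b[j, 0], b[j, 1] = -c0 / aj, -c1 / aj
        elif share_b[j]:
            (a0, a1), bj = _newton_a2_b(
                nodes, (r[0][j], r[1][j]), (nq[0], nq[1]), (a[j, 0], a[j, 1]), b[j, 0]
            )
            a[j, 0], a[j, 1] = a0, a1
            b[j, :] = bj
        else:
            for g in range(2):
                aj, cj = _newton_ac(nodes, r[g][j], nq[g], a[j, g], -a[j, g] * b[j, g])
                a[j, g], b[j, g] = aj, -cj / aj
    return a, b


# ---------------------------------------------------------------------------
# EM driver


@dataclass
class EMFit:
    a: np.ndarray           # (J, 2)
    b: np.ndarray           # (J, 2)
    mean_focal: float
    var_focal: float
    loglik: float
    n_iterations: int
    converged: bool
    trace: list[float] = field(default_factory=list)


def check_variation(Ys, share_a, share_b, item_ids, group_names):
    """Every item must show both responses in the data that estimate it."""
    two = len(Ys) == 2
    for j, item in enumerate(item_ids):
        if two and not (share_a[j] and share_b[j]):
            for g, Yg in enumerate(Ys):
                col = Yg[:, j]
                if col.size and col.min() == col.max():
                    raise BoundaryError(
                        f"item {item!r} has constant responses in group "
                        f"{group_names[g]!r}; its group-specific parameters "
                        "are on the boundary"
                    )
        else:
            col = np.concatenate([Yg[:, j] for Yg in Ys])
            if col.size and col.min() == col.max():
                raise BoundaryError(f"item {item!r} has constant responses")


def fit_em(
    Ys,
    share_a,
    share_b,
    nodes,
    *,
    estimate_moments: bool,
    item_ids=None,
    group_names=("reference", "focal"),
    a0=None,
    b0=None,
    mean0: float = 0.0,
    var0: float = 1.0,
    tol_loglik: float = 1e-5,
    tol_param: float = 1e-4,
    max_iter: int = 500,
) -> EMFit:
    """Run the EM loop; see the module docstring for the scheme.

    ``Ys`` is a list of one or two complete uint8 response arrays (reference
    first).  Starting values default to a=1, b=0 and focal moments (0, 1);
    pass ``a0``/``b0``/``mean0``/``var0`` to warm-start (e.g. from a nested
    fit during likelihood-ratio testing).
    """
    two_groups = len(Ys) == 2
    J = Ys[0].shape[1]
    share_a = np.asarray(share_a, dtype=bool)
    share_b = np.asarray(share_b, dtype=bool)
    if item_ids is None:
        item_ids = [f"item{j + 1}" for j in range(J)]
    check_variation(Ys, share_a, share_b, item_ids, group_names)

    a = np.ones((J, 2)) if a0 is None else np.array(a0, dtype=float).reshape(J, -1) + 0.0
    b = np.zeros((J, 2)) if b0 is None else np.array(b0, dtype=float).reshape(J, -1) + 0.0
    if a.shape[1] == 1:
        a = np.repeat(a, 2, axis=1)
    if b.shape[1] == 1:
        b = np.repeat(b, 2, axis=1)
    mean_f, var_f = float(mean0), float(var0)

    w_ref = normal_weights(nodes, 0.0, 1.0)
    weights = [w_ref, normal_weights(nodes, mean_f, var_f)] if two_groups else [w_ref]

    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, nq, r = e_step(Ys, a, b, weights, nodes)
        trace.append(ll)
        a_new, b_new = m_step(a, b, share_a, share_b, nq, r, nodes, two_groups)
        dparam = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
        if two_groups and estimate_moments:
            c = nq[1]
            tot = c.sum()
            mu = float(c @ nodes / tot)
            var = float(c @ (nodes - mu) ** 2 / tot)
            var = max(var, _MIN_VAR)
            dparam = max(dparam, abs(mu - mean_f), abs(var - var_f))
            mean_f, var_f = mu, var
            weights[1] = normal_weights(nodes, mean_f, var_f)
        a, b = a_new, b_new
        if n_iter > 1 and abs(ll - prev_ll) < tol_loglik and dparam < tol_param:
            converged = True
            break
        prev_ll = ll

    ll_final, _, _ = e_step(Ys, a, b, weights, nodes)
    trace.append(ll_final)
    return EMFit(a, b, mean_f, var_f, ll_final, n_iter, converged, trace)


# ---------------------------------------------------------------------------
# Standard errors via observed information of the marginal likelihood


def pack_params(a, b, share_a, share_b, mean_f, var_f, two_groups, estimate_moments):
    """Flatten the freely estimated parameters; returns (psi, names).

    Names are ``(kind, item_index, group_index)`` tuples with ``group_index``
    None for pooled parameters.
    """
    psi, names = [], []
    J = len(share_a)
    for j in range(J):
        for kind, arr, shared in (("a", a, share_a[j]), ("b", b, share_b[j])):
            if (not two_groups) or shared:
                psi.append(arr[j, 0])
                names.append((kind, j, None))
            else:
                psi.append(arr[j, 0])
                names.append((kind, j, 0))
                psi.append(arr[j, 1])
                names.append((kind, j, 1))
    if two_groups and estimate_moments:
        psi += [mean_f, var_f]
        names += [("mean", None, 1), ("var", None, 1)]
    return np.array(psi, dtype=float), names


def unpack_params(psi, names, J):
    a = np.zeros((J, 2))
    b = np.zeros((J, 2))
    mean_f, var_f = 0.0, 1.0
    for val, (kind, j, g) in zip(psi, names):
        if kind == "mean":
            mean_f = float(val)
        elif kind == "var":
            var_f = float(val)
        else:
            arr = a if kind == "a" else b
            if g is None:
                arr[j, :] = val
            else:
                arr[j, g] = val
    return a, b, mean_f, var_f


def score_vector(psi, names, Ys, nodes, estimate_moments):
    """Analytic gradient of the marginal log-likelihood at psi."""
    two_groups = len(Ys) == 2
    J = Ys[0].shape[1]
    a, b, mean_f, var_f = unpack_params(psi, names, J)
    weights = [normal_weights(nodes, 0.0, 1.0)]
    if two_groups:
        weights.append(normal_weights(nodes, mean_f, var_f))
    _, nq, r = e_step(Ys, a, b, weights, nodes)

    s = []  # per group (J, Q) residuals r - n*p
    for g in range(len(Ys)):
        p = expit(a[:, g][:, None] * (nodes[None, :] - b[:, g][:, None]))
        s.append(r[g] - nq[g][None, :] * p)

    grad = np.zeros(len(psi))
    for i, (kind, j, g) in enumerate(names):
        if kind in ("a", "b"):
            scope = range(len(Ys)) if g is None else (g,)
            tot = 0.0
            for gg in scope:
                if kind == "a":
                    tot += s[gg][j] @ (nodes - b[j, gg])
                else:
                    tot += -a[j, gg] * s[gg][j].sum()
            grad[i] = tot
        else:
            c = nq[1]
            w = weights[1]
            if kind == "mean":
                d = (nodes - mean_f) / var_f
            else:
                d = ((nodes - mean_f) ** 2 - var_f) / (2.0 * var_f ** 2)
            grad[i] = c @ d - c.sum() * (w @ d)
    return grad


def observed_information_se(fit: EMFit, Ys, nodes, share_a, share_b, estimate_moments):
    """SEs from the inverse observed information (central differences of the score)."""
    two_groups = len(Ys) == 2
    psi, names = pack_params(
        fit.a, fit.b, share_a, share_b, fit.mean_focal, fit.var_focal,
        two_groups, estimate_moments,
    )
    p_dim = len(psi)
    H = np.empty((p_dim, p_dim))
    for i in range(p_dim):
        h = 1e-4 * (1.0 + abs(psi[i]))
        e = np.zeros(p_dim)
        e[i] = h
        sp = score_vector(psi + e, names, Ys, nodes, estimate_moments)
        sm = score_vector(psi - e, names, Ys, nodes, estimate_moments)
        H[:, i] = (sp - sm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise IdentificationError(
            "observed information is singular; the model is likely empirically unidentified"
        )
    d = np.diag(cov)
    if not np.all(np.isfinite(d)) or (d <= 0).any():
        raise IdentificationError(
            "observed information is not positive definite; "
            "the model is likely empirically unidentified"
        )
    return np.sqrt(d), names
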