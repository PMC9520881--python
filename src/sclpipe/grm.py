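"""Marginal maximum-likelihood estimation of the graded response model.

The graded response model (GRM) for an item j with K ordered categories
puts ``P(X_j >= k | theta) = logistic(a_j * (theta - b_jk))`` for
k = 1..K-1, with discrimination ``a_j`` and strictly increasing
thresholds ``b_jk`` on the latent-trait metric (logistic metric, D = 1).

Estimation is Bock-Aitkin EM: the latent trait is integrated over a
fixed quadrature grid with standard-normal prior weights; the E-step
computes each person's posterior over the grid, the M-step maximizes the
expected complete-data log-likelihood per item by Newton steps with
step-halving (which keeps the marginal log-likelihood non-decreasing).
Standard errors come from the empirical cross-product (outer product of
per-person score vectors) form of the observed information, obtained via
the Fisher identity from the same posterior weights.

Missing responses (sentinel ``-1``) simply drop out of the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .core_io import MISSING

SLOPE_CAP = 25.0
SLOPE_FLOOR = 1e-3


@dataclass
class QuadratureGrid:
    """Latent-trait nodes and (normalized) prior masses."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        s = self.weights.sum()
        if not np.isclose(s, 1.0):
            self.weights = self.weights / s


def make_quadrature(n: int = 61, bound: float = 6.0,
                    mean: float = 0.0, var: float = 1.0) -> QuadratureGrid:
    """Equally spaced nodes on ``[-bound, bound]`` with normal prior mass."""
    nodes = np.linspace(-bound, bound, n)
    w = norm.pdf(nodes, loc=mean, scale=np.sqrt(var))
    return QuadratureGrid(nodes, w / w.sum())


@dataclass
class GRMParams:
    """Per-item slope and ordered thresholds (difficulty metric)."""

    a: np.ndarray            # (J,)
    b: np.ndarray            # (J, K-1), strictly increasing per item
    item_names: list[str] | None = None

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if self.a.shape[0] != self.b.shape[0]:
            raise ValueError("a and b disagree on the number of items")
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.b)):
            raise ValueError("parameters must be finite")
        if np.any(np.diff(self.b, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")

    @property
    def n_items(self) -> int:
        return self.a.shape[0]

    @property
    def n_categories(self) -> int:
        return self.b.shape[1] + 1


def cumulative_probabilities(params: GRMParams, theta: np.ndarray) -> np.ndarray:
    """P(X_j >= k | theta): shape (T, J, K-1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    z = params.a[None, :, None] * (theta[:, None, None] - params.b[None, :, :])
    return expit(z)


def category_probabilities(params: GRMParams, theta) -> np.ndarray:
    """Per-item per-category probabilities at one or many theta values.

    Returns shape (J, K) for scalar theta, else (T, J, K).  Categories
    sum to one at every theta.
    """
    scalar = np.isscalar(theta)
    pstar = cumulative_probabilities(params, theta)
    t, j, _ = pstar.shape
    full = np.concatenate(
        [np.ones((t, j, 1)), pstar, np.zeros((t, j, 1))], axis=2)
    probs = full[:, :, :-1] - full[:, :, 1:]
    return probs[0] if scalar else probs


def _probs_on_grid(a: np.ndarray, c: np.ndarray, nodes: np.ndarray):
    """Category probs and cumulative logistic terms in intercept form.

    Intercept form: P(X >= k) = logistic(a*theta + c_k) with c strictly
    decreasing; ``c = -a*b``.  Returns (probs (J,Q,K), pstar (J,Q,K+1)).
    """
    z = a[:, None, None] * nodes[None, :, None] + c[:, None, :]
    pstar = expit(z)
    jj, q, _ = pstar.shape
    full = np.concatenate(
        [np.ones((jj, q, 1)), pstar, np.zeros((jj, q, 1))], axis=2)
    probs = np.clip(full[:, :, :-1] - full[:, :, 1:], 1e-300, 1.0)
    return probs, full


@dataclass
class GRMFit:
    """Result of an EM fit: parameters, likelihood path, posteriors, SEs."""

    params: GRMParams
    loglik: float
    loglik_path: np.ndarray
    grid: QuadratureGrid
    posterior: np.ndarray          # (n_patterns, Q) posterior over nodes
    pattern_index: np.ndarray      # (n,) person -> pattern row
    pattern_counts: np.ndarray     # (n_patterns,) summed weights
    responses: np.ndarray          # (n, J) as fitted
    weights: np.ndarray            # (n,)
    se_a: np.ndarray | None = None
    se_b: np.ndarray | None = None
    cov: np.ndarray | None = None  # covariance of (a_j, b_j1..b_j,K-1) blocks, (J*K, J*K)
    converged: bool = True
    n_cycles: int = 0
    slope_capped: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]


def _item_gradient(r: np.ndarray, probs_j: np.ndarray, full_j: np.ndarray,
                   nodes: np.ndarray) -> np.ndarray:
    """Gradient of the expected complete-data log-likelihood for one item.

    ``r``: expected counts (Q, K); parameters are (a, c_1..c_{K-1}).
    """
    u = full_j * (1.0 - full_j)           # (Q, K+1); u[:,0] = u[:,K] = 0
    ratio = r / probs_j                   # (Q, K)
    # dQ/dc_l = sum_q u_l * (r_l/P_l - r_{l-1}/P_{l-1}); c_l enters
    # category l with +u_l and category l-1 with -u_l
    gc = u[:, 1:-1] * (ratio[:, 1:] - ratio[:, :-1])   # (Q, K-1) summand per node
    ga = (gc * nodes[:, None]).sum()
    return np.concatenate([[ga], gc.sum(axis=0)]), gc  # also return per-node parts


def _item_objective(r: np.ndarray, a: float, c: np.ndarray, nodes: np.ndarray) -> float:
    probs, _ = _probs_on_grid(np.array([a]), c[None, :], nodes)
    return float((r * np.log(probs[0])).sum())


def _mstep_item(r: np.ndarray, a: float, c: np.ndarray, nodes: np.ndarray,
                max_newton: int = 8, tol: float = 1e-9):
    """Newton ascent with step-halving; keeps c strictly decreasing, a > 0."""
    x = np.concatenate([[a], c])
    f = _item_objective(r, x[0], x[1:], nodes)
    for _ in range(max_newton):
        probs, full = _probs_on_grid(np.array([x[0]]), x[1:][None, :], nodes)
        grad, _ = _item_gradient(r, probs[0], full[0], nodes)
        if np.max(np.abs(grad)) < tol:
            break
        # Hessian by central differences of the analytic gradient
        h = 1e-5
        hess = np.empty((x.size, x.size))
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            pp, fp = _probs_on_grid(np.array([xp[0]]), xp[1:][None, :], nodes)
            gp, _ = _item_gradient(r, pp[0], fp[0], nodes)
            pm, fm = _probs_on_grid(np.array([xm[0]]), xm[1:][None, :], nodes)
            gm, _ = _item_gradient(r, pm[0], fm[0], nodes)
            hess[:, i] = (gp - gm) / (2 * h)
        hess = 0.5 * (hess + hess.T)
        try:
            step = np.linalg.solve(hess - 1e-10 * np.eye(x.size), grad)
            step = -step
        except np.linalg.LinAlgError:
            step = grad / max(1.0, np.abs(grad).max())
        # step-halving: accept only improving, admissible steps
        lam = 1.0
        for _ in range(30):
            xn = x + lam * step
            if xn[0] > SLOPE_FLOOR and np.all(np.diff(xn[1:]) < 0):
                fn = _item_objective(r, xn[0], xn[1:], nodes)
                if fn >= f:
                    x, f = xn, fn
                    break
            lam *= 0.5
        else:
            break
    capped = False
    if x[0] > SLOPE_CAP:
        x[0] = SLOPE_CAP
        capped = True
    return x[0], x[1:], capped


def _pattern_collapse(responses: np.ndarray, weights: np.ndarray):
    patterns, index = np.unique(responses, axis=0, return_inverse=True)
    counts = np.zeros(patterns.shape[0])
    np.add.at(counts, index, weights)
    return patterns, index, counts


def pattern_loglik(a: np.ndarray, c: np.ndarray, patterns: np.ndarray,
                   nodes: np.ndarray) -> np.ndarray:
    """log P(pattern | theta_q): (n_patterns, Q).  Missing items drop out."""
    probs, _ = _probs_on_grid(a, c, nodes)          # (J, Q, K)
    logp = np.log(probs)
    out = np.zeros((patterns.shape[0], nodes.size))
    for j in range(a.size):
        xj = patterns[:, j]
        obs = xj != MISSING
        out[obs] += logp[j][:, xj[obs]].T
    return out


def marginal_loglik(params: GRMParams, responses: np.ndarray,
                    weights: np.ndarray | None = None,
                    grid: QuadratureGrid | None = None) -> float:
    """Marginal log-likelihood of ``params`` on data, by quadrature."""
    grid = grid or make_quadrature()
    responses = np.asarray(responses, dtype=int)
    w = np.ones(responses.shape[0]) if weights is None else np.asarray(weights, float)
    patterns, _, counts = _pattern_collapse(responses, w)
    c = -params.a[:, None] * params.b
    ll = pattern_loglik(params.a, c, patterns, grid.nodes)
    m = ll.max(axis=1, keepdims=True)
    lik = np.exp(ll - m) @ grid.weights
    return float((counts * (np.log(lik) + m[:, 0])).sum())


def fit_grm(
    responses: np.ndarray,
    weights: np.ndarray | None = None,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
    item_names: list[str] | None = None,
    compute_se: bool = True,
    n_categories: int | None = None,
) -> GRMFit:
    """Bock-Aitkin EM fit of the unidimensional GRM.

    ``responses`` is (n, J) with integer categories ``0..K-1`` and
    missing coded ``-1``; ``weights`` are frequency weights entering the
    E-step as row multiplicities.  Convergence when the largest absolute
    parameter change falls below ``tol``.
    """
    responses = np.asarray(responses, dtype=int)
    n, j = responses.shape
    if n <= j:
        raise ValueError("need more persons than items")
    k = n_categories or int(responses.max()) + 1
    for col in range(j):
        obs = responses[:, col][responses[:, col] != MISSING]
        if np.unique(obs).size < 2:
            raise ValueError(f"item {col} has fewer than 2 observed categories")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    grid = grid or make_quadrature()
    nodes, prior = grid.nodes, grid.weights
    patterns, pindex, counts = _pattern_collapse(responses, w)

    # init: slopes 1, intercepts from inverse-normal marginal proportions
    a = np.ones(j)
    c = np.empty((j, k - 1))
    for col in range(j):
        obs = responses[:, col] != MISSING
        ww, xx = w[obs], responses[obs, col]
        cum = np.array([(ww * (xx >= kk)).sum() / ww.sum() for kk in range(1, k)])
        cum = np.clip(cum, 1e-4, 1 - 1e-4)
        c[col] = norm.ppf(cum)  # logit-scale start via probit is close enough
    c = np.sort(c, axis=1)[:, ::-1]
    eps = 1e-3 * np.arange(k - 1)[::-1]
    c = c + eps  # enforce strict decrease even with tied proportions
    if np.any(np.diff(c, axis=1) >= 0):
        c = np.linspace(1.0, -1.0, k - 1)[None, :].repeat(j, axis=0)

    loglik_path = []
    post = None
    capped = False
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        ll = pattern_loglik(a, c, patterns, nodes)
        m = ll.max(axis=1, keepdims=True)
        lik = np.exp(ll - m)
        marg = lik @ prior
        loglik = float((counts * (np.log(marg) + m[:, 0])).sum())
        loglik_path.append(loglik)
        post = lik * prior[None, :] / marg[:, None]

        weighted_post = post * counts[:, None]       # (n_pat, Q)
        old = np.concatenate([a, c.ravel()])
        for col in range(j):
            xj = patterns[:, col]
            r = np.zeros((nodes.size, k))
            for kk in range(k):
                sel = xj == kk
                if np.any(sel):
                    r[:, kk] = weighted_post[sel].sum(axis=0)
            a[col], c[col], cap = _mstep_item(r, a[col], c[col], nodes)
            capped = capped or cap
        if np.max(np.abs(np.concatenate([a, c.ravel()]) - old)) < tol:
            converged = True
            break

    # final E-step quantities at the solution
    ll = pattern_loglik(a, c, patterns, nodes)
    m = ll.max(axis=1, keepdims=True)
    lik = np.exp(ll - m)
    marg = lik @ prior
    loglik = float((counts * (np.log(marg) + m[:, 0])).sum())
    loglik_path.append(loglik)
    post = lik * prior[None, :] / marg[:, None]

    b = -c / a[:, None]
    params = GRMParams(a=a.copy(), b=b, item_names=item_names)
    fit = GRMFit(
        params=params, loglik=loglik, loglik_path=np.asarray(loglik_path),
        grid=grid, posterior=post, pattern_index=pindex, pattern_counts=counts,
        responses=responses, weights=w,
        converged=converged, n_cycles=cycle, slope_capped=capped,
    )
    if capped:
        fit.notes.append(f"slope capped at {SLOPE_CAP}")
    if not converged:
        fit.notes.append("EM did not converge within max_cycles")
    if compute_se:
        _attach_se(fit, a, c, patterns, post, counts)
    return fit


def _score_vectors(a, c, patterns, post, nodes):
    """Per-pattern score vectors d loglik / d(a_j, c_j.) via Fisher identity."""
    jj = a.size
    k = c.shape[1] + 1
    npat, q = post.shape
    scores = np.zeros((npat, jj * k))
    probs, full = _probs_on_grid(a, c, nodes)
    for col in range(jj):
        u = full[col] * (1 - full[col])           # (Q, K+1); u[:,0] = u[:,K] = 0
        ratio = 1.0 / probs[col]                  # (Q, K)
        # gradient of log P_k wrt c_1..c_{K-1} at each node; category k has
        # P_k = P*_k - P*_{k+1}, so c_k enters categories k-1 and k
        gc = np.zeros((q, k, k - 1))
        ga = np.zeros((q, k))
        for kk in range(k):
            if kk >= 1:
                gc[:, kk, kk - 1] += u[:, kk] * ratio[:, kk]
            if kk <= k - 2:
                gc[:, kk, kk] -= u[:, kk + 1] * ratio[:, kk]
            ga[:, kk] = nodes * (u[:, kk] - u[:, kk + 1]) * ratio[:, kk]
        xj = patterns[:, col]
        obs = xj != MISSING
        if not np.all(obs):
            gsel_a = np.zeros((npat, q))
            gsel_c = np.zeros((npat, q, k - 1))
            gsel_a[obs] = ga[:, xj[obs]].T
            gsel_c[obs] = np.moveaxis(gc[:, xj[obs], :], 1, 0)
        else:
            gsel_a = ga[:, xj].T                      # (n_pat, Q)
            gsel_c = np.moveaxis(gc[:, xj, :], 1, 0)  # (n_pat, Q, K-1)
        scores[:, col * k] = (post * gsel_a).sum(axis=1)
        scores[:, col * k + 1: (col + 1) * k] = np.einsum("pq,pqd->pd", post, gsel_c)
    return scores


def _attach_se(fit: GRMFit, a, c, patterns, post, counts):
    nodes = fit.grid.nodes
    k = c.shape[1] + 1
    jj = a.size
    scores = _score_vectors(a, c, patterns, post, nodes)
    info = (scores * counts[:, None]).T @ scores
    try:
        cov_ac = np.linalg.inv(info + 1e-12 * np.eye(info.shape[0]))
    except np.linalg.LinAlgError:
        fit.notes.append("information matrix singular; SEs unavailable")
        return
    # delta method to (a, b) per item: b_k = -c_k / a
    big_jac = np.zeros_like(cov_ac)
    for col in range(jj):
        sl = slice(col * k, (col + 1) * k)
        jac = np.zeros((k, k))
        jac[0, 0] = 1.0
        for kk in range(k - 1):
            jac[kk + 1, 0] = c[col, kk] / a[col] ** 2
            jac[kk + 1, kk + 1] = -1.0 / a[col]
        big_jac[sl, sl] = jac
    cov_ab = big_jac @ cov_ac @ big_jac.T
    d = np.sqrt(np.clip(np.diag(cov_ab), 0, None)).reshape(jj, k)
    fit.se_a = d[:, 0]
    fit.se_b = d[:, 1:]
    fit.cov = cov_ab


def test_curves(params: GRMParams, theta: np.ndarray | None = None) -> dict:
    """Item and test characteristic curves over a theta lattice.

    ICC here is the item expected score ``sum_k k * P_jk(theta)``; the
    TCC is its sum over items (monotone increasing when all slopes > 0).
    """
    theta = np.linspace(-6, 6, 201) if theta is None else np.asarray(theta, float)
    probs = category_probabilities(params, theta)     # (T, J, K)
    kvec = np.arange(params.n_categories)
    icc = probs @ kvec
    return {"theta": theta, "icc": icc, "tcc": icc.sum(axis=1)}


def information(params: GRMParams, theta: np.ndarray | None = None) -> dict:
    """Samejima item information functions and their total.

    ``I_j(theta) = sum_k (P'_jk)^2 / P_jk`` with
    ``P'_jk = a_j * (u_k - u_{k+1})``, ``u = P*(1-P*)``.
    """
    theta = np.linspace(-6, 6, 201) if theta is None else np.asarray(theta, float)
    pstar = cumulative_probabilities(params, theta)   # (T, J, K-1)
    t, j, _ = pstar.shape
    full = np.concatenate([np.ones((t, j, 1)), pstar, np.zeros((t, j, 1))], axis=2)
    probs = np.clip(full[:, :, :-1] - full[:, :, 1:], 1e-300, None)
    u = full * (1 - full)
    dprobs = params.a[None, :, None] * (u[:, :, :-1] - u[:, :, 1:])
    iif = (dprobs ** 2 / probs).sum(axis=2)
    return {"theta": theta, "iif": iif, "tif": iif.sum(axis=1)}


def eap_scores(fit: GRMFit) -> dict:
    """Expected a-posteriori trait estimates and posterior SDs per person.

    Rows with every item missing get the prior mean/SD and a flag.
    """
    nodes = fit.grid.nodes
    mean_pat = fit.posterior @ nodes
    var_pat = fit.posterior @ nodes ** 2 - mean_pat ** 2
    theta_hat = mean_pat[fit.pattern_index]
    psd = np.sqrt(np.clip(var_pat, 0, None))[fit.pattern_index]
    all_missing = np.all(fit.responses == MISSING, axis=1)
    if np.any(all_missing):
        prior_mean = float(fit.grid.weights @ nodes)
        prior_var = float(fit.grid.weights @ nodes ** 2 - prior_mean ** 2)
        theta_hat[all_missing] = prior_mean
        psd[all_missing] = np.sqrt(prior_var)
    return {"theta": theta_hat, "psd": psd, "all_missing": all_missing}


def empirical_marginal_reliability(fit: GRMFit) -> float:
    """rho = Var(EAP) / (Var(EAP) + mean posterior variance), in [0, 1]."""
    scores = eap_scores(fit)
    w = fit.weights / fit.weights.sum()
    mu = w @ scores["theta"]
    var_eap = w @ (scores["theta"] - mu) ** 2
    mean_pv = w @ scores["psd"] ** 2
    total = var_eap + mean_pv
    return float(var_eap / total) if total > 0 else 0.0


def person_item_map(fit: GRMFit, n_bins: int = 30) -> dict:
    """Plot-ready Wright map: EAP histogram plus threshold locations."""
    scores = eap_scores(fit)
    th = scores["theta"]
    lo = min(th.min(), fit.params.b.min())
    hi = max(th.max(), fit.params.b.max())
    hist, edges = np.histogram(th, bins=n_bins, range=(lo, hi),
                               weights=fit.weights)
    items = fit.params.item_names or [f"item{j + 1}" for j in range(fit.params.n_items)]
    return {
        "hist": hist, "bin_edges": edges,
        "thresholds": {items[j]: fit.params.b[j].copy()
                       for j in range(fit.params.n_items)},
        "theta_range": (lo, hi),
    }
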