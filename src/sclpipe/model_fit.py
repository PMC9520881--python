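"""Limited-information global fit, local dependence, item fit, monotonicity.

The global statistic is a C2-type quadratic form built from reduced
margins: the K-1 cumulative category proportions per item plus one
bivariate summary per item pair (the cross-moment ``E[X_i X_j]``).  With
``e`` the vector of observed-minus-implied statistics, ``Gamma`` their
asymptotic covariance under the model, and ``Delta`` the Jacobian of the
implied statistics with respect to the free parameters, the statistic is

    C2 = N * e' [Gamma^-1 - Gamma^-1 Delta (Delta' Gamma^-1 Delta)^-1
                 Delta' Gamma^-1] e

which is asymptotically chi-square because the weight is orthogonal to
the model Jacobian (first-order insensitive to parameter estimation).
The reported df follows the counting convention

    df = (#margin statistics) - (#free item parameters)

with latent-distribution parameters excluded from the count; for 8
five-category items in one group this gives 60 - 40 = 20.

RMSEA = sqrt(max(C2 - df, 0) / (df (N-1))), with a 90% CI by noncentral
chi-square inversion.  CFI/TLI compare against a zero-slope independence
baseline with free thresholds; SRMR is the root-mean-square difference
between observed and model-implied Pearson inter-item correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2

from .core_io import MISSING
from .grm import GRMFit, GRMParams, QuadratureGrid, _probs_on_grid, eap_scores


# ---------------------------------------------------------------------------
# reduced-margin statistics machinery (shared with the multigroup module)

def _model_moments(params: GRMParams, grid: QuadratureGrid) -> dict:
    """Conditional item moments on the quadrature grid."""
    a, b = params.a, params.b
    c = -a[:, None] * b
    probs, full = _probs_on_grid(a, c, grid.nodes)      # (J, Q, K), (J, Q, K+1)
    cums = full[:, :, 1:-1]                              # P(X >= k), k=1..K-1
    kvec = np.arange(probs.shape[2])
    m = probs @ kvec
    s = probs @ kvec ** 2
    # t[j, q, k] = E[X * 1{X >= k} | theta_q]
    xk = probs * kvec[None, None, :]
    t = np.cumsum(xk[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:]
    return {"probs": probs, "cums": cums, "m": m, "s": s, "t": t,
            "w": grid.weights}


def _stat_layout(j: int, k: int):
    pairs = [(i, jj) for i in range(j) for jj in range(i + 1, j)]
    return j * (k - 1), pairs


def _implied_stats(mom: dict) -> np.ndarray:
    w = mom["w"]
    uni = np.einsum("jqk,q->jk", mom["cums"], w)   # (J, K-1)
    j = uni.shape[0]
    _, pairs = _stat_layout(j, uni.shape[1] + 1)
    mw = mom["m"] * w[None, :]
    biv = np.array([(mw[i] * mom["m"][jj]).sum() for i, jj in pairs])
    return np.concatenate([uni.ravel(), biv])


def observed_stats(responses: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Sample analogues of the reduced margins (complete-case)."""
    x = np.asarray(responses, dtype=int)
    complete = np.all(x != MISSING, axis=1)
    x, w = x[complete], np.asarray(weights, float)[complete]
    wsum = w.sum()
    j = x.shape[1]
    uni = np.array([[(w * (x[:, col] >= kk)).sum() / wsum for kk in range(1, k)]
                    for col in range(j)])
    _, pairs = _stat_layout(j, k)
    biv = np.array([(w * x[:, i] * x[:, jj]).sum() / wsum for i, jj in pairs])
    return np.concatenate([uni.ravel(), biv])


def _gamma_matrix(mom: dict) -> np.ndarray:
    """Asymptotic covariance of the reduced margins under the model."""
    cums, m, s, t, w = mom["cums"], mom["m"], mom["s"], mom["t"], mom["w"]
    j, q, k1 = cums.shape
    n_uni, pairs = _stat_layout(j, k1 + 1)
    n_stat = n_uni + len(pairs)

    # conditional-expectation rows U (n_stat, Q)
    u_rows = np.empty((n_stat, q))
    for col in range(j):
        u_rows[col * k1:(col + 1) * k1] = cums[col].T
    for p, (i, jj) in enumerate(pairs):
        u_rows[n_uni + p] = m[i] * m[jj]
    mu = u_rows @ w
    gamma = (u_rows * w[None, :]) @ u_rows.T - np.outer(mu, mu)

    # within-theta corrections for statistics sharing an item
    for col in range(j):
        base = col * k1
        for ka in range(k1):
            for kb in range(ka, k1):
                corr = (w * (cums[col, :, max(ka, kb)]
                             - cums[col, :, ka] * cums[col, :, kb])).sum()
                gamma[base + ka, base + kb] += corr
                if ka != kb:
                    gamma[base + kb, base + ka] += corr
    for p, (i, jj) in enumerate(pairs):
        row = n_uni + p
        for col, other in ((i, jj), (jj, i)):
            for kk in range(k1):
                corr = (w * (t[col, :, kk] - cums[col, :, kk] * m[col]) * m[other]).sum()
                gamma[row, col * k1 + kk] += corr
                gamma[col * k1 + kk, row] += corr
    var_m = s - m ** 2
    for pa, (i, jj) in enumerate(pairs):
        for pb in range(pa, len(pairs)):
            ii, jb = pairs[pb]
            shared = {i, jj} & {ii, jb}
            if not shared:
                continue
            if pa == pb:
                corr = (w * (s[i] * s[jj] - m[i] ** 2 * m[jj] ** 2)).sum()
            else:
                sh = shared.pop()
                oa = jj if sh == i else i
                ob = jb if sh == ii else ii
                corr = (w * var_m[sh] * m[oa] * m[ob]).sum()
            gamma[n_uni + pa, n_uni + pb] += corr
            if pa != pb:
                gamma[n_uni + pb, n_uni + pa] += corr
    return gamma


def _implied_from_ab(a: np.ndarray, b: np.ndarray, grid: QuadratureGrid) -> np.ndarray:
    return _implied_stats(_model_moments(GRMParams(a=a, b=b), grid))


def _jacobian_items(params: GRMParams, grid: QuadratureGrid, h: float = 1e-5) -> np.ndarray:
    """d implied / d (a_j, b_j1..b_j,K-1), central differences, item-major."""
    a, b = params.a.copy(), params.b.copy()
    j, k1 = b.shape
    cols = []
    for col in range(j):
        ap, am = a.copy(), a.copy()
        ap[col] += h
        am[col] -= h
        cols.append((_implied_from_ab(ap, b, grid) - _implied_from_ab(am, b, grid)) / (2 * h))
        for kk in range(k1):
            bp, bm = b.copy(), b.copy()
            bp[col, kk] += h
            bm[col, kk] -= h
            cols.append((_implied_from_ab(a, bp, grid) - _implied_from_ab(a, bm, grid)) / (2 * h))
    return np.column_stack(cols)


def c2_quadform(u: np.ndarray, gamma: np.ndarray, delta: np.ndarray) -> tuple[float, bool]:
    """u' [G^-1 - G^-1 D (D'G^-1 D)^-1 D'G^-1] u with ridge fallback."""
    ridged = False
    for ridge in (0.0, 1e-8, 1e-6):
        try:
            gi = np.linalg.inv(gamma + ridge * np.eye(gamma.shape[0]))
            giu = gi @ u
            gid = gi @ delta
            a_mat = delta.T @ gid
            inner = np.linalg.solve(a_mat + ridge * np.eye(a_mat.shape[0]), gid.T @ u)
            val = float(u @ giu - (gid.T @ u) @ inner)
            if val >= -1e-6:
                return max(val, 0.0), ridged
        except np.linalg.LinAlgError:
            pass
        ridged = True
    raise np.linalg.LinAlgError("C2 weight matrix irreparably singular")


def _rmsea_from_stat(stat: float, df: int, n: float) -> tuple[float, tuple[float, float]]:
    if df <= 0 or n <= 1:
        return 0.0, (0.0, 0.0)
    rmsea = np.sqrt(max(stat - df, 0.0) / (df * (n - 1)))

    def _ncp(conf):
        # largest lambda with ncx2.cdf(stat, df, lambda) >= conf
        if ncx2.cdf(stat, df, 0.0) < conf:
            return 0.0
        hi = max(stat * 2, 10.0)
        while ncx2.cdf(stat, df, hi) > conf:
            hi *= 2
        return brentq(lambda lam: ncx2.cdf(stat, df, lam) - conf, 0.0, hi, xtol=1e-8)

    lo = np.sqrt(_ncp(0.95) / (df * (n - 1)))
    hi = np.sqrt(_ncp(0.05) / (df * (n - 1)))
    return float(rmsea), (float(lo), float(hi))


@dataclass
class FitIndices:
    """C2-based goodness-of-fit summary for one fitted model."""

    c2: float
    df: int
    p: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    cfi: float
    tli: float
    n: float
    srmr_per_group: dict | None = None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "C2": self.c2, "df": self.df, "p": self.p,
            "RMSEA": self.rmsea, "RMSEA_lo": self.rmsea_ci[0],
            "RMSEA_hi": self.rmsea_ci[1], "SRMR": self.srmr,
            "CFI": self.cfi, "TLI": self.tli, "N": self.n,
        }])


def _pearson_corr_implied(mom: dict) -> np.ndarray:
    w = mom["w"]
    mean = mom["m"] @ w
    var = mom["s"] @ w - mean ** 2
    j = mean.size
    _, pairs = _stat_layout(j, mom["probs"].shape[2])
    out = np.empty(len(pairs))
    for p, (i, jj) in enumerate(pairs):
        cov = ((mom["m"][i] * mom["m"][jj]) @ w) - mean[i] * mean[jj]
        out[p] = cov / np.sqrt(var[i] * var[jj])
    return out


def _pearson_corr_observed(responses: np.ndarray, weights: np.ndarray) -> np.ndarray:
    x = np.asarray(responses, float)
    complete = np.all(x != MISSING, axis=1)
    x, w = x[complete], np.asarray(weights, float)[complete]
    w = w / w.sum()
    mean = w @ x
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    j = x.shape[1]
    _, pairs = _stat_layout(j, 2)
    return np.array([corr[i, jj] for i, jj in pairs])


def srmr_value(params: GRMParams, grid: QuadratureGrid,
               responses: np.ndarray, weights: np.ndarray) -> float:
    mom = _model_moments(params, grid)
    diff = _pearson_corr_observed(responses, weights) - _pearson_corr_implied(mom)
    return float(np.sqrt(np.mean(diff ** 2)))


def _baseline_c2(responses: np.ndarray, weights: np.ndarray, k: int) -> tuple[float, int]:
    """Independence baseline: free thresholds, all slopes zero."""
    obs = observed_stats(responses, weights, k)
    x = np.asarray(responses, dtype=int)
    complete = np.all(x != MISSING, axis=1)
    w = np.asarray(weights, float)[complete]
    n = w.sum()
    j = x.shape[1]
    k1 = k - 1
    n_uni, pairs = _stat_layout(j, k)
    p_uni = obs[:n_uni].reshape(j, k1)          # fitted = observed margins
    # implied stats under independence with saturated margins
    means = p_uni.sum(axis=1)
    implied = obs.copy()
    for p, (i, jj) in enumerate(pairs):
        implied[n_uni + p] = means[i] * means[jj]
    e = obs - implied
    # moments of independent items with the fitted margins (Q = 1 grid)
    probs = np.zeros((j, 1, k))
    full = np.concatenate([np.ones((j, 1, 1)),
                           p_uni[:, None, :], np.zeros((j, 1, 1))], axis=2)
    probs = np.clip(full[:, :, :-1] - full[:, :, 1:], 1e-12, 1)
    kvec = np.arange(k)
    xk = probs * kvec[None, None, :]
    mom = {
        "probs": probs, "cums": full[:, :, 1:-1],
        "m": probs @ kvec, "s": probs @ kvec ** 2,
        "t": np.cumsum(xk[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:],
        "w": np.ones(1),
    }
    gamma = _gamma_matrix(mom)
    # Jacobian wrt the free cumulative margins p_jk (analytic)
    delta = np.zeros((len(obs), j * k1))
    for col in range(j):
        for kk in range(k1):
            delta[col * k1 + kk, col * k1 + kk] = 1.0
    for p, (i, jj) in enumerate(pairs):
        for kk in range(k1):
            delta[n_uni + p, i * k1 + kk] = means[jj]
            delta[n_uni + p, jj * k1 + kk] = means[i]
    stat, _ = c2_quadform(np.sqrt(n) * e, gamma, delta)
    return stat, len(obs) - j * k1


def incremental_indices(c2: float, df: int, c2_base: float, df_base: int) -> tuple[float, float, list[str]]:
    flags: list[str] = []
    num = max(c2 - df, 0.0)
    den = max(c2_base - df_base, c2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df > 0 and df_base > 0 and c2_base / df_base > 1.0:
        tli = ((c2_base / df_base) - (c2 / df)) / ((c2_base / df_base) - 1.0)
        if tli < 0:
            flags.append("TLI negative")
        tli = min(tli, 1.0)
    else:
        tli = 1.0
    return float(cfi), float(tli), flags


def c2_fit(fit: GRMFit) -> FitIndices:
    """Limited-information fit indices for a single-group GRM fit."""
    params, grid = fit.params, fit.grid
    k = params.n_categories
    x, w = fit.responses, fit.weights
    complete = np.all(x != MISSING, axis=1)
    n = float(w[complete].sum())

    mom = _model_moments(params, grid)
    e = observed_stats(x, w, k) - _implied_stats(mom)
    gamma = _gamma_matrix(mom)
    delta = _jacobian_items(params, grid)
    stat, ridged = c2_quadform(np.sqrt(n) * e, gamma, delta)
    df = len(e) - delta.shape[1]
    flags = ["ridge added to weight matrix"] if ridged else []
    if df <= 0:
        return FitIndices(c2=stat, df=max(df, 0), p=1.0, rmsea=0.0,
                          rmsea_ci=(0.0, 0.0),
                          srmr=srmr_value(params, grid, x, w),
                          cfi=1.0, tli=1.0, n=n,
                          flags=flags + ["saturated model: df <= 0"])
    p = float(chi2.sf(stat, df))
    rmsea, ci = _rmsea_from_stat(stat, df, n)
    c2_base, df_base = _baseline_c2(x, w, k)
    cfi, tli, f2 = incremental_indices(stat, df, c2_base, df_base)
    return FitIndices(c2=stat, df=df, p=p, rmsea=rmsea, rmsea_ci=ci,
                      srmr=srmr_value(params, grid, x, w),
                      cfi=cfi, tli=tli, n=n, flags=flags + f2)


# ---------------------------------------------------------------------------
# local dependence: signed Cramer's V residuals

def ld_residuals(fit: GRMFit) -> pd.DataFrame:
    """Signed Cramer's V of observed vs model-implied bivariate tables.

    The sign is the sign of the observed-minus-implied covariance of the
    two item scores; positive values indicate residual positive
    dependence the unidimensional model does not absorb.
    """
    params, grid = fit.params, fit.grid
    k = params.n_categories
    x = fit.responses
    complete = np.all(x != MISSING, axis=1)
    x, w = x[complete], fit.weights[complete]
    n = w.sum()
    mom = _model_moments(params, grid)
    probs, wq = mom["probs"], mom["w"]
    j = params.n_items
    names = params.item_names or [f"item{c + 1}" for c in range(j)]
    vmat = np.zeros((j, j))
    for i in range(j):
        for jj in range(i + 1, j):
            implied = np.einsum("qa,qb,q->ab", probs[i], probs[jj], wq)
            obs = np.zeros((k, k))
            np.add.at(obs, (x[:, i], x[:, jj]), w)
            obs /= n
            # pool cells with vanishing expected probability
            tiny = implied < 1e-10
            if tiny.any():
                keep = ~tiny
                obs_k = obs[keep]
                imp_k = implied[keep]
                obs_k[-1] += obs[tiny].sum()
                imp_k[-1] += implied[tiny].sum()
                x2 = n * ((obs_k - imp_k) ** 2 / imp_k).sum()
            else:
                x2 = n * ((obs - implied) ** 2 / implied).sum()
            v = np.sqrt(x2 / (n * (k - 1)))
            kvec = np.arange(k)
            cov_obs = kvec @ obs @ kvec - (obs.sum(1) @ kvec) * (obs.sum(0) @ kvec)
            cov_imp = kvec @ implied @ kvec - (implied.sum(1) @ kvec) * (implied.sum(0) @ kvec)
            vmat[i, jj] = vmat[jj, i] = np.sign(cov_obs - cov_imp) * v
    return pd.DataFrame(vmat, index=names, columns=names)


# ---------------------------------------------------------------------------
# generalized S-X2 item fit via the Lord-Wingersky recursion

def lw_score_distribution(probs: np.ndarray) -> np.ndarray:
    """Summed-score distribution given theta by the polytomous
    Lord-Wingersky recursion.

    ``probs``: (J, Q, K) conditional category probabilities; returns
    (Q, J*(K-1)+1).
    """
    j, q, k = probs.shape
    f = probs[0].copy()                              # scores 0..K-1
    for col in range(1, j):
        smax = f.shape[1] - 1
        new = np.zeros((q, smax + k))
        for kk in range(k):
            new[:, kk:kk + smax + 1] += probs[col][:, kk][:, None] * f
        f = new
    return f


def s_x2_item_fit(fit: GRMFit, min_expected: float = 1.0) -> pd.DataFrame:
    """Generalized S-X2 per item with item-level RMSEA effect sizes.

    Observed and expected category frequencies are compared conditional
    on the summed score; adjacent summed-score levels (and, within a
    level, adjacent categories) are collapsed until every expected count
    reaches ``min_expected``.  df is the number of free cells after
    collapsing minus the item's parameter count, floored at 1; items
    with no testable cells are flagged untestable.
    """
    params, grid = fit.params, fit.grid
    k = params.n_categories
    j = params.n_items
    x = fit.responses
    complete = np.all(x != MISSING, axis=1)
    x, w = x[complete], fit.weights[complete]
    n = w.sum()
    mom = _model_moments(params, grid)
    probs, wq = mom["probs"], mom["w"]
    smax = j * (k - 1)
    names = params.item_names or [f"item{c + 1}" for c in range(j)]
    total = x.sum(axis=1)

    rows = []
    for col in range(j):
        others = [c for c in range(j) if c != col]
        f_rest = lw_score_distribution(probs[others])        # (Q, smax-(K-1)+1)
        # joint P(X_j = k, S = s) with S the full summed score
        joint = np.zeros((smax + 1, k))
        for kk in range(k):
            contrib = (probs[col][:, kk][:, None] * f_rest) * wq[:, None]
            joint[kk:kk + f_rest.shape[1], kk] += contrib.sum(axis=0)
        marg = joint.sum(axis=1)
        obs = np.zeros((smax + 1, k))
        np.add.at(obs, (total, x[:, col]), w)

        # collapse interior score levels until every expected count is large
        scores = list(range(1, smax))       # extremes are deterministic
        groups: list[list[int]] = []
        current: list[int] = []
        for s in scores:
            current.append(s)
            exp_counts = n * joint[current].sum(axis=0)
            if exp_counts.sum() > 0 and np.all(
                    _collapse_cats(exp_counts, min_expected)[0] >= min_expected):
                groups.append(current)
                current = []
        if current and groups:
            groups[-1].extend(current)
        elif current:
            groups.append(current)

        x2 = 0.0
        n_cells = 0
        for grp in groups:
            e_cells = n * joint[grp].sum(axis=0)
            o_cells = obs[grp].sum(axis=0)
            if e_cells.sum() <= 0:
                continue
            e_pooled, pool_map = _collapse_cats(e_cells, min_expected)
            o_pooled = np.zeros_like(e_pooled)
            for src, dst in enumerate(pool_map):
                o_pooled[dst] += o_cells[src]
            # condition on the score group: compare category splits
            e_cond = e_pooled * (o_pooled.sum() / e_pooled.sum())
            x2 += ((o_pooled - e_cond) ** 2 / np.clip(e_cond, 1e-12, None)).sum()
            n_cells += e_pooled.size - 1
        df = n_cells - k  # item parameters: 1 slope + K-1 thresholds
        if df < 1:
            rows.append({"item": names[col], "S_X2": np.nan, "df": 0,
                         "p": np.nan, "RMSEA": np.nan, "untestable": True})
            continue
        p = float(chi2.sf(x2, df))
        rmsea = float(np.sqrt(max(x2 - df, 0.0) / (df * (n - 1))))
        rows.append({"item": names[col], "S_X2": float(x2), "df": int(df),
                     "p": p, "RMSEA": rmsea, "untestable": False})
    return pd.DataFrame(rows)


def _collapse_cats(expected: np.ndarray, min_expected: float):
    """Pool adjacent categories until every pooled cell >= min_expected.

    Returns pooled expected counts and a source->pooled index map.
    """
    k = expected.size
    pool_map = np.zeros(k, dtype=int)
    pooled = []
    acc = 0.0
    idx = 0
    members: list[int] = []
    for kk in range(k):
        acc += expected[kk]
        members.append(kk)
        if acc >= min_expected:
            for mm in members:
                pool_map[mm] = idx
            pooled.append(acc)
            idx += 1
            acc = 0.0
            members = []
    if members:
        if pooled:
            for mm in members:
                pool_map[mm] = idx - 1
            pooled[-1] += acc
        else:
            for mm in members:
                pool_map[mm] = 0
            pooled.append(acc)
    return np.asarray(pooled), pool_map


# ---------------------------------------------------------------------------
# monotonicity raw residuals

def monotonicity_residuals(fit: GRMFit, n_bins: int = 10,
                           min_bin: int = 10) -> pd.DataFrame:
    """Observed-minus-expected item score by trait bin (raw residual curves).

    For each item, persons are binned by the EAP estimate computed from
    the *other* items (the rest score), and the expected value is the
    item ICC averaged over that rest-score posterior.  Conditioning on
    the rest score makes ``E[X_j | rest] = E[ICC_j(theta) | rest]`` hold
    exactly under the model, so residuals are pure model misfit rather
    than selection artifacts.  Bins with fewer than ``min_bin`` persons
    merge into their neighbor.  With one bin the residual equals the
    overall observed-minus-expected mean per item.
    """
    params = fit.params
    x_all = fit.responses
    complete = np.all(x_all != MISSING, axis=1)
    x, w = x_all[complete], fit.weights[complete]
    nodes, prior = fit.grid.nodes, fit.grid.weights
    c = -params.a[:, None] * params.b
    probs, _ = _probs_on_grid(params.a, c, nodes)             # (J, Q, K)
    logp = np.log(probs)
    kvec = np.arange(params.n_categories)
    icc_grid = probs @ kvec                                   # (J, Q)

    names = params.item_names or [f"item{j + 1}" for j in range(params.n_items)]
    rows = []
    for col, name in enumerate(names):
        # collapse on the REST pattern so that persons sharing the same
        # rest responses get bit-identical bin positions regardless of
        # their response to the studied item
        others = [cc for cc in range(params.n_items) if cc != col]
        patterns, pindex = np.unique(x[:, others], axis=0, return_inverse=True)
        ll_rest = np.zeros((patterns.shape[0], nodes.size))
        for pos, jj in enumerate(others):
            ll_rest += logp[jj][:, patterns[:, pos]].T
        m = ll_rest.max(axis=1, keepdims=True)
        lik = np.exp(ll_rest - m) * prior[None, :]
        post = lik / lik.sum(axis=1, keepdims=True)
        th = (post @ nodes)[pindex]
        expected = (post @ icc_grid[col])[pindex]

        edges = np.quantile(th, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        bins = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, n_bins - 1)
        counts = np.bincount(bins, minlength=n_bins)
        for bb in range(n_bins):
            if 0 < counts[bb] < min_bin:
                target = bb - 1 if bb > 0 else bb + 1
                if 0 <= target < n_bins:
                    bins[bins == bb] = target
                    counts = np.bincount(bins, minlength=n_bins)
        for bb in np.unique(bins):
            sel = bins == bb
            wsel = w[sel]
            wsum = wsel.sum()
            obs_mean = (wsel * x[sel, col]).sum() / wsum
            exp_mean = (wsel * expected[sel]).sum() / wsum
            rows.append({
                "bin": int(bb), "n": int(sel.sum()),
                "theta_mid": float((wsel * th[sel]).sum() / wsum),
                "item": name, "observed": obs_mean, "expected": exp_mean,
                "residual": obs_mean - exp_mean,
            })
    return pd.DataFrame(rows)
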