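"""Weighted item descriptives and polychoric correlation estimation.

Polychoric correlations use the classical two-step estimator: item
thresholds from inverse-normal cumulative marginal proportions, then a
per-pair maximum-likelihood correlation of the underlying bivariate
normal over the observed contingency table.  Rectangle probabilities of
the bivariate normal are evaluated with the deterministic reduction

    Phi2(h, k, rho) = Phi(h) Phi(k) + int_0^rho phi2(h, k, r) dr

by fixed-order Gauss-Legendre quadrature, accurate to well below 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .core_io import GroupedDataset, MISSING

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def bivariate_normal_cdf(h, k, rho: float):
    """P(Z1 <= h, Z2 <= k) for the standard bivariate normal (deterministic).

    ``h`` and ``k`` may be arrays (broadcast together); the correlation-
    path integral from 0 to rho is evaluated by fixed-order
    Gauss-Legendre, accurate to well below 1e-10.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    scalar = h.ndim == 0 and k.ndim == 0
    h, k = np.broadcast_arrays(np.atleast_1d(h), np.atleast_1d(k))
    hh = np.clip(h, -37.0, 37.0)
    kk = np.clip(k, -37.0, 37.0)
    out = norm.cdf(hh) * norm.cdf(kk)
    if rho != 0.0:
        r = 0.5 * rho * (_GL_NODES + 1.0)
        w = 0.5 * rho * _GL_WEIGHTS
        om = 1.0 - r ** 2
        dens = np.exp(-(hh[..., None] ** 2 - 2 * r * hh[..., None] * kk[..., None]
                        + kk[..., None] ** 2) / (2 * om)) / (2 * np.pi * np.sqrt(om))
        out = out + dens @ w
    out = np.where((h == -np.inf) | (k == -np.inf), 0.0, out)
    return float(out[0]) if scalar else out


@dataclass
class PolychoricMatrix:
    """Item-by-item polychoric correlations with estimated thresholds."""

    corr: np.ndarray                       # (J, J), unit diagonal
    thresholds: list[np.ndarray]           # per item, normal-metric cuts
    item_names: list[str]
    n: float                               # (effective) sample size used
    repaired: bool = False                 # nearest-PSD repair applied
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        return pd.DataFrame(self.corr, index=self.item_names,
                            columns=self.item_names).to_csv(sep="\t")


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> dict:
    wsum = w.sum()
    mean = (w * x).sum() / wsum
    d = x - mean
    m2 = (w * d ** 2).sum() / wsum
    sd = np.sqrt(m2)
    if m2 <= 0:
        return {"mean": mean, "sd": 0.0, "skewness": np.nan,
                "kurtosis": np.nan, "degenerate": True}
    m3 = (w * d ** 3).sum() / wsum
    m4 = (w * d ** 4).sum() / wsum
    return {
        "mean": mean, "sd": sd,
        "skewness": m3 / m2 ** 1.5,
        "kurtosis": m4 / m2 ** 2 - 3.0,   # excess kurtosis
        "degenerate": False,
    }


def item_descriptives(data: GroupedDataset, weighted: bool = True) -> pd.DataFrame:
    """Per-group, per-item weighted mean/SD/skewness/excess kurtosis and
    category proportions.

    Constant items get SD 0 and NaN skewness/kurtosis with the
    ``degenerate`` flag set.  Statistics are invariant to a common
    rescaling of the weights.
    """
    k = data.n_categories
    rows = []
    for g in data.groups:
        sub = data.group_data(g)
        w_all = sub.effective_weights() if weighted else np.ones(sub.n_persons)
        for j, name in enumerate(data.item_names):
            x = sub.responses[:, j]
            obs = x != MISSING
            xx, ww = x[obs].astype(float), w_all[obs]
            if xx.size == 0:
                continue
            stats = _weighted_moments(xx, ww)
            props = {f"p{c}": float((ww * (xx == c)).sum() / ww.sum()) for c in range(k)}
            rows.append({"group": g, "item": name, "n": int(obs.sum()),
                         **stats, **props})
    return pd.DataFrame(rows)


def _pair_loglik(table: np.ndarray, tau_i: np.ndarray, tau_j: np.ndarray, rho: float) -> float:
    cut_i = np.concatenate([[-np.inf], tau_i, [np.inf]])
    cut_j = np.concatenate([[-np.inf], tau_j, [np.inf]])
    # rectangle probabilities by inclusion-exclusion on the corner CDF grid
    cdf = bivariate_normal_cdf(cut_i[:, None], cut_j[None, :], rho)
    probs = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    probs = np.maximum(probs, 1e-12)
    return float((table * np.log(probs)).sum())


def nearest_psd(mat: np.ndarray, eig_floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Eigenvalue clipping to the nearest PSD correlation matrix."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= eig_floor:
        return mat, False
    vals = np.clip(vals, eig_floor, None)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, True


def polychoric_matrix(
    responses: np.ndarray,
    weights: np.ndarray | None = None,
    item_names: list[str] | None = None,
    psd_repair: bool = True,
) -> PolychoricMatrix:
    """Two-step polychoric correlation matrix of an ordinal response matrix.

    Pairs with a degenerate contingency pattern (correlation
    unidentified) fall back to 0 with a warning.  The result is clipped
    to [-0.999, 0.999] and repaired to PSD by eigenvalue clipping when
    needed (the repair is logged on the result).
    """
    responses = np.asarray(responses, dtype=int)
    n, j = responses.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    item_names = item_names or [f"item{c + 1}" for c in range(j)]

    taus, codes = [], []
    for col in range(j):
        x = responses[:, col]
        obs = x != MISSING
        vals = np.unique(x[obs])
        if vals.size < 2:
            raise ValueError(f"item {item_names[col]} has fewer than 2 observed categories")
        codes.append(vals)
        ww = w[obs]
        cum = np.array([(ww * (x[obs] <= v)).sum() / ww.sum() for v in vals[:-1]])
        taus.append(norm.ppf(np.clip(cum, 1e-10, 1 - 1e-10)))

    corr = np.eye(j)
    warnings = []
    for i in range(j):
        for jj in range(i + 1, j):
            obs = (responses[:, i] != MISSING) & (responses[:, jj] != MISSING)
            xi = np.searchsorted(codes[i], responses[obs, i])
            xj = np.searchsorted(codes[jj], responses[obs, jj])
            table = np.zeros((codes[i].size, codes[jj].size))
            np.add.at(table, (xi, xj), w[obs])
            # unidentified when observations concentrate on one row/column
            if (table.sum(axis=1) > 0).sum() < 2 or (table.sum(axis=0) > 0).sum() < 2:
                warnings.append(f"pair ({item_names[i]}, {item_names[jj]}) unidentified; rho set to 0")
                continue
            res = minimize_scalar(
                lambda r: -_pair_loglik(table, taus[i], taus[jj], r),
                bounds=(-0.999, 0.999), method="bounded",
                options={"xatol": 1e-6},
            )
            corr[i, jj] = corr[jj, i] = float(np.clip(res.x, -0.999, 0.999))

    repaired = False
    if psd_repair:
        corr, repaired = nearest_psd(corr)
    return PolychoricMatrix(corr=corr, thresholds=taus, item_names=item_names,
                            n=float(w.sum()), repaired=repaired, warnings=warnings)
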