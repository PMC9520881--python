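"""Exploratory graph analysis: EBIC-glasso network + walktrap communities.

Dimensionality is assessed by estimating a regularized partial-
correlation network from the polychoric correlation matrix (graphical
lasso over a log-spaced penalty grid, selected by extended BIC) and
counting the communities found by the walktrap random-walk algorithm on
absolute edge weights.  The number of non-empty communities is the
estimated number of latent dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from .descriptives import PolychoricMatrix, polychoric_matrix


@dataclass
class EGAResult:
    network: np.ndarray          # partial correlations, zero diagonal
    membership: np.ndarray       # community id per item
    n_dimensions: int
    penalty: float               # selected glasso penalty
    ebic: float
    item_names: list[str]
    disconnected: bool = False   # every item isolated

    def memberships_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item": self.item_names, "community": self.membership})


def _partial_corr(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def _ebic(corr: np.ndarray, precision: np.ndarray, n: float, gamma: float) -> float:
    p = corr.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    ll = (n / 2.0) * (logdet - np.trace(corr @ precision))
    mask = np.triu(np.abs(precision) > 1e-10, k=1)
    n_edges = int(mask.sum())
    return -2.0 * ll + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def ebic_glasso(
    corr: np.ndarray | PolychoricMatrix,
    n: float | None = None,
    gamma: float = 0.5,
    n_penalties: int = 100,
    penalty_ratio: float = 0.01,
) -> dict:
    """Graphical lasso over a penalty grid, model chosen by minimum EBIC.

    Returns the selected partial-correlation network, the penalty, and
    the EBIC value.  The input correlation matrix must be PSD (repair it
    first, e.g. with :func:`sclpipe.descriptives.nearest_psd`).
    """
    if isinstance(corr, PolychoricMatrix):
        n = corr.n if n is None else n
        corr = corr.corr
    corr = np.asarray(corr, dtype=float)
    if n is None:
        raise ValueError("sample size n required")
    p = corr.shape[0]
    if p < 2:
        raise ValueError("network undefined for fewer than 2 items")
    if n <= p:
        raise ValueError("need n greater than the number of items")
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError("correlation matrix is not PSD; apply a PSD repair first")

    rho_max = np.abs(corr - np.eye(p)).max()
    if rho_max < 1e-12:
        pc = np.zeros_like(corr)
        return {"network": pc, "penalty": 0.0,
                "ebic": _ebic(corr, np.linalg.inv(corr), n, gamma)}
    grid = np.logspace(np.log10(penalty_ratio * rho_max), np.log10(rho_max), n_penalties)
    best = None
    import warnings as _warnings
    for alpha in grid:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                _, precision = graphical_lasso(corr, alpha=alpha, max_iter=500)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        score = _ebic(corr, precision, n, gamma)
        if best is None or score < best[0]:
            best = (score, alpha, precision)
    if best is None:
        raise RuntimeError("graphical lasso failed on every penalty in the grid")
    score, alpha, precision = best
    return {"network": _partial_corr(precision), "penalty": float(alpha),
            "ebic": float(score)}


def detect_communities(network: np.ndarray, steps: int = 4) -> dict:
    """Walktrap communities on absolute edge weights.

    A fully disconnected network yields one community per item, flagged.
    Ties in the dendrogram cut are resolved toward fewer communities.
    """
    network = np.asarray(network, dtype=float)
    p = network.shape[0]
    if p < 1:
        raise ValueError("network needs at least one node")
    absw = np.abs(np.triu(network, k=1))
    edges = np.argwhere(absw > 1e-10)
    if edges.size == 0:
        return {"membership": np.arange(p), "disconnected": True}
    g = ig.Graph(n=p, edges=[tuple(e) for e in edges])
    g.es["weight"] = [float(absw[i, jj]) for i, jj in edges]
    dendro = g.community_walktrap(weights="weight", steps=steps)
    clustering = dendro.as_clustering()   # modularity-optimal cut
    membership = np.asarray(clustering.membership)
    # components not touched by any edge become their own communities
    return {"membership": membership, "disconnected": False}


def ega(
    responses: np.ndarray,
    n: int | None = None,
    gamma: float = 0.5,
    weights: np.ndarray | None = None,
    item_names: list[str] | None = None,
) -> EGAResult:
    """Full exploratory graph analysis of an ordinal response matrix.

    Composition polychoric -> EBIC-glasso -> walktrap; the number of
    dimensions is the number of non-empty communities.
    """
    responses = np.asarray(responses, dtype=int)
    if responses.shape[1] < 2:
        raise ValueError("EGA undefined for a single item")
    poly = polychoric_matrix(responses, weights=weights, item_names=item_names)
    n = n or responses.shape[0]
    net = ebic_glasso(poly.corr, n=n, gamma=gamma)
    comm = detect_communities(net["network"])
    membership = comm["membership"]
    return EGAResult(
        network=net["network"],
        membership=membership,
        n_dimensions=int(np.unique(membership).size),
        penalty=net["penalty"],
        ebic=net["ebic"],
        item_names=poly.item_names,
        disconnected=comm["disconnected"],
    )
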