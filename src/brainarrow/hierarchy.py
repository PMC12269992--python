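"""Trophic hierarchy analysis of weighted directed graphs.

A directed graph with nonnegative weights w_mn (edge m -> n) induces
per-node in/out flows and an imbalance v_n = w_n^in - w_n^out. Trophic
levels h solve the weighted-Laplacian linear system

    Lambda h = v,   Lambda = diag(u) - W - W^T,   u = w^in + w^out,

which is singular along the constant vector (levels are a gauge: only
differences matter). The minimum-norm least-squares solution is taken per
weakly connected component and shifted to mean zero.

Trophic incoherence

    F0 = sum_mn w_mn (h_n - h_m - 1)^2 / sum_mn w_mn

is 0 for a perfectly coherent hierarchy (every edge drops exactly one
level, e.g. a directed chain) and 1 for a completely incoherent graph
(e.g. a directed cycle, where all levels coincide); coherence = 1 - F0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import wilcoxon

from .errors import ParameterError
from .signal_io import CouplingMatrix, validate_parcellation

logger = logging.getLogger(__name__)


@dataclass
class TrophicResult:
    """Hierarchy levels (mean-zero gauge) and flow bookkeeping."""

    levels: np.ndarray
    incoherence: float
    coherence: float
    in_weights: np.ndarray
    out_weights: np.ndarray
    total_weights: np.ndarray
    imbalance: np.ndarray


@dataclass
class RegionalHierarchy:
    """Hierarchy levels aggregated over anatomical groups."""

    group_means: dict[str, float]
    flatness: float
    pairwise_differences: pd.DataFrame


def _edge_matrix(gec: CouplingMatrix | np.ndarray) -> np.ndarray:
    """W[m, n] = weight of edge m -> n.

    CouplingMatrix stores weights[target, source] (the oscillator-model
    orientation), so the edge matrix is its transpose.
    """
    if isinstance(gec, CouplingMatrix):
        return np.asarray(gec.weights, float).T
    return np.asarray(gec, float)


def trophic_analysis(gec: CouplingMatrix | np.ndarray) -> TrophicResult:
    """Trophic levels, flows, and incoherence of a directed weighted graph.

    Accepts a :class:`CouplingMatrix` (influence orientation, transposed
    internally) or a plain edge matrix ``W[m, n] = weight of m -> n``.
    Weakly disconnected components are solved independently, each in its
    own mean-zero gauge.
    """
    W = _edge_matrix(gec)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ParameterError("edge matrix must be square")
    if np.any(W < 0):
        raise ParameterError("edge weights must be nonnegative")
    total = W.sum()
    if total <= 0:
        raise ParameterError("empty graph: all edge weights are zero")

    w_in = W.sum(axis=0)
    w_out = W.sum(axis=1)
    u = w_in + w_out
    v = w_in - w_out
    Lam = np.diag(u) - W - W.T

    n = W.shape[0]
    h = np.zeros(n)
    n_comp, labels = connected_components(
        (W + W.T) > 0, directed=False
    )
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            continue  # isolated node: level 0 in its own gauge
        sub = np.ix_(idx, idx)
        h_c, *_ = np.linalg.lstsq(Lam[sub], v[idx], rcond=None)
        h_c = h_c - h_c.mean()
        resid = np.abs(Lam[sub] @ h_c - v[idx]).max()
        if resid > 1e-8:
            raise ParameterError(
                f"trophic system inconsistent on a component (residual {resid:.3g})"
            )
        h[idx] = h_c

    drops = h[None, :] - h[:, None] - 1.0  # (m, n): h_n - h_m - 1
    f0 = float((W * drops**2).sum() / total)
    return TrophicResult(
        levels=h,
        incoherence=f0,
        coherence=1.0 - f0,
        in_weights=w_in,
        out_weights=w_out,
        total_weights=u,
        imbalance=v,
    )


def regional_hierarchy(tr: TrophicResult, parc: pd.DataFrame,
                       region_ids: list[str] | None = None) -> RegionalHierarchy:
    """Average ROI hierarchy levels within anatomical groups.

    Flatness is the standard deviation of h over all ROIs; the pairwise
    matrix holds differences of group means (antisymmetric).
    """
    parc = validate_parcellation(parc)
    h = np.asarray(tr.levels, float)
    if region_ids is None:
        if len(parc) != h.size:
            raise ParameterError("parcellation does not cover all nodes")
        groups = parc["group"].to_numpy()
    else:
        lookup = dict(zip(parc["region_id"], parc["group"]))
        missing = [r for r in region_ids if str(r) not in lookup]
        if missing:
            raise ParameterError(f"parcellation missing regions: {missing[:5]}")
        groups = np.array([lookup[str(r)] for r in region_ids])

    means: dict[str, float] = {}
    for g in pd.unique(groups):
        members = h[groups == g]
        if members.size == 0:
            logger.warning("group %r has no members; omitted", g)
            continue
        means[str(g)] = float(members.mean())
    names = list(means)
    diffs = pd.DataFrame(
        [[means[a] - means[b] for b in names] for a in names],
        index=names, columns=names,
    )
    flatness = float(np.std(h, ddof=1)) if h.size > 1 else 0.0
    return RegionalHierarchy(means, flatness, diffs)


def pairwise_region_tests(
    regional_results: list[RegionalHierarchy],
    method: str = "signed_rank",
) -> dict[str, pd.DataFrame]:
    """Within-cohort pairwise comparison of regional hierarchy levels.

    For each group pair (r, s), tests whether the per-subject difference of
    mean levels is nonzero (Wilcoxon signed-rank), with Benjamini-Hochberg
    correction over pairs. Returns raw p, adjusted p, and -log10(adjusted p)
    matrices (diagonal excluded, set to NaN).
    """
    from .group_stats import bh_fdr

    if method != "signed_rank":
        raise ParameterError(f"unknown method {method!r}")
    if len(regional_results) < 5:
        raise ParameterError("need >= 5 subjects per cohort for pairwise tests")
    groups = list(regional_results[0].group_means)
    data = np.array(
        [[res.group_means[g] for g in groups] for res in regional_results]
    )  # subjects x groups
    k = len(groups)
    p_raw = np.full((k, k), np.nan)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    p_list = []
    for i, j in pairs:
        d = data[:, i] - data[:, j]
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(wilcoxon(d, zero_method="wilcox").pvalue)
        p_list.append(p)
    p_adj_list = bh_fdr(np.asarray(p_list))
    p_adj = np.full((k, k), np.nan)
    for (i, j), p, q in zip(pairs, p_list, p_adj_list):
        p_raw[i, j] = p_raw[j, i] = p
        p_adj[i, j] = p_adj[j, i] = q
    as_df = lambda m: pd.DataFrame(m, index=groups, columns=groups)
    return {
        "p_raw": as_df(p_raw),
        "p_adjusted": as_df(p_adj),
        "neg_log10_p": as_df(-np.log10(np.maximum(p_adj, 1e-300))),
    }


def pagerank_centrality(
    gec: CouplingMatrix | np.ndarray, damping: float = 0.85
) -> np.ndarray:
    """PageRank of the weighted directed graph (dangling nodes -> uniform)."""
    W = _edge_matrix(gec)
    n = W.shape[0]
    G = nx.from_numpy_array(W, create_using=nx.DiGraph)
    pr = nx.pagerank(G, alpha=damping, weight="weight")
    return np.array([pr[i] for i in range(n)])
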