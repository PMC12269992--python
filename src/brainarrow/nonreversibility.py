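"""Model-free temporal non-reversibility (arrow of time) of BOLD signals.

The measure compares time-lagged dependencies of the observed signals with
those of the artificially time-reversed signals. For each ordered region
pair (i, j) the lagged Pearson correlation r = corr(s_i(t), s_j(t+dt)) is
mapped to a nonnegative functional-dependency value

    FS[i, j] = -1/2 * log(1 - r^2),

computed once on the forward series and once on the time-flipped series.
A system obeying detailed balance is statistically reversible, so the two
matrices coincide in expectation; their element-wise squared difference is
the non-reversibility ("pair") matrix, summarized globally, per node, and
per network. Larger values indicate stronger violation of detailed balance
(an entropy-production proxy, not a direct entropy estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .signal_io import RoiTimeSeries, validate_parcellation

logger = logging.getLogger(__name__)

# r^2 is clamped below 1 so the log transform stays finite on degenerate
# (perfectly dependent) pairs.
_R2_CLAMP = 1.0 - 1e-12


@dataclass
class LaggedDependencyMatrix:
    """Pairwise -1/2 log(1 - r^2) of lagged correlations, one direction."""

    values: np.ndarray
    lag_samples: int
    direction: str  # "forward" | "reversed"


@dataclass
class NonReversibilityResult:
    """Squared forward/reversed asymmetry and its reductions.

    ``pair_matrix[i, j]`` is the squared difference of the forward and
    reversed dependency of region j at t+dt on region i at t; the diagonal
    is zero. ``global_value`` is the off-diagonal mean, ``node_values[i]``
    the mean over j != i of row i, and ``network_values`` the mean over
    ordered pairs with both regions inside the named network.
    """

    pair_matrix: np.ndarray
    global_value: float
    node_values: np.ndarray
    network_values: dict[str, float]


def fs_from_r(r: np.ndarray) -> np.ndarray:
    """Map Pearson correlations to the nonnegative dependency scale."""
    r2 = np.minimum(np.square(r), _R2_CLAMP)
    return -0.5 * np.log1p(-r2)


def _lagged_correlation(values: np.ndarray, lag: int) -> np.ndarray:
    """r[i, j] = Pearson corr of (col_i[t], col_j[t + lag]) over M - lag samples."""
    a = values[:-lag, :]
    b = values[lag:, :]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    dead_a = sa < 1e-300
    dead_b = sb < 1e-300
    if dead_a.any() or dead_b.any():
        logger.warning(
            "zero-variance window in lagged correlation; affected elements set to r=0"
        )
    sa = np.where(dead_a, 1.0, sa)
    sb = np.where(dead_b, 1.0, sb)
    r = (a / sa).T @ (b / sb)
    r[dead_a, :] = 0.0
    r[:, dead_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def lagged_fs(
    ts: RoiTimeSeries, lag_samples: int, direction: str = "forward"
) -> LaggedDependencyMatrix:
    """Forward or time-reversed lagged dependency matrix.

    For ``direction="reversed"`` each column is independently time-flipped
    before the lagged correlation is taken; the flipped series itself is
    transient and never stored.
    """
    if direction not in ("forward", "reversed"):
        raise ParameterError(f"direction must be forward/reversed, got {direction!r}")
    if not ts.preprocessed:
        raise ParameterError("time series must be preprocessed before lagged_fs")
    lag = int(lag_samples)
    if lag < 1:
        raise ParameterError("lag_samples must be >= 1")
    if lag >= ts.n_timepoints:
        raise ParameterError(
            f"lag {lag} >= series length {ts.n_timepoints}"
        )
    if lag >= ts.n_timepoints / 3:
        raise ParameterError(
            f"lag {lag} too large for series length {ts.n_timepoints} (need lag < M/3)"
        )
    values = ts.values if direction == "forward" else ts.values[::-1, :]
    r = _lagged_correlation(values, lag)
    return LaggedDependencyMatrix(fs_from_r(r), lag, direction)


def nonreversibility(
    ts: RoiTimeSeries,
    lag_samples: int = 1,
    parc: pd.DataFrame | None = None,
) -> NonReversibilityResult:
    """Non-reversibility pair matrix and its global/node/network reductions.

    The diagonal is excluded everywhere: lagged autocorrelation is
    reversal-symmetric up to edge effects and would only add noise.
    """
    fsf = lagged_fs(ts, lag_samples, "forward").values
    fsr = lagged_fs(ts, lag_samples, "reversed").values
    pair = np.square(fsf - fsr)
    np.fill_diagonal(pair, 0.0)

    n = pair.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    global_value = float(pair[off_mask].mean())
    node_values = pair.sum(axis=1) / (n - 1)

    network_values: dict[str, float] = {}
    if parc is not None:
        parc = validate_parcellation(parc)
        order = {r: i for i, r in enumerate(ts.region_ids)}
        missing = [r for r in ts.region_ids if r not in set(parc["region_id"])]
        if missing:
            raise ParameterError(f"parcellation missing regions: {missing[:5]}")
        for net, sub in parc.groupby("network"):
            idx = [order[r] for r in sub["region_id"] if r in order]
            if len(idx) < 2:
                logger.warning(
                    "network %r has < 2 member regions; no value reported", net
                )
                continue
            block = pair[np.ix_(idx, idx)]
            m = len(idx)
            network_values[str(net)] = float(
                block[~np.eye(m, dtype=bool)].mean()
            )
    return NonReversibilityResult(pair, global_value, node_values, network_values)


def compare_nonrev_distributions(
    node_values_a: np.ndarray,
    node_values_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Distributional comparison of per-subject node vectors between cohorts.

    Runs both the unbiased squared maximum mean discrepancy (Gaussian
    kernel, median-heuristic bandwidth) and the Euclidean energy-distance
    two-sample statistic, each with a label-permutation null.

    Parameters are subject-by-node arrays; returns a dict of two
    :class:`~brainarrow.group_stats.GroupComparisonResult` objects keyed
    ``"mmd2"`` and ``"energy"``.
    """
    from .group_stats import energy_test, mmd2_test

    X = np.atleast_2d(np.asarray(node_values_a, dtype=float))
    Y = np.atleast_2d(np.asarray(node_values_b, dtype=float))
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ParameterError("both cohorts must be nonempty")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ParameterError("need >= 2 subjects per cohort for a permutation null")
    if X.shape[1] != Y.shape[1]:
        raise ParameterError(
            f"node-vector lengths differ: {X.shape[1]} vs {Y.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    return {
        "mmd2": mmd2_test(X, Y, n_perm=n_perm, seed=int(rng.integers(2**31))),
        "energy": energy_test(X, Y, n_perm=n_perm, seed=int(rng.integers(2**31))),
    }
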