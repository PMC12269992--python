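"""Independent oracles and small utilities shared across the test suite."""

import dataclasses

import numpy as np

from brainarrow.signal_io import RoiTimeSeries


def as_preprocessed(values: np.ndarray, tr: float = 1.0,
                    subject_id: str = "test") -> RoiTimeSeries:
    """Z-score columns and wrap as a preprocessed series (bypasses filtering)."""
    v = np.asarray(values, float)
    v = (v - v.mean(axis=0)) / v.std(axis=0)
    ids = [f"n{i}" for i in range(v.shape[1])]
    return RoiTimeSeries(subject_id, tr, v, ids, preprocessed=True)


def mark_preprocessed(ts: RoiTimeSeries) -> RoiTimeSeries:
    return dataclasses.replace(ts, preprocessed=True)


def simulate_linear_em(J: np.ndarray, sigma: float, dt: float, n_steps: int,
                       seed: int, burn_steps: int = 0,
                       sample_every: int = 1) -> np.ndarray:
    """Plain Euler-Maruyama integration of dX = J X dt + sigma dW.

    Deliberately independent of the package's simulator (real-valued state,
    explicit loop); serves as the simulation oracle for the analytic
    Lyapunov-equation statistics.
    """
    rng = np.random.default_rng(seed)
    d = J.shape[0]
    A = np.eye(d) + J * dt
    sd = sigma * np.sqrt(dt)
    x = np.zeros(d)
    n_keep = (n_steps - burn_steps) // sample_every
    out = np.empty((n_keep, d))
    k = 0
    for step in range(n_steps):
        x = A @ x + sd * rng.standard_normal(d)
        if step >= burn_steps and (step - burn_steps) % sample_every == 0 and k < n_keep:
            out[k] = x
            k += 1
    return out[:k]


def brute_force_nonrev(values: np.ndarray, lag: int):
    """Spreadsheet-style evaluation of the arrow-of-time pipeline.

    Plain Python loops over region pairs: lagged Pearson r on forward and
    per-column-flipped series, -1/2 log(1 - r^2), squared difference, and
    the off-diagonal-mean reductions.
    """
    def pearson(u, v):
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        u = u - u.mean()
        v = v - v.mean()
        return float(np.dot(u, v) / np.sqrt(np.dot(u, u) * np.dot(v, v)))

    def fs_matrix(x):
        n = x.shape[1]
        fs = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                r = pearson(x[:-lag, i], x[lag:, j])
                fs[i, j] = -0.5 * np.log(1 - min(r * r, 1 - 1e-12))
        return fs

    fsf = fs_matrix(values)
    fsr = fs_matrix(values[::-1, :])
    pair = (fsf - fsr) ** 2
    np.fill_diagonal(pair, 0.0)
    n = pair.shape[0]
    glob = pair.sum() / (n * (n - 1))
    node = pair.sum(axis=1) / (n - 1)
    return pair, glob, node
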