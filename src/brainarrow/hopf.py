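"""Linearized coupled Hopf whole-brain model and effective-connectivity fitting.

Each region j is a two-dimensional (complex) Hopf oscillator

    dz_j/dt = z_j (a_j + i w_j - |z_j|^2) + sum_k C_jk (z_k - z_j) + eta_j,

with bifurcation parameter a_j (< 0: noise-driven fluctuations around a
stable fixed point; > 0: limit cycle at w_j / 2 pi Hz), intrinsic angular
frequency w_j, directed coupling C_jk (from node k to node j) restricted to
anatomically connected pairs, and additive Gaussian noise eta_j.

For a_j < 0 and weak noise the cubic term is negligible and the system is a
linear (Ornstein-Uhlenbeck) process dX = J X dt + sigma dW whose stationary
covariance solves the continuous Lyapunov equation and whose lagged
covariance is Sigma expm(J^T T). That gives the model functional
connectivity (FC) and lagged covariance CSv(T) analytically, without
simulation, which is what makes gradient fitting of the generative
effective connectivity (GEC) tractable: each masked entry C_ij is nudged by
the FC and CSv misfits,

    C_ij <- C_ij + eps (FC_emp - FC_mod)_ij + eps' (CSv_emp - CSv_mod)_ij,

clamped to [0, c_max], until the joint Frobenius error stops improving.

Orientation convention: CSv[i, j] estimates corr(x_i(t), x_j(t + T)) on
both the empirical and the model side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.linalg import expm, solve_continuous_lyapunov

from .errors import InstabilityError, NumericalError, ParameterError
from .signal_io import CouplingMatrix, RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class HopfParameters:
    """Node-level parameters of the coupled oscillator model.

    ``a``: bifurcation parameters (< 0 required wherever the linearized
    analysis is used; > 0 yields limit cycles and is simulation-only);
    ``omega``: intrinsic angular frequencies in rad/s; ``sigma``: noise SD
    per real component; ``tr``: sampling interval of the observed signals in
    seconds.
    """

    a: np.ndarray
    omega: np.ndarray
    sigma: float = 0.02
    tr: float = 2.2

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.a.shape != self.omega.shape:
            raise ParameterError("a and omega must have the same length")
        # a >= 0 (limit-cycle regime) is valid for simulation; the linearized
        # analysis enforces stability via the Jacobian eigenvalue check.
        if np.any(self.omega < 0):
            raise ParameterError("omega must be >= 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")

    @classmethod
    def uniform(cls, n: int, a: float = -0.02, f_hz: float = 0.05,
                sigma: float = 0.02, tr: float = 2.2) -> "HopfParameters":
        return cls(np.full(n, a), np.full(n, 2 * np.pi * f_hz), sigma, tr)

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class ModelStatistics:
    """FC (correlation) and lag-T correlation-normalized covariance."""

    fc: np.ndarray
    csv: np.ndarray
    lag: float = 0.0


@dataclass
class GecModel:
    """Fitted generative effective connectivity and its fit diagnostics."""

    coupling: CouplingMatrix
    params: HopfParameters
    fit_error_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    iterations_run: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# Linear machinery
# ---------------------------------------------------------------------------


def build_jacobian(coupling: CouplingMatrix | np.ndarray,
                   params: HopfParameters, check: bool = True) -> np.ndarray:
    """Jacobian of the linearized system in (x_1..x_N, y_1..y_N) order.

    Block form [[A, -B], [B, A]] with A = diag(a_j - sum_k C_jk) + C and
    B = diag(omega). For nonnegative diffusive coupling the Gershgorin discs
    all sit left of a < 0, but stability is verified explicitly.
    """
    C = coupling.weights if isinstance(coupling, CouplingMatrix) else np.asarray(coupling, float)
    n = params.n
    if C.shape != (n, n):
        raise ParameterError(f"coupling shape {C.shape} does not match N={n}")
    A = C - np.diag(C.sum(axis=1)) + np.diag(params.a)
    B = np.diag(params.omega)
    J = np.block([[A, -B], [B, A]])
    if check:
        # eigenvalues of [[A,-B],[B,A]] are those of A + iB and conjugates
        ev = np.linalg.eigvals(A + 1j * B)
        max_re = float(ev.real.max())
        if max_re >= 0:
            raise InstabilityError(max_re)
    return J


def stationary_covariance(J: np.ndarray, sigma: float) -> np.ndarray:
    """Solve J Sigma + Sigma J^T + sigma^2 I = 0 for the stationary covariance."""
    q = sigma**2 * np.eye(J.shape[0])
    Sigma = solve_continuous_lyapunov(J, -q)
    Sigma = 0.5 * (Sigma + Sigma.T)
    resid = np.abs(J @ Sigma + Sigma @ J.T + q).max()
    if resid > 1e-8:
        raise NumericalError(f"Lyapunov residual {resid:.3g} > 1e-8")
    return Sigma


def model_statistics(coupling: CouplingMatrix | np.ndarray,
                     params: HopfParameters, lag: float) -> ModelStatistics:
    """Analytic FC and lag-T normalized covariance of the linearized model.

    csv[i, j] = [Sigma expm(J^T lag)]_xx[i, j] / sqrt(Sigma_xx[i,i] Sigma_xx[j,j]),
    i.e. the model estimate of corr(x_i(t), x_j(t + lag)).
    """
    J = build_jacobian(coupling, params)
    Sigma = stationary_covariance(J, params.sigma)
    n = params.n
    Sxx = Sigma[:n, :n]
    d = np.sqrt(np.diag(Sxx))
    norm = np.outer(d, d)
    fc = Sxx / norm
    np.fill_diagonal(fc, 1.0)
    if lag == 0:
        csv = fc.copy()
    else:
        Cv = Sigma @ expm(J.T * lag)
        csv = Cv[:n, :n] / norm
    return ModelStatistics(fc=fc, csv=csv, lag=lag)


def empirical_statistics(ts: RoiTimeSeries, lag_samples: int) -> ModelStatistics:
    """Empirical FC and lagged covariance of z-scored signals.

    csv[i, j] = (1 / (M - lag)) sum_t s_i(t) s_j(t + lag) with s the
    z-scored columns of the full series, matching the model-side
    orientation csv[i, j] ~ corr(x_i(t), x_j(t + lag)).
    """
    if not ts.preprocessed:
        raise ParameterError("time series must be preprocessed (z-scored)")
    lag = int(lag_samples)
    M = ts.n_timepoints
    if lag < 0 or lag >= M:
        raise ParameterError(f"lag {lag} out of range for series length {M}")
    s = ts.values
    s = (s - s.mean(axis=0)) / s.std(axis=0)
    fc = np.corrcoef(s, rowvar=False)
    if lag == 0:
        csv = (s.T @ s) / M  # unit-variance columns: equals fc exactly
    else:
        csv = (s[:-lag].T @ s[lag:]) / (M - lag)
    return ModelStatistics(fc=fc, csv=csv, lag=lag * ts.tr)


def estimate_frequencies(ts_list: list[RoiTimeSeries],
                         band: tuple[float, float] = (0.008, 0.08)) -> np.ndarray:
    """Per-node intrinsic angular frequencies from averaged Welch spectra.

    The power spectrum of each node is averaged across the supplied
    subjects; omega_j = 2 pi f_peak with f_peak the in-band peak of the
    averaged spectrum.
    """
    low, high = band
    if not ts_list:
        raise ParameterError("need at least one subject")
    tr = ts_list[0].tr
    nyq = 1.0 / (2 * tr)
    if not (0 < low < high < nyq):
        raise ParameterError(f"band ({low}, {high}) outside (0, Nyquist={nyq:.4g})")
    nperseg = min(256, min(ts.n_timepoints for ts in ts_list))
    acc = None
    for ts in ts_list:
        if abs(ts.tr - tr) > 1e-9:
            raise ParameterError("all subjects must share the same TR")
        freqs, pxx = sps.welch(ts.values, fs=1.0 / tr, axis=0, nperseg=nperseg)
        acc = pxx if acc is None else acc + pxx
    in_band = (freqs >= low) & (freqs <= high)
    if not in_band.any():
        raise ParameterError("no spectral bins inside the requested band")
    band_freqs = freqs[in_band]
    peak = band_freqs[np.argmax(acc[in_band, :], axis=0)]
    return 2 * np.pi * peak


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_hopf(
    coupling: CouplingMatrix | np.ndarray,
    params: HopfParameters,
    duration: float,
    dt: float | None = None,
    seed: int | None = None,
    burn_in: float = 60.0,
    subject_id: str = "sim",
    region_ids: list[str] | None = None,
    cubic: bool = True,
) -> RoiTimeSeries:
    """Euler-Maruyama integration of the full nonlinear Hopf system.

    Both real components of every node are driven by independent Gaussian
    noise of SD sigma*sqrt(dt) per step. A burn-in of ``burn_in`` seconds is
    discarded and the x components are subsampled at TR. Fully reproducible
    under a fixed seed.

    ``cubic=False`` drops the |z|^2 saturation term and integrates the
    linearized system instead — the regime whose statistics the Lyapunov
    machinery computes exactly, useful for validating it by simulation.
    """
    C = coupling.weights if isinstance(coupling, CouplingMatrix) else np.asarray(coupling, float)
    n = params.n
    tr = params.tr
    if dt is None:
        dt = tr / 10.0
    if dt > tr / 10.0 + 1e-12:
        raise ParameterError(f"dt={dt} must be <= tr/10 = {tr / 10:.4g}")
    if duration < 100 * tr:
        raise ParameterError(
            f"duration {duration} s below the minimum 100*tr = {100 * tr:.1f} s"
        )
    rng = np.random.default_rng(seed)
    row_sum = C.sum(axis=1)
    lam = params.a + 1j * params.omega
    n_volumes = int(round(duration / tr))
    sample_every = int(round(tr / dt))
    n_burn = int(round(burn_in / dt))
    n_steps = n_burn + n_volumes * sample_every
    sqdt = np.sqrt(dt)

    z = np.zeros(n, dtype=complex)
    out = np.empty((n_volumes, n))
    k = 0
    for step in range(1, n_steps + 1):
        noise = params.sigma * sqdt * (
            rng.standard_normal(n) + 1j * rng.standard_normal(n)
        )
        local = lam - np.abs(z) ** 2 if cubic else lam
        dz = z * local + (C @ z - row_sum * z)
        z = z + dt * dz + noise
        if not np.all(np.isfinite(z.view(float))):
            raise NumericalError(
                "numerical overflow during integration; use a smaller dt"
            )
        if step > n_burn and (step - n_burn) % sample_every == 0:
            out[k] = z.real
            k += 1
    ids = region_ids or [f"r{i:03d}" for i in range(n)]
    return RoiTimeSeries(subject_id, tr, out[:k], ids, preprocessed=False)


# ---------------------------------------------------------------------------
# GEC fitting
# ---------------------------------------------------------------------------


def fit_gec(
    emp: ModelStatistics,
    sc_mask: CouplingMatrix | np.ndarray,
    params: HopfParameters,
    lag: float,
    eps: float = 0.0004,
    eps_prime: float = 0.0001,
    init: CouplingMatrix | np.ndarray | None = None,
    max_iter: int = 5000,
    c_max: float = 0.2,
    patience: int = 100,
    tol: float = 1e-6,
    region_ids: list[str] | None = None,
) -> GecModel:
    """Gradient fit of the directed effective-connectivity matrix.

    Only off-diagonal entries where the structural mask is nonzero are
    updated (the mask is binarized; its magnitudes are not otherwise used).
    After each update the coupling is clamped to [0, c_max] and the model
    FC/CSv are recomputed analytically. The total error is the sum of the
    two Frobenius misfit norms; the best-error iterate is returned.
    ``converged`` is set when the best error improves by less than ``tol``
    over ``patience`` consecutive iterations.

    If an update renders the model unstable the offending step is halved
    and retried, up to 10 consecutive times.
    """
    mask_w = sc_mask.weights if isinstance(sc_mask, CouplingMatrix) else np.asarray(sc_mask, float)
    n = params.n
    if mask_w.shape != (n, n):
        raise ParameterError("mask shape does not match parameters")
    mask = mask_w > 0
    np.fill_diagonal(mask, False)

    if init is None:
        C = np.zeros((n, n))
    else:
        C = np.array(init.weights if isinstance(init, CouplingMatrix) else init,
                     dtype=float)
        C = np.where(mask, np.clip(C, 0.0, c_max), 0.0)

    def total_error(mod: ModelStatistics) -> float:
        return float(
            np.linalg.norm(emp.fc - mod.fc, "fro")
            + np.linalg.norm(emp.csv - mod.csv, "fro")
        )

    mod = model_statistics(C, params, lag)
    err = total_error(mod)
    best_err, best_C = err, C.copy()
    trace = [err]
    since_improve = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # C[i, j] carries influence j -> i, which drives corr(x_j(t), x_i(t+T))
        # = CSv[j, i]; each entry is nudged by the misfit it generates.
        delta = eps * (emp.fc - mod.fc) + eps_prime * (emp.csv - mod.csv).T
        delta = np.where(mask, delta, 0.0)
        stable = False
        for attempt in range(10):
            C_try = np.clip(C + delta, 0.0, c_max)
            try:
                mod = model_statistics(C_try, params, lag)
                stable = True
                break
            except InstabilityError:
                delta *= 0.5
        if not stable:
            raise InstabilityError(np.nan)
        C = C_try
        err = total_error(mod)
        trace.append(err)
        if err < best_err - tol:
            best_err, best_C = err, C.copy()
            since_improve = 0
        else:
            if err < best_err:
                best_err, best_C = err, C.copy()
            since_improve += 1
            if since_improve >= patience:
                converged = True
                break
    ids = region_ids or (sc_mask.region_ids if isinstance(sc_mask, CouplingMatrix)
                         else [f"r{i:03d}" for i in range(n)])
    cm = CouplingMatrix(best_C, list(ids), directed=True, kind="GEC")
    return GecModel(cm, params, np.asarray(trace), it, converged)


def fit_cohort(
    subject_stats: list[ModelStatistics],
    sc_mask: CouplingMatrix | np.ndarray,
    params: HopfParameters,
    lag: float,
    group_max_iter: int = 5000,
    subject_max_iter: int = 5000,
    init: CouplingMatrix | np.ndarray | None = None,
    **kwargs,
) -> tuple[GecModel, list[GecModel]]:
    """Two-stage cohort fit: group-mean pretraining, then per-subject fits.

    Stage 1 fits the cohort-mean FC/CSv (optionally from ``init``); stage 2
    fits every subject initialized at the group solution. Returns
    (group model, subject models).
    """
    if not subject_stats:
        raise ParameterError("cohort must contain at least one subject")
    mean_stats = ModelStatistics(
        fc=np.mean([s.fc for s in subject_stats], axis=0),
        csv=np.mean([s.csv for s in subject_stats], axis=0),
        lag=subject_stats[0].lag,
    )
    group = fit_gec(mean_stats, sc_mask, params, lag,
                    max_iter=group_max_iter, init=init, **kwargs)
    models = [
        fit_gec(s, sc_mask, params, lag, init=group.coupling,
                max_iter=subject_max_iter, **kwargs)
        for s in subject_stats
    ]
    return group, models


def node_strengths(gec: GecModel | CouplingMatrix | np.ndarray) -> np.ndarray:
    """Total (in + out) coupling weight per node."""
    if isinstance(gec, GecModel):
        C = gec.coupling.weights
    elif isinstance(gec, CouplingMatrix):
        C = gec.weights
    else:
        C = np.asarray(gec, float)
    return C.sum(axis=0) + C.sum(axis=1)
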