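"""Synthetic cohorts with known ground-truth directed coupling.

The generator emulates the study design the pipeline targets: two cohorts
of resting-state recordings (~200 volumes at TR = 2.2 s, dynamics in the
0.008-0.08 Hz band) over a shared sparse anatomical mask, where the
"patient-like" cohort carries a stronger directional imbalance in its
coupling. Directionality is injected as a layered feed-forward bias:
each reciprocal edge pair of the symmetric base network redistributes
weight toward the low-to-high-layer direction, conserving the pair's total
weight so that the manipulation changes the arrow-of-time signature
without changing mean coupling strength (and hence barely changing FC).

Every subject's coupling matrix passes the linear-stability check before
simulation, and everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hopf import HopfParameters, build_jacobian, simulate_hopf
from .signal_io import (
    CouplingMatrix,
    PARCELLATION_GROUPS,
    RoiTimeSeries,
    validate_cohort,
    validate_parcellation,
    write_cohort,
    write_coupling,
    write_parcellation,
    write_timeseries,
)


@dataclass
class SyntheticCohortSpec:
    """Generator settings; defaults are the desk-scale study conditions."""

    n_nodes: int = 40
    n_subjects: int = 15  # per cohort
    volumes: int = 200
    tr: float = 2.2
    band: tuple[float, float] = (0.008, 0.08)
    sc_density: float = 0.3
    base_coupling: float = 0.03
    asymmetry_factor: float = 2.0  # patient-like cohort
    asymmetry_base: float = 0.4  # control-like directional imbalance fraction
    subject_jitter: float = 0.1
    a: float = -0.02
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ParameterError("need at least 3 nodes")
        if self.volumes < 100:
            raise ParameterError(
                "need at least 100 volumes for lag analysis and stable filtering"
            )
        if not (0 < self.sc_density <= 1):
            raise ParameterError("sc_density must be in (0, 1]")
        if self.asymmetry_factor < 0:
            raise ParameterError("asymmetry_factor must be >= 0")


@dataclass
class SyntheticCohort:
    """Ground truth plus simulated data for two labeled cohorts."""

    spec: SyntheticCohortSpec
    sc_mask: CouplingMatrix  # shared binary-valued symmetric mask (as weights)
    ground_truth: dict[str, CouplingMatrix]  # per subject
    structural: dict[str, CouplingMatrix]  # per subject jittered SC
    timeseries: dict[str, RoiTimeSeries]
    cohort_table: pd.DataFrame
    parcellation: pd.DataFrame
    omega: np.ndarray


def _region_ids(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


def _base_network(spec: SyntheticCohortSpec, rng: np.random.Generator):
    """Symmetric sparse base weights + feed-forward orientation map.

    Node index doubles as layer depth; for every undirected edge {i, j}
    with i < j, the i -> j direction is the feed-forward one.
    """
    n = spec.n_nodes
    upper = np.triu(rng.random((n, n)) < spec.sc_density, k=1)
    # ensure weak connectivity via a path through consecutive nodes
    for i in range(n - 1):
        upper[i, i + 1] = True
    w = spec.base_coupling * (0.5 + rng.random((n, n)))
    sym = np.where(upper, w, 0.0)
    sym = sym + sym.T
    return sym, upper


def make_ground_truth(
    spec: SyntheticCohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, CouplingMatrix]], CouplingMatrix, np.ndarray]:
    """Per-subject coupling matrices for both cohorts plus the shared mask.

    Control-like subjects get the baseline directional imbalance
    (``asymmetry_base``); patient-like subjects get it scaled by
    ``asymmetry_factor``. With ``asymmetry_factor = 0`` the patient-like
    coupling is exactly symmetric. Per-subject multiplicative jitter is
    applied on top, and every draw must pass the stability check (with
    rescaling retries, although nonnegative diffusive coupling with a < 0
    is provably stable).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ids = _region_ids(spec.n_nodes)
    params = HopfParameters.uniform(spec.n_nodes, a=spec.a, sigma=spec.sigma,
                                    tr=spec.tr)

    sym, upper = _base_network(spec, rng)
    mask = CouplingMatrix((sym > 0).astype(float), ids, directed=False, kind="SC")

    def directed_base(asym_scale: float) -> np.ndarray:
        # C[target, source]: feed-forward edge i -> j (i < j) lives at C[j, i]
        delta = np.clip(spec.asymmetry_base * asym_scale, 0.0, 0.95)
        C = np.zeros_like(sym)
        iu, ju = np.nonzero(upper)
        C[ju, iu] = sym[iu, ju] * (1.0 + delta)  # feed-forward direction
        C[iu, ju] = sym[iu, ju] * (1.0 - delta)  # feedback direction
        return C

    cohorts: dict[str, dict[str, CouplingMatrix]] = {}
    for cohort, scale in (("control", 1.0), ("patient", spec.asymmetry_factor)):
        base = directed_base(scale)
        subjects = {}
        for s in range(spec.n_subjects):
            sid = f"{cohort}{s:02d}"
            for attempt in range(20):
                jitter = 1.0 + spec.subject_jitter * rng.standard_normal(base.shape)
                C = np.clip(base * jitter, 0.0, None)
                C[sym == 0] = 0.0
                try:
                    build_jacobian(C, params)
                    break
                except Exception:
                    base = base * 0.8
            else:
                raise ParameterError("could not draw a stable coupling in 20 tries")
            subjects[sid] = CouplingMatrix(C, ids, directed=True, kind="GEC")
        cohorts[cohort] = subjects
    return cohorts, mask, sym


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Simulate both cohorts end to end from a single seed."""
    rng = np.random.default_rng(spec.seed)
    ids = _region_ids(spec.n_nodes)
    cohorts, mask, sym = make_ground_truth(spec, rng)

    low, high = spec.band
    freqs = rng.uniform(low, high, size=spec.n_nodes)
    omega = 2 * np.pi * freqs
    params = HopfParameters(
        np.full(spec.n_nodes, spec.a), omega, spec.sigma, spec.tr
    )

    duration = spec.volumes * spec.tr
    timeseries: dict[str, RoiTimeSeries] = {}
    structural: dict[str, CouplingMatrix] = {}
    ground_truth: dict[str, CouplingMatrix] = {}
    rows = []
    for cohort, subjects in cohorts.items():
        for sid, cm in subjects.items():
            ground_truth[sid] = cm
            sim_seed = int(rng.integers(2**31))
            timeseries[sid] = simulate_hopf(
                cm, params, duration=duration, seed=sim_seed,
                subject_id=sid, region_ids=ids,
            )
            sc_jit = 1.0 + spec.subject_jitter * rng.standard_normal(sym.shape)
            sc = np.clip(sym * 0.5 * (sc_jit + sc_jit.T), 0.0, None)
            np.fill_diagonal(sc, 0.0)
            structural[sid] = CouplingMatrix(sc, ids, directed=False, kind="SC")
            rows.append(
                {
                    "subject_id": sid,
                    "cohort": cohort,
                    "age": float(np.round(rng.uniform(45, 80), 1)),
                    "sex": rng.choice(["F", "M"]),
                    # placeholder clinical draws, interface testing only
                    "updrs3": int(rng.integers(10, 50)) if cohort == "patient" else np.nan,
                    "hoehn_yahr": int(rng.integers(1, 4)) if cohort == "patient" else np.nan,
                    "sim_seed": sim_seed,
                }
            )
    cohort_table = validate_cohort(pd.DataFrame(rows))
    parcellation = _make_parcellation(ids)
    return SyntheticCohort(
        spec=spec, sc_mask=mask, ground_truth=ground_truth,
        structural=structural, timeseries=timeseries,
        cohort_table=cohort_table, parcellation=parcellation, omega=omega,
    )


def _make_parcellation(ids: list[str]) -> pd.DataFrame:
    """Round-robin anatomical groups; layered BTC/CTC-like network labels."""
    groups = sorted(PARCELLATION_GROUPS)
    n = len(ids)
    third = n // 3
    networks = ["BTC"] * third + ["CTC"] * third + ["none"] * (n - 2 * third)
    df = pd.DataFrame(
        {
            "region_id": ids,
            "region_name": [f"region {i}" for i in range(n)],
            "group": [groups[i % len(groups)] for i in range(n)],
            "network": networks,
        }
    )
    return validate_parcellation(df)


def write_cohort_dir(cohort: SyntheticCohort, out_dir) -> None:
    """Write the full artifact layout the pipeline consumes (plain text)."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    (out / "sc").mkdir(exist_ok=True)
    write_parcellation(cohort.parcellation, out / "parcellation.tsv")
    cohort.cohort_table.to_csv(out / "cohort.tsv", sep="\t", index=False)
    write_coupling(cohort.sc_mask, out / "sc_mask.tsv")
    for sid, ts in cohort.timeseries.items():
        write_timeseries(ts, out / "timeseries" / f"{sid}.tsv")
        write_coupling(cohort.ground_truth[sid], out / "ground_truth" / f"{sid}.tsv")
        write_coupling(cohort.structural[sid], out / "sc" / f"{sid}.tsv")
    pd.Series(asdict(cohort.spec)).to_json(out / "generator_spec.json")


# ---------------------------------------------------------------------------
# Canonical toy objects
# ---------------------------------------------------------------------------


def toy_fixtures() -> dict:
    """Small named graphs and series used across the test surface.

    Graph fixtures are plain edge matrices W[m, n] = weight of m -> n.
    """
    chain2 = np.array([[0.0, 1.0], [0.0, 0.0]])
    chain5 = np.diag(np.ones(4), k=1)
    cycle3 = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    sym_pair = np.array([[0.0, 1.0], [1.0, 0.0]])

    pal = np.array([1.0, 3.0, -2.0, -2.0, 3.0, 1.0])
    palindrome = RoiTimeSeries(
        "palindrome", 2.2,
        np.column_stack([pal, pal[::-1] * 0.5 + 1.0]),
        ["p0", "p1"], preprocessed=True,
    )
    hand6 = RoiTimeSeries(
        "hand6", 2.2,
        np.array(
            [[0.3, -1.2], [1.1, 0.4], [-0.7, 0.9], [0.2, -0.5],
             [-1.4, 1.3], [0.8, -0.6]]
        ),
        ["h0", "h1"], preprocessed=True,
    )
    return {
        "chain2": chain2,
        "chain5": chain5,
        "cycle3": cycle3,
        "symmetric_pair": sym_pair,
        "palindrome": palindrome,
        "hand6": hand6,
    }
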