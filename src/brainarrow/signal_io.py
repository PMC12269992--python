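"""Artifact I/O and ROI time-series preprocessing.

The pipeline starts from ROI-averaged BOLD signals; everything upstream
(volume registration, parcellation, nuisance regression) is out of scope.
This module owns the on-disk formats — delimited text for time series and
coupling matrices, TSV for parcellation/cohort tables — and the standard
signal conditioning: linear detrend, zero-phase Butterworth band-pass,
per-column z-scoring, and explicit node exclusion.

Conventions
-----------
* Time-series files: header row of region ids, one row per time point.
* Coupling-matrix files: first row and first column are region ids.
* Region columns are always matched by id, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError, ParameterError, ZeroVarianceError

PARCELLATION_GROUPS = frozenset(
    {
        "frontal",
        "parietal",
        "temporal",
        "occipital",
        "cingulate",
        "insula",
        "thalamus",
        "basal_ganglia",
        "brainstem",
        "cerebellum",
    }
)
NETWORK_LABELS = frozenset({"BTC", "CTC", "none"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RoiTimeSeries:
    """One subject's regional BOLD signals, time points x regions."""

    subject_id: str
    tr: float
    values: np.ndarray
    region_ids: list[str]
    preprocessed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        if self.tr <= 0:
            raise ParameterError(f"tr must be > 0, got {self.tr}")
        if self.values.ndim != 2:
            raise FormatError("time series must be a 2-D matrix")
        if self.values.shape[1] != len(self.region_ids):
            raise FormatError(
                f"{self.values.shape[1]} columns but {len(self.region_ids)} region ids"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            dupes = sorted({r for r in self.region_ids if self.region_ids.count(r) > 1})
            raise FormatError(f"duplicate region ids: {dupes}")
        if np.isnan(self.values).any():
            bad = int(np.argwhere(np.isnan(self.values))[0][0])
            raise FormatError(f"missing/non-numeric value first seen at row {bad}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class CouplingMatrix:
    """Directed or structural coupling between regions.

    ``weights[j, k]`` is the coupling strength *from region k to region j*
    (the orientation used by the oscillator model, where row j collects the
    inputs of node j). Structural connectivity (``kind="SC"``) must be
    symmetric with a zero diagonal; fitted effective connectivity
    (``kind="GEC"``) is generally asymmetric.
    """

    weights: np.ndarray
    region_ids: list[str]
    directed: bool
    kind: str  # "SC" | "GEC"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        n = len(self.region_ids)
        if self.weights.shape != (n, n):
            raise FormatError(
                f"weights shape {self.weights.shape} != ({n}, {n}) region ids"
            )
        if self.kind not in ("SC", "GEC"):
            raise ParameterError(f"kind must be SC or GEC, got {self.kind!r}")
        if np.any(self.weights < 0):
            raise ParameterError("coupling weights must be nonnegative")
        if self.kind == "SC":
            if not np.allclose(self.weights, self.weights.T, atol=1e-10):
                raise ParameterError("SC matrix must be symmetric within 1e-10")
            if np.any(np.abs(np.diag(self.weights)) > 0):
                raise ParameterError("SC matrix must have a zero diagonal")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def validate_parcellation(df: pd.DataFrame) -> pd.DataFrame:
    """Check the region_id/region_name/group/network schema; return the frame."""
    required = ["region_id", "region_name", "group", "network"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"parcellation table missing columns: {missing}")
    df = df.copy()
    df["region_id"] = df["region_id"].astype(str)
    if df["region_id"].duplicated().any():
        dupes = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        raise FormatError(f"duplicate region ids in parcellation: {dupes}")
    bad_group = set(df["group"]) - PARCELLATION_GROUPS
    if bad_group:
        raise FormatError(f"unknown anatomical groups: {sorted(bad_group)}")
    bad_net = set(df["network"]) - NETWORK_LABELS
    if bad_net:
        raise FormatError(f"unknown network labels: {sorted(bad_net)}")
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the subject_id/cohort/age/sex schema; return the frame."""
    required = ["subject_id", "cohort", "age", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise FormatError("duplicate subject ids in cohort table")
    if df["cohort"].isna().any() or (df["cohort"] == "").any():
        raise FormatError("cohort column has empty entries")
    bad = set(df["cohort"]) - {"patient", "control"}
    if bad:
        raise FormatError(f"cohort labels must be patient/control, got {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path.name}: {exc}") from exc
    return df


def read_timeseries(path, tr: float, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a delimited ROI-by-time table (header = region ids)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate region ids in header of {path.name}: {dupes}")
    df = _read_delimited(path)
    df.columns = header  # undo pandas' mangling of any odd names
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(numeric).any():
        row = int(np.argwhere(np.isnan(numeric))[0][0])
        col = df.columns[int(np.argwhere(np.isnan(numeric))[0][1])]
        raise FormatError(
            f"{Path(path).name}: missing or non-numeric cell at row {row}, "
            f"column {col!r}"
        )
    return RoiTimeSeries(
        subject_id=subject_id or Path(path).stem,
        tr=tr,
        values=numeric,
        region_ids=list(df.columns),
        preprocessed=False,
    )


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_ids).to_csv(
        path, sep="\t" if str(path).endswith((".tsv", ".txt")) else ",", index=False
    )


def read_coupling(path, kind: str, directed: bool | None = None) -> CouplingMatrix:
    """Read an N x N coupling matrix (first row and column = region ids)."""
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError(f"{Path(path).name}: row and column region ids disagree")
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(numeric).any():
        raise FormatError(f"{Path(path).name}: non-numeric cell in coupling matrix")
    if directed is None:
        directed = kind == "GEC"
    return CouplingMatrix(numeric, [str(c) for c in df.columns], directed, kind)


def write_coupling(cm: CouplingMatrix, path) -> None:
    df = pd.DataFrame(cm.weights, index=cm.region_ids, columns=cm.region_ids)
    df.index.name = "region_id"
    df.to_csv(path, sep="\t" if str(path).endswith((".tsv", ".txt")) else ",")


def read_parcellation(path) -> pd.DataFrame:
    return validate_parcellation(pd.read_csv(path, sep="\t"))


def write_parcellation(df: pd.DataFrame, path) -> None:
    validate_parcellation(df).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    ts: RoiTimeSeries, low: float = 0.008, high: float = 0.08, order: int = 2
) -> RoiTimeSeries:
    """Detrend, zero-phase band-pass, and z-score each region's signal.

    Each column is linearly detrended, filtered with an ``order``-th order
    Butterworth band-pass applied forward-backward (zero phase, so no
    artificial lag is introduced into the signals that the arrow-of-time
    asymmetry measure will see), then z-scored.

    Raises
    ------
    ParameterError
        If the band is empty or reaches the Nyquist frequency 1/(2*tr).
    ZeroVarianceError
        If any column has (numerically) zero variance after filtering.
        Zero-variance regions must be excluded explicitly by the caller via
        :func:`exclude_nodes`; they are never dropped silently per subject.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low < high):
        raise ParameterError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ParameterError(
            f"high={high} Hz must be below the Nyquist frequency {nyquist:.4g} Hz"
        )
    min_len = 3 * order * 2
    if ts.n_timepoints < min_len:
        raise ParameterError(
            f"need at least {min_len} time points for stable filtering, "
            f"got {ts.n_timepoints}"
        )

    detrended = sps.detrend(ts.values, axis=0, type="linear")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    filtered = sps.sosfiltfilt(sos, detrended, axis=0)

    sd = filtered.std(axis=0)
    dead = np.asarray(sd < 1e-12).nonzero()[0]
    if dead.size:
        raise ZeroVarianceError([ts.region_ids[i] for i in dead])

    z = (filtered - filtered.mean(axis=0)) / sd
    return replace(ts, values=z, preprocessed=True)


def exclude_nodes(
    ts: RoiTimeSeries, parc: pd.DataFrame, exclude_ids: list[str]
) -> tuple[RoiTimeSeries, pd.DataFrame]:
    """Drop the listed regions from a time series and its parcellation.

    Survivor order is preserved. Unknown ids raise; excluding every region
    raises (an empty matrix is not a valid analysis input).
    """
    exclude = [str(r) for r in exclude_ids]
    known = set(ts.region_ids)
    unknown = [r for r in exclude if r not in known]
    if unknown:
        raise ParameterError(f"unknown region ids in exclusion list: {unknown}")
    exclude_set = set(exclude)
    keep_idx = [i for i, r in enumerate(ts.region_ids) if r not in exclude_set]
    if not keep_idx:
        raise ParameterError("exclusion list removes every region")
    new_ts = replace(
        ts,
        values=ts.values[:, keep_idx],
        region_ids=[ts.region_ids[i] for i in keep_idx],
    )
    parc = validate_parcellation(parc)
    new_parc = parc[~parc["region_id"].isin(exclude_set)].reset_index(drop=True)
    return new_ts, new_parc


def align_to_regions(cm: CouplingMatrix, region_ids: list[str]) -> CouplingMatrix:
    """Reorder/subset a coupling matrix to match a region-id ordering."""
    region_ids = [str(r) for r in region_ids]
    pos = {r: i for i, r in enumerate(cm.region_ids)}
    missing = [r for r in region_ids if r not in pos]
    if missing:
        raise ParameterError(f"regions absent from coupling matrix: {missing}")
    idx = [pos[r] for r in region_ids]
    w = cm.weights[np.ix_(idx, idx)]
    return CouplingMatrix(w, region_ids, cm.directed, cm.kind)
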