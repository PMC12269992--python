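"""End-to-end study orchestration.

Runs the full analysis sequence on a synthetic two-cohort study:
simulate -> preprocess -> non-reversibility (global/network/node, with
cohort tests) -> generative effective connectivity (group pretraining +
per-subject fits) -> pattern separation (GEC vs FC vs SC, plus network
submodels) -> trophic hierarchy (levels, incoherence, flatness, regional
and pairwise comparisons, PageRank) -> machine-readable JSON report.

Every random procedure's seed is derived from the single study seed and
recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParameterError
from .group_stats import (
    clinical_correlations,
    lmm_contrast,
    pattern_separation,
    rank_tests,
)
from .hierarchy import (
    pagerank_centrality,
    pairwise_region_tests,
    regional_hierarchy,
    trophic_analysis,
)
from .hopf import HopfParameters, empirical_statistics, estimate_frequencies, fit_cohort
from .nonreversibility import compare_nonrev_distributions, nonreversibility
from .signal_io import preprocess
from .synthetic import SyntheticCohort, SyntheticCohortSpec, generate_cohort

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class StudyConfig:
    """All knobs of the synthetic study in one place."""

    synthetic: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    lag_tr: int = 1
    band: tuple[float, float] = (0.008, 0.08)
    a: float = -0.02
    sigma: float = 0.02
    eps: float = 0.0004
    eps_prime: float = 0.0001
    group_max_iter: int = 3000
    subject_max_iter: int = 1500
    n_permutations: int = 1000
    n_split_iterations: int = 1000
    loocv_permutations: int = 200
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if isinstance(syn, dict):
            if "band" in syn:
                syn["band"] = tuple(syn["band"])
            syn = SyntheticCohortSpec(**syn)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(synthetic=syn, **d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _gcr_to_dict(res) -> dict:
    return {
        "method": res.method,
        "statistic": None if np.isnan(res.statistic) else float(res.statistic),
        "p_value": None if np.isnan(res.p_value) else float(res.p_value),
        "direction": int(res.direction),
        "n_a": res.n_a,
        "n_b": res.n_b,
        **{
            k: (float(v) if isinstance(v, (int, float, np.number)) else v)
            for k, v in res.extra.items()
        },
    }


def _upper_triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _off_diagonal(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    return m[~np.eye(n, dtype=bool)]


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Execute the full synthetic study; return (and optionally write) the report."""
    rng = np.random.default_rng(config.seed)
    seeds = {
        "study": config.seed,
        "cohort_generation": int(config.synthetic.seed),
        "mmd_energy": int(rng.integers(2**31)),
        "pattern_separation": int(rng.integers(2**31)),
        "loocv": int(rng.integers(2**31)),
    }
    stage = {"name": "simulate"}
    try:
        cohort = generate_cohort(config.synthetic)
        report = _analyse(config, cohort, seeds, stage)
    except Exception as exc:
        raise RuntimeError(
            f"study failed at stage {stage['name']!r}: {exc}"
        ) from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _analyse(config: StudyConfig, cohort: SyntheticCohort, seeds: dict,
             stage: dict | None = None) -> dict:
    stage = stage if stage is not None else {"name": "analyse"}
    spec = cohort.spec
    lag = config.lag_tr
    parc = cohort.parcellation
    table = cohort.cohort_table
    by_cohort = {
        name: list(table.loc[table["cohort"] == name, "subject_id"])
        for name in ("control", "patient")
    }

    # ---- preprocessing -------------------------------------------------
    stage["name"] = "preprocess"
    clean = {
        sid: preprocess(ts, *config.band) for sid, ts in cohort.timeseries.items()
    }

    # ---- non-reversibility --------------------------------------------
    stage["name"] = "nonreversibility"
    nonrev = {sid: nonreversibility(ts, lag, parc) for sid, ts in clean.items()}
    global_by = {
        name: np.array([nonrev[s].global_value for s in sids])
        for name, sids in by_cohort.items()
    }
    network_names = sorted(next(iter(nonrev.values())).network_values)
    network_by = {
        net: {
            name: np.array([nonrev[s].network_values[net] for s in sids])
            for name, sids in by_cohort.items()
        }
        for net in network_names
    }
    node_by = {
        name: np.vstack([nonrev[s].node_values for s in sids])
        for name, sids in by_cohort.items()
    }

    nonrev_report = {
        "global": {
            "patient_mean": float(global_by["patient"].mean()),
            "control_mean": float(global_by["control"].mean()),
            "ranksum_two_sided": _gcr_to_dict(
                rank_tests(global_by["patient"], global_by["control"])
            ),
            "ranksum_patient_greater": _gcr_to_dict(
                rank_tests(global_by["patient"], global_by["control"],
                           alternative="greater")
            ),
        },
        "network": {
            net: {
                "patient_mean": float(vals["patient"].mean()),
                "control_mean": float(vals["control"].mean()),
                "ranksum_two_sided": _gcr_to_dict(
                    rank_tests(vals["patient"], vals["control"])
                ),
            }
            for net, vals in network_by.items()
        },
    }

    # node-level mixed model
    meta = table.set_index("subject_id")
    long_rows = []
    for name, sids in by_cohort.items():
        for s in sids:
            for val in nonrev[s].node_values:
                long_rows.append(
                    {
                        "subject": s,
                        "value": float(val),
                        "cohort": name,
                        "age": float(meta.loc[s, "age"]),
                        "sex": str(meta.loc[s, "sex"]),
                    }
                )
    nonrev_report["node_lmm"] = _gcr_to_dict(lmm_contrast(pd.DataFrame(long_rows)))

    dist = compare_nonrev_distributions(
        node_by["patient"], node_by["control"],
        n_perm=config.n_permutations, seed=seeds["mmd_energy"],
    )
    nonrev_report["node_distribution"] = {
        k: _gcr_to_dict(v) for k, v in dist.items()
    }

    # Brown-Forsythe on subject-averaged node values (variance comparison)
    nonrev_report["node_variance_brownforsythe"] = _gcr_to_dict(
        rank_tests(node_by["patient"].mean(axis=0),
                   node_by["control"].mean(axis=0), kind="brownforsythe")
    )

    # clinical correlations (placeholder scores; exercises the interface)
    patients = table[table["cohort"] == "patient"]
    clin = None
    if patients["updrs3"].notna().all() and len(patients) >= 5:
        idx = list(patients["subject_id"])
        measures = {
            "global_nonrev": np.array([nonrev[s].global_value for s in idx])
        }
        for net in network_names:
            measures[f"{net}_nonrev"] = np.array(
                [nonrev[s].network_values[net] for s in idx]
            )
        clin = clinical_correlations(
            measures, patients["updrs3"].to_numpy(float)
        ).to_dict(orient="records")
    nonrev_report["clinical_correlations"] = clin

    # ---- GEC fitting ---------------------------------------------------
    stage["name"] = "gec"
    omega = estimate_frequencies(list(clean.values()), config.band)
    params = HopfParameters(
        np.full(spec.n_nodes, config.a), omega, config.sigma, spec.tr
    )
    emp = {sid: empirical_statistics(ts, lag) for sid, ts in clean.items()}
    lag_seconds = lag * spec.tr

    gec_models = {}
    gec_report = {"group_fits": {}}
    for name, sids in by_cohort.items():
        group, models = fit_cohort(
            [emp[s] for s in sids], cohort.sc_mask, params, lag_seconds,
            eps=config.eps, eps_prime=config.eps_prime,
            group_max_iter=config.group_max_iter,
            subject_max_iter=config.subject_max_iter,
        )
        gec_report["group_fits"][name] = {
            "final_error": float(group.fit_error_trace.min()),
            "initial_error": float(group.fit_error_trace[0]),
            "iterations": int(group.iterations_run),
            "converged": bool(group.converged),
        }
        for s, m in zip(sids, models):
            gec_models[s] = m

    strengths = {
        s: m.coupling.weights.sum(axis=0) + m.coupling.weights.sum(axis=1)
        for s, m in gec_models.items()
    }
    strength_rows = []
    for name, sids in by_cohort.items():
        for s in sids:
            for val in strengths[s]:
                strength_rows.append(
                    {
                        "subject": s, "value": float(val), "cohort": name,
                        "age": float(meta.loc[s, "age"]),
                        "sex": str(meta.loc[s, "sex"]),
                    }
                )
    gec_report["node_strength_lmm"] = _gcr_to_dict(
        lmm_contrast(pd.DataFrame(strength_rows))
    )

    # ---- pattern separation -------------------------------------------
    stage["name"] = "pattern_separation"
    mask_off = cohort.sc_mask.weights > 0

    def gec_features(sids, node_subset=None):
        feats = []
        for s in sids:
            W = gec_models[s].coupling.weights
            if node_subset is not None:
                W = W[np.ix_(node_subset, node_subset)]
            feats.append(_off_diagonal(W))
        return np.vstack(feats)

    def fc_features(sids, node_subset=None):
        feats = []
        for s in sids:
            m = emp[s].fc
            if node_subset is not None:
                m = m[np.ix_(node_subset, node_subset)]
            feats.append(_upper_triangle(m))
        return np.vstack(feats)

    def sc_features(sids):
        return np.vstack(
            [_upper_triangle(cohort.structural[s].weights) for s in sids]
        )

    ps_seed = seeds["pattern_separation"]
    sep_report = {}
    for label, builder in (
        ("GEC", gec_features), ("FC", fc_features), ("SC", lambda s: sc_features(s))
    ):
        res = pattern_separation(
            builder(by_cohort["patient"]), builder(by_cohort["control"]),
            protocol="split_cv", seed=ps_seed,
            n_iterations=config.n_split_iterations,
        )
        sep_report[label] = {
            "mean_accuracy": res.mean_accuracy,
            "protocol": res.protocol,
        }

    node_order = {r: i for i, r in enumerate(cohort.sc_mask.region_ids)}
    for net in ("BTC", "CTC", "none"):
        subset = [
            node_order[r]
            for r in parc.loc[parc["network"] == net, "region_id"]
        ]
        if len(subset) < 3:
            continue
        res = pattern_separation(
            gec_features(by_cohort["patient"], subset),
            gec_features(by_cohort["control"], subset),
            protocol="split_cv", seed=ps_seed,
            n_iterations=config.n_split_iterations,
        )
        key = f"GEC_{net}" if net != "none" else "GEC_no_network"
        sep_report[key] = {
            "mean_accuracy": res.mean_accuracy,
            "protocol": res.protocol,
        }

    if config.loocv_permutations > 0:
        loocv = pattern_separation(
            gec_features(by_cohort["patient"]), gec_features(by_cohort["control"]),
            protocol="loocv_permutation", seed=seeds["loocv"],
            n_permutations=config.loocv_permutations,
        )
        sep_report["GEC_loocv"] = {
            "accuracy": loocv.mean_accuracy,
            "permutation_p": loocv.permutation_p,
            "n_permutations": loocv.n_permutations,
        }

    # ---- hierarchy -----------------------------------------------------
    stage["name"] = "hierarchy"
    troph = {s: trophic_analysis(m.coupling) for s, m in gec_models.items()}
    regional = {
        s: regional_hierarchy(t, parc, region_ids=cohort.sc_mask.region_ids)
        for s, t in troph.items()
    }
    coher_by = {
        name: np.array([troph[s].coherence for s in sids])
        for name, sids in by_cohort.items()
    }
    flat_by = {
        name: np.array([regional[s].flatness for s in sids])
        for name, sids in by_cohort.items()
    }
    hier_report = {
        "coherence": {
            "patient_mean": float(coher_by["patient"].mean()),
            "control_mean": float(coher_by["control"].mean()),
            "ranksum": _gcr_to_dict(
                rank_tests(coher_by["patient"], coher_by["control"])
            ),
        },
        "flatness": {
            "patient_mean": float(flat_by["patient"].mean()),
            "control_mean": float(flat_by["control"].mean()),
            "mannwhitney": _gcr_to_dict(
                rank_tests(flat_by["patient"], flat_by["control"],
                           kind="mannwhitney")
            ),
            "brownforsythe": _gcr_to_dict(
                rank_tests(flat_by["patient"], flat_by["control"],
                           kind="brownforsythe")
            ),
        },
        "regional_means": {
            name: {
                g: float(np.mean([regional[s].group_means[g] for s in sids]))
                for g in regional[sids[0]].group_means
            }
            for name, sids in by_cohort.items()
        },
        "pairwise_regional": {
            name: {
                "neg_log10_p": pairwise_region_tests(
                    [regional[s] for s in sids]
                )["neg_log10_p"].to_dict()
            }
            for name, sids in by_cohort.items()
        },
        "pagerank": {
            name: pagerank_centrality(
                np.mean(
                    [gec_models[s].coupling.weights for s in sids], axis=0
                ).T  # edge orientation
            ).tolist()
            for name, sids in by_cohort.items()
        },
    }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seeds": seeds,
        "config": _config_to_dict(config),
        "nonreversibility": nonrev_report,
        "gec": gec_report,
        "pattern_separation": sep_report,
        "hierarchy": hier_report,
    }
    return report


def _config_to_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["band"] = list(d["band"])
    d["synthetic"]["band"] = list(d["synthetic"]["band"])
    return d
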