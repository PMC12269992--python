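"""Trophic hierarchy of the fitted directed GEC graphs.

Computes per-subject hierarchy levels, incoherence F0 (coherence = 1 - F0),
flatness (SD of levels), regional aggregation, pairwise regional
comparisons, and PageRank centrality; compares cohorts. Reads GEC matrices
from results/gec/, writes summaries under results/hierarchy/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from brainarrow.group_stats import rank_tests
from brainarrow.hierarchy import (
    pagerank_centrality,
    pairwise_region_tests,
    regional_hierarchy,
    trophic_analysis,
)
from brainarrow.signal_io import read_cohort, read_coupling, read_parcellation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--gec-dir", type=Path, default=Path("results/gec"))
    ap.add_argument("--out", type=Path, default=Path("results/hierarchy"))
    args = ap.parse_args()

    table = read_cohort(args.cohort_dir / "cohort.tsv")
    parc = read_parcellation(args.cohort_dir / "parcellation.tsv")
    args.out.mkdir(parents=True, exist_ok=True)

    rows, regional, levels = [], {}, {}
    for sid, cohort in zip(table.subject_id, table.cohort):
        gec = read_coupling(args.gec_dir / f"{sid}.tsv", kind="GEC")
        tro = trophic_analysis(gec)
        reg = regional_hierarchy(tro, parc, region_ids=gec.region_ids)
        regional.setdefault(cohort, []).append(reg)
        levels[sid] = tro.levels
        rows.append({"subject_id": sid, "cohort": cohort,
                     "coherence": tro.coherence, "flatness": reg.flatness})
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "subject_hierarchy.tsv", sep="\t", index=False)
    pd.DataFrame(levels).to_csv(args.out / "levels.tsv", sep="\t", index=False)

    pat, ctl = df[df.cohort == "patient"], df[df.cohort == "control"]
    for col in ("coherence", "flatness"):
        r = rank_tests(pat[col], ctl[col], kind="mannwhitney")
        print(f"{col}: patient {pat[col].mean():.4f} vs control "
              f"{ctl[col].mean():.4f}, Mann-Whitney p = {r.p_value:.4g}")

    for cohort, regs in regional.items():
        mats = pairwise_region_tests(regs)
        mats["neg_log10_p"].to_csv(args.out / f"pairwise_{cohort}.tsv", sep="\t")
        sig = (mats["p_adjusted"] < 0.05).to_numpy()
        print(f"{cohort}: {np.nansum(sig) // 2:.0f} significant regional pairs "
              f"(BH-FDR < 0.05)")

    for cohort in ("control", "patient"):
        sids = table.loc[table.cohort == cohort, "subject_id"]
        mean_gec = np.mean(
            [read_coupling(args.gec_dir / f"{s}.tsv", kind="GEC").weights
             for s in sids], axis=0)
        pr = pagerank_centrality(mean_gec.T)
        np.savetxt(args.out / f"pagerank_{cohort}.tsv", pr, delimiter="\t")


if __name__ == "__main__":
    main()
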