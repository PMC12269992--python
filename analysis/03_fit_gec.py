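"""Fit generative effective connectivity (GEC) for every subject.

Estimates node intrinsic frequencies from the cohort spectra, computes each
subject's empirical FC and lagged covariance, pretrains a group-mean
coupling per cohort, then fits each subject initialized at its group
solution. Writes fitted GEC matrices under results/gec/.
"""

import argparse
from pathlib import Path

import numpy as np

from brainarrow.hopf import (
    HopfParameters,
    empirical_statistics,
    estimate_frequencies,
    fit_cohort,
)
from brainarrow.signal_io import (
    preprocess,
    read_cohort,
    read_coupling,
    read_timeseries,
    write_coupling,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--tr", type=float, default=2.2)
    ap.add_argument("--lag-tr", type=int, default=1)
    ap.add_argument("--a", type=float, default=-0.02)
    ap.add_argument("--sigma", type=float, default=0.02)
    ap.add_argument("--eps", type=float, default=4e-4)
    ap.add_argument("--eps-prime", type=float, default=1e-4)
    ap.add_argument("--max-iter", type=int, default=1500)
    ap.add_argument("--out", type=Path, default=Path("results/gec"))
    args = ap.parse_args()

    table = read_cohort(args.cohort_dir / "cohort.tsv")
    mask = read_coupling(args.cohort_dir / "sc_mask.tsv", kind="SC")
    clean = {
        sid: preprocess(read_timeseries(
            args.cohort_dir / "timeseries" / f"{sid}.tsv", tr=args.tr,
            subject_id=sid))
        for sid in table["subject_id"]
    }
    omega = estimate_frequencies(list(clean.values()))
    params = HopfParameters(np.full(mask.n_regions, args.a), omega,
                            args.sigma, args.tr)
    args.out.mkdir(parents=True, exist_ok=True)

    for cohort in ("control", "patient"):
        sids = list(table.loc[table.cohort == cohort, "subject_id"])
        stats = [empirical_statistics(clean[s], args.lag_tr) for s in sids]
        group, models = fit_cohort(
            stats, mask, params, args.lag_tr * args.tr,
            eps=args.eps, eps_prime=args.eps_prime,
            group_max_iter=2 * args.max_iter, subject_max_iter=args.max_iter,
        )
        write_coupling(group.coupling, args.out / f"group_{cohort}.tsv")
        for sid, m in zip(sids, models):
            write_coupling(m.coupling, args.out / f"{sid}.tsv")
        print(f"{cohort}: group fit error "
              f"{group.fit_error_trace[0]:.3f} -> {group.fit_error_trace.min():.3f} "
              f"({group.iterations_run} iterations, converged={group.converged}); "
              f"{len(models)} subject fits written")


if __name__ == "__main__":
    main()
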