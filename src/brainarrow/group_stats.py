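"""Cohort-level statistics.

Rank tests, random-intercept mixed-model contrasts, kernel (MMD^2) and
energy-distance permutation tests, Benjamini-Hochberg FDR, MAD outlier
screening, Spearman clinical correlations, and linear-SVM pattern
separation. Permutation p-values always use the add-one formula
p = (1 + #{perm >= observed}) / (1 + n_perm) and are reproducible under a
fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class GroupComparisonResult:
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None
    direction: int = 0  # sign of (group a - group b) effect
    extra: dict = field(default_factory=dict)


@dataclass
class PatternSeparationResult:
    mean_accuracy: float
    fold_accuracies: np.ndarray
    protocol: str
    n_permutations: int = 0
    permutation_p: float | None = None


# ---------------------------------------------------------------------------
# Rank tests and mixed models
# ---------------------------------------------------------------------------


def rank_tests(values_a, values_b, kind: str = "wilcoxon",
               alternative: str = "two-sided") -> GroupComparisonResult:
    """Two-sample rank test between cohorts.

    ``wilcoxon`` and ``mannwhitney`` both run the rank-sum / Mann-Whitney U
    test (the two are equivalent), exact when the data are tie-free and
    small; ``brownforsythe`` tests variance equality via absolute deviations
    from group medians.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise ParameterError("need at least 3 values per group")
    direction = int(np.sign(np.median(a) - np.median(b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("all values tied; p set to 1")
        return GroupComparisonResult(kind, 0.0, 1.0, a.size, b.size,
                                     direction=0)
    if kind in ("wilcoxon", "mannwhitney"):
        res = sst.mannwhitneyu(a, b, alternative=alternative, method="auto")
        return GroupComparisonResult(kind, float(res.statistic),
                                     float(res.pvalue), a.size, b.size,
                                     direction=direction)
    if kind == "brownforsythe":
        res = sst.levene(a, b, center="median")
        direction = int(np.sign(
            np.var(a, ddof=1) - np.var(b, ddof=1)
        ))
        return GroupComparisonResult(kind, float(res.statistic),
                                     float(res.pvalue), a.size, b.size,
                                     direction=direction)
    raise ParameterError(f"unknown rank test kind {kind!r}")


def lmm_contrast(table: pd.DataFrame) -> GroupComparisonResult:
    """Cohort contrast from a random-intercept linear mixed model.

    ``table`` is long-format with columns subject, value, cohort, age, sex;
    the model is value ~ cohort + age + sex with a subject random
    intercept. The cohort fixed effect is reported with its normal-
    approximation p-value. With a single value per subject the model
    collapses to ordinary covariate-adjusted regression; a singular mixed
    fit falls back to a model on subject means.
    """
    import statsmodels.formula.api as smf

    required = {"subject", "value", "cohort", "age", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"long table missing columns: {sorted(missing)}")
    df = table.copy()
    cohorts = sorted(df["cohort"].unique())
    if len(cohorts) != 2:
        raise ParameterError("need exactly two cohorts")
    # code patient (or lexicographically later level) as 1
    ref = "control" if "control" in cohorts else cohorts[0]
    other = [c for c in cohorts if c != ref][0]
    df["cohort_num"] = (df["cohort"] == other).astype(float)
    df["sex_num"] = pd.factorize(df["sex"])[0].astype(float)

    per_subject = df.groupby("subject").size()
    formula = "value ~ cohort_num + age + sex_num"

    def _ols_on_means():
        means = df.groupby("subject").agg(
            value=("value", "mean"), cohort_num=("cohort_num", "first"),
            age=("age", "first"), sex_num=("sex_num", "first"),
        )
        fit = smf.ols(formula, data=means).fit()
        return fit

    if per_subject.max() == 1:
        fit = _ols_on_means()
        method = "ols"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=df, groups=df["subject"])
                fit = model.fit(reml=True)
            if not np.isfinite(fit.bse["cohort_num"]) or fit.bse["cohort_num"] == 0:
                raise np.linalg.LinAlgError("degenerate SE")
            method = "lmm"
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("singular mixed fit; falling back to subject-mean OLS")
            fit = _ols_on_means()
            method = "ols_fallback"

    est = float(fit.params["cohort_num"])
    se = float(fit.bse["cohort_num"])
    tval = est / se if se > 0 else np.nan
    if method == "lmm":
        pval = float(2 * sst.norm.sf(abs(tval)))
    else:
        pval = float(fit.pvalues["cohort_num"])
    return GroupComparisonResult(
        method, tval, pval,
        n_a=int((df.groupby("subject")["cohort_num"].first() == 1).sum()),
        n_b=int((df.groupby("subject")["cohort_num"].first() == 0).sum()),
        direction=int(np.sign(est)),
        extra={"estimate": est, "se": se, "contrast": f"{other} - {ref}"},
    )


# ---------------------------------------------------------------------------
# Distributional two-sample tests
# ---------------------------------------------------------------------------


def _perm_pvalue(observed: float, null: np.ndarray) -> float:
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _check_two_sample(X, Y):
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[1] != Y.shape[1]:
        raise ParameterError("feature dimensions differ between samples")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ParameterError("need >= 2 observations per sample")
    return X, Y


def _mmd2_unbiased(K: np.ndarray, n_a: int) -> float:
    Kxx = K[:n_a, :n_a]
    Kyy = K[n_a:, n_a:]
    Kxy = K[:n_a, n_a:]
    m = n_a
    n = K.shape[0] - n_a
    term_x = (Kxx.sum() - np.trace(Kxx)) / (m * (m - 1))
    term_y = (Kyy.sum() - np.trace(Kyy)) / (n * (n - 1))
    return float(term_x + term_y - 2 * Kxy.mean())


def mmd2_test(X, Y, n_perm: int = 1000, seed: int | None = None) -> GroupComparisonResult:
    """Unbiased squared maximum mean discrepancy with a permutation null.

    Gaussian kernel k(x, y) = exp(-||x-y||^2 / (2 s^2)) with s the median
    pairwise Euclidean distance of the pooled sample (mean fallback when the
    median is zero). The kernel matrix is computed once on the pooled data
    and rows/columns are permuted for the null.
    """
    X, Y = _check_two_sample(X, Y)
    pooled = np.vstack([X, Y])
    d = pdist(pooled)
    bw = np.median(d)
    if bw <= 0:
        logger.warning("zero median pairwise distance; using mean distance")
        bw = d.mean()
        if bw <= 0:
            raise ParameterError("all observations identical; MMD degenerate")
    K = np.exp(-squareform(d) ** 2 / (2 * bw**2))
    np.fill_diagonal(K, 1.0)
    n_a = X.shape[0]
    observed = _mmd2_unbiased(K, n_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(K.shape[0])
    for i in range(n_perm):
        perm = rng.permutation(idx)
        null[i] = _mmd2_unbiased(K[np.ix_(perm, perm)], n_a)
    return GroupComparisonResult(
        "mmd2", observed, _perm_pvalue(observed, null),
        n_a, Y.shape[0], extra={"bandwidth": float(bw)},
    )


def _energy_stat(D: np.ndarray, n_a: int) -> float:
    Dxx = D[:n_a, :n_a]
    Dyy = D[n_a:, n_a:]
    Dxy = D[:n_a, n_a:]
    return float(2 * Dxy.mean() - Dxx.mean() - Dyy.mean())


def energy_test(X, Y, n_perm: int = 1000, seed: int | None = None) -> GroupComparisonResult:
    """Euclidean energy-distance two-sample statistic with permutation null."""
    X, Y = _check_two_sample(X, Y)
    pooled = np.vstack([X, Y])
    D = squareform(pdist(pooled))
    n_a = X.shape[0]
    observed = _energy_stat(D, n_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(D.shape[0])
    for i in range(n_perm):
        perm = rng.permutation(idx)
        null[i] = _energy_stat(D[np.ix_(perm, perm)], n_a)
    return GroupComparisonResult(
        "energy", observed, _perm_pvalue(observed, null), n_a, Y.shape[0]
    )


# ---------------------------------------------------------------------------
# Multiplicity, screening, correlations
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def mad_screen(values, k: float = 3.0) -> np.ndarray:
    """Inlier mask from the median-absolute-deviation rule.

    Flags x with |x - median| > k * 1.4826 * MAD. Returns True for inliers.
    A zero MAD flags nothing (with a warning).
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ParameterError("need at least 3 values for MAD screening")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        logger.warning("MAD is zero; no outliers flagged")
        return np.ones(x.size, dtype=bool)
    return np.abs(x - med) <= k * 1.4826 * mad


def clinical_correlation(measure, score) -> GroupComparisonResult:
    """Spearman rank correlation between one measure and one clinical score."""
    m = np.asarray(measure, float)
    s = np.asarray(score, float)
    if m.size != s.size:
        raise ParameterError("measure and score must be paired")
    if m.size < 5:
        raise ParameterError("need at least 5 paired subjects")
    if np.all(s == s[0]) or np.all(m == m[0]):
        logger.warning("constant input; Spearman rho undefined")
        return GroupComparisonResult("spearman", np.nan, np.nan, m.size, m.size)
    rho, p = sst.spearmanr(m, s)
    return GroupComparisonResult("spearman", float(rho), float(p),
                                 m.size, m.size, direction=int(np.sign(rho)))


def clinical_correlations(measures: dict[str, np.ndarray], score) -> pd.DataFrame:
    """Spearman correlations for a family of measures, BH-FDR corrected."""
    rows = []
    for name, m in measures.items():
        res = clinical_correlation(m, score)
        rows.append({"measure": name, "rho": res.statistic, "p": res.p_value})
    df = pd.DataFrame(rows)
    valid = df["p"].notna()
    df["p_adjusted"] = np.nan
    if valid.any():
        df.loc[valid, "p_adjusted"] = bh_fdr(df.loc[valid, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Pattern separation
# ---------------------------------------------------------------------------


def _make_classifier():
    # per-feature standardization is fit on training folds only (pipeline)
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def pattern_separation(
    features_a,
    features_b,
    protocol: str = "split_cv",
    seed: int | None = None,
    n_iterations: int = 1000,
    test_size: float = 0.15,
    n_components: int = 20,
    n_permutations: int = 1000,
    label_swap_fraction: float | None = None,
) -> PatternSeparationResult:
    """Linear-SVM separation of two cohorts' connectivity features.

    ``split_cv``: repeated stratified random 85/15 splits; the accuracy per
    split is recorded and averaged. ``loocv_permutation``: features are
    projected onto principal components fit on training folds, accuracy is
    leave-one-out, and significance comes from label-shuffle permutations
    (add-one p). ``label_swap_fraction`` additionally reports the accuracy
    after randomly swapping that fraction of labels (robustness check).

    This quantifies how separable the two groups' patterns are; it makes no
    claim of generalizable classification.
    """
    Xa = np.atleast_2d(np.asarray(features_a, float))
    Xb = np.atleast_2d(np.asarray(features_b, float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ParameterError("feature dimensions differ between cohorts")
    if Xa.shape[0] < 4 or Xb.shape[0] < 4:
        raise ParameterError("need >= 4 subjects per class")
    X = np.vstack([Xa, Xb])
    y = np.concatenate([np.zeros(Xa.shape[0]), np.ones(Xb.shape[0])])
    rng = np.random.default_rng(seed)

    if label_swap_fraction:
        n_swap = int(round(label_swap_fraction * y.size))
        swap_idx = rng.choice(y.size, size=n_swap, replace=False)
        y = y.copy()
        y[swap_idx] = 1 - y[swap_idx]

    if protocol == "split_cv":
        accs = np.empty(n_iterations)
        n_test = max(2, int(round(test_size * y.size)))
        min_per_class = 2 if n_test >= 4 else 1
        for i in range(n_iterations):
            for _attempt in range(100):
                splitter = StratifiedShuffleSplit(
                    n_splits=1, test_size=test_size,
                    random_state=int(rng.integers(2**31)),
                )
                train, test = next(splitter.split(X, y))
                counts = np.bincount(y[test].astype(int), minlength=2)
                if counts.min() >= min_per_class:
                    break
            clf = _make_classifier()
            clf.fit(X[train], y[train])
            accs[i] = float(np.mean(clf.predict(X[test]) == y[test]))
        return PatternSeparationResult(float(accs.mean()), accs, protocol)

    if protocol == "loocv_permutation":
        def loocv_accuracy(labels: np.ndarray) -> float:
            hits = 0
            for i in range(X.shape[0]):
                train = np.ones(X.shape[0], dtype=bool)
                train[i] = False
                if len(np.unique(labels[train])) < 2:
                    continue
                k = min(n_components, train.sum() - 1, X.shape[1])
                clf = make_pipeline(
                    StandardScaler(), PCA(n_components=k),
                    SVC(kernel="linear", C=1.0),
                )
                clf.fit(X[train], labels[train])
                hits += int(clf.predict(X[i:i + 1])[0] == labels[i])
            return hits / X.shape[0]

        observed = loocv_accuracy(y)
        null = np.empty(n_permutations)
        for p in range(n_permutations):
            null[p] = loocv_accuracy(rng.permutation(y))
        pval = _perm_pvalue(observed, null)
        return PatternSeparationResult(
            observed, np.asarray([observed]), protocol,
            n_permutations=n_permutations, permutation_p=pval,
        )

    raise ParameterError(f"unknown protocol {protocol!r}")
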