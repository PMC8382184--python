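"""Group statistics: rank tests, the nNI bootstrap null, FDR, and MVPA.

All group comparisons are non-parametric. Pairwise comparisons use the
Mann-Whitney U test, reported with a tie-corrected, continuity-corrected
normal z-score as the effect size. Paired comparisons across conditions use
the Friedman test (tie-corrected). To ask which ROIs drive seizures beyond a
homogeneous baseline, per-ROI median nNI values are compared against a
bootstrap null in which nNI entries are resampled with replacement from the
pooled participant x ROI matrix, destroying any ROI effect; p-values are
controlled with the Benjamini-Hochberg FDR procedure. Spatial NI/nNI
profiles are compared between groups with multivariate pattern analysis:
unregularized logistic regression, stratified 5-fold cross-validated AUC
averaged over 20 repetitions, and permutation testing that reuses the exact
same folds for every label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from ._rng import derive_seed

__all__ = [
    "RankTestResult",
    "BootstrapNNIResult",
    "MVPAResult",
    "mann_whitney",
    "friedman",
    "nni_bootstrap",
    "bh_fdr",
    "mvpa_auc",
    "mvpa_permutation",
]


@dataclass(frozen=True)
class RankTestResult:
    u: float
    z: float
    p: float
    n_x: int
    n_y: int


@dataclass(frozen=True)
class BootstrapNNIResult:
    z_per_roi: np.ndarray
    p_per_roi: np.ndarray
    q_per_roi: np.ndarray
    significant: np.ndarray
    null_medians: np.ndarray
    n_boot: int
    observed_medians: np.ndarray


@dataclass(frozen=True)
class MVPAResult:
    auc_mean: float
    auc_sd: float
    aucs: np.ndarray  # (n_reps, n_folds)
    folds: np.ndarray  # (n_reps, n_subjects) fold index per subject
    n_folds: int
    n_reps: int


def mann_whitney(x, y) -> RankTestResult:
    """Mann-Whitney U of ``x`` (first sample) vs ``y``, with effect size.

    U counts pairs where x > y (ties count half). The z-score uses midranks,
    the tie-corrected variance, and a 0.5 continuity correction toward the
    mean; p is two-sided (exact enumeration for small tie-free samples via
    scipy, normal approximation otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = x.size, y.size

    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        z = 0.0
    else:
        cc = 0.5 * np.sign(u - mu)
        z = (u - mu - cc) / np.sqrt(var)

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return RankTestResult(u=float(u), z=float(z), p=float(res.pvalue), n_x=n1, n_y=n2)


def friedman(matrix) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square over a participants x conditions
    matrix; df = conditions - 1. Returns (chi2, p)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    denom = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if denom == 0:  # every row fully tied
        return 0.0, 1.0
    chi2 = numer / denom
    return float(chi2), float(sps.chi2.sf(chi2, k - 1))


def bh_fdr(p, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; mask = adjusted <= q_level."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return adjusted, adjusted <= q_level


def nni_bootstrap(
    nni: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
    q_level: float = 0.05,
    alternative: str = "greater",
    chunk: int = 500,
) -> BootstrapNNIResult:
    """Bootstrap test of per-ROI median nNI against a homogeneous null.

    ``n_boot`` surrogate matrices of the original shape are sampled with
    replacement from the pooled entries (destroying any ROI effect); every
    surrogate contributes all of its per-ROI medians to one pooled null
    distribution (ROIs are exchangeable under pooled resampling). The
    one-sided p-value per ROI uses the add-one convention; z-scores are
    against the null's mean and SD; BH FDR is applied across ROIs.
    ``alternative='two-sided'`` doubles the smaller tail.
    """
    m = np.asarray(nni, dtype=float)
    if m.ndim != 2:
        raise ValueError("nni must be a participants x ROIs matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("nni contains missing or non-finite entries")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a very coarse null")
    n_part, n_roi = m.shape
    pooled = m.ravel()
    rng = np.random.default_rng(seed)

    null_meds = np.empty((n_boot, n_roi))
    done = 0
    while done < n_boot:
        c = min(chunk, n_boot - done)
        idx = rng.integers(0, pooled.size, size=(c, n_part, n_roi))
        null_meds[done : done + c] = np.median(pooled[idx], axis=1)
        done += c
    null_pool = np.sort(null_meds.ravel())

    observed = np.median(m, axis=0)
    # one-sided (high median drives seizures), add-one convention
    ge = null_pool.size - np.searchsorted(null_pool, observed, side="left")
    p_high = (1.0 + ge) / (1.0 + null_pool.size)
    if alternative == "greater":
        p = p_high
    elif alternative == "two-sided":
        le = np.searchsorted(null_pool, observed, side="right")
        p_low = (1.0 + le) / (1.0 + null_pool.size)
        p = np.minimum(1.0, 2.0 * np.minimum(p_high, p_low))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    sd = null_pool.std()
    z = (observed - null_pool.mean()) / sd if sd > 0 else np.zeros(n_roi)
    q, sig = bh_fdr(p, q_level)
    return BootstrapNNIResult(
        z_per_roi=z,
        p_per_roi=p,
        q_per_roi=q,
        significant=sig,
        null_medians=null_meds,
        n_boot=n_boot,
        observed_medians=observed,
    )


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    return (labels == classes[1]).astype(int)


def _make_folds(y: np.ndarray, n_folds: int, n_reps: int, seed: int | None) -> np.ndarray:
    """Stratified fold assignments, shape (n_reps, n_subjects)."""
    folds = np.empty((n_reps, y.size), dtype=int)
    for rep in range(n_reps):
        rs = None if seed is None else derive_seed(seed, "fold", rep)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
            folds[rep, test_idx] = f
    return folds


def _auc_over_folds(
    x: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    n_folds: int,
    on_degenerate: str = "raise",
) -> np.ndarray:
    """Cross-validated AUC for fixed fold assignments; (n_reps, n_folds).

    ``on_degenerate='chance'`` scores a single-class fold as AUC 0.5 instead
    of raising (folds are stratified on the *original* labels, so permuted
    labels can occasionally leave a fold single-class).
    """
    n_reps = folds.shape[0]
    aucs = np.empty((n_reps, n_folds))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs on separable data
        for rep in range(n_reps):
            for f in range(n_folds):
                test = folds[rep] == f
                train = ~test
                if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
                    if on_degenerate == "chance":
                        aucs[rep, f] = 0.5
                        continue
                    raise ValueError("single-class fold; need more subjects per class")
                clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
                clf.fit(x[train], y[train])
                scores = clf.decision_function(x[test])
                aucs[rep, f] = roc_auc_score(y[test], scores)
    return aucs


def mvpa_auc(
    features,
    labels,
    n_folds: int = 5,
    n_reps: int = 20,
    seed: int | None = None,
) -> MVPAResult:
    """Cross-validated MVPA of group labels from spatial feature profiles.

    Unregularized logistic regression; AUC is averaged over stratified folds
    and repetitions, with the SD across all folds and repetitions. Fold
    assignments are recorded so permutation testing can reuse them.
    """
    x = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    folds = _make_folds(y, n_folds, n_reps, seed)
    aucs = _auc_over_folds(x, y, folds, n_folds)
    return MVPAResult(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)),
        aucs=aucs,
        folds=folds,
        n_folds=n_folds,
        n_reps=n_reps,
    )


def mvpa_permutation(
    features,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    n_folds: int = 5,
    n_reps: int = 20,
    result: MVPAResult | None = None,
) -> tuple[float, MVPAResult]:
    """Permutation p-value for the MVPA AUC.

    Labels are permuted ``n_perm`` times; every permutation is evaluated with
    the SAME cross-validation folds and repetitions as the observed statistic
    (so the degree of overfitting is matched), and
    p = (1 + #{perm AUC >= observed}) / (1 + n_perm).
    """
    x = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    if result is None:
        result = mvpa_auc(features, labels, n_folds, n_reps, seed)
    rng = np.random.default_rng(None if seed is None else derive_seed(seed, "perm"))
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        aucs = _auc_over_folds(x, y_perm, result.folds, result.n_folds, on_degenerate="chance")
        if aucs.mean() >= result.auc_mean:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return p, result
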