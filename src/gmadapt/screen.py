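"""Species filtering and the cross-validated response-prediction screen.

Per-species univariate logistic models are scored by repeated stratified
k-fold AUROC (out-of-fold scores pooled within each repeat, averaged
across repeats); p-values come from a Mann-Whitney comparison of the
cross-validated scores, confidence intervals from a stratified subject
bootstrap, and an L1-regularised multivariate model provides a
complementary selection.  Fold splits are shared across species within a
repeat so AUROCs are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from . import stats

logger = logging.getLogger(__name__)

RIDGE = 1e-6  # tiny L2 on the slope: keeps Newton finite under separation


@dataclass(frozen=True)
class FilterCriteria:
    """Abundance/prevalence gate applied to pre-training samples."""

    min_mean_ra: float = 0.0005
    min_prevalence: float = 0.8
    detection_threshold: float = 0.0

    def __post_init__(self) -> None:
        for name in ("min_mean_ra", "min_prevalence", "detection_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ScreenResult:
    """Per-species screen outputs plus the shared CV bookkeeping."""

    table: pd.DataFrame  # species, auroc_mean, auroc_sd, ci_lo, ci_hi, p, q, flags
    subject_scores: pd.DataFrame  # subjects x species mean out-of-fold scores
    auroc_by_repeat: np.ndarray  # repeats x species
    fold_assignments: np.ndarray  # repeats x subjects


def filter_species(
    table_pre: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> list[str]:
    """Species passing mean-abundance and prevalence gates on pre samples.

    Returned in descending mean relative abundance, ties broken by id.
    """
    if len(table_pre) == 0:
        raise ValueError("need at least one pre-training sample")
    mean_ra = table_pre.mean(axis=0)
    prevalence = (table_pre > criteria.detection_threshold).mean(axis=0)
    keep = (mean_ra > criteria.min_mean_ra) & (prevalence >= criteria.min_prevalence)
    if not keep.any():
        raise ValueError(
            "no species pass the filter; relax min_mean_ra/min_prevalence"
        )
    kept = mean_ra[keep]
    order = sorted(kept.index, key=lambda s: (-kept[s], s))
    return list(order)


# ---------------------------------------------------------------------------
# AUROC primitives


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUROC via the rank/U identity with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1 = int(y.sum())
    n2 = int((~y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _auroc_columns(score_mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUROC of every column of ``score_mat`` against boolean ``y``."""
    n1 = int(y.sum())
    n2 = y.size - n1
    ranks = rankdata(score_mat, axis=0)
    u = ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def auc_pvalue_mannwhitney(
    scores: Sequence[float], labels: Sequence[bool]
) -> float:
    """Two-sided Mann-Whitney p on cross-validated scores between classes."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return stats.wilcoxon_rank_sum(scores[y], scores[~y])


def bootstrap_auroc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI of the AUROC of ``scores``."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("need >= 3 subjects per class for the bootstrap")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
        )
        vals[i] = auroc(scores[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1.0 - alpha)),
    )


# ---------------------------------------------------------------------------
# Cross-validated univariate screen


def stratified_kfold(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..k-1 per subject) stratifying on the binary label."""
    folds = np.empty(y.size, dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} members; cannot stratify into {k} folds"
            )
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _fit_univariate_logistic(
    x_train: np.ndarray, y_train: np.ndarray, ridge: float = RIDGE,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Newton fit of per-column logistic models.

    ``x_train`` is subjects x species; each column gets its own intercept
    and slope (on the per-fold z-scored feature).  Returns (a, b, mean, sd)
    so that scores for new data x are sigmoid(a + b * (x - mean)/sd).
    """
    y = y_train.astype(float)
    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x_train - mean) / sd
    s = z.shape[1]
    a = np.zeros(s)
    b = np.zeros(s)
    for _ in range(max_iter):
        eta = np.clip(a + b * z, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        ga = (mu - y[:, None]).sum(axis=0)
        gb = ((mu - y[:, None]) * z).sum(axis=0) + ridge * b
        haa = w.sum(axis=0) + 1e-12
        hab = (w * z).sum(axis=0)
        hbb = (w * z * z).sum(axis=0) + ridge + 1e-12
        det = haa * hbb - hab * hab
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        step = np.maximum(1.0, np.maximum(np.abs(da), np.abs(db)) / 5.0)
        a -= da / step
        b -= db / step
        if max(np.abs(ga).max(), np.abs(gb).max()) < 1e-8:
            break
    return a, b, mean, sd


def univariate_auroc_screen(
    table_pre: pd.DataFrame,
    labels: Sequence[bool],
    repeats: int = 10,
    k: int = 3,
    seed: int | None = None,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    auroc_threshold: float = 0.8,
    fdr_threshold: float = 0.1,
    aggregate: str = "pooled",
) -> ScreenResult:
    """Repeated stratified k-fold univariate AUROC screen.

    One fold split per repeat is shared by all species; out-of-fold
    predicted probabilities are pooled within a repeat into one AUROC
    (``aggregate='per_fold'`` averages per-fold AUROCs instead).  AUROC is
    reported for the fitted model's own score orientation and may fall
    below 0.5.  Set ``n_boot=0`` to skip the bootstrap CI.
    """
    y = np.asarray(labels, dtype=bool)
    if y.size != len(table_pre):
        raise ValueError("labels must align with the sample rows")
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    if y.size < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    if aggregate not in ("pooled", "per_fold"):
        raise ValueError("aggregate must be 'pooled' or 'per_fold'")
    species = list(table_pre.columns)
    x = table_pre.to_numpy(dtype=float)
    n, s = x.shape
    rng = np.random.default_rng(seed)

    auroc_by_repeat = np.empty((repeats, s))
    oof_sum = np.zeros((n, s))
    fold_assignments = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        folds = stratified_kfold(y, k, rng)
        fold_assignments[r] = folds
        oof = np.empty((n, s))
        fold_aucs = []
        for f in range(k):
            test = folds == f
            train = ~test
            if y[test].all() or not y[test].any() or y[train].all() or not y[train].any():
                raise ValueError("a fold lost a class; check the stratification")
            a, b, mean, sd = _fit_univariate_logistic(x[train], y[train])
            zt = (x[test] - mean) / sd
            oof[test] = 1.0 / (1.0 + np.exp(-np.clip(a + b * zt, -35.0, 35.0)))
            if aggregate == "per_fold":
                fold_aucs.append(_auroc_columns(oof[test], y[test]))
        if aggregate == "pooled":
            auroc_by_repeat[r] = _auroc_columns(oof, y)
        else:
            auroc_by_repeat[r] = np.mean(fold_aucs, axis=0)
        oof_sum += oof

    subject_scores = oof_sum / repeats
    auroc_mean = auroc_by_repeat.mean(axis=0)
    auroc_sd = auroc_by_repeat.std(axis=0, ddof=1) if repeats > 1 else np.zeros(s)

    pvals = np.array(
        [stats.wilcoxon_rank_sum(subject_scores[y, j], subject_scores[~y, j])
         for j in range(s)]
    )
    qvals = stats.bh_fdr(pvals)

    ci_lo = np.full(s, np.nan)
    ci_hi = np.full(s, np.nan)
    if n_boot > 0:
        pos = np.flatnonzero(y)
        neg = np.flatnonzero(~y)
        boots = np.empty((n_boot, s))
        for i in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
            )
            boots[i] = _auroc_columns(subject_scores[idx], y[idx])
        alpha = (1.0 - ci_level) / 2.0
        ci_lo = np.quantile(boots, alpha, axis=0)
        ci_hi = np.quantile(boots, 1.0 - alpha, axis=0)
        # the CI bootstraps the pooled-score AUROC; expand marginally so it
        # always covers the reported repeat-mean AUROC point estimate
        ci_lo = np.minimum(ci_lo, auroc_mean)
        ci_hi = np.maximum(ci_hi, auroc_mean)

    table = pd.DataFrame(
        {
            "species": species,
            "auroc_mean": auroc_mean,
            "auroc_sd": auroc_sd,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "p": pvals,
            "q": qvals,
        }
    )
    table["highly_predictive"] = table["auroc_mean"] > auroc_threshold
    table["robust"] = (table["q"] < fdr_threshold) & (table["ci_lo"] > 0.5)
    return ScreenResult(
        table=table,
        subject_scores=pd.DataFrame(
            subject_scores, index=table_pre.index, columns=species
        ),
        auroc_by_repeat=auroc_by_repeat,
        fold_assignments=fold_assignments,
    )


# ---------------------------------------------------------------------------
# Multivariate regularised check


def multivariate_regularized(
    table_pre: pd.DataFrame,
    labels: Sequence[bool],
    seed: int | None = None,
    k: int = 3,
    c_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """L1 logistic selection with the penalty chosen by stratified CV AUROC.

    Features are z-scored before penalisation.  The penalty is picked by a
    one-standard-error rule (the strongest penalty whose CV AUROC is within
    one SE of the best), so label-free data collapses to the empty model.
    Returns the species with nonzero coefficients (possibly empty, which is
    logged, not an error).
    """
    y = np.asarray(labels, dtype=bool)
    if y.size < 6:
        raise ValueError("need at least 6 samples")
    if c_grid is None:
        c_grid = np.logspace(-2, 2, 13)
    c_grid = np.sort(np.asarray(c_grid, dtype=float))
    x = table_pre.to_numpy(dtype=float)
    mean, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    rng = np.random.default_rng(seed)
    folds = stratified_kfold(y, k, rng)

    means = np.empty(c_grid.size)
    ses = np.empty(c_grid.size)
    for i, c in enumerate(c_grid):
        fold_aucs = []
        for f in range(k):
            test = folds == f
            clf = LogisticRegression(
                l1_ratio=1.0, C=float(c), solver="liblinear", max_iter=5000,
                random_state=0,
            )
            clf.fit(z[~test], y[~test])
            fold_aucs.append(auroc(clf.decision_function(z[test]), y[test]))
        means[i] = np.mean(fold_aucs)
        ses[i] = np.std(fold_aucs, ddof=1) / np.sqrt(k)
    best = int(np.argmax(means))
    threshold = means[best] - ses[best]
    chosen = int(np.flatnonzero(means >= threshold)[0])  # smallest C wins
    best_c, best_auc = float(c_grid[chosen]), float(means[chosen])
    clf = LogisticRegression(
        l1_ratio=1.0, C=best_c, solver="liblinear", max_iter=5000, random_state=0
    )
    clf.fit(z, y)
    coefs = clf.coef_.ravel()
    nz = np.flatnonzero(coefs)
    if nz.size == 0:
        logger.info("multivariate L1 model selected no species (C=%.3g)", best_c)
    out = pd.DataFrame(
        {
            "species": np.asarray(table_pre.columns)[nz],
            "coefficient": coefs[nz],
        }
    )
    out.attrs["C"] = best_c
    out.attrs["cv_auroc"] = best_auc
    return out


def compare_group_aurocs(
    screen_table: pd.DataFrame, group_flag: Sequence[bool]
) -> dict:
    """Rank-sum comparison of per-species mean AUROCs between two species sets."""
    flag = np.asarray(group_flag, dtype=bool)
    if flag.size != len(screen_table):
        raise ValueError("group_flag must align with the screen table")
    if not flag.any() or flag.all():
        raise ValueError("both species groups must be non-empty")
    a = screen_table["auroc_mean"].to_numpy()[flag]
    b = screen_table["auroc_mean"].to_numpy()[~flag]
    return {
        "p": stats.wilcoxon_rank_sum(a, b),
        "flagged_mean": float(a.mean()),
        "flagged_sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "other_mean": float(b.mean()),
        "other_sd": float(b.std(ddof=1)) if b.size > 1 else 0.0,
        "n_flagged": int(a.size),
        "n_other": int(b.size),
    }
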