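"""Responder classification and baseline balance checks.

A subject responds to training when the change in fat-free mass exceeds
the change in fat mass, i.e. (FFM_post - FFM_pre) - (FM_post - FM_pre) > 0
(strict: a zero score is a non-responder).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats

logger = logging.getLogger(__name__)

BALANCE_COVARIATES = ("age", "bmi_pre", "fm_pre", "ffm_pre")


def classify_response(cohort: pd.DataFrame) -> pd.DataFrame:
    """Label each subject responder/non-responder from body-composition change.

    Subjects with missing post measurements are excluded with a warning.
    Returns a frame with delta_ffm, delta_fm, score and the boolean label.
    """
    required = ["subject_id", "ffm_pre", "ffm_post", "fm_pre", "fm_post"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort missing columns: {missing_cols}")
    complete = cohort.dropna(subset=required)
    n_dropped = len(cohort) - len(complete)
    if n_dropped:
        dropped = cohort.loc[cohort.index.difference(complete.index), "subject_id"]
        logger.warning(
            "excluding %d subject(s) with missing body composition: %s",
            n_dropped, ", ".join(map(str, dropped)),
        )
    delta_ffm = complete["ffm_post"] - complete["ffm_pre"]
    delta_fm = complete["fm_post"] - complete["fm_pre"]
    score = delta_ffm - delta_fm
    out = pd.DataFrame(
        {
            "subject_id": complete["subject_id"].to_numpy(),
            "delta_ffm": delta_ffm.to_numpy(),
            "delta_fm": delta_fm.to_numpy(),
            "score": score.to_numpy(),
            "responder": (score > 0).to_numpy(),
        }
    )
    logger.info(
        "classified %d responders / %d non-responders",
        int(out["responder"].sum()), int((~out["responder"]).sum()),
    )
    return out


def baseline_balance(cohort: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Test pre-training covariate balance between response groups.

    Fisher's exact test for sex; exact Wilcoxon rank-sum for age and
    pre-training BMI, FM and FFM; BH q-values across the family of five.
    The frame carries a ``balanced`` attr: True when all q > 0.05.
    """
    merged = cohort.merge(labels[["subject_id", "responder"]], on="subject_id")
    resp = merged[merged["responder"]]
    non = merged[~merged["responder"]]
    if len(resp) < 2 or len(non) < 2:
        raise ValueError("each response group must contain at least 2 subjects")

    rows = []
    sex_table = [
        [int((resp["sex"] == "F").sum()), int((resp["sex"] == "M").sum())],
        [int((non["sex"] == "F").sum()), int((non["sex"] == "M").sum())],
    ]
    rows.append(("sex", "fisher_exact", stats.fisher_exact_2x2(sex_table)))
    for cov in BALANCE_COVARIATES:
        p = stats.wilcoxon_rank_sum(
            resp[cov].to_numpy(dtype=float), non[cov].to_numpy(dtype=float)
        )
        rows.append((cov, "wilcoxon_rank_sum", p))

    report = pd.DataFrame(rows, columns=["covariate", "test", "p"])
    report["q"] = stats.bh_fdr(report["p"].to_numpy())
    report.attrs["balanced"] = bool((report["q"] > 0.05).all())
    return report


def paired_change_test(
    values_pre: Sequence[float],
    values_post: Sequence[float],
    by_group: Sequence,
) -> pd.DataFrame:
    """Per-group paired Wilcoxon signed-rank test on pre-to-post change.

    Groups whose differences are all zero are flagged degenerate with p=1.
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    groups = np.asarray(by_group)
    if not (pre.shape == post.shape == groups.shape):
        raise ValueError("pre, post and group labels must be aligned")
    rows = []
    for g in pd.unique(groups):
        d = post[groups == g] - pre[groups == g]
        if d.size < 5:
            raise ValueError(f"group {g!r} has fewer than 5 pairs")
        if np.all(d == 0):
            rows.append((g, d.size, 1.0, True))
            continue
        rows.append((g, d.size, stats.wilcoxon_signed_rank(d), False))
    return pd.DataFrame(rows, columns=["group", "n", "p", "degenerate"])
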