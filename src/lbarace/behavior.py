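"""Behavioral statistics: utility-curve concavity, risk seeking,
counterfactual sensitivity, and their across-subject associations."""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import split_pair
from .task import stimuli

__all__ = [
    "relative_utility_20",
    "risk_seeking",
    "counterfactual_sensitivity",
    "pearson_association",
    "behavior_summary",
    "association_table",
]

log = logging.getLogger(__name__)


def relative_utility_20(mean_u0: float, mean_u20: float, mean_u40: float) -> float:
    """Concavity index on the points scale.

    ``40 * (mean utility of 20 - mean utility of 0) / (mean utility of 40 -
    mean utility of 0)``: equals 20 (i.e. 50% of 40) when the utility curve
    is linear and exceeds 20 when it is concave.
    """
    denom = mean_u40 - mean_u0
    if denom == 0:
        raise ZeroDivisionError("mean utility of 40 equals mean utility of 0")
    return 40.0 * (mean_u20 - mean_u0) / denom


def _is_high_risk(sid: str) -> bool:
    return stimuli()[sid].risk_level == "high"


def risk_seeking(trials: pd.DataFrame) -> float:
    """Percent of mixed-risk trials on which the high-risk gamble was chosen.

    Only the 4 pairs containing exactly one high-risk and one low-risk gamble
    enter the denominator; same-risk pairs are ignored.
    """
    qualifying = 0
    high_chosen = 0
    for pair, choice in zip(trials["pair"], trials["choice"]):
        a, b = split_pair(pair)
        if _is_high_risk(a) == _is_high_risk(b):
            continue
        qualifying += 1
        if _is_high_risk(choice):
            high_chosen += 1
    if qualifying == 0:
        raise ValueError("no mixed-risk trials; risk seeking undefined")
    return 100.0 * high_chosen / qualifying


def counterfactual_sensitivity(trials: pd.DataFrame) -> float:
    """Mean satisfaction with 20 when the foregone outcome was 0 minus when 40.

    Returns NaN (flagged via log) when either cell is empty — possible by
    chance in a 96-trial session.
    """
    cf = trials[(trials["block_type"] == "counterfactual") & (trials["outcome"] == 20)]
    low = cf.loc[cf["counterfactual"] == 0, "satisfaction"]
    high = cf.loc[cf["counterfactual"] == 40, "satisfaction"]
    if len(low) == 0 or len(high) == 0:
        log.warning(
            "counterfactual sensitivity undefined: %d cf=0 and %d cf=40 cells",
            len(low), len(high),
        )
        return float("nan")
    return float(low.mean() - high.mean())


def pearson_association(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r and two-sided p, dropping subjects with missing values pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(len(x) - keep.sum())
    if dropped:
        log.info("pearson_association: dropped %d subjects with missing values", dropped)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete subject pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: correlation undefined")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def behavior_summary(
    cohort_trials: pd.DataFrame,
    subjects: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-subject behavioral measures, joined with trait anxiety when given.

    Mean utilities are computed over all blocks; the counterfactual
    sensitivity is by definition restricted to counterfactual blocks.
    """
    rows = []
    for subject, sub in cohort_trials.groupby("subject_id", sort=True):
        means = {o: sub.loc[sub["outcome"] == o, "satisfaction"].mean() for o in (0, 20, 40)}
        if any(np.isnan(v) for v in means.values()):
            log.warning("subject %s lacks an outcome cell; relative utility missing", subject)
            rel = float("nan")
        else:
            rel = relative_utility_20(means[0], means[20], means[40])
        rows.append(
            {
                "subject_id": subject,
                "relative_utility_20": rel,
                "risk_seeking": risk_seeking(sub),
                "counterfactual_sensitivity": counterfactual_sensitivity(sub),
            }
        )
    out = pd.DataFrame(rows)
    if subjects is not None:
        out = out.merge(subjects[["subject_id", "stai_t"]], on="subject_id", how="left")
    return out


def association_table(summary: pd.DataFrame) -> pd.DataFrame:
    """The three headline association tests across subjects."""
    tests = [
        ("relative_utility_20", "risk_seeking"),
        ("stai_t", "risk_seeking"),
        ("stai_t", "counterfactual_sensitivity"),
    ]
    rows = []
    for xcol, ycol in tests:
        if xcol not in summary.columns or ycol not in summary.columns:
            continue
        x = summary[xcol].to_numpy(dtype=float)
        y = summary[ycol].to_numpy(dtype=float)
        n = int((np.isfinite(x) & np.isfinite(y)).sum())
        r, p = pearson_association(x, y)
        rows.append({"x": xcol, "y": ycol, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
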