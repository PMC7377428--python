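"""Goodness of fit and model comparison.

Cohort-level assessments: quantile-probability tables (response probability
plus choice-conditional RT quantiles per stimulus, for data and for large
seeded simulations from fitted parameters), a Pearson chi-square test of
choice counts against model-predicted counts, two-sample Kolmogorov-Smirnov
tests of RT distributions per stimulus, and the 2x2 risk-by-EV
repeated-measures ANOVA on normalized drift rates.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .io import pair_key, split_pair
from .lba import simulate_races
from .prediction import predict_choice_prob
from .task import PAIRS, STIMULUS_IDS, _mask, stimuli

__all__ = [
    "DEFAULT_QUANTILES",
    "quantile_probability_data",
    "choice_counts",
    "expected_choice_counts",
    "chisq_choice_gof",
    "ks_rt_gof",
    "rm_anova_drift",
    "qp_discrepancy",
    "plot_qp",
]

log = logging.getLogger(__name__)

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


# ---------------------------------------------------------------------------
# quantile-probability tables
# ---------------------------------------------------------------------------


def _qp_rows(
    trials: pd.DataFrame,
    source: str,
    levels: Sequence[float],
    appearances_per_subject: Optional[Dict[str, Dict[str, int]]] = None,
) -> pd.DataFrame:
    """Pooled per-stimulus response probability and choice-conditional RT quantiles."""
    rows = []
    for sid in STIMULUS_IDS:
        shown = trials["pair"].map(lambda p, sid=sid: sid in split_pair(p))
        sub = trials[shown]
        chosen = sub[sub["choice"] == sid]
        prob = len(chosen) / len(sub) if len(sub) else np.nan
        row = {"source": source, "stimulus": sid, "response_prob": prob}
        if len(chosen):
            qs = np.quantile(chosen["rt_s"].to_numpy(), levels)
        else:
            log.warning("stimulus %s never chosen in %s source; quantiles missing", sid, source)
            qs = [np.nan] * len(levels)
        for lvl, q in zip(levels, qs):
            row[f"q{lvl:g}"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_model_trials(
    fits: Dict[str, FitResult],
    n_per_subject: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate each subject on an equal mix of the 6 pairs from fitted params."""
    per_pair = max(n_per_subject // len(PAIRS), 1)
    frames = []
    for i, (subject, fit) in enumerate(sorted(fits.items())):
        rng = np.random.default_rng(np.random.SeedSequence((_mask(seed), 31, i)))
        for pair in PAIRS:
            choices, rts = simulate_races(pair, fit.params, per_pair, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject,
                        "pair": pair_key(*pair),
                        "choice": choices,
                        "rt_s": rts,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def quantile_probability_data(
    cohort_trials: pd.DataFrame,
    fits: Optional[Dict[str, FitResult]] = None,
    quantile_levels: Sequence[float] = DEFAULT_QUANTILES,
    n_sim_per_subject: int = 10_000,
    seed: int = 0,
    source_label: Optional[str] = None,
) -> pd.DataFrame:
    """QP table for the data and, when fits are given, for the fitted model.

    Data rows pool trials across subjects; each stimulus's response
    probability is its chosen count over its appearance count.  Model rows
    use a large seeded simulation from each subject's fitted parameters.
    """
    levels = tuple(quantile_levels)
    if any(not (0 < l < 1) for l in levels) or list(levels) != sorted(set(levels)):
        raise ValueError("quantile levels must be strictly increasing within (0, 1)")
    out = [_qp_rows(cohort_trials, "data", levels)]
    if fits is not None:
        variant = next(iter(fits.values())).variant
        sims = _simulate_model_trials(fits, n_sim_per_subject, seed)
        out.append(_qp_rows(sims, source_label or variant, levels))
    return pd.concat(out, ignore_index=True)


def qp_discrepancy(qp: pd.DataFrame, model_source: str) -> float:
    """Sum of squared differences between a model's QP cells and the data's."""
    levels = [c for c in qp.columns if c.startswith("q")]
    data = qp[qp["source"] == "data"].set_index("stimulus")
    model = qp[qp["source"] == model_source].set_index("stimulus")
    total = 0.0
    for sid in STIMULUS_IDS:
        total += float((data.loc[sid, "response_prob"] - model.loc[sid, "response_prob"]) ** 2)
        for c in levels:
            d, m = data.loc[sid, c], model.loc[sid, c]
            if np.isfinite(d) and np.isfinite(m):
                total += float((d - m) ** 2)
    return total


# ---------------------------------------------------------------------------
# chi-square choice GOF
# ---------------------------------------------------------------------------


def choice_counts(trials: pd.DataFrame) -> np.ndarray:
    """Observed chosen counts for the four stimuli, pooled over the cohort."""
    counts = trials["choice"].value_counts()
    return np.array([int(counts.get(sid, 0)) for sid in STIMULUS_IDS])


def expected_choice_counts(fits: Dict[str, FitResult], trials: pd.DataFrame) -> np.ndarray:
    """Model-expected chosen counts: predicted probabilities summed per trial."""
    expected = np.zeros(4)
    probs: Dict[Tuple[str, str], float] = {}
    for subject, fit in fits.items():
        for pair in PAIRS:
            probs[(subject, pair_key(*pair))] = predict_choice_prob(fit.params, pair)
    idx = {sid: i for i, sid in enumerate(STIMULUS_IDS)}
    for (subject, pair), n in trials.groupby(["subject_id", "pair"]).size().items():
        p_first = probs[(subject, pair)]
        first, second = split_pair(pair)
        expected[idx[first]] += n * p_first
        expected[idx[second]] += n * (1.0 - p_first)
    return expected


def chisq_choice_gof(
    observed_counts: Sequence[float],
    expected_counts: Sequence[float],
) -> Tuple[float, int, float]:
    """Pearson X^2 over the 4 stimulus-choice categories, df = 3."""
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_counts, dtype=float)
    if obs.shape != (4,) or exp.shape != (4,):
        raise ValueError("expected 4 per-stimulus counts")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    if abs(obs.sum() - exp.sum()) > 1e-6:
        raise ValueError(
            f"observed total {obs.sum()} and expected total {exp.sum()} disagree"
        )
    x2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p


# ---------------------------------------------------------------------------
# KS RT GOF
# ---------------------------------------------------------------------------


def ks_rt_gof(
    trials: pd.DataFrame,
    fits: Dict[str, FitResult],
    seed: int = 0,
    sim_multiplier: int = 100,
) -> Dict[str, Tuple[float, float]]:
    """Two-sample KS per stimulus: pooled data RTs vs pooled model RTs.

    The model sample is simulated per subject from its fitted parameters at
    ``sim_multiplier`` times the subject's trial count (choice-conditional on
    the stimulus, like the data sample).
    """
    n_per_subject = sim_multiplier * int(
        trials.groupby("subject_id").size().median()
    )
    sims = _simulate_model_trials(fits, n_per_subject, seed)
    out: Dict[str, Tuple[float, float]] = {}
    for sid in STIMULUS_IDS:
        data_rts = trials.loc[trials["choice"] == sid, "rt_s"].to_numpy()
        model_rts = sims.loc[sims["choice"] == sid, "rt_s"].to_numpy()
        if data_rts.size == 0 or model_rts.size == 0:
            raise ValueError(f"empty RT sample for stimulus {sid}")
        res = stats.ks_2samp(data_rts, model_rts)
        out[sid] = (float(res.statistic), float(res.pvalue))
    return out


# ---------------------------------------------------------------------------
# risk x EV repeated-measures ANOVA on normalized drift rates
# ---------------------------------------------------------------------------


def _risk_ev_levels(sid: str) -> Tuple[str, str]:
    stim = stimuli()[sid]
    return stim.risk_level, stim.ev_level


def rm_anova_drift(norm_drifts: pd.DataFrame) -> pd.DataFrame:
    """2 (risk) x 2 (EV) within-subject ANOVA.

    ``norm_drifts`` is long format with columns ``subject_id``, ``stimulus``
    and ``value`` (one complete 2x2 cell set per subject).  Each effect is
    tested against its effect-by-subject interaction; partial eta^2 is
    SS_effect / (SS_effect + SS_error).
    """
    df = norm_drifts.copy()
    df["risk"] = df["stimulus"].map(lambda s: _risk_ev_levels(s)[0])
    df["ev"] = df["stimulus"].map(lambda s: _risk_ev_levels(s)[1])
    subjects = sorted(df["subject_id"].unique())
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    # y[subject, risk, ev]
    y = np.full((n, 2, 2), np.nan)
    risk_levels = ("high", "low")
    ev_levels = ("high", "low")
    s_idx = {s: i for i, s in enumerate(subjects)}
    for row in df.itertuples(index=False):
        y[s_idx[row.subject_id], risk_levels.index(row.risk), ev_levels.index(row.ev)] = row.value
    if np.isnan(y).any():
        raise ValueError("incomplete risk x EV cells for at least one subject")

    grand = y.mean()
    subj_m = y.mean(axis=(1, 2))
    risk_m = y.mean(axis=(0, 2))
    ev_m = y.mean(axis=(0, 1))
    cell_re = y.mean(axis=0)          # risk x ev cell means
    sr_m = y.mean(axis=2)             # subject x risk
    se_m = y.mean(axis=1)             # subject x ev

    ss_subj = 4.0 * np.sum((subj_m - grand) ** 2)
    ss_risk = 2.0 * n * np.sum((risk_m - grand) ** 2)
    ss_ev = 2.0 * n * np.sum((ev_m - grand) ** 2)
    ss_inter = n * np.sum(
        (cell_re - risk_m[:, None] - ev_m[None, :] + grand) ** 2
    )
    ss_risk_subj = 2.0 * np.sum(
        (sr_m - subj_m[:, None] - risk_m[None, :] + grand) ** 2
    )
    ss_ev_subj = 2.0 * np.sum(
        (se_m - subj_m[:, None] - ev_m[None, :] + grand) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_resid = ss_total - (
        ss_subj + ss_risk + ss_ev + ss_inter + ss_risk_subj + ss_ev_subj
    )

    tiny = 1e-12 * max(float(ss_total), 1.0)  # numerically-zero SS cutoff
    rows = []
    for name, ss_eff, ss_err in (
        ("risk", ss_risk, ss_risk_subj),
        ("ev", ss_ev, ss_ev_subj),
        ("risk:ev", ss_inter, ss_resid),
    ):
        ss_eff = 0.0 if ss_eff < tiny else float(ss_eff)
        ss_err = 0.0 if ss_err < tiny else float(ss_err)
        df1, df2 = 1, n - 1
        ms_err = ss_err / df2
        if ms_err > 0:
            f = (ss_eff / df1) / ms_err
        else:
            f = 0.0 if ss_eff == 0.0 else np.inf  # noise-free degenerate data
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append(
            {
                "effect": name,
                "F": float(f),
                "df1": df1,
                "df2": df2,
                "p": p,
                "partial_eta_sq": float(eta),
                "ss_effect": float(ss_eff),
                "ss_error": float(ss_err),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = float(ss_total)
    out.attrs["ss_components"] = float(
        ss_subj + ss_risk + ss_ev + ss_inter + ss_risk_subj + ss_ev_subj + ss_resid
    )
    return out


def plot_qp(qp: pd.DataFrame, path) -> None:
    """Render the quantile-probability figure (probability on x, RT quantiles on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = [c for c in qp.columns if c.startswith("q")]
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = {"data": "o", "drift_model": "s", "boundary_model": "^"}
    for source, sub in qp.groupby("source"):
        sub = sub.sort_values("response_prob")
        for c in levels:
            ax.plot(
                sub["response_prob"], sub[c],
                marker=markers.get(source, "x"),
                linestyle="-" if source == "data" else "--",
                alpha=0.7,
                label=f"{source} {c}" if c == levels[0] else None,
            )
    ax.set_xlabel("response probability")
    ax.set_ylabel("RT quantile (s)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
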