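"""Choice-probability prediction, predicted-vs-actual correlation, held-out
validation.

Per-pair predicted probabilities come from the closed-form race densities:
``p_i`` is the integral of the winning density for option i times the other
option's survival function, normalized by the probability that at least one
accumulator finishes.  All bookkeeping is oriented toward the
lexicographically first member of each pair; results are
orientation-invariant because ``p_i + p_j = 1``.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import ndtr
from scipy.stats import pearsonr

from . import lba
from .fitting import FitConfig, FitError, FitResult, fit_subject
from .io import pair_key
from .task import PAIRS, _mask

__all__ = [
    "predict_choice_prob",
    "pair_predictions",
    "attach_empirical",
    "empirical_choice_rates",
    "predicted_vs_actual",
    "holdout_split",
    "holdout_evaluation",
]

log = logging.getLogger(__name__)


def predict_choice_prob(params, pair: Sequence[str], choice: Optional[str] = None) -> float:
    """Probability that ``choice`` (default: first pair member) wins the race.

    Computed by adaptive quadrature of ``f_choice(t) * (1 - F_other(t))``
    over the decision-time axis (compactified to handle the slow power-law
    tail), normalized by the probability that at least one accumulator
    finishes.
    """
    members = sorted(pair)
    if choice is None:
        choice = members[0]
    if choice not in members:
        raise ValueError(f"choice {choice!r} not in pair {pair!r}")
    other = members[1] if choice == members[0] else members[0]
    b_c, A_c, v_c, s = params.accumulator(choice)
    b_o, A_o, v_o, _ = params.accumulator(other)

    def integrand(t):
        return lba._defective_pdf(t, b_c, A_c, v_c, s) * (
            1.0 - lba._defective_cdf(t, b_o, A_o, v_o, s)
        )

    # the winning density's tail decays only ~ 1/t^2 (drifts near zero), so a
    # finite truncation loses mass; map (0, inf) -> (0, 1) via u = 1/(1+t),
    # under which the tail contribution becomes a bounded integrand at u -> 0
    def integrand_u(u):
        if u <= 0.0 or u >= 1.0:
            return 0.0
        t = (1.0 - u) / u
        return integrand(t) / (u * u)

    # breakpoints near each accumulator's characteristic passage times keep
    # adaptive quadrature from stepping over a narrow density peak
    pts = []
    for b, A, v in ((b_c, A_c, v_c), (b_o, A_o, v_o)):
        v_eff = max(v, 0.25 * s)
        pts += [(b - A) / (v_eff + s), b / v_eff, 2.0 * b / v_eff]
    upts = sorted({1.0 / (1.0 + p) for p in pts if p > 0.0})
    val, err = quad(integrand_u, 0.0, 1.0, limit=200, points=upts)
    if err > 1e-6 * max(val, 1.0):
        raise RuntimeError(f"quadrature failed to converge (estimate error {err})")
    norm = 1.0 - ndtr(-v_c / s) * ndtr(-v_o / s)
    return float(np.clip(val / norm, 0.0, 1.0))


def pair_predictions(fits: Dict[str, FitResult]) -> pd.DataFrame:
    """Predicted first-member probability for every subject x pair."""
    rows = [
        {
            "subject_id": subject,
            "pair": pair_key(*pair),
            "p_choose_first": predict_choice_prob(fit.params, pair),
        }
        for subject, fit in fits.items()
        for pair in PAIRS
    ]
    return pd.DataFrame(rows)


def empirical_choice_rates(trials: pd.DataFrame) -> Dict[str, float]:
    """Fraction of each pair's trials on which the first member was chosen."""
    rates: Dict[str, float] = {}
    grouped = trials.groupby("pair")
    for pair in PAIRS:
        key = pair_key(*pair)
        if key not in grouped.groups:
            raise ValueError(f"no trials for pair {key}")
        sub = grouped.get_group(key)
        rates[key] = float((sub["choice"] == pair[0]).mean())
    return rates


def predicted_vs_actual(
    fits: Dict[str, FitResult],
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Across-subject Pearson r between predicted and empirical rates, per pair."""
    subjects = sorted(fits)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for across-subject correlation")
    pred = pair_predictions(fits).set_index(["subject_id", "pair"])["p_choose_first"]
    emp = {
        subject: empirical_choice_rates(trials[trials["subject_id"] == subject])
        for subject in subjects
    }
    rows = []
    for pair in PAIRS:
        key = pair_key(*pair)
        x = np.array([pred.loc[(s, key)] for s in subjects])
        y = np.array([emp[s][key] for s in subjects])
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            raise ValueError(f"constant vector for pair {key}: correlation undefined")
        r, p = pearsonr(x, y)
        rows.append({"pair": key, "r": float(r), "p": float(p), "n": len(subjects)})
    return pd.DataFrame(rows)


def holdout_split(trials: pd.DataFrame, seed: int) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified half split of one subject's trials: 8 of 16 per pair held out."""
    rng = np.random.default_rng(np.random.SeedSequence((_mask(seed), 21)))
    test_mask = np.zeros(len(trials), dtype=bool)
    positions = {p: i for i, p in enumerate(trials.index)}
    for key, sub in trials.groupby("pair"):
        n = len(sub)
        if n % 2 != 0:
            raise ValueError(f"pair {key} has an odd trial count ({n}); cannot half-split")
        chosen = rng.choice(n, size=n // 2, replace=False)
        for idx in np.asarray(sub.index)[chosen]:
            test_mask[positions[idx]] = True
    return trials.loc[~test_mask], trials.loc[test_mask]


def holdout_evaluation(
    cohort_trials: pd.DataFrame,
    config: Optional[FitConfig] = None,
    seed: int = 0,
    variant: str = "drift_model",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fit on train halves, correlate predictions with test-half choice rates.

    Returns ``(correlations, predictions)``; subjects whose fit fails are
    dropped with a logged warning.
    """
    subjects = sorted(cohort_trials["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    fits: Dict[str, FitResult] = {}
    test_parts = []
    for i, subject in enumerate(subjects):
        sub = cohort_trials[cohort_trials["subject_id"] == subject]
        train, test = holdout_split(
            sub, seed=int(np.random.SeedSequence((_mask(seed), 22, i)).generate_state(1)[0])
        )
        try:
            fits[subject] = fit_subject(
                train, variant, config=config,
                seed=int(np.random.SeedSequence((_mask(seed), 23, i)).generate_state(1)[0]),
            )
        except FitError as exc:
            log.warning("dropping subject %s from held-out analysis: %s", subject, exc)
            continue
        test_parts.append(test)
    test_trials = pd.concat(test_parts, ignore_index=True)
    corr = predicted_vs_actual(fits, test_trials)
    pred = attach_empirical(pair_predictions(fits), test_trials)
    pred["split"] = "holdout"
    return corr, pred


def attach_empirical(predictions: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Add each subject x pair's empirical first-member choice rate."""
    rates = {
        (subject, key): rate
        for subject, sub in trials.groupby("subject_id")
        for key, rate in empirical_choice_rates(sub).items()
    }
    out = predictions.copy()
    out["empirical"] = [
        rates[(row.subject_id, row.pair)] for row in out.itertuples(index=False)
    ]
    return out
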