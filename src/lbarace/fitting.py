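"""Per-subject maximum-likelihood estimation of the two accumulator variants.

Both variants free 7 parameters.  The *drift model* frees one drift mean per
stimulus with a shared threshold, start-point range and non-decision time;
the *boundary model* frees one threshold per stimulus with a shared drift
mean.  The drift SD ``s`` is fixed (1.0 by default) for scale
identifiability.

Optimization is derivative-free simplex (Nelder-Mead) in a transformed
space — ``log A``, ``log (b - A)``, a logistic map keeping ``t0`` strictly
below the subject's minimum RT, and unconstrained drifts — restarted from
jittered heuristic initializations, keeping the best restart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import lba
from .lba import BoundaryModelParams, LBAParams
from .task import STIMULUS_IDS, _mask
from .io import split_pair

__all__ = [
    "VARIANTS",
    "FitConfig",
    "FitResult",
    "FitError",
    "initialize_params",
    "fit_subject",
    "fit_cohort",
    "normalized_drift_rates",
    "fits_frame",
]

log = logging.getLogger(__name__)

VARIANTS = ("drift_model", "boundary_model")

_STIM_INDEX = {sid: i for i, sid in enumerate(STIMULUS_IDS)}


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitConfig:
    n_restarts: int = 10
    max_iter: int = 1500
    xatol: float = 1e-4
    fatol: float = 1e-6
    drift_sd: float = 1.0   # fixed, not estimated
    jitter_sd: float = 0.2  # restart-to-restart spread of initializations


@dataclass(frozen=True)
class FitResult:
    variant: str
    params: object            # LBAParams or BoundaryModelParams
    nll: float
    n_restarts_used: int
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# trial compilation: turn a trials table into flat arrays once per fit
# ---------------------------------------------------------------------------


def _compile_trials(trials: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(trials) == 0:
        raise ValueError("empty trial set")
    choice_idx = np.empty(len(trials), dtype=np.int64)
    other_idx = np.empty(len(trials), dtype=np.int64)
    rt = trials["rt_s"].to_numpy(dtype=float)
    for i, (pair, choice) in enumerate(zip(trials["pair"], trials["choice"])):
        a, b = split_pair(pair)
        other = b if choice == a else a
        choice_idx[i] = _STIM_INDEX[choice]
        other_idx[i] = _STIM_INDEX[other]
    return choice_idx, other_idx, rt


# ---------------------------------------------------------------------------
# parameter transforms: theta (unconstrained R^7) <-> params
# theta layout, drift model:    [v HR_HEV, v HR_LEV, v LR_HEV, v LR_LEV,
#                                log A, log(b - A), logit(t0 / t0_cap)]
# theta layout, boundary model: [v, log A, log(b_i - A) x 4, logit(t0/cap)]
# ---------------------------------------------------------------------------


def _to_theta(params, variant: str, t0_cap: float) -> np.ndarray:
    frac = np.clip(params.nondecision / t0_cap, 1e-6, 1 - 1e-6)
    if variant == "drift_model":
        v = [params.drift_means[s] for s in STIMULUS_IDS]
        return np.array(
            v
            + [
                np.log(params.start_max),
                np.log(params.threshold - params.start_max),
                logit(frac),
            ]
        )
    gaps = [np.log(params.thresholds[s] - params.start_max) for s in STIMULUS_IDS]
    return np.array(
        [params.drift_mean, np.log(params.start_max)] + gaps + [logit(frac)]
    )


#: exp() outputs are floored so back-transformed params always satisfy
#: b > A >= MIN_START_RANGE even when the simplex drives a log-gap to -inf
_GAP_FLOOR = 1e-6


def _from_theta(theta: np.ndarray, variant: str, t0_cap: float, s: float):
    if variant == "drift_model":
        A = max(float(np.exp(theta[4])), lba.MIN_START_RANGE)
        b = A + max(float(np.exp(theta[5])), _GAP_FLOOR)
        t0 = t0_cap * float(expit(theta[6]))
        drifts = {sid: float(theta[i]) for i, sid in enumerate(STIMULUS_IDS)}
        return LBAParams(drift_means=drifts, start_max=A, threshold=b,
                         nondecision=t0, drift_sd=s)
    v = float(theta[0])
    A = max(float(np.exp(theta[1])), lba.MIN_START_RANGE)
    thresholds = {
        sid: A + max(float(np.exp(theta[2 + i])), _GAP_FLOOR)
        for i, sid in enumerate(STIMULUS_IDS)
    }
    t0 = t0_cap * float(expit(theta[6]))
    return BoundaryModelParams(thresholds=thresholds, drift_mean=v, start_max=A,
                               nondecision=t0, drift_sd=s)


def _objective(choice_idx, other_idx, rt, variant: str, t0_cap: float, s: float):
    """Fast NLL as a function of theta, avoiding params-object construction."""

    def nll(theta: np.ndarray) -> float:
        if variant == "drift_model":
            A = max(np.exp(theta[4]), lba.MIN_START_RANGE)
            b = A + max(np.exp(theta[5]), _GAP_FLOOR)
            t0 = t0_cap * expit(theta[6])
            v = theta[:4]
            b_c = b
            b_o = b
            v_c = v[choice_idx]
            v_o = v[other_idx]
        else:
            v_all = np.full(4, theta[0])
            A = max(np.exp(theta[1]), lba.MIN_START_RANGE)
            b_arr = A + np.maximum(np.exp(theta[2:6]), _GAP_FLOOR)
            t0 = t0_cap * expit(theta[6])
            b_c = b_arr[choice_idx]
            b_o = b_arr[other_idx]
            v_c = v_all[choice_idx]
            v_o = v_all[other_idx]
        if not np.all(np.isfinite(theta)):
            return 1e12
        ll = lba._race_loglik_arrays(rt - t0, b_c, A, v_c, b_o, A, v_o, s)
        total = float(-np.sum(ll))
        return total if np.isfinite(total) else 1e12

    return nll


# ---------------------------------------------------------------------------
# heuristics
# ---------------------------------------------------------------------------


def initialize_params(
    trials: pd.DataFrame,
    variant: str,
    rng: Optional[np.random.Generator] = None,
    drift_sd: float = 1.0,
    jitter_sd: float = 0.2,
):
    """Heuristic starting parameters, optionally jittered for a restart.

    Without an ``rng`` the deterministic base heuristic is returned:
    ``t0 = 0.9 * min RT``; ``b = 2 * SD(RT)`` at a unit evidence rate with
    ``A = b / 2``; drift starts ordered by each stimulus's empirical choice
    rate and centered at 1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    rts = trials["rt_s"].to_numpy(dtype=float)
    counts_shown = {sid: 0 for sid in STIMULUS_IDS}
    counts_chosen = {sid: 0 for sid in STIMULUS_IDS}
    for pair, choice in zip(trials["pair"], trials["choice"]):
        a, b = split_pair(pair)
        counts_shown[a] += 1
        counts_shown[b] += 1
        counts_chosen[choice] += 1
    zero = [sid for sid, n in counts_shown.items() if n == 0]
    if zero:
        raise ValueError(f"no trials for stimuli {zero}; cannot initialize")

    t0 = 0.9 * float(rts.min())
    b_init = max(2.0 * float(rts.std()), 0.2)
    A_init = b_init / 2.0
    rates = {sid: counts_chosen[sid] / counts_shown[sid] for sid in STIMULUS_IDS}
    mean_rate = float(np.mean(list(rates.values())))
    drifts = {sid: 1.0 + (rates[sid] - mean_rate) for sid in STIMULUS_IDS}

    if rng is not None:
        gap = (b_init - A_init) * float(np.exp(rng.normal(0.0, jitter_sd)))
        A_init *= float(np.exp(rng.normal(0.0, jitter_sd)))
        b_init = A_init + gap
        t0 = min(t0 * float(np.exp(rng.normal(0.0, jitter_sd / 2))), 0.999 * rts.min())
        drifts = {sid: v + float(rng.normal(0.0, jitter_sd)) for sid, v in drifts.items()}

    if variant == "drift_model":
        return LBAParams(drift_means=drifts, start_max=A_init, threshold=b_init,
                         nondecision=t0, drift_sd=drift_sd)
    return BoundaryModelParams(
        thresholds={sid: b_init for sid in STIMULUS_IDS},
        drift_mean=float(np.mean(list(drifts.values()))),
        start_max=A_init,
        nondecision=t0,
        drift_sd=drift_sd,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_subject(
    trials: pd.DataFrame,
    variant: str,
    config: Optional[FitConfig] = None,
    seed: int = 0,
) -> FitResult:
    """Best-of-restarts simplex ML fit of one subject's trials."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    cfg = config or FitConfig()
    choice_idx, other_idx, rt = _compile_trials(trials)
    t0_cap = float(rt.min())
    nll_fn = _objective(choice_idx, other_idx, rt, variant, t0_cap, cfg.drift_sd)

    best_theta = None
    best_nll = np.inf
    n_hits = 0
    any_success = False
    for restart in range(cfg.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((_mask(seed), 11, restart)))
        init = initialize_params(
            trials, variant, rng=None if restart == 0 else rng,
            drift_sd=cfg.drift_sd, jitter_sd=cfg.jitter_sd,
        )
        x0 = _to_theta(init, variant, t0_cap)
        res = minimize(
            nll_fn,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": cfg.max_iter,
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
            },
        )
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if res.fun < best_nll - 1e-2:
            best_nll, best_theta, n_hits = float(res.fun), res.x, 1
        elif res.fun < best_nll + 1e-2:
            n_hits += 1
            if res.fun < best_nll:
                best_nll, best_theta = float(res.fun), res.x
    if best_theta is None:
        raise FitError(f"no restart produced a finite likelihood (variant={variant})")
    if n_hits == 1 and cfg.n_restarts > 1:
        log.warning("best NLL reached by only one of %d restarts", cfg.n_restarts)
    params = _from_theta(best_theta, variant, t0_cap, cfg.drift_sd)
    return FitResult(
        variant=variant,
        params=params,
        nll=best_nll,
        n_restarts_used=cfg.n_restarts,
        converged=any_success,
        seed=seed,
    )


def fit_cohort(
    trials: pd.DataFrame,
    variant: str,
    config: Optional[FitConfig] = None,
    seed: int = 0,
) -> Dict[str, FitResult]:
    """Independent per-subject fits, seeded per subject."""
    fits: Dict[str, FitResult] = {}
    for i, (subject, sub) in enumerate(trials.groupby("subject_id", sort=True)):
        fits[subject] = fit_subject(
            sub, variant, config=config,
            seed=int(np.random.SeedSequence((_mask(seed), 12, i)).generate_state(1)[0]),
        )
    return fits


def normalized_drift_rates(fit: FitResult) -> Dict[str, float]:
    """Each stimulus's drift divided by the subject's mean drift (mean -> 1)."""
    if fit.variant != "drift_model":
        raise ValueError("normalized drift rates are defined for the drift model only")
    v = np.array([fit.params.drift_means[sid] for sid in STIMULUS_IDS])
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"mean drift must be positive, got {mean}")
    return {sid: float(vi / mean) for sid, vi in zip(STIMULUS_IDS, v)}


def fits_frame(fits: Dict[str, FitResult]) -> pd.DataFrame:
    """One row per subject: fitted parameters, NLL and diagnostics."""
    rows = []
    for subject, fit in fits.items():
        row = {
            "subject_id": subject,
            "variant": fit.variant,
            "nll": fit.nll,
            "converged": fit.converged,
            "n_restarts": fit.n_restarts_used,
            "start_max": fit.params.start_max,
            "nondecision": fit.params.nondecision,
            "drift_sd": fit.params.drift_sd,
        }
        if fit.variant == "drift_model":
            row["threshold"] = fit.params.threshold
            for sid in STIMULUS_IDS:
                row[f"v_{sid}"] = fit.params.drift_means[sid]
        else:
            row["drift_mean"] = fit.params.drift_mean
            for sid in STIMULUS_IDS:
                row[f"b_{sid}"] = fit.params.thresholds[sid]
        rows.append(row)
    return pd.DataFrame(rows)
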