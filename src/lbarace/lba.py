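"""Closed-form first-passage mathematics for the linear ballistic accumulator.

Each response option has an independent accumulator that starts at a level
drawn from Uniform(0, A), rises linearly at a drift sampled once per trial
from Normal(v, s^2), and triggers its response on reaching the threshold b.
The winning accumulator's passage time plus a non-decision offset t0 is the
observed reaction time.

The single-accumulator passage-time distribution is *defective*: an
accumulator whose sampled drift is non-positive never finishes, so the total
mass is ``1 - Phi(-v/s)``.  Race likelihoods and the trial simulator both
condition on at least one accumulator finishing, dividing by
``1 - Phi(-v_i/s) * Phi(-v_j/s)`` so the generative and inferential models
match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
from scipy.special import ndtr

__all__ = [
    "LBAParams",
    "BoundaryModelParams",
    "lba_cdf",
    "lba_pdf",
    "race_likelihood",
    "negative_log_likelihood",
    "simulate_race",
    "simulate_races",
]

#: smallest admissible start-point range; the A -> 0 limit is never reached
#: by the fitting transforms, so it is guarded rather than special-cased.
MIN_START_RANGE = 1e-6

#: per-trial log-likelihood floor: a zero-likelihood trial contributes
#: -log(1e-300) to the NLL so derivative-free optimizers see a finite,
#: comparable loss instead of inf.
_LOG_FLOOR = math.log(1e-300)

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _npdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / _SQRT_2PI


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LBAParams:
    """Drift-rate variant: one drift mean per stimulus, shared b, A, t0, s."""

    drift_means: Mapping[str, float]
    start_max: float
    threshold: float
    nondecision: float
    drift_sd: float = 1.0

    def __post_init__(self) -> None:
        _check_common(self.start_max, self.threshold, self.nondecision, self.drift_sd)
        for stim, v in self.drift_means.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite drift mean for {stim!r}")

    def accumulator(self, stimulus: str) -> Tuple[float, float, float, float]:
        """(b, A, v, s) for one stimulus's accumulator."""
        return (
            self.threshold,
            self.start_max,
            float(self.drift_means[stimulus]),
            self.drift_sd,
        )


@dataclass(frozen=True)
class BoundaryModelParams:
    """Response-boundary variant: one threshold per stimulus, shared v, A, t0, s."""

    thresholds: Mapping[str, float]
    drift_mean: float
    start_max: float
    nondecision: float
    drift_sd: float = 1.0

    def __post_init__(self) -> None:
        for stim, b in self.thresholds.items():
            _check_common(self.start_max, b, self.nondecision, self.drift_sd)
        if not np.isfinite(self.drift_mean):
            raise ValueError("non-finite shared drift mean")

    def accumulator(self, stimulus: str) -> Tuple[float, float, float, float]:
        return (
            float(self.thresholds[stimulus]),
            self.start_max,
            self.drift_mean,
            self.drift_sd,
        )


def _check_common(A: float, b: float, t0: float, s: float) -> None:
    if not (A >= MIN_START_RANGE):
        raise ValueError(f"start_max must be >= {MIN_START_RANGE}, got {A}")
    if not (b > A):
        raise ValueError(f"threshold b={b} must exceed start_max A={A}")
    if t0 < 0:
        raise ValueError(f"nondecision time must be >= 0, got {t0}")
    if not (s > 0):
        raise ValueError(f"drift_sd must be > 0, got {s}")


# ---------------------------------------------------------------------------
# defective single-accumulator distribution
# ---------------------------------------------------------------------------


def _defective_cdf(t, b, A, v, s):
    """P(passage time <= t) for one accumulator; vectorized, no validation."""
    t = np.asarray(t, dtype=float)
    ts = t * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    out = (
        1.0
        + (b - A - t * v) / A * ndtr(z1)
        - (b - t * v) / A * ndtr(z2)
        + ts / A * _npdf(z1)
        - ts / A * _npdf(z2)
    )
    return np.clip(out, 0.0, 1.0)


def _defective_pdf(t, b, A, v, s):
    """Density of the passage time; vectorized, no validation."""
    t = np.asarray(t, dtype=float)
    ts = t * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    out = (v * ndtr(z2) - v * ndtr(z1) + s * _npdf(z1) - s * _npdf(z2)) / A
    return np.maximum(out, 0.0)


def _validate_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("decision time t must be > 0")
    return t


def lba_cdf(t, b: float, A: float, v: float, s: float = 1.0):
    """Defective passage-time CDF F(t) of a single LBA accumulator.

    Non-decreasing in ``t`` with limit ``1 - Phi(-v/s)`` as t -> inf.

    Parameters
    ----------
    t
        Decision time(s) in seconds, strictly positive (scalar or array).
    b, A, v, s
        Threshold, start-point range, mean drift, drift SD.
    """
    _check_common(A, b, 0.0, s)
    t = _validate_t(t)
    out = _defective_cdf(t, b, A, v, s)
    return float(out) if out.ndim == 0 else out


def lba_pdf(t, b: float, A: float, v: float, s: float = 1.0):
    """Defective passage-time density f(t); integrates to ``1 - Phi(-v/s)``."""
    _check_common(A, b, 0.0, s)
    t = _validate_t(t)
    out = _defective_pdf(t, b, A, v, s)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# two-accumulator race
# ---------------------------------------------------------------------------


def _race_norm(v_i: float, v_j: float, s: float) -> float:
    """P(at least one accumulator finishes) = 1 - Phi(-v_i/s) Phi(-v_j/s)."""
    return float(1.0 - ndtr(-v_i / s) * ndtr(-v_j / s))


def race_likelihood(choice: str, rt: float, pair: Sequence[str], params) -> float:
    """Likelihood density of observing (choice, rt) in a two-option race.

    For decision time ``tau = rt - t0`` this is
    ``f_choice(tau) * (1 - F_other(tau))`` divided by the probability that at
    least one accumulator finishes.  Returns 0 when ``tau <= 0``.
    """
    members = list(pair)
    if len(members) != 2 or members[0] == members[1]:
        raise ValueError(f"pair must hold two distinct stimuli, got {pair!r}")
    if choice not in members:
        raise ValueError(f"choice {choice!r} not in pair {pair!r}")
    other = members[1] if choice == members[0] else members[0]
    tau = rt - params.nondecision
    if tau <= 0.0:
        return 0.0
    b_c, A_c, v_c, s = params.accumulator(choice)
    b_o, A_o, v_o, _ = params.accumulator(other)
    f = _defective_pdf(tau, b_c, A_c, v_c, s)
    surv = 1.0 - _defective_cdf(tau, b_o, A_o, v_o, s)
    return float(f * surv / _race_norm(v_c, v_o, s))


def _race_loglik_arrays(tau, b_c, A_c, v_c, b_o, A_o, v_o, s):
    """Vectorized per-trial log race likelihood with the zero-likelihood floor.

    All arguments are broadcastable arrays; ``tau`` entries <= 0 get the floor.
    """
    tau = np.asarray(tau, dtype=float)
    ok = tau > 0.0
    tau_safe = np.where(ok, tau, 1.0)
    f = _defective_pdf(tau_safe, b_c, A_c, v_c, s)
    surv = 1.0 - _defective_cdf(tau_safe, b_o, A_o, v_o, s)
    norm = 1.0 - ndtr(-v_c / s) * ndtr(-v_o / s)
    like = np.where(ok, f * surv / norm, 0.0)
    with np.errstate(divide="ignore"):
        ll = np.log(like)
    return np.where(np.isfinite(ll), ll, _LOG_FLOOR)


def negative_log_likelihood(trials, params, variant: str | None = None) -> float:
    """Summed -log race likelihood over a subject's trials.

    Parameters
    ----------
    trials
        DataFrame with columns ``choice``, ``rt_s`` and ``pair`` (canonical
        ``"STIM-STIM"`` string) — the trials-table schema — or an iterable of
        ``(choice, rt, (stim_i, stim_j))`` tuples.
    params
        :class:`LBAParams` or :class:`BoundaryModelParams`.
    variant
        Optional consistency check: ``"drift_model"`` requires LBAParams,
        ``"boundary_model"`` requires BoundaryModelParams.
    """
    if variant is not None:
        want = LBAParams if variant == "drift_model" else BoundaryModelParams
        if not isinstance(params, want):
            raise TypeError(f"variant {variant!r} incompatible with {type(params).__name__}")
    rows = _as_trial_tuples(trials)
    if not rows:
        raise ValueError("empty trial set")
    tau = np.empty(len(rows))
    acc_c = np.empty((len(rows), 3))
    acc_o = np.empty((len(rows), 3))
    s = params.drift_sd
    for i, (choice, rt, pair) in enumerate(rows):
        if choice not in pair:
            raise ValueError(f"choice {choice!r} not in pair {pair!r}")
        other = pair[1] if choice == pair[0] else pair[0]
        tau[i] = rt - params.nondecision
        acc_c[i] = params.accumulator(choice)[:3]
        acc_o[i] = params.accumulator(other)[:3]
    ll = _race_loglik_arrays(
        tau, acc_c[:, 0], acc_c[:, 1], acc_c[:, 2], acc_o[:, 0], acc_o[:, 1], acc_o[:, 2], s
    )
    return float(-np.sum(ll))


def _as_trial_tuples(trials):
    if hasattr(trials, "columns"):  # DataFrame path
        from .io import split_pair  # local import to avoid a cycle at import time

        return [
            (row.choice, float(row.rt_s), split_pair(row.pair))
            for row in trials.itertuples(index=False)
        ]
    return [(c, float(rt), tuple(p)) for c, rt, p in trials]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_races(
    pair: Sequence[str],
    params,
    n: int,
    rng: np.random.Generator,
    max_resample: int = 10_000,
):
    """Vectorized race simulation: ``n`` independent trials of one pair.

    Returns ``(choices, rts)`` where ``choices`` is an object array of
    stimulus ids and ``rts`` includes the non-decision time.  Trials on which
    both sampled drifts are non-positive are resampled wholesale, matching
    the conditioning used in :func:`race_likelihood`.
    """
    members = list(pair)
    if len(members) != 2 or members[0] == members[1]:
        raise ValueError(f"pair must hold two distinct stimuli, got {pair!r}")
    b0, A0, v0m, s = params.accumulator(members[0])
    b1, A1, v1m, _ = params.accumulator(members[1])

    choices = np.zeros(n, dtype=np.int64)
    rts = np.empty(n, dtype=float)
    todo = np.arange(n)
    for _ in range(max_resample):
        m = todo.size
        if m == 0:
            break
        k0 = rng.uniform(0.0, A0, size=m)
        k1 = rng.uniform(0.0, A1, size=m)
        d0 = rng.normal(v0m, s, size=m)
        d1 = rng.normal(v1m, s, size=m)
        with np.errstate(divide="ignore"):
            t0_fin = np.where(d0 > 0, (b0 - k0) / d0, np.inf)
            t1_fin = np.where(d1 > 0, (b1 - k1) / d1, np.inf)
        done = np.isfinite(t0_fin) | np.isfinite(t1_fin)
        idx = todo[done]
        # ties (measure zero) break toward the first pair element via <=
        first_wins = t0_fin[done] <= t1_fin[done]
        choices[idx] = np.where(first_wins, 0, 1)
        rts[idx] = params.nondecision + np.minimum(t0_fin[done], t1_fin[done])
        todo = todo[~done]
    else:
        raise RuntimeError(
            f"race resampling exceeded {max_resample} rounds; drifts are pathological"
        )
    if todo.size:
        raise RuntimeError(
            f"race resampling exceeded {max_resample} rounds; drifts are pathological"
        )
    labels = np.array(members, dtype=object)
    return labels[choices], rts


def simulate_race(pair: Sequence[str], params, rng: np.random.Generator,
                  max_resample: int = 10_000) -> Tuple[str, float]:
    """One simulated race trial: returns ``(choice, rt)``."""
    choices, rts = simulate_races(pair, params, 1, rng, max_resample=max_resample)
    return str(choices[0]), float(rts[0])
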