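"""Four-gamble risky-choice task structure and synthetic cohort generation.

The task presents pairwise choices between four gambles over outcomes
{0, 20, 40} points drawn from a pool of 100 chips.  Gambles cross two risk
levels (outcome variance 384 vs 96) with two expected values (24 vs 20).
A session is 4 blocks of 24 trials; each of the 6 unordered stimulus pairs
is encountered 16 times, so each stimulus appears on 48 trials.  Half the
blocks reveal the foregone gamble's outcome (counterfactual feedback).

Synthetic subjects carry ground-truth accumulator parameters, a concave
utility exponent, a counterfactual weight, rating noise, and a trait-anxiety
score drawn independently of everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lba import LBAParams, simulate_race

__all__ = [
    "OUTCOMES",
    "STIMULUS_IDS",
    "PAIRS",
    "GambleStimulus",
    "TrialSlot",
    "SubjectProfile",
    "PopulationConfig",
    "derive_stimulus_distributions",
    "stimuli",
    "build_task_schedule",
    "sample_population",
    "satisfaction_rating",
    "simulate_subject",
    "simulate_cohort",
]

OUTCOMES: Tuple[int, int, int] = (0, 20, 40)
N_CHIPS = 100

#: (risk_level, ev_level) -> target moments
_EV_TARGET = {"high": 24.0, "low": 20.0}
_VAR_TARGET = {"high": 384.0, "low": 96.0}

STIMULUS_IDS: Tuple[str, ...] = ("HR_HEV", "HR_LEV", "LR_HEV", "LR_LEV")

#: the 6 unordered pairs, members in lexicographic order
PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    (STIMULUS_IDS[i], STIMULUS_IDS[j])
    for i in range(4)
    for j in range(i + 1, 4)
)

BLOCK_TYPES = ("counterfactual", "no_counterfactual")


def _mask(seed: int) -> int:
    """Map any Python int (incl. negatives) onto the SeedSequence domain."""
    return int(seed) & 0xFFFFFFFFFFFFFFFF


@dataclass(frozen=True)
class GambleStimulus:
    """One gamble: chip counts over the three point values."""

    stimulus_id: str
    outcomes: Tuple[int, int, int]
    chip_counts: Tuple[int, int, int]
    risk_level: str
    ev_level: str

    def __post_init__(self) -> None:
        if sum(self.chip_counts) != N_CHIPS:
            raise ValueError(f"{self.stimulus_id}: chips must sum to {N_CHIPS}")
        if any(c < 0 for c in self.chip_counts):
            raise ValueError(f"{self.stimulus_id}: negative chip count")

    @property
    def probabilities(self) -> np.ndarray:
        return np.asarray(self.chip_counts, dtype=float) / N_CHIPS

    @property
    def ev(self) -> float:
        return float(np.dot(self.probabilities, self.outcomes))

    @property
    def variance(self) -> float:
        x = np.asarray(self.outcomes, dtype=float)
        return float(np.dot(self.probabilities, x**2) - self.ev**2)

    def draw_outcome(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.outcomes, p=self.probabilities))


def derive_stimulus_distributions() -> Dict[str, GambleStimulus]:
    """Solve each gamble's chip counts from its (EV, variance) targets.

    With outcomes (0, 20, 40) and probabilities (p0, p20, p40), the moment
    constraints are linear in (p20, p40):

        20 p20 + 40 p40   = EV
        400 p20 + 1600 p40 = Var + EV^2

    The 2x2 solve yields a unique triple; counts must come out as
    non-negative integers over 100 chips or the constants are corrupted.
    """
    out: Dict[str, GambleStimulus] = {}
    coef = np.array([[20.0, 40.0], [400.0, 1600.0]])
    for sid in STIMULUS_IDS:
        risk = "high" if sid.startswith("HR") else "low"
        ev_level = "high" if sid.endswith("HEV") else "low"
        ev, var = _EV_TARGET[ev_level], _VAR_TARGET[risk]
        p20, p40 = np.linalg.solve(coef, np.array([ev, var + ev**2]))
        counts = np.array([1.0 - p20 - p40, p20, p40]) * N_CHIPS
        rounded = np.rint(counts)
        if np.any(np.abs(counts - rounded) > 1e-9) or np.any(rounded < 0):
            raise ValueError(f"moment system for {sid} has no integer chip solution")
        out[sid] = GambleStimulus(
            stimulus_id=sid,
            outcomes=OUTCOMES,
            chip_counts=tuple(int(c) for c in rounded),
            risk_level=risk,
            ev_level=ev_level,
        )
    return out


_STIMULI_CACHE: Optional[Dict[str, GambleStimulus]] = None


def stimuli() -> Dict[str, GambleStimulus]:
    """The four task gambles (cached)."""
    global _STIMULI_CACHE
    if _STIMULI_CACHE is None:
        _STIMULI_CACHE = derive_stimulus_distributions()
    return _STIMULI_CACHE


@dataclass(frozen=True)
class TrialSlot:
    block_index: int
    block_type: str
    trial_index_in_block: int
    pair: Tuple[str, str]
    left_stimulus: str

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair members must be distinct")
        if self.left_stimulus not in self.pair:
            raise ValueError("left_stimulus must belong to the pair")
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")


def build_task_schedule(seed: int, counterbalance_arm: str = "cf_first") -> List[TrialSlot]:
    """4 blocks x 24 trials; each of the 6 pairs appears 4 times per block.

    Within-block order and left/right display position are randomized by
    ``seed``; feedback block types alternate, starting with counterfactual
    blocks for ``cf_first`` and without for ``nocf_first``.
    """
    if counterbalance_arm not in ("cf_first", "nocf_first"):
        raise ValueError(f"unknown counterbalance arm {counterbalance_arm!r}")
    rng = np.random.default_rng(_mask(seed))
    first = "counterfactual" if counterbalance_arm == "cf_first" else "no_counterfactual"
    second = BLOCK_TYPES[1] if first == BLOCK_TYPES[0] else BLOCK_TYPES[0]
    block_types = (first, second, first, second)

    slots: List[TrialSlot] = []
    for block in range(1, 5):
        pairs = [p for p in PAIRS for _ in range(4)]
        order = rng.permutation(len(pairs))
        for trial, k in enumerate(order, start=1):
            pair = pairs[k]
            left = pair[int(rng.integers(2))]
            slots.append(
                TrialSlot(
                    block_index=block,
                    block_type=block_types[block - 1],
                    trial_index_in_block=trial,
                    pair=pair,
                    left_stimulus=left,
                )
            )
    return slots


@dataclass(frozen=True)
class SubjectProfile:
    """Ground truth for one synthetic subject."""

    subject_id: str
    lba: LBAParams
    utility_exponent: float       # rho: curvature of the satisfaction curve
    counterfactual_weight: float  # kappa: regret/relief weight
    rating_noise_sd: float        # VAS units
    stai_t: int                   # trait anxiety, 20-80

    def __post_init__(self) -> None:
        if self.utility_exponent <= 0:
            raise ValueError("utility_exponent must be > 0")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        if not (20 <= self.stai_t <= 80):
            raise ValueError("stai_t must lie in [20, 80]")


@dataclass(frozen=True)
class PopulationConfig:
    """Means and SDs for synthetic-subject parameters.

    Stimulus drift means follow ``v = base + risk_benefit * [low risk]
    + ev_benefit * [high EV] + stimulus noise``; the subject-level low-risk
    benefit is coupled to utility curvature (``concavity_risk_coupling``) so
    that more-concave subjects are more risk averse, while ``stai`` is drawn
    independently of every choice parameter.
    """

    drift_base_mean: float = 2.0
    drift_base_sd: float = 0.4
    risk_benefit_mean: float = 0.9
    risk_benefit_sd: float = 0.35
    ev_benefit_mean: float = 0.5
    ev_benefit_sd: float = 0.30
    drift_stim_noise_sd: float = 0.1
    concavity_risk_coupling: float = 1.5
    start_max_mean: float = 0.8
    start_max_sd: float = 0.15
    threshold_gap_mean: float = 0.8
    threshold_gap_sd: float = 0.15
    nondecision_mean: float = 0.30
    nondecision_sd: float = 0.05
    utility_exponent_mean: float = 0.7
    utility_exponent_sd: float = 0.15
    cf_weight_mean: float = 0.3
    cf_weight_sd: float = 0.15
    rating_noise_sd: float = 8.0
    stai_mean: float = 40.0
    stai_sd: float = 10.0
    drift_sd: float = 1.0  # fixed scale parameter s

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.drift_sd <= 0:
            raise ValueError("drift_sd must be > 0")


def _truncate(value: float, lo: float, hi: float = np.inf) -> float:
    return float(min(max(value, lo), hi))


def sample_population(
    n_subjects: int,
    population_config: Optional[PopulationConfig] = None,
    seed: int = 0,
) -> List[SubjectProfile]:
    """Draw independent subject profiles from the population config."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = population_config or PopulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence((_mask(seed), 7001)))
    profiles: List[SubjectProfile] = []
    for i in range(n_subjects):
        rho = _truncate(rng.normal(cfg.utility_exponent_mean, cfg.utility_exponent_sd), 0.2, 3.0)
        base = rng.normal(cfg.drift_base_mean, cfg.drift_base_sd)
        # concave utility (small rho) pushes the low-risk benefit up
        risk_benefit = rng.normal(cfg.risk_benefit_mean, cfg.risk_benefit_sd)
        risk_benefit += cfg.concavity_risk_coupling * (cfg.utility_exponent_mean - rho)
        ev_benefit = rng.normal(cfg.ev_benefit_mean, cfg.ev_benefit_sd)
        drifts = {}
        for sid, stim in stimuli().items():
            v = base
            if stim.risk_level == "low":
                v += risk_benefit
            if stim.ev_level == "high":
                v += ev_benefit
            if cfg.drift_stim_noise_sd > 0:
                v += rng.normal(0.0, cfg.drift_stim_noise_sd)
            drifts[sid] = float(v)
        A = _truncate(rng.normal(cfg.start_max_mean, cfg.start_max_sd), 0.2)
        gap = _truncate(rng.normal(cfg.threshold_gap_mean, cfg.threshold_gap_sd), 0.2)
        t0 = _truncate(rng.normal(cfg.nondecision_mean, cfg.nondecision_sd), 0.05)
        kappa = _truncate(rng.normal(cfg.cf_weight_mean, cfg.cf_weight_sd), 0.0)
        stai = int(np.rint(_truncate(rng.normal(cfg.stai_mean, cfg.stai_sd), 20, 80)))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                lba=LBAParams(
                    drift_means=drifts,
                    start_max=A,
                    threshold=A + gap,
                    nondecision=t0,
                    drift_sd=cfg.drift_sd,
                ),
                utility_exponent=rho,
                counterfactual_weight=kappa,
                rating_noise_sd=cfg.rating_noise_sd,
                stai_t=stai,
            )
        )
    return profiles


def utility(outcome: float, rho: float) -> float:
    """VAS-scaled power utility: u(x) = 100 (x/40)^rho."""
    return 100.0 * (outcome / 40.0) ** rho


def satisfaction_rating(
    outcome: int,
    counterfactual: Optional[int],
    profile: SubjectProfile,
    rng: np.random.Generator,
) -> float:
    """Satisfaction on a 0-100 visual analogue scale.

    ``u(outcome) - kappa * (u(counterfactual) - u(outcome)) + noise`` with the
    counterfactual term dropped when no foregone outcome was shown; clipped to
    the scale bounds.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    rating = utility(outcome, profile.utility_exponent)
    if counterfactual is not None:
        rating -= profile.counterfactual_weight * (
            utility(counterfactual, profile.utility_exponent) - rating
        )
    if profile.rating_noise_sd > 0:
        rating += rng.normal(0.0, profile.rating_noise_sd)
    return float(np.clip(rating, 0.0, 100.0))


def simulate_subject(
    profile: SubjectProfile,
    schedule: Sequence[TrialSlot],
    seed: int,
) -> pd.DataFrame:
    """Play one subject through a schedule; returns the trials table.

    Choices and RTs come from the subject's true accumulator race, outcomes
    from the chosen gamble's chip distribution, counterfactual outcomes from
    the unchosen gamble in counterfactual blocks, and satisfaction from the
    subject's utility/regret process.
    """
    rng = np.random.default_rng(np.random.SeedSequence((_mask(seed), 7002)))
    gambles = stimuli()
    records = []
    for slot in schedule:
        choice, rt = simulate_race(slot.pair, profile.lba, rng)
        unchosen = slot.pair[1] if choice == slot.pair[0] else slot.pair[0]
        outcome = gambles[choice].draw_outcome(rng)
        if slot.block_type == "counterfactual":
            cf: Optional[int] = gambles[unchosen].draw_outcome(rng)
        else:
            cf = None
        records.append(
            {
                "subject_id": profile.subject_id,
                "block": slot.block_index,
                "block_type": slot.block_type,
                "trial": slot.trial_index_in_block,
                "pair": f"{slot.pair[0]}-{slot.pair[1]}",
                "left_stim": slot.left_stimulus,
                "choice": choice,
                "rt_s": rt,
                "outcome": outcome,
                "counterfactual": np.nan if cf is None else cf,
                "satisfaction": satisfaction_rating(outcome, cf, profile, rng),
            }
        )
    return pd.DataFrame.from_records(records)


def simulate_cohort(
    profiles: Sequence[SubjectProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every subject on its own seeded schedule, counterbalanced."""
    frames = []
    for i, profile in enumerate(profiles):
        arm = "cf_first" if i % 2 == 0 else "nocf_first"
        schedule = build_task_schedule(seed=_spawn_int(seed, 1, i), counterbalance_arm=arm)
        frames.append(simulate_subject(profile, schedule, seed=_spawn_int(seed, 2, i)))
    return pd.concat(frames, ignore_index=True)


def _spawn_int(seed: int, stage: int, index: int) -> int:
    """Deterministic per-stage, per-subject substream of a global seed."""
    return int(np.random.SeedSequence((_mask(seed), stage, index)).generate_state(1)[0])


def profiles_frame(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    """Subjects table: id, trait anxiety, and true-parameter columns."""
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "stai_t": p.stai_t,
            "utility_exponent": p.utility_exponent,
            "counterfactual_weight": p.counterfactual_weight,
            "rating_noise_sd": p.rating_noise_sd,
            "start_max": p.lba.start_max,
            "threshold": p.lba.threshold,
            "nondecision": p.lba.nondecision,
            "drift_sd": p.lba.drift_sd,
        }
        for sid in STIMULUS_IDS:
            row[f"v_{sid}"] = p.lba.drift_means[sid]
        rows.append(row)
    return pd.DataFrame(rows)
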