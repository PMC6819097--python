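"""Synthetic cohorts: game logs, FC profiles and covariates.

The games and scans of the original study cannot be regenerated on a
desk, so this module simulates a cohort with the statistical structure
the analysis assumes. The generative agent model is deliberately
minimal:

* a latent scalar *ability* per participant (standard-normal scale);
* Game 1 — the confederate sender plays the seed code verbatim on every
  trial; the receiver guesses correctly with probability
  ``logistic(intercept + learn_rate * exposures(e) * exp(ability))``,
  an increasing learning curve (the current hearing counts as an
  exposure), and otherwise picks a wrong emotion uniformly;
* Game 2 — the participant, now sender, reproduces the code learned as
  receiver, independently altering each signal position with probability
  ``innovation_rate``; an altered position copies its left neighbor's
  degree with probability ``regularization_bias`` (a contour-smoothing,
  interval-shrinking move), else takes a uniform random allowed degree;
* six ROI-pair Fisher-z connectivity values per participant, each
  ``mean + loading * ability + Normal(0, noise_sd)``, with positive
  loadings on the interhemispheric STG pair so that connectivity
  correlates positively with learning/transmission and negatively with
  innovation.

Everything is deterministic under a single master seed; per-participant
substreams are spawned so participants are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .bp_scale import BPScaleConfig, GAME_DEGREES, ToneSequence
from .game_metrics import (
    CodeMap,
    EMOTIONS,
    GameLog,
    MeasureConfig,
    SECOND_HALF_START,
    Trial,
    compute_measure_set,
    modal_code,
)

__all__ = [
    "PAIR_LABELS",
    "ParticipantParams",
    "CohortSpec",
    "CohortBundle",
    "make_seed_codes",
    "simulate_game1",
    "simulate_game2",
    "simulate_fc",
    "simulate_cohort",
    "cohort_measure_frame",
    "loading_for_correlation",
]

#: The six unordered ROI pairs of the auditory network.
PAIR_LABELS: tuple[str, ...] = (
    "lHG-rHG", "lHG-lSTG", "lHG-rSTG", "rHG-lSTG", "rHG-rSTG", "lSTG-rSTG",
)

CONFEDERATE = "confederate"

# Seed signal sets: per set, two signals with contour entropy 1 bit, two
# with 0.81 bits, one monotone control (0 bits), all over the game keys.
_SEED_DEGREES = {
    "A": ((0, 4, 6, 4, 0), (4, 0, 6, 10, 7), (0, 4, 6, 10, 7), (10, 7, 6, 4, 6), (6, 6, 6, 6, 6)),
    "B": ((7, 10, 4, 0, 4), (6, 0, 4, 10, 6), (10, 6, 4, 0, 4), (4, 6, 7, 10, 7), (7, 7, 7, 7, 7)),
}


@dataclass(frozen=True)
class ParticipantParams:
    """Latent parameters of one simulated participant."""

    ability: float = 0.0
    learn_rate: float = 0.25
    innovation_rate: float = 0.35
    regularization_bias: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.innovation_rate <= 1.0:
            raise ValueError(f"innovation_rate must be in [0, 1], got {self.innovation_rate}")
        if not 0.0 <= self.regularization_bias <= 1.0:
            raise ValueError(f"regularization_bias must be in [0, 1], got {self.regularization_bias}")
        if self.learn_rate < 0:
            raise ValueError(f"learn_rate must be >= 0, got {self.learn_rate}")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level conditions of a simulated cohort.

    Defaults reproduce the study design: 51 participants, 70-trial
    learning game, 30-trial transmission game, counterbalanced seed sets,
    six ROI-pair z values with an interhemispheric-STG ability loading.
    """

    n_participants: int = 51
    n_trials_g1: int = 70
    n_trials_g2: int = 30
    fc_means: tuple[float, ...] = (0.35, 0.45, 0.30, 0.30, 0.45, 0.40)
    fc_loadings: tuple[float, ...] = (0.0, 0.11, 0.0, 0.0, 0.0, 0.11)
    fc_noise_sd: float = 0.25
    digit_span_mean: float = 6.5
    digit_span_sd: float = 1.2
    guess_intercept: float = float(logit(0.2))  # chance level, 1 of 5
    learn_rate: float = 0.25
    innovation_logit_mean: float = float(logit(0.35))
    innovation_ability_slope: float = 0.8
    innovation_logit_sd: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not self.fc_noise_sd > 0:
            raise ValueError("fc_noise_sd must be > 0")
        if len(self.fc_means) != len(PAIR_LABELS) or len(self.fc_loadings) != len(PAIR_LABELS):
            raise ValueError(f"fc_means/fc_loadings must have {len(PAIR_LABELS)} entries")


def make_seed_codes(scale: BPScaleConfig | None = None) -> dict[str, CodeMap]:
    """The two counterbalanced seed codes (sets A and B).

    Each set maps the five emotions to five signals whose contour
    entropies are exactly {1, 1, 0.81, 0.81, 0} bits, all degrees drawn
    from the five game keys.
    """
    scale = scale or BPScaleConfig()
    codes = {}
    for set_id, signal_degrees in _SEED_DEGREES.items():
        signals = {
            emotion: ToneSequence(degs, scale=scale, validate_degrees=True)
            for emotion, degs in zip(EMOTIONS, signal_degrees)
        }
        codes[set_id] = CodeMap.from_signals(signals)
    return codes


def _state_schedule(n_trials: int, rng: np.random.Generator) -> list[str]:
    """Emotion presentation order: balanced blocks of the five emotions,
    each block independently permuted."""
    if n_trials % len(EMOTIONS):
        raise ValueError(f"n_trials={n_trials} not a multiple of {len(EMOTIONS)}")
    states: list[str] = []
    for _ in range(n_trials // len(EMOTIONS)):
        states.extend(str(e) for e in rng.permutation(EMOTIONS))
    return states


def _guess(state: str, p_correct: float, rng: np.random.Generator) -> str:
    if rng.random() < p_correct:
        return state
    others = [e for e in EMOTIONS if e != state]
    return others[rng.integers(len(others))]


def simulate_game1(params: ParticipantParams, seed_code: CodeMap,
                   rng: np.random.Generator | int | None = None,
                   n_trials: int = 70, participant_id: str = "p00",
                   intercept: float = float(logit(0.2))) -> GameLog:
    """Simulate the 70-trial learning game against a fixed confederate."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = _state_schedule(n_trials, rng)
    exposures = {e: 0 for e in EMOTIONS}
    gain = params.learn_rate * float(np.exp(params.ability))
    trials = []
    for i, state in enumerate(states, start=1):
        exposures[state] += 1  # hearing the signal on this trial counts
        p = float(expit(intercept + gain * exposures[state]))
        guess = _guess(state, p, rng)
        trials.append(Trial.make(1, i, CONFEDERATE, participant_id, state,
                                 seed_code.modal[state], guess))
    return GameLog(tuple(trials))


def _mutate(signal: ToneSequence, params: ParticipantParams,
            rng: np.random.Generator, degrees: tuple[int, ...]) -> ToneSequence:
    out = list(signal.degrees)
    for i in range(len(out)):
        if rng.random() < params.innovation_rate:
            if i > 0 and rng.random() < params.regularization_bias:
                out[i] = out[i - 1]
            else:
                out[i] = degrees[rng.integers(len(degrees))]
    return ToneSequence(tuple(out))


def simulate_game2(params: ParticipantParams, learned_code: CodeMap,
                   rng: np.random.Generator | int | None = None,
                   n_trials: int = 30, participant_id: str = "p00",
                   intercept: float = float(logit(0.2)),
                   receiver_learn_rate: float = 0.25) -> GameLog:
    """Simulate the 30-trial transmission game with the participant as sender.

    The participant reproduces each emotion's learned signal with
    positionwise innovation (see module docstring); the confederate
    receiver is an average learner (ability 0). An emotion the
    participant never learned a signal for is improvised as a uniform
    random five-tone sequence over the game keys, fixed for the game.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    degrees = tuple(sorted(GAME_DEGREES))
    base: dict[str, ToneSequence] = {}
    for e in EMOTIONS:
        sig = learned_code.modal.get(e)
        if sig is None:
            sig = ToneSequence(tuple(degrees[j] for j in rng.integers(len(degrees), size=5)))
        base[e] = sig
    states = _state_schedule(n_trials, rng)
    exposures = {e: 0 for e in EMOTIONS}
    trials = []
    for i, state in enumerate(states, start=1):
        exposures[state] += 1
        signal = _mutate(base[state], params, rng, degrees)
        p = float(expit(intercept + receiver_learn_rate * exposures[state]))
        guess = _guess(state, p, rng)
        trials.append(Trial.make(2, i, participant_id, CONFEDERATE, state, signal, guess))
    return GameLog(tuple(trials))


def simulate_fc(abilities: np.ndarray, spec: CohortSpec,
                rng: np.random.Generator | int | None = None,
                participant_ids: list[str] | None = None) -> pd.DataFrame:
    """Fisher-z connectivity per participant: mean + loading*ability + noise."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    abilities = np.asarray(abilities, dtype=float)
    n = abilities.shape[0]
    z = (np.asarray(spec.fc_means)[None, :]
         + abilities[:, None] * np.asarray(spec.fc_loadings)[None, :]
         + rng.normal(0.0, spec.fc_noise_sd, size=(n, len(PAIR_LABELS))))
    index = participant_ids if participant_ids is not None else [f"p{i:02d}" for i in range(n)]
    return pd.DataFrame(z, columns=list(PAIR_LABELS), index=pd.Index(index, name="participant_id"))


def loading_for_correlation(r: float, noise_sd: float) -> float:
    """Ability loading giving population corr(z, ability) = r for unit-variance
    ability: beta = noise_sd * r / sqrt(1 - r**2)."""
    if not -1 < r < 1:
        raise ValueError("r must be in (-1, 1)")
    return noise_sd * r / float(np.sqrt(1 - r * r))


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces."""

    spec: CohortSpec
    participants: pd.DataFrame          # id, seed_set, latent params, digit span
    seed_codes: dict[str, CodeMap]      # the two counterbalanced sets
    logs: dict[str, tuple[GameLog, GameLog]]
    fc: pd.DataFrame                    # participants x 6 pair z values


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> ParticipantParams:
    ability = float(rng.normal())
    innovation = float(expit(spec.innovation_logit_mean
                             - spec.innovation_ability_slope * ability
                             + rng.normal(0.0, spec.innovation_logit_sd)))
    bias = float(rng.beta(2.0, 2.0))
    return ParticipantParams(ability=ability, learn_rate=spec.learn_rate,
                             innovation_rate=innovation, regularization_bias=bias)


def simulate_cohort(spec: CohortSpec | None = None) -> CohortBundle:
    """Simulate a full cohort, deterministic under ``spec.master_seed``.

    Seed sets A/B alternate across participants (counterbalancing); every
    participant gets an independent substream spawned from the master
    seed.
    """
    spec = spec or CohortSpec()
    seed_codes = make_seed_codes()
    master = np.random.SeedSequence(spec.master_seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    substreams = master.spawn(spec.n_participants + 1)[1:]

    rows = []
    logs: dict[str, tuple[GameLog, GameLog]] = {}
    abilities = []
    pids = []
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        pid = f"p{i:02d}"
        set_id = "A" if i % 2 == 0 else "B"
        params = _draw_params(spec, rng)
        g1 = simulate_game1(params, seed_codes[set_id], rng, spec.n_trials_g1, pid,
                            intercept=spec.guess_intercept)
        learned = _learned_code(g1)
        g2 = simulate_game2(params, learned, rng, spec.n_trials_g2, pid,
                            intercept=spec.guess_intercept,
                            receiver_learn_rate=spec.learn_rate)
        digit_span = int(np.clip(round(rng.normal(spec.digit_span_mean, spec.digit_span_sd)), 2, 9))
        rows.append({"participant_id": pid, "seed_set": set_id, "ability": params.ability,
                     "learn_rate": params.learn_rate, "innovation_rate": params.innovation_rate,
                     "regularization_bias": params.regularization_bias, "digit_span": digit_span})
        logs[pid] = (g1, g2)
        abilities.append(params.ability)
        pids.append(pid)

    participants = pd.DataFrame(rows).set_index("participant_id")
    fc = simulate_fc(np.array(abilities), spec, cohort_rng, participant_ids=pids)
    return CohortBundle(spec=spec, participants=participants, seed_codes=seed_codes,
                        logs=logs, fc=fc)


def _learned_code(g1: GameLog, half_start: int = SECOND_HALF_START) -> CodeMap:
    """The code the participant learned: receiver modal code, 2nd half of Game 1."""
    import warnings

    from .game_metrics import MissingCodeWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingCodeWarning)
        return modal_code(g1, role="receiver",
                          window=(half_start, max(t.index for t in g1.trials)))


def cohort_measure_frame(bundle: CohortBundle,
                         config: MeasureConfig | None = None) -> pd.DataFrame:
    """Per-participant MeasureSet rows for a whole cohort, as a DataFrame."""
    import warnings

    from .game_metrics import MissingCodeWarning

    cfg = config or MeasureConfig()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingCodeWarning)
        for pid, (g1, g2) in bundle.logs.items():
            set_id = bundle.participants.loc[pid, "seed_set"]
            ms = compute_measure_set(g1, g2, bundle.seed_codes[set_id], cfg, participant_id=pid)
            rows.append(ms.as_dict())
    return pd.DataFrame(rows).set_index("participant_id")
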