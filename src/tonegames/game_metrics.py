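"""Formal measures of signaling-game behavior and melodic structure.

A *signaling game* pairs a sender, who maps private states (here, five
emotions) to five-tone signals, with a receiver who maps signals back to
states. Each participant plays a 70-trial learning game (Game 1, as
receiver, against a confederate with a fixed code) and a 30-trial
transmission game (Game 2, as sender). From the two trial logs this module
computes:

* Hamming-based code measures — coordination (learning), transmission
  (recall fidelity), innovation (within-player code change) — on either
  the raw tone strings (length 5) or their contour transforms (length 4);
* an asymmetry index (S - R) / (S + R) over code-change counts, the
  direction of information flow between the players;
* accuracy (correct trials in Game 1);
* Shannon entropy of each signal and its contour (code complexity), and
  the Game 1 - Game 2 entropy difference as a regularization measure;
* the interval compression ratio (ICR), a permutation-based index of
  pitch proximity, and its between-game change.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field, fields
from typing import Iterable, Literal, Sequence

import numpy as np

from .bp_scale import Contour, ToneSequence, contour_transform

__all__ = [
    "EMOTIONS",
    "Trial",
    "GameLog",
    "CodeMap",
    "MeasureSet",
    "MeasureConfig",
    "hamming_similarity",
    "hamming_distance",
    "modal_code",
    "coordination",
    "transmission",
    "innovation",
    "asymmetry",
    "accuracy",
    "shannon_entropy",
    "mean_code_entropy",
    "mean_code_icr",
    "regularization_delta",
    "icr",
    "compute_measure_set",
]

#: The five states: three simple emotions and two compounds.
EMOTIONS: tuple[str, ...] = ("peace", "joy", "sadness", "peace+joy", "peace+sadness")

DistanceMode = Literal["tone", "contour"]

#: Trial window regarded as the second half of the 70-trial learning game.
SECOND_HALF_START = 36


class MissingCodeWarning(UserWarning):
    """An emotion had no contributing trials and was excluded from a mean."""


@dataclass(frozen=True)
class Trial:
    """One signaling round: a state shown, a signal sent, a guess made."""

    game_id: int
    index: int
    sender_id: str
    receiver_id: str
    state: str
    signal: ToneSequence
    guess: str
    correct: bool

    def __post_init__(self) -> None:
        if self.state not in EMOTIONS:
            raise ValueError(f"unknown state {self.state!r}")
        if self.guess not in EMOTIONS:
            raise ValueError(f"unknown guess {self.guess!r}")
        if self.correct != (self.state == self.guess):
            raise ValueError(
                f"trial {self.index}: correct={self.correct} inconsistent with "
                f"state={self.state!r} / guess={self.guess!r}"
            )

    @classmethod
    def make(cls, game_id: int, index: int, sender_id: str, receiver_id: str,
             state: str, signal: ToneSequence, guess: str) -> "Trial":
        return cls(game_id, index, sender_id, receiver_id, state, signal, guess,
                   correct=state == guess)


@dataclass(frozen=True)
class GameLog:
    """Ordered trials of one game; all trials share a game id."""

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        if not trials:
            raise ValueError("a game log needs at least one trial")
        if len({t.game_id for t in trials}) != 1:
            raise ValueError("all trials in a log must share game_id")
        indices = [t.index for t in trials]
        if len(set(indices)) != len(indices):
            raise ValueError("trial indices must be unique within a game")

    @property
    def game_id(self) -> int:
        return self.trials[0].game_id

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def window(self, start: int, stop: int | None = None) -> tuple[Trial, ...]:
        """Trials with 1-based ``start <= index <= stop`` (inclusive)."""
        stop = stop if stop is not None else max(t.index for t in self.trials)
        return tuple(t for t in self.trials if start <= t.index <= stop)


@dataclass
class CodeMap:
    """Per-emotion signal frequency tables with a modal signal each.

    A snapshot of a signaling system: for every emotion, how often each
    tone sequence was paired with it, and which signal was paired most
    often. Emotions with no contributing trials are flagged missing.
    """

    counts: dict[str, Counter]
    modal: dict[str, ToneSequence | None]

    @property
    def missing(self) -> set[str]:
        return {e for e, m in self.modal.items() if m is None}

    def signals(self) -> dict[str, ToneSequence]:
        """Modal signal per emotion, missing emotions excluded."""
        return {e: m for e, m in self.modal.items() if m is not None}

    @classmethod
    def from_signals(cls, signals: dict[str, ToneSequence]) -> "CodeMap":
        """Build a degenerate CodeMap from one fixed signal per emotion."""
        counts = {e: Counter({s.degrees: 1}) for e, s in signals.items()}
        modal: dict[str, ToneSequence | None] = dict(signals)
        for e in EMOTIONS:
            counts.setdefault(e, Counter())
            modal.setdefault(e, None)
        return cls(counts=counts, modal=modal)


# ---------------------------------------------------------------------------
# string distances

def _symbols(seq: ToneSequence | Contour | Sequence[int], mode: DistanceMode | None = None) -> tuple[int, ...]:
    if isinstance(seq, ToneSequence):
        if mode == "contour":
            return contour_transform(seq).directions
        return seq.degrees
    if isinstance(seq, Contour):
        return seq.directions
    return tuple(seq)


def hamming_distance(a, b, mode: DistanceMode | None = None) -> float:
    """Normalized Hamming distance S/L between two equal-length strings."""
    sa, sb = _symbols(a, mode), _symbols(b, mode)
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb)) / len(sa)


def hamming_similarity(a, b, mode: DistanceMode | None = None) -> float:
    """1 - normalized Hamming distance; 1 iff identical, 0 iff all differ."""
    return 1.0 - hamming_distance(a, b, mode)


# ---------------------------------------------------------------------------
# code extraction

def modal_code(log: GameLog, role: Literal["sender", "receiver"],
               window: tuple[int, int] | None = None) -> CodeMap:
    """Most frequent signal per emotion within a trial window.

    ``role='sender'`` tallies the signal produced for each shown state;
    ``role='receiver'`` tallies the heard signal for each guessed emotion.
    Ties break to the signal whose maximal count was attained at the
    earliest trial; any residual tie breaks to the lowest lexicographic
    degree sequence. Emotions with no contributing trials get a None modal
    entry and are excluded (with a warning) from downstream means.
    """
    trials = log.window(*window) if window else log.trials
    counts: dict[str, Counter] = {e: Counter() for e in EMOTIONS}
    # trial at which each (emotion, signal) reached its current count
    reached_at: dict[tuple[str, tuple[int, ...]], int] = {}
    for t in sorted(trials, key=lambda t: t.index):
        emotion = t.state if role == "sender" else t.guess
        key = t.signal.degrees
        counts[emotion][key] += 1
        reached_at[(emotion, key)] = t.index
    modal: dict[str, ToneSequence | None] = {}
    for e in EMOTIONS:
        if not counts[e]:
            modal[e] = None
            warnings.warn(f"no {role} trials for emotion {e!r} in window", MissingCodeWarning)
            continue
        best = max(counts[e].values())
        tied = [sig for sig, c in counts[e].items() if c == best]
        tied.sort(key=lambda sig: (reached_at[(e, sig)], sig))
        modal[e] = ToneSequence(tied[0])
    return CodeMap(counts=counts, modal=modal)


def _sender_code(log: GameLog) -> CodeMap:
    """The sender's code over the full game (constant for a confederate)."""
    return modal_code(log, role="sender")


# ---------------------------------------------------------------------------
# behavioral measures

def coordination(log_g1: GameLog, mode: DistanceMode = "tone",
                 method: Literal["set_mean", "modal"] = "set_mean",
                 half_start: int = SECOND_HALF_START) -> tuple[dict[str, float], float]:
    """Sender-receiver code similarity in the second half of Game 1.

    For each emotion, compare the sender's signal with what the receiver
    mapped to that emotion in trials ``half_start``..end: either the mean
    similarity over the whole set of mapped signals (``set_mean``) or the
    similarity to the receiver's modal signal only (``modal``). Returns
    per-emotion values and their mean; 1 = fully shared system.
    """
    sender = _sender_code(log_g1)
    second_half = log_g1.window(half_start)
    per_emotion: dict[str, float] = {}
    if method == "modal":
        receiver = modal_code(log_g1, role="receiver", window=(half_start, max(t.index for t in log_g1.trials)))
    for e in EMOTIONS:
        sig = sender.modal.get(e)
        if sig is None:
            continue
        if method == "set_mean":
            mapped = [t.signal for t in second_half if t.guess == e]
            if not mapped:
                warnings.warn(f"receiver mapped nothing to {e!r} in second half", MissingCodeWarning)
                continue
            per_emotion[e] = float(np.mean([hamming_similarity(sig, s, mode) for s in mapped]))
        elif method == "modal":
            rsig = receiver.modal.get(e)
            if rsig is None:
                continue
            per_emotion[e] = hamming_similarity(sig, rsig, mode)
        else:
            raise ValueError(f"unknown coordination method {method!r}")
    if not per_emotion:
        return {}, float("nan")
    return per_emotion, float(np.mean(list(per_emotion.values())))


def transmission(seed_code: CodeMap, log_g2: GameLog, mode: DistanceMode = "tone",
                 method: Literal["modal", "all_trials"] = "modal") -> float:
    """Similarity between the seed code and the Game-2 sender's code.

    Per emotion, compare the seed signal with the Game-2 sender's modal
    signal (or with every Game-2 signal for that emotion under
    ``all_trials``); mean over emotions. 1 = faithful transmission.
    """
    per_emotion: list[float] = []
    if method == "modal":
        g2 = modal_code(log_g2, role="sender")
        for e, seed_sig in seed_code.signals().items():
            g2_sig = g2.modal.get(e)
            if g2_sig is None:
                continue
            per_emotion.append(hamming_similarity(seed_sig, g2_sig, mode))
    elif method == "all_trials":
        for e, seed_sig in seed_code.signals().items():
            sigs = [t.signal for t in log_g2.trials if t.state == e]
            if not sigs:
                continue
            per_emotion.append(float(np.mean([hamming_similarity(seed_sig, s, mode) for s in sigs])))
    else:
        raise ValueError(f"unknown transmission method {method!r}")
    return float(np.mean(per_emotion)) if per_emotion else float("nan")


def innovation(log_g1: GameLog, log_g2: GameLog, mode: DistanceMode = "tone",
               half_start: int = SECOND_HALF_START) -> float:
    """Within-player code change: mean Hamming *distance* between the code
    learned as receiver (second half of Game 1, modal) and the code
    produced as sender in Game 2 (modal). 0 = nothing changed."""
    learned = modal_code(log_g1, role="receiver",
                         window=(half_start, max(t.index for t in log_g1.trials)))
    produced = modal_code(log_g2, role="sender")
    dists = [hamming_distance(s, produced.modal[e], mode)
             for e, s in learned.signals().items() if produced.modal.get(e) is not None]
    return float(np.mean(dists)) if dists else float("nan")


def asymmetry(log: GameLog) -> float:
    """Directional information flow (S - R) / (S + R) over code changes.

    A *sender change* is a trial whose produced signal for a state differs
    from that sender's most recent signal for the same state; a *receiver
    change* is a trial whose guess for a previously heard signal differs
    from the receiver's most recent guess for the identical signal. First
    occurrences are not changes. -1 = only the receiver adapts (as in
    Game 1 with a fixed confederate code), +1 = only the sender does.
    Undefined (NaN, with a warning) when no changes occurred at all.
    """
    S = R = 0
    last_signal: dict[str, tuple[int, ...]] = {}
    last_guess: dict[tuple[int, ...], str] = {}
    for t in sorted(log.trials, key=lambda t: t.index):
        key = t.signal.degrees
        if t.state in last_signal and last_signal[t.state] != key:
            S += 1
        last_signal[t.state] = key
        if key in last_guess and last_guess[key] != t.guess:
            R += 1
        last_guess[key] = t.guess
    if S + R == 0:
        warnings.warn("no code changes by either player; asymmetry undefined", MissingCodeWarning)
        return float("nan")
    return (S - R) / (S + R)


def accuracy(log_g1: GameLog) -> int:
    """Number of correct trials (state == guess) — individual performance."""
    return sum(t.correct for t in log_g1.trials)


# ---------------------------------------------------------------------------
# structural measures

def shannon_entropy(symbols: Iterable) -> float:
    """Shannon entropy H(X) = -sum p(x) log2 p(x) of the empirical symbol
    distribution within one sequence, in bits; 0*log(0) is taken as 0."""
    counts = np.array(list(Counter(symbols).values()), dtype=float)
    if counts.size == 0:
        raise ValueError("cannot compute entropy of an empty sequence")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum()) + 0.0


def mean_code_entropy(code: CodeMap | dict[str, ToneSequence] | Sequence[ToneSequence],
                      mode: DistanceMode = "tone") -> float:
    """Mean per-signal entropy over the five emotions of a code.

    Tone mode measures the distribution of the five degrees of each
    signal; contour mode the four interval directions.
    """
    signals = _code_signals(code)
    if not signals:
        warnings.warn("no signals available for entropy", MissingCodeWarning)
        return float("nan")
    return float(np.mean([shannon_entropy(_symbols(s, mode)) for s in signals]))


def _code_signals(code) -> list[ToneSequence]:
    if isinstance(code, CodeMap):
        return list(code.signals().values())
    if isinstance(code, dict):
        return list(code.values())
    return list(code)


def _mean_abs_interval(degrees: np.ndarray) -> np.ndarray:
    """Mean absolute successive interval, in scale steps (macrotones)."""
    return np.abs(np.diff(degrees, axis=-1)).mean(axis=-1)


def icr(seq: ToneSequence | Sequence[int], n_shuffles: int = 100,
        rng: np.random.Generator | None = None, exact: bool = False) -> float:
    """Interval compression ratio: shuffled-over-original mean interval.

    The numerator is the mean, over random reorderings of the tones, of
    the reordered sequence's mean absolute successive interval — by
    default ``n_shuffles`` position permutations sampled uniformly with
    replacement, or all 120 permutations with ``exact=True``. The
    denominator is the original sequence's mean absolute interval.
    Values > 1 indicate a bias toward small (proximal) intervals.

    A constant sequence has a zero denominator; by convention its ICR is
    1.0, flagged with a warning (the monotone control signal).
    """
    degrees = np.asarray(_symbols(seq), dtype=float)
    denom = float(_mean_abs_interval(degrees))
    if denom == 0.0:
        warnings.warn("constant sequence: ICR degenerate, returning 1.0", MissingCodeWarning)
        return 1.0
    if exact:
        perms = np.array(list(itertools.permutations(degrees)))
        num = float(_mean_abs_interval(perms).mean())
    else:
        rng = rng if rng is not None else np.random.default_rng()
        shuffled = rng.permuted(np.tile(degrees, (n_shuffles, 1)), axis=1)
        num = float(_mean_abs_interval(shuffled).mean())
    return num / denom


def mean_code_icr(code, n_shuffles: int = 100, rng: np.random.Generator | None = None,
                  exact: bool = False, include_degenerate: bool = True) -> float:
    """Mean ICR over a code's five signals.

    Degenerate (constant) signals contribute 1.0 by convention; set
    ``include_degenerate=False`` to average over non-constant signals only.
    """
    signals = _code_signals(code)
    values = []
    for s in signals:
        degrees = np.asarray(_symbols(s), dtype=float)
        degenerate = float(_mean_abs_interval(degrees)) == 0.0
        if degenerate and not include_degenerate:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MissingCodeWarning)
            values.append(icr(s, n_shuffles=n_shuffles, rng=rng, exact=exact))
    return float(np.mean(values)) if values else float("nan")


def regularization_delta(measure_g1: float, measure_g2: float,
                         kind: Literal["entropy", "icr"]) -> float:
    """Between-game structural change; positive = regularization.

    Entropy: ``H_g1 - H_g2`` (positive when the participant reduced code
    complexity in Game 2). ICR: ``ICR_g2 - ICR_g1`` (positive when the
    reproduced signals compress intervals more strongly).
    """
    if kind == "entropy":
        return measure_g1 - measure_g2
    if kind == "icr":
        return measure_g2 - measure_g1
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# the full per-participant measure set

@dataclass
class MeasureConfig:
    """Options governing measure computation for one participant."""

    coordination_method: Literal["set_mean", "modal"] = "set_mean"
    transmission_method: Literal["modal", "all_trials"] = "modal"
    half_start: int = SECOND_HALF_START
    icr_shuffles: int = 100
    icr_exact: bool = False
    seed: int | None = 0


@dataclass
class MeasureSet:
    """All behavioral and structural measures for one participant."""

    participant_id: str
    coordination_tone: float
    coordination_contour: float
    transmission_tone: float
    transmission_contour: float
    innovation_tone: float
    innovation_contour: float
    asymmetry_g2: float
    accuracy: int
    entropy_tone_g1: float
    entropy_tone_g2: float
    entropy_contour_g1: float
    entropy_contour_g2: float
    icr_g1: float
    icr_g2: float
    delta_entropy_tone: float
    delta_entropy_contour: float
    delta_icr: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_measure_set(log_g1: GameLog, log_g2: GameLog, seed_code: CodeMap,
                        config: MeasureConfig | None = None,
                        participant_id: str | None = None) -> MeasureSet:
    """Compute every measure for one participant's pair of game logs.

    Game-1 entropies and ICR are those of the seed code the confederate
    played; Game-2 values are those of the participant-as-sender modal
    code. Deterministic given ``config.seed`` (used for ICR shuffling).
    """
    cfg = config or MeasureConfig()
    rng = np.random.default_rng(cfg.seed)
    pid = participant_id or log_g1.trials[0].receiver_id

    _, coord_tone = coordination(log_g1, "tone", cfg.coordination_method, cfg.half_start)
    _, coord_contour = coordination(log_g1, "contour", cfg.coordination_method, cfg.half_start)
    g2_code = modal_code(log_g2, role="sender")

    h_tone_g1 = mean_code_entropy(seed_code, "tone")
    h_tone_g2 = mean_code_entropy(g2_code, "tone")
    h_cont_g1 = mean_code_entropy(seed_code, "contour")
    h_cont_g2 = mean_code_entropy(g2_code, "contour")
    icr_g1 = mean_code_icr(seed_code, cfg.icr_shuffles, rng, cfg.icr_exact)
    icr_g2 = mean_code_icr(g2_code, cfg.icr_shuffles, rng, cfg.icr_exact)

    return MeasureSet(
        participant_id=pid,
        coordination_tone=coord_tone,
        coordination_contour=coord_contour,
        transmission_tone=transmission(seed_code, log_g2, "tone", cfg.transmission_method),
        transmission_contour=transmission(seed_code, log_g2, "contour", cfg.transmission_method),
        innovation_tone=innovation(log_g1, log_g2, "tone", cfg.half_start),
        innovation_contour=innovation(log_g1, log_g2, "contour", cfg.half_start),
        asymmetry_g2=asymmetry(log_g2),
        accuracy=accuracy(log_g1),
        entropy_tone_g1=h_tone_g1,
        entropy_tone_g2=h_tone_g2,
        entropy_contour_g1=h_cont_g1,
        entropy_contour_g2=h_cont_g2,
        icr_g1=icr_g1,
        icr_g2=icr_g2,
        delta_entropy_tone=regularization_delta(h_tone_g1, h_tone_g2, "entropy"),
        delta_entropy_contour=regularization_delta(h_cont_g1, h_cont_g2, "entropy"),
        delta_icr=regularization_delta(icr_g1, icr_g2, "icr"),
    )
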