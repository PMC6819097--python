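"""Auditory oddball stimulus stream and balanced event-set generation.

The functional-localizer run is a roving oddball: 1260 five-tone BP
sequences, 80% standards and 10% each of contour deviants (the fourth
tone flips the direction of the 3rd-to-4th interval while keeping its
size) and interval deviants (same direction, different size). Deviants of
one type always come in pairs 2400-4800 ms apart to strengthen the
oddball response, and every sequence is transposed to one of three
registers at random. For balanced GLM contrasts a subset of standards,
equal in number to one deviant category (126) and flanked by at least
five standards on each side, is extracted; the 882 left over are modeled
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bp_scale import BPScaleConfig, ToneSequence, contour_transform

__all__ = [
    "OddballTrial",
    "OddballDesign",
    "build_sequences",
    "generate_design",
    "extract_balanced_standards",
    "write_events_table",
    "read_events_table",
    "render_sequence",
    "render_audio",
]

#: Degree pattern of the standard sequence relative to a register base
#: (base 0 at k=440 Hz gives the printed 440, 521, 567, 617, 730.6 Hz).
STANDARD_OFFSETS = (0, 2, 3, 4, 6)

#: Register bases: lowest tones at degrees 0, 1, 3 (~440, 479, 567 Hz).
REGISTER_BASES = (0, 1, 3)

#: Highest degree renderable; two tritaves above the fundamental.
MAX_DEGREE = 26

TONE_MS = 50.0
TONE_GAP_MS = 50.0
RISE_FALL_MS = 5.0
SEQUENCE_MS = 5 * TONE_MS + 4 * TONE_GAP_MS  # 450 ms
ISI_MS = 750.0
STIM_PERIOD_MS = SEQUENCE_MS + ISI_MS  # 1200 ms onset-to-onset

CONDITIONS = ("STD", "C_DEV", "I_DEV")


@dataclass(frozen=True)
class OddballTrial:
    index: int
    condition: str
    onset_ms: float
    register: int
    sequence: ToneSequence


@dataclass
class OddballDesign:
    """An ordered oddball stimulus stream plus the balanced event split."""

    trials: tuple[OddballTrial, ...]
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    modeled_standards: frozenset[int] | None = None
    remaining_standards: frozenset[int] | None = None

    @property
    def n_total(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            counts[t.condition] += 1
        return counts

    def standard_indices(self) -> list[int]:
        return [t.index for t in self.trials if t.condition == "STD"]

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table: onset (s), duration (s), trial_type, register."""
        return pd.DataFrame({
            "onset": [t.onset_ms / 1000.0 for t in self.trials],
            "duration": [SEQUENCE_MS / 1000.0] * self.n_total,
            "trial_type": [t.condition for t in self.trials],
            "register": [t.register for t in self.trials],
        })


def build_sequences(register: int) -> tuple[ToneSequence, ToneSequence, ToneSequence]:
    """Standard, contour-deviant and interval-deviant sequences at a register.

    The standard is the fixed five-tone pattern transposed so its lowest
    tone is at degree ``register``. The contour deviant alters only the
    fourth tone so the 3rd-to-4th interval flips direction but keeps its
    absolute size; the interval deviant keeps the direction and changes
    the size (minimal degree change). Tones 1-3 and 5 are untouched.
    """
    if register not in REGISTER_BASES:
        raise ValueError(f"register must be one of {REGISTER_BASES}, got {register}")
    std = tuple(register + o for o in STANDARD_OFFSETS)
    step = std[3] - std[2]  # +1 in the standard pattern
    c_dev = std[:3] + (std[2] - step,) + std[4:]
    i_dev = std[:3] + (std[2] + 2 * step,) + std[4:]
    for name, degs in (("standard", std), ("C-deviant", c_dev), ("I-deviant", i_dev)):
        if any(d < 0 or d > MAX_DEGREE for d in degs):
            raise ValueError(f"{name} at register {register} leaves the renderable range: {degs}")
    make = lambda degs: ToneSequence(degs, scale=BPScaleConfig())
    return make(std), make(c_dev), make(i_dev)


def _pair_layout(n_std: int, pair_types: list[str], gaps: np.ndarray,
                 rng: np.random.Generator) -> list[int]:
    """Standards allocated to the slots around/between deviant pairs.

    Same-type adjacent pairs get >= 4 intervening standards so that a
    deviant's nearest same-type neighbor is always its partner; the
    surplus is laid down in chunks of 16 so that long standard runs exist
    for the flank-constrained extraction.
    """
    n_pairs = len(pair_types)
    slots = np.zeros(n_pairs + 1, dtype=int)
    for j in range(1, n_pairs):
        slots[j] = 4 if pair_types[j] == pair_types[j - 1] else 1
    interior = int((gaps - 1).sum())
    leftover = n_std - interior - int(slots.sum())
    if leftover < 0:
        raise ValueError("infeasible design: too many deviants for the pairing/gap rules")
    chunk = 16
    while leftover > 0:
        take = min(chunk, leftover)
        slots[rng.integers(0, n_pairs + 1)] += take
        leftover -= take
    return slots.tolist()


def generate_design(n_total: int = 1260, rng: np.random.Generator | int | None = None,
                    pair_gap_ms: tuple[float, float] = (2400.0, 4800.0),
                    isi_ms: float = ISI_MS) -> OddballDesign:
    """Generate a full oddball stream with paired deviants.

    Counts are exact (80/10/10); each deviant belongs to a same-type pair
    whose onset gap falls within ``pair_gap_ms``; registers are assigned
    uniformly at random per trial. Deterministic given the rng seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_total % 10 or (n_total // 10) % 2:
        raise ValueError(f"n_total={n_total} incompatible with paired 80/10/10 proportions")
    n_c = n_i = n_total // 10
    n_std = n_total - n_c - n_i
    period = SEQUENCE_MS + isi_ms
    lo = int(np.ceil(pair_gap_ms[0] / period))
    hi = int(np.floor(pair_gap_ms[1] / period))
    if hi < lo:
        raise ValueError("pair gap window admits no integer stimulus offset")

    pair_types = ["C_DEV"] * (n_c // 2) + ["I_DEV"] * (n_i // 2)
    rng.shuffle(pair_types)
    gaps = rng.integers(lo, hi + 1, size=len(pair_types))  # partner offset in positions
    slots = _pair_layout(n_std, pair_types, gaps, rng)

    conditions: list[str] = []
    conditions.extend(["STD"] * slots[0])
    for ptype, gap, slot_after in zip(pair_types, gaps, slots[1:]):
        conditions.append(ptype)
        conditions.extend(["STD"] * (gap - 1))
        conditions.append(ptype)
        conditions.extend(["STD"] * slot_after)
    assert len(conditions) == n_total

    registers = rng.choice(REGISTER_BASES, size=n_total)
    by_register = {r: build_sequences(r) for r in REGISTER_BASES}
    cond_slot = {"STD": 0, "C_DEV": 1, "I_DEV": 2}
    trials = tuple(
        OddballTrial(index=i, condition=c, onset_ms=i * period, register=int(r),
                     sequence=by_register[int(r)][cond_slot[c]])
        for i, (c, r) in enumerate(zip(conditions, registers))
    )
    return OddballDesign(trials=trials)


def extract_balanced_standards(design: OddballDesign,
                               rng: np.random.Generator | int | None = None,
                               flank: int = 5,
                               n_extract: int | None = None) -> tuple[frozenset[int], frozenset[int]]:
    """Randomly extract standards for the balanced GLM contrast.

    Picks ``n_extract`` standards (default: the size of one deviant
    category) uniformly among those preceded and followed by at least
    ``flank`` standards in the stream; the rest of the standards are the
    explicitly modeled remainder. Sets ``design.modeled_standards`` /
    ``design.remaining_standards`` and returns both.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = design.condition_counts()
    if n_extract is None:
        n_extract = counts["C_DEV"]
    is_std = np.array([t.condition == "STD" for t in design.trials])
    n = len(is_std)
    eligible = [
        i for i in range(flank, n - flank)
        if is_std[i] and is_std[i - flank:i].all() and is_std[i + 1:i + 1 + flank].all()
    ]
    if len(eligible) < n_extract:
        raise ValueError(
            f"flank constraint infeasible: {len(eligible)} eligible standards, "
            f"{n_extract} requested (flank={flank}, n_total={n})"
        )
    modeled = frozenset(int(i) for i in rng.choice(eligible, size=n_extract, replace=False))
    remaining = frozenset(design.standard_indices()) - modeled
    design.modeled_standards = modeled
    design.remaining_standards = remaining
    return modeled, remaining


def write_events_table(design: OddballDesign, path: str | Path) -> Path:
    """Write the design as a BIDS-style tab-separated events table."""
    path = Path(path)
    design.to_events_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# optional audio rendering

def render_sequence(seq: ToneSequence, sample_rate: int = 22050) -> np.ndarray:
    """Render one sequence: 50 ms sinusoidal tones with 5 ms linear
    rise/fall ramps, separated by 50 ms of silence (450 ms total)."""
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8 kHz")
    n_tone = int(round(TONE_MS / 1000 * sample_rate))
    n_gap = int(round(TONE_GAP_MS / 1000 * sample_rate))
    n_ramp = int(round(RISE_FALL_MS / 1000 * sample_rate))
    envelope = np.ones(n_tone)
    envelope[:n_ramp] = np.linspace(0, 1, n_ramp, endpoint=False)
    envelope[-n_ramp:] = np.linspace(1, 0, n_ramp)
    t = np.arange(n_tone) / sample_rate
    chunks = []
    freqs = seq.frequencies()
    for j, f in enumerate(freqs):
        chunks.append(np.sin(2 * np.pi * f * t) * envelope)
        if j < len(freqs) - 1:
            chunks.append(np.zeros(n_gap))
    return np.concatenate(chunks)


def render_audio(design: OddballDesign, sample_rate: int = 22050,
                 n_trials: int | None = None) -> np.ndarray:
    """Render the first ``n_trials`` of a design (default: all) including
    the 750 ms inter-sequence silences, as one float waveform in [-1, 1]."""
    trials = design.trials[: n_trials if n_trials is not None else design.n_total]
    n_isi = int(round(ISI_MS / 1000 * sample_rate))
    chunks = []
    for t in trials:
        chunks.append(render_sequence(t.sequence, sample_rate))
        chunks.append(np.zeros(n_isi))
    return np.concatenate(chunks)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int = 22050) -> Path:
    """Write a waveform as 16-bit PCM WAV (optional convenience)."""
    from scipy.io import wavfile

    path = Path(path)
    scaled = np.clip(waveform, -1, 1)
    wavfile.write(path, sample_rate, (scaled * 32767).astype(np.int16))
    return path
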