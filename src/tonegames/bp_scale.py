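"""Bohlen-Pierce (BP) scale arithmetic and melodic sequence types.

The BP scale divides the tritave (a 3:1 frequency ratio) into 13
logarithmically even steps, so the frequency of scale step ``n`` over a
fundamental ``k`` is ``F = k * 3**(n/13)``. Signals in the games are
five-tone sequences over a fixed subset of scale degrees; their melodic
*contour* is the sequence of the four interval directions (up / repeat /
down) between adjacent tones. Degrees, not frequencies, are the canonical
representation throughout the package — Hz values are derived for display
and audio only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAME_DEGREES",
    "BPScaleConfig",
    "ToneSequence",
    "Contour",
    "bp_frequency",
    "sequence_frequencies",
    "contour_transform",
]

#: Scale degrees available on the five keys of the game keyboard.
GAME_DEGREES: frozenset[int] = frozenset({0, 4, 6, 7, 10})

#: Number of tones in every game/oddball signal.
SEQUENCE_LENGTH = 5


@dataclass(frozen=True)
class BPScaleConfig:
    """Parameters of an equal-tempered Bohlen-Pierce scale.

    Parameters
    ----------
    fundamental_hz:
        Fundamental frequency ``k`` in Hz (default 440).
    steps_per_tritave:
        Number of equal steps the 3:1 tritave is divided into (13 for the
        standard equal-tempered BP scale).
    allowed_degrees:
        Degrees playable in game mode; the default is the five keys used
        in the signaling games.
    """

    fundamental_hz: float = 440.0
    steps_per_tritave: int = 13
    allowed_degrees: frozenset[int] = GAME_DEGREES

    def __post_init__(self) -> None:
        if not self.fundamental_hz > 0:
            raise ValueError(f"fundamental_hz must be > 0, got {self.fundamental_hz}")
        if self.steps_per_tritave < 1:
            raise ValueError(f"steps_per_tritave must be >= 1, got {self.steps_per_tritave}")
        if not self.allowed_degrees:
            raise ValueError("allowed_degrees must be non-empty")
        object.__setattr__(self, "allowed_degrees", frozenset(self.allowed_degrees))


def bp_frequency(k: float, n: int | np.ndarray, steps_per_tritave: int = 13) -> float | np.ndarray:
    """Frequency in Hz of BP scale step ``n`` above fundamental ``k``.

    Computes ``k * 3**(n / steps_per_tritave)``; strictly increasing in
    ``n``, with ``bp_frequency(k, steps_per_tritave) == 3 * k``.
    """
    if not k > 0:
        raise ValueError(f"fundamental k must be > 0, got {k}")
    return k * 3.0 ** (np.asarray(n) / steps_per_tritave) if isinstance(n, np.ndarray) else k * 3.0 ** (n / steps_per_tritave)


@dataclass(frozen=True)
class ToneSequence:
    """A five-tone melodic signal, stored as BP scale-degree indices.

    ``validate_degrees=True`` (game mode) additionally requires every
    degree to lie in ``scale.allowed_degrees``; the oddball generator
    disables this because its transposed registers leave the game keyset.
    """

    degrees: tuple[int, ...]
    # scale and validation mode are configuration, not identity: two signals
    # with the same degrees are the same signal
    scale: BPScaleConfig = field(default_factory=BPScaleConfig, compare=False)
    validate_degrees: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        degrees = tuple(int(d) for d in self.degrees)
        object.__setattr__(self, "degrees", degrees)
        if len(degrees) != SEQUENCE_LENGTH:
            raise ValueError(f"a tone sequence has exactly {SEQUENCE_LENGTH} tones, got {len(degrees)}")
        if self.validate_degrees:
            bad = [d for d in degrees if d not in self.scale.allowed_degrees]
            if bad:
                raise ValueError(f"degrees {bad} not in allowed set {sorted(self.scale.allowed_degrees)}")

    def frequencies(self) -> list[float]:
        return sequence_frequencies(self)

    def contour(self) -> "Contour":
        return contour_transform(self)

    def __str__(self) -> str:
        return " ".join(str(d) for d in self.degrees)

    @classmethod
    def parse(cls, text: str, scale: BPScaleConfig | None = None, validate_degrees: bool = False) -> "ToneSequence":
        """Parse the serialized form: five space-separated integers."""
        try:
            degrees = tuple(int(tok) for tok in text.split())
        except ValueError as exc:
            raise ValueError(f"cannot parse tone sequence from {text!r}") from exc
        return cls(degrees, scale=scale or BPScaleConfig(), validate_degrees=validate_degrees)


@dataclass(frozen=True)
class Contour:
    """Relative contour of a tone sequence: four directions in {+1, 0, -1}.

    The alphabet is ternary: the monotone (all-equal) control signal needs
    a 'repeat' symbol (0) for its contour entropy to be 0 bits.
    """

    directions: tuple[int, ...]

    def __post_init__(self) -> None:
        directions = tuple(int(d) for d in self.directions)
        object.__setattr__(self, "directions", directions)
        if len(directions) != SEQUENCE_LENGTH - 1:
            raise ValueError(f"a contour has exactly {SEQUENCE_LENGTH - 1} directions, got {len(directions)}")
        if any(d not in (-1, 0, 1) for d in directions):
            raise ValueError(f"contour directions must be in {{-1, 0, +1}}, got {directions}")


def sequence_frequencies(seq: ToneSequence) -> list[float]:
    """Hz value of each tone of ``seq`` (elementwise BP formula)."""
    k = seq.scale.fundamental_hz
    steps = seq.scale.steps_per_tritave
    return [bp_frequency(k, n, steps) for n in seq.degrees]


def contour_transform(seq: ToneSequence | Sequence[int]) -> Contour:
    """Relative contour of a sequence: sign of each successive degree step."""
    degrees: Iterable[int] = seq.degrees if isinstance(seq, ToneSequence) else seq
    d = np.asarray(list(degrees))
    return Contour(tuple(int(s) for s in np.sign(np.diff(d))))
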