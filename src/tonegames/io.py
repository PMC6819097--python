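"""File formats and run configuration.

All artifacts are plain UTF-8 CSV/TSV with headers. Game logs carry one
trial per row; the five-tone signal is serialized as five space-separated
degree integers in one field. FC profiles are long-format
(participant_id, pair_label, z). Parse errors report offending line
numbers; the ``correct`` column is validated against state/guess.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .bp_scale import ToneSequence
from .game_metrics import GameLog, MeasureSet, Trial
from .synthetic import CONFEDERATE, CohortBundle, PAIR_LABELS

__all__ = [
    "GAME_LOG_COLUMNS",
    "RunConfig",
    "write_game_logs",
    "read_game_logs",
    "write_measures",
    "read_measures",
    "write_fc",
    "read_fc",
    "write_cohort",
]

GAME_LOG_COLUMNS = [
    "participant_id", "game_id", "trial", "sender_role",
    "state", "signal", "guess", "correct",
]


class GameLogParseError(ValueError):
    """A game-log CSV violated the schema; message lists line numbers."""


class RunConfig(BaseModel):
    """Validated pipeline configuration with study defaults."""

    master_seed: int = 0
    n_participants: int = Field(51, ge=2)
    n_trials_g1: int = 70
    n_trials_g2: int = 30
    coordination_method: str = "set_mean"
    transmission_method: str = "modal"
    half_start: int = 36
    icr_shuffles: int = Field(100, ge=1)
    icr_exact: bool = False
    family_alpha: float = Field(0.05, gt=0, lt=1)
    n_tests: int = Field(7, ge=1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path


# ---------------------------------------------------------------------------
# game logs

def _log_rows(participant_id: str, log: GameLog) -> Iterable[dict]:
    for t in sorted(log.trials, key=lambda t: t.index):
        role = "confederate" if t.sender_id == CONFEDERATE else "participant"
        yield {
            "participant_id": participant_id, "game_id": t.game_id, "trial": t.index,
            "sender_role": role, "state": t.state, "signal": str(t.signal),
            "guess": t.guess, "correct": int(t.correct),
        }


def write_game_logs(logs: dict[str, tuple[GameLog, GameLog]] | list[tuple[str, GameLog]],
                    path: str | Path) -> Path:
    """Serialize game logs to the trial-level CSV format."""
    rows: list[dict] = []
    if isinstance(logs, dict):
        items = [(pid, g) for pid, pair in logs.items() for g in pair]
    else:
        items = list(logs)
    for pid, log in items:
        rows.extend(_log_rows(pid, log))
    path = Path(path)
    pd.DataFrame(rows, columns=GAME_LOG_COLUMNS).to_csv(path, index=False)
    return path


def read_game_logs(path: str | Path) -> list[tuple[str, GameLog]]:
    """Parse a game-log CSV into (participant_id, GameLog) pairs.

    Raises :class:`GameLogParseError` listing offending line numbers on
    schema violations (bad signals, unknown labels, or a ``correct``
    flag inconsistent with state/guess).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GAME_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise GameLogParseError(f"{path}: missing columns {missing}")
    errors: list[str] = []
    trials: dict[tuple[str, int], list[Trial]] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            pid = row.participant_id
            game_id = int(row.game_id)
            index = int(row.trial)
            signal = ToneSequence.parse(row.signal)
            correct = bool(int(row.correct))
            role = row.sender_role
            if role not in ("participant", "confederate"):
                raise ValueError(f"unknown sender_role {role!r}")
            sender = CONFEDERATE if role == "confederate" else pid
            receiver = pid if role == "confederate" else CONFEDERATE
            trial = Trial(game_id, index, sender, receiver, row.state, signal,
                          row.guess, correct)
        except (ValueError, TypeError) as exc:
            errors.append(f"line {pos}: {exc}")
            continue
        trials.setdefault((pid, game_id), []).append(trial)
    if errors:
        raise GameLogParseError(f"{path}: {len(errors)} malformed rows:\n" + "\n".join(errors))
    return [(pid, GameLog(tuple(sorted(ts, key=lambda t: t.index))))
            for (pid, _gid), ts in sorted(trials.items())]


# ---------------------------------------------------------------------------
# measures / FC / cohort bundles

def write_measures(measures: list[MeasureSet] | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = measures if isinstance(measures, pd.DataFrame) else (
        pd.DataFrame([m.as_dict() for m in measures]).set_index("participant_id"))
    df.to_csv(path)
    return path


def read_measures(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")


def write_fc(fc_wide: pd.DataFrame, path: str | Path) -> Path:
    """Write a participants x pairs table as long CSV (participant_id, pair_label, z)."""
    long = fc_wide.reset_index().melt(id_vars="participant_id",
                                      var_name="pair_label", value_name="z")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    long.to_csv(path, index=False)
    return Path(path)


def read_fc(path: str | Path) -> pd.DataFrame:
    """Read long FC CSV back into a participants x pairs table."""
    long = pd.read_csv(path)
    wide = long.pivot(index="participant_id", columns="pair_label", values="z")
    wide.columns.name = None
    return wide[[p for p in PAIR_LABELS if p in wide.columns]]


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as the full set of pipeline input files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "game_logs": write_game_logs(bundle.logs, out_dir / "game_logs.csv"),
        "fc": write_fc(bundle.fc, out_dir / "fc.csv"),
        "participants": out_dir / "participants.csv",
        "seed_codes": out_dir / "seed_codes.csv",
    }
    bundle.participants.to_csv(paths["participants"])
    seed_rows = [
        {"set_id": set_id, "emotion": e, "signal": str(sig)}
        for set_id, code in bundle.seed_codes.items()
        for e, sig in code.signals().items()
    ]
    pd.DataFrame(seed_rows).to_csv(paths["seed_codes"], index=False)
    return paths
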