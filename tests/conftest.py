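import numpy as np
import pytest

from tonegames.bp_scale import ToneSequence
from tonegames.game_metrics import EMOTIONS, GameLog, Trial
from tonegames.synthetic import CONFEDERATE, make_seed_codes


@pytest.fixture(scope="session")
def seed_codes():
    return make_seed_codes()


def make_log(game_id, rows, participant_id="p00"):
    """Build a GameLog from (state, signal_degrees, guess) rows.

    In game 1 the confederate is the sender; in game 2 the participant.
    """
    sender = CONFEDERATE if game_id == 1 else participant_id
    receiver = participant_id if game_id == 1 else CONFEDERATE
    trials = tuple(
        Trial.make(game_id, i, sender, receiver, state, ToneSequence(deg), guess)
        for i, (state, deg, guess) in enumerate(rows, start=1)
    )
    return GameLog(trials)


def perfect_logs(seed_code, participant_id="p00", n_g1=70, n_g2=30):
    """A participant who learns and retransmits the seed code flawlessly."""
    signals = seed_code.signals()
    rows_g1 = [(EMOTIONS[i % 5], signals[EMOTIONS[i % 5]].degrees, EMOTIONS[i % 5])
               for i in range(n_g1)]
    rows_g2 = [(EMOTIONS[i % 5], signals[EMOTIONS[i % 5]].degrees, EMOTIONS[i % 5])
               for i in range(n_g2)]
    return make_log(1, rows_g1, participant_id), make_log(2, rows_g2, participant_id)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
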