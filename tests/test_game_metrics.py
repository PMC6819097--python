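import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonegames.bp_scale import ToneSequence, contour_transform
from tonegames.game_metrics import (EMOTIONS, MeasureConfig, MissingCodeWarning,
                                    accuracy, asymmetry, compute_measure_set,
                                    coordination, hamming_distance,
                                    hamming_similarity, icr, innovation,
                                    mean_code_entropy, mean_code_icr,
                                    modal_code, regularization_delta,
                                    shannon_entropy, transmission)
from tonegames.synthetic import simulate_cohort, CohortSpec

from conftest import make_log, perfect_logs


# ---------------------------------------------------------------------------
# Hamming similarity / distance

@pytest.mark.parametrize("a,b,expected", [
    ([0, 4, 6, 7, 10], [0, 4, 6, 7, 10], 1.0),
    ([0, 4, 6, 7, 10], [4, 6, 7, 10, 0], 0.0),
    ([0, 4, 6, 7, 10], [0, 4, 6, 7, 4], 0.8),
])
def test_hamming_similarity(a, b, expected):
    assert hamming_similarity(a, b) == pytest.approx(expected)
    assert hamming_similarity(b, a) == pytest.approx(expected)  # symmetric


def test_hamming_length_mismatch_is_error():
    with pytest.raises(ValueError):
        hamming_similarity([0, 4, 6, 7, 10], [0, 4, 6, 7])


def test_hamming_contour_mode_compares_four_directions():
    a, b = ToneSequence((0, 4, 6, 7, 10)), ToneSequence((4, 6, 7, 10, 0))
    # tone strings fully differ but both ascend until the wrap in b
    assert hamming_similarity(a, b, mode="tone") == 0.0
    assert hamming_similarity(a, b, mode="contour") == 0.75


# ---------------------------------------------------------------------------
# modal code

def test_modal_code_tallies_plurality_signal():
    rows = ([("peace", (0, 4, 6, 7, 10), "peace")] * 3
            + [("peace", (4, 4, 6, 7, 10), "peace")] * 2
            + [("joy", (6, 6, 6, 6, 6), "joy")] * 5)
    log = make_log(1, rows)
    code = modal_code(log, role="sender")
    assert code.modal["peace"].degrees == (0, 4, 6, 7, 10)
    assert code.counts["peace"][(0, 4, 6, 7, 10)] == 3
    assert code.modal["joy"].degrees == (6, 6, 6, 6, 6)
    assert "sadness" in code.missing


def test_modal_code_tie_breaks_to_earliest_max_count():
    # both signals reach count 2; B attains its 2nd occurrence first
    rows = [("peace", (0, 0, 0, 0, 0), "peace"),   # A count 1 @1
            ("peace", (4, 4, 4, 4, 4), "peace"),   # B count 1 @2
            ("peace", (4, 4, 4, 4, 4), "peace"),   # B count 2 @3
            ("peace", (0, 0, 0, 0, 0), "peace")]   # A count 2 @4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingCodeWarning)
        code = modal_code(make_log(1, rows), role="sender")
    assert code.modal["peace"].degrees == (4, 4, 4, 4, 4)


def test_modal_code_receiver_role_keys_on_guess():
    rows = [("peace", (0, 4, 6, 7, 10), "joy"),
            ("peace", (0, 4, 6, 7, 10), "joy"),
            ("joy", (6, 6, 6, 6, 6), "peace")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingCodeWarning)
        code = modal_code(make_log(1, rows), role="receiver")
    assert code.modal["joy"].degrees == (0, 4, 6, 7, 10)
    assert code.modal["peace"].degrees == (6, 6, 6, 6, 6)


# ---------------------------------------------------------------------------
# coordination / transmission / innovation

def test_coordination_perfect_receiver_is_one(seed_codes):
    g1, _ = perfect_logs(seed_codes["A"])
    per_emotion, mean = coordination(g1, "tone", "set_mean")
    assert mean == 1.0
    assert all(v == 1.0 for v in per_emotion.values())
    _, mean_modal = coordination(g1, "tone", "modal")
    assert mean_modal == 1.0


def test_coordination_matches_brute_force_loop(seed_codes):
    """set_mean coordination equals an independent trial-by-trial loop."""
    rng = np.random.default_rng(11)
    signals = list(seed_codes["A"].signals().values())
    rows = [(EMOTIONS[rng.integers(5)], signals[rng.integers(5)].degrees,
             EMOTIONS[rng.integers(5)]) for _ in range(70)]
    # fixed sender code: signal determined by state
    sender_sig = {e: seed_codes["A"].signals()[e].degrees for e in EMOTIONS}
    rows = [(s, sender_sig[s], g) for s, _, g in rows]
    log = make_log(1, rows)

    expected = []
    for e in EMOTIONS:
        sims = []
        for t in log.trials:
            if t.index >= 36 and t.guess == e:
                a, b = sender_sig[e], t.signal.degrees
                sims.append(sum(x == y for x, y in zip(a, b)) / 5)
        if sims:
            expected.append(sum(sims) / len(sims))
    _, mean = coordination(log, "tone", "set_mean")
    assert mean == pytest.approx(sum(expected) / len(expected))


def test_transmission_examples(seed_codes):
    code = seed_codes["A"]
    _, g2 = perfect_logs(code)
    assert transmission(code, g2, "tone") == 1.0
    assert transmission(code, g2, "tone", method="all_trials") == 1.0

    # two of five positions changed in each emotion's signal -> 0.6
    altered = {}
    for e, sig in code.signals().items():
        degs = list(sig.degrees)
        degs[0] = degs[0] + 1
        degs[2] = degs[2] + 1
        altered[e] = tuple(degs)
    rows = [(EMOTIONS[i % 5], altered[EMOTIONS[i % 5]], EMOTIONS[i % 5]) for i in range(30)]
    assert transmission(code, make_log(2, rows), "tone") == pytest.approx(0.6)


def test_innovation_examples(seed_codes):
    g1, g2 = perfect_logs(seed_codes["A"])
    assert innovation(g1, g2, "tone") == 0.0

    # one position changed per signal -> mean distance 1/5
    altered = {e: (s.degrees[0] + 1,) + s.degrees[1:]
               for e, s in seed_codes["A"].signals().items()}
    rows = [(EMOTIONS[i % 5], altered[EMOTIONS[i % 5]], EMOTIONS[i % 5]) for i in range(30)]
    assert innovation(g1, make_log(2, rows), "tone") == pytest.approx(0.2)


def test_transmission_and_innovation_are_complementary(seed_codes):
    """Against the same reference code, similarity + distance = 1."""
    g1, _ = perfect_logs(seed_codes["A"])  # learned code == seed code
    rng = np.random.default_rng(5)
    prod = {e: tuple(int(d) for d in rng.integers(0, 12, size=5))
            for e in EMOTIONS}
    rows = [(EMOTIONS[i % 5], prod[EMOTIONS[i % 5]], EMOTIONS[i % 5]) for i in range(30)]
    g2 = make_log(2, rows)
    for mode in ("tone", "contour"):
        assert transmission(seed_codes["A"], g2, mode) + innovation(g1, g2, mode) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# asymmetry / accuracy

def test_asymmetry_constructed_counts():
    """A log with exactly S=3 sender changes and R=7 receiver changes -> -0.4."""
    sig = lambda d: (d, d, d, d, d)
    rows = []
    # sender changes its 'peace' signal 3 times (4 distinct signals in a row)
    for d in (0, 4, 6, 7):
        rows.append(("peace", sig(d), "peace"))
    # receiver flips its guess for the fixed 'joy' signal 7 times
    guesses = ["joy", "sadness"] * 4  # 8 guesses, 7 changes
    for g in guesses:
        rows.append(("joy", sig(10), g))
    log = make_log(1, rows)
    assert asymmetry(log) == pytest.approx((3 - 7) / 10)


def test_asymmetry_sender_only_changes_is_plus_one():
    rows = [("peace", (0, 0, 0, 0, 0), "peace"), ("peace", (4, 4, 4, 4, 4), "joy")]
    # different signals, so the receiver's differing guesses are first
    # occurrences, not changes
    assert asymmetry(make_log(1, rows)) == 1.0


def test_asymmetry_undefined_without_changes(seed_codes):
    g1, _ = perfect_logs(seed_codes["A"])
    with pytest.warns(MissingCodeWarning):
        assert np.isnan(asymmetry(g1))


def test_accuracy_counts_matches():
    rows = [("peace", (0, 0, 0, 0, 0), "peace" if i < 42 else "joy") for i in range(70)]
    assert accuracy(make_log(1, rows)) == 42


# ---------------------------------------------------------------------------
# entropy

@pytest.mark.parametrize("symbols,expected", [
    ((1, 1, -1, -1), 1.0),
    ((1, 1, 1, -1), 0.8113),
    ((0, 0, 0, 0), 0.0),
])
def test_shannon_entropy_contour_profile(symbols, expected):
    assert shannon_entropy(symbols) == pytest.approx(expected, abs=5e-5)


def test_shannon_entropy_empty_is_error():
    with pytest.raises(ValueError):
        shannon_entropy(())


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=12))
def test_shannon_entropy_invariances(symbols):
    h = shannon_entropy(symbols)
    assert h >= 0.0
    assert h <= np.log2(max(len(set(symbols)), 1)) + 1e-12
    assert shannon_entropy(list(reversed(symbols))) == pytest.approx(h)


def test_mean_code_entropy_of_seed_profile(seed_codes):
    """Seed contour entropies (1, 1, 0.81, 0.81, 0) average to 0.7245 bits."""
    mean = mean_code_entropy(seed_codes["A"], "contour")
    assert mean == pytest.approx((2 * 1.0 + 2 * 0.8112781) / 5, abs=1e-6)


def test_mean_code_entropy_edge_cases():
    monotone = [ToneSequence((d, d, d, d, d)) for d in (0, 4, 6, 7, 10)]
    assert mean_code_entropy(monotone, "tone") == 0.0
    distinct = [ToneSequence((0, 4, 6, 7, 10))] * 5
    assert mean_code_entropy(distinct, "tone") == pytest.approx(np.log2(5))


@pytest.mark.parametrize("g1,g2,kind,expected", [
    (0.724, 0.724, "entropy", 0.0),
    (0.724, 0.654, "entropy", 0.07),
    (1.0, 1.15, "icr", 0.15),
])
def test_regularization_delta_sign_conventions(g1, g2, kind, expected):
    assert regularization_delta(g1, g2, kind) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# interval compression ratio

def brute_force_icr(degrees):
    perms = list(itertools.permutations(degrees))
    num = np.mean([np.abs(np.diff(p)).mean() for p in perms])
    return num / np.abs(np.diff(degrees)).mean()


@pytest.mark.parametrize("degrees", [
    (0, 4, 6, 7, 10), (0, 10, 4, 7, 6), (0, 0, 4, 4, 10),
])
def test_icr_exact_equals_permutation_enumeration(degrees):
    assert icr(ToneSequence(degrees), exact=True) == pytest.approx(brute_force_icr(degrees))


def test_icr_ascending_sequence_exceeds_one():
    # the sorted order minimizes the mean interval, so shuffling raises it
    assert icr(ToneSequence((0, 4, 6, 7, 10)), exact=True) > 1.0


def test_icr_constant_sequence_is_degenerate_one():
    with pytest.warns(MissingCodeWarning):
        assert icr(ToneSequence((6, 6, 6, 6, 6))) == 1.0


def test_icr_monte_carlo_is_seed_deterministic():
    seq = ToneSequence((0, 4, 6, 7, 10))
    a = icr(seq, rng=np.random.default_rng(42))
    b = icr(seq, rng=np.random.default_rng(42))
    assert a == b


def test_mean_code_icr_degenerate_handling(seed_codes):
    rng = np.random.default_rng(0)
    incl = mean_code_icr(seed_codes["A"], exact=True, include_degenerate=True)
    excl = mean_code_icr(seed_codes["A"], exact=True, include_degenerate=False)
    # the monotone control contributes exactly 1.0 when included
    assert incl == pytest.approx((excl * 4 + 1.0) / 5)


# ---------------------------------------------------------------------------
# full measure set

def test_measure_set_perfect_learner(seed_codes):
    g1, g2 = perfect_logs(seed_codes["A"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingCodeWarning)
        ms = compute_measure_set(g1, g2, seed_codes["A"], MeasureConfig(icr_exact=True))
    assert ms.coordination_tone == 1.0
    assert ms.transmission_tone == 1.0
    assert ms.innovation_tone == 0.0
    assert ms.accuracy == 70
    assert ms.delta_entropy_tone == pytest.approx(0.0)
    assert ms.delta_icr == pytest.approx(0.0)
    # seed-code entropies reproduce the configured contour profile
    assert ms.entropy_contour_g1 == pytest.approx(0.72451, abs=1e-4)


def test_measure_set_ranges_over_random_cohort():
    """Every bounded measure stays in its declared range on simulated data."""
    bundle = simulate_cohort(CohortSpec(n_participants=20, master_seed=123))
    from tonegames.synthetic import cohort_measure_frame
    df = cohort_measure_frame(bundle)
    unit = ["coordination_tone", "coordination_contour", "transmission_tone",
            "transmission_contour", "innovation_tone", "innovation_contour"]
    assert ((df[unit] >= 0) & (df[unit] <= 1)).all().all()
    asym = df["asymmetry_g2"].dropna()
    assert ((asym >= -1) & (asym <= 1)).all()
    assert ((df["accuracy"] >= 0) & (df["accuracy"] <= 70)).all()
    assert (df[["entropy_tone_g1", "entropy_tone_g2",
                "entropy_contour_g1", "entropy_contour_g2"]] >= 0).all().all()
    assert (df[["icr_g1", "icr_g2"]] > 0).all().all()
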