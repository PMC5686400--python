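"""Repeat-abundance simulation: generation, counting, thresholds, detection."""

import numpy as np
import pytest

from pathcomplex.errors import DomainError
from pathcomplex.threshold import (
    SimConfig,
    count_repeats_by_size,
    detect_biosignature,
    generate_random_string,
    sigma_threshold,
    splice_motif,
)


def naive_counts(s, max_size, mode="windows"):
    """Quadratic reference counter."""
    out = {}
    for L in range(1, max_size + 1):
        frags = [s[i:i + L] for i in range(len(s) - L + 1)]
        from collections import Counter

        c = Counter(frags)
        if mode == "windows":
            out[L] = sum(1 for f in frags if c[f] >= 2)
        else:
            out[L] = sum(1 for f, k in c.items() if k >= 2)
    return out


# ---------------------------------------------------------------------- #
# generation
# ---------------------------------------------------------------------- #

def test_single_letter_alphabet():
    assert generate_random_string(5, "a", seed=123) == "aaaaa"


def test_generation_is_seed_deterministic():
    a = generate_random_string(300, "ab", seed=7)
    b = generate_random_string(300, "ab", seed=7)
    c = generate_random_string(300, "ab", seed=8)
    assert a == b
    assert a != c


def test_symbol_frequencies_are_uniform():
    n = 100_000
    s = generate_random_string(n, seed=42)
    expected = n / 26
    sd = (n * (1 / 26) * (25 / 26)) ** 0.5
    for ch in "abcdefghijklmnopqrstuvwxyz":
        assert abs(s.count(ch) - expected) < 5 * sd


def test_empty_alphabet_rejected():
    with pytest.raises(DomainError):
        generate_random_string(5, "")


# ---------------------------------------------------------------------- #
# splicing
# ---------------------------------------------------------------------- #

def test_splice_single_motif():
    out = splice_motif("aaaa", "b", 1, seed=0)
    assert len(out) == 5 and out.count("b") == 1


def test_splice_length_arithmetic_at_study_parameters():
    base = generate_random_string(100_000, seed=1)
    out = splice_motif(base, "complex", 1000, seed=1)
    assert len(out) == 107_000
    assert out.count("complex") >= 1000


def test_splice_zero_is_identity():
    assert splice_motif("abcd", "x", 0, seed=0) == "abcd"


def test_overwrite_mode_keeps_length():
    base = "a" * 50
    out = splice_motif(base, "zz", 5, seed=3, mode="overwrite")
    assert len(out) == 50
    assert "zz" in out


# ---------------------------------------------------------------------- #
# counting
# ---------------------------------------------------------------------- #

def test_counts_aaaa():
    # all three length-2 windows are "aa"
    assert count_repeats_by_size("aaaa", 2)[2] == 3


def test_counts_no_repeats():
    c = count_repeats_by_size("abcdef", 4)
    assert c[2] == c[3] == c[4] == 0


def test_counts_redrum_times_ten():
    c = count_repeats_by_size("redrum" * 10, 6)
    assert c[6] >= 55                       # every length-6 window repeats
    assert c == naive_counts("redrum" * 10, 6)


@pytest.mark.parametrize("mode", ["windows", "distinct"])
def test_fast_counter_equals_naive_oracle(rng, mode):
    for _ in range(8):
        n = rng.randint(2, 200)
        s = "".join(rng.choice("abcd") for _ in range(n))
        assert count_repeats_by_size(s, 8, mode) == naive_counts(s, 8, mode)


def test_window_counts_are_non_increasing_in_size():
    # a repeated (L+1)-window implies a repeated L-window at the same spot
    for seed in range(5):
        s = generate_random_string(2000, seed=seed)
        c = count_repeats_by_size(s, 8)
        for L in range(1, 8):
            assert c[L + 1] <= c[L]


# ---------------------------------------------------------------------- #
# thresholds
# ---------------------------------------------------------------------- #

def test_constant_replicates_have_zero_spread():
    thr = sigma_threshold({3: [7, 7, 7, 7]}, k=5)
    assert thr[3] == 7.0


def test_two_replicate_arithmetic():
    thr = sigma_threshold({2: [0, 2]}, k=3)
    assert thr[2] == pytest.approx(1 + 3 * np.std([0, 2], ddof=1))


def test_sigma_warns_outside_usual_range():
    with pytest.warns(UserWarning):
        sigma_threshold({1: [0, 1]}, k=25)


# ---------------------------------------------------------------------- #
# the full detector
# ---------------------------------------------------------------------- #

SMALL = dict(length=4000, insertions=60, replicates=8, seed=11)


def test_detector_is_deterministic():
    p1 = detect_biosignature(SimConfig(**SMALL))
    p2 = detect_biosignature(SimConfig(**SMALL))
    assert p1.counts == p2.counts
    assert p1.threshold == p2.threshold
    assert p1.flags == p2.flags


def test_null_case_flags_nothing():
    p = detect_biosignature(SimConfig(**{**SMALL, "insertions": 0}))
    assert p.flagged_sizes() == ()


def test_motif_inflates_sizes_up_to_its_length():
    p = detect_biosignature(SimConfig(**SMALL))
    flagged = set(p.flagged_sizes())
    assert {4, 5, 6, 7} <= flagged
    assert 1 not in flagged


def test_splicing_never_decreases_counts_at_motif_sizes():
    for seed in range(3):
        base = generate_random_string(3000, seed=seed)
        spliced = splice_motif(base, "complex", 40, seed=seed)
        cb = count_repeats_by_size(base, 7)
        cs = count_repeats_by_size(spliced, 7)
        for L in range(1, 8):
            assert cs[L] >= cb[L]


def test_short_motif_flags_its_own_size():
    """A 2-letter motif inflates 2-mer repeats. The effect is visible only
    while 2-mer counts are unsaturated (on ~10^5-character strings every
    2-mer repeats in both conditions), so the study uses a short base with
    a motif mass comparable to it."""
    cfg = SimConfig(length=200, motif="zz", insertions=100, replicates=8,
                    max_fragment_size=4, seed=5)
    p = detect_biosignature(cfg)
    assert p.flags[2]
    assert not p.flags[1]


def test_config_validation():
    with pytest.raises(DomainError):
        SimConfig(length=0)
    with pytest.raises(DomainError):
        SimConfig(replicates=1)
    with pytest.warns(UserWarning):
        SimConfig(motif="verylongmotif", max_fragment_size=8, length=100)
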