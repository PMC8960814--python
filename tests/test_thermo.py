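"""Nearest-neighbour thermodynamics against independent oracles."""

import math

import numpy as np
import pytest

from conftest import random_seq

from graphamp.sequence_core import reverse_complement
from graphamp.thermo import (
    ThermoParams,
    cross_dimer_screen,
    duplex_dG,
    hairpin_screen,
    melt_temperature,
)


def test_tm_symmetric_under_reverse_complement():
    rng = np.random.default_rng(3)
    for _ in range(10):
        s = random_seq(rng, int(rng.integers(10, 30)))
        assert melt_temperature(s).tm_celsius == pytest.approx(
            melt_temperature(reverse_complement(s)).tm_celsius, abs=1e-9
        )


def test_tm_gc_ordering():
    assert melt_temperature("G" * 12).tm_celsius > melt_temperature("A" * 12).tm_celsius


def test_tm_matches_hand_summed_oracle(tm_oracle):
    assert melt_temperature("ACGTACGTAC").tm_celsius == pytest.approx(
        tm_oracle("ACGTACGTAC"), abs=0.01
    )
    rng = np.random.default_rng(2024)
    for _ in range(20):
        s = random_seq(rng, int(rng.integers(10, 26)))
        assert melt_temperature(s).tm_celsius == pytest.approx(tm_oracle(s), abs=0.01)


def test_tm_salt_dependence_monotone():
    s = "ACGTACGTACGTACGTAACC"
    low = melt_temperature(s, ThermoParams(monovalent_mM=10, divalent_mM=0))
    high = melt_temperature(s, ThermoParams(monovalent_mM=200, divalent_mM=0))
    assert high.tm_celsius > low.tm_celsius


def test_tm_too_short_names_minimum():
    with pytest.raises(ValueError, match="8"):
        melt_temperature("ACGTAC")


def test_hairpin_no_self_complementarity_passes():
    res = hairpin_screen("A" * 24)
    assert res.passed and res.best is None


def test_hairpin_planted_stem_loop_fails():
    stem = "GCGCGCGC"
    seq = stem + "TTTTT" + reverse_complement(stem)
    res = hairpin_screen(seq)
    assert not res.passed
    assert res.best.stem_length == 8
    assert res.best.loop_length == 5


def test_hairpin_degenerate_threshold_passes_everything():
    stem = "GCGCGCGC"
    seq = stem + "TTTTT" + reverse_complement(stem)
    assert hairpin_screen(seq, max_stem_dG=-math.inf).passed


def test_hairpin_matches_bruteforce_on_short_sequences(hairpin_oracle):
    rng = np.random.default_rng(77)
    for _ in range(200):
        s = random_seq(rng, int(rng.integers(10, 17)), gc=0.55)
        best = hairpin_screen(s).best
        expect = hairpin_oracle(s)
        if expect is None:
            assert best is None
        else:
            assert best is not None
            assert best.dG_kcal == pytest.approx(expect, abs=1e-9)


def test_longer_stems_never_less_stable():
    # fixed 5-nt loop, growing perfect GC stem: dG must be non-increasing
    prev = None
    for k in range(3, 9):
        stem = ("GC" * k)[:k]
        seq = stem + "TTTTT" + reverse_complement(stem)
        dG = hairpin_screen(seq, max_stem_dG=-math.inf).best.dG_kcal
        if prev is not None:
            assert dG <= prev + 1e-9
        prev = dG


def test_cross_dimer_trivial_cases():
    assert cross_dimer_screen("A" * 20, "A" * 20).passed
    s = "ACGTTGCAGGCATTACGTGG"
    res = cross_dimer_screen(s, reverse_complement(s))
    assert not res.passed
    assert res.longest_3prime_run == len(s)


def test_cross_dimer_symmetric():
    a, b = "ACGTTGCAGGCATTACGTGG", "TTGCCAGTACCGGTAATGCA"
    ra = cross_dimer_screen(a, b)
    rb = cross_dimer_screen(b, a)
    assert ra.passed == rb.passed
    assert ra.longest_3prime_run == rb.longest_3prime_run
    assert ra.min_run_dG == pytest.approx(rb.min_run_dG)


def _bruteforce_cross(a, b, max_run, max_dG):
    """O(n*m) alignment scan re-deriving the screen decision."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    b_rc = "".join(comp[c] for c in reversed(b))
    worst_run3 = 0
    worst_dG = 0.0
    for off in range(-(len(a) - 1), len(b_rc)):
        i = 0
        while i < len(a):
            j = i + off
            if 0 <= j < len(b_rc) and a[i] == b_rc[j]:
                start = i
                while i < len(a) and 0 <= i + off < len(b_rc) and a[i] == b_rc[i + off]:
                    i += 1
                run = a[start:i]
                if (i == len(a)) or (start + off <= 0 < i + off):
                    worst_run3 = max(worst_run3, len(run))
                if len(run) >= 2:
                    worst_dG = min(worst_dG, duplex_dG(run))
            else:
                i += 1
    return worst_run3 <= max_run and worst_dG > max_dG


def test_cross_dimer_matches_alignment_oracle():
    rng = np.random.default_rng(5)
    for _ in range(30):
        a = random_seq(rng, 20)
        b = random_seq(rng, 20)
        res = cross_dimer_screen(a, b, max_3prime_run=4, max_dG=-8.0)
        assert res.passed == _bruteforce_cross(a, b, 4, -8.0)


def test_unknown_table_rejected():
    with pytest.raises(ValueError, match="unknown"):
        ThermoParams(table="nonexistent")
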