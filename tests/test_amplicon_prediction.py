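"""Tandem-repeat amplicon models, in-silico digestion, marker insertion."""

import re

import numpy as np
import pytest

from conftest import random_seq

from graphamp.amplicon_prediction import (
    AmpliconModel,
    digest,
    insert_marker,
    predict_amplicons,
)
from graphamp.primer_design import Primer
from graphamp.sequence_core import SequenceError


def test_unit_and_copy_arithmetic(prog_design):
    designs, _ = prog_design
    models = predict_amplicons(designs[0].primer_set, max_copies=3)
    assert models
    units = {str(m.unit) for m in models}
    assert "3a+1s+2s+3s" in units
    for m in models:
        assert len(m.sequence) == m.copies * m.unit_length
        if m.copies == 1:
            assert m.sequence * 3 == [
                x for x in models if x.unit == m.unit and x.copies == 3
            ][0].sequence


def test_generic_tail_models_include_tail_motif(gt_design):
    designs, _ = gt_design
    models = predict_amplicons(designs[0].primer_set, max_copies=2)
    assert "us+1s+2s+ua" in {str(m.unit) for m in models}


def test_digest_no_site_returns_whole_molecule():
    res = digest("ACGTACGTACGT", "TTTAAA", 1)
    assert res.lengths == (12,)


def test_digest_tandem_repeat_collapses_to_unit_bands():
    unit = "ACGTT" + "TCTAGA" + "GGCATCA"  # one site per 18-nt unit
    seq = unit * 3
    res = digest(seq, "TCTAGA", 1)
    assert sum(res.lengths) == len(seq)
    # n-copy model with one site per unit: internal fragments of unit length
    # plus two terminal partials -> at most 3 distinct lengths
    assert len(set(res.lengths)) <= 3
    assert res.lengths[1] == res.lengths[2] == len(unit)


def test_digest_boundary_zero_length_suppressed():
    res = digest("TCTAGAACGT", "TCTAGA", 0)
    assert res.lengths == (10,)
    res = digest("ACGTTCTAGA", "TCTAGA", 6)
    assert res.lengths == (10,)


def test_digest_empty_site_rejected():
    with pytest.raises(SequenceError):
        digest("ACGTACGT", "", 0)
    with pytest.raises(ValueError, match="cut_offset"):
        digest("ACGTACGT", "ACGT", 9)


def test_digest_matches_string_split_oracle_with_planted_sites():
    rng = np.random.default_rng(41)
    site = "TCTAGA"
    for _ in range(100):
        n_sites = int(rng.integers(0, 5))
        seq = random_seq(rng, int(rng.integers(10, 40)))
        for _ in range(n_sites):
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + site + seq[pos:]
        res = digest(seq, site, 1)
        assert sum(res.lengths) == len(seq)
        cuts = [m.start() + 1 for m in re.finditer(site, seq)]
        bounds = [0] + cuts + [len(seq)]
        expected = tuple(e - s for s, e in zip(bounds, bounds[1:]) if e > s)
        assert res.lengths == expected


def test_digest_overlapping_sites_match_regex_semantics():
    rng = np.random.default_rng(13)
    site = "ATA"  # can overlap itself
    for _ in range(50):
        seq = "".join(rng.choice(np.array(list("AT")), size=int(rng.integers(10, 200))))
        res = digest(seq, site, 1)
        cuts = [m.start() + 1 for m in re.finditer(site, seq)]
        bounds = [0] + cuts + [len(seq)]
        expected = tuple(e - s for s, e in zip(bounds, bounds[1:]) if e > s)
        assert res.lengths == expected
        assert sum(res.lengths) == len(seq)


def _primer():
    return Primer("inner_sense", (("us", "ACGTACGTACGTACGTACGA"), ("1s", "TTGACCATGGACCATTGACC")), "inner_1uM")


def test_insert_marker_grows_primer_by_site_length():
    p = _primer()
    marked = insert_marker(p, "TCTAGA", 1)
    assert marked.length == p.length + 6
    assert "marker[TCTAGA]" in marked.composition
    assert marked.seq == p.parts[0][1] + "TCTAGA" + p.parts[1][1]


def test_insert_empty_marker_is_identity():
    p = _primer()
    assert insert_marker(p, "", 1) is p


def test_insert_marker_invalid_junction_rejected():
    with pytest.raises(ValueError, match="junction"):
        insert_marker(_primer(), "TCTAGA", 2)


def test_marked_two_copy_amplicon_digests_into_multiple_fragments(gt_target):
    from graphamp.primer_design import DesignConfig, design

    target, _ = gt_target
    cfg = DesignConfig(scheme="generic_tail", seed=42, markers=True)
    designs = design(target, config=cfg)
    assert designs
    models = predict_amplicons(designs[0].primer_set, max_copies=2)
    two_copy = [m for m in models if m.copies == 2][0]
    assert two_copy.sequence.count("TCTAGA") >= 2  # once per repeat unit
    res = digest(two_copy.sequence, "TCTAGA", 1)
    assert len(res.fragments) >= 2
    assert sum(res.lengths) == len(two_copy.sequence)
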