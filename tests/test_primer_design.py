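"""The design pipeline: screening, tails, assembly, ranking, determinism."""

import numpy as np
import pytest

from conftest import random_seq

from graphamp.fixtures import generic_tail_target
from graphamp.primer_design import (
    DesignConfig,
    Primer,
    PrimerSet,
    design,
    generate_universal_tails,
    primer_table_tsv,
    rank_designs,
    screen_target,
)
from graphamp.reaction_graph import enumerate_products, validate_closure
from graphamp.sequence_core import Fragment, FragmentLabel, gc_content
from graphamp.thermo import cross_dimer_screen, hairpin_screen, melt_temperature


def test_screen_target_too_short_names_scheme_minimum():
    cfg = DesignConfig(scheme="generic_tail", seed=1)
    with pytest.raises(ValueError, match="40"):
        screen_target("ACGT" * 8, cfg)


def test_screen_target_rejects_out_of_bounds_windows():
    cfg = DesignConfig(scheme="generic_tail", seed=1)
    # homopolymer target: GC=0 everywhere, nothing can pass
    assert screen_target("A" * 80, cfg) == []


def test_screen_target_recovers_planted_regions(gt_target):
    target, truth = gt_target
    cfg = DesignConfig(scheme="generic_tail", seed=1)
    regions = screen_target(target, cfg)
    for planted in truth:
        assert any(
            r.start == planted.start and r.end == planted.end and r.strand == "+"
            for r in regions
        ), planted.role
    # every reported region re-passes its recorded filters
    for r in regions[:25]:
        assert cfg.gc_bounds[0] <= r.gc <= cfg.gc_bounds[1]
        seq = r.seq if r.strand == "+" else None
        tm = r.tm_celsius
        assert cfg.inner_tm_window[0] <= tm <= cfg.inner_tm_window[1]


def test_screen_candidates_monotone_in_target_extension(gt_target):
    target, _ = gt_target
    cfg = DesignConfig(scheme="generic_tail", seed=1)
    base = screen_target(target, cfg)
    rng = np.random.default_rng(99)
    extended = target + random_seq(rng, 60)
    ext = screen_target(extended, cfg)
    ext_keys = {(r.start, r.end, r.strand) for r in ext}
    # windows of the original target remain candidates in the extension
    lost = [
        (r.start, r.end, r.strand)
        for r in base
        if (r.start, r.end, r.strand) not in ext_keys
    ]
    assert not lost


def test_universal_tails_deterministic_and_screened(gt_target):
    target, _ = gt_target
    cfg = DesignConfig(scheme="generic_tail", seed=9)
    assert generate_universal_tails(cfg, 0) == []
    t1 = generate_universal_tails(cfg, 5, forbidden=[target])
    t2 = generate_universal_tails(cfg, 5, forbidden=[target])
    assert [t.seq for t in t1] == [t.seq for t in t2]
    assert len(t1) >= 1
    for tail in t1:
        assert (
            cfg.inner_tm_window[0]
            <= melt_temperature(tail.seq, cfg.thermo).tm_celsius
            <= cfg.inner_tm_window[1]
        )
        assert hairpin_screen(tail.seq, cfg.hairpin_max_dG, cfg.thermo).passed
        assert cross_dimer_screen(
            tail.seq, target, cfg.cross_max_run, cfg.cross_max_dG, cfg.thermo
        ).passed


def test_universal_tails_require_seed():
    cfg = DesignConfig(scheme="generic_tail", seed=None)
    with pytest.raises(ValueError, match="seed"):
        generate_universal_tails(cfg, 3)


def test_generic_tail_assembly_shares_tail_and_outer_tm_rule(gt_design):
    designs, cfg = gt_design
    assert designs
    for d in designs:
        pset = d.primer_set
        inner = pset.inner_primers
        tails = {p.parts[0][1] for p in inner}
        assert len(tails) == 1  # identical 5' tail on both inner primers
        assert all(p.parts[0][0] == "us" for p in inner)
        if pset.outer_primers:
            min_inner_tm = min(p.tm(cfg.thermo) for p in inner)
            for outer in pset.outer_primers:
                assert outer.tm(cfg.thermo) < min_inner_tm


def test_progressive_assembly_maps_antisense_primers_to_planted_sites(prog_target):
    """Given the screened planted regions, assembly assigns 2a..5a each to
    its planted interval (ground truth recorded by the fixture generator)."""
    from graphamp.primer_design import assemble_scheme_primers

    target, truth = prog_target
    cfg = DesignConfig(scheme="progressive", seed=1)
    planted = {(r.start, r.end) for r in truth}
    regions = [
        r
        for r in screen_target(target, cfg)
        if (r.start, r.end) in planted and r.strand == "+"
    ]
    assert len(regions) == 5
    sets = assemble_scheme_primers("progressive", regions, (), cfg, target)
    assert sets
    by_role = {r.role: (r.start, r.end) for r in truth}
    pset = sets[0]
    for i in (2, 3, 4, 5):
        matches = [
            p
            for p in pset.primers
            if p.role == "inner_antisense" and p.region[:2] == by_role[f"site{i}"]
        ]
        assert matches, f"no antisense primer on planted site{i}"
    sense = [p for p in pset.primers if p.role == "inner_sense"][0]
    assert sense.region[:2] == by_role["site1"]


def test_design_self_consistency_refilter(gt_design, prog_design):
    for designs, cfg in (gt_design, prog_design):
        for d in designs:
            results = d.primer_set.refilter(cfg)
            failing = [k for k, ok in results.items() if not ok]
            assert not failing


def test_design_deterministic_byte_identical(gt_target):
    target, _ = gt_target
    cfg = DesignConfig(scheme="generic_tail", seed=123)
    a = primer_table_tsv(design(target, config=cfg), cfg)
    b = primer_table_tsv(design(target, config=cfg), cfg)
    assert a == b


def test_generic_tail_design_graph_closes_and_contains_tail_motif(gt_design):
    designs, _ = gt_design
    for d in designs:
        g = d.primer_set.build_graph()
        assert validate_closure(g)
        assert "us+1s+2s+ua" in [str(m) for m in enumerate_products(g)]


def test_progressive_design_motifs_contain_core(prog_design):
    designs, _ = prog_design
    top = designs[0].primer_set
    motifs = [str(m) for m in enumerate_products(top.build_graph(), max_len=6)]
    assert motifs
    assert all(m.startswith("3a+1s+2s+3s") for m in motifs)


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="unknown scheme"):
        DesignConfig(scheme="unheard_of", seed=1)


def test_rank_designs_trivial_cases(gt_design):
    designs, cfg = gt_design
    assert rank_designs([], cfg) == []
    single = rank_designs([designs[0].primer_set], cfg)
    assert len(single) == 1 and single[0].rank == 1
    again = rank_designs([designs[0].primer_set], cfg)
    assert single[0].score == again[0].score


def _mk_set(inner_seqs, outer_seqs, frags):
    primers = [
        Primer("inner_sense", (("1s", inner_seqs[0]),), "inner_1uM", (0, len(inner_seqs[0]), "+")),
        Primer("inner_antisense", (("2a", inner_seqs[1]),), "inner_1uM", (30, 30 + len(inner_seqs[1]), "-")),
    ] + [
        Primer("outer_F3", (("F3", s),), "outer_0.1uM", (60, 60 + len(s), "+"))
        for s in outer_seqs
    ]
    return PrimerSet("basic", tuple(primers), frags)


def test_lower_tm_spread_ranks_first():
    """Two sets built from the same part multiset (so hairpin/GC/unit-length
    subscores match); only the inner-primer Tm spread differs."""
    cfg = DesignConfig(scheme="basic", seed=0)
    rng = np.random.default_rng(17)
    base = list("ACGT" * 5)
    pool = []
    while len(pool) < 40:
        rng.shuffle(base)
        s = "".join(base)
        if hairpin_screen(s, cfg.hairpin_max_dG, cfg.thermo).passed:
            pool.append((melt_temperature(s, cfg.thermo).tm_celsius, s))
    pool.sort()
    tight = (pool[18][1], pool[20][1])  # neighbouring Tm values
    wide = (pool[0][1], pool[-1][1])  # extreme Tm values
    frags = (
        Fragment(FragmentLabel(1, "s"), pool[5][1]),
        Fragment(FragmentLabel(2, "s"), pool[6][1]),
        Fragment(FragmentLabel(3, "s"), pool[7][1]),
    )
    set_tight = _mk_set(tight, wide, frags)
    set_wide = _mk_set(wide, tight, frags)
    ranked = rank_designs([set_wide, set_tight], cfg)
    assert ranked[0].primer_set is set_tight
    subs = {k: v for k, v in ranked[0].subscores}
    subs_wide = {k: v for k, v in ranked[1].subscores}
    assert subs["tm_uniformity"] > subs_wide["tm_uniformity"]
    for key in ("hairpin_margin", "unit_length"):
        assert subs[key] == pytest.approx(subs_wide[key])


def test_multiplex_design_two_targets_required():
    with pytest.raises(ValueError, match="two target"):
        design("ACGT" * 30, config=DesignConfig(scheme="multiplex", seed=1))
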