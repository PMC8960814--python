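"""The primer-design pipeline: screen target, generate tails, assemble sets.

The pipeline has three stages, composed by :func:`design`:

1. :func:`screen_target` slides windows over both strands of the target and
   keeps those passing the Tm window, GC bounds, hairpin screen and a
   uniqueness check (no second exact occurrence on either strand);
2. :func:`generate_universal_tails` randomly samples synthetic 5' tail
   ("us") sequences and screens each against the same thermodynamic filters
   plus cross-hybridisation against every forbidden sequence (target and
   primers);
3. :func:`assemble_scheme_primers` compiles scheme-specific primer sets --
   basic hairpin, tail-less variant, generic universal tail, progressive,
   and the cross-priming multiplex mode over two targets -- and
   :func:`rank_designs` orders them by a documented weighted score.

Filters are applied to *functional parts* (recognition fragments, tails),
not to full composite primers: composite LAMP-style primers inherently
contain designed self-structure, and cross primers intentionally carry each
other's priming sites, so mutual cross-dimer screening skips part pairs
that are designed complements.

Everything is deterministic under the configured seed; identical
(target, config, seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .reaction_graph import (
    ReactionGraph,
    SchemePrimer,
    SCHEMES,
    build_scheme_graph,
    enumerate_products,
)
from .sequence_core import (
    Fragment,
    FragmentComposition,
    FragmentLabel,
    SequenceError,
    clean_sequence,
    gc_content,
    reverse_complement,
)
from .thermo import (
    ThermoParams,
    cross_dimer_screen,
    hairpin_screen,
    melt_temperature,
)

__all__ = [
    "DesignConfig",
    "CandidateRegion",
    "UniversalTail",
    "Primer",
    "PrimerSet",
    "RankedDesign",
    "screen_target",
    "generate_universal_tails",
    "assemble_scheme_primers",
    "rank_designs",
    "design",
    "primer_table_tsv",
    "SCHEME_MIN_TARGET",
]

SCHEME_MIN_TARGET = {
    "basic": 54,
    "tailless": 36,
    "generic_tail": 40,
    "progressive": 90,
    "multiplex": 40,
}

MARKER_XBAI = "TCTAGA"
MARKER_BSTBI = "TTCGAA"


@dataclass(frozen=True)
class DesignConfig:
    """Design constraints; defaults follow conventional primer-design practice.

    ``inner_tm_window`` applies to recognition parts (the 3' target-binding
    fragments); ``outer_tm_offset`` is the allowed offset of outer-primer Tm
    below the coolest inner recognition part (must be negative).  The loop
    window bounds the combined loop-forming span (sites 1+2), defaulting to
    the 40-60 nt range with designs near 50 nt preferred.
    """

    scheme: str = "generic_tail"
    seed: Optional[int] = None
    inner_tm_window: Tuple[float, float] = (58.0, 64.0)
    outer_tm_offset: Tuple[float, float] = (-8.0, -3.0)
    gc_bounds: Tuple[float, float] = (0.30, 0.65)
    primer_len_bounds: Tuple[int, int] = (18, 25)
    loop_window: Tuple[int, int] = (40, 60)
    middle_max: int = 12
    universal_tail_length: int = 20
    n_tail_candidates: int = 8
    hairpin_max_dG: float = -2.0
    cross_max_run: int = 4
    cross_max_dG: float = -8.0
    thermo: ThermoParams = field(default_factory=ThermoParams)
    ranking_weights: Tuple[Tuple[str, float], ...] = (
        ("tm_uniformity", 1.0),
        ("gc_centrality", 1.0),
        ("hairpin_margin", 1.0),
        ("cross_margin", 1.0),
        ("unit_length", 1.0),
    )
    max_designs: int = 5
    markers: bool = False
    schema_version: int = 1

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {sorted(SCHEMES)}")
        for name, (lo, hi) in (
            ("inner_tm_window", self.inner_tm_window),
            ("gc_bounds", self.gc_bounds),
            ("primer_len_bounds", self.primer_len_bounds),
            ("loop_window", self.loop_window),
            ("outer_tm_offset", self.outer_tm_offset),
        ):
            if lo > hi:
                raise ValueError(f"{name}: empty window {lo}..{hi}")
        if self.outer_tm_offset[1] >= 0:
            raise ValueError("outer_tm_offset must be negative (outer Tm below inner)")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "a seed is mandatory for randomised design steps (universal tails)"
            )
        return int(self.seed)

    def echo(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "scheme": self.scheme,
            "seed": self.seed,
            "inner_tm_window": list(self.inner_tm_window),
            "outer_tm_offset": list(self.outer_tm_offset),
            "gc_bounds": list(self.gc_bounds),
            "primer_len_bounds": list(self.primer_len_bounds),
            "loop_window": list(self.loop_window),
            "middle_max": self.middle_max,
            "universal_tail_length": self.universal_tail_length,
            "n_tail_candidates": self.n_tail_candidates,
            "hairpin_max_dG": self.hairpin_max_dG,
            "cross_max_run": self.cross_max_run,
            "cross_max_dG": self.cross_max_dG,
            "ranking_weights": {k: v for k, v in self.ranking_weights},
            "max_designs": self.max_designs,
            "markers": self.markers,
            "thermo": {
                "monovalent_mM": self.thermo.monovalent_mM,
                "divalent_mM": self.thermo.divalent_mM,
                "strand_uM": self.thermo.strand_uM,
                "table": self.thermo.table,
                "celsius": self.thermo.celsius,
            },
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "DesignConfig":
        data = dict(data)
        data.pop("schema_version", None)
        thermo = data.pop("thermo", None)
        kwargs: dict = {}
        for key in (
            "scheme",
            "seed",
            "middle_max",
            "universal_tail_length",
            "n_tail_candidates",
            "hairpin_max_dG",
            "cross_max_run",
            "cross_max_dG",
            "max_designs",
            "markers",
        ):
            if key in data:
                kwargs[key] = data[key]
        for key in (
            "inner_tm_window",
            "outer_tm_offset",
            "gc_bounds",
            "primer_len_bounds",
            "loop_window",
        ):
            if key in data:
                kwargs[key] = tuple(data[key])
        if "ranking_weights" in data:
            kwargs["ranking_weights"] = tuple(sorted(data["ranking_weights"].items()))
        if thermo:
            kwargs["thermo"] = ThermoParams(**thermo)
        return cls(**kwargs)


@dataclass(frozen=True)
class CandidateRegion:
    """A target window passing all per-window filters (0-based half-open)."""

    start: int
    end: int
    strand: str  # '+' or '-'
    seq: str  # sense-strand sequence of the interval
    tm_celsius: float
    gc: float
    role: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class UniversalTail:
    seq: str
    tm_celsius: float
    report: Tuple[Tuple[str, bool], ...]  # (screen name, passed)


@dataclass(frozen=True)
class Primer:
    """A primer as an ordered list of named parts, 5'->3'.

    Part names are fragment labels ('us', '1s', '2a', ...) where the part is
    a fragment rendering, or free names (outer primers 'F3'/'B3', spliced
    markers).  The 3'-terminal part of every inner/cross primer is
    target-directed.
    """

    role: str
    parts: Tuple[Tuple[str, str], ...]
    conc_class: str
    region: Optional[Tuple[int, int, str]] = None  # recognition site interval
    marker_junctions: Tuple = ()

    @property
    def seq(self) -> str:
        return "".join(s for _, s in self.parts)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)

    @property
    def composition(self) -> str:
        return "+".join(name for name, _ in self.parts)

    @property
    def priming_label(self) -> str:
        return self.parts[-1][0]

    def tm(self, params: ThermoParams) -> float:
        return melt_temperature(self.seq, params).tm_celsius

    def recognition_tm(self, params: ThermoParams) -> float:
        """Tm of the 3' target-binding part."""
        return melt_temperature(self.parts[-1][1], params).tm_celsius


@dataclass(frozen=True)
class PrimerSet:
    """A scheme-specific primer set plus the fragment table it implies."""

    scheme: str
    primers: Tuple[Primer, ...]
    fragments: Tuple[Fragment, ...]
    tail: Optional[str] = None
    screen_report: Tuple[Tuple[str, float], ...] = ()

    @property
    def inner_primers(self) -> Tuple[Primer, ...]:
        return tuple(p for p in self.primers if not p.role.startswith("outer"))

    @property
    def outer_primers(self) -> Tuple[Primer, ...]:
        return tuple(p for p in self.primers if p.role.startswith("outer"))

    @property
    def markers(self) -> Tuple:
        out = []
        for p in self.primers:
            out.extend(p.marker_junctions)
        return tuple(out)

    def scheme_primers(self) -> List[SchemePrimer]:
        out = []
        for p in self.inner_primers:
            labels = []
            for name, _ in p.parts:
                try:
                    labels.append(FragmentLabel.parse(name))
                except SequenceError:
                    continue  # markers etc. are not part of the label algebra
            out.append(SchemePrimer(p.role, FragmentComposition(tuple(labels))))
        return out

    def build_graph(self, attach_target: bool = True, include_outer: Optional[bool] = None) -> ReactionGraph:
        if include_outer is None:
            include_outer = bool(self.outer_primers)
        graph = build_scheme_graph(
            self.scheme,
            fragments=self.fragments,
            primers=self.scheme_primers(),
            include_outer_primers=include_outer,
        )
        if attach_target and SCHEMES[self.scheme]["has_target_node"]:
            graph.attach_target(0)
        return graph

    def refilter(self, config: "DesignConfig") -> Dict[str, bool]:
        """Re-run every design filter on the emitted primers (idempotence)."""
        results: Dict[str, bool] = {}
        lo, hi = config.inner_tm_window
        for p in self.inner_primers:
            tm = p.recognition_tm(config.thermo)
            results[f"{p.role}:{p.priming_label}:tm"] = lo <= tm <= hi
            results[f"{p.role}:{p.priming_label}:gc"] = (
                config.gc_bounds[0] <= gc_content(p.parts[-1][1]) <= config.gc_bounds[1]
            )
        min_inner = min(p.recognition_tm(config.thermo) for p in self.inner_primers)
        for p in self.outer_primers:
            results[f"{p.role}:tm_below_inner"] = p.tm(config.thermo) < min_inner
        for p in self.primers:
            for name, seq in p.parts:
                results[f"{p.role}:{name}:hairpin"] = hairpin_screen(
                    seq, config.hairpin_max_dG, config.thermo
                ).passed
        for name, passed in _mutual_cross_screen(self.primers, config).items():
            results[name] = passed
        return results


@dataclass(frozen=True)
class RankedDesign:
    primer_set: PrimerSet
    score: float
    subscores: Tuple[Tuple[str, float], ...]
    rank: int


# -- stage 1: target screening ---------------------------------------------


def screen_target(target: str, config: DesignConfig) -> List[CandidateRegion]:
    """All primer-feasible windows of the target, both strands, deterministic.

    A window passes when its Tm falls in the inner window, its GC is within
    bounds, the hairpin screen passes, and it occurs exactly once across both
    strands of the target.
    """
    target = clean_sequence(target, name="target")
    minimum = SCHEME_MIN_TARGET[config.scheme]
    if len(target) < minimum:
        raise ValueError(
            f"target of {len(target)} nt is below the {config.scheme} scheme "
            f"minimum of {minimum} nt"
        )
    lo_len, hi_len = config.primer_len_bounds
    tm_lo, tm_hi = config.inner_tm_window
    gc_lo, gc_hi = config.gc_bounds
    out: List[CandidateRegion] = []
    n = len(target)
    for start in range(0, n - lo_len + 1):
        for length in range(lo_len, min(hi_len, n - start) + 1):
            window = target[start : start + length]
            gc = gc_content(window)
            if not gc_lo <= gc <= gc_hi:
                continue
            for strand in ("+", "-"):
                seq = window if strand == "+" else reverse_complement(window)
                tm = melt_temperature(seq, config.thermo).tm_celsius
                if not tm_lo <= tm <= tm_hi:
                    continue
                if target.count(seq) + target.count(reverse_complement(seq)) != 1:
                    continue
                if not hairpin_screen(seq, config.hairpin_max_dG, config.thermo).passed:
                    continue
                out.append(
                    CandidateRegion(
                        start=start,
                        end=start + length,
                        strand=strand,
                        seq=window,
                        tm_celsius=tm,
                        gc=gc,
                    )
                )
    out.sort(key=lambda r: (r.start, r.end, r.strand))
    return out


# -- stage 2: universal tails ----------------------------------------------


def generate_universal_tails(
    config: DesignConfig,
    n: int,
    forbidden: Sequence[str] = (),
) -> List[UniversalTail]:
    """Randomly design and screen synthetic 'us' tail candidates.

    Samples uniformly over the allowed base composition, keeping tails whose
    Tm is in the inner window, that pass the hairpin screen and that pass the
    cross-dimer screen against every forbidden sequence.  Bounded attempts:
    on exhaustion a partial list is returned with a warning.  Deterministic
    under the configured seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    seed = config.require_seed()
    rng = np.random.default_rng([seed, 701])
    forbidden = [clean_sequence(f, name="forbidden") for f in forbidden]
    length = config.universal_tail_length
    tm_lo, tm_hi = config.inner_tm_window
    tails: List[UniversalTail] = []
    seen: set = set()
    attempts = 0
    max_attempts = max(500, 400 * n)
    while len(tails) < n and attempts < max_attempts:
        attempts += 1
        gc = rng.uniform(max(config.gc_bounds[0], 0.35), min(config.gc_bounds[1], 0.60))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
        if seq in seen:
            continue
        seen.add(seq)
        tm = melt_temperature(seq, config.thermo).tm_celsius
        if not tm_lo <= tm <= tm_hi:
            continue
        report = [("tm_window", True)]
        if not hairpin_screen(seq, config.hairpin_max_dG, config.thermo).passed:
            continue
        report.append(("hairpin", True))
        ok = True
        for i, fseq in enumerate(forbidden):
            res = cross_dimer_screen(
                seq, fseq, config.cross_max_run, config.cross_max_dG, config.thermo
            )
            if not res.passed:
                ok = False
                break
        if not ok:
            continue
        report.append(("cross_dimer", True))
        tails.append(UniversalTail(seq=seq, tm_celsius=tm, report=tuple(report)))
    if len(tails) < n:
        warnings.warn(
            f"universal tail generation exhausted {max_attempts} attempts; "
            f"returning {len(tails)}/{n} tails",
            stacklevel=2,
        )
    return tails


# -- stage 3: assembly ------------------------------------------------------


def _designed_complements(name_a: str, name_b: str) -> bool:
    try:
        la = FragmentLabel.parse(name_a)
        lb = FragmentLabel.parse(name_b)
    except SequenceError:
        return False
    return la == lb.complement() or la == lb


def _three_prime_run(a: str, b: str) -> int:
    """Longest ungapped complementary run ending at a's 3' terminus when
    hybridised antiparallel anywhere along b."""
    b_rc = reverse_complement(b)
    last = len(a) - 1
    best = 0
    for j in range(len(b_rc)):
        k = 0
        while k <= min(last, j) and a[last - k] == b_rc[j - k]:
            k += 1
        best = max(best, k)
    return best


def _mutual_cross_screen(primers: Sequence[Primer], config: DesignConfig) -> Dict[str, bool]:
    """Cross-dimer screen across distinct primers.

    The duplex-stability rule runs part-pair-wise, skipping pairs that are
    designed complements (or the same fragment, e.g. a shared tail): their
    hybridisation is the mechanism, not a defect.  The 3'-run rule applies
    only to each primer's actual 3'-terminal part against the whole partner
    primer, and is skipped when the partner carries that part's designed
    complement (intended priming).
    """
    results: Dict[str, bool] = {}
    for i, pa in enumerate(primers):
        for pb in primers[i + 1 :]:
            ok = True
            for name_a, seq_a in pa.parts:
                for name_b, seq_b in pb.parts:
                    if _designed_complements(name_a, name_b):
                        continue
                    res = cross_dimer_screen(
                        seq_a,
                        seq_b,
                        max_3prime_run=10**6,
                        max_dG=config.cross_max_dG,
                        params=config.thermo,
                    )
                    if not res.passed:
                        ok = False
            for x, y in ((pa, pb), (pb, pa)):
                name_3p, seq_3p = x.parts[-1]
                if any(_designed_complements(name_3p, nb) and nb != name_3p for nb, _ in y.parts):
                    continue
                if _three_prime_run(seq_3p, y.seq) > config.cross_max_run:
                    ok = False
            results[f"cross:{pa.role}|{pb.role}"] = ok
    return results


def _cross_margin(primers: Sequence[Primer], config: DesignConfig) -> float:
    """Most stable non-designed cross duplex dG observed (0 if none)."""
    worst = 0.0
    for i, pa in enumerate(primers):
        for pb in primers[i + 1 :]:
            for name_a, seq_a in pa.parts:
                for name_b, seq_b in pb.parts:
                    if _designed_complements(name_a, name_b):
                        continue
                    res = cross_dimer_screen(
                        seq_a, seq_b, config.cross_max_run, config.cross_max_dG, config.thermo
                    )
                    worst = min(worst, res.min_run_dG)
    return worst


def _find_outer(
    target: str,
    interval: Tuple[int, int],
    strand: str,
    min_inner_tm: float,
    config: DesignConfig,
) -> List[CandidateRegion]:
    """Outer-primer candidate windows inside ``interval`` (flank of the core).

    Outer Tm must sit in [min_inner + offset_lo, min_inner + offset_hi];
    candidates are ordered by closeness to the middle of that band.
    """
    lo_t = min_inner_tm + config.outer_tm_offset[0]
    hi_t = min_inner_tm + config.outer_tm_offset[1]
    mid = (lo_t + hi_t) / 2
    a, b = interval
    found: List[Tuple[float, CandidateRegion]] = []
    lo_len, hi_len = config.primer_len_bounds
    for start in range(a, b - lo_len + 1):
        for length in range(lo_len, min(hi_len, b - start) + 1):
            window = target[start : start + length]
            seq = window if strand == "+" else reverse_complement(window)
            gc = gc_content(seq)
            if not config.gc_bounds[0] <= gc <= config.gc_bounds[1]:
                continue
            tm = melt_temperature(seq, config.thermo).tm_celsius
            if not lo_t <= tm <= hi_t:
                continue
            if not hairpin_screen(seq, config.hairpin_max_dG, config.thermo).passed:
                continue
            found.append((abs(tm - mid), CandidateRegion(start, start + length, strand, window, tm, gc)))
    found.sort(key=lambda x: (x[0], x[1].start, x[1].end))
    return [r for _, r in found[:10]]


def _chains(regions: Sequence[CandidateRegion], k: int, config: DesignConfig, cap: int = 40) -> List[Tuple[CandidateRegion, ...]]:
    """Chains of k exactly-adjacent sense-strand regions; sites 1+2 span the
    loop window (k >= 3)."""
    sense = [r for r in regions if r.strand == "+"]
    by_start: Dict[int, List[CandidateRegion]] = {}
    for r in sense:
        by_start.setdefault(r.start, []).append(r)
    chains: List[Tuple[CandidateRegion, ...]] = []

    def extend(chain: List[CandidateRegion]) -> None:
        if len(chains) >= cap:
            return
        if len(chain) == k:
            if k >= 3:
                loop = chain[0].length + chain[1].length
                if not config.loop_window[0] <= loop <= config.loop_window[1]:
                    return
            chains.append(tuple(chain))
            return
        for nxt in by_start.get(chain[-1].end, []):
            extend(chain + [nxt])

    for r in sense:
        extend([r])
    return chains


def _pairs(
    regions: Sequence[CandidateRegion], target: str, config: DesignConfig, cap: int = 40
) -> List[Tuple[CandidateRegion, CandidateRegion, str]]:
    """(site1, site2, middle) candidates for tail-style schemes.

    The sites sit on the sense strand separated by at most ``middle_max``
    background nt; the combined core span obeys the loop window (relaxed for
    short targets, the miRNA mode).
    """
    sense = [r for r in regions if r.strand == "+"]
    span_lo = min(config.loop_window[0], len(target))
    span_hi = config.loop_window[1]
    out = []
    for r1 in sense:
        for r2 in sense:
            gap = r2.start - r1.end
            if gap < 0 or gap > config.middle_max:
                continue
            span = r2.end - r1.start
            if not span_lo <= span <= span_hi:
                continue
            out.append((r1, r2, target[r1.end : r2.start]))
            if len(out) >= cap:
                return out
    return out


def _with_outers(
    primers: List[Primer],
    target: str,
    left_end: int,
    right_start: int,
    config: DesignConfig,
    conc: str = "outer_0.1uM",
) -> List[Primer]:
    inner_tms = [p.recognition_tm(config.thermo) for p in primers]
    min_inner = min(inner_tms)
    out = list(primers)
    for role, interval, strand in (
        ("outer_F3", (0, left_end), "+"),
        ("outer_B3", (right_start, len(target)), "-"),
    ):
        for cand in _find_outer(target, interval, strand, min_inner, config):
            seq = cand.seq if strand == "+" else reverse_complement(cand.seq)
            outer = Primer(
                role, ((role.split("_")[1], seq),), conc, (cand.start, cand.end, strand)
            )
            # an outer must not cross-react with the set it accelerates
            if all(_mutual_cross_screen(out + [outer], config).values()):
                out.append(outer)
                break
    return out


def _set_passes(primers: Sequence[Primer], config: DesignConfig) -> bool:
    return all(_mutual_cross_screen(primers, config).values())


def assemble_scheme_primers(
    scheme: str,
    regions,
    tails: Sequence[UniversalTail],
    config: DesignConfig,
    target: Union[str, Sequence[str], None] = None,
) -> List[PrimerSet]:
    """Compile candidate primer sets for a scheme from screened regions.

    ``regions`` is the output of :func:`screen_target` (a pair of region
    lists for the multiplex mode, along with a pair of targets).  Returns an
    empty list when the scheme is infeasible on the given regions.
    """
    if scheme == "multiplex":
        return _assemble_multiplex(regions, config, target)
    if target is None:
        raise ValueError("assembly requires the target sequence")
    target = clean_sequence(target, name="target")
    sets: List[PrimerSet] = []

    if scheme == "generic_tail":
        if not tails:
            return []
        for tail in tails:
            for r1, r2, middle in _pairs(regions, target, config):
                frag2_seq = middle + r2.seq
                pf = Primer(
                    "inner_sense",
                    (("us", tail.seq), ("1s", r1.seq)),
                    "inner_1uM",
                    (r1.start, r1.end, "+"),
                )
                pr = Primer(
                    "inner_antisense",
                    (("us", tail.seq), ("2a", reverse_complement(r2.seq))),
                    "inner_1uM",
                    (r2.start, r2.end, "-"),
                )
                primers = [pf, pr]
                if config.markers:
                    from .amplicon_prediction import insert_marker

                    primers = [
                        insert_marker(pf, MARKER_XBAI, 1),
                        insert_marker(pr, MARKER_BSTBI, 1),
                    ]
                primers = _with_outers(primers, target, r1.start, r2.end, config)
                if not _set_passes(primers, config):
                    continue
                fragments = (
                    Fragment(FragmentLabel(1, "s"), r1.seq),
                    Fragment(FragmentLabel(2, "s"), frag2_seq),
                    Fragment(FragmentLabel(None, "s"), tail.seq),
                )
                sets.append(
                    PrimerSet(
                        scheme,
                        tuple(primers),
                        fragments,
                        tail=tail.seq,
                        screen_report=(("cross_margin", _cross_margin(primers, config)),),
                    )
                )
                if len(sets) >= config.max_designs * 3:
                    return sets
    elif scheme in ("basic", "tailless", "progressive"):
        k = {"basic": 3, "tailless": 2, "progressive": 5}[scheme]
        for chain in _chains(regions, k, config):
            sites = {i + 1: r for i, r in enumerate(chain)}
            if scheme == "basic":
                primers = [
                    Primer("inner_antisense", (("2a", reverse_complement(sites[2].seq)),), "inner_1uM", (sites[2].start, sites[2].end, "-")),
                    Primer("inner_sense", (("1s", sites[1].seq),), "inner_1uM", (sites[1].start, sites[1].end, "+")),
                ]
                frags = tuple(Fragment(FragmentLabel(i, "s"), sites[i].seq) for i in (1, 2, 3))
            elif scheme == "tailless":
                # motif 3a+1s+3s: chain is (site1, site3); one priming site
                primers = [
                    Primer("inner_sense", (("1s", sites[1].seq),), "inner_1uM", (sites[1].start, sites[1].end, "+")),
                ]
                frags = (
                    Fragment(FragmentLabel(1, "s"), sites[1].seq),
                    Fragment(FragmentLabel(3, "s"), sites[2].seq),
                )
            else:
                primers = [
                    Primer(
                        "inner_sense",
                        (("3a", reverse_complement(sites[3].seq)), ("1s", sites[1].seq)),
                        "inner_1uM",
                        (sites[1].start, sites[1].end, "+"),
                    ),
                ] + [
                    Primer(
                        "inner_antisense",
                        ((f"{i}a", reverse_complement(sites[i].seq)),),
                        "inner_1uM",
                        (sites[i].start, sites[i].end, "-"),
                    )
                    for i in (2, 3, 4, 5)
                ]
                primers = _with_outers(primers, target, chain[0].start, chain[-1].end, config)
                frags = tuple(Fragment(FragmentLabel(i, "s"), sites[i].seq) for i in range(1, 6))
            if not _set_passes(primers, config):
                continue
            sets.append(
                PrimerSet(
                    scheme,
                    tuple(primers),
                    frags,
                    screen_report=(("cross_margin", _cross_margin(primers, config)),),
                )
            )
            if len(sets) >= config.max_designs * 3:
                return sets
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return sets


def _assemble_multiplex(
    regions_pair, config: DesignConfig, targets
) -> List[PrimerSet]:
    """Cross-priming sets over two targets: P1-P4 each carry three constructs
    (5' incorporated partner part, opposite-strand part, 3' target part)."""
    if targets is None or len(targets) != 2:
        raise ValueError("multiplex assembly requires two targets")
    regions1, regions2 = regions_pair
    t1 = clean_sequence(targets[0], name="target1")
    t2 = clean_sequence(targets[1], name="target2")
    sets: List[PrimerSet] = []
    for r1, r2, mid1 in _pairs(regions1, t1, config)[:6]:
        for r3, r4, mid2 in _pairs(regions2, t2, config)[:6]:
            s1, s2, s3, s4 = r1.seq, r2.seq, r3.seq, r4.seq
            primers = [
                Primer("cross_P1", (("3s", s3), ("2a", reverse_complement(s2)), ("1s", s1)), "inner_1uM", (r1.start, r1.end, "+")),
                Primer("cross_P2", (("4s", s4), ("1a", reverse_complement(s1)), ("2s", s2)), "inner_1uM", (r2.start, r2.end, "-")),
                Primer("cross_P3", (("1s", s1), ("4a", reverse_complement(s4)), ("3s", s3)), "inner_1uM", (r3.start, r3.end, "+")),
                Primer("cross_P4", (("2s", s2), ("3a", reverse_complement(s3)), ("4s", s4)), "inner_1uM", (r4.start, r4.end, "-")),
            ]
            primers = _with_outers(primers, t1, r1.start, r2.end, config, conc="outer_0.05uM")
            if not _set_passes(primers, config):
                continue
            frags = (
                Fragment(FragmentLabel(1, "s"), s1),
                Fragment(FragmentLabel(2, "s"), mid1 + s2),
                Fragment(FragmentLabel(3, "s"), s3),
                Fragment(FragmentLabel(4, "s"), mid2 + s4),
            )
            sets.append(
                PrimerSet(
                    "multiplex",
                    tuple(primers),
                    frags,
                    screen_report=(("cross_margin", _cross_margin(primers, config)),),
                )
            )
            if len(sets) >= config.max_designs * 3:
                return sets
    return sets


# -- stage 4: ranking -------------------------------------------------------


def _subscores(pset: PrimerSet, config: DesignConfig) -> Dict[str, float]:
    inner = pset.inner_primers
    tms = [p.recognition_tm(config.thermo) for p in inner]
    spread = max(tms) - min(tms)
    gcs = [gc_content(p.parts[-1][1]) for p in inner]
    gc_dev = sum(abs(g - 0.5) for g in gcs) / len(gcs)
    margins = []
    for p in pset.primers:
        for _, seq in p.parts:
            res = hairpin_screen(seq, config.hairpin_max_dG, config.thermo)
            margins.append(5.0 if res.best is None else res.best.dG_kcal - config.hairpin_max_dG)
    hp_margin = min(margins)
    cross = dict(pset.screen_report).get("cross_margin", 0.0)
    unit_len = sum(len(f.seq) for f in pset.fragments)
    return {
        "tm_uniformity": 1.0 / (1.0 + spread / 2.0),
        "gc_centrality": max(0.0, 1.0 - 2.0 * gc_dev),
        "hairpin_margin": min(1.0, max(0.0, hp_margin / 5.0)),
        "cross_margin": min(1.0, max(0.0, (cross - config.cross_max_dG) / abs(config.cross_max_dG))),
        "unit_length": max(0.0, 1.0 - unit_len / 300.0),
    }


def rank_designs(sets: Sequence[PrimerSet], config: DesignConfig) -> List[RankedDesign]:
    """Total order over candidate sets: weighted subscore sum, descending.

    Ties break by leftmost recognition region start, then by the
    lexicographic concatenation of primer sequences.
    """
    weights = dict(config.ranking_weights)
    scored = []
    for pset in sets:
        subs = _subscores(pset, config)
        total = sum(weights.get(k, 0.0) * v for k, v in subs.items()) / max(
            sum(weights.values()), 1e-12
        )
        leftmost = min(
            (p.region[0] for p in pset.primers if p.region is not None), default=0
        )
        seq_key = "|".join(p.seq for p in pset.primers)
        scored.append((total, leftmost, seq_key, pset, subs))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    return [
        RankedDesign(pset, score, tuple(sorted(subs.items())), rank)
        for rank, (score, _, _, pset, subs) in enumerate(scored[: config.max_designs], start=1)
    ]


# -- end-to-end -------------------------------------------------------------


def design(
    target: Union[str, Sequence[str]],
    scheme: Optional[str] = None,
    config: Optional[DesignConfig] = None,
) -> List[RankedDesign]:
    """End-to-end design: screen, (tails), assemble, rank.

    ``target`` is a sequence, or a pair of sequences for the multiplex mode.
    Deterministic under (target, config, seed).
    """
    if config is None:
        config = DesignConfig(scheme=scheme or "generic_tail")
    elif scheme is not None and scheme != config.scheme:
        config = replace(config, scheme=scheme)
    scheme = config.scheme
    if scheme == "multiplex":
        if isinstance(target, str) or len(target) != 2:
            raise ValueError("multiplex design requires two target sequences")
        regions = (
            screen_target(target[0], config),
            screen_target(target[1], config),
        )
        sets = assemble_scheme_primers(scheme, regions, (), config, target)
    else:
        if not isinstance(target, str):
            raise ValueError(f"scheme {scheme!r} takes a single target sequence")
        regions = screen_target(target, config)
        tails: Sequence[UniversalTail] = ()
        if scheme == "generic_tail":
            forbidden = [target] + [r.seq for r in regions[:20]]
            tails = generate_universal_tails(config, config.n_tail_candidates, forbidden)
        sets = assemble_scheme_primers(scheme, regions, tails, config, target)
    return rank_designs(sets, config)


def primer_table_tsv(designs: Sequence[RankedDesign], config: DesignConfig) -> str:
    """Primer table in the documented TSV dialect."""
    cols = [
        "design_rank",
        "role",
        "composition",
        "sequence_5to3",
        "length",
        "Tm_C",
        "GC",
        "conc_class",
        "region_start",
        "region_end",
        "strand",
    ]
    lines = ["\t".join(cols)]
    for d in designs:
        for p in d.primer_set.primers:
            start, end, strand = p.region if p.region else ("", "", "")
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        d.rank,
                        p.role,
                        p.composition,
                        p.seq,
                        p.length,
                        f"{p.tm(config.thermo):.2f}",
                        f"{p.gc:.3f}",
                        p.conc_class,
                        start,
                        end,
                        strand,
                    )
                )
            )
    return "\n".join(lines) + "\n"
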