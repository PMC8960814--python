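"""Symbolic amplicon prediction: tandem repeats and in-silico digestion.

Amplification products of hairpin-mediated isothermal reactions are
concatemers -- tandem repeats of a functional-motif unit.  This module
renders those repeat models from a validated reaction graph and predicts
restriction-digest fragment patterns (e.g. XbaI at TCTAGA) used to verify
them on a gel: with exactly one site per repeat unit, an n-copy concatemer
collapses to internal fragments of unit length plus two terminal partials.

Only the sense strand is scanned for sites by default; the 6-bp marker
sites used here (TCTAGA, TTCGAA) are palindromic, which makes the
single-strand scan equivalent to a double-strand one.  Overlapping site
occurrences are accepted greedily left-to-right in a single pass without
re-scanning, matching physical digestion of non-regenerating sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .reaction_graph import ReactionGraph, enumerate_products, validate_closure
from .sequence_core import (
    FragmentComposition,
    SequenceError,
    clean_sequence,
    compose_sequence,
    reverse_complement,
)

__all__ = [
    "AmpliconModel",
    "DigestResult",
    "predict_amplicons",
    "render_unit",
    "digest",
    "insert_marker",
    "write_amplicon_fasta",
]


@dataclass(frozen=True)
class AmpliconModel:
    """A predicted product: ``copies`` tandem repeats of a motif unit."""

    unit: FragmentComposition
    copies: int
    sequence: str
    unit_length: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        assert len(self.sequence) == self.copies * self.unit_length

    @property
    def header(self) -> str:
        return f"unit={self.unit}|copies={self.copies}|unit_nt={self.unit_length}"


@dataclass(frozen=True)
class DigestResult:
    site: str
    cut_offset: int
    fragments: Tuple[Tuple[int, int], ...]  # (start, end) along the molecule

    @property
    def lengths(self) -> Tuple[int, ...]:
        return tuple(e - s for s, e in self.fragments)


def _rc_junction(left: str, right: str) -> Optional[Tuple[str, str]]:
    """Junction as seen on the complementary strand, or None if the names
    are not fragment labels (e.g. an already-spliced marker part)."""
    from .sequence_core import FragmentLabel

    try:
        l_lab = FragmentLabel.parse(left)
        r_lab = FragmentLabel.parse(right)
    except SequenceError:
        return None
    return (str(r_lab.complement()), str(l_lab.complement()))


def render_unit(
    unit: FragmentComposition,
    fragment_table,
    markers: Sequence[Tuple[Tuple[str, str], str]] = (),
) -> str:
    """Render a motif unit, splicing any designed markers at their junctions.

    ``markers`` entries are ``((left_label, right_label), marker_seq)`` as
    recorded on a primer set; a junction also matches in its
    reverse-complement orientation, where the reverse complement of the
    marker is inserted instead (for the palindromic sites used here the two
    are identical).
    """
    pieces: List[str] = []
    labels = list(unit.labels)
    for i, lab in enumerate(labels):
        frag = fragment_table.get(lab.key)
        if frag is None:
            raise SequenceError(f"no fragment for key {lab.key!r} in unit {unit}")
        pieces.append(frag.seq if lab.sense == "s" else reverse_complement(frag.seq))
        if i + 1 < len(labels):
            junction = (str(lab), str(labels[i + 1]))
            for (left, right), mseq in markers:
                if junction == (left, right):
                    pieces.append(mseq)
                elif junction == _rc_junction(left, right):
                    pieces.append(reverse_complement(mseq))
    return "".join(pieces)


def predict_amplicons(
    primer_set=None,
    scheme: Optional[str] = None,
    fragments=None,
    max_copies: int = 5,
    graph: Optional[ReactionGraph] = None,
    max_len: int = 8,
) -> List[AmpliconModel]:
    """Tandem-repeat models for every motif the reaction graph can produce.

    Accepts either an assembled primer set (which knows its scheme, fragments
    and markers) or an explicit attached ``graph``.  A graph whose circuits do
    not close yields no models.
    """
    markers: Sequence = ()
    if graph is None:
        if primer_set is None:
            raise ValueError("provide either a primer_set or a graph")
        graph = primer_set.build_graph(attach_target=True)
        markers = getattr(primer_set, "markers", ())
        scheme = primer_set.scheme
    table = graph.fragment_table
    if fragments is not None:
        from .sequence_core import build_fragment_table

        table = build_fragment_table(fragments)
    if not validate_closure(graph):
        return []
    models: List[AmpliconModel] = []
    for unit in enumerate_products(graph, with_target=True, max_len=max_len):
        if not all(lab.key in table for lab in unit):
            continue  # symbolic-only graph without sequences for this motif
        unit_seq = render_unit(unit, table, markers)
        for copies in range(1, max_copies + 1):
            models.append(
                AmpliconModel(
                    unit=unit,
                    copies=copies,
                    sequence=unit_seq * copies,
                    unit_length=len(unit_seq),
                )
            )
    return models


def digest(seq: str, site: str, cut_offset: int) -> DigestResult:
    """Cut a linear molecule at every exact site occurrence on the sense strand.

    The cut falls after ``cut_offset`` bases within each site.  Matches are
    taken greedily left-to-right in a single pass (no re-scanning across a
    previous match), and zero-length terminal pieces are suppressed.
    Fragment lengths always sum to the input length.
    """
    seq = clean_sequence(seq)
    if not site:
        raise SequenceError("empty restriction site")
    site = clean_sequence(site, name="site")
    if not 0 <= cut_offset <= len(site):
        raise ValueError(f"cut_offset must be in [0, {len(site)}], got {cut_offset}")
    cuts: List[int] = []
    pos = seq.find(site)
    while pos != -1:
        cuts.append(pos + cut_offset)
        pos = seq.find(site, pos + len(site))
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(
        (s, e) for s, e in zip(bounds[:-1], bounds[1:]) if e > s
    )
    return DigestResult(site=site, cut_offset=cut_offset, fragments=fragments)


def insert_marker(primer, marker: str, junction: int):
    """Splice a marker sequence at a fragment boundary of a primer.

    ``junction`` indexes the boundary between primer parts (1 = after the
    first part).  An empty marker is the identity.  The marker is also
    recorded on the primer so downstream amplicon prediction renders it once
    per repeat unit.
    """
    if marker == "":
        return primer
    marker = clean_sequence(marker, name="marker")
    parts = list(primer.parts)
    if not 1 <= junction <= len(parts) - 1:
        raise ValueError(
            f"junction {junction} is not a part boundary of a {len(parts)}-part primer"
        )
    left_label = parts[junction - 1][0]
    right_label = parts[junction][0]
    parts.insert(junction, (f"marker[{marker}]", marker))
    return replace(
        primer,
        parts=tuple(parts),
        marker_junctions=primer.marker_junctions + (((left_label, right_label), marker),),
    )


def write_amplicon_fasta(models: Sequence[AmpliconModel], path) -> None:
    """Multi-FASTA export; headers encode unit composition and copy number."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.header}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i : i + 70] + "\n")
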