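"""Sequence primitives and the fragment-label algebra.

Every other module builds on two ideas:

* plain uppercase DNA strings over ``{A, C, G, T}``, always read 5'->3';
* *fragment labels* -- the ``1s/2a/us/ua`` notation for named segments of an
  amplification system, where the trailing letter gives the strand sense
  (``s`` = sense, ``a`` = antisense, i.e. the reverse complement of the
  stored sense-strand sequence) and the leading part is either a positive
  integer index or ``u`` for the universal (synthetic) tail.

Coordinates are 0-based half-open on the provided (sense) strand; antisense
features are represented as sense-strand intervals plus a strand flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceError",
    "clean_sequence",
    "reverse_complement",
    "gc_content",
    "FragmentLabel",
    "complement_label",
    "Fragment",
    "FragmentComposition",
    "build_fragment_table",
    "compose_sequence",
    "TargetRecord",
    "read_fasta",
]

_VALID = frozenset("ACGT")
_DEGENERATE = frozenset("RYSWKMBDHVN")


class SequenceError(ValueError):
    """Raised on malformed sequences, labels or compositions."""


def clean_sequence(raw: str, *, name: str = "sequence") -> str:
    """Validate and normalise a nucleotide string.

    Uppercases, maps U->T (RNA inputs such as miRNA targets), and rejects
    anything outside {A,C,G,T}.  Degenerate IUPAC codes are refused rather
    than expanded: the designer works against explicit sequences only.
    """
    if not isinstance(raw, str):
        raise SequenceError(f"{name}: expected a string, got {type(raw).__name__}")
    seq = raw.strip().upper().replace("U", "T")
    if not seq:
        raise SequenceError(f"{name}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        degen = sorted(bad & _DEGENERATE)
        if degen:
            raise SequenceError(
                f"{name}: degenerate IUPAC code(s) {','.join(degen)} are not "
                "supported; provide an explicit A/C/G/T sequence"
            )
        raise SequenceError(f"{name}: invalid character(s) {','.join(sorted(bad))}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (an involution on valid sequences)."""
    seq = clean_sequence(seq)
    return str(Seq(seq).reverse_complement())


def gc_content(seq: str) -> float:
    """Fraction of G+C bases, in [0, 1]."""
    seq = clean_sequence(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


_LABEL_RE = re.compile(r"^(u|[1-9][0-9]*)([sa])$")


@dataclass(frozen=True, order=True)
class FragmentLabel:
    """A named fragment with strand sense, e.g. ``2a``, ``us``.

    ``index`` is ``None`` for the universal tail (rendered ``us``/``ua``).
    """

    index: Union[int, None]
    sense: str  # 's' or 'a'

    def __post_init__(self) -> None:
        if self.sense not in ("s", "a"):
            raise SequenceError(f"label sense must be 's' or 'a', got {self.sense!r}")
        if self.index is not None and (not isinstance(self.index, int) or self.index < 1):
            raise SequenceError(f"label index must be a positive integer, got {self.index!r}")

    @property
    def universal(self) -> bool:
        return self.index is None

    @property
    def key(self) -> str:
        """Sense-independent fragment key ('u', '1', '2', ...)."""
        return "u" if self.index is None else str(self.index)

    def complement(self) -> "FragmentLabel":
        """Flip sense, preserve index/universal flag (involution)."""
        return FragmentLabel(self.index, "a" if self.sense == "s" else "s")

    @classmethod
    def parse(cls, text: str) -> "FragmentLabel":
        m = _LABEL_RE.match(text.strip())
        if not m:
            raise SequenceError(f"malformed fragment label {text!r} (expected e.g. '2a', 'us')")
        head, sense = m.groups()
        return cls(None if head == "u" else int(head), sense)

    def __str__(self) -> str:
        return f"{self.key}{self.sense}"

    def __repr__(self) -> str:  # keeps graph/test output compact
        return str(self)


def complement_label(label: FragmentLabel) -> FragmentLabel:
    """``2a -> 2s``, ``us -> ua``; an involution, injective by construction."""
    return label.complement()


@dataclass(frozen=True)
class Fragment:
    """A named segment: label plus its sense-strand sequence.

    The antisense rendering of the fragment is the reverse complement of the
    stored sequence; it is never stored separately.
    """

    label: FragmentLabel
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq, name=f"fragment {self.label}"))
        if len(self.seq) < 6:
            raise SequenceError(f"fragment {self.label}: length {len(self.seq)} < 6")


@dataclass(frozen=True)
class FragmentComposition:
    """An ordered 5'->3' list of fragment labels, e.g. ``3a+1s+2s+3s``."""

    labels: tuple

    def __post_init__(self) -> None:
        if not self.labels:
            raise SequenceError("empty fragment composition")
        object.__setattr__(self, "labels", tuple(self.labels))
        for lab in self.labels:
            if not isinstance(lab, FragmentLabel):
                raise SequenceError(f"composition element {lab!r} is not a FragmentLabel")

    @classmethod
    def parse(cls, text: str) -> "FragmentComposition":
        parts = [p for p in re.split(r"[+\s]+", text.strip()) if p]
        return cls(tuple(FragmentLabel.parse(p) for p in parts))

    def reverse_complement(self) -> "FragmentComposition":
        """Composition of the complementary strand, read 5'->3'."""
        return FragmentComposition(tuple(lab.complement() for lab in reversed(self.labels)))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __str__(self) -> str:
        return "+".join(str(lab) for lab in self.labels)

    def __repr__(self) -> str:
        return str(self)


FragmentTable = Mapping[str, Fragment]


def build_fragment_table(fragments: Iterable[Fragment]) -> dict:
    """Index fragments by their sense-independent key; duplicates rejected."""
    table: dict = {}
    for frag in fragments:
        key = frag.label.key
        if key in table and table[key].seq != frag.seq:
            raise SequenceError(f"conflicting sequences for fragment key {key!r}")
        table[key] = frag
    return table


def compose_sequence(comp: FragmentComposition, table) -> str:
    """Render a composition to a 5'->3' sequence given a fragment table.

    ``table`` may be a mapping from fragment key to Fragment or an iterable of
    Fragments.  An ``a``-sense label contributes the reverse complement of the
    stored sense-strand sequence.  Total length is the sum of fragment lengths.
    """
    if not isinstance(table, Mapping):
        table = build_fragment_table(table)
    pieces = []
    for lab in comp:
        frag = table.get(lab.key)
        if frag is None:
            raise SequenceError(f"composition {comp}: no fragment for key {lab.key!r}")
        pieces.append(frag.seq if lab.sense == "s" else reverse_complement(frag.seq))
    return "".join(pieces)


@dataclass(frozen=True)
class TargetRecord:
    """A FASTA record normalised to DNA, remembering the input alphabet."""

    id: str
    seq: str
    alphabet: str = "DNA"  # 'RNA' if the input contained U
    description: str = ""


def read_fasta(path) -> list:
    """Read single- or multi-record FASTA; sequences validated and normalised."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        alphabet = "RNA" if ("U" in raw.upper() and "T" not in raw.upper()) else "DNA"
        records.append(
            TargetRecord(
                id=rec.id,
                seq=clean_sequence(raw, name=f"record {rec.id}"),
                alphabet=alphabet,
                description=rec.description,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records
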