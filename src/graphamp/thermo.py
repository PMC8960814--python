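"""Nearest-neighbour melting thermodynamics and secondary-structure screens.

Implements the two-state nearest-neighbour duplex model:

    Tm = dH * 1000 / (dS_corrected + R * ln(C_T / x)) - 273.15

with x = 4 for non-self-complementary duplexes and x = 1 (plus a symmetry
entropy correction) for self-complementary ones, and an entropic salt
correction ``dS + 0.368 * N * ln([Na+]_eq)`` where N is the number of
stacks.  Divalent cations are folded into an effective monovalent
concentration as ``[Na+]_eq = monovalent + 120 * sqrt(divalent)`` (mM).

The parameter table ships as a versioned delimited text file
(``data/nn_unified_v1.tsv``) so results are bit-reproducible.

Three screens are provided:

* :func:`melt_temperature` -- duplex Tm and dG for a primer against its
  perfect complement;
* :func:`hairpin_screen` -- exhaustive search over contiguous stems
  (stem >= 3 bp, loop >= 3 nt) scoring stem stacks plus a tabulated
  loop-length penalty; a candidate fails when its most stable fold is at
  or below the cutoff;
* :func:`cross_dimer_screen` -- ungapped antiparallel alignment of two
  sequences, failing on long 3'-terminal complementary runs or on any
  contiguous duplex at or below a free-energy cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional, Tuple

from .sequence_core import clean_sequence, reverse_complement

__all__ = [
    "ThermoParams",
    "ThermoResult",
    "HairpinFold",
    "HairpinScreen",
    "CrossDimerScreen",
    "load_nn_table",
    "melt_temperature",
    "duplex_dG",
    "hairpin_screen",
    "cross_dimer_screen",
    "MIN_TM_LENGTH",
]

R_GAS = 1.9872  # cal / (mol K)
T37_K = 310.15
MIN_TM_LENGTH = 8

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@lru_cache(maxsize=4)
def load_nn_table(name: str = "unified-v1") -> dict:
    """Load a nearest-neighbour parameter set from the packaged data file.

    Returns a dict with keys ``stack`` (dinucleotide -> (dH, dS)),
    ``init_GC``/``init_AT`` ((dH, dS) per terminal pair), ``symmetry_dS``
    and ``loop`` (loop size -> dG37 penalty).
    """
    fname = f"nn_{name.replace('-', '_')}.tsv"
    try:
        text = resources.files("graphamp.data").joinpath(fname).read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown nearest-neighbour table {name!r}") from exc
    table: dict = {"stack": {}, "loop": {}}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("type\t"):
            continue
        kind, key, a, b = line.split("\t")
        if kind == "stack":
            table["stack"][key] = (float(a), float(b))
        elif kind == "init":
            if key == "symmetry":
                table["symmetry_dS"] = float(b)
            else:
                table[key] = (float(a), float(b))
        elif kind == "loop":
            table["loop"][int(key)] = float(a)
    if len(table["stack"]) != 16:
        raise ValueError(f"table {name!r} is incomplete: {len(table['stack'])} stacks")
    return table


@dataclass(frozen=True)
class ThermoParams:
    """Conditions under which Tm / dG are evaluated.

    Defaults reflect a typical strand-displacement amplification buffer:
    50 mM monovalent salt, 6 mM Mg2+, 1 uM primer strands.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 6.0
    strand_uM: float = 1.0
    table: str = "unified-v1"
    celsius: float = 37.0

    def __post_init__(self) -> None:
        if self.monovalent_mM <= 0 or self.strand_uM <= 0:
            raise ValueError("salt and strand concentrations must be positive")
        if self.divalent_mM < 0:
            raise ValueError("divalent concentration must be non-negative")
        load_nn_table(self.table)  # fail fast on unknown table ids

    @property
    def sodium_equivalent_M(self) -> float:
        """Effective monovalent concentration in mol/L (von Ahsen folding)."""
        return (self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM)) / 1000.0


DEFAULT_PARAMS = ThermoParams()


@dataclass(frozen=True)
class ThermoResult:
    tm_celsius: float
    dG_kcal: float  # at params.celsius, salt-corrected


def _nn_sums(seq: str, table: dict) -> Tuple[float, float]:
    """Sum stack and initiation dH (kcal/mol), dS (cal/mol K) for a duplex."""
    dH = 0.0
    dS = 0.0
    for i in range(len(seq) - 1):
        h, s = table["stack"][seq[i : i + 2]]
        dH += h
        dS += s
    for terminal in (seq[0], seq[-1]):
        h, s = table["init_GC"] if terminal in "GC" else table["init_AT"]
        dH += h
        dS += s
    return dH, dS


def melt_temperature(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> ThermoResult:
    """Two-state nearest-neighbour Tm with entropic salt correction.

    Deterministic; identical for a sequence and its reverse complement
    (the duplex is the same molecule).
    """
    seq = clean_sequence(seq)
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(
            f"melt_temperature requires length >= {MIN_TM_LENGTH}, got {len(seq)}"
        )
    table = load_nn_table(params.table)
    dH, dS = _nn_sums(seq, table)
    self_comp = seq == reverse_complement(seq)
    if self_comp:
        dS += table["symmetry_dS"]
    dS_corr = dS + 0.368 * (len(seq) - 1) * math.log(params.sodium_equivalent_M)
    ct = params.strand_uM * 1e-6
    x = 1.0 if self_comp else 4.0
    tm_K = dH * 1000.0 / (dS_corr + R_GAS * math.log(ct / x))
    t_K = params.celsius + 273.15
    dG = dH - t_K * dS_corr / 1000.0
    return ThermoResult(tm_celsius=tm_K - 273.15, dG_kcal=dG)


def duplex_dG(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> float:
    """Salt-corrected dG (kcal/mol) of a perfect duplex at params.celsius."""
    seq = clean_sequence(seq)
    table = load_nn_table(params.table)
    dH, dS = _nn_sums(seq, table)
    if seq == reverse_complement(seq):
        dS += table["symmetry_dS"]
    dS += 0.368 * (len(seq) - 1) * math.log(params.sodium_equivalent_M)
    return dH - (params.celsius + 273.15) * dS / 1000.0


@dataclass(frozen=True)
class HairpinFold:
    """A single stem-loop fold: paired indices, loop size and fold dG."""

    stem_pairs: tuple  # ((i, j), ...) with i < j, non-crossing by construction
    loop_length: int
    dG_kcal: float

    @property
    def stem_length(self) -> int:
        return len(self.stem_pairs)


@dataclass(frozen=True)
class HairpinScreen:
    passed: bool
    best: Optional[HairpinFold]


def _loop_penalty(n: int, table: dict) -> float:
    loops = table["loop"]
    if n in loops:
        return loops[n]
    nmax = max(loops)
    return loops[nmax] + 1.75 * (R_GAS / 1000.0) * T37_K * math.log(n / nmax)


def _stem_dG(stem: str, params: ThermoParams, table: dict) -> float:
    """dG of the stacked stem helix (no initiation terms; the loop table
    absorbs the closing penalty)."""
    log_na = math.log(params.sodium_equivalent_M)
    t_K = params.celsius + 273.15
    dG = 0.0
    for i in range(len(stem) - 1):
        h, s = table["stack"][stem[i : i + 2]]
        dG += h - t_K * (s + 0.368 * log_na) / 1000.0
    return dG


@lru_cache(maxsize=65536)
def _hairpin_best_cached(seq: str, params: ThermoParams) -> Optional[HairpinFold]:
    table = load_nn_table(params.table)
    n = len(seq)
    best: Optional[HairpinFold] = None
    max_stem = n // 2
    for k in range(3, max_stem + 1):
        for i in range(0, n - 2 * k - 3 + 1):
            left = seq[i : i + k]
            target = reverse_complement(left)
            for j in range(i + k + 3, n - k + 1):
                if seq[j : j + k] != target:
                    continue
                loop = j - (i + k)
                dG = _stem_dG(left, params, table) + _loop_penalty(loop, table)
                if best is None or dG < best.dG_kcal:
                    pairs = tuple((i + p, j + k - 1 - p) for p in range(k))
                    best = HairpinFold(stem_pairs=pairs, loop_length=loop, dG_kcal=dG)
    return best


def hairpin_screen(
    seq: str,
    max_stem_dG: float = -2.0,
    params: ThermoParams = DEFAULT_PARAMS,
) -> HairpinScreen:
    """Exhaustive contiguous-stem hairpin search.

    Considers every stem of length 3..n/2 paired with a downstream reverse
    complement separated by a loop of >= 3 nt; the fold score is the sum of
    stem stack free energies plus the tabulated loop penalty.  The screen
    passes iff the most stable fold has dG strictly above ``max_stem_dG``
    (or no fold exists).
    """
    seq = clean_sequence(seq)
    best = _hairpin_best_cached(seq, params)
    passed = best is None or best.dG_kcal > max_stem_dG
    return HairpinScreen(passed=passed, best=best)


@dataclass(frozen=True)
class CrossDimerScreen:
    passed: bool
    longest_3prime_run: int
    min_run_dG: float  # most stable contiguous duplex found (0.0 if none)
    reason: str = ""


def cross_dimer_screen(
    a: str,
    b: str,
    max_3prime_run: int = 4,
    max_dG: float = -8.0,
    params: ThermoParams = DEFAULT_PARAMS,
) -> CrossDimerScreen:
    """Ungapped antiparallel cross-hybridisation screen, symmetric in (a, b).

    Slides ``a`` against the reverse complement of ``b`` over every offset.
    Fails if a contiguous complementary run covering either molecule's 3'
    terminus exceeds ``max_3prime_run`` nucleotides, or if any contiguous
    complementary run has duplex dG <= ``max_dG``.
    """
    a = clean_sequence(a, name="a")
    b = clean_sequence(b, name="b")
    table = load_nn_table(params.table)
    b_rc = reverse_complement(b)
    na, nb = len(a), len(b_rc)
    worst_run3 = 0
    worst_dG = 0.0
    reason = ""
    # offset: index in b_rc aligned with a[0]; b's 3' terminus sits at b_rc[0]
    for off in range(-(na - 1), nb):
        runs = []
        run_start = None
        for i in range(na):
            j = i + off
            matched = 0 <= j < nb and a[i] == b_rc[j]
            if matched and run_start is None:
                run_start = i
            elif not matched and run_start is not None:
                runs.append((run_start, i))
                run_start = None
        if run_start is not None:
            runs.append((run_start, na))
        for s, e in runs:
            length = e - s
            # 3' terminal involvement: a's 3' end (i == na-1) or b's 3' end
            # (b_rc index 0, i.e. i == -off)
            involves_3p = (e == na) or (s + off <= 0 < e + off)
            if involves_3p and length > worst_run3:
                worst_run3 = length
            if length >= 2:
                dG = duplex_dG(a[s:e], params)
                if dG < worst_dG:
                    worst_dG = dG
    passed = True
    if worst_run3 > max_3prime_run:
        passed = False
        reason = f"3'-terminal complementary run of {worst_run3} nt > {max_3prime_run}"
    if worst_dG <= max_dG:
        passed = False
        reason = (reason + "; " if reason else "") + (
            f"cross-duplex dG {worst_dG:.2f} kcal/mol <= {max_dG}"
        )
    return CrossDimerScreen(
        passed=passed,
        longest_3prime_run=worst_run3,
        min_run_dG=worst_dG,
        reason=reason,
    )
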