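"""Shared fixtures: synthetic targets/curves and independent thermo oracles.

The oracle functions are deliberately self-contained re-derivations
(spreadsheet-style nearest-neighbour summation, brute-force fold/alignment
enumeration) so they never share code paths with the implementation they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from graphamp.fixtures import generic_tail_target, progressive_target
from graphamp.primer_design import DesignConfig, design

# published unified DNA NN parameters, re-keyed independently of the package
_ORACLE_STACKS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _stack_params(dinuc: str):
    if dinuc in _ORACLE_STACKS:
        return _ORACLE_STACKS[dinuc]
    return _ORACLE_STACKS[_revcomp(dinuc)]


def oracle_tm(
    seq: str,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 6.0,
    strand_uM: float = 1.0,
) -> float:
    """Hand-summed two-state NN Tm: sum stacks + initiation, salt-correct
    the entropy, apply the two-state formula."""
    dH = 0.0
    dS = 0.0
    for i in range(len(seq) - 1):
        h, s = _stack_params(seq[i : i + 2])
        dH += h
        dS += s
    for base in (seq[0], seq[-1]):
        if base in "GC":
            dH += 0.1
            dS += -2.8
        else:
            dH += 2.3
            dS += 4.1
    self_comp = seq == _revcomp(seq)
    if self_comp:
        dS += -1.4
    na_eq = (monovalent_mM + 120.0 * math.sqrt(divalent_mM)) / 1000.0
    dS += 0.368 * (len(seq) - 1) * math.log(na_eq)
    ct = strand_uM * 1e-6
    x = 1.0 if self_comp else 4.0
    return dH * 1000.0 / (dS + 1.9872 * math.log(ct / x)) - 273.15


def oracle_hairpin_best(seq: str, loop_table: dict) -> float | None:
    """Brute-force enumeration of every stem/loop partition; returns the
    minimum fold dG or None when no stem of >= 3 bp exists."""
    na_eq = (50.0 + 120.0 * math.sqrt(6.0)) / 1000.0
    log_na = math.log(na_eq)
    n = len(seq)
    best = None
    for i in range(n):
        for k in range(3, n // 2 + 1):
            if i + k > n:
                break
            for j in range(i + k + 3, n - k + 1):
                stem_ok = all(seq[i + p] == _COMP[seq[j + k - 1 - p]] for p in range(k))
                if not stem_ok:
                    continue
                dG = 0.0
                for p in range(k - 1):
                    h, s = _stack_params(seq[i + p : i + p + 2])
                    dG += h - 310.15 * (s + 0.368 * log_na) / 1000.0
                loop = j - (i + k)
                if loop in loop_table:
                    dG += loop_table[loop]
                else:
                    nmax = max(loop_table)
                    dG += loop_table[nmax] + 1.75 * 0.0019872 * 310.15 * math.log(loop / nmax)
                if best is None or dG < best:
                    best = dG
    return best


@pytest.fixture(scope="session")
def tm_oracle():
    return oracle_tm


@pytest.fixture(scope="session")
def hairpin_oracle():
    from graphamp.thermo import load_nn_table

    loops = load_nn_table()["loop"]  # shared published constants, independent search
    return lambda seq: oracle_hairpin_best(seq, loops)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


@pytest.fixture(scope="session")
def gt_target():
    """Generic-tail fixture target with recorded planted sites."""
    return generic_tail_target(seed=11)


@pytest.fixture(scope="session")
def prog_target():
    """Progressive fixture target with five planted contiguous sites."""
    return progressive_target(seed=7)


@pytest.fixture(scope="session")
def gt_design(gt_target):
    target, _ = gt_target
    cfg = DesignConfig(scheme="generic_tail", seed=42)
    return design(target, config=cfg), cfg


@pytest.fixture(scope="session")
def prog_design(prog_target):
    target, _ = prog_target
    cfg = DesignConfig(scheme="progressive", seed=1)
    return design(target, config=cfg), cfg
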