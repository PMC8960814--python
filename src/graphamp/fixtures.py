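"""Synthetic-data generators with recorded ground truth.

Everything the designer consumes can be generated here without downloads:
targets with planted primer-feasible regions, noisy sigmoid amplification
curves with an analytically known threshold-crossing time, and near-identical
miRNA pairs.  Every generator takes an explicit seed (never defaulted
silently) and returns its ground truth alongside the data, so tests consume
recorded coordinates/values instead of re-deriving them by eye.

What these fixtures emulate -- and what they do not: planted regions have
realistic length/GC/Tm/hairpin properties but the background is uniform
random DNA, so genomic repeat structure, homology between near-target sites
and clinical-sample inhibitors are not represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .assay_analysis import KineticCurve
from .sequence_core import gc_content
from .thermo import ThermoParams, hairpin_screen, melt_temperature

__all__ = [
    "PlantedRegion",
    "SyntheticTargetSpec",
    "SyntheticCurveSpec",
    "generate_target",
    "generate_curve",
    "generate_mirna_pair",
    "generic_tail_target",
    "progressive_target",
    "multiplex_targets",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedRegion:
    """Ground truth for one planted, primer-feasible window."""

    role: str
    start: int
    end: int  # half-open, sense strand
    seq: str
    gc: float
    tm_celsius: float


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """A target layout: total length plus (role, start, length, gc) plants."""

    length: int
    regions: Tuple[Tuple[str, int, int, float], ...]  # (role, start, length, gc)
    seed: int
    tm_window: Tuple[float, float] = (58.0, 64.0)

    def __post_init__(self) -> None:
        spans = sorted((s, s + l) for _, s, l, _ in self.regions)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b:
                raise ValueError("planted regions must be disjoint")
        if spans and (spans[0][0] < 0 or spans[-1][1] > self.length):
            raise ValueError("planted regions must lie within the target")


def _random_seq(rng: np.random.Generator, n: int, gc: Optional[float] = None) -> str:
    if gc is None:
        return "".join(rng.choice(_BASES, size=n))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _plant_window(
    rng: np.random.Generator,
    length: int,
    gc_target: float,
    tm_window: Tuple[float, float],
    params: ThermoParams,
    max_attempts: int = 5000,
) -> str:
    """Rejection-sample a window passing the designer's default filters."""
    lo, hi = tm_window
    for _ in range(max_attempts):
        n_gc = int(round(gc_target * length))
        bases = list("G" * (n_gc // 2) + "C" * (n_gc - n_gc // 2))
        n_at = length - n_gc
        bases += list("A" * (n_at // 2) + "T" * (n_at - n_at // 2))
        rng.shuffle(bases)
        seq = "".join(bases)
        tm = melt_temperature(seq, params).tm_celsius
        if not lo <= tm <= hi:
            continue
        if not hairpin_screen(seq, params=params).passed:
            continue
        return seq
    raise ValueError(
        f"could not plant a feasible {length}-nt window at GC={gc_target:.2f} "
        f"within Tm window {tm_window}; the GC target is thermodynamically infeasible"
    )


def generate_target(
    spec: SyntheticTargetSpec,
    params: ThermoParams = ThermoParams(),
) -> Tuple[str, List[PlantedRegion]]:
    """Random background with planted primer-feasible regions.

    Deterministic under the spec's seed; each planted region passes the
    default Tm window, GC target and hairpin screen, and the returned table
    records its coordinates and measured properties.
    """
    rng = np.random.default_rng(spec.seed)
    ground_truth: List[PlantedRegion] = []
    seq = list(_random_seq(rng, spec.length))
    for role, start, length, gc in sorted(spec.regions, key=lambda r: r[1]):
        window = _plant_window(rng, length, gc, spec.tm_window, params)
        seq[start : start + length] = window
        ground_truth.append(
            PlantedRegion(
                role=role,
                start=start,
                end=start + length,
                seq=window,
                gc=gc_content(window),
                tm_celsius=melt_temperature(window, params).tm_celsius,
            )
        )
    return "".join(seq), ground_truth


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """A logistic amplification curve: plateau / (1 + exp(-(t - mid)/slope))."""

    midpoint_min: float = 25.0
    slope_min: float = 2.0
    plateau: float = 100.0
    noise_sd: float = 0.0
    interval_min: float = 0.5
    duration_min: float = 60.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.plateau <= 0 or self.interval_min <= 0:
            raise ValueError("plateau and sampling interval must be positive")


def _logistic(t: np.ndarray, spec: SyntheticCurveSpec) -> np.ndarray:
    return spec.plateau / (1.0 + np.exp(-(t - spec.midpoint_min) / spec.slope_min))


def generate_curve(spec: SyntheticCurveSpec) -> Tuple[KineticCurve, dict]:
    """Sampled noisy sigmoid plus its analytic 20 %-crossing ground truth.

    The recorded crossing solves f(t) = f_min + 0.2 (f_max - f_min) on the
    sampled window for the noiseless curve, i.e. exactly the baseline-
    subtracted threshold rule applied to the ideal signal.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_min + spec.interval_min / 2, spec.interval_min)
    clean = _logistic(t, spec)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=t.size)
    f_lo, f_hi = float(clean[0]), float(clean[-1])
    level = f_lo + 0.20 * (f_hi - f_lo)
    # invert the logistic at the threshold level
    tt = spec.midpoint_min - spec.slope_min * math.log(spec.plateau / level - 1.0)
    curve = KineticCurve(tuple(t), tuple(noisy), sample_id=spec.sample_id)
    return curve, {"tt_min": tt, "fraction": 0.20, "interval_min": spec.interval_min}


def generate_mirna_pair(seed: int, length: int = 22) -> Tuple[str, str]:
    """A miRNA-like sequence and a variant differing at exactly two positions."""
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length, gc=0.5)
    pos = rng.choice(length, size=2, replace=False)
    variant = list(base)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != variant[p]]
        variant[p] = alternatives[int(rng.integers(3))]
    return base, "".join(variant)


# -- convenience layouts matched to the designer's schemes -----------------


def _sites_mutually_clean(site_seqs: Sequence[str], roles_antisense: Sequence[int]) -> bool:
    """Set-level feasibility: the primers implied by the planted sites must
    pass the designer's mutual cross-dimer screen (individually feasible
    windows can still share chance 3'-complementary runs)."""
    from .primer_design import DesignConfig, Primer, _mutual_cross_screen
    from .sequence_core import reverse_complement

    cfg = DesignConfig(scheme="basic", seed=0)
    primers = []
    for i, seq in enumerate(site_seqs, start=1):
        if i in roles_antisense:
            primers.append(
                Primer("inner_antisense", ((f"{i}a", reverse_complement(seq)),), "inner_1uM")
            )
        else:
            primers.append(Primer("inner_sense", ((f"{i}s", seq),), "inner_1uM"))
    return all(_mutual_cross_screen(primers, cfg).values())


def generic_tail_target(
    seed: int,
    site_length: int = 20,
    middle: int = 4,
    flank: int = 40,
) -> Tuple[str, List[PlantedRegion]]:
    """A conserved-core target for the generic-tail scheme.

    Two adjacent recognition sites (separated by ``middle`` background nt)
    form a 40-60 bp core, embedded in flanks long enough to host outer
    primers.
    """
    core_start = flank
    for attempt in range(50):
        spec = SyntheticTargetSpec(
            length=2 * flank + 2 * site_length + middle,
            regions=(
                ("site1", core_start, site_length, 0.45),
                ("site2", core_start + site_length + middle, site_length, 0.45),
            ),
            seed=seed + attempt * 1000003,
        )
        target, truth = generate_target(spec)
        if _sites_mutually_clean([r.seq for r in truth], roles_antisense=(2,)):
            return target, truth
    raise RuntimeError("could not plant a mutually clean generic-tail site pair")


def progressive_target(
    seed: int,
    site_length: int = 21,
    flank: int = 45,
) -> Tuple[str, List[PlantedRegion]]:
    """Five contiguous planted sites (roles site1..site5) with flanks."""
    regions = tuple(
        (f"site{i + 1}", flank + i * site_length, site_length, 0.45) for i in range(5)
    )
    for attempt in range(50):
        spec = SyntheticTargetSpec(
            length=2 * flank + 5 * site_length, regions=regions, seed=seed + attempt * 1000003
        )
        target, truth = generate_target(spec)
        if _sites_mutually_clean([r.seq for r in truth], roles_antisense=(2, 3, 4, 5)):
            return target, truth
    raise RuntimeError("could not plant a mutually clean progressive site chain")


def multiplex_targets(seed: int) -> Tuple[Tuple[str, list], Tuple[str, list]]:
    """Two independent generic-tail-style targets for the cross-priming mode."""
    return generic_tail_target(seed), generic_tail_target(seed + 104729)


def write_fasta(path, records: Sequence[Tuple[str, str]]) -> None:
    """Write (id, seq) pairs as FASTA in the tool's input dialect."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
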