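# Methods

## The reaction-graph model

An amplification system is a typed multigraph.  Node kinds: `target`
(initiator), `primer`, `duplex_product` (a double-stranded functional-motif
amplicon, stored by its sense-strand fragment composition), `folded_sense`
and `folded_antisense` (the two self-folded single strands, each stored by
its own 5'→3' composition, the antisense being the reverse complement of
the duplex composition).  Edge kinds: `self_folding` (duplex → fold) and
`primer_extension` (fold → duplex, or target → duplex for the initiation
step; each extension edge is annotated with the priming label of the primer
that drives it).

A *circuit* is a minimal closed cycle alternating the two edge kinds, where
"minimal" means no proper subset of its nodes forms such a cycle; under the
edge-kind constraints these are exactly the duplex ↔ fold pairs whose
closure sustains amplification.  Circuit labels are assigned by a
deterministic convention: motifs in descending fragment count (ties broken
lexicographically), sense-side before antisense; a graph with a single
motif uses the plain `S`/`A` labels, otherwise circuits are numbered
(`S1`, `A1`, `S2`, `A2`, ...), so the longest motif drives the
first-numbered circuits.  The cross-priming multiplex graph additionally
has extension edges from each region's folds into the partner region's
duplex (the opened stem exposes the partner's priming site), which is what
makes the output non-empty when either target alone is introduced.

Product enumeration is reachability from the declared initiators by
alternating steps, collecting duplex compositions up to a fragment-count
cap (default 8; the longest motif any scheme builds has 6).  Unbounded
concatemers seen on gels are represented only as tandem repeats in the
amplicon module, never as graph nodes.  Target-dependent schemes
(`generic_tail`, `progressive`, `multiplex`) are built with *no* duplex
node until a target is attached: no starting point means no products,
which is how target-dependence (no-template silence) is programmed.  In
the `progressive` scheme the core motif `3a+1s+2s+3s` is the terminal
product generated inside the four circuits of the two longer motifs; the
core motif's own self-sustaining pair is the `basic` scheme.  The
`tailless` variant removes priming site 2 from the basic motif, leaving a
single antisense-side circuit.  Outer primers (F3/B3) appear only as
parallel target-side extension edges plus primer nodes: removing them
never changes the reachable product set, reflecting their purely kinetic
role (they are annotated at a tenth of the inner-primer concentration and
a lower Tm, and are omitted entirely when no flank window passes the
screens).

## Thermodynamics

Two-state nearest-neighbour model with the unified DNA stack parameters
(16 stacks, terminal initiation terms, self-complementary symmetry
correction), shipped as `data/nn_unified_v1.tsv` so results are
bit-reproducible.  Salt enters as the entropic correction
`ΔS + 0.368·N·ln[Na+]eq` with `[Na+]eq = monovalent + 120·√divalent` (mM);
defaults are 50 mM monovalent, 6 mM Mg²⁺ and 1 µM strands, matching a
typical strand-displacement reaction buffer.  ΔG is evaluated at 37 °C by
default.

Hairpin screening enumerates every contiguous stem (3 bp to n/2) paired
with a downstream reverse complement across a loop of ≥ 3 nt; fold score =
stem stack ΔG sum plus a loop penalty tabulated for 3–30 nt and
extrapolated as `ΔG(30) + 1.75·R·T·ln(n/30)` beyond.  A candidate fails
when its best fold is at or below −2.0 kcal/mol (configurable).  The
cross-dimer screen slides one sequence along the reverse complement of the
other over every ungapped offset and fails on (i) a complementary run
covering a 3' terminus longer than 4 nt or (ii) any contiguous duplex at
or below −8.0 kcal/mol.  Cutoffs follow conventional primer-design
practice and are all exposed in the configuration.

Filters apply to *functional parts* — recognition fragments, tails, outer
primers — not to full composite primers: composite primers carry designed
self-structure, and cross primers intentionally contain each other's
priming sites, so the mutual cross-dimer screen skips part pairs that are
designed complements, and the 3'-run rule is applied only to each primer's
actual 3'-terminal part (skipped where that priming is the mechanism).

## Design pipeline and defaults

Window screening keeps windows of 18–25 nt (both strands) whose
recognition Tm lies in 58–64 °C, GC in 0.30–0.65, that pass the hairpin
screen, and that occur exactly once across both strands of the target.
Universal tails (20 nt) are sampled with GC drawn uniformly in
[0.35, 0.60] and must pass the same Tm window and hairpin screen plus the
cross-dimer screen against the target and all candidate regions; sampling
is bounded, returning a partial list with a warning on exhaustion.

Assembly is scheme-specific.  Tail schemes pair two sense-strand sites
separated by at most 12 background nt, with the core span inside the
40–60 nt loop window (relaxed to the target length for short miRNA-style
targets); fragment 2 is defined as the middle plus the right site, so the
motif `us+1s+2s+ua` always tiles the core exactly while the antisense
primer's recognition part is the right site proper.  Chain schemes
(`basic` 3 sites, `tailless` 2, `progressive` 5) require exactly adjacent
sense windows with sites 1+2 spanning the loop window.  Cross-priming
primers follow the 5'-[incorporated partner part]-[opposite-strand
part]-[3' target part]-3' construct order.  Outer primers are searched in
the flanks at a Tm of 3–8 °C below the coolest inner recognition part and
must themselves pass the mutual screen.  Optional verification markers
(`TCTAGA`, `TTCGAA`) are spliced at the tail/recognition junctions and
propagate once per repeat unit into predicted amplicons.

Ranking is a weighted mean (equal weights by default) of five documented
subscores: inner-Tm uniformity `1/(1+spread/2)`, recognition-GC centrality
`1−2·mean|GC−0.5|`, hairpin margin `(bestΔG−cutoff)/5` clipped to [0, 1],
cross-dimer margin `(minΔG−cutoff)/|cutoff|` clipped, and unit-length
compactness `1−unit/300`.  Ties break by leftmost region start, then
lexicographic primer sequences, giving a total order.

## Amplicon prediction and digestion

Products are tandem repeats of each enumerated motif unit for 1..5 copies
(longer concatemers add no symbolic information).  Digestion scans the
sense strand only — the shipped 6-bp sites are palindromes, making this
equivalent to double-strand scanning — accepting exact matches greedily
left-to-right in a single pass without re-scanning (non-regenerating
sites), cutting after `cut_offset` bases, suppressing zero-length terminal
pieces; fragment lengths always sum to the input length.

## Curve analysis

Threshold time Tt is the first time the signal reaches 20 % of its
maximum, computed after subtracting the curve minimum so Tt is invariant
to detector offset and affine rescaling (a flag disables baseline
subtraction); crossings are linearly interpolated between samples and an
unreached threshold yields an explicit undefined value.  Concordance
percentages are reported to one decimal, rounding half up (52/54 → 96.3).
Relative speed-up of Tt_a against baseline Tt_b is `100·(Tt_b−Tt_a)/Tt_b`.

## Synthetic fixtures

Targets are uniform random DNA with planted windows rejection-sampled to
pass the designer's default filters at the stated GC (0.45 by default);
the convenience layouts additionally resample (deterministically, by
offsetting the seed) until the *set* of planted sites passes the mutual
cross-dimer screen, since individually clean windows can still share
chance 3'-complementary runs.  Curves are logistic
(`plateau/(1+exp(−(t−mid)/slope))`, default midpoint 25 min, slope 2 min,
0.5-min sampling over 60 min) with Gaussian noise and the analytic
20 %-crossing recorded as ground truth.  miRNA pairs are 22-mers differing
at exactly two positions.  Fixtures emulate length/GC/Tm/structure
properties of real priming regions but not genomic repeat structure,
cross-homology or clinical-sample inhibitors, so passing tests demonstrate
the correctness of the design logic, not wet-lab performance.  Test and
acceptance runs use targets of roughly 120–200 nt, which exercise every
code path in seconds.

## Numerical and interface choices

All randomness flows from one user-supplied seed through named
`numpy` generators; identical (target, config, seed) reproduce
byte-identical outputs (the run manifest records version, config echo,
input checksums and a timestamp).  Graphs export as DOT with node kind and
composition attributes.  Degenerate IUPAC bases are rejected rather than
expanded; `U` is mapped to `T` with the original alphabet recorded.
Coordinates are 0-based half-open on the sense strand.  Exit codes: 0
success, 1 infeasible design, 2 usage/input error.

## Known limitations

No partition-function folding, pseudoknots or RNA parameters; no kinetic
or free-energy pathway modelling (product prediction is symbolic); no
multiple-alignment conserved-region discovery (the user supplies the
conserved target); LNA placement is out of scope (an annotation concern
downstream of design); no gel-mobility modelling.  The published reference
material for this class of assays does not state the nearest-neighbour
parameter set or salt model used there, so agreement with any particular
external Tm calculator is not claimed; the parameter file documents
exactly what is computed.
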