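# graphamp

Reaction-graph design of hairpin-mediated isothermal nucleic acid
amplification assays.

## The problem

Isothermal amplification methods such as LAMP and CPA work by creating
*functional hairpin motifs*: single-stranded products that self-fold into a
stem-loop whose loop exposes a priming site, so that every round of primer
extension regenerates the template for the next round.  Designing such
assays by hand is slow and error-prone, because the mechanism lives in the
relationships between sequence fragments, not in any single primer.

`graphamp` makes those relationships explicit.  An amplification system is
modelled as a **reaction graph**:

* nodes are species — double-stranded motif products (`duplex_product`),
  self-folded sense/antisense strands (`folded_sense` / `folded_antisense`),
  primers and targets;
* solid edges are self-folding disassembly, dashed edges are primer
  extension by a strand-displacing polymerase;
* a closed cycle alternating the two edge kinds — a **circuit** (S, A, S1,
  A1, ...) — means sustained amplification.

Fragments are named in the field's `1s/2a/us/ua` notation: a number (or `u`
for the synthetic *universal tail*), plus `s`/`a` for sense or antisense
(`2a` is the reverse complement of `2s`).  A functional motif is a fragment
composition such as `3a+1s+2s+3s`: stem `3a:3s`, loop `1s+2s`.

The package is for assay developers: given a target sequence it screens
priming regions, generates and screens universal-tail sequences, compiles
primer sets for five scheme topologies (`basic`, `tailless`,
`generic_tail`, `progressive`, and the two-target cross-priming
`multiplex`), validates circuit closure, predicts amplicons as tandem
repeats of the motif unit (with in-silico restriction digests, e.g. XbaI at
`TCTAGA`, for gel verification), and provides utilities for real-time curve
analysis (threshold time Tt at 20 % of maximum fluorescence) and 2x2
clinical concordance.

## The thermodynamic core

Primer filters use the two-state nearest-neighbour duplex model

```
Tm = ΔH° · 1000 / (ΔS°corr + R · ln(C_T / x)) − 273.15
ΔS°corr = ΔS° + 0.368 · N · ln[Na+]eq ,   [Na+]eq = [mono] + 120·√[div]  (mM)
```

with the unified DNA stack table shipped as a versioned text file
(`src/graphamp/data/nn_unified_v1.tsv`), hairpin screening by exhaustive
stem/loop enumeration with a tabulated loop penalty, and an ungapped
cross-dimer screen (3'-terminal complementary runs and duplex ΔG).

## Worked example

```
graphamp fixtures --kind generic_tail --seed 11 --out target.fasta
graphamp design --target target.fasta --scheme generic_tail --seed 42 --out run1
```

prints `5 ranked design(s) written to run1` and writes `primers.tsv`,
`report.yaml`, `graph.dot`, `amplicons.fasta` and `manifest.json`.  The top
of the primer table:

```
design_rank  role             composition  sequence_5to3                            length  Tm_C   GC     conc_class
1            inner_sense      us+1s        ACTCTTACGTGTAAGTCAAAAATCGGGACACTGAGATT   38      74.90  0.395  inner_1uM
1            inner_antisense  us+2a        ACTCTTACGTGTAAGTCAAACTAGGCAAACGCTAGTAGA  39      75.41  0.410  inner_1uM
1            outer_B3         B3           ATGGAGTCTATTGTACAG                       18      55.74  0.389  outer_0.1uM
```

Both inner primers share the same 20-nt 5' tail (`ACTCTTACGTGTAAGTCAAA`,
the randomly designed and screened `us` sequence) and differ in their 3'
target-recognition parts; the outer primer's Tm (55.7 °C) sits below the
inner recognition window (58-64 °C) and it is annotated at a tenth of the
inner concentration.  The predicted amplicon unit is the 85-nt motif
`us+1s+2s+ua` (`amplicons.fasta` holds its 1..5-copy tandem repeats), and
`graph.dot` contains the attached-target graph whose circuits S and A
close.  Without the target the same graph has no `duplex_product` node at
all — the designed primers coexist silently.

Curve and concordance analysis:

```
graphamp analyze --counts 35,2,0,17 --out concordance.tsv
```

writes overall/positive/negative agreement of `96.3 / 94.6 / 100.0` percent
for a 54-sample comparison with 2 discordant results.

## Layout

| module | contents |
| --- | --- |
| `sequence_core` | DNA string validation, fragment-label algebra, composition rendering, FASTA I/O |
| `thermo` | nearest-neighbour Tm/ΔG, hairpin and cross-dimer screens |
| `reaction_graph` | typed graph, scheme topologies, circuit closure, product enumeration, DOT export |
| `primer_design` | target screening, universal tails, scheme assembly, ranking |
| `amplicon_prediction` | tandem-repeat models, in-silico digestion, marker insertion |
| `assay_analysis` | threshold time, curve normalisation, concordance, speed-up |
| `fixtures` | synthetic targets/curves/miRNA pairs with recorded ground truth |
| `io_cli` | `graphamp` command-line tool, config, run manifests |

See `docs/methods.md` for the model, parameter defaults and limitations.
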