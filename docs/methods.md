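# Methods

## Mass arithmetic and conventions

All mass computation rests on fixed monoisotopic masses (Da):
H 1.0078250319, C 12 (exact), N 14.0030740052, O 15.9949146221,
S 31.97207069, Na 22.98976928, electron 0.00054858. Only singly charged
even-electron adducts are supported — [M+H]⁺, [M−H]⁻, [M+Na]⁺ — and ion
masses carry the electron correction (proton = H − e⁻; sodiation adds
Na − e⁻). This choice is load-bearing: without the ~0.7 ppm electron term
the positive-mode reference errors of the disinapoyl-sucrose data set
(−0.309 ppm for the sodiated parent, −0.773 for the sodiated
ester-cleavage product, −4.438 for the protonated demethoxylation
product, 0.456 and −0.338 for the sinapic-acid derivatives) no longer
reproduce. The signed error convention is
ppm = 10⁶(measured − theoretical)/theoretical, i.e. a measurement above
theory is positive, matching the signs of the positive-mode reference
values. Negative-mode printed errors in the source data set are not
reproducible under either electron-corrected or hydrogen-atom arithmetic;
the package stores them as provenance and asserts nothing about them.

RDB (ring-double-bond equivalents) is computed on neutral compositions as
C + 1 − (H + Na)/2 + N/2, with sodium treated as monovalent. Nominal mass
shifts used in metabolite reasoning (206 Da for glycosidic cleavage,
42 Da for triple demethylation, 18 Da for hydration, 32 Da between the
two deprotonated glycoside products) are nearest-integer differences of
measured m/z.

## Formula enumeration

`enumerate_formulas` searches the full bounded lattice (defaults: C 0–50,
H 0–100, O 0–50, N 0–5, S 0–5, Na 0, RDB 0–15, 5 ppm tolerance), pruning
partial masses above the window and solving the oxygen count range in
closed form per (Na,S,N,C,H) prefix. Results carry signed ppm and are
sorted by |ppm| with Hill-notation tie-breaks. No valence heuristics
beyond the RDB window are applied: the enumeration is deliberately the
exhaustive predictor its bounds describe, and the test suite pins it to
an independent dense-grid brute force over 50 random masses in
50–800 Da. Degenerate inputs: non-positive target mass returns an empty
list; a non-positive tolerance is an error.

## Biotransformation closure

Candidate metabolites come from a breadth-first closure of the parent
formula under a catalog of signed element-count deltas. The bundled
catalog holds 12 rules: de/methylation (∓CH₂), demethoxylation (−CH₂O),
reduction/dehydrogenation (±H₂), hydroxylation/dehydroxylation (±O),
hydration/dehydration (±H₂O), sinapoyl ester cleavage (−C₁₁H₁₀O₄),
glycosidic (anhydrohexose) cleavage (−C₆H₁₀O₅), and a C₇H₆ loss. The
+H₂O delta intentionally stands in for the hydroxylation-plus-reduction
composite so that the hydroxylated sinapic acid is reachable at depth 4,
matching how 18-Da shifts are reasoned about in practice.

The closure deduplicates by formula, keeping the shortest path (ties:
lexicographically earliest rule-name sequence), and must be bounded to
keep gain rules from wandering: heavy atoms (C, N, Na, O, S) are capped
at the parent count + 2, while hydrogen is bounded by valence instead —
RDB of every member must stay ≥ 0, which terminates every +H₂ chain.
A fixed H cap tied to the parent would be wrong here: successive
reductions legitimately push metabolites 4–6 hydrogens above the parent
(the di/tri-hydrogenated products), yet they remain valence-sane. With
the default depth of 8 the closure holds ~5,500 formulas and reaches all
20 identified metabolites; the deepest required route is 7 steps
(ester cleavage, two glycosidic cleavages, reduction, methylation,
dehydroxylation, reduction).

`label_reaction` reports the shortest closure path between two formulas
or "unexplained"; it purposely reports the literal shortest delta path
even where a data source uses a looser verbal label for a composite
transformation.

## Grouping and candidate assignment

Cross-polarity grouping is single linkage: two features merge when their
retention times agree within 0.2 min and their deduced neutral masses
within 10 ppm (relative to the pair mean). These defaults merge every
dual-polarity pair in the packaged table (worst observed discrepancy
2.4 ppm / 0.04 min) while keeping the positional-isomer groups — which
share compositions but elute ≥ 0.62 min apart — distinct. Grouping is a
partition and is order-independent (verified by shuffling).

A group's candidates are the closure members whose theoretical adduct
m/z lies within the 5 ppm MS1 gate of *every* member feature; ranking is
(path depth, mean |ppm|, Hill order), so the parent wins at depth 0 when
it fits. Groups with no candidate are retained as "unidentified" rows
rather than dropped. On the packaged table, 19 of 20 groups receive
their published composition at 5 ppm; the one failure sits at −6.4 ppm
under electron-corrected arithmetic and is recovered at 7 ppm, so the
19/20-at-5, 20/20-at-7 behavior is asserted in the tests as the expected
outcome, not patched over. Isomer groups sharing a composition are
distinguished by retention-time rank (earlier elution → lower rank).

## MS2 fragment annotation

Fragment candidates are the element-wise sub-compositions of the
precursor ion (the neutral plus adduct atoms), carrying the precursor's
polarity; fragment m/z = mass ∓ mₑ. Even-electron ions are assumed, i.e.
half-integer RDB; integer-RDB compositions are admitted only as
methyl-radical losses (loss ⊇ CH₃), reflecting the observed
205 → 190 → 175 demethylation ladder of the sinapoyl fragment. The MS2
tolerance defaults to 10 ppm — looser than the 5 ppm MS1 gate because
printed fragment masses scatter more than precursors. The best candidate
is the smallest |ppm|; the complementary composition is reported as the
neutral loss and labeled when it matches the canonical dictionary (H₂O,
CO, CO₂, CH₃, CH₂O, CH₃OH, C₆H₁₀O₅, C₁₁H₁₀O₄). A separate validator
audits *printed* fragment assignments for sub-formula containment and
10-ppm mass agreement and flags violations (21 printed compositions in
the packaged table are impossible sub-formulas of their precursors);
flags are reported, never silently corrected.

## Distribution differencing and behavioral statistics

A metabolite's per-group distribution is the union of its polarity rows:
detection in either ionization mode is detection. Differencing is pure
set arithmetic (sham∖model, model∖sham; both empty = concordant), and
blood–brain-barrier penetrance reads matrix code 6 alone. Under union
semantics exactly 10 of the 20 packaged metabolites are non-concordant —
a superset of the seven named in the source discussion; the three extras
follow literally from the table's codes, and the individually narrated
claims (brain gains/losses, kidney, urine/feces, feces-only-in-sham) are
asserted one by one.

The recognition index is RI = T_novel/(T_novel + T_familiar) (the
printed expression is ambiguous; the ratio-of-total definition is the
one consistent with its verbal description and value range). The
two-sample test is the pooled-variance Student form from summary
statistics, df = n₁ + n₂ − 2, with Welch's approximation behind a flag;
p-values are kept at full precision and compared at 3 decimals. The test
suite checks p against an independent numerical oracle that integrates a
hand-written gamma-function t density. Bonferroni adjustment multiplies
by the family size and caps at 1.

## Synthetic data and what it does (not) show

The simulator emulates the measurement model the pipeline assumes: true
metabolites drawn (seeded) from the closure with the parent always
included; per adduct, measured m/z = theoretical · (1 + ε·10⁻⁶) with
ε ~ N(0, σ) in ppm — multiplicative because Orbitrap error scales with
mass; formula-free decoy masses uniform over 150–800 Da; uniform
retention times over 5–24 min (the observed elution window; RT carries
no chemical meaning in simulation); per-matrix Bernoulli detection.
Defaults, chosen once for the study's conditions: σ = 1 ppm (comfortably
inside the 5 ppm gate, as the verified sub-ppm reference errors
suggest), 20 true metabolites, 50 decoys, detection probability 0.6
(approximately the fill fraction of the packaged distribution table),
adduct emission probabilities 0.6/0.35/0.5 for H⁺/Na⁺/−H (reproducing
the mix of single- and dual-polarity detections); deprotonation is
skipped for hydrogen-free compositions. MS2 spectra are random
neutral-loss cuts from the dictionary.

Recovery experiments score recall (true metabolites whose group receives
the true formula as top candidate) and precision (identified groups
traced to a single correct truth). At σ = 1 ppm against the 5 ppm gate
recall stays ≥ 0.95; recall is monotone non-increasing in noise
(checked at σ ∈ {0, 1, 3, 10} ppm over 10 seeds) and collapses when the
gate is tightened to 0.01 ppm. What passing these tests does *not* show:
the simulator has no chromatographic peak shapes, no intensity model, no
isotopologue envelopes, no correlated calibration drift, and decoys are
random masses rather than chemically plausible wrong formulas — so the
recovery rates characterize the mass-arithmetic pipeline, not real-world
detectability.

## Problem sizes and numerical choices

The default test and validation workload is desk-scale by construction:
closure ≈ 5.5 k formulas (≈ 0.2 s), brute-force oracle grid ≈ 9.5 M
lattice points evaluated once per session, 40 recovery runs over a
shared closure. Tolerance comparisons use absolute ppm; candidate
windows are padded ×2 before exact per-feature checks so the neutral-
versus-ion ppm scale difference cannot exclude a boundary candidate.
Tables serialize m/z to 5 decimals and ppm to 3; adduct ppm values are
recomputed (not parsed) on read so write/read round-trips are exact.

## Known limitations

Charge states beyond ±1, isotope-pattern simulation, structure-level
(connectivity) prediction, enzyme assignment, retention-time modeling,
spectral-library scoring, and quantitation are out of scope. The
packaged table transcription inherits the source's internal
inconsistencies (irreconcilable printed "exact mass" column entries,
impossible printed fragment compositions, one composition conflict
resolved in favor of the narrative/mass-consistent C₂₇H₃₆O₁₉); these are
preserved verbatim with flags rather than corrected.
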