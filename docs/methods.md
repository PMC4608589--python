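# Methods

`memfam` implements the statistical machinery used to infer deep homology
among membrane-transporter families — the approach by which the LysE
superfamily of exporters was expanded from three families to eleven — and
a synthetic-data generator that reproduces the structure of that problem
well enough to validate every stage against known ground truth.

## The comparison score

The central statistic is the *comparison score*: the optimal global
(Needleman–Wunsch, affine-gap) alignment score of two protein sequences,
expressed in standard deviations of an empirical null distribution
obtained by re-aligning the first sequence against many random shuffles
of the second,

    z = (S − mean(S_k)) / sd(S_k),   S_k = score(a, shuffle_k(b)).

Shuffling permutes residues uniformly (Fisher–Yates), so every shuffle
preserves composition exactly: the null measures what these two *bags of
residues* can score by chance, and z measures how much the actual
*arrangement* exceeds that. Each shuffle k draws its permutation from an
independent counter-keyed stream (`SeedSequence([seed, k])`), so any
single shuffle is reproducible in isolation. The sample standard
deviation (ddof = 1) is used; a null with zero spread (e.g. homopolymer
inputs) raises an error rather than returning an arbitrary z.

Scoring defaults are BLOSUM62 with gap cost `8 + 2·L` for a gap of
length L, end gaps charged. The tools this statistic descends from do
not publish their exact matrix and penalties, so these are configurable,
and reproduction of historical scores is expected only within a
tolerance band. Two properties of this configuration matter:

* **Calibration.** For unrelated random sequences, the aligned pair is
  itself one draw from the composition null, so z is approximately
  standard normal. The acceptance suite verifies |mean| < 0.15 and
  sd ∈ [0.8, 1.2] over 1,000 pairs, with no pair near the 13 S.D.
  evidence threshold.
* **End gaps are charged.** Leaving terminal gaps free (the semi-global
  convention) collapses the spread of the shuffle null and roughly
  doubles the z of chance matches between proteins that merely share
  membrane architecture; with end gaps charged, such matches stay in the
  single digits of S.D., where the published negative-control scores
  live. `AlignParams(free_end_gaps=True)` exposes the other convention.

Convention: 2,000 shuffles for screening, 20,000 for confirmation-grade
scores (z itself is unbiased in the shuffle count; more shuffles only
tighten its noise).

## Evidence criteria and the superfamily principle

Homology between families is accepted on three conditions: a comparison
score of at least **13.0 S.D.**, at least **3 aligned TMSs**, and a
shared evolutionary pathway (here operationalized by the internal-repeat
analysis below). Aligned-TMS counting walks the residue-pair path of the
optimal alignment and counts segment pairs sharing at least
`overlap_min = 5` aligned residue pairs — about one helical turn — with
each segment participating in at most one counted pair (greedy by
overlap size).

Family pairs whose best direct score falls short are linked
transitively: a chain A–B–C–D (A, D established members of families X
and Y; B, C their homologues) establishes X–Y when the bridge B–C meets
both criteria and the anchors A–B and C–D each meet the z criterion.
The direct A–D score is reported but never used — the method's point is
that it can be insignificant while the chain is conclusive. Anchors are
held to the full 13.0 S.D. standard; the published chains all satisfy
this easily, and requiring it makes the verdict monotone in the
criteria. Family-level verdicts form a graph whose connected components
are the inferred superfamilies; with the published chain table as input,
the eleven candidate families form a single component and the
mitochondrial-carrier control remains isolated.

## Topology: hydropathy, amphipathicity, TMS calling, AveHAS

Hydropathy is the Kyte–Doolittle index averaged over a centered window
(default 19, truncated at the termini). Amphipathicity is the Eisenberg
hydrophobic moment at 100°/residue over an 11-residue window. TMS
calling is a transparent thresholder, not an HMM: maximal runs of
windowed hydropathy ≥ 1.6 are merged across dips ≤ 3 residues, runs
shorter than 15 are dropped, runs longer than 25 trimmed symmetrically.
Externally produced annotations can be imported (TSV, 1-based
inclusive) and override predictions wherever annotations are accepted.

AveHAS-style profiles average per-sequence hydropathy and
amphipathicity over alignment columns (contributors only). Column
similarity is the mean over residue pairs of
`(s(a,b) − s_min) / (max(s(a,a), s(b,b)) − s_min)`, which is 1 for an
identical pair and 0 at the matrix minimum; columns with fewer than two
residues score 0 by convention. The same substitution matrix serves
alignment, identity, and similarity, so one scoring configuration
governs the suite.

## Internal repeats

A 6-TMS protein descended from a tandemly duplicated 3-TMS unit carries
residual similarity between TMSs 1–3 and TMSs 4–6. The detector excises
the two TMS-delimited regions (flank 5, clipped at the central loop's
midpoint if they would overlap), scores them with the shuffle null, and
grades: `repeat_supported` at ≥ 13 S.D., `suggestive` at 5–13 S.D.
(ancient duplications typically land here; published half-vs-half
scores run 5.7–13.5), else `not_supported`. For proteins with more than
six TMSs the first six define the units; a leading extra TMS can be
skipped with `tms_offset`.

## Motifs

Patterns use the compact notation of conserved-motif tables — letters,
`X` wildcard, `(K/R)` alternatives. Scanning is exhaustive and ungapped;
hits are localized to the TMS containing their midpoint, and prevalence
("n displaying / n total") can be restricted to a stated TMS. Per-column
residue-frequency tables support conservation claims as thresholds:
fully = 1.00, strongly ≥ 0.90, well ≥ 0.70 (the thresholds are package
conventions).

## Superfamily trees

MSAs degrade across the distances separating these families, so the
tree is built from pairwise scores instead: all-vs-all global raw
scores are rescaled to bits with Karlin–Altschul constants
(λ = 0.267, K = 0.041, the standard gapped-BLOSUM62 values), turned
into distances `d(i,j) = 1 − b(i,j)/min(b(i,i), b(j,j))` clipped to
[0, 1.5], and passed to neighbor joining. The transform is a heuristic,
not an additive distance — triangle violations are counted
(`triangle_violations`), never repaired — and the reproduction surface
is family-level clustering, not branch lengths. An ensemble (default
100) of trees built from per-pair column-bootstrapped score matrices
yields a majority-rule consensus; clade frequencies serve as supports.
NJ recovers additive matrices exactly (property-tested); consensus of a
self-consistent ensemble is idempotent.

## The synthetic generator

The generator produces the study's assumed structure with known truth:
families of ~230-residue 6-TMS proteins descended from one tandem
duplication of a 3-TMS unit (TMS 21, loop 15, tails 12), with topology
variants (3+3+1, 1+3+3, 3+3+2), target pairwise divergences within and
between families, rare short loop deletions (so the true alignment
lives on one shared column frame), planted motifs, and a
negative-control decoy lineage: a 2-TMS unit triplicated, copies
mutually diverged to saturation, with carrier-like geometry (25-residue
loops, ~310 aa total).

Residues come in two classes — TMS (I/L-dominant hydrophobic, mean
Kyte–Doolittle ≈ +3.5, with 4-residue pure-hydrophobic edge anchors)
and loop (broad polar/small/charged mix, mean ≈ −1.1). Substitutions
stay within class, biased by `exp(BLOSUM62/2)`, so TMSs remain callable
while loops diverge freely — the conservation pattern averaged-
hydropathy plots show on real homolog sets. Site rates are solved from
target pairwise divergence d via `2p(1−p) + p²(1−c) = d` (c the kernel's
collision probability); past the saturation point `d = 1/(1+c)` the
solver caps at the maximizing rate, the "diverged beyond recognition"
regime used for the decoy's copies.

Three design points came out of pilot simulation and are deliberate:

1. **Near-exact composition sampling.** Segment residues are drawn with
   largest-remainder-rounded counts (arrangement random). I.i.d.
   sampling gives windowed-hydropathy noise that erodes run edges below
   the caller's 15-residue minimum; real helices and loops are far more
   compositionally uniform than an i.i.d. draw.
2. **Lineage-specific compositions.** Each root draws Dirichlet-jittered
   class weights (constrained to preserve the class hydropathy mean),
   and the decoy has disjoint palettes (F/M/C/V-emphasis against the
   families' I/L). Unrelated superfamilies differ in composition; a
   decoy that is a composition clone of the families scores 15–17 S.D.
   against them on architecture alone, whereas distinct palettes put
   chance scores at 8–12 S.D. — the band the real mitochondrial-carrier
   control occupies (4.1–10.5, top-five mean 9.8).
3. **Decoy geometry.** The decoy's 6 TMSs are spaced by long loops, so
   its helices sit out of register with the 3+3 families'; in-register
   architecture matching is a genuine component of chance similarity
   between membrane proteins and must be present, but not length-for-
   length identical.

What the generator does **not** model: insertions (indels are loop
deletions only), site-rate heterogeneity, codon structure, domain-level
insertions (the large hydrophilic domains of some real families), or
realistic phylogenies within families (members are i.i.d. around a
family ancestor). Passing tests therefore show the statistics behave
correctly under the model's assumptions — duplicated architecture,
class-conserved substitution, composition-distinct outgroups — not that
they are robust to everything real data contains.

## Problem sizes and numerics

Default experiment sizes: null calibration 1,000 pairs × 200 shuffles
(length 200); linkage 10 replicates of 4 families × 8 members at 35%
divergence with 2,000-shuffle screening; repeat discrimination 20 exact
tandems and 100 decoy proteins at 1,000 shuffles; trees 100 bootstrap
replicates over 4 members per family. These sizes give the rates the
package reports a resolution of 1/10 to 1/1000 while each driver stays
in the minutes range on one core.

Tie-breaking: the aligner returns the first optimal path (deterministic
for fixed inputs); NJ ties resolve by input label order; screening
ranks deterministically by (score, index). Degenerate inputs: empty
sequences, sub-30-residue comparison inputs, ragged alignments, and
zero-spread nulls all raise typed errors; short proteins are skipped
with warnings at load and in repeat surveys.

## Known limitations

* Exact reproduction of historical comparison scores depends on scoring
  parameters the original web tools never published; the recomputation
  path (`recompute_reported_pairs`) is therefore held to a ±2 S.D.
  band, and the sequences themselves must be supplied by the user
  (`data/uniprot/<accession>.fasta`) since the study deposits none.
* The z statistic cannot fully separate "shared architecture" from
  "shared ancestry" for membrane proteins; the aligned-TMS criterion,
  the 13 S.D. threshold, and the negative control exist precisely to
  manage that, and the generator reproduces the effect rather than
  hiding it.
* The hydropathy caller is deliberately simple; on real sequences an
  HMM-based predictor will disagree at segment edges, which is why
  imported annotations override predictions everywhere.
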