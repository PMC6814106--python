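# Methods

## Domain model and scanning

A zinc-finger domain is modelled as an ordered chain of eight metal
ligands (C or H) with class-specific constraints:

| class | ligand order | gap between ligands 4 and 5 | span (first→last ligand) |
|-------|--------------|------------------------------|---------------------------|
| PHD   | C C C C H C C C | 4–5 residues | 50–80 aa |
| RING  | C C C H C C C C | 2–3 residues | 30–90 aa |
| LIM   | C C H C C C C C | 2 residues   | 30–90 aa |

Only the 4th–5th gap and the PHD span are canonical constraints of the
classes; the remaining six gaps are bounded by a permissive default of
1–30 residues, and the RING/LIM spans by 30–90 aa. These defaults are
wide enough for real domains while keeping enumeration bounded, and all
four bounds are per-template configuration, not code.

`enumerate_chains` performs a depth-first search over ligand positions
with window pruning on every gap and on the running span; once the
wildcard budget (`allow_missing`, at most 2) is spent, the search jumps
directly between indexed C/H positions, which makes scanning linear-ish
in practice on ligand-sparse backgrounds. 'X' is accepted in sequences
but never as a ligand.

Classification checks the ligand pattern, the 4th–5th gap and the span
against each template in priority order (PHD > RING > LIM). A chain
whose spacing is PHD-like but with 1–2 mismatched ligand slots is
SUSPECTED; the canonical degenerate rule mentions only "two or more"
absent ligands, and single-ligand losses are deliberately included here
(reported via `missing_slots`) because they are biologically the same
degeneracy mode.

Overlap resolution is two-phase. Intact-class candidates compete under
(earliest start, shortest span, class priority). SUSPECTED candidates
then fill only regions no intact annotation claims, ordered by (most
matched ligands, earliest start, shortest span): a degenerate call is
meaningful only where no intact domain exists, and preferring the most
complete chain keeps single-mutation domains labelled with 7/8 ligands
instead of a shorter 6/8 variant. Note that the exact coordinates of a
degenerate domain are not identifiable in general — a wildcard slot can
legally sit at several background positions — so tests assert overlap
and ligand-count identity for SUSPECTED domains, and exact coordinates
for intact ones.

Coordinates are 1-based inclusive everywhere; conversion happens only at
I/O boundaries.

## Protein statistics

Molecular weight is the sum of average (isotope-averaged) free
amino-acid masses minus one water (18.0153 Da) per peptide bond; 'X'
contributes a configurable mass defaulting to the mean of the 20
standard residues. The theoretical pI uses a Henderson–Hasselbalch net
charge over the two termini and D, E, C, Y, H, K, R with the EMBOSS pKa
set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1). The charge is strictly decreasing in pH, so the zero
is unique; bisection runs to a 10⁻⁶-wide bracket, which guarantees both
|charge| < 10⁻⁴ and positional agreement with a 0.001-pH grid search.

## Family tables

Percentages are computed as decimal `100·n/d` rounded **half-up** to one
decimal: this convention reproduces every self-consistent printed cell
of the reference survey's tables, whereas banker's rounding would not
(e.g. 18.75 → 18.8). Each table carries its denominator (row, column or
grand total) explicitly, and emitted TSVs record it in a header line.
`discrepancy_report` compares recomputed against printed percentages
cell-by-cell; the reference survey contains a small number of internally
inconsistent printed values (e.g. 65.7% printed for 92/145 = 63.4%),
which the package flags and never reproduces.

## Phylogenetics

Distances are uncorrected p-distances with pairwise gap deletion — the
proportion of mismatching mutually ungapped columns — chosen for exact
testability; a Poisson correction (−ln(1−p)) sits behind a flag. The
tree method is Saitou–Nei neighbor joining with the Q-criterion; ties in
Q are broken toward the smallest index pair, so results are
deterministic. Negative branch-length estimates (possible for
non-additive inputs) are clamped to zero and logged. For additive
matrices NJ is consistent: the suite verifies exact recovery (topology
and path lengths to 10⁻⁹) on random 5–8 leaf trees, and cross-checks
topology against scikit-bio's independent NJ implementation.

Bootstrap support resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and scores each internal edge of the
full-data tree by the percentage of replicates containing the same leaf
bipartition (canonical orientation: lexicographically smaller side).
Supports are attached as internal node labels and survive Newick round
trips. Grouping trees into named clades (A–F style) was a manual step in
the reference survey and is intentionally not automated; the bipartition
utilities support any downstream grouping.

## Expression analysis

FPKM matrices are log₂(x+1)-transformed (pseudocount 1 so that zero
FPKM maps to zero; configurable), then clustered with average linkage on
Euclidean row distances via scipy. Merge heights equal mean inter-
cluster distances; a brute-force agglomeration oracle checks this
exactly for small n. The three expression groups are assigned by rule:

* **III (silent)** — every tissue < 1 FPKM;
* **II (preferential)** — some tissue ≥ 1 FPKM and > 2× the median of
  the other tissues (median rather than max keeps one co-expressed
  tissue from masking a preference; the baseline is configurable);
* **I (constitutive)** — every tissue ≥ 1 FPKM and not preferential.

Genes matching none of the rules are borderline and mapped to I or III
by their maximum value, flagged as such. The expressed threshold of
1 FPKM is the common field convention. Cluster-based labels (k=3 cut)
are emitted alongside rule-based ones because the reference workflow
combined clustering with visual inspection and the two need not agree.

Triplet comparison classifies a retained LF/MF1/MF2 paralog set as
`with-degenerated-copy` if any copy is rule-silent, `one-dominant` if a
single copy exceeds 2× every other copy in all tissues,
`partial-dominant` if in some but not all tissues, else `balanced`.

### What the synthetic FPKM design does and does not show

The generator plants 50 genes per class over six tissues: constitutive
log-normal(μ=4, σ=0.5) everywhere, preferential log-normal(μ=5) in one
random tissue and log-normal(0, 0.5) elsewhere, silent uniform[0, 0.3].
Two consequences are worth stating plainly, because they bound what the
tests can show:

1. With σ = 0.5, about half of the *constitutive* genes genuinely have
   one tissue more than 2-fold above the median of the others, so the
   preferential rule correctly fires on them and planted-label recovery
   plateaus around 80–90%, not near 100%. The per-class checks confirm
   that every misclassified constitutive gene is exactly one whose row
   trips the 2-fold rule — the rule is right; the planted labels are
   noisy at this spread.
2. Preferential genes with different peak tissues are mutually farther
   apart in log₂ Euclidean distance (≈√2 × peak height) than each is
   from the silent class (≈ peak height), so average linkage merges
   preferential genes into the silent cluster before the 3-cluster
   level, and the k=3 cut recovers the planted partition only partially
   (Rand index ≈ 0.78). A tissue-aligned preferential class (all peaks
   in one tissue) is recovered exactly, as the archetype test shows.

Real tissue panels are also zero-inflated and library-size confounded;
the generator does not emulate those features, so passing tests say
nothing about normalisation issues.

## Genome context

Intron count is exon count − 1 from GFF3 gene models (first mRNA's
exons; exons directly on the gene are accepted). Retention counts each
ortholog group once by the number of *distinct* subgenomes retained
(duplicates within a subgenome are flagged but not double-counted), per
the fractionation model of the Brassiceae whole-genome triplication.

Tandem duplicates: consecutive family members along a chromosome with at
most 5 intervening annotated genes and at most 100 kb between their
spans (both configurable). The field has no single convention; this one
is conservative, and a tandem array of three genes yields the two
chain-adjacent pairs, not the clique. Segmental duplicates require an
externally declared table of collinear block pairs: a pair is called
when two family genes fall in the two regions of one block pair and
share an ortholog group.

## qPCR quantification

ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt is the difference of
stratum mean ΔCt values between a sample and its calibrator, which
defaults to the control condition at the same time point (the common
reading of a time-course design; the 0-h calibrator is available by
argument). Fold change is 2^−ΔΔCt with amplification efficiency fixed
at 2 (no efficiency correction, matching the reference workflow).
"Student's t-test" is read as the classical pooled-variance test
(Welch behind a flag) and is applied two-sided to per-replicate fold
values by default; testing on ΔCt values is available because the
reference workflow does not state which quantity was tested (the
direction calls agree on the synthetic design). No multiple-testing
correction is applied — deliberately, to match the workflow being
modelled; the null simulation in the suite confirms the nominal 5% star
rate. Gene-level up/down tallies over a time course use the majority of
starred directions; a tie counts in neither bucket.

## Synthetic data generators

All generators draw from `numpy.random.default_rng(seed)` and are
byte-reproducible. Sizes and conditions default to the reference
study's scale:

* **Proteome**: 200 proteins; class mix ≈ 40/12/7/4% with one–four PHD
  domains, 12% RING, 10% LIM, 15% motif-free, echoing the reference
  family's domain-count distribution with enough non-PHD classes to
  exercise spacing discrimination. Gaps are drawn template-legally
  (span forced into range by rejection), motifs are separated by ≥ 25
  background residues, and the default background alphabet excludes C/H
  so planted truth is exact; a natural-frequency background exists to
  measure (not assert) false positives. Degenerate motifs mutate 1–2
  interior ligand slots (2–7) to alanine so planted endpoints stay
  well-defined.
* **Synteny**: exactly (7, 21, 68) ortholog groups with 3/2/1 retained
  copies, 14 subgenome-unassigned genes (145 family genes total), 5 on
  scaffolds, one planted tandem pair and 29 segmental block pairs.
  Family genes are placed ≥ 30 gene slots (150 kb) apart so only
  planted clusters can qualify as tandem.
* **MSA**: per-site, per-branch substitution with probability equal to
  the branch length (or an override), on a caller-supplied Newick tree.
* **Ct tables**: 18 genes × {control, salt, drought} × {0, 1, 3, 24} h
  × 3 replicates; planted effects of ±2.5 log₂ units with 11/7 genes
  up/down under salt and 16/2 under drought, Ct noise SD 0.1 — the
  reference study's qualitative outcome encoded as ground truth.

## Problem sizes in the test suite

The suite runs the planted-recovery scan on 200 proteins, NJ recovery on
50 random 5–8 leaf trees, clustering oracles at n ≤ 7, the FPKM design
at 150 genes, and the qPCR null calibration at 1000 gene-tests — sizes
chosen so each check is statistically meaningful while the whole suite
stays interactive (~20 s).

## Known limitations

* The scanner embodies only the ligand-spacing rule; it is not an HMM
  and does not score sequence context, so it cannot reproduce
  SMART/Pfam calls on real proteomes — by design.
* Exact reproduction of the reference survey's tree figures is not
  attempted: the original tool's distance model and gap handling beyond
  "NJ, 1000 bootstraps" are unreported.
* Headline counts of the reference family (145 proteins, 233 domains)
  require the real proteome and are not reproducible from synthetic
  data; the package reproduces the *table arithmetic* exactly and the
  *procedures* on planted truth.
* Degenerate-domain coordinates are reported from one maximal chain
  among equally valid alternatives (see scanning section).
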