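# zfsurvey

A toolkit for genome-wide surveys of zinc-finger gene families, built
around the *Brassica rapa* PHD-finger family (145 proteins carrying 233
PHD domains) as its reference use case. It is aimed at plant comparative
genomicists who need the whole chain of a family survey — domain
inventory, family tables, phylogeny, expression grouping, triplication
retention and stress qPCR — as reproducible, testable code rather than a
one-off mix of web tools and spreadsheets.

## What it computes

**Domain scanning by ligand spacing** (`zfsurvey.zf_scan`). A PHD finger
is a Cys-rich domain of ~50–80 aa whose eight metal ligands follow the
Cys₄-His-Cys₃ order and chelate two Zn²⁺ ions. The scanner enumerates
every chain of eight candidate ligand positions whose inter-ligand gaps
and total span satisfy a class template, and classifies it by the gap
between the 4th and 5th ligands: 4–5 residues → PHD, 2–3 → RING
(C₃HC₄), 2 → LIM. Chains with one or two absent ligands but PHD-like
spacing are reported as SUSPECTED (degenerate) domains. Overlaps are
resolved deterministically (leftmost start, then shortest span, then
class priority; degenerate candidates only fill regions no intact domain
claims). Protein MW and theoretical pI follow the Pepstats conventions
(average masses; EMBOSS pKa set, bisection to |charge| < 10⁻⁴).

**Family tables** (`family_tables`, `published`). Cross-tabulations with
explicit denominators and half-up rounding to one decimal, so recomputed
cells can be compared digit-for-digit with published tables;
`discrepancy_report` flags printed percentages inconsistent with their
own counts.

**Phylogenetics** (`phylo`). p-distances with pairwise gap deletion,
Saitou–Nei neighbor joining (negative branch lengths clamped to zero),
and bootstrap support as the percentage of column-resampled replicates
containing each leaf bipartition. For an additive distance matrix the
tree reproduces the input path lengths exactly.

**Expression** (`expression`). log₂(FPKM+1) transform, average-linkage
clustering on Euclidean distances, a k-cluster cut, and rule-based
assignment of the three classical tissue-panel groups: I constitutive
(≥ 1 FPKM everywhere), II preferential (> 2-fold above the median of the
other tissues), III silent (< 1 FPKM everywhere). Triplicated paralog
sets retained across the LF/MF1/MF2 subgenomes are classified as
balanced, one-dominant, partial-dominant or carrying a degenerated copy.

**Genome context** (`genome_context`). Intron counts from GFF3, per-
chromosome distributions with an unplaced bucket, ortholog-group
retention (3/2/1 subgenome copies kept after the Brassiceae whole-genome
triplication), and tandem/segmental duplicate detection.

**qPCR** (`qpcr`). 2^−ΔΔCt relative expression (Livak convention,
time-matched control calibrator), pooled-variance Student t-tests with
the `*`/`**` star convention, and gene-level up/down tallies over a
stress time course.

**Synthetic data** (`synthetic`). Every input above can be generated
with machine-readable ground truth (planted motifs, expression classes,
retention structure, duplication pairs, qPCR effect sizes), so the whole
pipeline is testable without any downloads.

## Worked example

Simulate a small proteome with planted motifs and scan it:

```
$ survey simulate proteome --seed 7 --n 8 --out sim
$ survey scan --fasta sim/proteome.fasta --out-dir scan
$ head -5 scan/domain_inventory.tsv | cut -f1-8,12-14
protein_id  class  start  end  gap1  gap2  gap3  gap4  span  n_matched  missing_slots
syn0001     PHD    49     100  7     6     6     4     52    8
syn0001     PHD    160    223  18    4     5     4     64    8
syn0001     PHD    277    345  3     6     23    5     69    8
syn0002     RING   50     108  8     2     12    2     59    8
```

`syn0001` carries three PHD fingers: each row lists the eight-ligand
chain's span, the inter-ligand gaps (gap4 ∈ {4,5} is what makes the call
PHD rather than RING/LIM) and that all 8 expected ligands matched. The
per-protein statistics table carries Pepstats-style numbers:

```
$ head -4 scan/protein_stats.tsv
id       length  mw        pi     n_domains
syn0001  391     46409.74  7.72   3
syn0002  144     17481.89  4.66   1
syn0003  36      4303.11   10.44  0
```

Recompute the published family tables and audit the printed cells:

```
$ survey checktables
[compartment] 0 discrepant cells
[phylo_group] 2 discrepant cells
row   col  recomputed  printed  abs_diff
  A 3-PHD        17.6     16.7       0.9
  A 4-PHD        11.8     11.7       0.1
...
[in-text] one_domain_of_family: 92/145 -> 63.4 (printed 65.7)
[in-text] go_disulfide_reductase: 20/138 -> 14.5 (printed 14.4)
```

i.e. all compartment-table percentages reproduce exactly from their
counts, and the handful of internally inconsistent printed values are
flagged rather than propagated.

The full pipeline runs from one YAML config over any mix of inputs
(`survey run --config survey.yaml --out-dir out`), writing per-stage
tables and a checksummed manifest; identical configs and seeds give
identical manifests.

## Layout

- `src/zfsurvey/` — library modules (one per survey stage) and the
  `survey` CLI.
- `tests/` — unit, property and acceptance tests; oracles are
  independent brute-force implementations (exhaustive ligand-subset
  enumeration, step-by-step agglomeration, grid-search pI, least-squares
  topology fits).
- `docs/methods.md` — models, parameter choices, numerical conventions
  and known limitations.
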