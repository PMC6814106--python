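"""Gene structure, chromosomal distribution, subgenome retention and
duplication analyses.

Inputs are GFF3 gene models, a synteny table (gene, chromosome, block,
subgenome in {LF, MF1, MF2, unassigned}, ortholog_group) describing the
whole-genome-triplication ancestry of each family member, and a declared
table of duplicated chromosomal block pairs.  Tandem duplicates are family
members on one chromosome separated by at most ``max_intervening``
annotated genes and ``max_distance`` bp (both configurable: the field has
no single convention); segmental duplicates are family members falling in
the two regions of one declared block pair and sharing an ortholog group.
Coordinates are 1-based inclusive, GFF3's native convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "BlockPair",
    "read_gff3",
    "write_gff3",
    "intron_counts",
    "chromosome_distribution",
    "retention_summary",
    "find_tandem",
    "find_segmental",
]

SUBGENOMES = ("LF", "MF1", "MF2")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: a gene model needs >= 1 exon")
        exons = tuple(sorted(self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e in exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
        object.__setattr__(self, "exons", exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def genomic_span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BlockPair:
    """Two chromosomal regions declared as duplicated segments."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self):
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError("degenerate block region")

    def contains_a(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom_a and self.start_a <= pos <= self.end_a

    def contains_b(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom_b and self.start_b <= pos <= self.end_b


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from GFF3 into gene models.

    Exons are collected per gene through mRNA parents (or directly when
    attached to the gene); when a gene has several mRNAs the union of the
    first mRNA's exons is used.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons: list[tuple[int, int]] = []
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            exons = [(e.start, e.end)
                     for e in db.children(mrnas[0], featuretype="exon",
                                          order_by="start")]
        if not exons:
            exons = [(e.start, e.end)
                     for e in db.children(gene, featuretype="exon",
                                          order_by="start")]
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(GeneModel(gene_id=gene.id, chromosome=gene.seqid,
                                strand=gene.strand or ".",
                                start=gene.start, end=gene.end,
                                exons=tuple(exons)))
    return models


def write_gff3(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{m.chromosome}\tzfsurvey\tgene\t{m.start}\t{m.end}\t."
                     f"\t{m.strand}\t.\tID={m.gene_id}\n")
            mrna = f"{m.gene_id}.1"
            fh.write(f"{m.chromosome}\tzfsurvey\tmRNA\t{m.start}\t{m.end}\t."
                     f"\t{m.strand}\t.\tID={mrna};Parent={m.gene_id}\n")
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{m.chromosome}\tzfsurvey\texon\t{s}\t{e}\t."
                         f"\t{m.strand}\t.\tID={mrna}.exon{k};Parent={mrna}\n")


def intron_counts(models: Iterable[GeneModel]) -> pd.DataFrame:
    rows = [{"gene_id": m.gene_id, "n_introns": m.n_introns,
             "genomic_span": m.genomic_span} for m in models]
    return pd.DataFrame(rows, columns=["gene_id", "n_introns", "genomic_span"])


def chromosome_distribution(genes: pd.DataFrame,
                            unplaced_label: str = "unplaced") -> pd.Series:
    """Gene counts per chromosome plus an 'unplaced' bucket.

    ``genes`` needs columns gene_id and chromosome; missing/empty
    chromosome values (or scaffold names, if flagged upstream as missing)
    count as unplaced.  Bucket counts always sum to the input size.
    """
    if genes.empty:
        return pd.Series(dtype=int)
    chrom = genes["chromosome"].astype(object)
    placed = chrom[chrom.notna() & (chrom != "")]
    counts = placed.value_counts().sort_index()
    n_unplaced = len(genes) - len(placed)
    if n_unplaced:
        counts[unplaced_label] = n_unplaced
    return counts.astype(int)


def retention_summary(synteny: pd.DataFrame,
                      family_genes: Iterable[str] | None = None,
                      ) -> tuple[pd.Series, pd.Series]:
    """Ortholog-group retention classes and per-subgenome totals.

    Returns (groups_by_copies, subgenome_totals): the number of ortholog
    groups retaining 3, 2 and 1 distinct subgenome copies, and the number
    of family genes assigned to each subgenome.  Duplicate subgenomes
    within one group are counted once (distinct-subgenome rule).
    """
    df = synteny.copy()
    if family_genes is not None:
        fam = set(family_genes)
        df = df[df["gene"].isin(fam)]
    assigned = df[df["subgenome"].isin(SUBGENOMES)]
    by_group = assigned.groupby("ortholog_group")["subgenome"].nunique()
    copies = pd.Series({k: int((by_group == k).sum()) for k in (3, 2, 1)},
                       name="n_groups")
    totals = (assigned["subgenome"].value_counts()
              .reindex(SUBGENOMES, fill_value=0).astype(int))
    return copies, totals


def find_tandem(family: pd.DataFrame, all_genes: pd.DataFrame,
                max_intervening: int = 5, max_distance: int = 100_000,
                ) -> set[tuple[str, str]]:
    """Tandem-duplicate pairs among family genes.

    ``family`` and ``all_genes`` need columns gene_id, chromosome, start,
    end.  A pair qualifies when the two genes are consecutive family
    members along one chromosome (chain, not clique: a tandem array of
    three yields two pairs) separated by at most ``max_intervening``
    annotated genes and at most ``max_distance`` bp between their spans.
    Result is symmetric (pairs stored sorted) and independent of input
    order.
    """
    fam_ids = set(family["gene_id"])
    pairs: set[tuple[str, str]] = set()
    for chrom, sub in all_genes.groupby("chromosome"):
        if not isinstance(chrom, str) or not chrom:
            continue
        ordered = sub.sort_values(["start", "gene_id"]).reset_index(drop=True)
        members = [(idx, r) for idx, r in ordered.iterrows()
                   if r.gene_id in fam_ids]
        for (ia, ra), (ib, rb) in zip(members, members[1:]):
            if ib - ia - 1 > max_intervening:
                continue
            gap = max(0, int(rb.start) - int(ra.end))
            if gap <= max_distance:
                pairs.add(tuple(sorted((ra.gene_id, rb.gene_id))))
    return pairs


def find_segmental(family: pd.DataFrame, blocks: Sequence[BlockPair],
                   ) -> set[tuple[str, str]]:
    """Segmental-duplicate pairs: family genes in the two regions of one
    block pair sharing an ortholog group.

    ``family`` needs columns gene_id, chromosome, start, ortholog_group.
    A gene may participate in several pairs; a gene falling in both
    regions of one block pair is skipped as an anomaly (self pairing).
    """
    pairs: set[tuple[str, str]] = set()
    rows = list(family.itertuples())
    for bp in blocks:
        in_a = [r for r in rows
                if isinstance(r.chromosome, str)
                and bp.contains_a(r.chromosome, int(r.start))]
        in_b = [r for r in rows
                if isinstance(r.chromosome, str)
                and bp.contains_b(r.chromosome, int(r.start))]
        for ra in in_a:
            for rb in in_b:
                if ra.gene_id == rb.gene_id:
                    continue
                if (pd.notna(ra.ortholog_group)
                        and ra.ortholog_group == rb.ortholog_group):
                    pairs.add(tuple(sorted((ra.gene_id, rb.gene_id))))
    return pairs
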