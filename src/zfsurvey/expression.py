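"""FPKM matrix transforms, hierarchical clustering and expression grouping.

The workflow mirrors a standard tissue-panel survey: log2(FPKM + 1)
transform, average-linkage (UPGMA-style) agglomeration on Euclidean row
distances, a k-cluster cut, and a rule-based assignment of the three
classical expression classes:

* group I   -- constitutive: expressed (>= ``expressed_threshold`` FPKM)
  in every tissue, no strong single-tissue preference;
* group II  -- preferential: some tissue more than ``fold``-fold above the
  median of the other tissues;
* group III -- silent / very low: below ``low_threshold`` everywhere.

Genes matching none of the three rules are borderline and mapped to the
nearest group by their maximum FPKM.  Triplicated paralog sets retained
across the three subgenomes are compared tissue-by-tissue and classified
as balanced, one-dominant, partial-dominant, or carrying a degenerated
(silent) copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "ExpressionMatrix",
    "Dendrogram",
    "ExpressionGroupLabel",
    "TripletRecord",
    "log_transform",
    "average_linkage",
    "cut_tree",
    "classify_pattern",
    "classify_matrix",
    "triplet_compare",
    "export_clustered_matrix",
]

DEFAULT_TISSUES = ("callus", "root", "stem", "leaf", "flower", "silique")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x tissues FPKM values with an explicit transform state."""

    values: pd.DataFrame
    transform_state: str = "raw"      # 'raw' | 'log2'
    pseudocount: float | None = None  # set once log-transformed

    def __post_init__(self):
        if self.transform_state not in ("raw", "log2"):
            raise ValueError("transform_state must be 'raw' or 'log2'")
        if self.transform_state == "raw" and (self.values.values < 0).any():
            raise ValueError("negative FPKM values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.values.columns)

    def all_zero_genes(self) -> list[str]:
        return list(self.values.index[(self.values == 0).all(axis=1)])

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0,
                  ) -> ExpressionMatrix:
    """log2(FPKM + pseudocount); order preserving, applied at most once."""
    if matrix.transform_state != "raw":
        raise ValueError("matrix is already log2-transformed")
    values = np.log2(matrix.values + pseudocount)
    return ExpressionMatrix(values, "log2", pseudocount)


def inverse_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.transform_state != "log2":
        raise ValueError("matrix is not log2-transformed")
    values = np.exp2(matrix.values) - matrix.pseudocount
    return ExpressionMatrix(values.clip(lower=0.0), "raw")


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge history in scipy linkage form plus leaf order."""

    gene_ids: tuple[str, ...]
    linkage: np.ndarray          # (n-1) x 4 scipy linkage matrix
    leaf_order: tuple[str, ...]

    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.linkage]


def average_linkage(matrix: ExpressionMatrix) -> Dendrogram:
    """UPGMA-style agglomeration on Euclidean distances between log2 rows.

    Merge heights equal the mean pairwise inter-cluster distance; ties are
    broken deterministically by scipy's smallest-index convention.
    """
    if matrix.transform_state != "log2":
        raise ValueError("cluster on the log2-transformed matrix")
    genes = tuple(matrix.gene_ids)
    if len(genes) < 2:
        return Dendrogram(genes, np.empty((0, 4)), genes)
    Z = hierarchy.linkage(matrix.values.values, method="average",
                          metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return Dendrogram(genes, Z, tuple(genes[i] for i in order))


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cluster labels (1..k) at the height giving exactly k clusters."""
    n = len(dendrogram.gene_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    if k == n:
        labels = np.arange(1, n + 1)
    elif k == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(dendrogram.gene_ids), name="cluster")


@dataclass(frozen=True)
class ExpressionGroupLabel:
    gene_id: str
    group: str                        # 'I' | 'II' | 'III'
    basis: str                        # 'rule' | 'clustering'
    preferential_tissues: tuple[str, ...] = ()
    borderline: bool = False

    def __post_init__(self):
        if self.group not in ("I", "II", "III"):
            raise ValueError("group must be I, II or III")
        if (self.basis == "rule" and self.group == "II"
                and not self.preferential_tissues):
            raise ValueError("rule-based group II needs preferential tissues")


def classify_pattern(gene_row: pd.Series, expressed_threshold: float = 1.0,
                     fold: float = 2.0, low_threshold: float = 1.0,
                     baseline: str = "median") -> ExpressionGroupLabel:
    """Rule-based expression class for one raw FPKM row.

    Preference is judged against the median (default) or max of the other
    tissues.  Borderline genes (neither constitutive, preferential nor
    silent) are mapped to group I when their maximum reaches the
    expressed threshold, group III otherwise, and flagged.
    """
    if gene_row.empty:
        raise ValueError("empty expression row")
    values = gene_row.astype(float)
    gene_id = str(gene_row.name)
    if (values < low_threshold).all():
        return ExpressionGroupLabel(gene_id, "III", "rule")
    pref = []
    for t in values.index:
        others = values.drop(t)
        base = others.median() if baseline == "median" else others.max()
        if values[t] >= expressed_threshold and values[t] > fold * base:
            pref.append(t)
    if pref:
        return ExpressionGroupLabel(gene_id, "II", "rule", tuple(pref))
    if (values >= expressed_threshold).all():
        return ExpressionGroupLabel(gene_id, "I", "rule")
    group = "I" if values.max() >= expressed_threshold else "III"
    return ExpressionGroupLabel(gene_id, group, "rule", borderline=True)


def classify_matrix(matrix: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """Rule-based labels for every gene of a raw FPKM matrix."""
    if matrix.transform_state != "raw":
        raise ValueError("rule-based classification uses raw FPKM values")
    labels = [classify_pattern(matrix.values.loc[g], **kwargs)
              for g in matrix.gene_ids]
    return pd.DataFrame({
        "gene": [l.gene_id for l in labels],
        "group": [l.group for l in labels],
        "basis": [l.basis for l in labels],
        "preferential_tissues": [",".join(l.preferential_tissues)
                                 for l in labels],
        "borderline": [l.borderline for l in labels],
    }).set_index("gene")


@dataclass(frozen=True)
class TripletRecord:
    ortholog_group: str
    copies: tuple[tuple[str, str], ...]   # (gene_id, subgenome)
    dominance_class: str
    degenerated: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()

    def __post_init__(self):
        subs = [s for _, s in self.copies]
        if len(set(subs)) != len(subs):
            raise ValueError("duplicate subgenome within a triplet record")


def triplet_compare(matrix: ExpressionMatrix, triplets: pd.DataFrame,
                    fold: float = 2.0, low_threshold: float = 1.0,
                    ) -> list[TripletRecord]:
    """Classify triplicated paralog sets by relative expression.

    ``triplets`` columns: ortholog_group, gene, subgenome.  A copy whose
    row is silent (rule group III) is degenerated; otherwise a copy
    exceeding ``fold`` times every other copy in all tissues is dominant
    (in some but not all tissues: partial-dominant); else balanced.
    Triplets referencing genes absent from the matrix are recorded as
    incomplete, not fatal.
    """
    if matrix.transform_state != "raw":
        raise ValueError("triplet comparison uses raw FPKM values")
    out = []
    for group, sub in triplets.groupby("ortholog_group", sort=True):
        present = [(r.gene, r.subgenome) for r in sub.itertuples()
                   if r.gene in matrix.values.index]
        missing = tuple(r.gene for r in sub.itertuples()
                        if r.gene not in matrix.values.index)
        if len(present) < 2:
            out.append(TripletRecord(str(group), tuple(present),
                                     "incomplete", missing=missing))
            continue
        rows = {g: matrix.values.loc[g].astype(float) for g, _ in present}
        degenerated = tuple(
            g for g, _ in present
            if classify_pattern(rows[g], low_threshold=low_threshold,
                                fold=fold).group == "III")
        if degenerated:
            cls = "with-degenerated-copy"
        else:
            cls = "balanced"
            for g, _ in present:
                others = [rows[o] for o, _ in present if o != g]
                dominant_in = np.ones(len(matrix.tissue_labels), dtype=bool)
                some = np.zeros(len(matrix.tissue_labels), dtype=bool)
                for o in others:
                    cmp = rows[g].values > fold * o.values
                    dominant_in &= cmp
                    some |= cmp
                if dominant_in.all():
                    cls = "one-dominant"
                    break
                if dominant_in.any():
                    cls = "partial-dominant"
        out.append(TripletRecord(str(group), tuple(present), cls,
                                 degenerated=degenerated, missing=missing))
    return out


def export_clustered_matrix(matrix: ExpressionMatrix, dendrogram: Dendrogram,
                            path, labels: pd.Series | None = None) -> None:
    """Write the matrix in dendrogram leaf order as TSV (tissues as header);
    an optional label series adds a trailing 'group' column."""
    if set(dendrogram.gene_ids) != set(matrix.gene_ids):
        raise ValueError("dendrogram and matrix cover different genes")
    ordered = matrix.values.loc[list(dendrogram.leaf_order)].copy()
    if labels is not None:
        ordered["group"] = labels.reindex(ordered.index)
    ordered.to_csv(path, sep="\t", index_label="gene")
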