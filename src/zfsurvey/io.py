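"""File-format boundaries: FASTA (Biopython) and small TSV helpers."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .zf_scan import DomainAnnotation, ProteinRecord

__all__ = [
    "read_protein_fasta",
    "write_fasta",
    "annotations_to_frame",
    "protein_stats_frame",
]


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Multi-record protein FASTA; the id is the description up to the
    first whitespace (Biopython's convention)."""
    return [ProteinRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def annotations_to_frame(annotations: dict[str, list[DomainAnnotation]],
                         ) -> pd.DataFrame:
    """Flat domain-inventory table: one row per detected domain."""
    rows = []
    for pid, anns in annotations.items():
        for a in anns:
            row = {"protein_id": pid, "class": a.domain_class,
                   "start": a.start, "end": a.end}
            for i, g in enumerate(a.chain.gaps, 1):
                row[f"gap{i}"] = g
            row["span"] = a.chain.span
            row["n_matched"] = a.chain.n_matched
            row["missing_slots"] = ",".join(map(str, a.missing_slots))
            rows.append(row)
    cols = (["protein_id", "class", "start", "end"]
            + [f"gap{i}" for i in range(1, 8)]
            + ["span", "n_matched", "missing_slots"])
    return pd.DataFrame(rows, columns=cols)


def protein_stats_frame(records: Iterable[ProteinRecord],
                        annotations: dict[str, list[DomainAnnotation]] | None = None,
                        ) -> pd.DataFrame:
    rows = []
    for rec in records:
        n_domains = len(annotations.get(rec.id, [])) if annotations else None
        rows.append({"id": rec.id, "length": rec.length,
                     "mw": round(rec.mw, 2), "pi": round(rec.pi, 2),
                     "n_domains": n_domains})
    return pd.DataFrame(rows, columns=["id", "length", "mw", "pi", "n_domains"])
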