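"""Orchestration of the full survey from one configuration.

Stages run in dependency order (scan -> tables -> phylo -> expression ->
genome context -> qPCR); a stage whose inputs are absent from the config
is skipped with a logged notice; a stage failure aborts with the stage
named, preserving completed outputs.  A manifest records parameters and
SHA-256 checksums of every output, so identical configs and seeds yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import expression, family_tables, genome_context, io, phylo, qpcr
from . import zf_scan
from .genome_context import BlockPair

log = logging.getLogger(__name__)

__all__ = ["load_config", "run_survey"]

STAGES = ("scan", "tables", "phylo", "expression", "genome", "qpcr")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("survey config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_scan(cfg: dict, outdir: Path) -> list[Path]:
    records = io.read_protein_fasta(cfg["proteins_fasta"])
    config = zf_scan.default_config(
        max_missing=int(cfg.get("allow_missing", 2)))
    annotations = zf_scan.scan_proteome(records, config)
    inventory = io.annotations_to_frame(annotations)
    inventory.to_csv(outdir / "domain_inventory.tsv", sep="\t", index=False)
    zf_scan.summarize_domain_counts(annotations).to_csv(
        outdir / "domain_counts.tsv", sep="\t", index=False)
    io.write_fasta(zf_scan.extract_domain_sequences(records, annotations),
                   outdir / "domains.fasta")
    io.protein_stats_frame(records, annotations).to_csv(
        outdir / "protein_stats.tsv", sep="\t", index=False)
    return [outdir / "domain_inventory.tsv", outdir / "domain_counts.tsv",
            outdir / "domains.fasta", outdir / "protein_stats.tsv"]


def _stage_tables(cfg: dict, outdir: Path) -> list[Path]:
    ann = pd.read_csv(cfg["annotations_tsv"], sep="\t")
    out = []
    specs = {
        "compartment": ("domain_count_class", "compartment", "row"),
        "phylo_group": ("phylo_group", "domain_count_class", "row"),
        "expression_group": ("expression_group", "phylo_group", "col"),
    }
    for name, (row_col, col_col, denom) in specs.items():
        if row_col not in ann.columns or col_col not in ann.columns:
            continue
        sub = ann[[row_col, col_col]].dropna()
        table = family_tables.crosstab(
            list(sub.itertuples(index=False, name=None)), denominator=denom)
        path = outdir / f"table_{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# denominator: {denom}\n")
            table.formatted().to_csv(fh, sep="\t")
        table.to_long().to_csv(outdir / f"table_{name}_long.tsv", sep="\t",
                               index=False)
        out += [path, outdir / f"table_{name}_long.tsv"]
    return out


def _stage_phylo(cfg: dict, outdir: Path) -> list[Path]:
    fmt = cfg.get("msa_format", "fasta")
    aln = phylo.Alignment.read(cfg["msa"], fmt)
    tree = phylo.bootstrap_support(aln, int(cfg.get("bootstrap", 1000)),
                                   seed=int(cfg.get("phylo_seed", 42)))
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    supports = tree.supports()
    pd.DataFrame(
        [{"bipartition": "|".join(side), "support": s}
         for side, s in sorted(supports.items())]
    ).to_csv(outdir / "supports.tsv", sep="\t", index=False)
    return [outdir / "tree.nwk", outdir / "supports.tsv"]


def _stage_expression(cfg: dict, outdir: Path) -> list[Path]:
    matrix = expression.ExpressionMatrix.read_tsv(cfg["fpkm"])
    labels = expression.classify_matrix(
        matrix,
        expressed_threshold=float(cfg.get("expressed_threshold", 1.0)),
        fold=float(cfg.get("fold", 2.0)),
        low_threshold=float(cfg.get("low_threshold", 1.0)))
    labels.to_csv(outdir / "expression_labels.tsv", sep="\t")
    logm = expression.log_transform(matrix,
                                    float(cfg.get("pseudocount", 1.0)))
    dend = expression.average_linkage(logm)
    clusters = expression.cut_tree(dend, int(cfg.get("k", 3)))
    clusters.to_csv(outdir / "clusters.tsv", sep="\t")
    expression.export_clustered_matrix(logm, dend,
                                       outdir / "clustered_matrix.tsv")
    (outdir / "dendrogram.json").write_text(
        json.dumps({"leaf_order": list(dend.leaf_order),
                    "merges": dend.merges()}))
    out = [outdir / "expression_labels.tsv", outdir / "clusters.tsv",
           outdir / "clustered_matrix.tsv", outdir / "dendrogram.json"]
    if "triplets" in cfg:
        triplets = pd.read_csv(cfg["triplets"], sep="\t")
        recs = expression.triplet_compare(matrix, triplets)
        pd.DataFrame([{
            "ortholog_group": r.ortholog_group,
            "genes": ",".join(g for g, _ in r.copies),
            "dominance_class": r.dominance_class,
            "degenerated": ",".join(r.degenerated),
        } for r in recs]).to_csv(outdir / "triplets.tsv", sep="\t",
                                 index=False)
        out.append(outdir / "triplets.tsv")
    return out


def _stage_genome(cfg: dict, outdir: Path) -> list[Path]:
    out = []
    if "gff" in cfg:
        models = genome_context.read_gff3(cfg["gff"])
        genome_context.intron_counts(models).to_csv(
            outdir / "intron_counts.tsv", sep="\t", index=False)
        out.append(outdir / "intron_counts.tsv")
    synteny = pd.read_csv(cfg["synteny"], sep="\t")
    dist = genome_context.chromosome_distribution(
        synteny.rename(columns={"gene": "gene_id"}))
    dist.rename("n_genes").to_csv(outdir / "chromosome_distribution.tsv",
                                  sep="\t", index_label="chromosome")
    copies, totals = genome_context.retention_summary(synteny)
    copies.rename("n_groups").to_csv(outdir / "retention.tsv", sep="\t",
                                     index_label="copies_retained")
    totals.rename("n_genes").to_csv(outdir / "subgenome_totals.tsv",
                                    sep="\t", index_label="subgenome")
    out += [outdir / "chromosome_distribution.tsv", outdir / "retention.tsv",
            outdir / "subgenome_totals.tsv"]
    if "family_coords" in cfg and "all_genes" in cfg:
        family = pd.read_csv(cfg["family_coords"], sep="\t")
        all_genes = pd.read_csv(cfg["all_genes"], sep="\t")
        tandem = genome_context.find_tandem(
            family, all_genes,
            max_intervening=int(cfg.get("max_intervening", 5)),
            max_distance=int(cfg.get("max_distance", 100_000)))
        pd.DataFrame(sorted(tandem), columns=["gene_a", "gene_b"]).to_csv(
            outdir / "tandem_pairs.tsv", sep="\t", index=False)
        out.append(outdir / "tandem_pairs.tsv")
        if "blocks" in cfg:
            bl = pd.read_csv(cfg["blocks"], sep="\t")
            blocks = [BlockPair(r.chrom_a, r.start_a, r.end_a,
                                r.chrom_b, r.start_b, r.end_b)
                      for r in bl.itertuples()]
            seg = genome_context.find_segmental(family, blocks)
            pd.DataFrame(sorted(seg), columns=["gene_a", "gene_b"]).to_csv(
                outdir / "segmental_pairs.tsv", sep="\t", index=False)
            out.append(outdir / "segmental_pairs.tsv")
    return out


def _stage_qpcr(cfg: dict, outdir: Path) -> list[Path]:
    ct = pd.read_csv(cfg["ct"], sep="\t")
    summary = qpcr.timecourse_summary(
        ct, calibrator_condition=cfg.get("calibrator", "control"),
        test_on=cfg.get("test_on", "fold"))
    summary.to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False)
    return [outdir / "qpcr_summary.tsv"]


_STAGE_FUNCS = {
    "scan": (_stage_scan, ("proteins_fasta",)),
    "tables": (_stage_tables, ("annotations_tsv",)),
    "phylo": (_stage_phylo, ("msa",)),
    "expression": (_stage_expression, ("fpkm",)),
    "genome": (_stage_genome, ("synteny",)),
    "qpcr": (_stage_qpcr, ("ct",)),
}


def run_survey(cfg: dict, outdir) -> dict:
    """Run all configured stages; returns and writes the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": cfg}
    for stage in STAGES:
        func, required = _STAGE_FUNCS[stage]
        missing = [k for k in required if k not in cfg]
        if missing:
            log.info("stage %s skipped (missing inputs: %s)", stage, missing)
            manifest["stages"][stage] = {"status": "skipped",
                                         "missing": missing}
            continue
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            outputs = func(cfg, stage_dir)
        except Exception as exc:   # noqa: BLE001 - named-stage abort contract
            manifest["stages"][stage] = {"status": "failed",
                                         "error": str(exc)}
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True, default=str))
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {str(p.relative_to(outdir)): _sha256(p)
                        for p in outputs},
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
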