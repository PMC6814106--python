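"""Synthetic inputs with machine-readable ground truth for every stage.

Each generator emulates one class of input the survey pipeline consumes --
a proteome with planted zinc-finger motifs, a tissue-panel FPKM matrix
with planted expression classes, a triplication synteny table with planted
retention/duplication structure, an alignment evolved on a known tree, and
a qPCR Ct table with planted log2 fold changes -- and returns the data
together with the planted truth, so detection, classification and
quantification can be audited exactly.  All generators are deterministic
given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
import io as _io

from .expression import DEFAULT_TISSUES, ExpressionMatrix
from .genome_context import BlockPair, GeneModel
from .phylo import Alignment
from .zf_scan import (LIM_TEMPLATE, PHD_TEMPLATE, RING_TEMPLATE,
                      DomainTemplate, ProteinRecord)

__all__ = [
    "TruthBundle",
    "sim_proteome",
    "sim_fpkm",
    "sim_synteny",
    "sim_msa",
    "sim_ct",
    "sim_gene_models",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BACKGROUND_NO_LIGAND = "ADEFGIKLMNPQRSTVWY"   # C/H excluded
# Rough natural amino-acid frequencies (for the stress policy).
_NATURAL_FREQ = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.014,
    "E": 0.062, "Q": 0.039, "G": 0.072, "H": 0.023, "I": 0.053,
    "L": 0.091, "K": 0.058, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.068, "T": 0.059, "W": 0.013, "Y": 0.032, "V": 0.066,
}

_TEMPLATES = {"PHD": PHD_TEMPLATE, "RING": RING_TEMPLATE, "LIM": LIM_TEMPLATE}

# Study-like default class mix: mostly 1-4 PHD-domain proteins, some RING
# and LIM for spacing discrimination, some motif-free background proteins.
DEFAULT_CLASS_MIX = {
    "PHD1": 0.40, "PHD2": 0.12, "PHD3": 0.07, "PHD4": 0.04,
    "RING": 0.12, "LIM": 0.10, "none": 0.15,
}


@dataclass
class TruthBundle:
    """Planted ground truth for one generated dataset."""

    seed: int
    kind: str
    entries: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "kind": self.kind,
                       "entries": self.entries}, fh, indent=1, sort_keys=True,
                      default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], kind=d["kind"], entries=d["entries"])


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set, frozenset)):
        return list(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------- proteome

def _sample_motif(template: DomainTemplate, rng: np.random.Generator,
                  max_tries: int = 10_000) -> tuple[str, list[int]]:
    """Motif sequence and 0-based ligand offsets with template-legal gaps.

    gap45 is drawn from the class range, the six other gaps uniformly from
    the default range; the total span is forced into span_range by
    rejection.
    """
    glo, ghi = template.gap_range_default
    for _ in range(max_tries):
        gaps = [int(rng.integers(glo, ghi + 1)) for _ in range(7)]
        gaps[3] = int(rng.integers(template.gap45_range[0],
                                   template.gap45_range[1] + 1))
        span = 8 + sum(gaps)
        if template.span_range[0] <= span <= template.span_range[1]:
            break
    else:
        raise RuntimeError("infeasible gap/span combination for "
                           f"{template.name}")
    offsets = [0]
    for g in gaps:
        offsets.append(offsets[-1] + g + 1)
    seq = ["_"] * span
    filler = [BACKGROUND_NO_LIGAND[i]
              for i in rng.integers(0, len(BACKGROUND_NO_LIGAND), size=span)]
    for i in range(span):
        seq[i] = filler[i]
    for off, residue in zip(offsets, template.ligand_pattern):
        seq[off] = residue
    return "".join(seq), offsets


def _background(n: int, rng: np.random.Generator, policy: str) -> str:
    if n <= 0:
        return ""
    if policy == "exclude":
        alphabet = BACKGROUND_NO_LIGAND
        idx = rng.integers(0, len(alphabet), size=n)
        return "".join(alphabet[i] for i in idx)
    if policy == "natural":
        letters = list(_NATURAL_FREQ)
        probs = np.array(list(_NATURAL_FREQ.values()))
        probs = probs / probs.sum()
        return "".join(rng.choice(letters, size=n, p=probs))
    raise ValueError(f"unknown background policy {policy!r}")


def sim_proteome(n: int = 200, class_mix: dict[str, float] | None = None,
                 background_ligand_policy: str = "exclude",
                 seed: int = 0, spacer_range: tuple[int, int] = (25, 60),
                 ) -> tuple[list[ProteinRecord], TruthBundle]:
    """Proteome with planted zinc-finger motifs at known coordinates.

    ``class_mix`` weights protein archetypes: 'PHD1'..'PHD4' (that many
    PHD motifs), 'RING', 'LIM', 'SUSPECTED' (a PHD motif with 1-2 interior
    ligand slots mutated to alanine) and 'none'.  Motifs are separated by
    at least 25 background residues; under the default policy the
    background contains no C or H, so the planted truth is exact.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    labels = sorted(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("class_mix weights must be positive")
    probs = probs / probs.sum()
    if spacer_range[0] < 25:
        raise ValueError("motif spacer must be >= 25 residues")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth = TruthBundle(seed=seed, kind="proteome")
    for i in range(n):
        pid = f"syn{i + 1:04d}"
        archetype = labels[int(rng.choice(len(labels), p=probs))]
        if archetype == "none":
            plan: list[str] = []
        elif archetype.startswith("PHD"):
            plan = ["PHD"] * int(archetype[3])
        else:
            plan = [archetype]
        parts = [_background(int(rng.integers(*spacer_range)), rng,
                             background_ligand_policy)]
        planted = []
        for cls in plan:
            template = _TEMPLATES["PHD" if cls == "SUSPECTED" else cls]
            motif, offsets = _sample_motif(template, rng)
            missing_slots: list[int] = []
            if cls == "SUSPECTED":
                k = int(rng.integers(1, 3))
                slots = sorted(rng.choice(np.arange(2, 8), size=k,
                                          replace=False).tolist())
                motif_l = list(motif)
                for s in slots:
                    motif_l[offsets[s - 1]] = "A"
                motif = "".join(motif_l)
                missing_slots = [int(s) for s in slots]
            start = sum(len(p) for p in parts) + 1
            parts.append(motif)
            planted.append({
                "class": cls, "start": start, "end": start + len(motif) - 1,
                "positions": [start + o for o in offsets],
                "missing_slots": missing_slots,
            })
            parts.append(_background(int(rng.integers(*spacer_range)), rng,
                                     background_ligand_policy))
        records.append(ProteinRecord(id=pid, sequence="".join(parts)))
        truth.entries[pid] = planted
    return records, truth


# -------------------------------------------------------------------- fpkm

def sim_fpkm(n_per_group: tuple[int, int, int] = (50, 50, 50),
             tissues: Sequence[str] = DEFAULT_TISSUES, seed: int = 0,
             constitutive_mu: float = 4.0, constitutive_sigma: float = 0.5,
             preferential_mu: float = 5.0, off_mu: float = 0.0,
             off_sigma: float = 0.5, silent_max: float = 0.3,
             ) -> tuple[ExpressionMatrix, TruthBundle]:
    """Tissue-panel FPKM matrix with planted expression classes.

    Constitutive genes draw log-normal(mu=4, sigma=0.5) in every tissue;
    preferential genes log-normal(mu=5) in one random tissue and
    log-normal(mu=0, sigma=0.5) elsewhere; silent genes uniform[0, 0.3].
    """
    rng = np.random.default_rng(seed)
    n_con, n_pref, n_sil = n_per_group
    tissues = list(tissues)
    rows, gene_ids = [], []
    truth = TruthBundle(seed=seed, kind="fpkm")
    counter = 0
    for _ in range(n_con):
        counter += 1
        gid = f"gene{counter:04d}"
        rows.append(rng.lognormal(constitutive_mu, constitutive_sigma,
                                  size=len(tissues)))
        gene_ids.append(gid)
        truth.entries[gid] = {"group": "constitutive", "tissue": None}
    for _ in range(n_pref):
        counter += 1
        gid = f"gene{counter:04d}"
        t = int(rng.integers(0, len(tissues)))
        row = rng.lognormal(off_mu, off_sigma, size=len(tissues))
        row[t] = rng.lognormal(preferential_mu, off_sigma)
        rows.append(row)
        gene_ids.append(gid)
        truth.entries[gid] = {"group": "preferential", "tissue": tissues[t]}
    for _ in range(n_sil):
        counter += 1
        gid = f"gene{counter:04d}"
        rows.append(rng.uniform(0.0, silent_max, size=len(tissues)))
        gene_ids.append(gid)
        truth.entries[gid] = {"group": "silent", "tissue": None}
    values = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=tissues)
    return ExpressionMatrix(values.round(4)), truth


# ----------------------------------------------------------------- synteny

_CHROMS = tuple(f"A{i:02d}" for i in range(1, 11))
_SLOT_BP = 5_000
_GENE_LEN = 2_000
_N_SLOTS = 600
_FAMILY_SEP_SLOTS = 30     # > 5 intervening genes and > 100 kb apart


@dataclass
class SimSynteny:
    """Generated triplication context: tables, blocks and planted truth."""

    synteny: pd.DataFrame       # gene, chromosome, block, subgenome, ortholog_group
    family: pd.DataFrame        # gene_id, chromosome, start, end, subgenome, ortholog_group
    all_genes: pd.DataFrame     # gene_id, chromosome, start, end
    blocks: list[BlockPair]
    truth: TruthBundle


def _slot_coords(slot: int) -> tuple[int, int]:
    start = slot * _SLOT_BP + 1
    return start, start + _GENE_LEN - 1


def sim_synteny(retention_counts: tuple[int, int, int] = (7, 21, 68),
                n_unassigned: int = 14, n_scaffold: int = 5,
                tandem_cluster_sizes: tuple[int, ...] = (2,),
                n_segmental_pairs: int = 29, seed: int = 0) -> SimSynteny:
    """Triplication synteny tables with planted retention and duplications.

    ``retention_counts`` = ortholog groups retaining (3, 2, 1) subgenome
    copies -- the default plants the study-scale (7, 21, 68).  Family
    genes are placed on 10 chromosomes far enough apart that only the
    planted tandem clusters qualify as tandem; ``n_segmental_pairs``
    block pairs are declared around same-group gene pairs.  Unassigned
    genes carry no subgenome/group; ``n_scaffold`` of them sit on
    scaffolds (unplaced).
    """
    rng = np.random.default_rng(seed)
    n3, n2, n1 = retention_counts
    one_copy_weights = np.array([0.45, 0.32, 0.23])  # mild LF bias

    groups: list[dict] = []
    gid = 0
    for _ in range(n3):
        gid += 1
        groups.append({"id": f"og{gid:03d}", "subgenomes": ["LF", "MF1", "MF2"]})
    for _ in range(n2):
        gid += 1
        pair = sorted(rng.choice(["LF", "MF1", "MF2"], size=2, replace=False))
        groups.append({"id": f"og{gid:03d}", "subgenomes": list(pair)})
    for _ in range(n1):
        gid += 1
        sub = str(rng.choice(["LF", "MF1", "MF2"], p=one_copy_weights))
        groups.append({"id": f"og{gid:03d}", "subgenomes": [sub]})

    fam_rows = []
    k = 0
    for g in groups:
        for sub in g["subgenomes"]:
            k += 1
            fam_rows.append({"gene_id": f"fam{k:04d}", "subgenome": sub,
                             "ortholog_group": g["id"]})
    for _ in range(n_unassigned):
        k += 1
        fam_rows.append({"gene_id": f"fam{k:04d}", "subgenome": "unassigned",
                         "ortholog_group": None})

    n_family = len(fam_rows)
    n_extra_tandem = sum(s - 1 for s in tandem_cluster_sizes)
    if n_scaffold + n_extra_tandem > n_unassigned:
        raise ValueError("not enough unassigned genes for scaffolds + tandem")

    # Placement grid: widely separated slots so random placement cannot
    # create accidental tandem pairs.
    grid = [(c, s) for c in _CHROMS
            for s in range(0, _N_SLOTS - 5, _FAMILY_SEP_SLOTS)]
    n_placed = n_family - n_scaffold
    if n_placed > len(grid):
        raise ValueError("family too large for the placement grid")
    order = rng.permutation(len(grid))[:n_placed]
    placements = [grid[i] for i in order]

    unassigned_ids = [r["gene_id"] for r in fam_rows
                      if r["subgenome"] == "unassigned"]
    scaffold_ids = set(unassigned_ids[:n_scaffold])
    tandem_partner_ids = unassigned_ids[n_scaffold:n_scaffold + n_extra_tandem]

    placed_iter = iter(placements)
    for r in fam_rows:
        if r["gene_id"] in scaffold_ids:
            idx = unassigned_ids.index(r["gene_id"]) + 1
            r["chromosome"] = None
            r["scaffold"] = f"Scaffold{idx:04d}"
            r["start"], r["end"] = 1, _GENE_LEN
        elif r["gene_id"] in tandem_partner_ids:
            r["chromosome"] = "pending"   # placed next to a host below
        else:
            chrom, slot = next(placed_iter)
            r["chromosome"] = chrom
            r["start"], r["end"] = _slot_coords(slot)
            r["slot"] = slot

    # Tandem clusters: adjacent slots next to randomly chosen hosts.
    hosts = [r for r in fam_rows if r.get("slot") is not None
             and r["subgenome"] != "unassigned"]
    truth_tandem: list[list[str]] = []
    partner_iter = iter(tandem_partner_ids)
    host_idx = rng.choice(len(hosts), size=len(tandem_cluster_sizes),
                          replace=False)
    for size, hi in zip(tandem_cluster_sizes, host_idx):
        host = hosts[int(hi)]
        cluster = [host["gene_id"]]
        for j in range(1, size):
            pid = next(partner_iter)
            r = next(x for x in fam_rows if x["gene_id"] == pid)
            r["chromosome"] = host["chromosome"]
            slot = host["slot"] + j
            r["start"], r["end"] = _slot_coords(slot)
            r["slot"] = slot
            cluster.append(pid)
        truth_tandem.append(cluster)
    tandem_pairs = sorted(
        tuple(sorted(p)) for cluster in truth_tandem
        for p in zip(cluster, cluster[1:]))

    # Segmental block pairs around same-group gene pairs.
    by_group: dict[str, list[dict]] = {}
    for r in fam_rows:
        if r["ortholog_group"] and r.get("chromosome") not in (None, "pending"):
            by_group.setdefault(r["ortholog_group"], []).append(r)
    candidate_pairs = []
    for og in sorted(by_group):
        members = sorted(by_group[og], key=lambda r: r["gene_id"])
        if len(members) == 2:
            candidate_pairs.append((members[0], members[1]))
    for og in sorted(by_group):
        members = sorted(by_group[og], key=lambda r: r["gene_id"])
        if len(members) == 3:
            candidate_pairs.append((members[0], members[1]))
            candidate_pairs.append((members[1], members[2]))
    if n_segmental_pairs > len(candidate_pairs):
        raise ValueError("not enough multi-copy groups for the requested "
                         "segmental pairs")
    blocks: list[BlockPair] = []
    truth_segmental = []
    for ra, rb in candidate_pairs[:n_segmental_pairs]:
        blocks.append(BlockPair(
            chrom_a=ra["chromosome"],
            start_a=max(1, ra["start"] - 10_000), end_a=ra["end"] + 10_000,
            chrom_b=rb["chromosome"],
            start_b=max(1, rb["start"] - 10_000), end_b=rb["end"] + 10_000))
        truth_segmental.append(tuple(sorted((ra["gene_id"], rb["gene_id"]))))
    truth_segmental.sort()

    family = pd.DataFrame([{
        "gene_id": r["gene_id"],
        "chromosome": r["chromosome"] if r["chromosome"] not in (None,) else None,
        "start": r.get("start"), "end": r.get("end"),
        "subgenome": r["subgenome"], "ortholog_group": r["ortholog_group"],
    } for r in fam_rows])

    # Background annotated genes filling every chromosome.
    bg_rows = []
    occupied = {(r["chromosome"], r.get("slot")) for r in fam_rows
                if r.get("slot") is not None}
    for chrom in _CHROMS:
        for slot in range(_N_SLOTS):
            if (chrom, slot) in occupied:
                continue
            s, e = _slot_coords(slot)
            bg_rows.append({"gene_id": f"bg_{chrom}_{slot:04d}",
                            "chromosome": chrom, "start": s, "end": e})
    all_genes = pd.concat(
        [family[family["chromosome"].notna()][
            ["gene_id", "chromosome", "start", "end"]],
         pd.DataFrame(bg_rows)], ignore_index=True)

    synteny = family.rename(columns={"gene_id": "gene"})[
        ["gene", "chromosome", "subgenome", "ortholog_group"]].copy()
    synteny.insert(2, "block", [
        f"blk{(int(og[2:]) % 23) + 1:02d}" if og else ""
        for og in synteny["ortholog_group"].fillna("")])

    truth = TruthBundle(seed=seed, kind="synteny", entries={
        "retention_counts": {"3": n3, "2": n2, "1": n1},
        "tandem_pairs": [list(p) for p in tandem_pairs],
        "segmental_pairs": [list(p) for p in truth_segmental],
        "n_family": n_family,
        "n_unplaced": n_scaffold,
        "subgenome_totals": family["subgenome"].value_counts().to_dict(),
    })
    return SimSynteny(synteny=synteny, family=family, all_genes=all_genes,
                      blocks=blocks, truth=truth)


# --------------------------------------------------------------------- msa

def sim_msa(tree_spec: str, n_columns: int,
            per_branch_sub_prob: float | None = None, seed: int = 0,
            ) -> tuple[Alignment, str]:
    """Ungapped alignment evolved on a known tree.

    A root sequence is drawn uniformly over the 20 residues; along each
    branch every site is replaced, with probability ``per_branch_sub_prob``
    (default: the branch length), by a uniformly random different residue.
    Returns the alignment of the leaves and the generating Newick string.
    """
    tree = TreeNode.read(_io.StringIO(tree_spec))
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, len(aa), size=n_columns)

    ids, rows = [], []

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p = per_branch_sub_prob if per_branch_sub_prob is not None \
                else float(child.length or 0.0)
            child_seq = seq.copy()
            hits = rng.random(n_columns) < p
            for j in np.nonzero(hits)[0]:
                shift = int(rng.integers(1, len(aa)))
                child_seq[j] = (child_seq[j] + shift) % len(aa)
            if child.is_tip():
                ids.append(child.name)
                rows.append("".join(aa[child_seq]))
            else:
                evolve(child, child_seq)

    evolve(tree, root_seq)
    return Alignment(tuple(ids), tuple(rows)), tree_spec


# ---------------------------------------------------------------------- ct

def default_stress_effects(genes: Sequence[str],
                           n_up: dict[str, int] | None = None,
                           magnitude: float = 2.5,
                           times: tuple[float, ...] = (1.0, 3.0, 24.0),
                           ) -> dict[tuple[str, str, float], float]:
    """Study-like planted effects: per condition, the first ``n_up`` genes
    are up-regulated and the rest down-regulated by ``magnitude`` log2
    units at every post-treatment time point."""
    n_up = n_up or {"salt": 11, "drought": 16}
    effects = {}
    for cond, k in n_up.items():
        for i, g in enumerate(genes):
            fc = magnitude if i < k else -magnitude
            for t in times:
                effects[(g, cond, t)] = fc
    return effects


def sim_ct(genes: Sequence[str] | None = None,
           conditions: Sequence[str] = ("salt", "drought"),
           times: Sequence[float] = (0.0, 1.0, 3.0, 24.0),
           n_replicates: int = 3,
           effects: dict[tuple[str, str, float], float] | None = None,
           noise_sd: float = 0.1, baseline_ct: float = 24.0,
           reference_ct: float = 18.0, seed: int = 0,
           ) -> tuple[pd.DataFrame, TruthBundle]:
    """qPCR Ct table for a stress time course with planted log2 effects.

    Ct_target = baseline - effect + N(0, noise_sd); Ct_reference =
    constant + N(0, noise_sd).  The default design is 18 genes x
    {control, salt, drought} x {0, 1, 3, 24} h x 3 replicates with 11/7
    genes up/down under salt and 16/2 under drought.
    """
    if genes is None:
        genes = [f"g{i:02d}" for i in range(1, 19)]
    genes = list(genes)
    if effects is None:
        effects = default_stress_effects(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        for cond in ["control", *conditions]:
            for t in times:
                eff = 0.0 if cond == "control" else \
                    effects.get((g, cond, float(t)), 0.0)
                for rep in range(1, n_replicates + 1):
                    rows.append({
                        "gene": g, "condition": cond, "time_h": float(t),
                        "replicate": rep,
                        "ct_target": round(baseline_ct - eff
                                           + rng.normal(0, noise_sd), 4),
                        "ct_reference": round(reference_ct
                                              + rng.normal(0, noise_sd), 4),
                    })
    truth = TruthBundle(seed=seed, kind="ct", entries={
        "effects": {f"{g}|{c}|{t}": fc for (g, c, t), fc in effects.items()},
        "noise_sd": noise_sd,
    })
    return pd.DataFrame(rows), truth


# -------------------------------------------------------------- gene models

def sim_gene_models(n: int = 30, seed: int = 0,
                    max_introns: int = 30) -> tuple[list[GeneModel], TruthBundle]:
    """Random gene models with known intron counts, for GFF3 round trips."""
    rng = np.random.default_rng(seed)
    models, truth = [], TruthBundle(seed=seed, kind="gene_models")
    for i in range(n):
        gid = f"mod{i + 1:04d}"
        chrom = f"A{int(rng.integers(1, 11)):02d}"
        n_exons = int(rng.integers(1, max_introns + 2))
        start = int(rng.integers(1, 1_000_000))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 400))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(60, 500))
        end = exons[-1][1]
        models.append(GeneModel(gene_id=gid, chromosome=chrom,
                                strand="+" if rng.random() < 0.5 else "-",
                                start=start, end=end, exons=tuple(exons)))
        truth.entries[gid] = {"n_introns": n_exons - 1,
                              "genomic_span": end - start + 1}
    return models, truth
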