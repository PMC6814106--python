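"""Reported counts from the Brassica rapa PHD-finger gene-family survey.

The survey identified 145 PHD-finger proteins carrying 233 PHD domains.
The count tables below (domain-number x subcellular compartment,
domain-number x phylogenetic group, expression group x phylogenetic group)
and the in-text fractions are inputs to the table-recomputation machinery:
percentages are always recomputed from these integer counts, never copied.
``printed`` frames carry the percentage values as originally printed so
that ``family_tables.discrepancy_report`` can flag the handful of cells
whose printed value does not match its own counts.
"""

from __future__ import annotations

import pandas as pd

from .family_tables import ContingencyTable

__all__ = [
    "compartment_table",
    "compartment_printed",
    "phylo_group_table",
    "phylo_group_printed",
    "expression_group_table",
    "expression_group_printed",
    "IN_TEXT_FRACTIONS",
]

_COMPARTMENTS = ["nuclear", "cytoplasm", "extracellular",
                 "plasma membrane", "chloroplast"]
_DOMAIN_ROWS = ["1-PHD", "2-PHD", "3-PHD", "4-PHD"]
_PHYLO_GROUPS = ["A", "B", "C", "D", "E", "F"]
_EXPR_GROUPS = ["I", "II", "III"]


def compartment_table() -> ContingencyTable:
    """Proteins with 1..4 PHD domains by predicted compartment (row %)."""
    counts = pd.DataFrame(
        [[72, 7, 11, 0, 2],
         [14, 0, 5, 5, 3],
         [9, 0, 5, 3, 0],
         [3, 0, 4, 2, 0]],
        index=_DOMAIN_ROWS, columns=_COMPARTMENTS)
    return ContingencyTable(counts, denominator="row")


def compartment_printed() -> pd.DataFrame:
    return pd.DataFrame(
        [[78.3, 7.6, 12.0, 0.0, 2.2],
         [51.9, 0.0, 18.5, 18.5, 11.1],
         [52.9, 0.0, 29.4, 17.6, 0.0],
         [33.3, 0.0, 44.4, 22.2, 0.0]],
        index=_DOMAIN_ROWS, columns=_COMPARTMENTS)


def phylo_group_table() -> ContingencyTable:
    """Proteins with 1..4 PHD domains by phylogenetic group (group-total %).

    Rows are groups A-F so the declared denominator is the row total
    (each group's gene count), matching the printed convention.
    """
    counts = pd.DataFrame(
        [[28, 8, 9, 6],
         [3, 4, 0, 2],
         [23, 4, 0, 0],
         [8, 0, 1, 0],
         [18, 4, 7, 1],
         [12, 7, 0, 0]],
        index=_PHYLO_GROUPS, columns=_DOMAIN_ROWS)
    return ContingencyTable(counts, denominator="row")


def phylo_group_printed() -> pd.DataFrame:
    return pd.DataFrame(
        [[54.9, 15.7, 16.7, 11.7],
         [33.3, 44.4, 0.0, 22.2],
         [85.2, 14.8, 0.0, 0.0],
         [88.9, 0.0, 11.1, 0.0],
         [60.0, 13.3, 23.3, 3.3],
         [63.2, 36.8, 0.0, 0.0]],
        index=_PHYLO_GROUPS, columns=_DOMAIN_ROWS)


def expression_group_table() -> ContingencyTable:
    """Expression groups I-III by phylogenetic group for the 140 genes with
    RNA-Seq data (percent per phylogenetic-group column total)."""
    counts = pd.DataFrame(
        [[21, 8, 19, 5, 17, 8],
         [9, 1, 8, 3, 10, 5],
         [19, 0, 0, 1, 3, 3]],
        index=_EXPR_GROUPS, columns=_PHYLO_GROUPS)
    return ContingencyTable(counts, denominator="col")


def expression_group_printed() -> pd.DataFrame:
    return pd.DataFrame(
        [[42.9, 88.9, 70.4, 55.6, 56.7, 50.0],
         [18.4, 11.1, 29.6, 33.3, 33.3, 31.3],
         [38.7, 0.0, 0.0, 11.1, 10.0, 18.7]],
        index=_EXPR_GROUPS, columns=_PHYLO_GROUPS)


# In-text fractions: name -> (numerator, denominator, printed percent).
# Names describe the quantity; printed values that are inconsistent with
# their own counts are retained verbatim (the recomputation flags them).
IN_TEXT_FRACTIONS: dict[str, tuple[int, int, float]] = {
    "one_domain_of_family": (92, 145, 65.7),        # inconsistent: 63.4
    "two_domains_of_family": (27, 145, 18.6),
    "three_domains_of_family": (17, 145, 11.7),
    "four_domains_of_family": (9, 145, 6.2),
    "go_protein_binding": (126, 138, 91.3),
    "go_disulfide_reductase": (20, 138, 14.4),      # inconsistent: 14.5
    "go_transcription_cofactor": (10, 138, 7.2),
    "nuclear_localized": (98, 145, 67.6),
    "extracellular_localized": (25, 145, 17.2),
    "one_domain_nuclear": (72, 92, 78.3),
    "chromosome_mapped": (140, 145, 96.6),
    "segmental_duplication": (58, 140, 41.4),
    "tandem_duplication": (2, 140, 1.4),
    "subgenome_lf": (59, 145, 40.7),
    "subgenome_mf1": (46, 145, 31.7),
    "subgenome_mf2": (40, 145, 27.6),
    "syntenic_ortholog_present": (118, 145, 81.4),
    "intronless_genes": (26, 145, 17.9),
    "single_intron_genes": (15, 145, 10.3),
    "constitutive_expression": (78, 140, 55.7),
    "preferential_expression": (36, 140, 25.7),
    "silent_expression": (26, 140, 18.6),
    "group_specific_extra_domains": (46, 56, 82.1),
    "expression_I_in_group_C": (19, 27, 70.4),
}

# Subgenome retention of ortholog groups: copies retained -> group count.
RETENTION_GROUP_COUNTS: dict[int, int] = {3: 7, 2: 21, 1: 68}
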