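"""Domain detection/classification against brute-force enumeration."""

from itertools import combinations

import pytest

from zfsurvey import synthetic, zf_scan
from zfsurvey.zf_scan import (LIM_TEMPLATE, PHD_TEMPLATE, RING_TEMPLATE,
                              LigandChain, ProteinRecord, ScanConfig,
                              default_config)


def sequence_with_ligands(length, ligands, background="A"):
    """Background sequence with (position, residue) ligands planted."""
    seq = [background] * length
    for pos, res in ligands:
        seq[pos - 1] = res
    return "".join(seq)


# the spec-style worked example: C at 1,6,21,34,54,59,64 and H at 39
EXAMPLE_64 = sequence_with_ligands(
    64, [(p, "C") for p in (1, 6, 21, 34, 54, 59, 64)] + [(39, "H")])


def oracle_chains(seq, template, allow_missing=0):
    """Independent oracle: filter all 8-subsets of C/H positions."""
    positions = [i + 1 for i, ch in enumerate(seq) if ch in "CH"]
    found = []
    for combo in combinations(positions, 8):
        residues = tuple(seq[p - 1] for p in combo)
        mismatches = sum(r != e
                         for r, e in zip(residues, template.ligand_pattern))
        if mismatches > allow_missing:
            continue
        gaps = tuple(b - a - 1 for a, b in zip(combo, combo[1:]))
        ok = all(template.gap_range(i + 1)[0] <= g <= template.gap_range(i + 1)[1]
                 for i, g in enumerate(gaps))
        span = combo[-1] - combo[0] + 1
        if ok and template.span_range[0] <= span <= template.span_range[1]:
            found.append(combo)
    return sorted(found, key=lambda c: (c[0], c[-1] - c[0] + 1))


def make_chain(seq, positions, template=PHD_TEMPLATE):
    residues = tuple(seq[p - 1] for p in positions)
    gaps = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    n = sum(r == e for r, e in zip(residues, template.ligand_pattern))
    return LigandChain(positions=tuple(positions), residues=residues,
                       gaps=gaps, span=8 + sum(gaps), n_matched=n)


class TestEnumerateChains:
    def test_worked_example_single_chain(self):
        chains = zf_scan.enumerate_chains(EXAMPLE_64, PHD_TEMPLATE, 0)
        assert len(chains) == 1
        (chain,) = chains
        assert chain.positions == (1, 6, 21, 34, 39, 54, 59, 64)
        assert chain.span == 64
        assert chain.gap45 == 4
        assert chain.gaps == (4, 14, 12, 4, 14, 4, 4)

    def test_no_candidate_ligands_gives_empty(self):
        assert zf_scan.enumerate_chains("A" * 100, PHD_TEMPLATE, 0) == []

    def test_one_wildcard_slot(self):
        # His ligand mutated away: slot 5 becomes a wildcard, legal at
        # either of the two positions with a 4- or 5-residue gap45
        seq = EXAMPLE_64[:38] + "A" + EXAMPLE_64[39:]
        chains = zf_scan.enumerate_chains(seq, PHD_TEMPLATE, 1)
        assert [c.positions for c in chains] == [
            (1, 6, 21, 34, 39, 54, 59, 64), (1, 6, 21, 34, 40, 54, 59, 64)]
        assert all(c.n_matched == 7 for c in chains)

    def test_matches_bruteforce_oracle(self):
        seqs = [EXAMPLE_64,
                sequence_with_ligands(
                    90, [(p, "C") for p in (3, 9, 30, 44, 68, 74, 80)]
                    + [(50, "H"), (85, "C"), (88, "H")]),
                "A" * 55 + "C" * 9]
        for seq in seqs:
            for template in (PHD_TEMPLATE, RING_TEMPLATE, LIM_TEMPLATE):
                got = [c.positions
                       for c in zf_scan.enumerate_chains(seq, template, 0)]
                assert got == oracle_chains(seq, template, 0)

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            zf_scan.enumerate_chains("ACB" * 30, PHD_TEMPLATE, 0)
        with pytest.raises(ValueError):
            zf_scan.enumerate_chains("", PHD_TEMPLATE, 0)


class TestClassifyChain:
    def setup_method(self):
        self.config = default_config()

    def test_phd_spacing(self):
        seq = EXAMPLE_64
        chain = make_chain(seq, (1, 6, 21, 34, 39, 54, 59, 64))
        assert zf_scan.classify_chain(chain, self.config) == "PHD"

    def test_ring_spacing(self):
        # C3HC4 with three residues between ligands 4 and 5, span 55
        ligands = [(1, "C"), (8, "C"), (15, "C"), (22, "H"), (26, "C"),
                   (33, "C"), (45, "C"), (55, "C")]
        seq = sequence_with_ligands(55, ligands)
        chain = make_chain(seq, tuple(p for p, _ in ligands))
        assert zf_scan.classify_chain(chain, self.config) == "RING"

    def test_gap45_outside_all_templates_is_none(self):
        ligands = [(1, "C"), (8, "C"), (15, "C"), (22, "C"), (30, "H"),
                   (36, "C"), (45, "C"), (55, "C")]   # gap45 == 7
        seq = sequence_with_ligands(55, ligands)
        chain = make_chain(seq, tuple(p for p, _ in ligands))
        assert zf_scan.classify_chain(chain, self.config) == "NONE"


class TestScanProtein:
    def test_two_planted_motifs_separated_by_short_spacer(self):
        motif = EXAMPLE_64
        seq = motif + "A" * 20 + motif
        rec = ProteinRecord("two", seq)
        anns = zf_scan.scan_protein(rec)
        assert [(a.domain_class, a.start, a.end) for a in anns] == [
            ("PHD", 1, 64), ("PHD", 85, 148)]

    def test_single_ring_motif(self):
        ligands = [(1, "C"), (8, "C"), (15, "C"), (22, "H"), (26, "C"),
                   (33, "C"), (45, "C"), (55, "C")]
        seq = "A" * 10 + sequence_with_ligands(55, ligands) + "A" * 10
        anns = zf_scan.scan_protein(ProteinRecord("ring", seq))
        assert [a.domain_class for a in anns] == ["RING"]
        assert not any(a.domain_class == "PHD" for a in anns)

    def test_too_short_for_any_span(self):
        anns = zf_scan.scan_protein(ProteinRecord("short", "C" * 8 + "A" * 32))
        assert anns == []

    def test_scan_equals_oracle_scan_without_wildcards(self):
        """scan_protein against exhaustive C/H 8-subset enumeration plus an
        independently coded greedy overlap resolution, on <=120 aa."""
        config = default_config(max_missing=0)
        rank = {"PHD": 0, "RING": 1, "LIM": 2}

        def oracle_scan(seq):
            cands = []
            for template in (PHD_TEMPLATE, RING_TEMPLATE, LIM_TEMPLATE):
                for combo in oracle_chains(seq, template, 0):
                    residues = tuple(seq[p - 1] for p in combo)
                    if residues != template.ligand_pattern:
                        continue
                    cands.append((combo[0], combo[-1] - combo[0] + 1,
                                  rank[template.name], combo[-1],
                                  template.name))
            cands.sort()
            picked, last_end = [], 0
            for start, span, _, end, name in cands:
                if start > last_end:
                    picked.append((name, start, end))
                    last_end = end
            return picked

        rng_seqs = [
            EXAMPLE_64,
            EXAMPLE_64 + "A" * 25 + EXAMPLE_64[:30],
            sequence_with_ligands(
                120, [(p, "C") for p in (5, 12, 25, 40, 75, 83, 95)]
                + [(46, "H"), (100, "C"), (110, "H"), (118, "C")]),
            sequence_with_ligands(
                110, [(1, "C"), (8, "C"), (15, "C"), (22, "H"), (26, "C"),
                      (33, "C"), (45, "C"), (55, "C"), (60, "C"), (70, "H")]),
            "C" * 10 + "A" * 45 + "CHCH" * 3,
        ]
        for seq in rng_seqs:
            got = [(a.domain_class, a.start, a.end)
                   for a in zf_scan.scan_protein(ProteinRecord("x", seq),
                                                 config)]
            assert got == oracle_scan(seq)

    def test_annotations_revalidate_and_do_not_overlap(self):
        records, _ = synthetic.sim_proteome(n=40, seed=5)
        config = default_config()
        for rec in records:
            anns = zf_scan.scan_protein(rec, config)
            for a in anns:
                template = config.template(
                    "PHD" if a.domain_class == "SUSPECTED" else a.domain_class)
                lo, hi = template.gap45_range
                assert lo <= a.chain.gap45 <= hi
                slo, shi = template.span_range
                assert slo <= a.chain.span <= shi
                if a.domain_class != "SUSPECTED":
                    assert a.chain.residues == template.ligand_pattern
            for x, y in zip(anns, anns[1:]):
                assert x.end < y.start

    def test_gap45_contraction_flips_phd_to_ring(self):
        """Deleting one residue between ligands 4 and 5 of a PHD (and
        moving the His to slot 4, giving C3HC4 order) yields a RING call."""
        chain = zf_scan.enumerate_chains(EXAMPLE_64, PHD_TEMPLATE, 0)[0]
        p4, p5 = chain.positions[3], chain.positions[4]
        seq = list(EXAMPLE_64)
        seq[p4 - 1], seq[p5 - 1] = "H", "C"      # swap ligand order
        del seq[p4]                              # gap45: 4 -> 3
        mutated = "".join(seq)
        anns = zf_scan.scan_protein(ProteinRecord("m", mutated))
        assert [a.domain_class for a in anns] == ["RING"]

    def test_x_never_accepted_as_ligand(self):
        seq = EXAMPLE_64.replace("H", "X")
        chains = zf_scan.enumerate_chains(seq, PHD_TEMPLATE, 0)
        assert chains == []


class TestSuspectedDetection:
    def test_planted_degenerate_motifs_recovered(self):
        records, truth = synthetic.sim_proteome(
            n=30, class_mix={"SUSPECTED": 0.5, "PHD1": 0.3, "none": 0.2},
            seed=7)
        anns = zf_scan.scan_proteome(records)
        for rec in records:
            for planted in truth.entries[rec.id]:
                cls = planted["class"]
                expected = "SUSPECTED" if cls == "SUSPECTED" else cls
                n_expected = 8 - len(planted["missing_slots"])
                hits = [a for a in anns[rec.id]
                        if not (a.end < planted["start"]
                                or planted["end"] < a.start)]
                assert len(hits) == 1
                assert hits[0].domain_class == expected
                assert hits[0].chain.n_matched == n_expected

    def test_suspected_only_with_strict_config(self):
        records, _ = synthetic.sim_proteome(
            n=10, class_mix={"SUSPECTED": 1.0}, seed=3)
        strict = default_config(max_missing=0)
        for rec in records:
            assert zf_scan.scan_protein(rec, strict) == []


class TestSummaries:
    def test_domain_count_table(self):
        records, truth = synthetic.sim_proteome(
            n=3, class_mix={"PHD1": 1.0}, seed=1)
        anns = zf_scan.scan_proteome(records)
        table = zf_scan.summarize_domain_counts(anns)
        assert table["n_PHD"].tolist() == [1, 1, 1]
        assert int(table[["n_PHD", "n_RING", "n_LIM",
                          "n_SUSPECTED"]].values.sum()) == \
            sum(len(v) for v in anns.values())

    def test_empty_proteome(self):
        assert zf_scan.summarize_domain_counts({}).empty

    def test_phd_plus_suspected_is_not_suspected_only(self):
        motif = EXAMPLE_64
        degenerate = motif[:38] + "A" + motif[39:]
        rec = ProteinRecord("mix", motif + "A" * 30 + degenerate)
        anns = {"mix": zf_scan.scan_protein(rec)}
        table = zf_scan.summarize_domain_counts(anns)
        row = table.iloc[0]
        assert (row["n_PHD"], row["n_SUSPECTED"]) == (1, 1)
        assert not row["suspected_only"]

    def test_extract_domain_sequences(self):
        records, _ = synthetic.sim_proteome(n=50, seed=9)
        anns = zf_scan.scan_proteome(records)
        entries = zf_scan.extract_domain_sequences(records, anns)
        names = [n for n, _ in entries]
        assert len(names) == len(set(names))
        by_id = {r.id: r for r in records}
        for name, seq in entries:
            pid, start, end = name.rsplit("_", 2)
            assert seq == by_id[pid].sequence[int(start) - 1:int(end)]

    def test_extract_full_length_annotation_is_identity(self):
        rec = ProteinRecord("full", EXAMPLE_64)
        anns = {"full": zf_scan.scan_protein(rec)}
        (entry,) = zf_scan.extract_domain_sequences([rec], anns)
        assert entry == ("full_1_64", EXAMPLE_64)


class TestConfigValidation:
    def test_priority_must_cover_templates(self):
        with pytest.raises(ValueError):
            ScanConfig(templates=(PHD_TEMPLATE,), class_priority=("RING",))

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            zf_scan.DomainTemplate(name="bad",
                                   ligand_pattern=("C",) * 8,
                                   gap45_range=(5, 4), span_range=(50, 80))
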