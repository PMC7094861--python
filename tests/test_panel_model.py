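"""Panel loading, dual-pool validation and target statistics."""

import numpy as np
import pytest

import hsapanel as h
from hsapanel.panel_model import PanelError, bed_to_vcf_pos, merge_intervals, vcf_to_bed_pos


def write_toy_panel(tmp_path, bed_lines, manifest_text):
    bed = tmp_path / "panel.bed"
    bed.write_text("\n".join(bed_lines) + "\n")
    manifest = tmp_path / "panel.yaml"
    manifest.write_text(manifest_text)
    return manifest, bed


TOY_MANIFEST = """
panel_id: toy
genes:
  - {gene: G1, mode: full_coding}
amplicons:
  amp1_A: {pool: A, strand: "+", gene: G1}
  amp1_B: {pool: B, strand: "-", gene: G1}
"""


class TestLoadPanel:
    def test_minimal_mirrored_panel(self, tmp_path):
        manifest, bed = write_toy_panel(
            tmp_path, ["chr1\t100\t300\tamp1_A", "chr1\t100\t300\tamp1_B"],
            TOY_MANIFEST)
        panel = h.load_panel(manifest, bed)
        assert len(panel.amplicons) == 2
        assert panel.target_region == {"chr1": [(100, 300)]}

    def test_degenerate_interval_rejected_with_line_number(self, tmp_path):
        manifest, bed = write_toy_panel(
            tmp_path, ["chr1\t100\t300\tamp1_A", "chr1\t300\t300\tamp1_B"],
            TOY_MANIFEST)
        with pytest.raises(PanelError, match="line 2"):
            h.load_panel(manifest, bed)

    def test_duplicate_amplicon_id_rejected(self, tmp_path):
        manifest, bed = write_toy_panel(
            tmp_path, ["chr1\t100\t300\tamp1_A", "chr1\t400\t600\tamp1_A"],
            TOY_MANIFEST)
        with pytest.raises(PanelError, match="duplicate"):
            h.load_panel(manifest, bed)

    def test_undeclared_gene_rejected(self):
        with pytest.raises(PanelError, match="undeclared gene"):
            h.PanelDesign(panel_id="t", genes=[h.GeneTarget("G1")],
                          amplicons=[h.Amplicon("a", "chr1", 0, 100, "A", "+",
                                                gene="MYSTERY")])

    def test_roundtrip_via_files(self, tmp_path, panel):
        h.write_panel(panel, tmp_path / "m.yaml", tmp_path / "p.bed")
        again = h.load_panel(tmp_path / "m.yaml", tmp_path / "p.bed")
        assert again.target_region == panel.target_region
        assert {a.amplicon_id for a in again.amplicons} == \
            {a.amplicon_id for a in panel.amplicons}


class TestTargetStats:
    def test_disjoint_amplicons_arithmetic(self):
        amps = [h.Amplicon("a", "chr1", 0, 150, "A", "+"),
                h.Amplicon("b", "chr1", 200, 400, "A", "+")]
        panel = h.PanelDesign(panel_id="t", genes=[], amplicons=amps)
        stats = h.target_stats(panel)
        assert stats["n_amplicons"] == 2
        assert stats["mean_length"] == 175
        assert stats["target_bp"] == 350

    def test_overlapping_amplicons_union(self):
        amps = [h.Amplicon("a", "chr1", 0, 100, "A", "+"),
                h.Amplicon("b", "chr1", 50, 150, "A", "+")]
        panel = h.PanelDesign(panel_id="t", genes=[], amplicons=amps)
        assert h.target_stats(panel)["target_bp"] == 150

    def test_desired_region_absent_flags_warning(self):
        amps = [h.Amplicon("a", "chr1", 0, 100, "A", "+")]
        panel = h.PanelDesign(panel_id="t", genes=[], amplicons=amps)
        stats = h.target_stats(panel)
        assert stats["desired_missing"] is True
        assert stats["fraction_desired_covered"] == 1.0

    def test_default_panel_covers_desired_region(self, panel):
        stats = h.target_stats(panel)
        assert stats["fraction_desired_covered"] >= 0.99

    def test_union_size_matches_per_base_oracle(self, panel):
        # brute-force per-base set union over the whole (small) panel
        per_base = {(a.chrom, p) for a in panel.amplicons
                    for p in range(a.start, a.end)}
        assert h.target_stats(panel)["target_bp"] == len(per_base)


class TestDualPoolValidation:
    def test_mirrored_toy_panel_is_complete(self, toy_mirrored_panel):
        report = h.validate_dual_pool(toy_mirrored_panel)
        assert report.ok and report.n_single_pool == 0

    def test_removing_one_pool_b_amplicon_flags_its_bases(self, panel):
        victim = next(a for a in panel.amplicons if a.pool == "B")
        rest = [a for a in panel.amplicons if a is not victim]
        broken = h.PanelDesign(panel_id="broken", genes=panel.genes, amplicons=rest,
                               reference=panel.reference)
        report = h.validate_dual_pool(broken)
        # the orphaned bases are exactly those covered only by the victim's mirror
        mirrors = {(a.chrom, p) for a in rest if a.pool == "B"
                   for p in range(a.start, a.end)}
        expected = {(victim.chrom, p) for p in range(victim.start, victim.end)
                    if (victim.chrom, p) not in mirrors}
        flagged = {(c, int(p)) for c, arr in report.single_pool_bases.items()
                   for p in arr}
        assert flagged == expected

    def test_default_panel_has_no_single_pool_bases(self, panel):
        report = h.validate_dual_pool(panel)
        assert report.ok

    def test_report_invariant_under_amplicon_permutation(self, panel):
        rng = np.random.default_rng(5)
        shuffled = list(panel.amplicons)
        rng.shuffle(shuffled)
        permuted = h.PanelDesign(panel_id=panel.panel_id, genes=panel.genes,
                                 amplicons=shuffled, reference=panel.reference)
        r1, r2 = h.validate_dual_pool(panel), h.validate_dual_pool(permuted)
        assert {c: list(v) for c, v in r1.single_pool_bases.items()} == \
            {c: list(v) for c, v in r2.single_pool_bases.items()}

    def test_same_strand_mirror_rejected(self):
        with pytest.raises(PanelError, match="same template strand"):
            h.PanelDesign(panel_id="t", genes=[], amplicons=[
                h.Amplicon("a", "chr1", 0, 100, "A", "+"),
                h.Amplicon("b", "chr1", 0, 100, "B", "+")])


class TestGeneModel:
    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(PanelError, match="divisible by 3"):
            h.GeneModel(gene="G", chrom="chr1", strand="+",
                        cds_intervals=[(0, 10)], protein_length=2)

    def test_protein_length_checked_against_cds(self):
        with pytest.raises(PanelError, match="protein_length"):
            h.GeneModel(gene="G", chrom="chr1", strand="+",
                        cds_intervals=[(0, 12)], protein_length=9)

    def test_minus_strand_cds_positions_descend(self, panel):
        tp53 = panel.gene_models["TP53"]
        pos = tp53.cds_positions()
        assert pos[0] > pos[-1]
        assert tp53.codon_of(int(pos[0])) == 1

    def test_coordinate_conversions_are_inverse(self):
        assert bed_to_vcf_pos(99) == 100
        assert vcf_to_bed_pos(bed_to_vcf_pos(1234)) == 1234

    def test_merge_intervals(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]
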