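"""Effect annotation, driver classification, canine->human homology."""

import numpy as np
import pytest
from Bio.Seq import Seq

import hsapanel as h
from hsapanel.dualpool_caller import ConsensusVariant
from hsapanel.effects import indel_effect, snv_effect
from hsapanel.synthetic_panel import LESIONS, lesion_variant


def consensus(chrom, pos, ref, alt):
    return ConsensusVariant(
        sample_id="S1", chrom=chrom, pos=pos, ref=ref, alt=alt,
        pool_evidence={"A": (600, 60, 0.1), "B": (600, 60, 0.1)},
        called_pools=frozenset({"A", "B"}))


class TestAnnotateVariant:
    def test_every_catalogued_lesion_annotates_to_its_protein_change(self, panel):
        """Round-trip: each genomic lesion recovers its protein-level notation,
        covering missense/nonsense on both strands, frameshifts and splice."""
        for name, lesion in LESIONS.items():
            chrom, pos, ref, alt, change = lesion_variant(name, panel)
            av = h.annotate_variant(consensus(chrom, pos, ref, alt),
                                    panel.gene_models, panel.reference)
            assert av.gene == lesion.gene, name
            assert str(av.protein_change) == change, name

    def test_nras_q61r_is_missense(self, panel):
        chrom, pos, ref, alt, _ = lesion_variant("NRAS:Q61R", panel)
        av = h.annotate_variant(consensus(chrom, pos, ref, alt),
                                panel.gene_models, panel.reference)
        assert av.effect == "missense"
        assert str(av.protein_change) == "Q61R"

    def test_third_position_wobble_is_synonymous(self, panel):
        # NRAS codon 61 is planted as CAA; CAA->CAG is still glutamine
        model = panel.gene_models["NRAS"]
        g = int(model.cds_positions()[3 * 60 + 2])
        ref = panel.reference[model.chrom][g]
        assert ref == "A"
        effect, change = snv_effect(model, panel.reference, g + 1, "A", "G")
        assert effect == "synonymous"
        assert change.ref_aa == change.alt_aa == "Q"

    def test_minus_strand_nonsense(self, panel):
        chrom, pos, ref, alt, _ = lesion_variant("TP53:R196*", panel)
        av = h.annotate_variant(consensus(chrom, pos, ref, alt),
                                panel.gene_models, panel.reference)
        assert av.effect == "nonsense"
        assert str(av.protein_change) == "R196*"

    def test_two_bp_deletion_matches_bruteforce_translation(self, panel):
        # oracle: translate the mutated CDS directly and find the first
        # diverging codon; compare with the annotated frameshift position
        model = panel.gene_models["NRAS"]
        seq = panel.reference[model.chrom]
        cds_pos = np.sort(model.cds_positions())
        anchor0 = int(cds_pos[299])  # somewhere mid-CDS, away from boundaries
        ref = seq[anchor0: anchor0 + 3]
        effect, change = indel_effect(model, panel.reference, anchor0 + 1, ref, ref[0])
        assert effect == "frameshift"
        cds = "".join(seq[int(g)] for g in cds_pos)
        mutated = cds[:300] + cds[302:]  # the two bases after the anchor removed
        aa_ref = str(Seq(cds).translate())
        aa_mut = str(Seq(mutated[:len(mutated) // 3 * 3]).translate())
        first_diff = next(i for i, (a, b) in enumerate(zip(aa_ref, aa_mut)) if a != b)
        assert change.position == first_diff + 1
        assert change.kind == "fs"

    def test_inframe_deletion(self, panel):
        model = panel.gene_models["NRAS"]
        seq = panel.reference[model.chrom]
        cds_pos = np.sort(model.cds_positions())
        anchor0 = int(cds_pos[299])
        ref = seq[anchor0: anchor0 + 4]
        effect, _ = indel_effect(model, panel.reference, anchor0 + 1, ref, ref[0])
        assert effect == "inframe_indel"

    def test_essential_splice_site_and_deeper_intron(self, panel):
        model = panel.gene_models["PTEN"]
        exon1_end = model.cds_intervals[0][1]
        seq = panel.reference[model.chrom]
        for offset, expected in [(0, "splice_site"), (1, "splice_site"),
                                 (5, "intronic")]:
            g = exon1_end + offset
            ref = seq[g]
            alt = "A" if ref != "A" else "C"
            effect, _ = snv_effect(model, panel.reference, g + 1, ref, alt)
            assert effect == expected, offset

    def test_utr_and_intergenic(self, panel):
        model = panel.gene_models["PTEN"]
        seq = panel.reference[model.chrom]
        g_utr = model.cds_intervals[0][0] - 50   # inside tx, upstream of CDS
        ref = seq[g_utr]
        effect, _ = snv_effect(model, panel.reference, g_utr + 1, ref,
                               "A" if ref != "A" else "C")
        assert effect == "UTR"
        g_far = model.tx_start - 100
        av = h.annotate_variant(
            consensus(model.chrom, g_far + 1, seq[g_far],
                      "A" if seq[g_far] != "A" else "C"),
            panel.gene_models, panel.reference)
        assert av.effect == "intergenic" and av.gene is None

    def test_reference_mismatch_rejected(self, panel):
        model = panel.gene_models["NRAS"]
        g = int(np.sort(model.cds_positions())[0])
        ref = panel.reference[model.chrom][g]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="does not match reference"):
            snv_effect(model, panel.reference, g + 1, wrong, ref)


class TestClassifyDriver:
    @pytest.mark.parametrize("name,expected", [
        ("PIK3CA:H1047R", "activating"),
        ("NRAS:Q61R", "activating"),
        ("PLCG1:G797E", "activating"),
        ("PTEN:D246_splice", "inactivating"),
        ("PTEN:T56fs", "inactivating"),
        ("TP53:R196*", "inactivating"),
        ("TP53:P152fs", "inactivating"),
        ("TP53:R248W", "candidate_driver"),
    ])
    def test_catalogued_lesions(self, panel, name, expected):
        chrom, pos, ref, alt, _ = lesion_variant(name, panel)
        av = h.annotate_variant(consensus(chrom, pos, ref, alt),
                                panel.gene_models, panel.reference)
        assert h.classify_driver(av, h.default_driver_catalog()) == expected

    def test_non_hotspot_missense_in_catalog_gene_is_vus(self, panel):
        # NRAS codon 61 CAA->GAA is Q61E: nonsynonymous but not catalogued
        model = panel.gene_models["NRAS"]
        g = int(model.cds_positions()[3 * 60])
        av = h.annotate_variant(consensus(model.chrom, g + 1, "C", "G"),
                                panel.gene_models, panel.reference)
        assert av.effect == "missense"
        assert h.classify_driver(av, h.default_driver_catalog()) == "VUS"

    def test_gene_outside_catalog_is_none(self, panel):
        model = panel.gene_models["PTEN"]
        g_far = model.tx_start - 100
        seq = panel.reference[model.chrom]
        av = h.annotate_variant(
            consensus(model.chrom, g_far + 1, seq[g_far],
                      "A" if seq[g_far] != "A" else "C"),
            panel.gene_models, panel.reference)
        assert h.classify_driver(av, h.default_driver_catalog()) == "none"


class TestHomology:
    def test_plcg1_segment_offset_plus_72(self):
        table = h.default_homology_table()
        assert h.map_to_human("PLCG1", 273, table) == 345
        assert h.map_to_human("PLCG1", 797, table) == 869

    def test_pten_segment_offset_plus_22(self):
        table = h.default_homology_table()
        assert h.map_to_human("PTEN", 56, table) == 78
        assert h.map_to_human("PTEN", 246, table) == 268

    def test_nras_identical_numbering(self):
        assert h.map_to_human("NRAS", 61, h.default_homology_table()) == 61

    def test_position_outside_segments_gives_no_guess(self):
        table = h.default_homology_table()
        assert h.map_to_human("PLCG1", 5000, table) is None
        assert h.map_to_human("UNKNOWN_GENE", 10, table) is None

    def test_human_notation_rebuilt(self, panel):
        chrom, pos, ref, alt, _ = lesion_variant("PLCG1:G797E", panel)
        av = h.annotate_variant(consensus(chrom, pos, ref, alt),
                                panel.gene_models, panel.reference,
                                homology=h.default_homology_table())
        assert av.human_change == "G869E"

    def test_catalog_and_homology_tsv_roundtrip(self, tmp_path):
        from hsapanel.annotation import (read_driver_catalog, read_homology_table,
                                         write_driver_catalog, write_homology_table)
        catalog = h.default_driver_catalog()
        write_driver_catalog(catalog, tmp_path / "drv.tsv")
        again = read_driver_catalog(tmp_path / "drv.tsv")
        assert again == catalog
        table = h.default_homology_table()
        write_homology_table(table, tmp_path / "hom.tsv")
        assert read_homology_table(tmp_path / "hom.tsv") == table
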