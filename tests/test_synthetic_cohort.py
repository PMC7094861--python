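"""Cohort truth generation and dual-pool read-count simulation."""

import numpy as np
import pytest

import hsapanel as h
from hsapanel.synthetic_cohort import TruthVariant, largest_remainder_counts


class TestCohortTruth:
    def test_default_fifty_case_subtype_counts(self, config, panel):
        truths = h.sample_cohort(config, panel)
        counts = {}
        for t in truths:
            counts[t.true_subtype] = counts.get(t.true_subtype, 0) + 1
        assert counts == {"PI3K_pathway": 26, "NRAS": 12, "TP53_only": 6,
                          "PLCG1": 2, "NONE": 4}

    @pytest.mark.parametrize("n,props", [
        (7, {"PI3K_pathway": 0.5, "NRAS": 0.5}),
        (13, {"PI3K_pathway": 0.52, "NRAS": 0.24, "TP53_only": 0.12,
              "PLCG1": 0.04, "NONE": 0.08}),
        (1, {"NONE": 1.0}),
        (99, {"PI3K_pathway": 1 / 3, "NRAS": 1 / 3, "NONE": 1 / 3}),
    ])
    def test_apportionment_conserves_total(self, n, props):
        counts = largest_remainder_counts(n, props)
        assert sum(counts.values()) == n
        for name, c in counts.items():
            assert abs(c - n * props[name]) < 1

    def test_single_none_case_has_no_drivers(self, panel):
        cfg = h.SimConfig(n_cases=1, subtype_proportions={"NONE": 1.0}, seed=3)
        truths = h.sample_cohort(cfg, panel)
        assert len(truths) == 1
        assert truths[0].of_class("somatic_driver") == []

    def test_too_few_cases_for_classes_rejected(self, panel):
        cfg = h.SimConfig(n_cases=3, seed=1)
        with pytest.raises(ValueError, match="fewer than"):
            h.sample_cohort(cfg, panel)

    def test_fixed_seed_reproduces_truth_exactly(self, panel):
        cfg = h.SimConfig(seed=42)
        assert h.sample_cohort(cfg, panel) == h.sample_cohort(cfg, panel)

    def test_drivers_match_subtype_and_artifacts_are_single_stranded(self, config, panel):
        catalog = h.default_driver_catalog()
        for t in h.sample_cohort(config, panel):
            driver_genes = {v.gene for v in t.of_class("somatic_driver")}
            if t.true_subtype == "PI3K_pathway":
                assert driver_genes & {"PIK3CA", "PTEN"}
            elif t.true_subtype in ("NRAS", "PLCG1"):
                assert t.true_subtype in driver_genes
            elif t.true_subtype == "TP53_only":
                assert driver_genes == {"TP53"}
            else:
                assert driver_genes == set()
            assert driver_genes <= catalog.genes
            for a in t.of_class("artifact"):
                assert a.damaged_strand in "+-"
                assert (a.ref, a.alt) in {("C", "T"), ("G", "A")}

    def test_mt_duplicates_share_somatic_drivers(self, panel):
        cfg = h.SimConfig(seed=9, mt_duplicates=2)
        truths = h.sample_cohort(cfg, panel)
        mts = [t for t in truths if t.tissue == "MT"]
        assert len(mts) == 2
        primaries = {t.case_id: t for t in truths if t.tissue == "PT"}
        for mt in mts:
            src = primaries[mt.case_id.removesuffix("-MT")]
            key = lambda vs: {v.key for v in vs}
            assert key(mt.of_class("somatic_driver")) == key(src.of_class("somatic_driver"))


class TestTruthIO:
    def test_fifty_case_roundtrip(self, config, panel, tmp_path):
        truths = h.sample_cohort(config, panel)
        h.write_truth(truths, tmp_path / "truth.tsv")
        assert h.read_truth(tmp_path / "truth.tsv") == truths

    def test_empty_cohort_writes_header_only(self, tmp_path):
        h.write_truth([], tmp_path / "truth.tsv")
        text = (tmp_path / "truth.tsv").read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("case_id\t")
        assert h.read_truth(tmp_path / "truth.tsv") == []

    def test_unicode_case_id_preserved(self, tmp_path):
        case = h.CaseTruth(case_id="犬-001", true_subtype="NONE", variants=[])
        h.write_truth([case], tmp_path / "truth.tsv")
        assert h.read_truth(tmp_path / "truth.tsv")[0].case_id == "犬-001"

    def test_schema_mismatch_names_columns(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("case_id\tgene\nx\ty\n")
        with pytest.raises(ValueError, match="chrom"):
            h.read_truth(tmp_path / "bad.tsv")

    def test_counts_tsv_roundtrip(self, config, panel, tmp_path):
        case = h.sample_cohort(config, panel)[0]
        a, _ = h.simulate_counts(case, panel, config)
        h.write_counts(a, tmp_path / "a.tsv")
        again = h.read_counts(tmp_path / "a.tsv")
        assert again.equals(a)


def _clean_config(**kw):
    return h.SimConfig(seed=kw.pop("seed", 5), base_error_rate=0.0,
                       artifact_site_rate=kw.pop("artifact_site_rate", 0.0), **kw)


class TestSimulateCounts:
    def test_noise_free_alt_sites_are_exactly_the_injected_variants(self, panel):
        cfg = _clean_config()
        case = h.sample_cohort(cfg, panel)[0]
        a, b = h.simulate_counts(case, panel, cfg)
        injected = {(v.chrom, v.pos) for v in case.variants}
        for counts in (a, b):
            alt_sites = set()
            for base in "ACGT":
                hit = counts.df[(counts.df[base] > 0) & (counts.df["ref"] != base)]
                alt_sites |= {(r.chrom, int(r.pos)) for r in hit.itertuples()}
            alt_sites |= set(counts.indels)
            assert alt_sites <= injected

    def test_artifact_reads_confined_to_damaged_strand_pool(self, panel):
        cfg = _clean_config()
        # pick a real C site inside the target so the ref base is consistent
        seq = panel.reference["chr17"]
        pos0 = next(p for p in range(10_000, 10_200) if seq[p] == "C")
        art = TruthVariant(gene=None, chrom="chr17", pos=pos0 + 1, ref="C", alt="T",
                           protein_change=None, vaf=0.5, var_class="artifact",
                           damaged_strand="+")
        case = h.CaseTruth(case_id="ART", true_subtype="NONE", variants=[art])
        a, b = h.simulate_counts(case, panel, cfg)
        sel_a = (a.df["chrom"] == "chr17") & (a.df["pos"] == pos0 + 1)
        sel_b = (b.df["chrom"] == "chr17") & (b.df["pos"] == pos0 + 1)
        t_in_a = int(a.df.loc[sel_a, "T"].iloc[0])
        t_in_b = int(b.df.loc[sel_b, "T"].iloc[0])
        assert t_in_a > 0 and t_in_b == 0  # pool A templates "+", pool B "-"

    def test_single_pool_alt_sites_equal_artifact_truth(self, panel):
        # artifact fractions high enough that every damaged site leaves reads
        cfg = h.SimConfig(seed=8, base_error_rate=0.0, artifact_site_rate=0.02,
                          artifact_vaf_range=(0.04, 0.08))
        case = h.sample_cohort(cfg, panel)[0]
        a, b = h.simulate_counts(case, panel, cfg)
        single_pool = set()
        for counts, other in ((a, b), (b, a)):
            for base in "ACGT":
                sel = (counts.df[base] > 0) & (counts.df["ref"] != base)
                osel = (other.df[base] > 0) & (other.df["ref"] != base)
                single_pool |= {(r.chrom, int(r.pos))
                                for r in counts.df[sel & ~osel].itertuples()}
        artifacts = {(v.chrom, v.pos) for v in case.of_class("artifact")}
        assert single_pool == artifacts

    def test_alt_counts_match_binomial_expectation(self, panel):
        # 200 replicate sites at VAF 0.10: mean per-pool alt count within 3 SE
        cfg = _clean_config(seed=21)
        sites = []
        seen = set()
        seq = panel.reference["chr34"]
        for p in panel.target_positions("chr34"):
            p = int(p)
            if len(sites) == 200:
                break
            if p in seen:
                continue
            seen.add(p)
            ref = seq[p]
            alt = "A" if ref != "A" else "G"
            sites.append(TruthVariant(gene=None, chrom="chr34", pos=p + 1, ref=ref,
                                      alt=alt, protein_change=None, vaf=0.10,
                                      var_class="somatic_passenger"))
        case = h.CaseTruth(case_id="REP", true_subtype="NONE", variants=sites)
        a, _ = h.simulate_counts(case, panel, cfg)
        pos_set = {v.pos for v in sites}
        sub = a.df[(a.df["chrom"] == "chr34") & a.df["pos"].isin(pos_set)]
        alt_counts = [int(r.A if r.ref != "A" else r.G) for r in sub.itertuples()]
        d, p, k = cfg.depth_mean_per_pool, 0.10, cfg.depth_dispersion
        var_alt = d * p * (1 - p) + p ** 2 * (d + d ** 2 / k)
        se = np.sqrt(var_alt / len(alt_counts))
        assert abs(np.mean(alt_counts) - d * p) < 3 * se

    def test_depth_equals_sum_of_allele_counts(self, config, panel):
        case = h.sample_cohort(config, panel)[0]
        a, _ = h.simulate_counts(case, panel, config)
        base_sum = a.df[list("ACGT")].sum(axis=1)
        indel_sum = np.zeros(len(a.df), dtype=int)
        pos_index = {(c, p): i for i, (c, p) in enumerate(zip(a.df["chrom"], a.df["pos"]))}
        for key, alleles in a.indels.items():
            indel_sum[pos_index[key]] += sum(alleles.values())
        assert (a.df["depth"] == base_sum + indel_sum).all()

    def test_ref_mismatch_rejected(self, config, panel):
        bad = TruthVariant(gene=None, chrom="chr17", pos=10_001, ref="N", alt="A",
                           protein_change=None, vaf=0.1, var_class="somatic_passenger")
        case = h.CaseTruth(case_id="BAD", true_subtype="NONE", variants=[bad])
        with pytest.raises(ValueError, match="mismatch"):
            h.simulate_counts(case, panel, config)

    def test_fixed_seed_reproduces_counts(self, panel):
        cfg = h.SimConfig(seed=13)
        case = h.sample_cohort(cfg, panel)[0]
        a1, _ = h.simulate_counts(case, panel, cfg)
        a2, _ = h.simulate_counts(case, panel, cfg)
        assert a1.equals(a2)
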