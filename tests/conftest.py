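import pandas as pd
import pytest

import hsapanel as h
from hsapanel.synthetic_cohort import SiteCounts


@pytest.fixture(scope="session")
def panel():
    return h.build_default_panel()


@pytest.fixture(scope="session")
def config():
    return h.SimConfig(seed=11)


def mk_counts(sample_id="S1", pool="A", rows=None, indels=None):
    """Build a SiteCounts table from (chrom, pos, ref, {base: count}) rows.

    Depth is the sum of all allele counts at the site (indels included).
    """
    recs = []
    indels = indels or {}
    for chrom, pos, ref, alleles in rows:
        counts = {b: alleles.get(b, 0) for b in "ACGT"}
        depth = sum(counts.values()) + sum(indels.get((chrom, pos), {}).values())
        recs.append({"chrom": chrom, "pos": pos, "ref": ref, **counts,
                     "depth": depth})
    return SiteCounts(sample_id=sample_id, pool=pool,
                      df=pd.DataFrame(recs), indels=dict(indels))


@pytest.fixture
def toy_mirrored_panel():
    """Two mirrored amplicons over one interval, opposite template strands."""
    amps = [
        h.Amplicon("amp1_A", "chr1", 100, 300, "A", "+", gene="G1"),
        h.Amplicon("amp1_B", "chr1", 100, 300, "B", "-", gene="G1"),
    ]
    return h.PanelDesign(panel_id="toy", genes=[h.GeneTarget("G1")], amplicons=amps)
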