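"""Annotate catalogued driver lesions and map them to human coordinates.

Each lesion is realised as a genomic variant on the panel reference,
annotated back to its protein-level change, classified against the driver
catalog and mapped to the homologous human protein position.
"""
import hsapanel as h
from hsapanel.dualpool_caller import ConsensusVariant
from hsapanel.synthetic_panel import lesion_variant

panel = h.build_default_panel()
catalog = h.default_driver_catalog()
homology = h.default_homology_table()

for name in ["PIK3CA:H1047R", "NRAS:Q61R", "PLCG1:S273F", "PLCG1:G797E",
             "PTEN:T56fs", "PTEN:D246_splice", "TP53:R248W", "TP53:R196*"]:
    chrom, pos, ref, alt, _ = lesion_variant(name, panel)
    v = ConsensusVariant(sample_id="demo", chrom=chrom, pos=pos, ref=ref, alt=alt,
                         pool_evidence={"A": (700, 70, 0.1), "B": (700, 70, 0.1)},
                         called_pools=frozenset({"A", "B"}))
    av = h.annotate_variant(v, panel.gene_models, panel.reference, homology)
    av.driver_status = h.classify_driver(av, catalog)
    human = f" -> human {av.human_change}" if av.human_change else ""
    print(f"{av.gene:7s} {str(av.protein_change):12s} {av.effect:12s} "
          f"{av.driver_status}{human}")
# Canine PLCG1/PTEN positions shift by +72/+22 in the human proteins;
# PIK3CA, NRAS and TP53 numbering is identical between the species.
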