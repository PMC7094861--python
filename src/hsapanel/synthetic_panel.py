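"""Synthetic default panel: five driver genes with planted hotspot codons.

The default panel is a scaled-down stand-in for a proprietary amplicon
design: full coding regions of the five recurrently mutated hemangiosarcoma
driver genes (PIK3CA, PTEN, NRAS, TP53, PLCG1), each tiled by mirrored
amplicon pools A (+ template) and B (- template), ~175 bp amplicons with
35 bp overlap and 30 bp exon flanks. Gene sequences are random but carry
the reference codons required at every catalogued hotspot position, so that
the catalogued protein changes are realisable as single-nucleotide (or
1 bp indel / splice-site) lesions against this reference. Protein
coordinates of the planted hotspots match the positions the field uses for
these genes (PIK3CA and NRAS numbering is identical in dog and human;
PLCG1 and PTEN differ by fixed offsets handled by the homology table).

The panel itself is deterministic (its own fixed seed) and independent of
the cohort-simulation seed: a panel is a fixed lab design, not a random
draw per experiment.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .panel_model import Amplicon, GeneModel, GeneTarget, PanelDesign, merge_intervals

_BASES = np.array(["A", "C", "G", "T"])
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PANEL_SEED = 57619  # fixed design seed

AMPLICON_LENGTH = 175
AMPLICON_STEP = 140
EXON_FLANK = 30

# chrom, strand, protein length (aa), exon breakpoints in CDS coordinates
_GENE_LAYOUT = {
    "PIK3CA": ("chr34", "+", 1068, [801, 1602, 2403]),
    "PTEN": ("chr26", "+", 403, [240, 738]),       # exon boundary after codon 246
    "NRAS": ("chr17", "+", 189, [285]),
    "TP53": ("chr5", "-", 393, [393, 786]),
    "PLCG1": ("chr24", "+", 1290, [777, 1554, 2331, 3108]),
}

# reference codons planted at hotspot / lesion positions (protein coords)
PLANTED_CODONS = {
    "PIK3CA": {350: "GAT", 420: "TGC", 726: "GAA", 1025: "ACA",
               1044: "AAC", 1047: "CAC", 1049: "GGA"},
    "NRAS": {61: "CAA", 153: "GAA"},
    "PLCG1": {273: "TCC", 797: "GGA"},
    "PTEN": {56: "ACT", 246: "GAT"},
    "TP53": {152: "CCT", 196: "CGA", 241: "TCC", 248: "CGG", 273: "CGT"},
}


@dataclass(frozen=True)
class Lesion:
    """A realisable genomic lesion with a known protein-level consequence."""

    gene: str
    protein_change: str       # e.g. "H1047R", "T56fs", "D246_splice"
    kind: str                 # snv | frameshift | splice
    aa_pos: int
    codon_offset: int = 0     # for SNVs: 0..2 within the codon (transcript sense)
    alt_codon_base: str = ""  # for SNVs: replacement base, transcript sense


# activating hotspots + representative TP53/PTEN lesions used by the simulator
LESIONS = {
    "PIK3CA:D350G": Lesion("PIK3CA", "D350G", "snv", 350, 1, "G"),
    "PIK3CA:C420R": Lesion("PIK3CA", "C420R", "snv", 420, 0, "C"),
    "PIK3CA:E726K": Lesion("PIK3CA", "E726K", "snv", 726, 0, "A"),
    "PIK3CA:T1025A": Lesion("PIK3CA", "T1025A", "snv", 1025, 0, "G"),
    "PIK3CA:N1044K": Lesion("PIK3CA", "N1044K", "snv", 1044, 2, "G"),
    "PIK3CA:H1047R": Lesion("PIK3CA", "H1047R", "snv", 1047, 1, "G"),
    "PIK3CA:G1049R": Lesion("PIK3CA", "G1049R", "snv", 1049, 0, "A"),
    "NRAS:Q61R": Lesion("NRAS", "Q61R", "snv", 61, 1, "G"),
    "NRAS:E153K": Lesion("NRAS", "E153K", "snv", 153, 0, "A"),
    "PLCG1:S273F": Lesion("PLCG1", "S273F", "snv", 273, 1, "T"),
    "PLCG1:G797E": Lesion("PLCG1", "G797E", "snv", 797, 1, "A"),
    "PTEN:T56fs": Lesion("PTEN", "T56fs", "frameshift", 56),
    "PTEN:D246_splice": Lesion("PTEN", "D246_splice", "splice", 246),
    "TP53:P152fs": Lesion("TP53", "P152fs", "frameshift", 152),
    "TP53:R196*": Lesion("TP53", "R196*", "snv", 196, 0, "T"),
    "TP53:S241F": Lesion("TP53", "S241F", "snv", 241, 1, "T"),
    "TP53:R248W": Lesion("TP53", "R248W", "snv", 248, 0, "T"),
    "TP53:R273H": Lesion("TP53", "R273H", "snv", 273, 1, "A"),
}

PIK3CA_HOTSPOTS = ["PIK3CA:H1047R", "PIK3CA:G1049R", "PIK3CA:N1044K",
                   "PIK3CA:C420R", "PIK3CA:T1025A", "PIK3CA:E726K", "PIK3CA:D350G"]
PTEN_LESIONS = ["PTEN:T56fs", "PTEN:D246_splice"]
TP53_MISSENSE = ["TP53:R248W", "TP53:R273H", "TP53:S241F"]
TP53_LOF = ["TP53:R196*", "TP53:P152fs"]
PLCG1_HOTSPOTS = ["PLCG1:S273F", "PLCG1:G797E"]


def _gene_rng(gene: str) -> np.random.Generator:
    return np.random.default_rng([_PANEL_SEED, zlib.crc32(gene.encode())])


def build_default_panel() -> PanelDesign:
    """Build the default five-gene dual-pool panel with embedded reference."""
    gene_targets, amplicons, models = [], [], {}
    reference: dict[str, str] = {}
    desired: dict[str, list[tuple[int, int]]] = {}

    for gene, (chrom, strand, plen, cds_breaks) in _GENE_LAYOUT.items():
        cds_len = (plen + 1) * 3
        # genomic exon intervals: 300 bp introns, gene starts at 10,000
        bounds = [0] + list(cds_breaks) + [cds_len]
        exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
        gstart = 10_000
        exons, cursor = [], gstart
        for L in exon_lens:
            exons.append((cursor, cursor + L))
            cursor += L + 300
        model = GeneModel(gene=gene, chrom=chrom, strand=strand,
                          cds_intervals=exons, protein_length=plen)
        models[gene] = model

        contig_len = exons[-1][1] + 500
        rng = _gene_rng(gene)
        seq = rng.choice(_BASES, size=contig_len)
        # canonical splice dinucleotides at every intron, transcript sense
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if strand == "+":
                seq[e1], seq[e1 + 1] = "G", "T"        # donor
                seq[s2 - 2], seq[s2 - 1] = "A", "G"    # acceptor
            else:
                seq[s2 - 2], seq[s2 - 1] = "A", "C"    # donor (revcomp GT)
                seq[e1], seq[e1 + 1] = "C", "T"        # acceptor (revcomp AG)
        cds_pos = model.cds_positions()
        plant = dict(PLANTED_CODONS.get(gene, {}))
        plant[plen + 1] = "TAA"  # stop
        for aa, codon in plant.items():
            for i, base in enumerate(codon):
                g = cds_pos[3 * (aa - 1) + i]
                seq[g] = base if strand == "+" else _COMP[base]
        reference[chrom] = "".join(seq)

        gene_targets.append(GeneTarget(gene=gene, mode="full_coding"))
        desired.setdefault(chrom, []).extend(
            (max(0, s - 2), e + 2) for s, e in exons)

        n_amp = 0
        for s, e in exons:
            lo, hi = s - EXON_FLANK, e + EXON_FLANK
            start = lo
            while start < hi:
                n_amp += 1
                aid = f"{gene}_{n_amp:03d}"
                for pool, st in (("A", "+"), ("B", "-")):
                    amplicons.append(Amplicon(
                        amplicon_id=f"{aid}_{pool}", chrom=chrom,
                        start=start, end=start + AMPLICON_LENGTH,
                        pool=pool, template_strand=st, gene=gene))
                start += AMPLICON_STEP

    desired = {c: merge_intervals(v) for c, v in desired.items()}
    return PanelDesign(panel_id="hsa-synthetic-v1", genes=gene_targets,
                       amplicons=amplicons, desired_region=desired,
                       reference=reference, gene_models=models)


def lesion_variant(name: str, panel: PanelDesign) -> tuple[str, int, str, str, str]:
    """Genomic realisation of a catalogued lesion on the panel reference.

    Returns (chrom, pos 1-based, ref, alt, protein_change).
    """
    lesion = LESIONS[name]
    model = panel.gene_models[lesion.gene]
    seq = panel.reference[model.chrom]
    cds_pos = model.cds_positions()
    comp = model.strand == "-"
    if lesion.kind == "snv":
        g = int(cds_pos[3 * (lesion.aa_pos - 1) + lesion.codon_offset])
        alt = _COMP[lesion.alt_codon_base] if comp else lesion.alt_codon_base
        return model.chrom, g + 1, seq[g], alt, lesion.protein_change
    if lesion.kind == "frameshift":
        # delete the first base of the codon (genome-left anchored)
        g = int(cds_pos[3 * (lesion.aa_pos - 1)])
        a = g - 1
        return model.chrom, a + 1, seq[a:g + 1], seq[a], lesion.protein_change
    if lesion.kind == "splice":
        # SNV at the first intronic base after the exon ending at this codon
        boundary = int(cds_pos[3 * lesion.aa_pos - 1])  # last base of codon
        if model.strand == "+":
            g = boundary + 1
        else:
            g = boundary - 1
        ref = seq[g]
        alt = "A" if ref != "A" else "C"
        return model.chrom, g + 1, ref, alt, lesion.protein_change
    raise ValueError(f"unknown lesion kind {lesion.kind!r}")
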