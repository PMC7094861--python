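"""Codon-level effect classification of variants against gene models.

Strand-aware translation of the affected codon (standard genetic code via
Biopython) assigns SNVs to synonymous / missense / nonsense; coding indels
are frameshift unless their length is a multiple of three; positions within
``splice_window`` (default 2 bp, the essential donor/acceptor dinucleotide)
of an intron boundary are splice-site; the remainder fall to intronic, UTR
or intergenic by position.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .panel_model import GeneModel

EFFECTS = ("synonymous", "missense", "nonsense", "frameshift", "inframe_indel",
           "splice_site", "intronic", "UTR", "intergenic")

LOF_EFFECTS = frozenset({"nonsense", "frameshift", "splice_site"})


@dataclass(frozen=True)
class ProteinChange:
    """Protein-level consequence in the field's shorthand notation."""

    position: int            # 1-based codon index
    kind: str                # missense | synonymous | nonsense | fs | splice | inframe
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __str__(self) -> str:
        if self.kind in ("missense", "synonymous", "nonsense"):
            return f"{self.ref_aa}{self.position}{self.alt_aa}"
        if self.kind == "fs":
            return f"{self.ref_aa}{self.position}fs"
        if self.kind == "splice":
            return f"{self.ref_aa}{self.position}_splice"
        return f"{self.ref_aa}{self.position}del"


def parse_protein_change(text: str) -> ProteinChange:
    """Parse shorthand like ``H1047R``, ``R196*``, ``T56fs``, ``D246_splice``."""
    import re
    m = re.fullmatch(r"([A-Z*])(\d+)(fs|_splice|del|[A-Z*])", text)
    if not m:
        raise ValueError(f"cannot parse protein change {text!r}")
    ref_aa, pos, tail = m.group(1), int(m.group(2)), m.group(3)
    if tail == "fs":
        return ProteinChange(position=pos, kind="fs", ref_aa=ref_aa)
    if tail == "_splice":
        return ProteinChange(position=pos, kind="splice", ref_aa=ref_aa)
    if tail == "del":
        return ProteinChange(position=pos, kind="inframe", ref_aa=ref_aa)
    kind = ("synonymous" if tail == ref_aa else
            "nonsense" if tail == "*" else "missense")
    return ProteinChange(position=pos, kind=kind, ref_aa=ref_aa, alt_aa=tail)


def effect_of_change(change: ProteinChange) -> str:
    return {"missense": "missense", "synonymous": "synonymous",
            "nonsense": "nonsense", "fs": "frameshift",
            "splice": "splice_site", "inframe": "inframe_indel"}[change.kind]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _codon_seq(model: GeneModel, reference: dict[str, str], codon: int) -> str:
    """Reference codon (transcript sense) at a 1-based codon index."""
    seq = reference[model.chrom]
    pos = model.cds_positions()[3 * (codon - 1): 3 * codon]
    bases = "".join(seq[int(g)] for g in pos)
    # positions are already in transcript order, so a minus-strand codon
    # needs the complement only, not the reverse complement
    return bases if model.strand == "+" else str(Seq(bases).complement())


def ref_aa_at(model: GeneModel, reference: dict[str, str], codon: int) -> str:
    return _translate(_codon_seq(model, reference, codon))


def _nearest_cds(model: GeneModel, gpos0: int) -> tuple[int, int]:
    """(distance, genomic position) of the nearest CDS base."""
    best = None
    for s, e in model.cds_intervals:
        if s <= gpos0 < e:
            return 0, gpos0
        cand = s if gpos0 < s else e - 1
        d = abs(gpos0 - cand)
        if best is None or d < best[0]:
            best = (d, cand)
    return best


def _in_intron(model: GeneModel, gpos0: int) -> bool:
    return (model.cds_intervals[0][0] <= gpos0 < model.cds_intervals[-1][1]
            and not any(s <= gpos0 < e for s, e in model.cds_intervals))


def find_gene(models: dict[str, GeneModel], chrom: str, pos1: int) -> GeneModel | None:
    gpos0 = pos1 - 1
    for m in models.values():
        if m.chrom == chrom and m.tx_start <= gpos0 < m.tx_end:
            return m
    return None


def _splice_change(model: GeneModel, reference: dict[str, str], gpos0: int) -> ProteinChange:
    _, near = _nearest_cds(model, gpos0)
    codon = model.codon_of(near)
    return ProteinChange(position=codon, kind="splice",
                         ref_aa=ref_aa_at(model, reference, codon))


def snv_effect(model: GeneModel, reference: dict[str, str], pos1: int,
               ref: str, alt: str) -> tuple[str, ProteinChange | None]:
    """Effect of a single-nucleotide substitution within a gene's span."""
    gpos0 = pos1 - 1
    seq = reference[model.chrom]
    if seq[gpos0] != ref:
        raise ValueError(
            f"{model.chrom}:{pos1}: ref {ref!r} does not match reference {seq[gpos0]!r}")
    idx = model.cds_index(gpos0)
    if idx is not None:
        codon_i = idx // 3 + 1
        offset = idx % 3
        ref_codon = _codon_seq(model, reference, codon_i)
        alt_base = alt if model.strand == "+" else str(Seq(alt).complement())
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
        ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
        if alt_aa == ref_aa:
            kind = "synonymous"
        elif alt_aa == "*":
            kind = "nonsense"
        else:
            kind = "missense"
        return kind, ProteinChange(position=codon_i, kind=kind,
                                   ref_aa=ref_aa, alt_aa=alt_aa)
    dist, _ = _nearest_cds(model, gpos0)
    if _in_intron(model, gpos0):
        if dist <= model.splice_window:
            return "splice_site", _splice_change(model, reference, gpos0)
        return "intronic", None
    return "UTR", None


def indel_effect(model: GeneModel, reference: dict[str, str], pos1: int,
                 ref: str, alt: str) -> tuple[str, ProteinChange | None]:
    """Effect of a left-anchored indel (VCF style: shared first base)."""
    gpos0 = pos1 - 1
    seq = reference[model.chrom]
    if seq[gpos0: gpos0 + len(ref)] != ref:
        raise ValueError(
            f"{model.chrom}:{pos1}: ref {ref!r} does not match reference")
    if len(ref) > 1:  # deletion: affected bases start one past the anchor
        affected = range(gpos0 + 1, gpos0 + len(ref))
        net = len(ref) - len(alt)
    else:             # insertion: anchored at the shared base
        affected = [gpos0, gpos0 + 1]
        net = len(alt) - len(ref)
    in_cds = [g for g in affected if model.cds_index(g) is not None]
    if not in_cds:
        dist = min(_nearest_cds(model, g)[0] for g in affected)
        if any(_in_intron(model, g) for g in affected):
            if dist <= model.splice_window:
                return "splice_site", _splice_change(model, reference, gpos0)
            return "intronic", None
        return "UTR", None
    if len(in_cds) != len(list(affected)):
        warnings.warn(f"{model.chrom}:{pos1}: indel spans a CDS/intron boundary; "
                      "classified as splice_site")
        return "splice_site", _splice_change(model, reference, gpos0)
    idx = min(model.cds_index(g) for g in in_cds)
    codon_i = idx // 3 + 1
    ref_aa = ref_aa_at(model, reference, codon_i)
    if net % 3 != 0:
        return "frameshift", ProteinChange(position=codon_i, kind="fs", ref_aa=ref_aa)
    return "inframe_indel", ProteinChange(position=codon_i, kind="inframe", ref_aa=ref_aa)


def variant_effect(models: dict[str, GeneModel], reference: dict[str, str],
                   chrom: str, pos1: int, ref: str, alt: str
                   ) -> tuple[str | None, str, ProteinChange | None]:
    """(gene, effect, protein change) for a variant; gene None if intergenic."""
    model = find_gene(models, chrom, pos1)
    if model is None:
        return None, "intergenic", None
    if len(ref) == 1 and len(alt) == 1:
        effect, change = snv_effect(model, reference, pos1, ref, alt)
    else:
        effect, change = indel_effect(model, reference, pos1, ref, alt)
    return model.gene, effect, change
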