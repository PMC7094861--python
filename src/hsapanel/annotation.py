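"""Effect annotation, driver classification and canine->human homology.

Drivers are classified against a curated catalog: activating hotspots
(PIK3CA, NRAS, PLCG1), loss-of-function lesions in the tumor suppressors
PTEN and TP53 (nonsense / frameshift / essential splice site), and TP53
missense changes as candidate drivers. Protein positions are mapped to the
human homolog through per-gene constant-offset segments (e.g. canine PLCG1
G797E is human G869E; canine PTEN D246 splice is human D268); PIK3CA, NRAS
and TP53 positions are written directly in human-identical coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import effects
from .dualpool_caller import ConsensusVariant
from .effects import ProteinChange
from .panel_model import GeneModel

DRIVER_STATUSES = ("activating", "inactivating", "candidate_driver", "VUS", "none")


@dataclass
class AnnotatedVariant(ConsensusVariant):
    gene: str | None = None
    effect: str | None = None
    protein_change: ProteinChange | None = None
    human_change: str | None = None
    driver_status: str = "none"


@dataclass
class DriverCatalog:
    activating_hotspots: dict[str, frozenset[str]]
    lof_driver_genes: frozenset[str]
    broad_missense_genes: frozenset[str]  # any missense counts as candidate driver

    @property
    def genes(self) -> frozenset[str]:
        return (frozenset(self.activating_hotspots) | self.lof_driver_genes
                | self.broad_missense_genes)


def default_driver_catalog() -> DriverCatalog:
    return DriverCatalog(
        activating_hotspots={
            "PIK3CA": frozenset({"H1047R", "G1049R", "N1044K", "C420R",
                                 "T1025A", "E726K", "D350G"}),
            "NRAS": frozenset({"Q61R", "E153K"}),
            "PLCG1": frozenset({"S273F", "G797E"}),
        },
        lof_driver_genes=frozenset({"PTEN", "TP53"}),
        broad_missense_genes=frozenset({"TP53"}),
    )


def write_driver_catalog(catalog: DriverCatalog, path) -> None:
    lines = ["gene\tchange\tstatus"]
    for gene, changes in sorted(catalog.activating_hotspots.items()):
        for change in sorted(changes):
            lines.append(f"{gene}\t{change}\tactivating")
    for gene in sorted(catalog.lof_driver_genes):
        lines.append(f"{gene}\t*LOF\tinactivating")
    for gene in sorted(catalog.broad_missense_genes):
        lines.append(f"{gene}\t*missense\tcandidate_driver")
    Path(path).write_text("\n".join(lines) + "\n")


def read_driver_catalog(path) -> DriverCatalog:
    hotspots: dict[str, set[str]] = {}
    lof, broad = set(), set()
    for line in Path(path).read_text().splitlines()[1:]:
        gene, change, status = line.split("\t")
        if status == "activating":
            hotspots.setdefault(gene, set()).add(change)
        elif status == "inactivating":
            lof.add(gene)
        elif status == "candidate_driver":
            broad.add(gene)
        else:
            raise ValueError(f"unknown driver status {status!r}")
    return DriverCatalog(
        activating_hotspots={g: frozenset(v) for g, v in hotspots.items()},
        lof_driver_genes=frozenset(lof), broad_missense_genes=frozenset(broad))


@dataclass
class HomologyTable:
    """Per-gene segments of constant canine->human protein-position offset."""

    segments: dict[str, list[tuple[int, int, int]]]  # gene -> [(start, end, offset)]

    def __post_init__(self):
        for gene, segs in self.segments.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{gene}: overlapping homology segments")


def default_homology_table() -> HomologyTable:
    return HomologyTable(segments={
        "PIK3CA": [(1, 1068, 0)],
        "NRAS": [(1, 189, 0)],
        "TP53": [(1, 393, 0)],
        "PTEN": [(1, 403, 22)],
        "PLCG1": [(1, 1290, 72)],
    })


def write_homology_table(table: HomologyTable, path) -> None:
    lines = ["gene\tcanine_start\tcanine_end\toffset"]
    for gene, segs in sorted(table.segments.items()):
        for s, e, off in segs:
            lines.append(f"{gene}\t{s}\t{e}\t{off}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_homology_table(path) -> HomologyTable:
    segments: dict[str, list[tuple[int, int, int]]] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        gene, s, e, off = line.split("\t")
        segments.setdefault(gene, []).append((int(s), int(e), int(off)))
    return HomologyTable(segments=segments)


def map_to_human(gene: str, canine_pos: int, table: HomologyTable) -> int | None:
    """Human protein position homologous to a canine position, or None."""
    for s, e, off in table.segments.get(gene, []):
        if s <= canine_pos <= e:
            return canine_pos + off
    return None


def human_notation(change: ProteinChange, human_pos: int) -> str:
    return str(ProteinChange(position=human_pos, kind=change.kind,
                             ref_aa=change.ref_aa, alt_aa=change.alt_aa))


def annotate_variant(v: ConsensusVariant, gene_models: dict[str, GeneModel],
                     reference: dict[str, str],
                     homology: HomologyTable | None = None) -> AnnotatedVariant:
    """Assign gene, effect class and protein change to a consensus variant."""
    gene, effect, change = effects.variant_effect(
        gene_models, reference, v.chrom, v.pos, v.ref, v.alt)
    human = None
    if change is not None and homology is not None and gene is not None:
        hpos = map_to_human(gene, change.position, homology)
        if hpos is not None:
            human = human_notation(change, hpos)
    return AnnotatedVariant(
        sample_id=v.sample_id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
        pool_evidence=dict(v.pool_evidence), called_pools=v.called_pools,
        filter_flags=set(v.filter_flags), gene=gene, effect=effect,
        protein_change=change, human_change=human)


def classify_driver(v: AnnotatedVariant, catalog: DriverCatalog) -> str:
    """Driver status of an annotated variant against the catalog."""
    if v.gene is None or v.gene not in catalog.genes:
        return "none"
    change = str(v.protein_change) if v.protein_change is not None else None
    if (change is not None
            and change in catalog.activating_hotspots.get(v.gene, frozenset())):
        return "activating"
    if v.gene in catalog.lof_driver_genes and v.effect in effects.LOF_EFFECTS:
        return "inactivating"
    if v.gene in catalog.broad_missense_genes and v.effect == "missense":
        return "candidate_driver"
    return "VUS"


def annotate_and_classify(variants: list[ConsensusVariant],
                          gene_models: dict[str, GeneModel],
                          reference: dict[str, str],
                          catalog: DriverCatalog | None = None,
                          homology: HomologyTable | None = None
                          ) -> list[AnnotatedVariant]:
    catalog = catalog or default_driver_catalog()
    homology = homology or default_homology_table()
    out = []
    for v in variants:
        av = annotate_variant(v, gene_models, reference, homology)
        av.driver_status = classify_driver(av, catalog)
        out.append(av)
    return out
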