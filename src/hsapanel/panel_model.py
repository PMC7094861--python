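"""Dual-pool amplicon panel and gene models.

The panel targets a set of genes with two mirrored amplicon pools ("A" and
"B") that convert opposite template strands to library. A true variant is
seen by both pools; a single-strand lesion (e.g. FFPE cytidine deamination)
is seen by only the pool whose template strand carries the damage. All
downstream artifact suppression rests on the panel invariant checked here:
every targeted base is covered by both pools with opposite template strands.

Coordinate conventions: genomic intervals are 0-based half-open (BED);
variant positions are 1-based (VCF). Conversion is centralised in
:func:`bed_to_vcf_pos` / :func:`vcf_to_bed_pos`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

POOLS = ("A", "B")
STRANDS = ("+", "-")


class PanelError(ValueError):
    """Malformed or internally inconsistent panel definition."""


def bed_to_vcf_pos(start0: int) -> int:
    """0-based interval start -> 1-based variant position."""
    return start0 + 1


def vcf_to_bed_pos(pos1: int) -> int:
    """1-based variant position -> 0-based coordinate."""
    return pos1 - 1


def merge_intervals(intervals):
    """Merge a list of 0-based half-open (start, end) tuples."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_size(region: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for ivls in region.values() for s, e in ivls)


def intersect_size(a: dict, b: dict) -> int:
    total = 0
    for chrom in set(a) & set(b):
        for s1, e1 in a[chrom]:
            for s2, e2 in b[chrom]:
                total += max(0, min(e1, e2) - max(s1, s2))
    return total


@dataclass(frozen=True)
class Amplicon:
    amplicon_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    pool: str
    template_strand: str
    gene: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise PanelError(
                f"amplicon {self.amplicon_id}: end ({self.end}) <= start ({self.start})")
        if self.pool not in POOLS:
            raise PanelError(f"amplicon {self.amplicon_id}: pool must be A or B, got {self.pool!r}")
        if self.template_strand not in STRANDS:
            raise PanelError(
                f"amplicon {self.amplicon_id}: strand must be + or -, got {self.template_strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneTarget:
    gene: str
    mode: str = "full_coding"  # or "hotspot"
    hotspot_positions: list[int] | None = None

    def __post_init__(self):
        if self.mode not in ("full_coding", "hotspot"):
            raise PanelError(f"gene {self.gene}: unknown mode {self.mode!r}")
        if self.mode == "hotspot" and not self.hotspot_positions:
            raise PanelError(f"gene {self.gene}: hotspot mode requires hotspot_positions")
        if self.mode == "full_coding" and self.hotspot_positions:
            raise PanelError(f"gene {self.gene}: full_coding mode forbids hotspot_positions")


@dataclass
class GeneModel:
    """Single-transcript coding gene model used for effect annotation.

    ``cds_intervals`` are 0-based half-open genomic intervals in ascending
    genomic order; the total CDS length includes the stop codon, so
    ``protein_length == cds_length // 3 - 1``.
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    protein_length: int
    splice_window: int = 2
    tx_start: int | None = None
    tx_end: int | None = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise PanelError(f"gene {self.gene}: bad strand {self.strand!r}")
        ivls = [tuple(i) for i in self.cds_intervals]
        if ivls != sorted(ivls):
            raise PanelError(f"gene {self.gene}: CDS intervals not sorted")
        for (s1, e1), (s2, e2) in zip(ivls, ivls[1:]):
            if s2 < e1:
                raise PanelError(f"gene {self.gene}: overlapping CDS intervals")
        for s, e in ivls:
            if e <= s:
                raise PanelError(f"gene {self.gene}: empty CDS interval ({s},{e})")
        self.cds_intervals = ivls
        if self.cds_length % 3 != 0:
            raise PanelError(f"gene {self.gene}: CDS length {self.cds_length} not divisible by 3")
        if self.protein_length != self.cds_length // 3 - 1:
            raise PanelError(
                f"gene {self.gene}: protein_length {self.protein_length} != "
                f"CDS/3 - 1 = {self.cds_length // 3 - 1}")
        if self.tx_start is None:
            self.tx_start = self.cds_intervals[0][0] - 200
        if self.tx_end is None:
            self.tx_end = self.cds_intervals[-1][1] + 200
        self._cds_pos: np.ndarray | None = None
        self._cds_index: dict[int, int] | None = None

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_positions(self) -> np.ndarray:
        """Genomic 0-based positions of CDS bases in transcript order."""
        if self._cds_pos is None:
            fwd = np.concatenate([np.arange(s, e) for s, e in self.cds_intervals])
            self._cds_pos = fwd if self.strand == "+" else fwd[::-1]
        return self._cds_pos

    def cds_index(self, gpos0: int) -> int | None:
        """Transcript-order CDS index of a genomic position, or None."""
        if self._cds_index is None:
            self._cds_index = {int(g): i for i, g in enumerate(self.cds_positions())}
        return self._cds_index.get(int(gpos0))

    def codon_of(self, gpos0: int) -> int | None:
        """1-based codon index containing a genomic CDS position."""
        i = self.cds_index(gpos0)
        return None if i is None else i // 3 + 1


@dataclass
class PanelDesign:
    panel_id: str
    genes: list[GeneTarget]
    amplicons: list[Amplicon]
    target_region: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    desired_region: dict[str, list[tuple[int, int]]] | None = None
    # Optional payload for synthetic panels so simulation/annotation can run
    # without external reference files.
    reference: dict[str, str] | None = None
    gene_models: dict[str, GeneModel] | None = None

    def __post_init__(self):
        if not self.target_region:
            self.target_region = self._union()
        self.validate()

    def _union(self):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for a in self.amplicons:
            by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
        return {c: merge_intervals(v) for c, v in sorted(by_chrom.items())}

    def validate(self):
        ids = [a.amplicon_id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate amplicon ids: {dup}")
        declared = {g.gene for g in self.genes}
        for a in self.amplicons:
            if a.gene and a.gene not in declared:
                raise PanelError(
                    f"amplicon {a.amplicon_id} assigned to undeclared gene {a.gene!r}")
        # mirrored amplicons on the same interval must flip template strand
        seen: dict[tuple, Amplicon] = {}
        for a in self.amplicons:
            key = (a.chrom, a.start, a.end)
            other = seen.get(key)
            if other is not None and other.pool != a.pool:
                if other.template_strand == a.template_strand:
                    raise PanelError(
                        f"amplicons {other.amplicon_id}/{a.amplicon_id} share an interval "
                        "across pools but have the same template strand")
            seen.setdefault(key, a)
        # union of amplicons must contain target_region
        union = self._union()
        if intersect_size(union, self.target_region) != union_size(self.target_region):
            raise PanelError("target_region extends outside the amplicon union")

    @property
    def target_bp(self) -> int:
        return union_size(self.target_region)

    def target_positions(self, chrom: str) -> np.ndarray:
        """Sorted 0-based target positions on one chromosome."""
        ivls = self.target_region.get(chrom, [])
        if not ivls:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in ivls])

    def chroms(self):
        return sorted(self.target_region)


@dataclass
class ValidationReport:
    """Per-base dual-pool coverage audit (report-only, never raises)."""

    single_pool_bases: dict[str, np.ndarray]
    same_strand_bases: dict[str, np.ndarray]

    @property
    def n_single_pool(self) -> int:
        return sum(len(v) for v in self.single_pool_bases.values())

    @property
    def ok(self) -> bool:
        return self.n_single_pool == 0 and not any(
            len(v) for v in self.same_strand_bases.values())


def load_panel(manifest_path, bed_path) -> PanelDesign:
    """Load a panel from a BED of amplicon intervals plus a YAML/JSON manifest.

    BED columns: chrom, start, end, amplicon_id. The manifest supplies
    panel_id, the gene list, and per-amplicon pool/strand/gene assignments.
    """
    intervals: dict[str, tuple[str, int, int]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise PanelError(f"{bed_path}: line {lineno}: expected >=4 BED columns")
            chrom, s, e, amp_id = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise PanelError(f"{bed_path}: line {lineno}: non-integer coordinates") from None
            if end <= start:
                raise PanelError(f"{bed_path}: line {lineno}: end <= start")
            if amp_id in intervals:
                raise PanelError(f"{bed_path}: line {lineno}: duplicate amplicon id {amp_id!r}")
            intervals[amp_id] = (chrom, start, end)

    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    genes = [GeneTarget(gene=g["gene"], mode=g.get("mode", "full_coding"),
                        hotspot_positions=g.get("hotspot_positions"))
             for g in manifest.get("genes", [])]
    amp_meta = manifest.get("amplicons", {})
    missing = sorted(set(intervals) - set(amp_meta))
    if missing:
        raise PanelError(f"amplicons in BED but not in manifest: {missing}")
    extra = sorted(set(amp_meta) - set(intervals))
    if extra:
        raise PanelError(f"amplicons in manifest but not in BED: {extra}")
    amplicons = []
    for amp_id, (chrom, start, end) in sorted(intervals.items()):
        meta = amp_meta[amp_id]
        amplicons.append(Amplicon(
            amplicon_id=amp_id, chrom=chrom, start=start, end=end,
            pool=str(meta["pool"]), template_strand=str(meta["strand"]),
            gene=str(meta.get("gene", ""))))
    desired = None
    if "desired_region" in manifest:
        desired = {}
        for chrom, s, e in manifest["desired_region"]:
            desired.setdefault(chrom, []).append((int(s), int(e)))
        desired = {c: merge_intervals(v) for c, v in desired.items()}
    return PanelDesign(panel_id=str(manifest.get("panel_id", "panel")),
                       genes=genes, amplicons=amplicons, desired_region=desired)


def write_panel(panel: PanelDesign, manifest_path, bed_path) -> None:
    with open(bed_path, "w") as fh:
        for a in sorted(panel.amplicons, key=lambda a: (a.chrom, a.start, a.amplicon_id)):
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.amplicon_id}\n")
    manifest = {
        "panel_id": panel.panel_id,
        "genes": [{"gene": g.gene, "mode": g.mode,
                   **({"hotspot_positions": g.hotspot_positions}
                      if g.hotspot_positions else {})}
                  for g in panel.genes],
        "amplicons": {a.amplicon_id: {"pool": a.pool, "strand": a.template_strand,
                                      "gene": a.gene}
                      for a in panel.amplicons},
    }
    if panel.desired_region:
        manifest["desired_region"] = [
            [c, s, e] for c, ivls in sorted(panel.desired_region.items()) for s, e in ivls]
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def validate_dual_pool(panel: PanelDesign) -> ValidationReport:
    """Audit every target base for coverage by both pools on opposite strands."""
    single: dict[str, np.ndarray] = {}
    same: dict[str, np.ndarray] = {}
    for chrom in panel.chroms():
        pos = panel.target_positions(chrom)
        if len(pos) == 0:
            continue
        lo, hi = int(pos[0]), int(pos[-1]) + 1
        cov = {p: np.zeros(hi - lo, dtype=bool) for p in POOLS}
        strands = {p: np.full(hi - lo, " ", dtype="U1") for p in POOLS}
        mixed = np.zeros(hi - lo, dtype=bool)
        for a in panel.amplicons:
            if a.chrom != chrom:
                continue
            s, e = max(a.start, lo) - lo, min(a.end, hi) - lo
            if e <= s:
                continue
            sl = slice(s, e)
            prev = strands[a.pool][sl]
            mixed[sl] |= cov[a.pool][sl] & (prev != a.template_strand)
            cov[a.pool][sl] = True
            strands[a.pool][sl] = a.template_strand
        idx = pos - lo
        dual = cov["A"][idx] & cov["B"][idx]
        single[chrom] = pos[~dual]
        opp = dual & (strands["A"][idx] == strands["B"][idx])
        same[chrom] = pos[opp | mixed[idx]]
    return ValidationReport(single_pool_bases=single, same_strand_bases=same)


def target_stats(panel: PanelDesign, desired_region=None) -> dict:
    """Panel summary: amplicon count, mean length, merged target size, and the
    fraction of the desired region covered by the target."""
    desired = desired_region if desired_region is not None else panel.desired_region
    n = len(panel.amplicons)
    mean_len = float(np.mean([a.length for a in panel.amplicons])) if n else 0.0
    stats = {
        "n_amplicons": n,
        "mean_length": mean_len,
        "target_bp": panel.target_bp,
        "desired_missing": desired is None,
    }
    if desired is None:
        stats["fraction_desired_covered"] = 1.0
    else:
        want = union_size(desired)
        have = intersect_size(desired, panel.target_region)
        stats["fraction_desired_covered"] = have / want if want else 1.0
    return stats


# --- gene-model JSON IO ---------------------------------------------------

def gene_models_to_json(models: dict[str, GeneModel], path) -> None:
    payload = {
        name: {
            "gene": m.gene, "chrom": m.chrom, "strand": m.strand,
            "cds_intervals": [[s, e] for s, e in m.cds_intervals],
            "protein_length": m.protein_length,
            "splice_window": m.splice_window,
            "tx_start": m.tx_start, "tx_end": m.tx_end,
        }
        for name, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def gene_models_from_json(path) -> dict[str, GeneModel]:
    payload = json.loads(Path(path).read_text())
    return {
        name: GeneModel(
            gene=d["gene"], chrom=d["chrom"], strand=d["strand"],
            cds_intervals=[tuple(i) for i in d["cds_intervals"]],
            protein_length=d["protein_length"],
            splice_window=d.get("splice_window", 2),
            tx_start=d.get("tx_start"), tx_end=d.get("tx_end"))
        for name, d in payload.items()
    }
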