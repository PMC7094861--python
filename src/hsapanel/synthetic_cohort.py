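"""Synthetic FFPE tumor/normal cohort with known truth.

Emulates the observable features of a dual-pool amplicon experiment on
formalin-fixed tissue:

* per-pool sequencing depth ~ negative binomial (mean 700 reads/pool with
  low dispersion, so cumulative coverage averages well over 1000X);
* true somatic and germline alt reads drawn binomially at the variant's
  allele fraction, independently in each pool;
* FFPE cytidine-deamination artifacts: low-fraction C>T changes confined to
  the pool whose template strand carries the damaged cytosine (G>A in
  reference orientation when the damaged strand is "-");
* uniform per-read base-call errors.

Cohort composition follows the published subtype proportions
(PI3K pathway 52%, NRAS 24%, TP53-only 12%, PLCG1 4%, none 8%), with the
PI3K group split between PIK3CA-activating and PTEN-inactivating lesions
and frequent TP53 co-lesions. Every case carries a known truth record, so
downstream calling, filtering, annotation and subtyping are testable
without external data.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import effects
from .panel_model import GeneModel, PanelDesign
from .synthetic_panel import (LESIONS, PIK3CA_HOTSPOTS, PLCG1_HOTSPOTS, PTEN_LESIONS,
                              TP53_LOF, TP53_MISSENSE, build_default_panel,
                              lesion_variant)

SUBTYPES = ("PI3K_pathway", "NRAS", "TP53_only", "PLCG1", "NONE")
VAR_CLASSES = ("somatic_driver", "somatic_passenger", "artifact", "germline")

DEFAULT_PROPORTIONS = {"PI3K_pathway": 0.52, "NRAS": 0.24, "TP53_only": 0.12,
                       "PLCG1": 0.04, "NONE": 0.08}


@dataclass
class SimConfig:
    """Cohort simulation conditions (defaults are the study conditions)."""

    n_cases: int = 50
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    vaf_range: tuple[float, float] = (0.05, 0.40)
    low_vaf_range: tuple[float, float] = (0.06, 0.17)
    low_vaf_fraction: float = 0.3       # drivers drawn in the low-AF validation band
    depth_mean_per_pool: float = 700.0
    depth_dispersion: float = 100.0     # negative-binomial size parameter
    base_error_rate: float = 1e-3
    artifact_site_rate: float = 0.02    # fraction of eligible C:G sites damaged
    artifact_vaf_range: tuple[float, float] = (0.01, 0.08)
    n_normals: int = 30
    n_passengers: int = 3
    n_germline_per_case: int = 5
    germline_pool_size: int = 12        # segregating polymorphisms in the population
    pten_fraction: float = 3 / 26       # PTEN share within the PI3K-pathway group
    tp53_co_lesion_pi3k: float = 0.9
    tp53_co_lesion_nras: float = 1 / 6
    tp53_co_lesion_plcg1: float = 0.5
    nras_e153k_fraction: float = 1 / 12
    tp53_missense_fraction: float = 0.6
    mt_duplicates: int = 0              # paired metastatic duplicates to emit
    seed: int = 0

    def __post_init__(self):
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, not 1")
        for name in self.subtype_proportions:
            if name not in SUBTYPES:
                raise ValueError(f"unknown subtype {name!r}")
        lo, hi = self.vaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"vaf_range {self.vaf_range} must satisfy 0 < lo <= hi < 1")
        for rate in (self.base_error_rate, self.artifact_site_rate, self.low_vaf_fraction):
            if not (0 <= rate <= 1):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.depth_mean_per_pool <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("vaf_range", "low_vaf_range", "artifact_vaf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {**self.__dict__}
        for key in ("vaf_range", "low_vaf_range", "artifact_vaf_range"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthVariant:
    gene: str | None
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    protein_change: str | None
    vaf: float
    var_class: str      # somatic_driver | somatic_passenger | artifact | germline
    damaged_strand: str | None = None  # artifacts only

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CaseTruth:
    case_id: str
    true_subtype: str
    variants: list[TruthVariant]
    tissue: str = "PT"

    def __post_init__(self):
        for v in self.variants:
            if v.var_class == "artifact" and v.damaged_strand not in ("+", "-"):
                raise ValueError(f"{self.case_id}: artifact without damaged strand")
        if self.true_subtype == "NONE" and any(
                v.var_class == "somatic_driver" for v in self.variants):
            raise ValueError(f"{self.case_id}: NONE case carries a driver")

    def of_class(self, var_class: str) -> list[TruthVariant]:
        return [v for v in self.variants if v.var_class == var_class]


@dataclass(eq=False)
class SiteCounts:
    """Per-pool, per-site allele read counts (pileup-style caller input).

    ``df`` columns: chrom, pos (1-based), ref, A, C, G, T, depth; indel
    alleles live in ``indels`` keyed (chrom, pos) -> {"REF>ALT": count}.
    Depth equals the sum of all allele counts at a site.
    """

    sample_id: str
    pool: str
    df: pd.DataFrame
    indels: dict[tuple[str, int], dict[str, int]] = field(default_factory=dict)

    def equals(self, other: "SiteCounts") -> bool:
        return (self.sample_id == other.sample_id and self.pool == other.pool
                and self.df.equals(other.df) and self.indels == other.indels)


# --------------------------------------------------------------------------
# cohort truth generation
# --------------------------------------------------------------------------

def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Apportion n into integer counts that sum to n exactly."""
    items = sorted(proportions.items())
    quotas = [(name, n * p) for name, p in items]
    counts = {name: int(np.floor(q)) for name, q in quotas}
    short = n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda t: (-(t[1] - np.floor(t[1])), t[0]))
    for name, _ in by_remainder[:short]:
        counts[name] += 1
    return counts


def _case_rng(seed: int, case_id: str, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(case_id.encode()), stream])


def _draw_vaf(rng, config: SimConfig) -> float:
    lo, hi = (config.low_vaf_range if rng.random() < config.low_vaf_fraction
              else config.vaf_range)
    return float(rng.uniform(lo, hi))


def _driver(name: str, panel: PanelDesign, rng, config: SimConfig) -> TruthVariant:
    chrom, pos, ref, alt, change = lesion_variant(name, panel)
    return TruthVariant(gene=LESIONS[name].gene, chrom=chrom, pos=pos, ref=ref,
                        alt=alt, protein_change=change, vaf=_draw_vaf(rng, config),
                        var_class="somatic_driver")


def _tp53_lesion(rng, config: SimConfig) -> str:
    menu = (TP53_MISSENSE if rng.random() < config.tp53_missense_fraction else TP53_LOF)
    return menu[rng.integers(len(menu))]


def _subtype_drivers(subtype: str, panel: PanelDesign, rng,
                     config: SimConfig) -> list[TruthVariant]:
    names: list[str] = []
    if subtype == "PI3K_pathway":
        if rng.random() < config.pten_fraction:
            names.append(PTEN_LESIONS[rng.integers(len(PTEN_LESIONS))])
        else:
            names.append(PIK3CA_HOTSPOTS[rng.integers(len(PIK3CA_HOTSPOTS))])
        if rng.random() < config.tp53_co_lesion_pi3k:
            names.append(_tp53_lesion(rng, config))
    elif subtype == "NRAS":
        names.append("NRAS:E153K" if rng.random() < config.nras_e153k_fraction
                     else "NRAS:Q61R")
        if rng.random() < config.tp53_co_lesion_nras:
            names.append(_tp53_lesion(rng, config))
    elif subtype == "PLCG1":
        names.append(PLCG1_HOTSPOTS[rng.integers(len(PLCG1_HOTSPOTS))])
        if rng.random() < config.tp53_co_lesion_plcg1:
            names.append(_tp53_lesion(rng, config))
    elif subtype == "TP53_only":
        names.append(_tp53_lesion(rng, config))
    return [_driver(name, panel, rng, config) for name in names]


_SITE_CACHE: dict[int, dict] = {}


def _chrom_sites(panel: PanelDesign, chrom: str):
    """(pos0 array, ref array, pos->index dict) for one chromosome, cached."""
    cache = _SITE_CACHE.setdefault(id(panel), {})
    if chrom not in cache:
        pos = panel.target_positions(chrom)
        seq = panel.reference[chrom]
        refs = np.array([seq[int(p)] for p in pos], dtype="U1")
        cache[chrom] = (pos, refs, {int(p): i for i, p in enumerate(pos)})
    return cache[chrom]


def _all_target_sites(panel: PanelDesign):
    """(chrom, pos0, ref) arrays concatenated across the target."""
    chroms, positions, refs = [], [], []
    for chrom in panel.chroms():
        pos, ref, _ = _chrom_sites(panel, chrom)
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
        refs.append(ref)
    return (np.concatenate(chroms), np.concatenate(positions), np.concatenate(refs))


def _lesion_positions(panel: PanelDesign) -> set[tuple[str, int]]:
    out = set()
    for name in LESIONS:
        chrom, pos, ref, _alt, _change = lesion_variant(name, panel)
        out.update((chrom, pos + k) for k in range(len(ref)))
    return out


def _random_snv(rng, ref: str) -> str:
    alts = [b for b in "ACGT" if b != ref]
    return alts[rng.integers(3)]


def _passenger(panel: PanelDesign, rng, config: SimConfig,
               used: set, forbidden: set) -> TruthVariant:
    """Random coding SNV that does not meet the driver definition."""
    cds_sites = _cds_sites(panel)
    for _ in range(200):
        i = int(rng.integers(len(cds_sites[0])))
        gene, chrom, pos0 = cds_sites[0][i], cds_sites[1][i], int(cds_sites[2][i])
        pos1 = pos0 + 1
        if (chrom, pos1) in used or (chrom, pos1) in forbidden:
            continue
        model = panel.gene_models[gene]
        ref = panel.reference[chrom][pos0]
        alt = _random_snv(rng, ref)
        effect, change = effects.snv_effect(model, panel.reference, pos1, ref, alt)
        if effect == "nonsense":
            continue
        if gene in ("PTEN", "TP53") and effect in effects.LOF_EFFECTS:
            continue
        if gene == "TP53" and effect == "missense":
            continue  # any nonsynonymous TP53 change is a driver by definition
        if f"{gene}:{change}" in LESIONS:
            continue
        return TruthVariant(gene=gene, chrom=chrom, pos=pos1, ref=ref, alt=alt,
                            protein_change=str(change) if change else None,
                            vaf=_draw_vaf(rng, config), var_class="somatic_passenger")
    raise RuntimeError("could not place a passenger variant")


_CDS_CACHE: dict[int, tuple] = {}


def _cds_sites(panel: PanelDesign):
    key = id(panel)
    if key not in _CDS_CACHE:
        genes, chroms, pos = [], [], []
        for gene, model in panel.gene_models.items():
            p = np.sort(model.cds_positions())
            genes.append(np.full(len(p), gene, dtype=object))
            chroms.append(np.full(len(p), model.chrom, dtype=object))
            pos.append(p)
        _CDS_CACHE[key] = (np.concatenate(genes), np.concatenate(chroms),
                           np.concatenate(pos))
    return _CDS_CACHE[key]


def _artifacts(panel: PanelDesign, rng, config: SimConfig,
               used: set) -> list[TruthVariant]:
    chroms, pos0, refs = _all_target_sites(panel)
    eligible = np.flatnonzero((refs == "C") | (refs == "G"))
    eligible = np.array([i for i in eligible
                         if (chroms[i], int(pos0[i]) + 1) not in used])
    n = rng.binomial(len(eligible), config.artifact_site_rate)
    picked = rng.choice(eligible, size=n, replace=False) if n else []
    lo, hi = config.artifact_vaf_range
    out = []
    for i in picked:
        ref = str(refs[i])
        damaged = "+" if ref == "C" else "-"
        out.append(TruthVariant(
            gene=None, chrom=str(chroms[i]), pos=int(pos0[i]) + 1, ref=ref,
            alt="T" if ref == "C" else "A", protein_change=None,
            vaf=float(rng.uniform(lo, hi)), var_class="artifact",
            damaged_strand=damaged))
    return out


def sample_cohort(config: SimConfig, panel: PanelDesign | None = None) -> list[CaseTruth]:
    """Draw a cohort truth: subtypes, drivers, passengers, germline, artifacts.

    Subtype counts are the deterministic largest-remainder apportionment of
    ``n_cases x proportions``; each case's variant content is drawn from a
    per-case RNG substream keyed by the case id, so results are reproducible
    and independent of iteration order.
    """
    panel = panel or build_default_panel()
    nonzero = [s for s, p in config.subtype_proportions.items() if p > 0]
    if config.n_cases < len(nonzero):
        raise ValueError(
            f"n_cases={config.n_cases} is fewer than the {len(nonzero)} subtype classes")
    counts = largest_remainder_counts(config.n_cases, config.subtype_proportions)
    labels = [s for s in sorted(counts, key=lambda s: (-counts[s], s))
              for _ in range(counts[s])]
    master = np.random.default_rng([config.seed, 0xC0C0])
    master.shuffle(labels)

    forbidden = _lesion_positions(panel)
    chroms, pos0, refs = _all_target_sites(panel)
    pool_idx = []
    while len(pool_idx) < config.germline_pool_size:
        i = int(master.integers(len(pos0)))
        if (chroms[i], int(pos0[i]) + 1) not in forbidden and i not in pool_idx:
            pool_idx.append(i)
    germline_pool = [
        TruthVariant(gene=None, chrom=str(chroms[i]), pos=int(pos0[i]) + 1,
                     ref=str(refs[i]), alt=_random_snv(master, str(refs[i])),
                     protein_change=None, vaf=0.5, var_class="germline")
        for i in pool_idx]

    cases: list[CaseTruth] = []
    for k, subtype in enumerate(labels, 1):
        case_id = f"C{k:03d}"
        rng = _case_rng(config.seed, case_id)
        variants = _subtype_drivers(subtype, panel, rng, config)
        used = {(v.chrom, v.pos) for v in variants}
        g_pick = rng.choice(len(germline_pool),
                            size=min(config.n_germline_per_case, len(germline_pool)),
                            replace=False)
        for i in sorted(g_pick):
            g = germline_pool[int(i)]
            if (g.chrom, g.pos) not in used:
                variants.append(g)
                used.add((g.chrom, g.pos))
        for _ in range(config.n_passengers):
            p = _passenger(panel, rng, config, used, forbidden)
            variants.append(p)
            used.add((p.chrom, p.pos))
        variants.extend(_artifacts(panel, rng, config, used))
        cases.append(CaseTruth(case_id=case_id, true_subtype=subtype,
                               variants=variants))

    for k in range(min(config.mt_duplicates, len(cases))):
        src = cases[k]
        mt_id = src.case_id + "-MT"
        rng = _case_rng(config.seed, mt_id)
        shared = [v for v in src.variants if v.var_class != "artifact"]
        used = {(v.chrom, v.pos) for v in shared}
        cases.append(CaseTruth(
            case_id=mt_id, true_subtype=src.true_subtype, tissue="MT",
            variants=shared + _artifacts(panel, rng, config, used)))
    return cases


# --------------------------------------------------------------------------
# read-count simulation
# --------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_OTHERS = {b: [j for c, j in _BASE_IDX.items() if c != b] for b in _BASE_IDX}


def _pool_strand(panel: PanelDesign, pool: str, chrom: str, pos0: int) -> str | None:
    for a in panel.amplicons:
        if a.pool == pool and a.chrom == chrom and a.start <= pos0 < a.end:
            return a.template_strand
    return None


def _simulate_pool(sample_id: str, pool: str, variants, panel: PanelDesign,
                   config: SimConfig, rng) -> SiteCounts:
    frames, indels = [], {}
    mean, k = config.depth_mean_per_pool, config.depth_dispersion
    for chrom in panel.chroms():
        pos, refs, pos_to_idx = _chrom_sites(panel, chrom)
        npos = len(pos)
        seq = panel.reference[chrom]
        depth = rng.negative_binomial(k, k / (k + mean), size=npos).astype(np.int64)
        counts = np.zeros((npos, 4), dtype=np.int64)
        assigned = np.zeros(npos, dtype=np.int64)
        for v in variants:
            if v.chrom != chrom:
                continue
            i = pos_to_idx.get(v.pos - 1)
            if i is None:
                raise ValueError(f"{sample_id}: variant {chrom}:{v.pos} outside target")
            if seq[v.pos - 1: v.pos - 1 + len(v.ref)] != v.ref:
                raise ValueError(
                    f"{sample_id}: {chrom}:{v.pos} ref {v.ref!r} mismatches panel reference")
            if v.var_class == "artifact" and (
                    _pool_strand(panel, pool, chrom, v.pos - 1) != v.damaged_strand):
                continue  # the mirrored pool sees only base error at this site
            n = int(rng.binomial(depth[i], v.vaf))
            n = min(n, int(depth[i] - assigned[i]))
            if n <= 0:
                continue
            if len(v.ref) == 1 and len(v.alt) == 1:
                counts[i, _BASE_IDX[v.alt]] += n
            else:
                key = f"{v.ref}>{v.alt}"
                site = indels.setdefault((chrom, v.pos), {})
                site[key] = site.get(key, 0) + n
            assigned[i] += n
        if config.base_error_rate > 0:
            room = depth - assigned
            errs = rng.binomial(room, config.base_error_rate)
            e1 = rng.binomial(errs, 1 / 3)
            e2 = rng.binomial(errs - e1, 1 / 2)
            e3 = errs - e1 - e2
            for j, e in enumerate((e1, e2, e3)):
                for base, col in _BASE_IDX.items():
                    sel = refs == base
                    counts[sel, _OTHERS[base][j]] += e[sel]
            assigned += errs
        ref_cols = np.array([_BASE_IDX[b] for b in refs])
        counts[np.arange(npos), ref_cols] += depth - assigned
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos + 1, "ref": refs,
            "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3],
            "depth": depth}))
    df = pd.concat(frames, ignore_index=True)
    return SiteCounts(sample_id=sample_id, pool=pool, df=df, indels=indels)


def simulate_counts(case: CaseTruth, panel: PanelDesign,
                    config: SimConfig) -> tuple[SiteCounts, SiteCounts]:
    """Simulate dual-pool tumor allele counts for one case."""
    rng = _case_rng(config.seed, case.case_id, stream=1)
    a = _simulate_pool(case.case_id, "A", case.variants, panel, config, rng)
    b = _simulate_pool(case.case_id, "B", case.variants, panel, config, rng)
    return a, b


def simulate_normal_counts(case: CaseTruth, panel: PanelDesign,
                           config: SimConfig) -> tuple[SiteCounts, SiteCounts]:
    """Simulate the matched normal: germline variants plus fresh FFPE damage."""
    sample_id = case.case_id + "-N"
    rng = _case_rng(config.seed, sample_id, stream=2)
    germline = case.of_class("germline")
    used = {(v.chrom, v.pos) for v in germline}
    variants = germline + _artifacts(panel, rng, config, used)
    a = _simulate_pool(sample_id, "A", variants, panel, config, rng)
    b = _simulate_pool(sample_id, "B", variants, panel, config, rng)
    return a, b


# --------------------------------------------------------------------------
# truth / counts TSV IO
# --------------------------------------------------------------------------

_TRUTH_COLS = ["case_id", "tissue", "true_subtype", "gene", "chrom", "pos",
               "ref", "alt", "protein_change", "vaf", "var_class", "damaged_strand"]


def write_truth(case_truths: list[CaseTruth], path) -> None:
    rows = []
    for case in case_truths:
        if not case.variants:
            rows.append({"case_id": case.case_id, "tissue": case.tissue,
                         "true_subtype": case.true_subtype, "gene": ".",
                         "chrom": ".", "pos": 0, "ref": ".", "alt": ".",
                         "protein_change": ".", "vaf": 0.0,
                         "var_class": "__empty__", "damaged_strand": "."})
        for v in case.variants:
            rows.append({"case_id": case.case_id, "tissue": case.tissue,
                         "true_subtype": case.true_subtype,
                         "gene": v.gene or ".", "chrom": v.chrom, "pos": v.pos,
                         "ref": v.ref, "alt": v.alt,
                         "protein_change": v.protein_change or ".",
                         "vaf": repr(v.vaf), "var_class": v.var_class,
                         "damaged_strand": v.damaged_strand or "."})
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[CaseTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TRUTH_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"truth file missing columns: {missing}")
    cases: dict[str, CaseTruth] = {}
    for row in df.itertuples():
        case = cases.get(row.case_id)
        if case is None:
            case = CaseTruth(case_id=row.case_id, true_subtype=row.true_subtype,
                             tissue=row.tissue, variants=[])
            cases[row.case_id] = case
        if row.var_class == "__empty__":
            continue
        case.variants.append(TruthVariant(
            gene=None if row.gene == "." else row.gene,
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            protein_change=None if row.protein_change == "." else row.protein_change,
            vaf=float(row.vaf), var_class=row.var_class,
            damaged_strand=None if row.damaged_strand == "." else row.damaged_strand))
    return list(cases.values())


def write_counts(counts: SiteCounts, path) -> None:
    df = counts.df.copy()
    df.insert(0, "sample", counts.sample_id)
    df.insert(1, "pool", counts.pool)
    ser = []
    for row in counts.df.itertuples():
        alleles = counts.indels.get((row.chrom, int(row.pos)))
        ser.append(";".join(f"{k}:{n}" for k, n in sorted(alleles.items()))
                   if alleles else ".")
    df["indels"] = ser
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> SiteCounts:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "indels": str},
                     keep_default_na=False)
    sample = str(df["sample"].iloc[0])
    pool = str(df["pool"].iloc[0])
    indels = {}
    for row in df.itertuples():
        if row.indels and row.indels != ".":
            indels[(row.chrom, int(row.pos))] = {
                k: int(n) for k, n in
                (item.split(":") for item in row.indels.split(";"))}
    core = df[["chrom", "pos", "ref", "A", "C", "G", "T", "depth"]].reset_index(drop=True)
    return SiteCounts(sample_id=sample, pool=pool, df=core, indels=indels)
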