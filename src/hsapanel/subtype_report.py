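"""Mutually exclusive molecular subtype assignment and cohort summary.

Each case is collapsed onto one of five subtypes from its PASS driver
variants: PI3K_pathway (PIK3CA activating or PTEN inactivating — both
elevate PI3K signaling), NRAS, PLCG1, TP53_only, or NONE. The observed
patterns are mutually exclusive in real cohorts, so the precedence order
only matters for out-of-distribution inputs and any multi-class case is
flagged ``conflict`` rather than silently resolved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotatedVariant

SUBTYPE_ORDER = ("PI3K_pathway", "NRAS", "PLCG1", "TP53_only", "NONE")
DRIVER_STATUSES = frozenset({"activating", "inactivating", "candidate_driver"})


@dataclass
class CaseProfile:
    case_id: str
    driver_variants: list[AnnotatedVariant]
    tissue: str = "PT"

    def __post_init__(self):
        bad = [v for v in self.driver_variants if v.driver_status not in DRIVER_STATUSES]
        if bad:
            raise ValueError(f"{self.case_id}: non-driver variants in profile")

    @property
    def genes_hit(self) -> set[str]:
        return {v.gene for v in self.driver_variants}


@dataclass
class SubtypeCall:
    case_id: str
    subtype: str
    conflict: bool = False
    evidence: list[tuple] = field(default_factory=list)


@dataclass
class CohortSummary:
    n_cases: int
    counts: dict[str, int]
    percents: dict[str, float]
    informative_rate: float  # percent of cases with at least one driver
    gene_case_counts: dict[str, int]


def _has(profile: CaseProfile, gene: str, statuses) -> bool:
    return any(v.gene == gene and v.driver_status in statuses
               for v in profile.driver_variants)


def assign_subtype(profile: CaseProfile) -> SubtypeCall:
    """Collapse a case's drivers to one subtype, flagging multi-class cases."""
    pi3k = (_has(profile, "PIK3CA", {"activating"})
            or _has(profile, "PTEN", {"inactivating"}))
    nras = _has(profile, "NRAS", {"activating"})
    plcg1 = _has(profile, "PLCG1", {"activating"})
    tp53 = _has(profile, "TP53", DRIVER_STATUSES)
    if pi3k:
        subtype = "PI3K_pathway"
    elif nras:
        subtype = "NRAS"
    elif plcg1:
        subtype = "PLCG1"
    elif tp53:
        subtype = "TP53_only"
    else:
        subtype = "NONE"
    return SubtypeCall(
        case_id=profile.case_id, subtype=subtype,
        conflict=sum([pi3k, nras, plcg1]) > 1,
        evidence=[v.key for v in profile.driver_variants])


def _largest_remainder_percents(counts: dict[str, int], n: int) -> dict[str, float]:
    """Percents to one decimal, reconciled so the printed values sum to 100.0."""
    if n == 0:
        return {k: 0.0 for k in counts}
    raw = {k: 1000 * c / n for k, c in counts.items()}  # tenths of a percent
    floors = {k: int(v) for k, v in raw.items()}
    short = 1000 - sum(floors.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - floors[k]), k))
    for k in order[:short]:
        floors[k] += 1
    return {k: floors[k] / 10 for k in counts}


def summarize_cohort(calls: list[SubtypeCall],
                     profiles: list[CaseProfile]) -> CohortSummary:
    """Cohort frequency table over primary cases (MT duplicates excluded)."""
    primaries = [p for p in profiles if p.tissue != "MT"]
    primary_ids = [p.case_id for p in primaries]
    if len(primary_ids) != len(set(primary_ids)):
        dup = sorted({i for i in primary_ids if primary_ids.count(i) > 1})
        raise ValueError(f"duplicate case ids among primaries: {dup}")
    call_by_id = {c.case_id: c for c in calls}
    n = len(primaries)
    counts = {s: 0 for s in SUBTYPE_ORDER}
    gene_counts: dict[str, int] = {}
    for p in primaries:
        counts[call_by_id[p.case_id].subtype] += 1
        for gene in p.genes_hit:
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
    percents = _largest_remainder_percents(counts, n)
    # defined as the complement of the printed NONE percent so that
    # informative_rate + NONE% == 100 exactly, rounding included
    informative = 100.0 - percents["NONE"] if n else 0.0
    return CohortSummary(
        n_cases=n, counts=counts, percents=percents,
        informative_rate=informative,
        gene_case_counts=dict(sorted(gene_counts.items())))


def write_oncoprint(profiles: list[CaseProfile], calls: list[SubtypeCall],
                    path) -> None:
    """Gene x case TSV matrix; cells are missense, lof, both or '.'.

    Columns are sorted by subtype (fixed order) then case id.
    """
    call_by_id = {c.case_id: c.subtype for c in calls}
    cols = sorted((p.case_id for p in profiles),
                  key=lambda cid: (SUBTYPE_ORDER.index(call_by_id[cid]), cid))
    genes = sorted({g for p in profiles for g in p.genes_hit})
    cells = {cid: {} for cid in cols}
    for p in profiles:
        for v in p.driver_variants:
            kind = "lof" if v.effect in ("nonsense", "frameshift", "splice_site") \
                else "missense"
            prev = cells[p.case_id].get(v.gene)
            cells[p.case_id][v.gene] = kind if prev in (None, kind) else "both"
    lines = ["\t".join(["gene"] + cols)]
    for gene in genes:
        lines.append("\t".join([gene] + [cells[cid].get(gene, ".") for cid in cols]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_oncoprint(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
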