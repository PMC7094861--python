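"""The published 50-case cohort composition as a ready-made fixture.

Reconstructs the reported driver landscape of 50 canine hemangiosarcoma
cases — 23 with activating PIK3CA mutations, 3 with inactivating PTEN
lesions, 12 with activating NRAS, 2 with activating PLCG1, 6 with TP53
mutations only and 4 with no detected driver; TP53 lesions co-occur in 33
cases total — and runs driver classification, subtype assignment and the
cohort summary on it. The headline numbers this reproduces: subtypes
26/12/6/2/4 (52/24/12/4/8%), PIK3CA in 46% of cases, TP53 in 66%, and an
informative rate of 92% (46/50).
"""
from __future__ import annotations

from itertools import cycle

from .annotation import (AnnotatedVariant, classify_driver, default_driver_catalog,
                         default_homology_table, human_notation, map_to_human)
from .effects import effect_of_change, parse_protein_change
from .subtype_report import (CaseProfile, CohortSummary, SubtypeCall, assign_subtype,
                             summarize_cohort)

# (primary lesion gene, protein changes cycled over the group's cases,
#  n cases, n of them with a TP53 co-lesion)
_COMPOSITION = [
    ("PIK3CA", ["H1047R", "H1047R", "H1047R", "E726K", "E726K", "G1049R",
                "G1049R", "N1044K", "C420R", "T1025A", "D350G"], 23, 21),
    ("PTEN", ["T56fs", "D246_splice", "D246_splice"], 3, 3),
    ("NRAS", ["Q61R"] * 11 + ["E153K"], 12, 2),
    ("PLCG1", ["S273F", "G797E"], 2, 1),
    ("TP53", [], 6, 6),   # TP53-only group
    (None, [], 4, 0),     # no driver detected
]

_TP53_CHANGES = ["R248W", "R273H", "S241F", "R196*", "P152fs"]


def _stub(case_id: str, gene: str, change_text: str) -> AnnotatedVariant:
    """A classified driver variant record with nominal dual-pool evidence."""
    change = parse_protein_change(change_text)
    v = AnnotatedVariant(
        sample_id=case_id, chrom=gene, pos=change.position, ref="N", alt="V",
        pool_evidence={"A": (525, 52, 52 / 525), "B": (525, 52, 52 / 525)},
        called_pools=frozenset({"A", "B"}), filter_flags=set(),
        gene=gene, effect=effect_of_change(change), protein_change=change)
    v.driver_status = classify_driver(v, default_driver_catalog())
    hpos = map_to_human(gene, change.position, default_homology_table())
    if hpos is not None:
        v.human_change = human_notation(change, hpos)
    return v


def reported_cohort_profiles() -> list[CaseProfile]:
    """50 case profiles matching the printed cohort composition."""
    profiles = []
    tp53_cycle = cycle(_TP53_CHANGES)
    case_no = 0
    for gene, changes, n, n_tp53 in _COMPOSITION:
        change_cycle = cycle(changes) if changes else None
        for i in range(n):
            case_no += 1
            case_id = f"P{case_no:02d}"
            drivers = []
            if gene == "TP53":
                drivers.append(_stub(case_id, "TP53", next(tp53_cycle)))
            elif gene is not None:
                drivers.append(_stub(case_id, gene, next(change_cycle)))
                if i < n_tp53:
                    drivers.append(_stub(case_id, "TP53", next(tp53_cycle)))
            profiles.append(CaseProfile(case_id=case_id, driver_variants=drivers))
    return profiles


def reported_summary() -> tuple[CohortSummary, list[SubtypeCall], list[CaseProfile]]:
    """Assign subtypes and summarize the reported 50-case composition."""
    profiles = reported_cohort_profiles()
    calls = [assign_subtype(p) for p in profiles]
    return summarize_cohort(calls, profiles), calls, profiles
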