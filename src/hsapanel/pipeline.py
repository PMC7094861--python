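"""End-to-end orchestration: simulate -> call -> merge -> QC -> annotate ->
panel-of-normals subtraction -> subtype.

``run_cohort`` runs the whole procedure on a simulated cohort and returns
both the per-case results and diagnostics against the simulation truth, so
properties like artifact suppression and subtype recovery can be measured
directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from . import synthetic_cohort as sc
from .annotation import (AnnotatedVariant, DriverCatalog, HomologyTable,
                         annotate_and_classify, default_driver_catalog,
                         default_homology_table)
from .dualpool_caller import (DEFAULT_ALPHA, DEFAULT_BASE_ERROR_RATE,
                              DEFAULT_MIN_ALT_READS, ConsensusVariant, call_pool,
                              merge_pools)
from .panel_model import PanelDesign
from .subtype_report import (CaseProfile, SubtypeCall, assign_subtype,
                             summarize_cohort)
from .variant_filters import (PanelOfNormals, QCThresholds, apply_qc,
                              build_normal_set, filter_effect_classes,
                              subtract_normals)


@dataclass
class CallerSettings:
    min_alt_reads: int = DEFAULT_MIN_ALT_READS
    alpha: float = DEFAULT_ALPHA
    base_error_rate: float = DEFAULT_BASE_ERROR_RATE


def consensus_from_counts(counts_a, counts_b,
                          settings: CallerSettings = CallerSettings()
                          ) -> list[ConsensusVariant]:
    """Per-pool calling followed by the dual-pool cross-comparison merge."""
    calls_a = call_pool(counts_a, settings.min_alt_reads, settings.alpha,
                        settings.base_error_rate)
    calls_b = call_pool(counts_b, settings.min_alt_reads, settings.alpha,
                        settings.base_error_rate)
    return merge_pools(calls_a, calls_b, counts_a, counts_b)


def single_pool_consensus(counts_a,
                          settings: CallerSettings = CallerSettings()
                          ) -> list[ConsensusVariant]:
    """Deliberately crippled comparator: one pool only, no cross-comparison.

    Used to quantify what the dual-pool design buys: without the mirrored
    pool there is no ``single_pool`` gate, so strand-restricted artifacts
    with sufficient allele fraction sail through.
    """
    calls = call_pool(counts_a, settings.min_alt_reads, settings.alpha,
                      settings.base_error_rate)
    return merge_pools(calls, [], counts_a, counts_a)


SINGLE_POOL_THRESHOLDS = QCThresholds(min_cumulative_depth=500,
                                      min_mean_depth_per_pool=250)


def filter_and_annotate(consensus: list[ConsensusVariant], panel: PanelDesign,
                        pon: PanelOfNormals | None = None,
                        thresholds: QCThresholds = QCThresholds(),
                        catalog: DriverCatalog | None = None,
                        homology: HomologyTable | None = None,
                        gates=("both_pools", "depth", "vaf")
                        ) -> list[AnnotatedVariant]:
    """QC cascade, effect annotation/exclusion and PoN subtraction."""
    variants = apply_qc(consensus, thresholds, gates=gates)
    annotated = annotate_and_classify(variants, panel.gene_models, panel.reference,
                                      catalog, homology)
    annotated = filter_effect_classes(annotated)
    if pon is not None:
        annotated = subtract_normals(annotated, pon)
    return annotated


def build_pon(truths: list[sc.CaseTruth], panel: PanelDesign, config: sc.SimConfig,
              thresholds: QCThresholds = QCThresholds(),
              settings: CallerSettings = CallerSettings()) -> PanelOfNormals:
    """Sequence the matched normals of the first n_normals cases and pool
    their PASS variants."""
    normals = []
    primaries = [t for t in truths if t.tissue != "MT"]
    for case in primaries[:config.n_normals]:
        na, nb = sc.simulate_normal_counts(case, panel, config)
        consensus = consensus_from_counts(na, nb, settings)
        normals.append(apply_qc(consensus, thresholds))
    return build_normal_set(normals)


def profile_from_variants(case_id: str, annotated: list[AnnotatedVariant],
                          tissue: str = "PT") -> CaseProfile:
    drivers = [v for v in annotated if v.status == "PASS"
               and v.driver_status in ("activating", "inactivating", "candidate_driver")]
    return CaseProfile(case_id=case_id, driver_variants=drivers, tissue=tissue)


@dataclass
class CohortResult:
    truths: list[sc.CaseTruth]
    pon: PanelOfNormals
    annotated: dict[str, list[AnnotatedVariant]]
    profiles: list[CaseProfile]
    calls: list[SubtypeCall]
    summary: object
    diagnostics: dict = field(default_factory=dict)


def run_cohort(config: sc.SimConfig, panel: PanelDesign | None = None,
               thresholds: QCThresholds = QCThresholds(),
               settings: CallerSettings = CallerSettings()) -> CohortResult:
    """Simulate a cohort and run the full pipeline on every tumor sample."""
    panel = panel or sc.build_default_panel()
    truths = sc.sample_cohort(config, panel)
    pon = build_pon(truths, panel, config, thresholds, settings)
    catalog, homology = default_driver_catalog(), default_homology_table()
    annotated: dict[str, list[AnnotatedVariant]] = {}
    profiles, calls = [], []
    n_correct = 0
    artifact_sites = artifact_pass = 0
    for case in truths:
        ca, cb = sc.simulate_counts(case, panel, config)
        consensus = consensus_from_counts(ca, cb, settings)
        result = filter_and_annotate(consensus, panel, pon, thresholds,
                                     catalog, homology)
        annotated[case.case_id] = result
        profile = profile_from_variants(case.case_id, result, tissue=case.tissue)
        profiles.append(profile)
        call = assign_subtype(profile)
        calls.append(call)
        if case.tissue != "MT" and call.subtype == case.true_subtype:
            n_correct += 1
        truth_artifacts = {v.key for v in case.of_class("artifact")}
        artifact_sites += len(truth_artifacts)
        artifact_pass += sum(1 for v in result
                             if v.key in truth_artifacts and v.status == "PASS")
    primary_profiles = [p for p in profiles if p.tissue != "MT"]
    primary_calls = [c for c in calls
                     if c.case_id in {p.case_id for p in primary_profiles}]
    summary = summarize_cohort(primary_calls, primary_profiles)
    n_primary = len(primary_profiles)
    return CohortResult(
        truths=truths, pon=pon, annotated=annotated, profiles=profiles,
        calls=calls, summary=summary,
        diagnostics={
            "subtype_accuracy": n_correct / n_primary if n_primary else 1.0,
            "n_artifact_sites": artifact_sites,
            "n_artifact_pass": artifact_pass,
        })
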