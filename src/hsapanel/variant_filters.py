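"""QC cascade, effect-class exclusion and panel-of-normals subtraction.

The QC gates mirror a strict dual-pool amplicon protocol: a variant passes
only if it was (1) called in both pools, (2) covered at a cumulative depth
of 1000X — equivalently an average of 500X per pool — and (3) observed at a
merged allele fraction strictly above 3%. Gates annotate flags rather than
delete records, so every rejection is auditable; the gates are conjunctive
and therefore commute and are idempotent.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

from .dualpool_caller import ConsensusVariant


def _clone(v):
    """Shallow copy with an independent flag set (records are otherwise
    treated as immutable by the filter stages)."""
    out = copy.copy(v)
    out.filter_flags = set(v.filter_flags)
    return out

QC_GATES = ("both_pools", "depth", "vaf")


@dataclass(frozen=True)
class QCThresholds:
    min_cumulative_depth: int = 1000
    min_mean_depth_per_pool: int = 500  # per-pool-average form, for != 2 pools
    min_vaf_exclusive: float = 0.03     # strict: vaf must exceed this

    def __post_init__(self):
        if min(self.min_cumulative_depth, self.min_mean_depth_per_pool) <= 0:
            raise ValueError("depth thresholds must be positive")
        if self.min_vaf_exclusive <= 0:
            raise ValueError("VAF threshold must be positive")


@dataclass
class PanelOfNormals:
    """Variant keys observed in normal tissue samples (set semantics)."""

    entries: set[tuple[str, int, str, str]]
    n_samples: int

    def __contains__(self, key) -> bool:
        return key in self.entries


def apply_qc(variants: list[ConsensusVariant], thresholds: QCThresholds = QCThresholds(),
             gates: tuple[str, ...] = QC_GATES) -> list[ConsensusVariant]:
    """Recompute QC flags on a copy of the input, preserving order.

    ``gates`` selects which of the three conjunctive gates to evaluate;
    flags owned by unevaluated gates are left untouched, as are the
    ``in_normals`` / ``effect_excluded`` flags owned by other stages.
    """
    n_pools = 2
    out = []
    for v in variants:
        v = _clone(v)
        if "both_pools" in gates:
            v.filter_flags.discard("single_pool")
            if len(v.called_pools) < n_pools:
                v.filter_flags.add("single_pool")
        if "depth" in gates:
            v.filter_flags.discard("low_depth")
            mean_per_pool = v.cumulative_depth / max(len(v.pool_evidence), 1)
            if (v.cumulative_depth < thresholds.min_cumulative_depth
                    and mean_per_pool < thresholds.min_mean_depth_per_pool):
                v.filter_flags.add("low_depth")
        if "vaf" in gates:
            v.filter_flags.discard("low_vaf")
            if not v.merged_vaf > thresholds.min_vaf_exclusive:
                v.filter_flags.add("low_vaf")
        out.append(v)
    return out


def build_normal_set(normal_sample_variants: list[list[ConsensusVariant]]) -> PanelOfNormals:
    """Union of PASS variant keys across post-QC normal samples."""
    if not normal_sample_variants:
        warnings.warn("building a panel of normals from zero samples")
        return PanelOfNormals(entries=set(), n_samples=0)
    entries = {v.key for sample in normal_sample_variants for v in sample
               if v.status == "PASS"}
    return PanelOfNormals(entries=entries, n_samples=len(normal_sample_variants))


def subtract_normals(variants: list[ConsensusVariant],
                     pon: PanelOfNormals) -> list[ConsensusVariant]:
    """Flag variants whose exact (chrom, pos, ref, alt) key is in the PoN."""
    out = []
    for v in variants:
        v = _clone(v)
        v.filter_flags.discard("in_normals")
        if v.key in pon:
            v.filter_flags.add("in_normals")
        out.append(v)
    return out


EXCLUDED_EFFECTS = frozenset({"synonymous", "intronic", "UTR"})


def filter_effect_classes(annotated: list) -> list:
    """Flag synonymous / intronic / UTR variants; splice sites are retained.

    Requires effect annotation; calling this before annotation is an
    ordering violation and raises.
    """
    out = []
    for v in annotated:
        effect = getattr(v, "effect", None)
        if effect is None:
            raise ValueError(
                f"{v.chrom}:{v.pos}: variant not annotated; run annotation first")
        v = _clone(v)
        v.filter_flags.discard("effect_excluded")
        if effect in EXCLUDED_EFFECTS:
            v.filter_flags.add("effect_excluded")
        out.append(v)
    return out
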