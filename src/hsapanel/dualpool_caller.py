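"""Per-pool variant calling and dual-pool consensus merge.

Each pool is called independently from its allele-count table: an allele is
emitted when it clears a raw read-count gate *and* a one-sided binomial
tail test against the sequencing error rate. The two pools are then
cross-compared and combined into one consensus record per allele; a
variant seen in only one pool is flagged ``single_pool`` and will fail the
QC cascade, which is what suppresses single-strand FFPE deamination
artifacts: a true variant sits on both template strands, a deamination
lesion on one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .synthetic_cohort import SiteCounts

BASES = ("A", "C", "G", "T")

DEFAULT_MIN_ALT_READS = 4
DEFAULT_ALPHA = 1e-6
DEFAULT_BASE_ERROR_RATE = 1e-3

FILTER_FLAGS = ("single_pool", "low_depth", "low_vaf", "in_normals", "effect_excluded")


@dataclass(frozen=True)
class PoolVariantCall:
    sample_id: str
    pool: str
    chrom: str
    pos: int        # 1-based
    ref: str
    alt: str
    depth: int
    alt_count: int
    vaf: float
    p_error: float

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"{self.chrom}:{self.pos}: alt equals ref")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"{self.chrom}:{self.pos}: vaf {self.vaf} outside [0,1]")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    """Cross-pool merged call with per-pool evidence and filter flags."""

    sample_id: str
    chrom: str
    pos: int        # 1-based
    ref: str
    alt: str
    pool_evidence: dict[str, tuple[int, int, float]]  # pool -> (depth, alt, vaf)
    called_pools: frozenset[str]
    filter_flags: set[str] = field(default_factory=set)

    @property
    def cumulative_depth(self) -> int:
        return sum(d for d, _, _ in self.pool_evidence.values())

    @property
    def cumulative_alt(self) -> int:
        return sum(a for _, a, _ in self.pool_evidence.values())

    @property
    def merged_vaf(self) -> float:
        depth = self.cumulative_depth
        return self.cumulative_alt / depth if depth else 0.0

    @property
    def status(self) -> str:
        return "PASS" if not self.filter_flags else "FAIL"

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


def _parse_indel_key(key: str) -> tuple[str, str]:
    ref, _, alt = key.partition(">")
    if not ref or not alt or any(c not in BASES for c in ref + alt):
        raise ValueError(f"malformed indel allele key {key!r}")
    return ref, alt


def call_pool(counts: SiteCounts,
              min_alt_reads: int = DEFAULT_MIN_ALT_READS,
              alpha: float = DEFAULT_ALPHA,
              base_error_rate: float = DEFAULT_BASE_ERROR_RATE) -> list[PoolVariantCall]:
    """Call variants in one pool from its allele-count table.

    An allele at a site is emitted iff ``alt_count >= min_alt_reads`` and the
    one-sided binomial tail P(X >= alt_count | depth, base_error_rate) is at
    most ``alpha``.
    """
    df = counts.df
    depth = df["depth"].to_numpy()
    chrom_arr = df["chrom"].to_numpy()
    pos_arr = df["pos"].to_numpy()
    ref_arr = df["ref"].to_numpy()
    calls: list[PoolVariantCall] = []
    for base in BASES:
        cnt = df[base].to_numpy()
        cand = np.flatnonzero((cnt >= min_alt_reads) & (ref_arr != base) & (depth > 0))
        if len(cand) == 0:
            continue
        tail = binom.sf(cnt[cand] - 1, depth[cand], base_error_rate)
        for i, p in zip(cand, tail):
            if p <= alpha:
                calls.append(PoolVariantCall(
                    sample_id=counts.sample_id, pool=counts.pool,
                    chrom=str(chrom_arr[i]), pos=int(pos_arr[i]),
                    ref=str(ref_arr[i]), alt=base,
                    depth=int(depth[i]), alt_count=int(cnt[i]),
                    vaf=float(cnt[i] / depth[i]), p_error=float(p)))
    if counts.indels:
        wanted = set(counts.indels)
        pos_lookup = {(c, int(p)): (r, int(d)) for c, p, r, d in
                      zip(df["chrom"], df["pos"], df["ref"], df["depth"])
                      if (c, int(p)) in wanted}
    for (chrom, pos), alleles in counts.indels.items():
        site_ref, site_depth = pos_lookup[(chrom, pos)]
        for key, n in alleles.items():
            ref, alt = _parse_indel_key(key)
            if ref[0] != site_ref:
                raise ValueError(
                    f"{chrom}:{pos}: indel key {key!r} anchored on {ref[0]!r}, "
                    f"site reference is {site_ref!r}")
            if n < min_alt_reads or site_depth == 0:
                continue
            p = float(binom.sf(n - 1, site_depth, base_error_rate))
            if p <= alpha:
                calls.append(PoolVariantCall(
                    sample_id=counts.sample_id, pool=counts.pool,
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    depth=site_depth, alt_count=int(n),
                    vaf=float(n / site_depth), p_error=p))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls


class _CountsIndex:
    """Depth / allele-count lookup on a SiteCounts table."""

    def __init__(self, counts: SiteCounts):
        self.counts = counts
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in counts.df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = {
                "pos": sub["pos"].to_numpy(),
                "ref": sub["ref"].to_numpy(),
                "depth": sub["depth"].to_numpy(),
                **{b: sub[b].to_numpy() for b in BASES},
            }

    def _index(self, chrom: str, pos: int) -> tuple[dict, int]:
        arrs = self._by_chrom[chrom]
        i = int(np.searchsorted(arrs["pos"], pos))
        if i >= len(arrs["pos"]) or arrs["pos"][i] != pos:
            raise KeyError(f"{chrom}:{pos} not covered")
        return arrs, i

    def evidence(self, chrom: str, pos: int, ref: str, alt: str) -> tuple[int, int, float]:
        arrs, i = self._index(chrom, pos)
        depth = int(arrs["depth"][i])
        if len(ref) == 1 and len(alt) == 1:
            n = int(arrs[alt][i])
        else:
            n = int(self.counts.indels.get((chrom, pos), {}).get(f"{ref}>{alt}", 0))
        return depth, n, (n / depth if depth else 0.0)

    def ref_base(self, chrom: str, pos: int) -> str:
        arrs, i = self._index(chrom, pos)
        return str(arrs["ref"][i])


def merge_pools(calls_a: list[PoolVariantCall], calls_b: list[PoolVariantCall],
                counts_a: SiteCounts, counts_b: SiteCounts) -> list[ConsensusVariant]:
    """Cross-compare the two pools and merge into consensus records.

    One record is produced per (chrom, pos, ref, alt) called in *either*
    pool; evidence for the uncalled pool is filled in from its raw counts,
    and ``single_pool`` is flagged unless both pools called the allele.
    """
    idx = {counts_a.pool: _CountsIndex(counts_a), counts_b.pool: _CountsIndex(counts_b)}
    pools = sorted(idx)
    called: dict[tuple, set[str]] = {}
    sample_id = counts_a.sample_id
    for call in list(calls_a) + list(calls_b):
        called.setdefault(call.key, set()).add(call.pool)
    out: list[ConsensusVariant] = []
    for key in sorted(called):
        chrom, pos, ref, alt = key
        refs = {p: idx[p].ref_base(chrom, pos) for p in pools}
        if len(set(refs.values())) != 1:
            raise ValueError(
                f"{chrom}:{pos}: reference base disagrees between pools: {refs}")
        evidence = {p: idx[p].evidence(chrom, pos, ref, alt) for p in pools}
        flags = set()
        if called[key] != set(pools):
            flags.add("single_pool")
        out.append(ConsensusVariant(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            pool_evidence=evidence, called_pools=frozenset(called[key]),
            filter_flags=flags))
    return out


def coverage_summary(counts_a: SiteCounts, counts_b: SiteCounts) -> dict:
    """Cumulative (pool A + pool B) depth statistics over target positions.

    ``uniformity`` is the fraction of positions at >= 0.2x the mean
    cumulative depth.
    """
    a = counts_a.df.set_index(["chrom", "pos"])["depth"]
    b = counts_b.df.set_index(["chrom", "pos"])["depth"]
    if not a.index.equals(b.index):
        raise ValueError("pools cover different position sets")
    cum = a + b
    mean = float(cum.mean())
    return {
        "mean_cumulative_depth": mean,
        "depths": cum,
        "uniformity": float((cum >= 0.2 * mean).mean()) if mean > 0 else 0.0,
    }
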