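"""Domain merging, replicate-adjusted length and E-value assignment.

Candidate segments from the individual replicate-pair scans are merged
into group-level domains by single-linkage clustering of bin overlap:
each cluster's coverage is the union of its members' intervals and its
differential chromatin score (DCS) is the arithmetic mean of the member
raw scores. Each merged domain receives an E-value

    E = K * L * exp(-lambda * DCS)

the expected number of chance segments with at least that score in a
comparison of random sequences of effective length ``L``. ``L`` adapts
the plain chromosome length to replicate variation: within a group, the
first replicate contributes the full length and every further replicate
adds only the positions where it shows a state not seen in the previous
replicates (equivalently, the per-position count of distinct states,
summed). The two group lengths combine per chromosome as their maximum,
which reduces to the plain length for 1-vs-1 comparisons. Domains with
``E`` below a threshold (default: strictly below 1) form the final set
of differential chromatin domains (DCDs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .karlin import KarlinParams
from .scan import CandidateSegment
from .dataset import SegmentationMap

__all__ = [
    "MergedDomain",
    "EffectiveLength",
    "merge_candidates",
    "effective_group_length",
    "comparison_length",
    "assign_evalues",
    "filter_dcds",
]

DEFAULT_E_THRESHOLD = 1.0


@dataclass(frozen=True)
class MergedDomain:
    """Union of overlapping candidate segments from one comparison."""

    chrom: str
    start: int
    end: int
    dcs: float
    members: tuple[CandidateSegment, ...]
    evalue: float | None = None
    neg_log10_e: float | None = None

    @property
    def n_bins(self) -> int:
        return self.end - self.start

    @property
    def n_support_pairs(self) -> int:
        return len({m.source_pair for m in self.members})


@dataclass(frozen=True)
class EffectiveLength:
    """Replicate-adjusted sequence length, per chromosome and total."""

    per_chrom: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_chrom.values())


def merge_candidates(segments: list[CandidateSegment]) -> list[MergedDomain]:
    """Single-linkage merge of bin-overlapping segments into domains.

    Half-open intervals sharing only a boundary do not overlap. The
    members of one domain form a transitive-closure cluster, so the
    union coverage is always one contiguous interval. Segments that
    overlap nothing pass through as single-member domains.
    """
    if not segments:
        return []
    x_side = {m.source_pair[0] for m in segments}
    y_side = {m.source_pair[1] for m in segments}
    if x_side & y_side:
        raise ValidationError(
            "candidate segments mix comparisons: a sample occurs on both sides"
        )
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.end))
    domains: list[MergedDomain] = []
    cluster: list[CandidateSegment] = []

    def flush() -> None:
        if cluster:
            domains.append(
                MergedDomain(
                    chrom=cluster[0].chrom,
                    start=min(s.start for s in cluster),
                    end=max(s.end for s in cluster),
                    dcs=float(np.mean([s.score for s in cluster])),
                    members=tuple(cluster),
                )
            )

    current_end = -1
    current_chrom = None
    for seg in ordered:
        if seg.chrom == current_chrom and seg.start < current_end:
            cluster.append(seg)
            current_end = max(current_end, seg.end)
        else:
            flush()
            cluster = [seg]
            current_chrom = seg.chrom
            current_end = seg.end
    flush()
    return domains


def effective_group_length(maps: list[SegmentationMap]) -> EffectiveLength:
    """Replicate-adjusted length of one sample group, per chromosome.

    Per chromosome this is the sum over positions of the number of
    distinct states observed across the group's replicates, which is
    order-independent and reduces to the plain bin count for a single
    replicate or fully concordant replicates.
    """
    if not maps:
        raise ValidationError("empty sample group")
    ref = maps[0]
    per_chrom: dict[str, int] = {}
    for chrom in sorted(ref.chrom_states):
        stack = np.stack([m.chrom_states[chrom] for m in maps], axis=0)
        if len(maps) == 1:
            per_chrom[chrom] = int(stack.shape[1])
            continue
        stack.sort(axis=0)
        distinct = 1 + (np.diff(stack, axis=0) != 0).sum(axis=0)
        per_chrom[chrom] = int(distinct.sum())
    return EffectiveLength(per_chrom)


def comparison_length(
    lx: EffectiveLength, ly: EffectiveLength, rule: str = "max"
) -> EffectiveLength:
    """Combine the two group lengths into the single L of the E-value.

    ``rule="max"`` (default) takes the larger, i.e. more conservative,
    search space per chromosome; ``"sum"`` adds them.
    """
    if set(lx.per_chrom) != set(ly.per_chrom):
        raise ValidationError("groups computed on different chromosome sets")
    if rule == "max":
        combined = {c: max(lx.per_chrom[c], ly.per_chrom[c]) for c in lx.per_chrom}
    elif rule == "sum":
        combined = {c: lx.per_chrom[c] + ly.per_chrom[c] for c in lx.per_chrom}
    else:
        raise ValidationError(f"unknown length combination rule {rule!r}")
    return EffectiveLength(combined)


def assign_evalues(
    domains: list[MergedDomain], params: KarlinParams, length: int
) -> list[MergedDomain]:
    """Annotate each domain with E = K * L * exp(-lambda * DCS).

    The exponential is evaluated in log space so very high-scoring
    domains report an exact ``neg_log10_e`` even when ``E`` underflows
    to zero.
    """
    if length < 1:
        raise ValidationError("effective length must be positive")
    log_kl = math.log(params.K) + math.log(length)
    out = []
    for dom in domains:
        log_e = log_kl - params.lam * dom.dcs
        out.append(
            replace(
                dom,
                evalue=math.exp(log_e) if log_e > -745 else 0.0,
                neg_log10_e=-log_e / math.log(10.0),
            )
        )
    return out


def filter_dcds(
    domains: list[MergedDomain], threshold_e: float = DEFAULT_E_THRESHOLD
) -> list[MergedDomain]:
    """Keep domains with E-value strictly below ``threshold_e``."""
    if threshold_e < 0:
        raise ValidationError("E-value threshold must be non-negative")
    kept = [d for d in domains if d.evalue is not None and d.evalue < threshold_e]
    kept.sort(key=lambda d: (d.chrom, d.start, d.end))
    return kept
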