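"""Position-wise scoring and maximal-scoring-segment extraction.

Comparing two samples' state maps position by position yields one
integer score sequence per chromosome. The candidate differential
regions are exactly the maximal scoring subsequences of that sequence:
the disjoint positive-sum segments obtained by repeatedly taking the
highest-scoring subsegment (shortest, then leftmost, on ties) and
recursing on the flanks. They are extracted in linear time with the
Ruzzo–Tompa algorithm.

Implementation note: maximal runs of positive scores always coalesce
into a single candidate, so the input is first collapsed (vectorised)
into positive runs with their flanking cumulative sums; the Ruzzo–Tompa
list bookkeeping then only touches those runs. Chromosomes are
independent: segments never span a chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, SampleGroup, SegmentationMap
from .errors import ValidationError
from .scoring import ScoreMatrix

__all__ = [
    "ScoreSequence",
    "CandidateSegment",
    "score_pair",
    "max_scoring_segments",
    "scan_comparison",
]


@dataclass(frozen=True)
class ScoreSequence:
    """Integer score per bin for one chromosome of one sample pair."""

    chrom: str
    scores: np.ndarray
    source_pair: tuple[str, str]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.ndim != 1 or scores.size == 0:
            raise ValidationError("score sequence must be non-empty 1-D")
        object.__setattr__(self, "scores", scores)


@dataclass(frozen=True, order=True)
class CandidateSegment:
    """A maximal scoring segment from one replicate-pair scan.

    ``start``/``end`` are bin indices, half-open; ``score`` is the raw
    cumulative score R of the segment (always positive).
    """

    chrom: str
    start: int
    end: int
    score: int
    source_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError("segment interval must be non-empty")
        if self.score <= 0:
            raise ValidationError("segment raw score must be positive")

    @property
    def n_bins(self) -> int:
        return self.end - self.start


def score_pair(
    map_x: SegmentationMap, map_y: SegmentationMap, matrix: ScoreMatrix
) -> list[ScoreSequence]:
    """Score two state maps position-wise, one sequence per chromosome."""
    if map_x.bin_size != map_y.bin_size or map_x.chrom_lengths != map_y.chrom_lengths:
        raise ValidationError(
            f"samples {map_x.sample_id!r} and {map_y.sample_id!r} are not "
            "on a shared binning"
        )
    pair = (map_x.sample_id, map_y.sample_id)
    out = []
    for chrom in sorted(map_x.chrom_states):
        x = map_x.chrom_states[chrom]
        y = map_y.chrom_states[chrom]
        if int(max(x.max(), y.max())) >= matrix.size:
            raise ValidationError(f"{chrom}: state index outside score matrix")
        out.append(ScoreSequence(chrom, matrix.scores[x, y], pair))
    return out


def _max_segments_core(scores: np.ndarray) -> tuple[list[int], list[int], list[int]]:
    """Ruzzo–Tompa over positive-run candidates; returns starts, ends, sums."""
    pos = scores > 0
    if not pos.any():
        return [], [], []
    prefix = np.concatenate(([0], np.cumsum(scores)))
    edges = np.diff(pos.astype(np.int8))
    run_starts = (np.flatnonzero(edges == 1) + 1).tolist()
    run_ends = (np.flatnonzero(edges == -1) + 1).tolist()
    if pos[0]:
        run_starts.insert(0, 0)
    if pos[-1]:
        run_ends.append(int(scores.size))

    # list items: [start, end, L, R, prev] where L/R are the cumulative
    # sums flanking the subsequence and prev points to the nearest earlier
    # item with smaller L (enables the amortised-linear backward search).
    items: list[list[int]] = []
    prefix_list = prefix.tolist()
    for a, b in zip(run_starts, run_ends):
        lk = prefix_list[a]
        rk = prefix_list[b]
        while True:
            j = len(items) - 1
            while j >= 0 and items[j][2] >= lk:
                j = items[j][4]
            if j < 0 or items[j][3] >= rk:
                items.append([a, b, lk, rk, j])
                break
            # merge with item j: extend it to the current end, drop
            # everything after it, and reconsider the merged candidate
            a, lk = items[j][0], items[j][2]
            del items[j:]
    starts = [it[0] for it in items]
    ends = [it[1] for it in items]
    sums = [it[3] - it[2] for it in items]
    return starts, ends, sums


def max_scoring_segments(seq: ScoreSequence) -> list[CandidateSegment]:
    """All maximal scoring segments of one score sequence, sorted by start."""
    starts, ends, sums = _max_segments_core(seq.scores)
    return [
        CandidateSegment(seq.chrom, a, b, r, seq.source_pair)
        for a, b, r in zip(starts, ends, sums)
    ]


def scan_comparison(
    dataset: Dataset,
    group_x: SampleGroup,
    group_y: SampleGroup,
    matrix: ScoreMatrix,
) -> list[CandidateSegment]:
    """Candidate segments from every replicate pairing of two groups.

    Performs ``|X| * |Y|`` pairwise scans and returns the combined
    candidate list sorted by (chrom, start, end, source pair) so the
    output is independent of scan scheduling.
    """
    if set(group_x.members) & set(group_y.members):
        raise ValidationError(
            f"groups {group_x.name!r} and {group_y.name!r} share samples"
        )
    segments: list[CandidateSegment] = []
    for x_id in group_x.members:
        for y_id in group_y.members:
            for seq in score_pair(dataset.maps[x_id], dataset.maps[y_id], matrix):
                segments.extend(max_scoring_segments(seq))
    segments.sort(key=lambda s: (s.chrom, s.start, s.end, s.source_pair))
    return segments
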