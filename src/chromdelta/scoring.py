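"""Chromatin-state dissimilarity scoring.

Every pair of chromatin states ``(a_i, a_j)`` receives an integer score
``s_ij``: positive for dissimilar states (interesting when comparing two
samples), negative for similar states. Scores are derived from the
segmentation model's emission probabilities via the Jensen–Shannon
divergence

    JSD(E_i, E_j) = 2 * H((E_i + E_j) / 2) - H(E_i) - H(E_j)

with Shannon entropy ``H`` in nats (note the factor of two relative to
the conventional JSD; the range is [0, 2 ln 2]). The JSD matrix is
shifted by its mean over distinct state pairs so that similar states
score negative, scaled (default x10) and rounded to integers. All scores
involving the background ("quiescent") state are then replaced by the
matrix minimum: absence of signal is treated as non-differential against
everything, which keeps domains from being driven by missing data.

The local-score statistics downstream require two properties of the
scoring system relative to the background letter frequencies: a positive
score must be attainable, and the expected score must be negative.
:func:`check_assumptions` verifies both before any analysis runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Dataset, EmissionMatrix, SampleGroup
from .errors import AssumptionError, ValidationError

__all__ = [
    "shannon_entropy",
    "jsd",
    "ScoreMatrix",
    "BackgroundFreqs",
    "build_score_matrix",
    "AssumptionReport",
    "check_assumptions",
    "empirical_state_freqs",
]

DEFAULT_SCALE_FACTOR = 10

_SUM_TOL = 1e-6


def _check_distribution(p: np.ndarray, name: str = "distribution") -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector")
    if np.any(p < 0):
        raise ValidationError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"{name} does not sum to 1 (sum={p.sum():.8f})")
    return p


def shannon_entropy(dist) -> float:
    """Shannon entropy of a probability vector, in nats; 0*log(0) := 0."""
    p = _check_distribution(dist)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def jsd(ei, ej) -> float:
    """Jensen–Shannon divergence between two distributions, range [0, 2 ln 2].

    Symmetric and zero iff the inputs are equal. Carries a factor of two
    relative to the conventional definition (twice the mean KL divergence
    to the midpoint).
    """
    ei = _check_distribution(ei, "E_i")
    ej = _check_distribution(ej, "E_j")
    if ei.shape != ej.shape:
        raise ValidationError("distributions have different lengths")
    mid = 0.5 * (ei + ej)
    return 2.0 * shannon_entropy(mid) - shannon_entropy(ei) - shannon_entropy(ej)


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric integer state-dissimilarity matrix over an alphabet."""

    scores: np.ndarray
    labels: tuple[str, ...]
    background_state: int | None = None
    scale_factor: int = DEFAULT_SCALE_FACTOR
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.round(scores)):
                raise ValidationError("score matrix entries must be integers")
        scores = scores.astype(np.int64)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = len(self.labels)
        if scores.shape != (n, n):
            raise ValidationError(f"score matrix shape {scores.shape} != ({n}, {n})")
        if not np.array_equal(scores, scores.T):
            raise ValidationError("score matrix must be symmetric")
        if self.background_state is not None and not 0 <= self.background_state < n:
            raise ValidationError("background state index outside alphabet")

    @property
    def size(self) -> int:
        return len(self.labels)

    @property
    def min_score(self) -> int:
        return int(self.scores.min())

    @property
    def max_score(self) -> int:
        return int(self.scores.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, background_state: int | None = None) -> "ScoreMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
            raise ValidationError(f"{path}: row and column labels differ")
        return cls(
            frame.to_numpy(), tuple(frame.index.astype(str)),
            background_state=background_state, provenance="user-supplied",
        )


@dataclass(frozen=True)
class BackgroundFreqs:
    """Background state frequencies for the two compared groups.

    The local-score theory models each group's state sequence as i.i.d.
    draws; ``p`` and ``q`` are the per-state letter frequencies for the
    first and second group, so a random state *pair* has probability
    ``p_i * q_j``.
    """

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p", "q"):
            vec = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be non-negative and sum to 1")
            object.__setattr__(self, name, vec)
        if self.p.shape != self.q.shape:
            raise ValidationError("p and q must have equal length")

    @property
    def pair_probs(self) -> np.ndarray:
        """Outer product matrix of pair probabilities p_i * q_j."""
        return np.outer(self.p, self.q)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half-to-even; scores use half-away-from-zero so the
    # integerization is independent of the parity of neighbouring values.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_score_matrix(
    emissions: EmissionMatrix,
    background_state: int | None = None,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
    mean_mode: str = "global",
) -> ScoreMatrix:
    """Derive the integer dissimilarity score matrix from emissions.

    Emission rows are normalised to sum to one (ChromHMM rows are
    per-mark Bernoulli parameters), pairwise JSDs are computed, shifted
    by the mean JSD, scaled and rounded half-away-from-zero. Finally the
    background state's row and column are overwritten with the matrix
    minimum.

    Parameters
    ----------
    background_state
        0-based index of the quiescent state; defaults to the alphabet's
        declared background state.
    mean_mode
        ``"global"`` (default) subtracts one mean computed over all
        unordered off-diagonal state pairs. ``"per_state"`` subtracts the
        symmetrised per-state mean ``(m_i + m_j) / 2`` where ``m_i`` is
        the mean JSD of state ``i`` against all other states.
    """
    if scale_factor < 1:
        raise ValidationError("scale factor must be >= 1")
    if mean_mode not in ("global", "per_state"):
        raise ValidationError(f"unknown mean_mode {mean_mode!r}")
    if background_state is None:
        background_state = emissions.alphabet.background_state

    probs = emissions.probs
    row_sums = probs.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValidationError("emission rows must have positive mass")
    rows = probs / row_sums[:, None]

    n = rows.shape[0]
    jsd_mat = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            jsd_mat[i, j] = jsd_mat[j, i] = jsd(rows[i], rows[j])

    off = ~np.eye(n, dtype=bool)
    if mean_mode == "global":
        shift = np.full((n, n), jsd_mat[off].mean())
    else:
        per_state = jsd_mat.sum(axis=1) / (n - 1)
        shift = 0.5 * (per_state[:, None] + per_state[None, :])

    scores = _round_half_away(scale_factor * (jsd_mat - shift)).astype(np.int64)
    if background_state is not None:
        minimum = scores.min()
        scores[background_state, :] = minimum
        scores[:, background_state] = minimum
    return ScoreMatrix(
        scores,
        emissions.alphabet.labels,
        background_state=background_state,
        scale_factor=scale_factor,
        provenance=f"jsd-emission(mean={mean_mode},scale={scale_factor})",
    )


@dataclass(frozen=True)
class AssumptionReport:
    """Outcome of the scoring-system applicability checks.

    ``positive_score_possible`` requires a positive score with positive
    pair probability; ``expected_score`` must be strictly negative.
    """

    max_attainable_score: int
    expected_score: float
    positive_score_possible: bool
    expected_score_negative: bool

    @property
    def passed(self) -> bool:
        return self.positive_score_possible and self.expected_score_negative

    def raise_if_failed(self) -> None:
        if not self.passed:
            raise AssumptionError(str(self))

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"scoring assumptions: {verdict} "
            f"(max attainable score={self.max_attainable_score}, "
            f"positive possible={self.positive_score_possible}; "
            f"expected score={self.expected_score:.6f}, "
            f"negative={self.expected_score_negative})"
        )


def check_assumptions(matrix: ScoreMatrix, freqs: BackgroundFreqs) -> AssumptionReport:
    """Verify that local-score statistics apply to ``matrix`` under ``freqs``.

    Returns a report rather than raising, so a caller can surface both
    quantities; use :meth:`AssumptionReport.raise_if_failed` to abort.
    """
    if freqs.p.size != matrix.size:
        raise ValidationError("frequency vectors do not match matrix size")
    pair = freqs.pair_probs
    attainable = pair > 0
    if not attainable.any():
        raise ValidationError("no state pair has positive probability")
    max_attain = int(matrix.scores[attainable].max())
    expected = float(np.sum(pair * matrix.scores))
    return AssumptionReport(
        max_attainable_score=max_attain,
        expected_score=expected,
        positive_score_possible=max_attain > 0,
        expected_score_negative=expected < 0,
    )


def empirical_state_freqs(dataset: Dataset, group: SampleGroup) -> np.ndarray:
    """State frequencies over all bins of all member maps of ``group``."""
    if not group.members:
        raise ValidationError("empty sample group")
    counts = np.zeros(dataset.alphabet.size, dtype=np.int64)
    for smap in dataset.group_maps(group):
        for vec in smap.chrom_states.values():
            counts += np.bincount(vec, minlength=dataset.alphabet.size)
    return counts / counts.sum()
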