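"""Local-score (Karlin–Altschul) parameter estimation.

For an i.i.d. sequence of integer scores with negative mean and some
positive mass on positive values, the number of maximal scoring segments
with score at least ``x`` in a sequence of length ``L`` is asymptotically
Poisson with mean ``K * L * exp(-lambda * x)``. ``lambda`` is the unique
positive root of the moment condition

    sum_s P(s) * exp(lambda * s) = 1

and ``K`` is a search-space scaling constant. Both depend only on the
score distribution induced by the scoring matrix and the background
state frequencies of the two compared groups.

``lambda`` is found by bracketed bisection/Brent on the (convex) moment
function. ``K`` is computed with the classical lattice-case series: with
``delta`` the lattice span (gcd of attained scores),

    K = delta * lambda * exp(-2 * sigma) / (H * (1 - exp(-lambda * delta)))

where ``H = lambda * sum_s s P(s) exp(lambda s)`` is the relative entropy
per position and

    sigma = sum_{k>=1} (1/k) * [ P(S_k >= 0) + E(exp(lambda S_k); S_k < 0) ]

is accumulated over k-fold convolutions of the score distribution until
the (geometrically decaying) terms fall below a tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import AssumptionError, ValidationError
from .scoring import BackgroundFreqs, ScoreMatrix

__all__ = [
    "ScoreDistribution",
    "KarlinParams",
    "score_distribution",
    "estimate_lambda",
    "estimate_K",
    "estimate_params",
]

LAMBDA_RESIDUAL_TOL = 1e-9
_BRACKET_TOL = 1e-12


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability distribution over the attainable integer scores."""

    values: np.ndarray  # sorted unique integer scores with positive mass
    probs: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if values.ndim != 1 or values.shape != probs.shape or values.size == 0:
            raise ValidationError("score distribution must be parallel 1-D vectors")
        if np.any(np.diff(values) <= 0):
            raise ValidationError("score values must be strictly increasing")
        if np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("probabilities must be positive and sum to 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probs", probs)

    @property
    def expected_score(self) -> float:
        return float(np.dot(self.values, self.probs))

    @property
    def span(self) -> int:
        """Greatest common divisor of the attained scores (lattice span)."""
        return int(np.gcd.reduce(np.abs(self.values[self.values != 0])))


def score_distribution(matrix: ScoreMatrix, freqs: BackgroundFreqs) -> ScoreDistribution:
    """Collapse the pair model ``p_i * q_j`` onto integer score values."""
    if freqs.p.size != matrix.size:
        raise ValidationError("frequency vectors do not match matrix size")
    pair = freqs.pair_probs.ravel()
    scores = matrix.scores.ravel()
    keep = pair > 0
    if not keep.any():
        raise ValidationError("no state pair has positive probability")
    values, inverse = np.unique(scores[keep], return_inverse=True)
    probs = np.bincount(inverse, weights=pair[keep])
    return ScoreDistribution(values, probs)


def _check_scannable(dist: ScoreDistribution) -> None:
    if dist.values[-1] <= 0:
        raise AssumptionError("no positive score attainable; statistics undefined")
    if dist.expected_score >= 0:
        raise AssumptionError(
            f"expected score {dist.expected_score:.6g} is not negative; "
            "statistics undefined"
        )


def estimate_lambda(dist: ScoreDistribution, tol: float = _BRACKET_TOL) -> float:
    """Unique positive root of ``sum_s P(s) exp(lambda s) = 1``.

    Raises :class:`AssumptionError` when no positive score is attainable
    or the expected score is non-negative (no positive root exists).
    """
    _check_scannable(dist)
    span = dist.span
    values = dist.values / span  # lattice-normalised, keeps exp() well scaled
    probs = dist.probs

    def moment_minus_one(lam: float) -> float:
        return float(np.dot(probs, np.exp(lam * values)) - 1.0)

    # lambda = 0 is always a root of the moment condition; bracket away
    # from it on the side where the function is negative (E[S] < 0).
    lo = 1e-8
    while moment_minus_one(lo) >= 0:
        lo /= 16.0
        if lo < 1e-300:  # pragma: no cover - defensive
            raise AssumptionError("failed to bracket lambda away from zero")
    hi = 1.0
    while moment_minus_one(hi) <= 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise AssumptionError("failed to bracket lambda")
    lam_norm = brentq(moment_minus_one, lo, hi, xtol=tol, rtol=8.9e-16)
    lam = lam_norm / span
    residual = abs(float(np.dot(dist.probs, np.exp(lam * dist.values))) - 1.0)
    if residual > LAMBDA_RESIDUAL_TOL:
        raise ValidationError(f"lambda residual {residual:.3e} above tolerance")
    return lam


def estimate_K(
    dist: ScoreDistribution,
    lam: float,
    tol: float = 1e-7,
    max_terms: int = 20000,
) -> float:
    """Karlin–Altschul K for a lattice score distribution given ``lam``.

    Accumulates the correction series ``sigma`` over k-fold convolutions
    of the score distribution. The terms decay geometrically; the series
    is truncated once a geometric bound on the remaining tail of
    ``sigma`` falls below ``tol``, and an error is raised if that bound
    is not reached within ``max_terms`` terms.
    """
    _check_scannable(dist)
    span = dist.span
    values = (dist.values // span).astype(np.int64)
    probs = dist.probs
    lam_norm = lam * span

    # relative entropy per position, invariant under lattice normalisation
    relative_entropy = float(lam * np.dot(dist.values * dist.probs, np.exp(lam * dist.values)))

    low, high = int(values[0]), int(values[-1])
    # conv[i] = P(S_k = offset_low + i) for the k-fold sum
    conv = np.zeros(high - low + 1, dtype=np.float64)
    conv[values - low] = probs
    base = conv.copy()
    offset_low = low

    sigma = 0.0
    converged = False
    recent: list[float] = []
    for k in range(1, max_terms + 1):
        support = offset_low + np.arange(conv.size)
        neg = support < 0
        term = float(conv[~neg].sum() + np.dot(conv[neg], np.exp(lam_norm * support[neg])))
        sigma += term / k
        if term <= 0.0:
            converged = True
            break
        # terms decay geometrically but may oscillate with the lattice
        # period, so the envelope decay rate is estimated at lag 2:
        # tail bound sum_{j>k} t_j / j <= t_k * r / ((k+1) * (1 - r))
        if len(recent) >= 2 and term < recent[-2]:
            rate = math.sqrt(term / recent[-2])
            tail = term * rate / ((k + 1) * (1.0 - rate))
            if tail < tol:
                converged = True
                break
        recent = (recent + [term])[-2:]
        conv = np.convolve(conv, base)
        offset_low += low
    if not converged:
        raise ValidationError(
            f"K series tail bound not below {tol:.0e} within {max_terms} terms"
        )

    K = (
        span * lam * math.exp(-2.0 * sigma)
        / (relative_entropy * -math.expm1(-lam_norm))
    )
    if not (K > 0 and math.isfinite(K)):
        raise ValidationError(f"K estimate invalid: {K}")
    return K


@dataclass(frozen=True)
class KarlinParams:
    """Estimated local-score scaling parameters for one comparison."""

    lam: float
    K: float
    score_range: tuple[int, int]
    freqs: BackgroundFreqs

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValidationError("lambda and K must be positive")

    def evalue(self, score: float, length: float) -> float:
        """Expected number of chance segments scoring >= ``score``."""
        return self.K * length * math.exp(-self.lam * score)


def estimate_params(matrix: ScoreMatrix, freqs: BackgroundFreqs) -> KarlinParams:
    """Estimate lambda and K for a scoring matrix under group frequencies."""
    dist = score_distribution(matrix, freqs)
    lam = estimate_lambda(dist)
    K = estimate_K(dist, lam)
    return KarlinParams(
        lam=lam,
        K=K,
        score_range=(int(dist.values[0]), int(dist.values[-1])),
        freqs=freqs,
    )
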