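"""Threshold optimization: minimum FPT noise at fixed mean FPT.

Given the intrinsic noise of each gene and a prescribed dimensionless mean
time ``gamma <T>``, the relative thresholds that minimize the total timing
noise have the closed form

    alpha_n* = 1 - e^{-gamma<T>/N} * CV_n / GM(CV)

with ``GM`` the geometric mean over all N intrinsic noise levels (as
standard deviations, not variances).  At the optimum the stationarity
identity ``CV_i / (1 - alpha_i*) = const`` holds across genes: noisier
genes get thresholds closer to zero and contribute less accumulation time.

A gene whose noise is too far from the geometric mean of the rest gets an
optimal threshold outside the feasible range ``[0, 1 - e^{-gamma<T>})``
and must be left out of the cascade; for two genes this classification is
the familiar three-regime picture (use gene 1 only / couple both / use
gene 2 only) governed by whether ``CV_2/CV_1`` lies inside
``(e^{-gamma<T>}, e^{gamma<T>})``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .theory import fpt_stats_cascade

__all__ = [
    "TwoGeneRegime",
    "CascadeRegime",
    "OptimizationResult",
    "classify_two_gene",
    "optimize_two_gene",
    "optimal_thresholds_general",
    "inclusion_criterion",
    "optimal_mean_time_identical",
    "min_noise_identical",
]


class TwoGeneRegime(str, enum.Enum):
    GENE1_ONLY = "gene1_only"
    COUPLED = "coupled"
    GENE2_ONLY = "gene2_only"


class CascadeRegime(str, enum.Enum):
    ALL_INCLUDED = "all_included"
    SOME_EXCLUDED = "some_excluded"


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal thresholds and the noise they achieve, at fixed mean FPT."""

    regime: TwoGeneRegime | CascadeRegime
    alphas_opt: tuple[float, ...]
    cv2_T_opt: float
    gammaT: float
    excluded_genes: tuple[int, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "regime": self.regime.value,
            "alphas_opt": list(self.alphas_opt),
            "cv2_T_opt": self.cv2_T_opt,
            "gammaT": self.gammaT,
            "excluded_genes": list(self.excluded_genes),
        }


def classify_two_gene(cv_ratio: float, gammaT: float) -> TwoGeneRegime:
    """Which of the three two-gene regimes a noise ratio falls in.

    ``cv_ratio`` is CV_2/CV_1 (standard deviations).  Boundary equalities
    classify as the adjacent single-gene regime; the coupled-regime
    formulas give alpha = 0 exactly there, so the optimum is continuous
    across the boundary.
    """
    if not cv_ratio > 0 or not gammaT > 0:
        raise ValueError("cv_ratio and gammaT must be > 0")
    if cv_ratio >= np.exp(gammaT):
        return TwoGeneRegime.GENE1_ONLY
    if cv_ratio <= np.exp(-gammaT):
        return TwoGeneRegime.GENE2_ONLY
    return TwoGeneRegime.COUPLED


def optimize_two_gene(
    cv2_1: float, cv2_2: float, gammaT: float
) -> OptimizationResult:
    """Optimal ``(alpha1, alpha2)`` for a two-gene cascade at fixed mean.

    In the coupled regime,

        alpha_1* = 1 - sqrt(CV_1/CV_2 e^{-gamma<T>})
        alpha_2* = 1 - sqrt(CV_2/CV_1 e^{-gamma<T>})

    and in the one-gene regimes the whole mean goes to the quieter gene,
    ``(1 - e^{-gamma<T>}, 0)`` or ``(0, 1 - e^{-gamma<T>})``.  The result
    always satisfies ``(1-alpha1)(1-alpha2) = e^{-gamma<T>}``.
    """
    if not (cv2_1 > 0 and cv2_2 > 0 and gammaT > 0):
        raise ValueError("cv2_1, cv2_2 and gammaT must be > 0")
    ratio = np.sqrt(cv2_2 / cv2_1)
    regime = classify_two_gene(ratio, gammaT)
    e = np.exp(-gammaT)
    if regime is TwoGeneRegime.GENE1_ONLY:
        alphas = (1.0 - e, 0.0)
        excluded: tuple[int, ...] = (1,)
    elif regime is TwoGeneRegime.GENE2_ONLY:
        alphas = (0.0, 1.0 - e)
        excluded = (0,)
    else:
        alphas = (
            float(1.0 - np.sqrt(e / ratio)),
            float(1.0 - np.sqrt(e * ratio)),
        )
        excluded = ()
    pred = fpt_stats_cascade(alphas, [cv2_1, cv2_2], gamma=1.0)
    return OptimizationResult(
        regime=regime,
        alphas_opt=alphas,
        cv2_T_opt=pred.cv2_T,
        gammaT=gammaT,
        excluded_genes=excluded,
    )


def inclusion_criterion(cv_n: float, cv_list, gammaT: float) -> bool:
    """Can gene ``n`` contribute to an N-gene cascade's precision?

    True iff ``CV_n / GM(CV)`` lies strictly inside
    ``(e^{-(N-1) gamma<T> / N}, e^{gamma<T>/N})`` with the geometric mean
    taken over all N genes including gene n itself.  Genes outside the
    interval would need an infeasible threshold and should be left out.
    For N = 2 this reduces to the familiar
    ``e^{-gamma<T>} < CV_2/CV_1 < e^{gamma<T>}`` interval; as gamma -> 0
    the interval collapses, so without dilution only identical-noise genes
    can share the timing task.
    """
    cv = np.asarray(cv_list, dtype=float)
    if np.any(cv <= 0) or not cv_n > 0 or not gammaT > 0:
        raise ValueError("noise levels and gammaT must be > 0")
    n = len(cv)
    gm = np.exp(np.mean(np.log(cv)))
    r = cv_n / gm
    return bool(np.exp(-(n - 1) * gammaT / n) < r < np.exp(gammaT / n))


def optimal_thresholds_general(cv2_list, gammaT: float) -> OptimizationResult:
    """Optimal thresholds for N genes, excluding those that cannot help.

    Applies the closed-form optimum to the candidate set; if any gene's
    optimal threshold falls outside ``[0, 1 - e^{-gamma<T>})`` the noisiest
    offender is dropped and the problem re-solved on the remaining genes,
    iterating until the solution is feasible.  The least-noisy gene always
    survives (for N = 1 the whole mean is one stage, always feasible).
    Excluded genes are reported and carry ``alpha = 0``.
    """
    cv2 = np.asarray(cv2_list, dtype=float)
    if cv2.ndim != 1 or len(cv2) < 1:
        raise ValueError("cv2_list must be a non-empty 1-D sequence")
    if np.any(cv2 <= 0) or not gammaT > 0:
        raise ValueError("intrinsic noises and gammaT must be > 0")

    cv = np.sqrt(cv2)
    included = list(range(len(cv)))
    while True:
        sub = cv[included]
        n = len(sub)
        gm = np.exp(np.mean(np.log(sub)))
        ratios = sub / gm
        # feasibility of the closed form on the current set
        upper_viol = ratios >= np.exp(gammaT / n)
        if n > 1 and np.any(upper_viol):
            # drop the noisiest offender; its alpha* would be negative
            worst = included[int(np.argmax(ratios))]
            included.remove(worst)
            continue
        alphas_sub = 1.0 - np.exp(-gammaT / n) * ratios
        break

    assert included, "the least-noisy gene always survives exclusion"
    alphas = np.zeros(len(cv))
    alphas[included] = alphas_sub
    excluded = tuple(i for i in range(len(cv)) if i not in included)
    pred = fpt_stats_cascade(alphas, cv2, gamma=1.0)
    regime = CascadeRegime.SOME_EXCLUDED if excluded else CascadeRegime.ALL_INCLUDED
    return OptimizationResult(
        regime=regime,
        alphas_opt=tuple(float(a) for a in alphas),
        cv2_T_opt=pred.cv2_T,
        gammaT=gammaT,
        excluded_genes=excluded,
    )


def optimal_mean_time_identical(n: int = 1) -> float:
    """Dimensionless mean time ``gamma<T>*`` minimizing identical-gene noise.

    Relaxing the fixed-mean constraint, the noise of N identical stages is
    convex in ``gamma<T>`` with minimum where the per-stage relative time
    ``x = gamma<T>/N`` solves the transcendental equation

        (1 - x) e^{2x} = 1,   0 < x < 1

    whose unique positive root is x* ~= 0.797; the cascade optimum is
    simply ``N x*``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return n * _per_stage_root()


def _per_stage_root() -> float:
    # (1-x)e^{2x}-1 is positive at 0+ and negative at 1-; unique sign change
    f = lambda x: (1.0 - x) * np.exp(2.0 * x) - 1.0
    return brentq(f, 1e-9, 1.0 - 1e-9, xtol=1e-14, rtol=8.9e-16)


def min_noise_identical(n: int, cv2_1: float) -> float:
    """Minimum achievable FPT noise of N identical genes, free mean time.

    Evaluating the identical-gene noise at ``gamma<T>* = N x*`` collapses
    to ``CV_1^2 / (N x* (1 - x*))`` — about ``6.18 CV_1^2 / N`` — so the
    floor on timing noise falls off as 1/N in cascade length.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not cv2_1 > 0:
        raise ValueError("cv2_1 must be > 0")
    x = _per_stage_root()
    return cv2_1 / (n * x * (1.0 - x))
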