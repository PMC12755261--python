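"""Small-noise first-passage-time statistics for activation cascades.

The first-passage time (FPT) of a cascade is the instant the last gene
product crosses its threshold.  Under step activation the stages are
independent, so the total FPT is a sum of per-stage crossing times.  In the
small-noise regime each stage's statistics follow from the deterministic
mean trajectory and the protein variance at the threshold:

    <T_i>        = (1/gamma) ln 1/(1 - alpha_i)
    CV_{T_i}^2   via the slope of the mean trajectory at the crossing

which combine into, for a cascade of relative thresholds alpha_1..alpha_N
and intrinsic noises CV_1^2..CV_N^2,

    gamma <T> = sum_i -ln(1 - alpha_i)
    CV_T^2    = (1 / (gamma <T>)^2) sum_i CV_i^2 alpha_i (2 - alpha_i)
                                           / (1 - alpha_i)^2

All functions are vectorized over alpha so threshold sweeps are cheap, and
accept either a dilution rate in min^-1 or (where the quantity is
dimensionless) the product ``gamma <T>`` directly.  The approximation is
accurate for thresholds well separated from both zero and steady state; it
overestimates the noise as alpha -> 0 or alpha -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TheoryPrediction",
    "mean_fpt_single",
    "fpt_noise_single",
    "fpt_noise_two_gene",
    "fpt_stats_cascade",
    "fpt_noise_identical",
]


@dataclass(frozen=True)
class TheoryPrediction:
    """Analytic FPT statistics for one cascade parameterization."""

    mean_T: float  # minutes
    cv2_T: float  # dimensionless, var(T)/<T>^2
    per_stage_alphas: tuple[float, ...] = field(default_factory=tuple)
    #: True when every alpha lies strictly inside (0, 1 - e^{-gamma <T>}),
    #: the region where no single stage absorbs the whole mean.
    regime_valid: bool = True

    def to_dict(self) -> dict:
        return {
            "mean_T": self.mean_T,
            "cv2_T": self.cv2_T,
            "per_stage_alphas": list(self.per_stage_alphas),
            "regime_valid": self.regime_valid,
        }


def _check_open_unit(alpha, name: str = "alpha") -> np.ndarray:
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0) or np.any(a >= 1):
        raise ValueError(f"{name} must lie in the open interval (0, 1)")
    return a


def mean_fpt_single(alpha, gamma: float = 1.0):
    """Mean crossing time of a single gene: ``(1/gamma) ln 1/(1-alpha)``.

    With the default ``gamma=1`` the result is the dimensionless relative
    time ``gamma <T>``.
    """
    a = _check_open_unit(alpha)
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    out = -np.log1p(-a) / gamma
    return float(out) if np.isscalar(alpha) else out


def fpt_noise_single(alpha, cv2_gene):
    """Squared CV of a single gene's crossing time.

    ``CV_T^2 = CV_1^2 * alpha (2 - alpha) / [(1 - alpha)^2 ln^2(1 - alpha)]``

    Convex in alpha: too low a threshold is crossed during the steep noisy
    rise, too high a threshold sits where the mean trajectory flattens out,
    so an intermediate threshold is optimal.
    """
    a = _check_open_unit(alpha)
    cv2 = np.asarray(cv2_gene, dtype=float)
    if np.any(cv2 <= 0):
        raise ValueError("cv2_gene must be > 0")
    out = cv2 * a * (2.0 - a) / ((1.0 - a) ** 2 * np.log1p(-a) ** 2)
    return float(out) if np.isscalar(alpha) and np.isscalar(cv2_gene) else out


def fpt_noise_two_gene(alpha2, cv2_1: float, cv2_2: float, gammaT: float):
    """Total FPT noise of a two-gene cascade as a function of ``alpha2``.

    The mean constraint ``(1-alpha1)(1-alpha2) = e^{-gamma<T>}`` eliminates
    alpha1, leaving

        CV_T^2 = [ CV_1^2 ((1-alpha2)^2 e^{2 gamma T} - 1)
                   + CV_2^2 alpha2 (2-alpha2)/(1-alpha2)^2 ] / (gamma T)^2

    on the feasible range ``0 <= alpha2 < 1 - e^{-gamma T}``.  At
    ``alpha2 = 0`` this reduces to the single-gene value at
    ``alpha = 1 - e^{-gamma T}``.
    """
    if not gammaT > 0:
        raise ValueError(f"gammaT must be > 0, got {gammaT}")
    a2 = np.asarray(alpha2, dtype=float)
    upper = 1.0 - np.exp(-gammaT)
    if np.any(a2 < 0) or np.any(a2 >= upper):
        raise ValueError(
            f"alpha2 must satisfy 0 <= alpha2 < 1 - e^-gammaT = {upper:.6g}"
        )
    one_m = 1.0 - a2
    val = (
        cv2_1 * (one_m**2 * np.exp(2.0 * gammaT) - 1.0)
        + cv2_2 * a2 * (2.0 - a2) / one_m**2
    ) / gammaT**2
    return float(val) if np.isscalar(alpha2) else val


def fpt_stats_cascade(alphas, cv2_list, gamma: float) -> TheoryPrediction:
    """Mean and noise of the total FPT for an N-stage cascade.

    Stages with ``alpha_i = 0`` are unused genes and contribute neither
    time nor variance.  The symmetric sum form is used throughout, so no
    stage is singled out as the dependent variable.
    """
    a = np.asarray(alphas, dtype=float)
    cv2 = np.asarray(cv2_list, dtype=float)
    if a.shape != cv2.shape or a.ndim != 1:
        raise ValueError("alphas and cv2_list must be 1-D of equal length")
    if np.any(a < 0) or np.any(a >= 1):
        raise ValueError("each alpha must lie in [0, 1)")
    if np.any(cv2 <= 0):
        raise ValueError("intrinsic noises must be > 0")
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")

    gT = -np.sum(np.log1p(-a))
    if gT == 0:
        raise ValueError("at least one alpha must be positive")
    mean_T = gT / gamma
    cv2_T = float(np.sum(cv2 * a * (2.0 - a) / (1.0 - a) ** 2) / gT**2)
    upper = 1.0 - np.exp(-gT)
    valid = bool(np.all((a > 0) & (a < upper))) if len(a) > 1 else True
    return TheoryPrediction(
        mean_T=float(mean_T),
        cv2_T=cv2_T,
        per_stage_alphas=tuple(float(x) for x in a),
        regime_valid=valid,
    )


def fpt_noise_identical(n: int, cv2_1: float, gammaT):
    """FPT noise of N identical genes at the shared optimal-split threshold.

    With every stage at ``alpha = 1 - e^{-gamma<T>/N}``,

        CV_T^2 = CV_1^2 N (e^{2 gamma<T>/N} - 1) / (gamma<T>)^2

    which decreases with N at fixed total mean: longer cascades of equally
    noisy genes are better timers.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    x = np.asarray(gammaT, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gammaT must be > 0")
    out = cv2_1 * n * (np.exp(2.0 * x / n) - 1.0) / x**2
    return float(out) if np.isscalar(gammaT) else out
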