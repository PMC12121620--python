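"""Per-peak termination calling against a per-locus 2-D noise model.

Within a user-defined region around each riboswitch, every convolution
peak other than the one under test forms the "noise set". A bivariate
normal over (width, |amplitude|) is fitted to that set; the probability
that a draw from the fitted normal is less likely than the observed
peak, ``exp(-d^2 / 2)`` for squared Mahalanobis distance ``d^2``, serves
as a pseudo p-value. A positive peak is called a transcription
termination event when it is significant against the noise model and
the total coverage falls across the peak by at least the configured
fraction of mean riboswitch coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coverage import CoverageProfile
from .edges import Peak

#: fail reasons, in the order the criteria are checked
FAIL_REASONS = (
    "wrong_sign",
    "outside_region",
    "insufficient_noise_set",
    "not_significant",
    "insufficient_drop",
    "none",
)


@dataclass
class NoiseModel:
    """Bivariate normal over (width, |amplitude|) of a locus's noise peaks."""

    mean: np.ndarray
    covariance: np.ndarray
    n_peaks: int


@dataclass
class PeakCall:
    peak: Peak
    pseudo_p: float
    coverage_drop_fraction: float
    decision: str  # pass | fail
    fail_reason: str
    noise_model: Optional[NoiseModel] = None


def noise_region(
    riboswitch_start: int,
    riboswitch_end: int,
    ext_prop: tuple[float, float] = (-0.3, 1.0),
    window_length: Optional[int] = None,
) -> tuple[int, int]:
    """Noise-set region scaled to riboswitch size.

    The region runs from ``start - ext_prop[0] * size`` to
    ``end + ext_prop[1] * size``. With the default ``(-0.3, 1.0)`` it
    excludes the first 30% of the riboswitch, keeps the remainder, and
    continues one full riboswitch length past the 3' end. Clipped to
    window bounds when ``window_length`` is given.
    """
    size = riboswitch_end - riboswitch_start
    if size <= 0:
        raise ValueError("riboswitch size must be positive")
    lo = int(round(riboswitch_start - ext_prop[0] * size))
    hi = int(round(riboswitch_end + ext_prop[1] * size))
    lo = max(lo, 0)
    if window_length is not None:
        hi = min(hi, window_length)
    if hi <= lo:
        raise ValueError("noise region is empty after clipping")
    return lo, hi


def fit_noise_model(
    peaks_in_region: Sequence[Peak],
    exclude: Optional[Peak] = None,
    min_noise_set: int = 3,
) -> Optional[NoiseModel]:
    """Fit the 2-D noise model to all region peaks except the one under test.

    Both peak signs contribute, on |amplitude|; they share the
    fragmentation/library noise processes the model is meant to capture.
    Returns None when fewer than ``min_noise_set`` peaks remain (the
    caller fails the peak with reason ``insufficient_noise_set``).
    """
    noise = [p for p in peaks_in_region if p is not exclude]
    if len(noise) < min_noise_set:
        return None
    xy = np.array([[p.width, abs(p.amplitude)] for p in noise], dtype=float)
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        cov = cov + 1e-9 * np.eye(2)
    return NoiseModel(mean=mean, covariance=cov, n_peaks=len(noise))


def pseudo_p_value(peak: Peak, model: NoiseModel) -> float:
    """Probability that a bivariate-normal draw is less likely than this peak.

    For squared Mahalanobis distance ``d^2``, this tail probability is
    exactly ``exp(-d^2 / 2)`` under a 2-D normal, giving a scale-free
    pseudo p-value in (0, 1].
    """
    x = np.array([peak.width, abs(peak.amplitude)], dtype=float)
    diff = x - model.mean
    try:
        d2 = float(diff @ np.linalg.solve(model.covariance, diff))
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance singular after regularization") from exc
    if d2 < 0:  # numerical guard for near-singular covariance
        d2 = 0.0
    return math.exp(-d2 / 2.0)


def coverage_drop(peak: Peak, profile: CoverageProfile) -> float:
    """Fractional coverage change across the peak bounds.

    ``(total[right_bound] - total[left_bound]) / mean riboswitch total
    coverage``; the exclusive right bound is used (clipped to the last
    window base). Negative values are drops; a termination event shows a
    strong drop.
    """
    total = profile.total_coverage
    mean_cov = profile.mean_riboswitch_read_coverage
    if mean_cov == 0:
        raise ValueError("zero mean riboswitch coverage (depth filter should prevent)")
    left = peak.left_bound
    right = min(peak.right_bound, len(total) - 1)
    return float((total[right] - total[left]) / mean_cov)


def call_peak(
    peak: Peak,
    peaks_in_region: Sequence[Peak],
    profile: CoverageProfile,
    region: tuple[int, int],
    alpha: float = 0.05,
    min_drop: float = 0.20,
    min_noise_set: int = 3,
) -> PeakCall:
    """Evaluate one peak as a candidate transcription termination event.

    Criteria, in order: positive sign; summit inside the noise region;
    a large enough noise set; pseudo p below ``alpha``; coverage drop of
    at least ``min_drop`` of mean riboswitch coverage.
    """
    drop = coverage_drop(peak, profile)
    peak.fractional_coverage_change = drop

    if peak.sign != "+":
        return PeakCall(peak, float("nan"), drop, "fail", "wrong_sign")
    if not (region[0] <= peak.summit < region[1]):
        return PeakCall(peak, float("nan"), drop, "fail", "outside_region")
    model = fit_noise_model(peaks_in_region, exclude=peak, min_noise_set=min_noise_set)
    if model is None:
        return PeakCall(peak, float("nan"), drop, "fail", "insufficient_noise_set")
    p = pseudo_p_value(peak, model)
    if not p < alpha:
        return PeakCall(peak, p, drop, "fail", "not_significant", model)
    if not drop <= -min_drop:
        return PeakCall(peak, p, drop, "fail", "insufficient_drop", model)
    return PeakCall(peak, p, drop, "pass", "none", model)
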