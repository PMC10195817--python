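"""FRAP normalization and single-exponential recovery fitting.

Raw bleach-ROI, reference-ROI and background series are double-normalized
(correcting acquisition photobleaching via the reference) and then
full-scale normalized (bleach floor 0, pre-bleach plateau 1), so the fitted
plateau of I(t) = M·(1 − e^(−k·t)) is directly the mobile fraction and
t½ = ln 2 / k the recovery half-time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from smquant.io import ParameterError
from smquant.simulate import FRAPTrace

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedFRAP:
    t: np.ndarray            # s, original clock
    intensity: np.ndarray    # full-scale normalized
    bleach_index: int

    @property
    def t_post(self) -> np.ndarray:
        """Time since the bleach for the post-bleach samples."""
        return self.t[self.bleach_index:] - self.t[self.bleach_index]

    @property
    def i_post(self) -> np.ndarray:
        return self.intensity[self.bleach_index:]


@dataclass
class FRAPFit:
    t_half: float            # s
    mobile_fraction: float
    k: float                 # 1/s
    residual: float          # RMS of fit residuals
    failed: bool = False


def normalize_frap(trace: FRAPTrace) -> NormalizedFRAP:
    """Double + full-scale normalization of a raw FRAP trace.

    I_dn(t) = [ref_pre / (ref(t) − bg)] · [(frap(t) − bg) / frap_pre] with
    pre-bleach means taken over all frames before ``bleach_index``; then
    I_fs(t) = (I_dn(t) − I_dn(t_bleach)) / (1 − I_dn(t_bleach)). The
    pre-bleach mean of I_fs is 1 up to noise and I_fs at the bleach frame
    is exactly 0.
    """
    ref = trace.reference_roi - trace.background
    frap = trace.bleach_roi - trace.background
    if np.any(ref <= 0):
        bad = int(np.argmax(ref <= 0))
        raise NormalizationError(
            f"reference minus background is non-positive at frame {bad}"
        )
    pre = slice(0, trace.bleach_index)
    ref_pre = float(np.mean(ref[pre]))
    frap_pre = float(np.mean(frap[pre]))
    if frap_pre <= 0:
        raise NormalizationError("pre-bleach bleach-ROI mean is non-positive")
    i_dn = (ref_pre / ref) * (frap / frap_pre)
    floor = i_dn[trace.bleach_index]
    if floor >= 1.0:
        raise NormalizationError("no bleach depth: I_dn at bleach frame >= 1")
    i_fs = (i_dn - floor) / (1.0 - floor)
    return NormalizedFRAP(t=trace.t, intensity=i_fs,
                          bleach_index=trace.bleach_index)


def fit_recovery(norm: NormalizedFRAP) -> FRAPFit:
    """Least-squares fit of I(t) = M·(1 − e^(−k·t)) to the post-bleach curve.

    Initial guesses: M from the final-quartile mean; k from the linearly
    interpolated time at which the curve first reaches M/2. Mobile fractions
    outside [0, 1] are clipped with a warning.
    """
    t = norm.t_post
    y = norm.i_post
    if len(t) < 10:
        raise ParameterError("need at least 10 post-bleach samples")
    m0 = float(np.mean(y[-max(1, len(y) // 4):]))
    m0 = min(max(m0, 1e-3), 1.5)
    t_half0 = _time_to_half(t, y, m0)
    k0 = np.log(2.0) / t_half0 if t_half0 > 0 else 1.0 / max(t[-1], 1.0)
    try:
        popt, _ = curve_fit(
            lambda tt, m, k: m * (1.0 - np.exp(-k * tt)),
            t, y, p0=(m0, k0), maxfev=10000,
        )
    except RuntimeError:
        logger.warning("FRAP fit failed to converge (initial guess M=%.3g, k=%.3g)",
                       m0, k0)
        return FRAPFit(t_half=np.nan, mobile_fraction=np.nan, k=np.nan,
                       residual=np.nan, failed=True)
    m, k = popt
    if not (0.0 <= m <= 1.0):
        logger.warning("fitted mobile fraction %.3f outside [0, 1]; clipped", m)
        m = float(np.clip(m, 0.0, 1.0))
    resid = y - popt[0] * (1.0 - np.exp(-popt[1] * t))
    return FRAPFit(
        t_half=float(np.log(2.0) / k),
        mobile_fraction=float(m),
        k=float(k),
        residual=float(np.sqrt(np.mean(resid ** 2))),
    )


def _time_to_half(t: np.ndarray, y: np.ndarray, m: float) -> float:
    """First linearly interpolated crossing of m/2; ~t[-1]/4 fallback."""
    half = m / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return float(t[-1] / 4.0) if len(above) == 0 else float(max(t[1] / 2, 1e-6))
    j = above[0]
    t0, t1 = t[j - 1], t[j]
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(t1)
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))
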