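"""Temporal preprocessing of BOLD runs.

The fixed stage order is: discard initial volumes -> linear detrend ->
ideal band-pass.  Motion screening consumes tabulated per-subject maxima
(translation mm, rotation degrees); this package does not estimate motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import ConfigError
from .io import BoldSeries, PipelineConfig


@dataclass
class MotionScreenResult:
    subject_id: str
    max_translation: float
    max_rotation: float
    excluded: bool


def discard_initial_volumes(bold: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (steady-state magnetization)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= bold.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes"
        )
    if n_discard == 0:
        return bold.with_data(bold.data.copy())
    return bold.with_data(bold.data[..., n_discard:])


def screen_head_motion(max_translation_mm: float, max_rotation_deg: float,
                       limits: tuple[float, float] = (1.0, 1.0),
                       subject_id: str = "") -> MotionScreenResult:
    """Flag a subject for exclusion when motion *exceeds* either limit.

    The boundary itself (exactly at the limit) is retained: exclusion uses
    strict inequality.
    """
    if max_translation_mm < 0 or max_rotation_deg < 0:
        raise ValueError("motion maxima must be non-negative")
    limit_mm, limit_deg = limits
    excluded = (max_translation_mm > limit_mm) or (max_rotation_deg > limit_deg)
    return MotionScreenResult(
        subject_id=subject_id,
        max_translation=float(max_translation_mm),
        max_rotation=float(max_rotation_deg),
        excluded=bool(excluded),
    )


def detrend_linear(bold: BoldSeries) -> BoldSeries:
    """Remove the per-voxel least-squares line (intercept + slope * t)."""
    if bold.n_volumes < 3:
        raise ValueError("linear detrending needs at least 3 time points")
    out = scipy.signal.detrend(bold.data, axis=-1, type="linear")
    return bold.with_data(out)


def bandpass_ideal(bold: BoldSeries, low: float, high: float) -> BoldSeries:
    """Ideal (rectangular) frequency-domain band-pass filter.

    Discrete Fourier bins whose frequency f satisfies ``low <= f <= high``
    (inclusive edges) are retained; all other bins — including DC whenever
    ``low > 0`` — are zeroed.  The output is real-valued.
    """
    nyquist = 1.0 / (2.0 * bold.tr)
    if not (0 <= low < high):
        raise ConfigError(f"band must satisfy 0 <= low < high, got ({low}, {high})")
    if high > nyquist + 1e-12:
        raise ConfigError(f"band upper edge {high} Hz exceeds Nyquist {nyquist} Hz")
    n = bold.n_volumes
    freqs = np.fft.rfftfreq(n, d=bold.tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    spec = np.fft.rfft(bold.data, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=-1)
    return bold.with_data(out)


def preprocess_bold(bold: BoldSeries, config: PipelineConfig) -> BoldSeries:
    """Apply the full temporal chain: discard -> detrend -> band-pass."""
    out = discard_initial_volumes(bold, config.n_discard)
    out = detrend_linear(out)
    low, high = config.band
    return bandpass_ideal(out, low, high)
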