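"""Spectrum preprocessing: baseline subtraction, m/z windowing, TIC scaling.

The fixed order of operations is subtract -> window -> normalize, so signal
below the analysis window never influences total-ion-current scaling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from seldi_nodal.spectra_io import Spectrum

logger = logging.getLogger(__name__)


def _window_size_points(spectrum: Spectrum, half_width: float) -> int:
    step = float(np.median(np.diff(spectrum.mz))) if len(spectrum) > 1 else 1.0
    half_points = max(1, int(round(half_width / step)))
    return 2 * half_points + 1


def subtract_baseline(spectrum: Spectrum, half_width: float = 150.0) -> Spectrum:
    """Remove the slowly varying baseline under the peaks.

    The baseline is a rolling minimum over +-``half_width`` (Da) followed by
    a rolling mean of the same width, clipped so it stays nonnegative and
    never exceeds the measured envelope. Output intensity is
    max(input - baseline, 0).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    size = _window_size_points(spectrum, half_width)
    if len(spectrum) < size:
        raise ValueError(
            f"spectrum of {len(spectrum)} points shorter than the "
            f"{size}-point baseline window"
        )
    eroded = ndimage.minimum_filter1d(spectrum.intensity, size, mode="nearest")
    smooth = ndimage.uniform_filter1d(eroded, size, mode="nearest")
    baseline = np.minimum(np.maximum(smooth, 0.0), spectrum.intensity)
    out = spectrum.copy()
    out.intensity = np.maximum(spectrum.intensity - baseline, 0.0)
    out.meta["baseline_half_width"] = half_width
    return out


def window_mz(spectrum: Spectrum, mz_min: float = 2000.0,
              mz_max: float = 20000.0) -> Spectrum:
    """Keep only points with mz_min <= m/z <= mz_max."""
    if mz_min >= mz_max:
        raise ValueError("require mz_min < mz_max")
    mask = (spectrum.mz >= mz_min) & (spectrum.mz <= mz_max)
    if not mask.any():
        raise ValueError(
            f"window [{mz_min}, {mz_max}] retains no points of spectrum "
            f"{spectrum.sample_id!r}"
        )
    out = spectrum.copy()
    out.mz = spectrum.mz[mask]
    out.intensity = spectrum.intensity[mask]
    return out


def normalize_tic(spectra: list) -> list:
    """Scale every spectrum so its TIC equals the cohort mean TIC.

    Spectra must already be baseline-subtracted and windowed to a common
    range. Zero-TIC spectra are excluded with a logged warning (never
    silently scaled). Scale factors are recorded in each spectrum's
    ``meta`` (``tic_raw``, ``tic_scale``).
    """
    if not spectra:
        return []
    tics = np.array([float(np.sum(s.intensity)) for s in spectra])
    keep = tics > 0
    if not keep.any():
        logger.warning("normalize_tic: all spectra have zero TIC; nothing to scale")
        return []
    target = float(np.mean(tics[keep]))
    out = []
    for s, tic, ok in zip(spectra, tics, keep):
        if not ok:
            logger.warning("normalize_tic: excluding zero-TIC spectrum %r",
                           s.sample_id)
            continue
        scaled = s.copy()
        scale = target / tic
        scaled.intensity = s.intensity * scale
        scaled.meta["tic_raw"] = tic
        scaled.meta["tic_scale"] = scale
        out.append(scaled)
    return out


def preprocess_cohort(spectra, mz_min: float = 2000.0, mz_max: float = 20000.0,
                      baseline_half_width: float = 150.0) -> list:
    """subtract_baseline -> window_mz -> normalize_tic over a whole cohort."""
    stage = [window_mz(subtract_baseline(s, baseline_half_width), mz_min, mz_max)
             for s in spectra]
    return normalize_tic(stage)
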