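"""Two-pass peak detection and cross-spectrum clustering.

First pass: per-spectrum local maxima at S/N >= 3, kept when present in at
least 20% of spectra; peaks are greedily agglomerated across spectra within
a 0.5% mass window (ordered by descending prevalence, ties by ascending
m/z). Second pass: the sample x cluster matrix is completed by taking the
window maximum at a relaxed S/N of 2, flagging cells that fall below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from seldi_nodal.spectra_io import Spectrum


@dataclass
class Peak:
    mz: float
    height: float
    snr: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.height < 0 or self.snr < 0:
            raise ValueError("peak height and snr must be >= 0")


@dataclass
class PeakCluster:
    cluster_id: int
    mz_center: float
    window: tuple  # (lo, hi) in Da
    prevalence: int = 0

    def contains(self, mz: float) -> bool:
        lo, hi = self.window
        return lo <= mz <= hi


@dataclass
class PeakMatrix:
    """samples x peak-cluster intensity table; the pipeline's feature table."""

    sample_ids: list
    clusters: list
    values: np.ndarray
    labels: list
    below_snr: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length mismatch with values")
        if len(self.clusters) != k:
            raise ValueError("clusters length mismatch with values")
        if np.any(np.isnan(self.values)):
            raise ValueError("peak matrix must be complete (no missing cells)")
        if np.any(self.values < 0):
            raise ValueError("peak matrix values must be nonnegative")
        centers = [c.mz_center for c in self.clusters]
        if centers != sorted(centers):
            raise ValueError("clusters must be sorted by mz_center")
        if self.below_snr is None:
            self.below_snr = np.zeros_like(self.values, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_names(self) -> list:
        return [f"mz_{int(round(c.mz_center))}" for c in self.clusters]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster_id": [c.cluster_id for c in self.clusters],
            "mz_center": [c.mz_center for c in self.clusters],
            "window_lo": [c.window[0] for c in self.clusters],
            "window_hi": [c.window[1] for c in self.clusters],
            "prevalence": [c.prevalence for c in self.clusters],
        })

    @classmethod
    def from_csv(cls, path) -> "PeakMatrix":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["sample_id", "label"]:
            raise ValueError("matrix CSV must start with sample_id,label columns")
        centers = [float(c.split("_", 1)[1]) for c in df.columns[2:]]
        clusters = [
            PeakCluster(cluster_id=i, mz_center=c,
                        window=(c * 0.9975, c * 1.0025))
            for i, c in enumerate(centers)
        ]
        return cls(sample_ids=df["sample_id"].tolist(), clusters=clusters,
                   values=df.iloc[:, 2:].to_numpy(float),
                   labels=df["label"].tolist())


# ---------------------------------------------------------------------------
# Noise estimation and per-spectrum detection
# ---------------------------------------------------------------------------

def _trend_and_noise(y: np.ndarray, window_points: int) -> tuple:
    size = min(window_points, len(y)) | 1  # odd
    trend = ndimage.median_filter(y, size=size, mode="nearest")
    mad = ndimage.median_filter(np.abs(y - trend), size=size, mode="nearest")
    return trend, 1.4826 * mad


def estimate_noise(spectrum: Spectrum, window_points: int = 151) -> np.ndarray:
    """Pointwise noise level: 1.4826 x sliding MAD of the detrended signal."""
    if window_points < 11:
        raise ValueError("window_points must be >= 11")
    y = spectrum.intensity
    if len(y) == 0:
        return np.array([])
    return _trend_and_noise(y, window_points)[1]


def _detection_fields(y: np.ndarray, noise_window_points: int,
                      smooth_points: int) -> tuple:
    """(smoothed signal, local trend, floored noise) used by both passes.

    Returns (smoothed signal, median trend, floored noise, background).
    The median trend feeds the S/N criterion; the morphological (rolling
    minimum then mean) background is the height reference — unlike the
    median it cannot ride up on peak tails in crowded regions. The
    pointwise noise is floored at the spectrum-wide median so that regions
    where zero-clipping after baseline subtraction collapses the MAD
    cannot produce runaway S/N values.
    """
    if smooth_points > 1:
        ys = ndimage.uniform_filter1d(y, size=smooth_points, mode="nearest")
    else:
        ys = y
    trend, noise = _trend_and_noise(ys, noise_window_points)
    size = min(noise_window_points, len(ys)) | 1
    background = ndimage.uniform_filter1d(
        ndimage.minimum_filter1d(ys, size, mode="nearest"), size,
        mode="nearest")
    background = np.minimum(np.maximum(background, 0.0), ys)
    positive = noise[noise > 0]
    if positive.size:
        noise = np.maximum(noise, float(np.median(positive)))
    return ys, trend, noise, background


def detect_peaks(spectrum: Spectrum, snr_min: float = 3.0,
                 noise_window_points: int = 151,
                 neighborhood_fraction: float = 0.0025,
                 smooth_points: int = 5) -> list:
    """Local maxima with S/N >= ``snr_min``.

    Candidates are local maxima of a lightly smoothed copy of the signal;
    S/N is the smoothed height above the local median trend divided by the
    smoothed noise level, so slow residual background never counts as
    signal. A candidate must further be the largest within a
    resolution-scaled neighbourhood of +-``neighborhood_fraction`` x m/z
    (non-maximum suppression, largest first). Apex m/z and height are then
    refined on the raw signal by a three-point parabola; the reported
    height is the apex above the local trend.
    """
    y = spectrum.intensity
    if len(y) < 3 or not np.any(y > 0):
        return []
    ys, trend, noise, background = _detection_fields(y, noise_window_points,
                                                     smooth_points)
    idx, _ = signal.find_peaks(ys)
    # S/N is ill-defined where the noise window is truncated by the edges
    margin = min(noise_window_points // 2, (len(y) - 1) // 3)
    idx = idx[(idx >= margin) & (idx <= len(y) - 1 - margin)]
    if idx.size == 0:
        return []
    prominence = ys[idx] - trend[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise[idx] > 0, prominence / noise[idx],
                       np.where(prominence > 0, np.inf, 0.0))
    ok = (snr >= snr_min) & (prominence > 0)
    idx, snr = idx[ok], snr[ok]
    if idx.size == 0:
        return []
    # non-maximum suppression within the relative neighbourhood
    heights = ys[idx]
    order = np.argsort(-heights, kind="stable")
    mz_cand = spectrum.mz[idx]
    accepted: list[int] = []
    accepted_mz: list[float] = []
    for j in order:
        radius = neighborhood_fraction * mz_cand[j]
        if all(abs(mz_cand[j] - m) > radius for m in accepted_mz):
            accepted.append(j)
            accepted_mz.append(mz_cand[j])
    half = max(1, smooth_points // 2)
    peaks = []
    for j in sorted(accepted, key=lambda j: mz_cand[j]):
        i = idx[j]
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        i_raw = lo + int(np.argmax(y[lo:hi]))
        mz_hat, h_hat = _parabolic_apex(spectrum.mz, y, i_raw)
        peaks.append(Peak(mz=mz_hat,
                          height=max(h_hat - background[i_raw], 0.0),
                          snr=float(snr[j]), sample_id=spectrum.sample_id))
    return peaks


def _parabolic_apex(mz: np.ndarray, y: np.ndarray, i: int) -> tuple:
    if i == 0 or i == len(y) - 1:
        return float(mz[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not concave; keep the grid apex
        return float(mz[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = 0.5 * (mz[i + 1] - mz[i - 1])
    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return float(mz[i] + delta * step), float(height)


# ---------------------------------------------------------------------------
# First pass: greedy cross-spectrum clustering + prevalence filter
# ---------------------------------------------------------------------------

def first_pass_filter(per_spectrum_peaks: dict, min_fraction: float = 0.20,
                      window: float = 0.005) -> list:
    """Cluster first-pass peaks across spectra; keep prevalent clusters.

    ``per_spectrum_peaks`` maps sample_id -> list of Peak (the dict covers
    every spectrum, including peak-free ones, so the denominator of the
    prevalence fraction is the cohort size). Greedy agglomeration: the
    candidate window (+- window/2 x m/z) holding peaks from the most
    distinct spectra is made a cluster, its members removed, repeat. Ties
    break toward ascending m/z. Clusters whose members come from
    >= ``min_fraction`` of spectra are retained.
    """
    if not (0 <= min_fraction <= 1):
        raise ValueError("min_fraction must be in [0, 1]")
    n_spectra = len(per_spectrum_peaks)
    if n_spectra == 0:
        raise ValueError("at least one spectrum required")
    all_peaks = [p for peaks in per_spectrum_peaks.values() for p in peaks]
    if not all_peaks:
        return []
    sample_index = {sid: i for i, sid in enumerate(per_spectrum_peaks)}
    mz = np.array([p.mz for p in all_peaks])
    samp = np.array([sample_index[p.sample_id] for p in all_peaks])
    order = np.argsort(mz, kind="stable")
    mz, samp = mz[order], samp[order]
    peaks_sorted = [all_peaks[i] for i in order]
    half = window / 2.0

    clusters = []
    alive = np.ones(len(mz), dtype=bool)
    while alive.any():
        live_idx = np.flatnonzero(alive)
        live_mz = mz[live_idx]
        lo = np.searchsorted(live_mz, live_mz * (1 - half), side="left")
        hi = np.searchsorted(live_mz, live_mz * (1 + half), side="right")
        counts = np.array([
            len(np.unique(samp[live_idx[l:h]])) for l, h in zip(lo, hi)
        ])
        best = int(np.argmax(counts))  # first max -> smallest m/z on ties
        members = live_idx[lo[best]:hi[best]]
        prevalence = int(counts[best])
        clusters.append({
            "mz_center": float(np.mean(mz[members])),
            "members": [peaks_sorted[i] for i in members],
            "prevalence": prevalence,
        })
        alive[members] = False

    kept = [c for c in clusters
            if c["prevalence"] / n_spectra >= min_fraction]
    kept.sort(key=lambda c: c["mz_center"])
    return kept


# ---------------------------------------------------------------------------
# Second pass: matrix completion
# ---------------------------------------------------------------------------

def cluster_and_complete(spectra, provisional_clusters, window: float = 0.005,
                         snr_second: float = 2.0,
                         noise_window_points: int = 151,
                         smooth_points: int = 5) -> PeakMatrix:
    """Build the complete sample x cluster matrix.

    A cell takes the matched first-pass peak height when the spectrum
    contributed one; otherwise the maximum intensity inside the cluster
    window (its S/N checked against ``snr_second``; below-threshold fills
    are recorded in ``below_snr`` but still kept, so the matrix has no
    holes). Cluster windows of +-``window/2`` x center are clipped at
    midpoints between adjacent centers so they never overlap.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra")
    clusters_in = sorted(provisional_clusters, key=lambda c: c["mz_center"])
    centers = [c["mz_center"] for c in clusters_in]
    half = window / 2.0
    final = []
    for k, c in enumerate(centers):
        lo, hi = c * (1 - half), c * (1 + half)
        if k > 0:
            lo = max(lo, 0.5 * (centers[k - 1] + c))
        if k + 1 < len(centers):
            hi = min(hi, 0.5 * (c + centers[k + 1]))
        final.append(PeakCluster(cluster_id=k, mz_center=c, window=(lo, hi),
                                 prevalence=clusters_in[k]["prevalence"]))
    for a, b in zip(final, final[1:]):
        if a.window[1] > b.window[0]:
            raise RuntimeError(
                f"internal error: cluster windows overlap at "
                f"{a.mz_center:.1f}/{b.mz_center:.1f}"
            )

    matched = {}
    for k, c in enumerate(clusters_in):
        for p in c["members"]:
            if final[k].contains(p.mz):
                key = (p.sample_id, k)
                if key not in matched or p.height > matched[key]:
                    matched[key] = p.height

    n, m = len(spectra), len(final)
    values = np.zeros((n, m))
    flags = np.zeros((n, m), dtype=bool)
    for i, s in enumerate(spectra):
        ys, _, noise, background = _detection_fields(
            s.intensity, noise_window_points, smooth_points)
        for k, cl in enumerate(final):
            got = matched.get((s.sample_id, k))
            if got is not None:
                values[i, k] = got
                continue
            lo_i = np.searchsorted(s.mz, cl.window[0], side="left")
            hi_i = np.searchsorted(s.mz, cl.window[1], side="right")
            if lo_i >= hi_i:
                values[i, k] = 0.0
                flags[i, k] = True
                continue
            # S/N judged in the smoothed detection channel; the recorded
            # value is the raw window maximum above the local background
            seg = ys[lo_i:hi_i] - background[lo_i:hi_i]
            j = lo_i + int(np.argmax(seg))
            height = float(max(s.intensity[j] - background[j], 0.0))
            snr = seg[j - lo_i] / noise[j] if noise[j] > 0 else (
                np.inf if seg[j - lo_i] > 0 else 0.0)
            values[i, k] = height
            flags[i, k] = snr < snr_second
    return PeakMatrix(sample_ids=[s.sample_id for s in spectra],
                      clusters=final, values=values,
                      labels=[s.label for s in spectra], below_snr=flags)


def build_peak_matrix(spectra, snr_first: float = 3.0,
                      min_fraction: float = 0.20, window: float = 0.005,
                      snr_second: float = 2.0,
                      noise_window_points: int = 151) -> PeakMatrix:
    """Run the full two-pass procedure on preprocessed spectra."""
    per_spectrum = {
        s.sample_id: detect_peaks(s, snr_min=snr_first,
                                  noise_window_points=noise_window_points,
                                  neighborhood_fraction=window / 2.0)
        for s in spectra
    }
    provisional = first_pass_filter(per_spectrum, min_fraction=min_fraction,
                                    window=window)
    return cluster_and_complete(spectra, provisional, window=window,
                                snr_second=snr_second,
                                noise_window_points=noise_window_points)
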