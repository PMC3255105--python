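"""Synthetic SELDI spectrum generator.

Produces cohorts of spectra (or ready-made feature matrices) whose
class-conditional peak intensities follow the published 22 differential
peaks, padded with 24 nuisance peaks of equal class means to a 46-peak
panel. Spectra are rendered as Gaussian peaks on a uniform m/z grid over
an exponentially decaying baseline with additive noise, per-spectrum mass
jitter and per-peak multiplicative intensity error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from seldi_nodal.spectra_io import (
    NODE_NEGATIVE,
    NODE_POSITIVE,
    Cohort,
    Spectrum,
    write_manifest,
    write_spectrum,
)

# The 22 differential peaks: (m/z, mean+, sd+, mean-, sd-) where +/- are the
# node-positive / node-negative classes, intensities on the normalized scale.
_DIFFERENTIAL_PEAKS = [
    (5867, 3.534, 0.547, 0.230, 0.107),
    (9290, 3.271, 0.587, 1.443, 0.103),
    (7970, 12.364, 1.08, 7.913, 0.668),
    (14433, 0.891, 0.168, 0.404, 0.102),
    (15621, 1.782, 0.609, 5.873, 0.655),
    (15824, 0.729, 0.111, 2.072, 0.255),
    (13652, 1.388, 0.168, 2.423, 0.259),
    (3781, 4.268, 0.216, 6.799, 0.977),
    (15006, 0.641, 0.150, 1.824, 0.084),
    (7802, 6.580, 0.504, 5.170, 0.635),
    (4497, 9.154, 0.639, 5.139, 0.916),
    (7504, 0.034, 0.005, 0.704, 0.271),
    (5967, 8.809, 0.705, 6.021, 0.879),
    (5808, 4.947, 0.797, 2.252, 0.990),
    (10057, 1.809, 0.301, 1.206, 0.245),
    (7597, 44.557, 1.121, 37.993, 1.763),
    (5786, 16.269, 1.880, 11.966, 0.994),
    (15089, 0.708, 0.198, 1.678, 0.042),
    (3104, 4.719, 0.478, 6.626, 0.791),
    (14869, 1.922, 0.653, 4.278, 1.079),
    (7620, 12.534, 2.920, 8.908, 1.474),
    (5662, 1.760, 0.601, 0.266, 0.131),
]

# Nuisance (non-differential) peaks: (m/z, mean). Positions are > 1% away
# from every differential peak and from each other; amplitudes are sized so
# that the class-independent signal dominates the total ion current and TIC
# normalization stays nearly class-neutral.
_NUISANCE_PEAKS = [
    (3250, 18.0), (3420, 7.0), (3600, 25.0), (3950, 11.0),
    (4150, 30.0), (4700, 5.0), (4950, 14.0), (5200, 40.0),
    (5450, 9.0), (6200, 22.0), (6500, 16.0), (6850, 6.0),
    (7150, 35.0), (8300, 12.0), (8700, 28.0), (9700, 8.0),
    (10500, 20.0), (11000, 15.0), (11600, 10.0), (12300, 24.0),
    (12900, 13.0), (16300, 9.0), (17200, 7.0), (18100, 5.0),
]
_NUISANCE_SD_FRACTION = 0.08


@dataclass(frozen=True)
class PeakSpec:
    """Class-conditional parameters for one planted peak."""

    mz_center: float
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    differential: bool

    def __post_init__(self) -> None:
        if self.sd_pos < 0 or self.sd_neg < 0:
            raise ValueError("peak SDs must be >= 0")

    def mean(self, label: str) -> float:
        return self.mean_pos if label == NODE_POSITIVE else self.mean_neg

    def sd(self, label: str) -> float:
        return self.sd_pos if label == NODE_POSITIVE else self.sd_neg


def table1_params() -> list:
    """The 22 differential peaks (published class means/SDs), verbatim."""
    return [
        PeakSpec(float(mz), mp, sp, mn, sn, differential=True)
        for mz, mp, sp, mn, sn in _DIFFERENTIAL_PEAKS
    ]


def nuisance_params() -> list:
    """The 24 implementer-chosen non-differential peaks (equal class means)."""
    return [
        PeakSpec(float(mz), mean, mean * _NUISANCE_SD_FRACTION,
                 mean, mean * _NUISANCE_SD_FRACTION, differential=False)
        for mz, mean in _NUISANCE_PEAKS
    ]


@dataclass
class GeneratorConfig:
    """Peak panel plus grid / line-shape / noise settings for rendering.

    ``peak_width_fraction`` is the Gaussian sigma as a fraction of m/z.
    ``mass_jitter_cv`` perturbs each spectrum's mass axis multiplicatively;
    ``intensity_cv`` is per-peak multiplicative measurement error. The
    ``chip_*`` terms add a between-chip component for QC replicates.
    """

    peaks: list = field(default_factory=lambda: table1_params() + nuisance_params())
    grid_min: float = 1000.0
    grid_max: float = 20000.0
    grid_step: float = 1.0
    peak_width_fraction: float = 0.0008
    baseline_amplitude: float = 20.0
    baseline_decay: float = 3000.0
    noise_sd: float = 0.05
    mass_jitter_cv: float = 0.0003
    intensity_cv: float = 0.17
    chip_intensity_cv: float = 0.09
    chip_mass_cv: float = 0.0003
    n_chips: int = 31
    seed: int = 0

    def validate(self, cluster_window: float = 0.005) -> None:
        """Check peaks lie on the grid and are resolvable into 1:1 clusters.

        Planted centers must be separated by more than half the clustering
        window (the per-cluster matching radius) so each peak maps to its
        own cluster.
        """
        centers = sorted(p.mz_center for p in self.peaks)
        for c in centers:
            if not (self.grid_min <= c <= self.grid_max):
                raise ValueError(f"peak center {c} outside grid "
                                 f"[{self.grid_min}, {self.grid_max}]")
        half = cluster_window / 2.0
        for a, b in zip(centers, centers[1:]):
            if (b - a) / a <= half:
                raise ValueError(
                    f"peak centers {a} and {b} closer than the cluster "
                    f"matching radius ({half:.2%})"
                )

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


def default_generator_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def sample_feature_vector(config: GeneratorConfig, label: str,
                          rng: np.random.Generator) -> dict:
    """Draw one sample's true peak intensities (m/z center -> intensity).

    Each peak is drawn independently from Normal(class mean, class SD)
    truncated at zero; nuisance peaks use the class-independent mean.
    """
    if label not in (NODE_POSITIVE, NODE_NEGATIVE):
        raise ValueError(f"label must be a class, got {label!r}")
    out = {}
    for peak in config.peaks:
        value = rng.normal(peak.mean(label), peak.sd(label))
        out[peak.mz_center] = max(value, 0.0)
    return out


def _measurement_factors(config: GeneratorConfig, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    if config.intensity_cv == 0:
        return np.ones(n)
    return np.maximum(rng.normal(1.0, config.intensity_cv, size=n), 0.0)


def render_spectrum(features: dict, config: GeneratorConfig,
                    rng: np.random.Generator, *, sample_id: str = "S",
                    label: str = "unlabelled", chip_id: str = "",
                    mass_scale: float | None = None) -> Spectrum:
    """Render a feature vector as a full spectrum on the configured grid.

    intensity(x) = baseline(x) + sum_p A_p * exp(-(x - c_p*j)^2 / 2 sigma_p^2)
    + noise, with j the per-spectrum mass-jitter factor (drawn from
    Normal(1, mass_jitter_cv) unless ``mass_scale`` is given) and
    sigma_p = peak_width_fraction * c_p. Peak amplitude equals the feature
    value, so the apex height recovered after preprocessing matches it.
    """
    grid = config.grid()
    if mass_scale is None:
        mass_scale = 1.0 + (rng.normal(0.0, config.mass_jitter_cv)
                            if config.mass_jitter_cv > 0 else 0.0)
    y = config.baseline_amplitude * np.exp(-(grid - config.grid_min)
                                           / config.baseline_decay)
    for center, amplitude in features.items():
        if amplitude <= 0:
            continue
        c = center * mass_scale
        sigma = config.peak_width_fraction * c
        lo = np.searchsorted(grid, c - 8 * sigma)
        hi = np.searchsorted(grid, c + 8 * sigma)
        if lo >= hi:
            continue
        x = grid[lo:hi]
        y[lo:hi] += amplitude * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=len(grid))
    return Spectrum(sample_id=sample_id, mz=grid, intensity=y,
                    label=label, chip_id=chip_id,
                    meta={"mass_scale": mass_scale})


def _chip_ids(config: GeneratorConfig, n: int) -> list:
    width = max(2, len(str(config.n_chips)))
    return [f"chip{(i % config.n_chips) + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: GeneratorConfig, n_pos: int, n_neg: int,
                    role: str = "training", seed: int | None = None,
                    out_dir=None) -> Cohort:
    """Generate a labelled cohort of rendered spectra (plus manifest on disk).

    Sample order is all positives then all negatives; chip ids are assigned
    round-robin over ``config.n_chips``. Deterministic given ``seed``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("cohort sizes must be >= 0")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = [NODE_POSITIVE] * n_pos + [NODE_NEGATIVE] * n_neg
    sample_ids = [f"P{i + 1:03d}" for i in range(n_pos)] + \
                 [f"N{i + 1:03d}" for i in range(n_neg)]
    chips = _chip_ids(config, n_pos + n_neg)
    centers = [p.mz_center for p in config.peaks]
    spectra = []
    for sid, label, chip in zip(sample_ids, labels, chips):
        truth = sample_feature_vector(config, label, rng)
        factors = _measurement_factors(config, len(centers), rng)
        observed = {c: truth[c] * f for c, f in zip(centers, factors)}
        spectra.append(render_spectrum(observed, config, rng, sample_id=sid,
                                       label=label, chip_id=chip))
    cohort = Cohort(spectra=spectra, role=role)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = [f"{s.sample_id}.csv" for s in cohort]
        for s, p in zip(cohort, paths):
            write_spectrum(s, out_dir / p)
        write_manifest(cohort, out_dir / "manifest.csv", paths)
    return cohort


def generate_feature_matrix(config: GeneratorConfig, n_pos: int, n_neg: int,
                            seed: int | None = None,
                            measurement_error: bool = False):
    """Sample peak-intensity vectors directly into a PeakMatrix.

    Bypasses spectrum rendering and detection: columns are the planted
    peaks, values the truncated-normal class draws (optionally with the
    multiplicative measurement error applied).
    """
    from seldi_nodal.peak_detection import PeakCluster, PeakMatrix

    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = [NODE_POSITIVE] * n_pos + [NODE_NEGATIVE] * n_neg
    sample_ids = [f"P{i + 1:03d}" for i in range(n_pos)] + \
                 [f"N{i + 1:03d}" for i in range(n_neg)]
    centers = sorted(p.mz_center for p in config.peaks)
    peak_by_center = {p.mz_center: p for p in config.peaks}
    values = np.zeros((len(labels), len(centers)))
    for i, label in enumerate(labels):
        truth = sample_feature_vector(config, label, rng)
        factors = (_measurement_factors(config, len(centers), rng)
                   if measurement_error else np.ones(len(centers)))
        values[i] = [truth[c] * f for c, f in zip(centers, factors)]
    clusters = [
        PeakCluster(cluster_id=k, mz_center=c,
                    window=(c * 0.9975, c * 1.0025),
                    prevalence=len(labels))
        for k, c in enumerate(centers)
    ]
    _ = peak_by_center
    return PeakMatrix(sample_ids=sample_ids, clusters=clusters,
                      values=values, labels=labels)


def generate_qc_replicates(config: GeneratorConfig, n_per_chip: int,
                           n_chips: int, seed: int | None = None) -> Cohort:
    """Replicate spectra of one fixed feature vector for CV quality control.

    The base vector is the midpoint of the two class means (a stand-in for
    the healthy-volunteer control serum). Between-chip variability enters
    through per-chip mass and per-peak intensity factors; within-chip
    variability through per-replicate jitter and intensity error.
    """
    if n_per_chip < 1 or n_chips < 1:
        raise ValueError("replicate counts must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    centers = [p.mz_center for p in config.peaks]
    base = {p.mz_center: 0.5 * (p.mean_pos + p.mean_neg) for p in config.peaks}
    spectra = []
    width = max(2, len(str(n_chips)))
    for chip in range(n_chips):
        chip_id = f"chip{chip + 1:0{width}d}"
        chip_mass = 1.0 + (rng.normal(0.0, config.chip_mass_cv)
                           if config.chip_mass_cv > 0 else 0.0)
        if config.chip_intensity_cv > 0:
            chip_factors = np.maximum(
                rng.normal(1.0, config.chip_intensity_cv, size=len(centers)), 0.0)
        else:
            chip_factors = np.ones(len(centers))
        for rep in range(n_per_chip):
            rep_jitter = 1.0 + (rng.normal(0.0, config.mass_jitter_cv)
                                if config.mass_jitter_cv > 0 else 0.0)
            rep_factors = _measurement_factors(config, len(centers), rng)
            observed = {c: base[c] * cf * rf
                        for c, cf, rf in zip(centers, chip_factors, rep_factors)}
            spectra.append(render_spectrum(
                observed, config, rng,
                sample_id=f"QC_{chip_id}_r{rep + 1:02d}",
                chip_id=chip_id, mass_scale=chip_mass * rep_jitter))
    return Cohort(spectra=spectra, role="qc_replicates")


def noiseless_config(**overrides) -> GeneratorConfig:
    """A GeneratorConfig with every random component switched off."""
    cfg = default_generator_config()
    zero = dict(noise_sd=0.0, mass_jitter_cv=0.0, intensity_cv=0.0,
                chip_intensity_cv=0.0, chip_mass_cv=0.0)
    zero.update(overrides)
    cfg = replace(cfg, **zero)
    return cfg


def zero_variance_peaks() -> list:
    """The default panel with all peak SDs forced to zero."""
    return [replace(p, sd_pos=0.0, sd_neg=0.0)
            for p in table1_params() + nuisance_params()]


def differential_count_pos_higher() -> int:
    """How many differential peaks are over-expressed in the positive class."""
    return sum(1 for p in table1_params() if p.mean_pos > p.mean_neg)


def _nuisance_total_intensity_mass() -> float:  # used in design sanity checks
    return math.fsum(mz * a for mz, a in _NUISANCE_PEAKS)
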