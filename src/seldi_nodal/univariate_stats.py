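"""Univariate screening and reproducibility QC.

Per-cluster two-sample Student t tests (pooled variance), the strict/
reported significance screens, the 2x2 Pearson chi-square rate comparison,
and intra-/inter-assay coefficient-of-variance QC on replicate spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from seldi_nodal.spectra_io import NODE_NEGATIVE, NODE_POSITIVE

logger = logging.getLogger(__name__)


@dataclass
class PeakTestResult:
    mz_center: float
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    t_stat: float
    p_value: float
    significant_at_alpha: bool
    degenerate: bool = False


@dataclass
class QCReport:
    """Intra-/inter-assay CVs in percent (inter is None with < 2 chips)."""

    cv_mass_intra: float
    cv_mass_inter: float | None
    cv_intensity_intra: float
    cv_intensity_inter: float | None
    n_replicates: int
    n_chips: int


def t_from_summary(n1: int, mean1: float, sd1: float,
                   n2: int, mean2: float, sd2: float) -> tuple:
    """Pooled-variance two-sample t and two-sided p from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        return float(np.sign(mean1 - mean2)) * np.inf, 0.0
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def welch_t_from_summary(n1, mean1, sd1, n2, mean2, sd2) -> tuple:
    """Welch (unequal-variance) alternative to :func:`t_from_summary`."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        return float(np.sign(mean1 - mean2)) * np.inf, 0.0
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def t_test_peaks(matrix, alpha: float = 0.05, welch: bool = False) -> list:
    """Student t test for every peak cluster, sorted by ascending p.

    The positive class is ``node_positive``. With zero pooled variance and
    unequal means the result is flagged degenerate (p -> 0).
    """
    labels = np.asarray(matrix.labels)
    pos = labels == NODE_POSITIVE
    neg = labels == NODE_NEGATIVE
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    results = []
    func = welch_t_from_summary if welch else t_from_summary
    for k, cluster in enumerate(matrix.clusters):
        x1 = matrix.values[pos, k]
        x2 = matrix.values[neg, k]
        m1, s1 = float(np.mean(x1)), float(np.std(x1, ddof=1))
        m2, s2 = float(np.mean(x2)), float(np.std(x2, ddof=1))
        t, p = func(len(x1), m1, s1, len(x2), m2, s2)
        results.append(PeakTestResult(
            mz_center=cluster.mz_center, mean_pos=m1, sd_pos=s1,
            mean_neg=m2, sd_neg=s2, t_stat=t, p_value=p,
            significant_at_alpha=p < alpha,
            degenerate=not np.isfinite(t)))
    results.sort(key=lambda r: (r.p_value, r.mz_center))
    return results


def screen_differential(results, alpha_strict: float = 1e-4,
                        alpha_report: float = 0.05) -> dict:
    """Split test results into the strict and reported significance lists."""
    if not results:
        raise ValueError("no test results to screen")
    strict = [r for r in results if r.p_value < alpha_strict]
    reported = [r for r in results if r.p_value < alpha_report]
    return {"strict": strict, "reported": reported}


def results_table(results, n_pos: int = None, n_neg: int = None) -> pd.DataFrame:
    """Tabulate test results (with a Bonferroni column for transparency)."""
    m = len(results)
    df = pd.DataFrame({
        "mz": [r.mz_center for r in results],
        "mean_pos": [r.mean_pos for r in results],
        "sd_pos": [r.sd_pos for r in results],
        "mean_neg": [r.mean_neg for r in results],
        "sd_neg": [r.sd_neg for r in results],
        "T": [abs(r.t_stat) for r in results],
        "P": [r.p_value for r in results],
        "P_bonferroni": [min(1.0, r.p_value * m) for r in results],
    })
    return df


def chi_square_rates(k1: int, n1: int, k2: int, n2: int,
                     correction: bool = False) -> tuple:
    """Pearson chi-square on the 2x2 table of two rates, 1 df.

    Computed by the direct closed form N(ad-bc)^2 / (row and column
    products); Yates continuity correction optional.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("trial counts must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must satisfy 0 <= k <= n")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    total = n1 + n2
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - total / 2.0, 0.0)
    chi2 = total * diff ** 2 / (n1 * n2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------

def _cv_percent(values: np.ndarray) -> float:
    mean = np.mean(values)
    if mean == 0:
        return 0.0
    return 100.0 * float(np.std(values, ddof=1) / mean)


def qc_cv(replicates, target_mzs, snr_min: float = 3.0,
          match_window: float = 0.005, mz_min: float = 2000.0,
          mz_max: float = 20000.0, baseline_half_width: float = 150.0) -> QCReport:
    """Mass and intensity CVs of target peaks over replicate spectra.

    Replicates are preprocessed together, peaks detected per spectrum, and
    each target m/z matched to the nearest detected peak within
    +-``match_window``/2. Intra-assay CVs are computed within chips (>= 2
    usable replicates) then averaged over chips and targets; inter-assay
    CVs across per-chip means (>= 2 chips). Replicates missing a target
    are excluded for that target with a logged warning.
    """
    from seldi_nodal.peak_detection import detect_peaks
    from seldi_nodal.preprocessing import preprocess_cohort

    spectra = list(replicates)
    if len(spectra) < 2:
        raise ValueError("need >= 2 replicates")
    processed = preprocess_cohort(spectra, mz_min=mz_min, mz_max=mz_max,
                                  baseline_half_width=baseline_half_width)
    chips = sorted({s.chip_id for s in processed})
    detected = {s.sample_id: detect_peaks(s, snr_min=snr_min,
                                          neighborhood_fraction=match_window / 2)
                for s in processed}

    # measurements[target][chip] -> list of (mz, height)
    half = match_window / 2.0
    measurements = {t: {c: [] for c in chips} for t in target_mzs}
    for s in processed:
        peaks = detected[s.sample_id]
        for target in target_mzs:
            best = None
            for p in peaks:
                if abs(p.mz - target) <= half * target:
                    if best is None or abs(p.mz - target) < abs(best.mz - target):
                        best = p
            if best is None:
                logger.warning("qc_cv: target m/z %.0f undetected in replicate %r",
                               target, s.sample_id)
                continue
            measurements[target][s.chip_id].append((best.mz, best.height))

    intra_mass, intra_int = [], []
    inter_mass, inter_int = [], []
    for target in target_mzs:
        per_chip = measurements[target]
        chip_mass_cvs, chip_int_cvs = [], []
        chip_mass_means, chip_int_means = [], []
        for chip in chips:
            obs = per_chip[chip]
            if not obs:
                continue
            mzs = np.array([m for m, _ in obs])
            hts = np.array([h for _, h in obs])
            chip_mass_means.append(float(np.mean(mzs)))
            chip_int_means.append(float(np.mean(hts)))
            if len(obs) >= 2:
                chip_mass_cvs.append(_cv_percent(mzs))
                chip_int_cvs.append(_cv_percent(hts))
        if chip_mass_cvs:
            intra_mass.append(float(np.mean(chip_mass_cvs)))
            intra_int.append(float(np.mean(chip_int_cvs)))
        if len(chip_mass_means) >= 2:
            inter_mass.append(_cv_percent(np.array(chip_mass_means)))
            inter_int.append(_cv_percent(np.array(chip_int_means)))

    if not intra_mass:
        raise ValueError("no target peak had >= 2 within-chip detections")
    n_chips = len(chips)
    return QCReport(
        cv_mass_intra=float(np.mean(intra_mass)),
        cv_mass_inter=float(np.mean(inter_mass)) if n_chips >= 2 and inter_mass else None,
        cv_intensity_intra=float(np.mean(intra_int)),
        cv_intensity_inter=float(np.mean(inter_int)) if n_chips >= 2 and inter_int else None,
        n_replicates=len(processed),
        n_chips=n_chips,
    )
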