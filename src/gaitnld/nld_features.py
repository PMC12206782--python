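"""Nonlinear features of gait interval series.

Four scalar features per series:

C0 complexity
    Fraction of signal energy not captured by the spectrally "regular"
    part of the signal. The regular part keeps only the Fourier bins
    whose power exceeds r times the mean bin power (r = 5 by default);
    C0 = sum |x - x_reg|^2 / sum |x|^2, in [0, 1]. A constant or pure
    tone scores ~0, broadband noise scores near 1. Reliable on short
    series, which suits stride-indexed gait records (a few hundred
    strides per 5-minute walk).

Sample entropy (SampEn)
    -ln of the conditional probability that length-m templates matching
    within Chebyshev tolerance r also match at length m+1; self-matches
    excluded. Defaults m = 2, r = 0.2 * SD of the series.

Wavelet entropy
    Shannon entropy of the relative energies of a multilevel discrete
    wavelet decomposition (detail bands plus the final approximation);
    0 when all energy sits in one band, ln(J) when spread evenly over
    J bands.

Wavelet-coefficient summary
    RMS of all detail coefficients over the RMS of the signal — a
    dimensionless, scale-invariant measure of how much of the signal
    lives in the detail (fluctuation) bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .gait_io import GaitRecord, Group, Phase, SERIES_COLUMNS, SeriesKind, Side, Unit
from .preprocess import MedianFilterParams, PreprocessConfig, all_ratio_series, median_filter

__all__ = [
    "SpectralDecomposition",
    "WaveletEnergyProfile",
    "WaveletDecomposition",
    "FeatureConfig",
    "FeatureVector",
    "spectral_regular_part",
    "c0_complexity",
    "sample_entropy",
    "wavelet_decompose",
    "wavelet_energy_profile",
    "wavelet_coeff_feature",
    "extract_all",
    "MIN_SERIES_LENGTH",
]

#: Series shorter than this after preprocessing are skipped, not analysed.
MIN_SERIES_LENGTH = 16


@dataclass
class SpectralDecomposition:
    """Regular (spectrally thresholded) part of a signal, for C0."""

    regular_part: np.ndarray
    threshold_factor: float
    kept_bins: int
    N: int


@dataclass
class WaveletEnergyProfile:
    """Per-band wavelet energies, relative energies and their entropy."""

    level_energies: np.ndarray  # detail levels coarse->fine, then approximation
    relative_energies: np.ndarray
    entropy: float
    n_levels: int


@dataclass
class WaveletDecomposition:
    detail_coeffs: list[np.ndarray]
    approx_coeffs: np.ndarray
    wavelet_name: str
    max_level: int


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    c0_r
        Spectral threshold factor r for C0 (default 5).
    sampen_m, sampen_r_factor
        SampEn template length and tolerance as a fraction of the series
        SD (field-standard 2 and 0.2).
    wavelet, levels
        Wavelet family and decomposition depth; depth is capped at the
        maximum the series length allows.
    prefilter
        Median-filter the series (width ``filter.n``) before feature
        extraction; set False for raw-mode sensitivity analysis.
    """

    c0_r: float = 5.0
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    wavelet: str = "db4"
    levels: int = 4
    prefilter: bool = True
    filter: MedianFilterParams = field(default_factory=MedianFilterParams)


@dataclass
class FeatureVector:
    """One series' nonlinear feature set (a cell row of the summary tables)."""

    subject_id: str
    group: Group
    series_kind: str
    c0: float
    sampen: float
    wavelet_entropy: float
    wavelet_coeff: float
    series_mean: float
    series_sd: float
    series_cv: float
    n: int
    prefiltered: bool


def spectral_regular_part(x: Sequence[float], r: float = 5.0) -> SpectralDecomposition:
    """Split a signal into its spectrally regular part.

    The DFT bins whose squared magnitude exceeds ``r`` times the mean
    squared magnitude are kept; all others are zeroed; the inverse
    transform of the kept spectrum is the regular part (real-valued for
    real input, since thresholding on magnitude preserves conjugate
    symmetry).
    """
    if r <= 0:
        raise ValueError("threshold factor r must be > 0")
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    X = np.fft.fft(x)
    power = np.abs(X) ** 2
    keep = power > r * power.mean()
    Xk = np.where(keep, X, 0.0)
    regular = np.fft.ifft(Xk).real
    return SpectralDecomposition(
        regular_part=regular,
        threshold_factor=float(r),
        kept_bins=int(keep.sum()),
        N=int(x.size),
    )


def c0_complexity(x: Sequence[float], r: float = 5.0) -> float:
    """C0 complexity: residual energy fraction after spectral thresholding.

    ``sum |x - x_reg|^2 / sum |x|^2`` — 0 for a constant (fully regular),
    approaching 1 for broadband noise. Raises on an identically-zero
    signal (zero denominator).
    """
    x = np.asarray(x, dtype=float)
    denom = float(np.sum(x**2))
    if denom == 0.0:
        raise ValueError("C0 undefined for the all-zero signal")
    dec = spectral_regular_part(x, r)
    num = float(np.sum((x - dec.regular_part) ** 2))
    # clip fp residue; Parseval bounds the true value in [0, 1]
    return min(max(num / denom, 0.0), 1.0)


def sample_entropy(x: Sequence[float], m: int = 2, r_tol: float | None = None) -> float:
    """Sample entropy with Chebyshev distance, self-matches excluded.

    ``r_tol`` is an absolute tolerance in the units of ``x``; if None it
    defaults to 0.2 times the sample SD. Returns ``-ln(A/B)`` where B
    counts matching template pairs of length m and A of length m+1;
    returns ``inf`` when A = 0 (no length-m+1 matches) and 0 when B = 0
    is impossible but A = B (e.g. constant input).
    """
    if m < 1:
        raise ValueError("embedding length m must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    if r_tol is None:
        r_tol = 0.2 * float(np.std(x, ddof=1))
    if r_tol < 0:
        raise ValueError("tolerance must be >= 0")

    # align template counts: use n-m templates for both lengths (standard)
    n_tm = n - m
    temp_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_tm]
    d_m = np.abs(temp_m[:, None, :] - temp_m[None, :, :]).max(axis=2)
    b = int((np.count_nonzero(d_m <= r_tol) - n_tm) // 2)
    temp_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    d_m1 = np.abs(temp_m1[:, None, :] - temp_m1[None, :, :]).max(axis=2)
    a = int((np.count_nonzero(d_m1 <= r_tol) - n_tm) // 2)

    if b == 0:
        return math.inf
    if a == 0:
        return math.inf
    return -math.log(a / b)


def wavelet_decompose(
    x: Sequence[float], wavelet_name: str = "db4", levels: int = 4
) -> WaveletDecomposition:
    """Multilevel DWT; raises if ``levels`` exceeds what the length allows."""
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(wavelet_name)
    max_lev = pywt.dwt_max_level(x.size, wav.dec_len)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels > max_lev:
        raise ValueError(
            f"levels={levels} exceeds maximum {max_lev} for length {x.size} with {wavelet_name}"
        )
    # periodized DWT: dyadic coefficient counts and exact energy accounting
    coeffs = pywt.wavedec(x, wav, level=levels, mode="periodization")
    return WaveletDecomposition(
        detail_coeffs=list(coeffs[1:]),
        approx_coeffs=coeffs[0],
        wavelet_name=wavelet_name,
        max_level=levels,
    )


def wavelet_energy_profile(
    x: Sequence[float],
    wavelet_name: str = "db4",
    levels: int = 4,
    normalized: bool = False,
) -> WaveletEnergyProfile:
    """Relative wavelet energies and their Shannon entropy.

    Band j's energy is the sum of squared detail coefficients at level j;
    the final approximation counts as one more band. Entropy is
    ``-sum p_j ln p_j`` (0*ln 0 = 0), optionally divided by ln(n_bands)
    when ``normalized``.
    """
    dec = wavelet_decompose(x, wavelet_name, levels)
    energies = [float(np.sum(d**2)) for d in dec.detail_coeffs]
    energies.append(float(np.sum(dec.approx_coeffs**2)))
    e = np.asarray(energies)
    total = e.sum()
    if total == 0.0:
        raise ValueError("zero-energy signal has no energy profile")
    p = e / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    if normalized:
        entropy /= math.log(p.size)
    return WaveletEnergyProfile(
        level_energies=e, relative_energies=p, entropy=entropy, n_levels=int(p.size)
    )


def wavelet_coeff_feature(x: Sequence[float], wavelet_name: str = "db4", levels: int = 4) -> float:
    """Detail-RMS over signal-RMS: dimensionless fluctuation content.

    0 for a constant input (every detail coefficient of a wavelet with a
    vanishing moment is 0), invariant under positive rescaling of the
    input. Raises on a zero-RMS signal.
    """
    x = np.asarray(x, dtype=float)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        raise ValueError("zero-RMS signal")
    dec = wavelet_decompose(x, wavelet_name, levels)
    detail = np.concatenate(dec.detail_coeffs)
    return float(np.sqrt(np.mean(detail**2))) / rms


def _features_of(
    x: np.ndarray,
    kind_name: str,
    rec: GaitRecord,
    cfg: FeatureConfig,
) -> FeatureVector:
    if cfg.prefilter:
        x = median_filter(x, cfg.filter)
    wav = pywt.Wavelet(cfg.wavelet)
    levels = min(cfg.levels, pywt.dwt_max_level(x.size, wav.dec_len))
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return FeatureVector(
        subject_id=rec.subject_id,
        group=rec.group,
        series_kind=kind_name,
        c0=c0_complexity(x, cfg.c0_r),
        sampen=sample_entropy(x, cfg.sampen_m, cfg.sampen_r_factor * sd),
        wavelet_entropy=wavelet_energy_profile(x, cfg.wavelet, levels).entropy,
        wavelet_coeff=wavelet_coeff_feature(x, cfg.wavelet, levels),
        series_mean=mean,
        series_sd=sd,
        series_cv=100.0 * sd / mean if mean != 0 else math.nan,
        n=int(x.size),
        prefiltered=cfg.prefilter,
    )


def extract_all(
    rec: GaitRecord,
    cfg: FeatureConfig | None = None,
    pre: PreprocessConfig | None = None,
) -> tuple[list[FeatureVector], list[tuple[str, str]]]:
    """Feature vectors for the 10 left/right interval series and 5 ratio series.

    Returns ``(features, skipped)`` where ``skipped`` holds
    ``(series_name, reason)`` for series too short to analyse
    (< ``MIN_SERIES_LENGTH`` strides after preprocessing). Double-support
    columns are inventoried by the parser but carry no left/right
    contrast, so they are not feature-extracted.
    """
    cfg = cfg or FeatureConfig()
    pre = pre or PreprocessConfig()
    out: list[FeatureVector] = []
    skipped: list[tuple[str, str]] = []

    def _try(x: np.ndarray, name: str) -> None:
        if x.size < MIN_SERIES_LENGTH:
            skipped.append((name, f"too short: {x.size} < {MIN_SERIES_LENGTH}"))
            return
        out.append(_features_of(np.asarray(x, dtype=float), name, rec, cfg))

    for kind in SERIES_COLUMNS:
        if kind.side is Side.BOTH:
            continue
        _try(rec.series[kind], kind.name)
    for rs in all_ratio_series(rec, pre):
        _try(rs.values, rs.name)
    return out, skipped
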