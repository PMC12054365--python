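"""Intensity and residual diagnostics: second moments, rankits, histograms.

Second moments.  For untwinned acentric data the Wilson distribution
rho(I) = exp(-I/Sigma)/Sigma implies <I^2>/<I>^2 = 2 within a resolution
shell.  Gaussian measurement error on the normalized intensity
Z = I/Sigma turns the observed distribution into an exponentially
modified Gaussian with mean 1 and variance 1 + sigma_Z^2, so the observed
second moment should rise above two as

    <Z_obs^2>/<Z_obs>^2 = 2 + <sigma_Z^2>,

where sigma_Z is the merged sigma divided by the shell mean intensity.
Comparing the observed curve with this expectation tests whether the
calibrated sigmas are consistent with the intensities themselves.  The
treatment here is acentric-only; centric reflections follow a different
law and are out of scope.

Rankit (normal-probability) profiles.  Sorted statistics are plotted
against the expected order statistics of a reference distribution
(half-normal, or half-t with given nu) at Blom plotting positions
(i - 0.375)/(n + 0.25); correctly calibrated omega values fall on a line
through the origin with slope one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .merging import ResolutionBins, make_resolution_bins

__all__ = [
    "SecondMomentProfile",
    "RankitProfile",
    "observed_second_moment",
    "expected_second_moment",
    "second_moment_profile",
    "rankit_profile",
    "statistic_histograms",
    "mad_z_filter",
]


@dataclass
class SecondMomentProfile:
    """Observed vs expected second moments per resolution shell."""

    table: pd.DataFrame  # d_max d_min n observed expected

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class RankitProfile:
    """Sorted statistic values against reference-order-statistic rankits."""

    sorted_values: np.ndarray
    rankits: np.ndarray
    reference: str
    nu: float | None
    slope: float
    intercept: float

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"rankit": self.rankits, "value": self.sorted_values}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _bin_moments(values: np.ndarray, bin_idx: np.ndarray, n_bins: int):
    cnt = np.bincount(bin_idx, minlength=n_bins).astype(float)
    s1 = np.bincount(bin_idx, weights=values, minlength=n_bins)
    s2 = np.bincount(bin_idx, weights=values**2, minlength=n_bins)
    return cnt, s1, s2


def observed_second_moment(
    merged: pd.DataFrame,
    resolution_bins: ResolutionBins,
    min_count: int = 10,
) -> pd.DataFrame:
    """<Z^2>/<Z>^2 per shell from merged intensities (Z = I / shell mean).

    Shells with fewer than ``min_count`` reflections are reported as NaN.
    """
    d = merged["d_spacing"].to_numpy()
    intensity = merged["intensity"].to_numpy()
    idx = resolution_bins.assign(d)
    nb = resolution_bins.n_bins
    cnt, s1, s2 = _bin_moments(intensity, idx, nb)
    out = resolution_bins.d_limits()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        mean_sq = s2 / cnt
        moment = mean_sq / mean**2
    moment[cnt < min_count] = np.nan
    out["n"] = cnt.astype(np.int64)
    out["observed"] = moment
    return out


def expected_second_moment(
    merged: pd.DataFrame,
    resolution_bins: ResolutionBins,
    min_count: int = 10,
) -> pd.DataFrame:
    """Expected second moment 2 + <sigma_Z^2> per shell.

    sigma_Z is each reflection's merged sigma over the shell mean
    intensity; the shell aggregates individual sigma_Z as the mean of
    squares (the variance-consistent pooling).  Equals exactly 2 when all
    sigmas vanish.
    """
    d = merged["d_spacing"].to_numpy()
    intensity = merged["intensity"].to_numpy()
    sigma = merged["sigma"].to_numpy()
    idx = resolution_bins.assign(d)
    nb = resolution_bins.n_bins
    cnt, s1, _ = _bin_moments(intensity, idx, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        shell_mean = s1 / cnt
        sigma_z2 = (sigma / shell_mean[idx]) ** 2
        mean_sz2 = np.bincount(idx, weights=sigma_z2, minlength=nb) / cnt
    out = resolution_bins.d_limits()
    expected = 2.0 + mean_sz2
    expected[cnt < min_count] = np.nan
    out["n"] = cnt.astype(np.int64)
    out["expected"] = expected
    return out


def second_moment_profile(
    merged: pd.DataFrame, n_bins: int = 10, min_count: int = 10
) -> SecondMomentProfile:
    """Observed and expected second-moment curves on equal-volume shells."""
    bins = make_resolution_bins(merged["d_spacing"].to_numpy(), n_bins)
    obs = observed_second_moment(merged, bins, min_count)
    exp = expected_second_moment(merged, bins, min_count)
    table = obs.copy()
    table["expected"] = exp["expected"]
    return SecondMomentProfile(table=table)


def _reference_ppf(p: np.ndarray, reference: str, nu: float | None):
    if reference == "half_normal":
        return stats.halfnorm.ppf(p)
    if reference == "half_t":
        if nu is None or nu <= 0:
            raise ValueError("half_t reference requires nu > 0")
        return stats.t.ppf(0.5 * (1.0 + p), df=nu)
    raise ValueError(f"unknown reference distribution: {reference}")


def rankit_profile(
    values: np.ndarray, reference: str = "half_normal", nu: float | None = None
) -> RankitProfile:
    """Normal-probability profile of a nonnegative statistic.

    Returns sorted values, reference rankits at Blom plotting positions,
    and the least-squares slope/intercept of values against rankits.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n < 10:
        raise ValueError("rankit profile requires at least 10 values")
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    rankits = _reference_ppf(p, reference, nu)
    slope, intercept = np.polyfit(rankits, values, 1)
    return RankitProfile(
        sorted_values=values,
        rankits=rankits,
        reference=reference,
        nu=nu,
        slope=float(slope),
        intercept=float(intercept),
    )


def _reference_pdf(x: np.ndarray, reference: str, nu: float | None):
    if reference == "half_normal":
        return stats.halfnorm.pdf(x)
    if reference == "half_t":
        return 2.0 * stats.t.pdf(x, df=nu)
    raise ValueError(f"unknown reference distribution: {reference}")


def statistic_histograms(
    values: np.ndarray,
    bins: int | str = "auto",
    nu: float | None = None,
) -> pd.DataFrame:
    """Histogram of omega or |delta| with reference-density overlays.

    Returns a frame with bin edges/centers, counts, the unit-area density
    of the data, and half-normal (and half-t, if ``nu`` given) reference
    densities evaluated on the bin centers.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty statistic set")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = np.diff(edges)
    density = counts / (counts.sum() * width)
    out = pd.DataFrame(
        {
            "left": edges[:-1],
            "right": edges[1:],
            "center": centers,
            "count": counts,
            "density": density,
            "half_normal": _reference_pdf(centers, "half_normal", None),
        }
    )
    if nu is not None:
        out["half_t"] = _reference_pdf(centers, "half_t", nu)
    return out


def mad_z_filter(values: np.ndarray, cutoff: float = 10.0) -> np.ndarray:
    """Optional, off-by-default outlier mask via median absolute deviation.

    A simple robust Z-filter, *not* equivalent to the outlier rejection
    performed by phasing pipelines before their second-moment analysis.
    Returns a boolean keep-mask.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.ones(len(values), dtype=bool)
    z = 0.6745 * (values - med) / mad
    return np.abs(z) <= cutoff
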