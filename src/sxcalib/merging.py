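"""Merging and merged-data statistics.

Inverse-variance weighted averaging of the observations of each Miller
index is the maximum-likelihood estimate of its mean when the calibrated
sigmas are correct; unweighted averaging with a standard-error sigma is
kept as the alternative.  Per-resolution-shell quality metrics (mean
I/sigma, half-data-set correlation CC1/2, multiplicities) are computed on
equal-volume shells in 1/d^3.

The only observation filter implemented here is the per-lattice
correlation filter: lattices whose Pearson correlation to the scaling
reference falls below a threshold are removed wholesale (threshold -1
disables the filter, the default operating practice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errormodels import Ev11Params, MM24Params, ev11_sigma, mm24_sigma
from .mm24 import miller_seed
from .reflections import UnmergedReflectionTable, miller_group_arrays

__all__ = [
    "ResolutionBins",
    "make_resolution_bins",
    "lattice_correlations",
    "correlation_filter",
    "calibrated_sigmas",
    "merge",
    "cc_half",
    "binned_i_over_sigma",
    "binned_stats",
]


@dataclass
class ResolutionBins:
    """Equal-volume resolution shells (even spacing in 1/d^3)."""

    edges_inv_d3: np.ndarray  # ascending in 1/d^3 (low to high resolution)

    @property
    def n_bins(self) -> int:
        return len(self.edges_inv_d3) - 1

    def d_limits(self) -> pd.DataFrame:
        d_hi = self.edges_inv_d3[1:] ** (-1.0 / 3.0)
        d_lo = self.edges_inv_d3[:-1] ** (-1.0 / 3.0)
        return pd.DataFrame({"d_max": d_lo, "d_min": d_hi})

    def assign(self, d: np.ndarray) -> np.ndarray:
        """Bin index per d-spacing; values at the edges are clipped in."""
        x = 1.0 / np.asarray(d, dtype=float) ** 3
        idx = np.searchsorted(self.edges_inv_d3, x, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def make_resolution_bins(d: np.ndarray, n_bins: int = 10) -> ResolutionBins:
    d = np.asarray(d, dtype=float)
    x = 1.0 / d**3
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        hi = lo * (1 + 1e-9) + 1e-12
    return ResolutionBins(edges_inv_d3=np.linspace(lo, hi, n_bins + 1))


def lattice_correlations(
    table: UnmergedReflectionTable,
    reference: pd.Series | dict,
    min_shared: int = 3,
) -> UnmergedReflectionTable:
    """Pearson correlation of each lattice's intensities to a reference.

    ``reference`` maps Miller index tuples (h, k, l) to reference
    intensities.  Lattices sharing fewer than ``min_shared`` Miller
    indices with the reference are flagged with cc = 0 and a warning.
    Returns a new table with updated lattice records.
    """
    if isinstance(reference, dict):
        reference = pd.Series(reference)
    if len(reference) == 0:
        raise ValueError("empty scaling reference")
    refl = table.reflections
    key = pd.MultiIndex.from_arrays([refl["h"], refl["k"], refl["l"]])
    ref_vals = reference.reindex(key).to_numpy(dtype=float)
    have_ref = np.isfinite(ref_vals)
    cc_map: dict[str, float] = {}
    starved: list[str] = []
    for lid, sub in refl[have_ref].groupby(refl["lattice_id"][have_ref]):
        x = sub["intensity"].to_numpy()
        y = reference.reindex(
            pd.MultiIndex.from_arrays([sub["h"], sub["k"], sub["l"]])
        ).to_numpy(dtype=float)
        if len(x) < min_shared or np.std(x) == 0 or np.std(y) == 0:
            cc_map[lid] = 0.0
            starved.append(lid)
            continue
        cc_map[lid] = float(np.corrcoef(x, y)[0, 1])
    for lid in table.lattices["lattice_id"]:
        if lid not in cc_map:
            cc_map[lid] = 0.0
            starved.append(lid)
    if starved:
        warnings.warn(
            f"{len(starved)} lattice(s) share fewer than {min_shared} "
            "reflections with the reference; cc set to 0"
        )
    return table.with_lattice_cc(cc_map)


def correlation_filter(
    table: UnmergedReflectionTable, threshold: float
) -> tuple[UnmergedReflectionTable, dict]:
    """Remove lattices with cc below ``threshold`` (with all observations).

    ``threshold = -1`` removes nothing.  Returns the filtered table and a
    report of removed lattice ids and observation counts.
    """
    lat = table.lattices
    removed = lat[lat["cc"] < threshold]
    kept = lat[lat["cc"] >= threshold]["lattice_id"]
    report = {
        "threshold": threshold,
        "n_lattices_removed": int(len(removed)),
        "n_obs_removed": int(removed["n_obs"].sum()),
        "removed_lattice_ids": removed["lattice_id"].tolist(),
    }
    if len(removed) == len(lat):
        warnings.warn("correlation filter removed every lattice")
    return table.subset_lattices(kept), report


def calibrated_sigmas(
    table: UnmergedReflectionTable,
    params: Ev11Params | MM24Params | None,
) -> np.ndarray:
    """Per-observation sigma' under the given error model (counting sigma
    if ``params`` is None)."""
    refl = table.reflections
    sigma = refl["sigma"].to_numpy()
    if params is None:
        return sigma
    _, _, mean_i, _, _ = miller_group_arrays(table)
    if isinstance(params, Ev11Params):
        return np.asarray(ev11_sigma(sigma, mean_i, params))
    if isinstance(params, MM24Params):
        return np.asarray(
            mm24_sigma(sigma, mean_i, table.cc_per_observation(), params)
        )
    raise TypeError(f"unsupported parameter set: {type(params)!r}")


def _merge_arrays(intensity, sp, gid, n_groups, weighting):
    if weighting == "inverse_variance":
        w = 1.0 / sp**2
        sw = np.bincount(gid, weights=w, minlength=n_groups)
        swi = np.bincount(gid, weights=w * intensity, minlength=n_groups)
        merged_i = swi / sw
        merged_s = 1.0 / np.sqrt(sw)
        n = np.bincount(gid, minlength=n_groups)
    elif weighting == "unweighted":
        n = np.bincount(gid, minlength=n_groups)
        si = np.bincount(gid, weights=intensity, minlength=n_groups)
        merged_i = np.divide(si, n, out=np.zeros(n_groups), where=n > 0)
        resid2 = (intensity - merged_i[gid]) ** 2
        ss = np.bincount(gid, weights=resid2, minlength=n_groups)
        merged_s = np.empty(n_groups)
        multi = n >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            merged_s[multi] = np.sqrt(ss[multi] / (n[multi] * (n[multi] - 1.0)))
        # single observations fall back to their calibrated sigma
        single_sig = np.zeros(n_groups)
        np.maximum.at(single_sig, gid, sp)
        merged_s[~multi] = single_sig[~multi]
        # degenerate all-equal groups: keep a positive sigma
        zero = multi & (merged_s <= 0)
        if np.any(zero):
            inv = np.bincount(gid, weights=1.0 / sp**2, minlength=n_groups)
            merged_s[zero] = 1.0 / np.sqrt(inv[zero])
    else:
        raise ValueError(f"unknown weighting: {weighting}")
    return merged_i, merged_s, n


def merge(
    table: UnmergedReflectionTable,
    params: Ev11Params | MM24Params | None = None,
    weighting: str = "inverse_variance",
) -> pd.DataFrame:
    """Merge symmetry-equivalent observations.

    Returns a DataFrame ``h k l intensity sigma multiplicity [d_spacing]``
    with one row per Miller index.  Inverse-variance weighting uses
    w = 1/sigma'^2 and merged sigma (sum w)^(-1/2); unweighted merging
    uses the arithmetic mean with the standard error of the mean (n >= 2)
    or the single calibrated sigma (n = 1).
    """
    refl = table.reflections
    gid, _, _, sizes, _ = miller_group_arrays(table)
    sp = calibrated_sigmas(table, params)
    merged_i, merged_s, n = _merge_arrays(
        refl["intensity"].to_numpy(), sp, gid, len(sizes), weighting
    )
    first = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    out = pd.DataFrame(
        {
            "h": refl["h"].to_numpy()[first],
            "k": refl["k"].to_numpy()[first],
            "l": refl["l"].to_numpy()[first],
            "intensity": merged_i,
            "sigma": merged_s,
            "multiplicity": n.astype(np.int64),
        }
    )
    if "d_spacing" in refl.columns:
        out["d_spacing"] = refl["d_spacing"].to_numpy()[first]
    return out


def cc_half(
    table: UnmergedReflectionTable,
    params: Ev11Params | MM24Params | None = None,
    weighting: str = "inverse_variance",
    resolution_bins: ResolutionBins | None = None,
    extra_offset: int = 0,
    min_groups: int = 3,
) -> dict:
    """Half-data-set correlation CC1/2, overall and per resolution shell.

    Each Miller group's observations are split into two halves by a fresh
    PCG64 generator seeded from the Miller index (odd group sizes place
    the extra observation by the same generator), each half is merged, and
    CC1/2 is the Pearson correlation of the two merged intensity sets over
    groups with at least one observation in each half.  Deterministic for
    a fixed ``extra_offset``; shells with fewer than ``min_groups`` usable
    groups are reported as NaN.
    """
    refl = table.reflections
    intensity = refl["intensity"].to_numpy()
    h = refl["h"].to_numpy()
    k = refl["k"].to_numpy()
    l = refl["l"].to_numpy()
    gid, _, _, sizes, _ = miller_group_arrays(table)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    sp = calibrated_sigmas(table, params)

    half = np.zeros(len(refl), dtype=np.int64)
    for g in range(len(sizes)):
        n = int(sizes[g])
        if n < 2:
            half[starts[g] : starts[g] + n] = -1
            continue
        s = int(starts[g])
        rng = np.random.Generator(
            np.random.PCG64(miller_seed(int(h[s]), int(k[s]), int(l[s]), extra_offset))
        )
        perm = rng.permutation(n)
        m = n // 2
        if n % 2:
            m += int(rng.integers(0, 2))
        lab = np.zeros(n, dtype=np.int64)
        lab[perm[m:]] = 1
        half[s : s + n] = lab

    usable_obs = half >= 0
    n_groups = len(sizes)
    res = {}
    halves = []
    for side in (0, 1):
        sel = usable_obs & (half == side)
        mi, _, cnt = _merge_arrays(
            intensity[sel], sp[sel], gid[sel], n_groups, weighting
        )
        halves.append((mi, cnt))
    both = (halves[0][1] > 0) & (halves[1][1] > 0)

    def _cc(mask):
        if mask.sum() < min_groups:
            return float("nan")
        a = halves[0][0][mask]
        b = halves[1][0][mask]
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    res["overall"] = _cc(both)
    res["n_groups_used"] = int(both.sum())
    if resolution_bins is not None:
        if "d_spacing" not in refl.columns:
            raise ValueError("resolution-binned CC1/2 requires d_spacing")
        first = starts[:-1]
        d_group = refl["d_spacing"].to_numpy()[first]
        bin_of_group = resolution_bins.assign(d_group)
        per_bin = []
        for b in range(resolution_bins.n_bins):
            per_bin.append(_cc(both & (bin_of_group == b)))
        res["per_bin"] = np.array(per_bin)
    return res


def binned_i_over_sigma(
    merged: pd.DataFrame, resolution_bins: ResolutionBins
) -> pd.DataFrame:
    """Arithmetic mean of merged I/sigma per resolution shell."""
    if "d_spacing" not in merged.columns:
        raise ValueError("merged table lacks d_spacing")
    bin_idx = resolution_bins.assign(merged["d_spacing"].to_numpy())
    ratio = merged["intensity"].to_numpy() / merged["sigma"].to_numpy()
    nb = resolution_bins.n_bins
    cnt = np.bincount(bin_idx, minlength=nb).astype(float)
    tot = np.bincount(bin_idx, weights=ratio, minlength=nb)
    out = resolution_bins.d_limits()
    with np.errstate(invalid="ignore"):
        out["i_over_sigma"] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    out["n_unique"] = cnt.astype(np.int64)
    return out


def binned_stats(
    table: UnmergedReflectionTable,
    params: Ev11Params | MM24Params | None = None,
    weighting: str = "inverse_variance",
    n_bins: int = 10,
    extra_offset: int = 0,
) -> pd.DataFrame:
    """Per-shell merging statistics: counts, mean I/sigma and CC1/2."""
    refl = table.reflections
    if "d_spacing" not in refl.columns:
        raise ValueError("binned statistics require d_spacing")
    bins = make_resolution_bins(refl["d_spacing"].to_numpy(), n_bins)
    merged = merge(table, params=params, weighting=weighting)
    out = binned_i_over_sigma(merged, bins)
    obs_bins = bins.assign(refl["d_spacing"].to_numpy())
    out["n_obs"] = np.bincount(obs_bins, minlength=bins.n_bins).astype(np.int64)
    cc = cc_half(
        table,
        params=params,
        weighting=weighting,
        resolution_bins=bins,
        extra_offset=extra_offset,
    )
    out["cc_half"] = cc["per_bin"]
    return out
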