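"""MM24 robust error calibration from normalized pairwise differences.

Instead of leave-one-out deviations, MM24 measures the spread of redundant
observations through pairwise differences of symmetry mates,

    omega_hjk = |I_hj - I_hk| / (sigma'_hj^2 + sigma'_hk^2)^(1/2),

which quantify scale without needing a mean estimate and are symmetric by
construction.  If the calibrated sigmas are correct the differences are
half-normal; fitting instead a half Student-t with free degrees of freedom
makes the scale estimate robust to heavy tails and gross outliers.  The
parameters (s_fac, s_add_0, s_add_1, s_add_2[, nu]) minimize the negative
log-likelihood of the observed pairwise differences

    NLL = -sum_p [ log p_std(omega_p; nu) - log s_p ],
    s_p = (sigma'_j^2 + sigma'_k^2)^(1/2),

with analytic gradients under L-BFGS-B box constraints (nu on a log
scale).  The -log s_p change-of-variable term makes this a proper scale
maximum likelihood: without it the objective would be minimized by
inflating every sigma.

To bound memory on data sets with ~1e7 observations, at most ``cap``
(default 100) pairs per Miller index are subsampled.  Reproducibility
across runs and across arbitrary partitionings of the data is guaranteed
by giving each Miller index its own PCG64 generator seeded through
Cantor's pairing function of the (offset) indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import digamma

from .errormodels import (
    LOG_HALF_NORMAL_NORM,
    MM24Params,
    half_normal_log_pdf,
    half_t_log_pdf,
    s_add_of_cc,
)
from .ev11 import CalibrationError
from .reflections import UnmergedReflectionTable, miller_group_arrays

__all__ = [
    "PairwiseDifferenceSet",
    "cantor_pair",
    "miller_seed",
    "subsample_pairs",
    "build_pair_set",
    "normalized_pairwise_differences",
    "initialize_mm24",
    "mm24_loss_and_gradient",
    "fit_mm24",
    "MM24Calibration",
    "MM24Results",
]

#: default per-Miller-index cap on subsampled pairs
DEFAULT_PAIR_CAP = 100
#: RNG pinned by algorithm name for cross-run determinism
RNG_ALGORITHM = "PCG64"
#: optimizer box constraints; nu is optimized on a log scale
MM24_BOUNDS = {
    "s_fac": (1e-3, 1e3),
    "s_add_0": (0.0, 10.0),
    "s_add_1": (0.0, 10.0),
    "s_add_2": (0.0, 50.0),
    "nu": (1.5, 200.0),
}
_INIT_CONST = 0.001  # starting value of s_add_0 and s_add_2
_HALF_NORMAL_FOLD = 2.0 / math.sqrt(math.pi)  # E|X-Y| = (2/sqrt(pi)) sigma


def cantor_pair(k1: int, k2: int) -> int:
    """Cantor's pairing function pi(k1, k2) = (k1+k2)(k1+k2+1)/2 + k2.

    A bijection between pairs of natural numbers and natural numbers;
    evaluated in exact integer arithmetic.
    """
    k1, k2 = int(k1), int(k2)
    if k1 < 0 or k2 < 0:
        raise ValueError("Cantor pairing is defined on natural numbers")
    s = k1 + k2
    return s * (s + 1) // 2 + k2


def miller_seed(h: int, k: int, l: int, extra_offset: int = 0) -> int:
    """Unique deterministic seed for a Miller index.

    Each index is shifted by +1000 to make it a natural number, then the
    pairing function is applied iteratively: pi(pi(h', k'), l').  The
    optional offset perturbs every seed to obtain a different (but still
    reproducible) subsampling.
    """
    for x in (h, k, l):
        if abs(int(x)) >= 1000:
            raise ValueError("Miller index magnitude must be < 1000")
    return cantor_pair(cantor_pair(int(h) + 1000, int(k) + 1000), int(l) + 1000) + int(
        extra_offset
    )


def _pair_indices_from_linear(linear: np.ndarray, n: int):
    """Map linear indices over the lexicographic enumeration of pairs
    (j < k) of ``range(n)`` back to (j, k)."""
    # pairs for row j start at offset_j = j*n - j(j+1)/2 - j ... derive by
    # counting: number of pairs with first element < j is j*(2n-j-1)/2
    linear = np.asarray(linear, dtype=np.int64)
    j = np.empty_like(linear)
    k = np.empty_like(linear)
    counts = np.arange(n - 1, 0, -1, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(counts)])
    j = np.searchsorted(starts, linear, side="right") - 1
    k = linear - starts[j] + j + 1
    return j, k


def subsample_pairs(
    n: int, h: int, k: int, l: int, cap: int = DEFAULT_PAIR_CAP, extra_offset: int = 0
):
    """Deterministically subsample pairs (j < k) of ``n`` observations.

    If n(n-1)/2 <= cap, all pairs are returned in lexicographic order.
    Otherwise exactly ``cap`` pairs are drawn without replacement from the
    canonical enumeration by a fresh PCG64 generator seeded with
    :func:`miller_seed`.  Observation order must itself be canonical
    (the table sorts by (h, k, l, lattice_id, input order)).
    """
    if n < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= cap:
        j, kk = np.triu_indices(n, k=1)
        return j.astype(np.int64), kk.astype(np.int64)
    rng = np.random.Generator(np.random.PCG64(miller_seed(h, k, l, extra_offset)))
    linear = np.sort(rng.choice(n_pairs, size=cap, replace=False))
    return _pair_indices_from_linear(linear, n)


@dataclass
class PairwiseDifferenceSet:
    """Subsampled pairs of symmetry-equivalent observations.

    Row ``p`` pairs observations ``i_j[p]`` and ``i_k[p]`` (positional rows
    of the parent table, i_j enumerated before i_k in canonical order) of
    Miller group ``group_id[p]``; ``abs_diff`` holds |I_hj - I_hk|.
    ``omega`` and ``sigma_prime_{j,k}`` are populated by
    :func:`normalized_pairwise_differences`.
    """

    i_j: np.ndarray
    i_k: np.ndarray
    group_id: np.ndarray
    abs_diff: np.ndarray
    omega: np.ndarray | None = None
    sigma_prime_j: np.ndarray | None = None
    sigma_prime_k: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.abs_diff)


def build_pair_set(
    table: UnmergedReflectionTable,
    cap: int = DEFAULT_PAIR_CAP,
    extra_offset: int = 0,
) -> PairwiseDifferenceSet:
    """Enumerate/subsample pairs for every Miller group with n >= 2."""
    refl = table.reflections
    intensity = refl["intensity"].to_numpy()
    h = refl["h"].to_numpy()
    k = refl["k"].to_numpy()
    l = refl["l"].to_numpy()
    gid, n_per_obs, _, sizes, _ = miller_group_arrays(table)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    all_j, all_k, all_g = [], [], []
    for g in range(len(sizes)):
        n = int(sizes[g])
        if n < 2:
            continue
        s = int(starts[g])
        pj, pk = subsample_pairs(
            n, int(h[s]), int(k[s]), int(l[s]), cap=cap, extra_offset=extra_offset
        )
        all_j.append(pj + s)
        all_k.append(pk + s)
        all_g.append(np.full(len(pj), g, dtype=np.int64))
    if not all_j:
        return PairwiseDifferenceSet(
            *(np.empty(0, dtype=np.int64),) * 3, np.empty(0)
        )
    i_j = np.concatenate(all_j)
    i_k = np.concatenate(all_k)
    group_id = np.concatenate(all_g)
    return PairwiseDifferenceSet(
        i_j=i_j,
        i_k=i_k,
        group_id=group_id,
        abs_diff=np.abs(intensity[i_j] - intensity[i_k]),
    )


def normalized_pairwise_differences(
    pairs: PairwiseDifferenceSet,
    table: UnmergedReflectionTable,
    params: MM24Params,
) -> PairwiseDifferenceSet:
    """Populate omega = |dI| / (sigma'_j^2 + sigma'_k^2)^(1/2)."""
    from .errormodels import mm24_sigma

    refl = table.reflections
    _, _, mean_i, _, _ = _obs_arrays(table)
    sigma = refl["sigma"].to_numpy()
    cc = table.cc_per_observation()
    sp = mm24_sigma(sigma, mean_i, cc, params)
    spj = sp[pairs.i_j]
    spk = sp[pairs.i_k]
    omega = pairs.abs_diff / np.sqrt(spj**2 + spk**2)
    return PairwiseDifferenceSet(
        i_j=pairs.i_j,
        i_k=pairs.i_k,
        group_id=pairs.group_id,
        abs_diff=pairs.abs_diff,
        omega=omega,
        sigma_prime_j=spj,
        sigma_prime_k=spk,
    )


def _obs_arrays(table: UnmergedReflectionTable):
    gid, n_per, mean_per, sizes, means = miller_group_arrays(table)
    return gid, n_per, mean_per, sizes, means


def initialize_mm24(
    table: UnmergedReflectionTable,
    pairs: PairwiseDifferenceSet | None = None,
    n_bins: int = 100,
) -> MM24Params:
    """Initialize (s_fac, s_add_1) from binned mean absolute differences.

    The mean absolute pairwise difference in an intensity bin scales as
    (2/sqrt(pi)) sigma_error, so <|dI|>_b is fitted by least squares to
    (2/sqrt(pi)) s_fac (<sigma^2>_b + s_add_1^2 <I>_b^2)^(1/2) in
    ``n_bins`` even bins spanning [0, 0.1 max<I_h>] (groups outside the
    range are excluded; <I>_b is the bin center).  The first non-empty
    bin's mean — the expected nonzero error of low-intensity reflections —
    anchors the starting s_fac of this inner fit.  s_add_0 and s_add_2
    start at 0.001.  Falls back to (1.0, 0.05) with a warning if fewer
    than three bins are populated.
    """
    import warnings

    if pairs is None:
        pairs = build_pair_set(table)
    gid, _, mean_per_obs, sizes, means = _obs_arrays(table)
    sigma2 = table.reflections["sigma"].to_numpy() ** 2

    hi = 0.1 * float(np.max(means))
    edges = np.linspace(0.0, hi, n_bins + 1)
    width = hi / n_bins
    in_range_group = (means >= 0.0) & (means <= hi)
    bin_of_group = np.full(len(means), -1, dtype=np.int64)
    bin_of_group[in_range_group] = np.clip(
        (means[in_range_group] / width).astype(np.int64), 0, n_bins - 1
    )

    pair_bins = bin_of_group[pairs.group_id]
    ok = pair_bins >= 0
    m_count = np.bincount(pair_bins[ok], minlength=n_bins).astype(float)
    m_sum = np.bincount(pair_bins[ok], weights=pairs.abs_diff[ok], minlength=n_bins)

    obs_bins = bin_of_group[gid]
    obs_ok = obs_bins >= 0
    s_count = np.bincount(obs_bins[obs_ok], minlength=n_bins).astype(float)
    s_sum = np.bincount(obs_bins[obs_ok], weights=sigma2[obs_ok], minlength=n_bins)

    nonempty = (m_count > 0) & (s_count > 0)
    if nonempty.sum() < 3:
        warnings.warn(
            "fewer than 3 populated intensity bins; falling back to the "
            "default initialization (s_fac=1.0, s_add_1=0.05)"
        )
        return MM24Params(
            s_fac=1.0, s_add_0=_INIT_CONST, s_add_1=0.05, s_add_2=_INIT_CONST
        )

    mean_abs = m_sum[nonempty] / m_count[nonempty]
    mean_sig2 = s_sum[nonempty] / s_count[nonempty]
    centers = 0.5 * (edges[:-1] + edges[1:])[nonempty]

    # anchor: the first populated bin estimates the low-intensity error
    first = mean_abs[0]
    s_fac0 = max(first / (_HALF_NORMAL_FOLD * math.sqrt(max(mean_sig2[0], 1e-300))), 1e-3)

    def resid(x):
        s_fac, s_add_1 = x
        model = _HALF_NORMAL_FOLD * s_fac * np.sqrt(mean_sig2 + s_add_1**2 * centers**2)
        return model - mean_abs

    sol = least_squares(
        resid,
        x0=[s_fac0, 0.05],
        bounds=([1e-3, 0.0], [1e3, 10.0]),
        method="trf",
    )
    s_fac_init, s_add_1_init = (float(v) for v in sol.x)
    return MM24Params(
        s_fac=s_fac_init,
        s_add_0=_INIT_CONST,
        s_add_1=s_add_1_init,
        s_add_2=_INIT_CONST,
    )


def _pair_context(table: UnmergedReflectionTable, pairs: PairwiseDifferenceSet):
    """Static per-pair arrays used by the likelihood."""
    _, _, mean_i, _, _ = _obs_arrays(table)
    sigma2 = table.reflections["sigma"].to_numpy() ** 2
    cc = table.cc_per_observation()
    return {
        "d": pairs.abs_diff,
        "sig2_j": sigma2[pairs.i_j],
        "sig2_k": sigma2[pairs.i_k],
        "mi_j": mean_i[pairs.i_j],
        "mi_k": mean_i[pairs.i_k],
        "cc_j": cc[pairs.i_j],
        "cc_k": cc[pairs.i_k],
    }


def _nll_and_grad(theta, ctx, likelihood_kind, free_nu):
    """NLL of the pairwise differences and gradient in optimization coords.

    theta = (s_fac, s_add_0, s_add_1, s_add_2[, log nu]).
    """
    s_fac, a0, a1, a2 = theta[:4]
    nu = math.exp(theta[4]) if free_nu else None

    ej = np.exp(-a2 * ctx["cc_j"])
    ek = np.exp(-a2 * ctx["cc_k"])
    gj = a0 + a1 * ej
    gk = a0 + a1 * ek
    mi2_j = ctx["mi_j"] ** 2
    mi2_k = ctx["mi_k"] ** 2
    bj = ctx["sig2_j"] + gj**2 * mi2_j
    bk = ctx["sig2_k"] + gk**2 * mi2_k
    s2 = s_fac**2 * (bj + bk)  # pair variance s_p^2
    s = np.sqrt(s2)
    omega = ctx["d"] / s

    if likelihood_kind == "half_normal":
        # -log p(dI) = -log sqrt(2/pi) + log s + omega^2/2
        nll = float(
            np.sum(0.5 * omega**2 + np.log(s)) - len(s) * LOG_HALF_NORMAL_NORM
        )
        # dl/ds for one pair: (1 - omega^2)/s
        dl_ds = (1.0 - omega**2) / s
    else:
        logp = half_t_log_pdf(omega, nu)
        nll = float(np.sum(-logp + np.log(s)))
        w2 = omega**2
        dl_ds = (1.0 - (nu + 1.0) * w2 / (nu + w2)) / s

    # ds/dtheta = (dv_j + dv_k) / (2 s), v = s_fac^2 b
    half_inv_s = 0.5 / s
    grad = np.empty(len(theta))
    # s_fac: dv = 2 s_fac (bj + bk) => ds = s2 / s_fac / s = s / s_fac
    grad[0] = float(np.sum(dl_ds * s / s_fac))
    c = s_fac**2 * half_inv_s
    grad[1] = float(np.sum(dl_ds * c * 2.0 * (gj * mi2_j + gk * mi2_k)))
    grad[2] = float(np.sum(dl_ds * c * 2.0 * (gj * mi2_j * ej + gk * mi2_k * ek)))
    grad[3] = float(
        np.sum(
            dl_ds
            * c
            * (-2.0 * a1)
            * (gj * mi2_j * ctx["cc_j"] * ej + gk * mi2_k * ctx["cc_k"] * ek)
        )
    )
    if free_nu:
        w2 = omega**2
        dlogp_dnu = (
            0.5 * (digamma((nu + 1.0) / 2.0) - digamma(nu / 2.0))
            - 0.5 / nu
            - 0.5 * np.log1p(w2 / nu)
            + (nu + 1.0) * w2 / (2.0 * nu * (nu + w2))
        )
        grad[4] = float(-np.sum(dlogp_dnu)) * nu  # chain rule through log nu
    return nll, grad


def mm24_loss_and_gradient(
    pairs: PairwiseDifferenceSet,
    table: UnmergedReflectionTable,
    params: MM24Params,
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood of the pairwise differences and its gradient.

    The gradient is over (s_fac, s_add_0, s_add_1, s_add_2) plus nu for the
    half-t likelihood (reported in natural nu units).
    """
    if pairs.n_pairs == 0:
        raise ValueError("empty pairwise-difference set")
    ctx = _pair_context(table, pairs)
    free_nu = params.likelihood_kind == "half_t"
    theta = [params.s_fac, params.s_add_0, params.s_add_1, params.s_add_2]
    if free_nu:
        theta.append(math.log(params.nu))
    nll, grad = _nll_and_grad(np.asarray(theta), ctx, params.likelihood_kind, free_nu)
    if not np.isfinite(nll):
        raise CalibrationError("non-finite loss in MM24 likelihood")
    if free_nu:
        grad = grad.copy()
        grad[4] /= params.nu  # back to d/dnu from d/dlog nu
    return nll, grad


class MM24Calibration:
    """MM24 error-model fit for an unmerged reflection table.

    Parameters
    ----------
    table : the unmerged observations (cc populated per lattice).
    likelihood : "half_t" (robust, default) or "half_normal".
    cap : maximum subsampled pairs per Miller index.
    extra_offset : integer added to every Miller seed, for alternative
        reproducible subsamplings.
    fix_nu : optimize with the degrees of freedom frozen at this value.
    """

    def __init__(
        self,
        table: UnmergedReflectionTable,
        likelihood: str = "half_t",
        cap: int = DEFAULT_PAIR_CAP,
        extra_offset: int = 0,
        fix_nu: float | None = None,
    ):
        if likelihood not in ("half_normal", "half_t"):
            raise ValueError(f"unknown likelihood: {likelihood}")
        self.table = table
        self.likelihood = likelihood
        self.cap = cap
        self.extra_offset = extra_offset
        self.fix_nu = fix_nu
        self.pairs = build_pair_set(table, cap=cap, extra_offset=extra_offset)
        if self.pairs.n_pairs == 0:
            raise ValueError("no Miller group has multiplicity >= 2")
        self._ctx = _pair_context(table, self.pairs)

    def initial_params(self) -> MM24Params:
        init = initialize_mm24(self.table, self.pairs)
        nu = None
        if self.likelihood == "half_t":
            nu = self.fix_nu if self.fix_nu is not None else 10.0
        return MM24Params(
            s_fac=init.s_fac,
            s_add_0=init.s_add_0,
            s_add_1=init.s_add_1,
            s_add_2=init.s_add_2,
            nu=nu,
            likelihood_kind=self.likelihood,
        )

    def fit(self, start: MM24Params | None = None) -> "MM24Results":
        start = start or self.initial_params()
        free_nu = self.likelihood == "half_t" and self.fix_nu is None
        x0 = [start.s_fac, start.s_add_0, start.s_add_1, start.s_add_2]
        bounds = [
            MM24_BOUNDS["s_fac"],
            MM24_BOUNDS["s_add_0"],
            MM24_BOUNDS["s_add_1"],
            MM24_BOUNDS["s_add_2"],
        ]
        if free_nu:
            x0.append(math.log(start.nu))
            bounds.append(tuple(math.log(v) for v in MM24_BOUNDS["nu"]))
        x0 = np.asarray(x0, dtype=float)

        if self.likelihood == "half_t" and not free_nu:
            nu_fixed = float(self.fix_nu)

            def objective(theta):
                full = np.concatenate([theta, [math.log(nu_fixed)]])
                nll, grad = _nll_and_grad(full, self._ctx, "half_t", True)
                return nll, grad[:4]

        else:

            def objective(theta):
                return _nll_and_grad(theta, self._ctx, self.likelihood, free_nu)

        nll0, _ = objective(x0)
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success and res.status != 1:
            raise CalibrationError(f"MM24 optimization failed: {res.message}", trace=res)
        nu = None
        if self.likelihood == "half_t":
            nu = math.exp(res.x[4]) if free_nu else float(self.fix_nu)
        params = MM24Params(
            s_fac=float(res.x[0]),
            s_add_0=float(res.x[1]),
            s_add_1=float(res.x[2]),
            s_add_2=float(res.x[3]),
            nu=nu,
            likelihood_kind=self.likelihood,
        )
        return MM24Results(
            model=self,
            params=params,
            initial_params=start,
            initial_nll=float(nll0),
            final_nll=float(res.fun),
            n_iter=int(res.nit),
            n_pairs=self.pairs.n_pairs,
            optimizer_message=str(res.message),
        )


@dataclass
class MM24Results:
    """Fitted MM24 parameters with optimization diagnostics."""

    model: MM24Calibration
    params: MM24Params
    initial_params: MM24Params
    initial_nll: float
    final_nll: float
    n_iter: int
    n_pairs: int
    optimizer_message: str

    def omega(self) -> PairwiseDifferenceSet:
        """Pairwise differences normalized with the fitted parameters."""
        return normalized_pairwise_differences(
            self.model.pairs, self.model.table, self.params
        )

    def s_add_curve(self, cc: np.ndarray) -> np.ndarray:
        return s_add_of_cc(cc, self.params)

    def report(self) -> dict:
        p = self.params
        return {
            "model": "mm24",
            "likelihood": p.likelihood_kind,
            "s_fac": p.s_fac,
            "s_add_0": p.s_add_0,
            "s_add_1": p.s_add_1,
            "s_add_2": p.s_add_2,
            "nu": p.nu,
            "n_pairs": self.n_pairs,
            "initial_nll": self.initial_nll,
            "final_nll": self.final_nll,
            "n_iter": self.n_iter,
            "optimizer_message": self.optimizer_message,
        }

    def summary(self) -> str:
        p = self.params
        lines = [
            "MM24 error calibration",
            "======================",
            f"likelihood:         {p.likelihood_kind}",
            f"pairs (cap {self.model.cap}/index): {self.n_pairs}",
            f"s_fac:   {p.s_fac:12.6g}",
            f"s_add_0: {p.s_add_0:12.6g}",
            f"s_add_1: {p.s_add_1:12.6g}",
            f"s_add_2: {p.s_add_2:12.6g}",
        ]
        if p.nu is not None:
            lines.append(f"nu:      {p.nu:12.6g}")
        lines.append(
            f"NLL: {self.initial_nll:.6g} -> {self.final_nll:.6g} "
            f"in {self.n_iter} iterations"
        )
        return "\n".join(lines)


def fit_mm24(
    table: UnmergedReflectionTable,
    likelihood: str = "half_t",
    fix_nu: float | None = None,
    cap: int = DEFAULT_PAIR_CAP,
    extra_offset: int = 0,
) -> MM24Results:
    """Convenience wrapper: ``MM24Calibration(...).fit()``."""
    return MM24Calibration(
        table,
        likelihood=likelihood,
        cap=cap,
        extra_offset=extra_offset,
        fix_nu=fix_nu,
    ).fit()
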