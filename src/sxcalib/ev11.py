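"""Ev11 error calibration: normalized deviations and the binned RMS target.

The Ev11 procedure tunes (s_fac, s_B, s_add) so that the leave-one-out
residual of each redundant observation, divided by its modeled uncertainty,
has unit standard deviation.  Deviations are pooled in 100 intensity bins
(evenly spaced in the all-in group mean <I_h>) and the target

    L = sum_b w_b (RMS_b(delta) - 1)^2,   w_b = sqrt(m_b),

is minimized with a bounded quasi-Newton optimizer using analytic
gradients.  The sqrt(m_b) weight sits between weighting bins equally
(w_b = 1) and weighting observations equally (w_b = m_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errormodels import Ev11Params, SigmaDomainError, ev11_sigma
from .reflections import UnmergedReflectionTable, miller_group_arrays

__all__ = [
    "DeviationSet",
    "IntensityBinning",
    "normalized_deviations",
    "make_intensity_bins",
    "ev11_target",
    "fit_ev11",
    "Ev11Calibration",
    "Ev11Results",
    "CalibrationError",
]

# optimizer box constraints
EV11_BOUNDS = {"s_fac": (1e-3, 1e3), "s_B": (-1e3, 1e3), "s_add": (0.0, 10.0)}


class CalibrationError(RuntimeError):
    """Optimization failed; carries the optimizer trace in ``.trace``."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class DeviationSet:
    """Normalized leave-one-out deviations for groups with n >= 2.

    ``delta[i]`` belongs to observation ``obs_index[i]`` of the parent
    table; ``sigma_prime`` holds the calibrated sigmas used.
    """

    delta: np.ndarray
    obs_index: np.ndarray
    group_id: np.ndarray
    mean_intensity: np.ndarray  # all-in <I_h> per retained observation
    sigma_prime: np.ndarray

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.delta**2)))


@dataclass
class IntensityBinning:
    """Even intensity bins over [min <I_h>, max <I_h>].

    ``bin_of_group[g]`` maps a Miller-group id to its bin; ``m_b`` counts
    *observations* (in groups with n >= 2) per bin; ``w_b = sqrt(m_b)``.
    """

    edges: np.ndarray
    bin_of_group: np.ndarray
    m_b: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def w_b(self) -> np.ndarray:
        return np.sqrt(self.m_b)


def _prepared(table: UnmergedReflectionTable):
    """Per-observation arrays restricted to groups with n >= 2."""
    gid, n_per_obs, mean_per_obs, sizes, means = miller_group_arrays(table)
    keep = n_per_obs >= 2
    refl = table.reflections
    return {
        "obs_index": np.flatnonzero(keep),
        "gid": gid[keep],
        "n": n_per_obs[keep].astype(float),
        "mean_i": mean_per_obs[keep],
        "intensity": refl["intensity"].to_numpy()[keep],
        "sigma": refl["sigma"].to_numpy()[keep],
        "group_sizes": sizes,
        "group_means": means,
    }


def normalized_deviations(
    table: UnmergedReflectionTable, params: Ev11Params
) -> DeviationSet:
    """delta_hk = (I_hk - <I_h>_{loo}) / sqrt(sig'_hk^2 + sum_{j!=k} sig'_hj^2/(n-1)^2).

    The numerator uses the leave-one-out mean; the sigma transform uses the
    all-in mean <I_h> (the "biased" mean).  Groups with n = 1 contribute
    nothing.
    """
    p = _prepared(table)
    if len(p["gid"]) == 0:
        raise ValueError("no Miller group has multiplicity >= 2")
    sp = ev11_sigma(p["sigma"], p["mean_i"], params)
    n = p["n"]
    loo_mean = (p["mean_i"] * n - p["intensity"]) / (n - 1.0)
    resid = p["intensity"] - loo_mean
    sp2 = sp**2
    group_sum_sp2 = np.bincount(p["gid"], weights=sp2)[p["gid"]]
    var = sp2 + (group_sum_sp2 - sp2) / (n - 1.0) ** 2
    delta = resid / np.sqrt(var)
    return DeviationSet(
        delta=delta,
        obs_index=p["obs_index"],
        group_id=p["gid"],
        mean_intensity=p["mean_i"],
        sigma_prime=sp,
    )


def make_intensity_bins(
    table: UnmergedReflectionTable, n_bins: int = 100
) -> IntensityBinning:
    """Even bins spanning [min <I_h>, max <I_h>]; a whole Miller group goes
    into one bin by its all-in mean.  ``m_b`` counts observations of groups
    with multiplicity >= 2; empty bins are allowed (skipped downstream).
    Bins are half-open [edge_b, edge_{b+1}); the value at the max closes
    the last bin.
    """
    _, _, _, sizes, means = miller_group_arrays(table)
    lo, hi = float(np.min(means)), float(np.max(means))
    if not hi > lo:
        raise ValueError("all group mean intensities are equal; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    bin_of_group = np.clip(((means - lo) / width).astype(int), 0, n_bins - 1)
    contributing = np.where(sizes >= 2, sizes, 0)
    m_b = np.bincount(bin_of_group, weights=contributing, minlength=n_bins)
    return IntensityBinning(edges=edges, bin_of_group=bin_of_group, m_b=m_b)


def ev11_target(
    dev: DeviationSet, bins: IntensityBinning
) -> tuple[float, np.ndarray | None]:
    """Loss sum_b w_b (RMS_b - 1)^2 over non-empty bins (no gradient).

    Use :class:`Ev11Calibration` for the gradient path; this standalone
    form evaluates the loss for a precomputed deviation set.
    """
    bin_of_obs = bins.bin_of_group[dev.group_id]
    nb = bins.n_bins
    m = np.bincount(bin_of_obs, minlength=nb).astype(float)
    ssq = np.bincount(bin_of_obs, weights=dev.delta**2, minlength=nb)
    nonempty = m > 0
    rms = np.sqrt(ssq[nonempty] / m[nonempty])
    loss = float(np.sum(np.sqrt(m[nonempty]) * (rms - 1.0) ** 2))
    return loss, None


class Ev11Calibration:
    """Ev11 error-model fit for an unmerged reflection table.

    Examples
    --------
    >>> model = Ev11Calibration(table)
    >>> res = model.fit()
    >>> res.params.s_fac
    """

    def __init__(self, table: UnmergedReflectionTable, n_bins: int = 100):
        self.table = table
        self.n_bins = n_bins
        self._p = _prepared(table)
        if len(self._p["gid"]) == 0:
            raise ValueError("table has no redundant observations")
        self.bins = make_intensity_bins(table, n_bins)
        # residuals and leave-one-out means do not depend on the parameters
        p = self._p
        n = p["n"]
        loo = (p["mean_i"] * n - p["intensity"]) / (n - 1.0)
        self._resid = p["intensity"] - loo
        self._bin_of_obs = self.bins.bin_of_group[p["gid"]]
        self._m = np.bincount(self._bin_of_obs, minlength=self.n_bins).astype(float)
        self._w = np.sqrt(self._m, where=self._m > 0, out=np.zeros_like(self._m))

    # -- objective --------------------------------------------------------
    def loss_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Target and analytic gradient at theta = (s_fac, s_B, s_add)."""
        s_fac, s_B, s_add = theta
        p = self._p
        mean_i, sigma, n, gid = p["mean_i"], p["sigma"], p["n"], p["gid"]
        bracket = sigma**2 + s_B * mean_i + s_add**2 * mean_i**2
        if np.any(bracket <= 0):
            # graceful barrier: push the optimizer back toward the feasible
            # region instead of raising inside a line search
            worst = float(np.min(bracket))
            loss = 1e8 * (1.0 - worst)
            grad = np.array([0.0, -1e8 * float(np.min(mean_i)), 0.0])
            return loss, grad
        u = s_fac**2 * bracket  # sigma'^2
        du = np.stack(
            [
                2.0 * s_fac * bracket,
                np.full_like(bracket, s_fac**2) * mean_i,
                2.0 * s_fac**2 * s_add * mean_i**2,
            ]
        )
        inv_nm1_sq = 1.0 / (n - 1.0) ** 2
        sum_u = np.bincount(gid, weights=u)[gid]
        var = u + (sum_u - u) * inv_nm1_sq
        delta2 = self._resid**2 / var
        # dvar/dtheta_i and d(delta^2) = -(delta^2/var) dvar
        bo = self._bin_of_obs
        nb = self.n_bins
        ssq = np.bincount(bo, weights=delta2, minlength=nb)
        nonempty = self._m > 0
        rms = np.zeros(nb)
        rms[nonempty] = np.sqrt(ssq[nonempty] / self._m[nonempty])
        dev = rms - 1.0
        loss = float(np.sum(self._w[nonempty] * dev[nonempty] ** 2))

        # dL/dtheta = sum_b w_b (rms_b-1)/rms_b * mean_b(d delta^2)
        coef = np.zeros(nb)
        ok = nonempty & (rms > 0)
        coef[ok] = self._w[ok] * dev[ok] / (rms[ok] * self._m[ok])
        coef_obs = coef[bo]
        grad = np.empty(3)
        for i in range(3):
            sum_du = np.bincount(gid, weights=du[i])[gid]
            dvar = du[i] + (sum_du - du[i]) * inv_nm1_sq
            ddelta2 = -delta2 / var * dvar
            grad[i] = float(np.sum(coef_obs * ddelta2))
        return loss, grad

    def initial_params(self) -> Ev11Params:
        """s_fac starts at the overall RMS deviation under the identity
        transform; s_B = 0; s_add = 0.01."""
        dev = normalized_deviations(self.table, Ev11Params(1.0, 0.0, 0.0))
        return Ev11Params(s_fac=max(dev.rms(), 1e-3), s_B=0.0, s_add=0.01)

    def fit(self, start: Ev11Params | None = None) -> "Ev11Results":
        start = start or self.initial_params()
        x0 = np.array([start.s_fac, start.s_B, start.s_add])
        bounds = [EV11_BOUNDS["s_fac"], EV11_BOUNDS["s_B"], EV11_BOUNDS["s_add"]]
        loss0, _ = self.loss_and_grad(x0)
        res = minimize(
            self.loss_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if not res.success and res.status != 1:  # 1 = maxiter, still usable
            raise CalibrationError(
                f"Ev11 optimization failed: {res.message}", trace=res
            )
        params = Ev11Params(
            s_fac=float(res.x[0]), s_B=float(res.x[1]), s_add=float(res.x[2])
        )
        return Ev11Results(
            model=self,
            params=params,
            initial_params=start,
            initial_loss=loss0,
            final_loss=float(res.fun),
            n_iter=int(res.nit),
            optimizer_message=str(res.message),
        )


@dataclass
class Ev11Results:
    """Fitted Ev11 parameters with optimization diagnostics."""

    model: Ev11Calibration
    params: Ev11Params
    initial_params: Ev11Params
    initial_loss: float
    final_loss: float
    n_iter: int
    optimizer_message: str

    def deviations(self) -> DeviationSet:
        return normalized_deviations(self.model.table, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Ev11 error calibration",
            "======================",
            f"observations (multiplicity >= 2): {len(self.model._p['gid'])}",
            f"intensity bins:                   {self.model.n_bins}",
            f"s_fac: {p.s_fac:12.6g}",
            f"s_B:   {p.s_B:12.6g}",
            f"s_add: {p.s_add:12.6g}",
            f"loss:  {self.initial_loss:.6g} -> {self.final_loss:.6g} "
            f"in {self.n_iter} iterations",
            f"RMS normalized deviation at fit: {self.deviations().rms():.4f}",
        ]
        return "\n".join(lines)


def fit_ev11(table: UnmergedReflectionTable, n_bins: int = 100) -> Ev11Results:
    """Convenience wrapper: ``Ev11Calibration(table, n_bins).fit()``."""
    return Ev11Calibration(table, n_bins=n_bins).fit()
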