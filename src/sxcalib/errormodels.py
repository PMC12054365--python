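"""Parameterized error transforms and the half-normal / half-t kernels.

Two empirical transforms turn a counting-statistics sigma into a final
measurement uncertainty:

* the Ev11 transform,
  ``sigma'^2 = s_fac^2 (sigma^2 + s_B <I_h> + s_add^2 <I_h>^2)``,
  with one global (s_fac, s_B, s_add) for the whole data set, and
* the MM24 transform,
  ``sigma'^2 = s_fac^2 (sigma^2 + s_add(cc_l)^2 <I_h>^2)``,
  where the fractional term decays exponentially with the lattice's
  correlation cc_l to the scaling reference:
  ``s_add(cc) = s_add_0 + s_add_1 exp(-s_add_2 cc)``.

The exponential form keeps s_add positive and monotone decreasing in cc
(a polynomial could cross zero and divide-by-zero the normalization).
The s_B term has no physical interpretation and is dropped in MM24; the
s_fac^2 factor multiplies the whole bracket, keeping the Ev11 convention.
s_fac rescales uncertainties only — observed intensities are never touched
by calibration.

The likelihood kernels are densities on [0, inf) for normalized pairwise
differences: a standard half-normal and a half Student-t whose degrees of
freedom ``nu`` tune the tail weight (nu = 1 is half-Cauchy; nu -> inf
recovers the half-normal).  All kernel math is done in log space with
``gammaln``; the gamma function itself is never evaluated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Ev11Params",
    "MM24Params",
    "ev11_sigma",
    "s_add_of_cc",
    "mm24_sigma",
    "half_normal_log_pdf",
    "half_t_log_pdf",
    "SigmaDomainError",
]

LOG_HALF_NORMAL_NORM = 0.5 * math.log(2.0 / math.pi)


class SigmaDomainError(ValueError):
    """The parameterized variance bracket is non-positive."""


@dataclass
class Ev11Params:
    """Ev11 error-model coefficients.

    s_fac : global rescale of the bracket (dimensionless, > 0)
    s_B   : intensity-linear term, intensity units, any sign
    s_add : fractional error whose variance scales with <I_h>^2 (>= 0)
    """

    s_fac: float = 1.0
    s_B: float = 0.0
    s_add: float = 0.0

    def __post_init__(self) -> None:
        if self.s_fac <= 0:
            raise ValueError("s_fac must be positive")

    def to_json(self) -> str:
        doc = {"model": "ev11", **asdict(self)}
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Ev11Params":
        doc = json.loads(text)
        return cls(s_fac=doc["s_fac"], s_B=doc["s_B"], s_add=doc["s_add"])


@dataclass
class MM24Params:
    """MM24 error-model coefficients.

    The per-lattice fractional error is
    ``s_add(cc) = s_add_0 + s_add_1 exp(-s_add_2 cc)``; all three
    coefficients are global, lattice dependence enters only through cc.
    ``nu`` is the half-t degrees of freedom and is present (``> 1``) only
    for the half-t likelihood.
    """

    s_fac: float = 1.0
    s_add_0: float = 0.0
    s_add_1: float = 0.0
    s_add_2: float = 0.0
    nu: float | None = None
    likelihood_kind: Literal["half_normal", "half_t"] = "half_normal"

    def __post_init__(self) -> None:
        if self.s_fac <= 0:
            raise ValueError("s_fac must be positive")
        if self.likelihood_kind not in ("half_normal", "half_t"):
            raise ValueError(f"unknown likelihood: {self.likelihood_kind}")
        if self.likelihood_kind == "half_t":
            if self.nu is None or self.nu <= 1:
                raise ValueError("half_t requires nu > 1")
        # positivity of s_add on cc in [-1, 1] (exp factor is maximal at -1)
        if min(self.s_add_0, self.s_add_1, self.s_add_2) < 0:
            if self.s_add_0 + self.s_add_1 * math.exp(self.s_add_2) <= 0:
                raise ValueError("s_add(cc) must stay positive on [-1, 1]")

    def to_json(self) -> str:
        doc = {"model": "mm24", **asdict(self)}
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MM24Params":
        doc = json.loads(text)
        return cls(
            s_fac=doc["s_fac"],
            s_add_0=doc["s_add_0"],
            s_add_1=doc["s_add_1"],
            s_add_2=doc["s_add_2"],
            nu=doc.get("nu"),
            likelihood_kind=doc.get("likelihood_kind", "half_normal"),
        )


def ev11_sigma(sigma_counting, mean_intensity, params: Ev11Params):
    """Ev11 calibrated sigma: s_fac (sigma^2 + s_B<I> + s_add^2<I>^2)^1/2.

    Raises :class:`SigmaDomainError` if the bracket is non-positive for any
    observation (possible when s_B <I> is negative enough).
    """
    sigma = np.asarray(sigma_counting, dtype=float)
    mean_i = np.asarray(mean_intensity, dtype=float)
    bracket = sigma**2 + params.s_B * mean_i + params.s_add**2 * mean_i**2
    if np.any(bracket <= 0):
        idx = int(np.argmin(bracket))
        raise SigmaDomainError(
            f"non-positive variance bracket ({bracket.flat[idx]:.4g}) at "
            f"observation {idx}; s_B={params.s_B} is too negative"
        )
    out = params.s_fac * np.sqrt(bracket)
    return out if out.ndim else float(out)


def s_add_of_cc(cc, params: MM24Params):
    """Per-lattice fractional error s_add(cc), exponential decay in cc."""
    cc = np.asarray(cc, dtype=float)
    out = params.s_add_0 + params.s_add_1 * np.exp(-params.s_add_2 * cc)
    return out if out.ndim else float(out)


def mm24_sigma(sigma_counting, mean_intensity, cc, params: MM24Params):
    """MM24 calibrated sigma: s_fac (sigma^2 + s_add(cc)^2 <I>^2)^1/2."""
    sigma = np.asarray(sigma_counting, dtype=float)
    mean_i = np.asarray(mean_intensity, dtype=float)
    s_add = s_add_of_cc(cc, params)
    out = params.s_fac * np.sqrt(sigma**2 + np.square(s_add * mean_i))
    return out if out.ndim else float(out)


def half_normal_log_pdf(omega):
    """log of the standard half-normal density (2/pi)^1/2 exp(-w^2/2)."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("half-normal support is [0, inf)")
    out = LOG_HALF_NORMAL_NORM - 0.5 * w**2
    return out if out.ndim else float(out)


def half_t_log_pdf(omega, nu):
    """log of the half Student-t density on [0, inf).

    p(w; nu) = 2 G((nu+1)/2) / ((nu pi)^1/2 G(nu/2)) (1 + w^2/nu)^-(nu+1)/2
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("half-t support is [0, inf)")
    norm = (
        math.log(2.0)
        + gammaln((nu + 1.0) / 2.0)
        - 0.5 * math.log(nu * math.pi)
        - gammaln(nu / 2.0)
    )
    out = norm - 0.5 * (nu + 1.0) * np.log1p(w**2 / nu)
    return out if out.ndim else float(out)
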