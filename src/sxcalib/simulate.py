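"""Synthetic serial-crystallography data with known ground truth.

The generator mirrors the statistical structure the calibrators assume,
so every fit in this package can be exercised at desk scale with exact
truth available:

1.  Miller indices are taken from a reciprocal-space grid inside a
    resolution window; the shell mean intensity follows a Wilson falloff
    Sigma(d) = scale * exp(-B / (2 d^2)) and true intensities are drawn
    from the acentric Wilson (exponential) distribution with that mean.
2.  Observations are distributed over lattices.  Each lattice carries a
    latent quality q in (0, 1] mapped monotonically to its quality score
    cc_l (the role the correlation to the scaling reference plays in real
    data) and to a mild counting-noise inflation (poorer lattices are
    also weaker).  Counting sigmas follow a Poisson-motivated square-root
    law with an intensity floor.
3.  The total per-observation error has the exact MM24 structure
    sd = s_fac * (sigma_count^2 + s_add(cc_l)^2 I_h^2)^(1/2) with the
    noise drawn either normal or Student-t (rescaled to the same sd); an
    optional fraction of observations is replaced by 100x gross outliers.
4.  The lattice records carry the assigned score cc_l; the Pearson
    correlation each lattice actually realizes against the true
    intensities is additionally computed and kept in the ground truth
    (it is monotone in q but compresses toward 1 under realistic noise,
    which is why the assigned score, not the realized correlation, is
    the covariate the error model is asked to recover).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errormodels import MM24Params, s_add_of_cc
from .reflections import (
    UnitCell,
    UnmergedReflectionTable,
    compute_d_spacing,
    write_unmerged_table,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_experiment", "make_fixture"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults give ~1e5 observations over 5000 Miller indices and 200
    lattices with quality scores spread over [0.15, 0.97] — the scale at
    which the calibrators are validated.
    """

    n_miller: int = 5000
    mean_multiplicity: float = 20.0
    cell: UnitCell = field(default_factory=lambda: UnitCell(60.0, 70.0, 80.0))
    d_min: float = 1.6
    d_max: float = 30.0
    wilson_scale: float = 2000.0
    wilson_b: float = 30.0  # A^2
    n_lattices: int = 200
    cc_lo: float = 0.15  # quality score of the worst lattice
    cc_hi: float = 0.97  # ... and the best
    intensity_floor: float = 1.0  # counting-sigma floor term
    background: float = 50.0  # flat background term under the sqrt law
    counting_inflation: float = 2.0  # extra counting noise of the worst lattice
    true_params: MM24Params = field(
        default_factory=lambda: MM24Params(
            s_fac=1.2, s_add_0=0.01, s_add_1=0.15, s_add_2=2.0
        )
    )
    noise_family: str = "normal"  # or "t"
    nu_true: float = 5.0  # t noise shape (SD still sigma_error)
    quality_map: str = "exponential"  # or "power": mis-specified s_add(cc)
    outlier_fraction: float = 0.0
    outlier_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_miller < 1 or self.n_lattices < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.outlier_fraction <= 0.5:
            raise ValueError("outlier fraction must lie in [0, 0.5]")
        if self.noise_family not in ("normal", "t"):
            raise ValueError(f"unknown noise family: {self.noise_family}")
        if self.noise_family == "t" and self.nu_true <= 2:
            raise ValueError("t noise needs nu_true > 2 for a finite SD")
        if not 0 < self.cc_lo <= self.cc_hi < 1:
            raise ValueError("need 0 < cc_lo <= cc_hi < 1")


@dataclass
class GroundTruth:
    """Exact generative state of one simulated experiment."""

    miller: pd.DataFrame  # h k l d_spacing true_intensity
    per_observation: pd.DataFrame  # sigma_error true_intensity is_outlier
    lattices: pd.DataFrame  # lattice_id q cc_score cc_realized noise_scale
    params: MM24Params
    config: SimulationConfig


def _lattice_additional_error(cc, config: SimulationConfig):
    """Per-lattice fractional error driving the noise."""
    if config.quality_map == "exponential":
        return s_add_of_cc(cc, config.true_params)
    if config.quality_map == "power":
        # deliberately mis-specified alternative for robustness studies
        p = config.true_params
        return p.s_add_0 + p.s_add_1 * (1.0 - np.asarray(cc)) ** max(p.s_add_2, 1e-6)
    raise ValueError(f"unknown quality map: {config.quality_map}")


def _choose_miller_indices(config: SimulationConfig, rng) -> pd.DataFrame:
    """Grid Miller indices with d inside [d_min, d_max]."""
    cell = config.cell
    hmax = int(cell.a / config.d_min) + 1
    kmax = int(cell.b / config.d_min) + 1
    lmax = int(cell.c / config.d_min) + 1
    h, k, l = np.meshgrid(
        np.arange(0, hmax), np.arange(0, kmax), np.arange(1, lmax), indexing="ij"
    )
    h, k, l = (x.ravel() for x in (h, k, l))
    d = compute_d_spacing(cell, (h, k, l))
    ok = (d >= config.d_min) & (d <= config.d_max)
    h, k, l, d = h[ok], k[ok], l[ok], d[ok]
    if len(h) < config.n_miller:
        raise ValueError(
            f"resolution window holds only {len(h)} grid indices; "
            f"reduce n_miller or widen the window"
        )
    pick = np.sort(rng.choice(len(h), size=config.n_miller, replace=False))
    return pd.DataFrame(
        {"h": h[pick], "k": k[pick], "l": l[pick], "d_spacing": d[pick]}
    )


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[UnmergedReflectionTable, GroundTruth]:
    """Draw one synthetic unmerged data set with ground truth."""
    rng = np.random.default_rng(config.seed)
    miller = _choose_miller_indices(config, rng)
    sigma_big = config.wilson_scale * np.exp(
        -config.wilson_b / (2.0 * miller["d_spacing"].to_numpy() ** 2)
    )
    i_true_group = rng.exponential(scale=sigma_big)
    miller["true_intensity"] = i_true_group

    # multiplicities: 2 + Poisson keeps every group calibratable
    mult = 2 + rng.poisson(max(config.mean_multiplicity - 2.0, 0.0), config.n_miller)
    n_obs = int(mult.sum())
    group_of_obs = np.repeat(np.arange(config.n_miller), mult)
    lattice_of_obs = rng.integers(0, config.n_lattices, size=n_obs)

    i_true = i_true_group[group_of_obs]
    d_obs = miller["d_spacing"].to_numpy()[group_of_obs]
    sigma0 = np.sqrt(np.maximum(i_true, config.intensity_floor) + config.background)

    # per-lattice latent quality -> quality score (monotone, spread evenly
    # over [cc_lo, cc_hi]) and a mild counting-noise inflation
    q = (np.arange(config.n_lattices) + 0.5) / config.n_lattices
    q = q[rng.permutation(config.n_lattices)]
    cc_score = config.cc_lo + (config.cc_hi - config.cc_lo) * q
    s_add_l = _lattice_additional_error(cc_score, config)
    s_fac = config.true_params.s_fac

    noise_scale = 1.0 + config.counting_inflation * (1.0 - q)
    sigma_count = sigma0 * noise_scale[lattice_of_obs]
    sigma_error = s_fac * np.sqrt(
        sigma_count**2 + (s_add_l[lattice_of_obs] * i_true) ** 2
    )

    if config.noise_family == "normal":
        eps = rng.standard_normal(n_obs) * sigma_error
    else:
        nu = config.nu_true
        eps = rng.standard_t(nu, size=n_obs) * sigma_error / math.sqrt(nu / (nu - 2.0))
    i_obs = i_true + eps

    is_outlier = np.zeros(n_obs, dtype=bool)
    if config.outlier_fraction > 0:
        n_out = round(config.outlier_fraction * n_obs)
        idx = rng.choice(n_obs, size=n_out, replace=False)
        is_outlier[idx] = True
        i_obs[idx] = i_true[idx] * config.outlier_scale

    # realized per-lattice correlation against the exact true intensities
    cc_real = np.zeros(config.n_lattices)
    for lid in range(config.n_lattices):
        sel = lattice_of_obs == lid
        if sel.sum() < 3 or np.std(i_true[sel]) == 0 or np.std(i_obs[sel]) == 0:
            cc_real[lid] = 0.0
            continue
        cc_real[lid] = float(np.corrcoef(i_obs[sel], i_true[sel])[0, 1])
    cc_real = np.clip(cc_real, -1.0, 1.0)

    lattice_ids = np.array([f"L{lid:05d}" for lid in range(config.n_lattices)])
    refl = pd.DataFrame(
        {
            "h": miller["h"].to_numpy()[group_of_obs],
            "k": miller["k"].to_numpy()[group_of_obs],
            "l": miller["l"].to_numpy()[group_of_obs],
            "lattice_id": lattice_ids[lattice_of_obs],
            "intensity": i_obs,
            "sigma": sigma_count,
            "d_spacing": d_obs,
        }
    )
    lat = pd.DataFrame({"lattice_id": lattice_ids, "cc": cc_score})
    table = UnmergedReflectionTable(refl, lat)

    truth = GroundTruth(
        miller=miller,
        per_observation=pd.DataFrame(
            {
                "sigma_error": sigma_error,
                "true_intensity": i_true,
                "is_outlier": is_outlier,
                "lattice_id": lattice_ids[lattice_of_obs],
            }
        ),
        lattices=pd.DataFrame(
            {
                "lattice_id": lattice_ids,
                "q": q,
                "cc_score": cc_score,
                "cc_realized": cc_real,
                "noise_scale": noise_scale,
            }
        ),
        params=config.true_params,
        config=config,
    )
    return table, truth


FIXTURES = {
    "tiny": dict(
        n_miller=20,
        mean_multiplicity=4.0,
        n_lattices=8,
        seed=11,
    ),
    "calibration": dict(
        n_miller=20000,
        mean_multiplicity=5.0,
        n_lattices=200,
        seed=12,
    ),
    "robustness": dict(
        n_miller=20000,
        mean_multiplicity=5.0,
        n_lattices=200,
        outlier_fraction=0.01,
        seed=12,
    ),
}


def make_fixture(name: str, out_dir) -> dict:
    """Write a canned fixture (reflections/lattices TSV + manifest JSON).

    Names: ``tiny`` (20 Miller indices, ~4 obs each), ``calibration``
    (2e4 groups, ~1e5 obs), ``robustness`` (calibration + 1% outliers).
    Byte-stable across runs.  Returns the manifest.
    """
    from pathlib import Path

    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(**FIXTURES[name])
    table, truth = simulate_experiment(config)
    refl_path = out_dir / f"{name}.reflections.tsv"
    lat_path = out_dir / f"{name}.lattices.tsv"
    write_unmerged_table(table, refl_path, lat_path)
    cfg = asdict(config)
    cfg["cell"] = asdict(config.cell)
    cfg["true_params"] = asdict(config.true_params)
    manifest = {
        "fixture": name,
        "seed": config.seed,
        "n_obs": table.n_obs,
        "n_lattices": table.n_lattices,
        "n_outliers": int(truth.per_observation["is_outlier"].sum()),
        "config": cfg,
        "reflections": refl_path.name,
        "lattices": lat_path.name,
    }
    with open(out_dir / f"{name}.manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
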