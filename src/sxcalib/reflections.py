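"""Unmerged reflection tables: in-memory model, TSV/MTZ input and grouping.

The calibrators in this package operate strictly downstream of scaling:
observations are assumed to be symmetry-reduced (all symmetry mates mapped
to one representative Miller index) and placed on a common scale, so no
space-group machinery lives here.  A table couples two frames:

* per-observation rows ``h k l lattice_id intensity sigma [d_spacing]``,
  where ``sigma`` is the counting-statistics uncertainty from spot
  integration (the lower bound of the total measurement error), and
* per-lattice rows ``lattice_id cc [n_obs]``, where ``cc`` is the Pearson
  correlation of the lattice's intensities to the scaling reference.

Negative intensities are legitimate (weak reflections after background
subtraction) and are retained; rows with non-positive or non-finite
counting sigmas are rejected at read time.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "LatticeRecord",
    "MillerGroup",
    "UnmergedReflectionTable",
    "read_unmerged_table",
    "write_unmerged_table",
    "read_mtz_unmerged",
    "group_by_miller",
    "compute_d_spacing",
    "ReflectionFormatError",
    "TableConsistencyError",
]

#: Column order of the native reflection TSV.
REFLECTION_COLUMNS = ["h", "k", "l", "lattice_id", "intensity", "sigma"]
LATTICE_COLUMNS = ["lattice_id", "cc", "n_obs"]


class ReflectionFormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class TableConsistencyError(ValueError):
    """Observations and lattice records disagree."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("cell angles are geometrically inconsistent")

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Å²)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * np.cos(ga), a * c * np.cos(be)],
                [a * b * np.cos(ga), b * b, b * c * np.cos(al)],
                [a * c * np.cos(be), b * c * np.cos(al), c * c],
            ]
        )

    def d_spacing(self, h, k, l) -> np.ndarray | float:
        """Resolution d(hkl) in Å via the reciprocal metric tensor."""
        return compute_d_spacing(self, (h, k, l))


def compute_d_spacing(cell: UnitCell, miller) -> np.ndarray | float:
    """d-spacing in Å for Miller indices under ``cell``.

    Accepts a single ``(h, k, l)`` triple or three equal-length arrays.
    1/d² = m^T G* m with G* the inverse of the direct metric tensor.
    """
    h, k, l = (np.asarray(x, dtype=float) for x in miller)
    if np.any((h == 0) & (k == 0) & (l == 0)):
        raise ValueError("d-spacing is undefined for (0, 0, 0)")
    g_star = np.linalg.inv(cell.metric_tensor())
    m = np.stack([h, k, l], axis=-1)
    inv_d2 = np.einsum("...i,ij,...j->...", m, g_star, m)
    d = 1.0 / np.sqrt(inv_d2)
    if d.ndim == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class LatticeRecord:
    """Per-lattice metadata: quality score and observation count."""

    lattice_id: str
    cc: float
    n_obs: int = 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.cc <= 1.0:
            raise ValueError(f"cc must lie in [-1, 1], got {self.cc}")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")


@dataclass(frozen=True)
class MillerGroup:
    """All observations of one Miller index."""

    h: int
    k: int
    l: int
    indices: np.ndarray  # positional row indices into the parent table
    intensities: np.ndarray

    @property
    def n(self) -> int:
        return len(self.indices)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))


def _float17(x: float) -> str:
    # 17 significant digits round-trips any IEEE double exactly.
    return format(float(x), ".17g")


class UnmergedReflectionTable:
    """Validated, canonically ordered unmerged reflection observations.

    Parameters
    ----------
    reflections : DataFrame with columns ``h k l lattice_id intensity sigma``
        and optionally ``d_spacing``.
    lattices : DataFrame with columns ``lattice_id cc`` and optionally
        ``n_obs`` (recomputed from the observations regardless).

    The constructor validates invariants (finite intensities, positive
    sigmas, one lattice record per referenced lattice, cc in [-1, 1]) and
    sorts observations by ``(h, k, l, lattice_id, input order)`` so that
    downstream pair enumeration and binning are deterministic.
    """

    def __init__(self, reflections: pd.DataFrame, lattices: pd.DataFrame):
        refl = reflections.copy()
        missing = [c for c in REFLECTION_COLUMNS if c not in refl.columns]
        if missing:
            raise ReflectionFormatError(f"missing reflection column(s): {missing}")
        for c in ("h", "k", "l"):
            refl[c] = refl[c].astype(np.int64)
        refl["lattice_id"] = refl["lattice_id"].astype(str)
        for c in ("intensity", "sigma"):
            refl[c] = refl[c].astype(float)
        if "d_spacing" in refl.columns:
            refl["d_spacing"] = refl["d_spacing"].astype(float)

        if not np.all(np.isfinite(refl["intensity"])):
            raise ValueError("non-finite intensity encountered")
        bad = ~(np.isfinite(refl["sigma"]) & (refl["sigma"] > 0))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} observation(s) with non-positive or "
                "non-finite sigma; filter before construction"
            )

        lat = lattices.copy()
        lat_missing = [c for c in ("lattice_id", "cc") if c not in lat.columns]
        if lat_missing:
            raise ReflectionFormatError(f"missing lattice column(s): {lat_missing}")
        lat["lattice_id"] = lat["lattice_id"].astype(str)
        lat["cc"] = lat["cc"].astype(float)
        if lat["lattice_id"].duplicated().any():
            raise TableConsistencyError("duplicate lattice records")
        if np.any((lat["cc"] < -1) | (lat["cc"] > 1)):
            raise ValueError("lattice cc outside [-1, 1]")

        referenced = set(refl["lattice_id"])
        known = set(lat["lattice_id"])
        orphans = referenced - known
        if orphans:
            raise TableConsistencyError(
                f"observations reference lattice(s) without a record: "
                f"{sorted(orphans)[:5]}"
            )

        # canonical deterministic order; intensity/sigma break ties when a
        # lattice holds several observations of one index, making the order
        # (hence pair subsampling) invariant to input permutation; mergesort
        # is stable so exact duplicates keep input order
        refl = refl.reset_index(drop=True)
        refl = refl.sort_values(
            ["h", "k", "l", "lattice_id", "intensity", "sigma"], kind="mergesort"
        ).reset_index(drop=True)

        counts = refl["lattice_id"].value_counts()
        lat = lat.sort_values("lattice_id", kind="mergesort").reset_index(drop=True)
        lat["n_obs"] = lat["lattice_id"].map(counts).fillna(0).astype(np.int64)

        self.reflections = refl
        self.lattices = lat

    # -- basic protocol ---------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.reflections)

    @property
    def n_lattices(self) -> int:
        return len(self.lattices)

    def __len__(self) -> int:
        return self.n_obs

    def __eq__(self, other) -> bool:
        if not isinstance(other, UnmergedReflectionTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.reflections, other.reflections, rtol=1e-12, atol=0
            )
            a = self.lattices[["lattice_id", "cc", "n_obs"]]
            b = other.lattices[["lattice_id", "cc", "n_obs"]]
            pd.testing.assert_frame_equal(a, b, rtol=1e-12, atol=0)
        except AssertionError:
            return False
        return True

    def cc_by_lattice(self) -> pd.Series:
        return self.lattices.set_index("lattice_id")["cc"]

    def cc_per_observation(self) -> np.ndarray:
        """cc of the parent lattice, aligned with the observation rows."""
        return (
            self.reflections["lattice_id"].map(self.cc_by_lattice()).to_numpy(float)
        )

    def with_lattice_cc(self, cc: Mapping[str, float]) -> "UnmergedReflectionTable":
        lat = self.lattices.copy()
        lat["cc"] = lat["lattice_id"].map(dict(cc)).fillna(lat["cc"])
        return UnmergedReflectionTable(self.reflections, lat)

    def subset_lattices(self, keep: Iterable[str]) -> "UnmergedReflectionTable":
        keep = set(keep)
        refl = self.reflections[self.reflections["lattice_id"].isin(keep)]
        lat = self.lattices[self.lattices["lattice_id"].isin(keep)]
        return UnmergedReflectionTable(refl, lat)

    def attach_d_spacings(self, cell: UnitCell) -> "UnmergedReflectionTable":
        refl = self.reflections.copy()
        refl["d_spacing"] = compute_d_spacing(
            cell, (refl["h"].to_numpy(), refl["k"].to_numpy(), refl["l"].to_numpy())
        )
        return UnmergedReflectionTable(refl, self.lattices)


def group_by_miller(table: UnmergedReflectionTable) -> list[MillerGroup]:
    """Group observations by exact (h, k, l).

    Every observation lands in exactly one group; the group's
    ``mean_intensity`` is the all-in arithmetic mean of its members.
    """
    refl = table.reflections
    groups: list[MillerGroup] = []
    for (h, k, l), sub in refl.groupby(["h", "k", "l"], sort=True):
        groups.append(
            MillerGroup(
                h=int(h),
                k=int(k),
                l=int(l),
                indices=sub.index.to_numpy(),
                intensities=sub["intensity"].to_numpy(),
            )
        )
    return groups


def miller_group_arrays(table: UnmergedReflectionTable):
    """Vectorized grouping companion used by the calibrators.

    Returns ``(group_id, n_in_group, mean_in_group)`` aligned with the
    (canonically sorted) observation rows, plus the per-group frames
    ``group_sizes`` and ``group_means`` indexed by group id.
    """
    refl = table.reflections
    gid = refl.groupby(["h", "k", "l"], sort=True).ngroup().to_numpy()
    order = np.argsort(gid, kind="stable")
    # rows are already sorted by (h,k,l,...) so gid is nondecreasing
    assert np.array_equal(order, np.arange(len(gid)))
    sizes = np.bincount(gid)
    sums = np.bincount(gid, weights=refl["intensity"].to_numpy())
    means = sums / sizes
    return gid, sizes[gid], means[gid], sizes, means


# -- on-disk formats ------------------------------------------------------

def _read_tsv(path, expected: Sequence[str], optional: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in expected:
        if col not in df.columns:
            raise ReflectionFormatError(f"{path}: missing required column '{col}'")
    keep = list(expected) + [c for c in optional if c in df.columns]
    return df[keep]


def read_unmerged_table(
    reflections_path, lattices_path
) -> tuple[UnmergedReflectionTable, int]:
    """Read the native TSV pair; returns ``(table, n_dropped)``.

    Rows whose counting sigma is non-positive or non-finite are dropped and
    counted in ``n_dropped``.
    """
    refl = _read_tsv(reflections_path, REFLECTION_COLUMNS, ["d_spacing"])
    for c in ("h", "k", "l"):
        refl[c] = refl[c].astype(np.int64)
    for c in ("intensity", "sigma") + (("d_spacing",) if "d_spacing" in refl else ()):
        refl[c] = refl[c].astype(float)
    sig = refl["sigma"].to_numpy()
    good = np.isfinite(sig) & (sig > 0)
    n_dropped = int((~good).sum())
    refl = refl[good]

    lat = _read_tsv(lattices_path, ["lattice_id", "cc"], ["n_obs"])
    lat["cc"] = lat["cc"].astype(float)
    return UnmergedReflectionTable(refl, lat), n_dropped


def write_unmerged_table(
    table: UnmergedReflectionTable, reflections_path, lattices_path
) -> None:
    """Write the native TSV pair, byte-deterministically.

    Floats are serialized with 17 significant digits so that
    read -> write -> read is the identity.
    """
    refl = table.reflections
    float_cols = ["intensity", "sigma"] + (
        ["d_spacing"] if "d_spacing" in refl.columns else []
    )
    cols = REFLECTION_COLUMNS + (
        ["d_spacing"] if "d_spacing" in refl.columns else []
    )
    with open(reflections_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in refl.itertuples(index=False):
            rec = dict(zip(refl.columns, row))
            out = [str(rec["h"]), str(rec["k"]), str(rec["l"]), rec["lattice_id"]]
            out += [_float17(rec[c]) for c in float_cols]
            fh.write("\t".join(out) + "\n")
    with open(lattices_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LATTICE_COLUMNS) + "\n")
        for row in table.lattices.itertuples(index=False):
            fh.write(f"{row.lattice_id}\t{_float17(row.cc)}\t{row.n_obs}\n")


def read_mtz_unmerged(path, lattice_column: str | None = None):
    """Optional adapter: read an unmerged MTZ file via :mod:`gemmi`.

    Uses the first columns of type J/Q as intensity/sigma and ``BATCH``
    (or ``lattice_column``) as the lattice identifier.  Lattice cc values
    are initialized to 0 and should be supplied afterwards, e.g. with
    :func:`sxcalib.merging.lattice_correlations`.
    Returns ``(table, n_dropped)``.
    """
    import gemmi  # deferred: optional dependency

    mtz = gemmi.read_mtz_file(str(path))
    df = pd.DataFrame(
        np.asarray(mtz, dtype=float), columns=[c.label for c in mtz.columns]
    )
    types = {c.label: c.type for c in mtz.columns}
    i_col = next((lbl for lbl, t in types.items() if t == "J"), None)
    s_col = next((lbl for lbl, t in types.items() if t == "Q"), None)
    if i_col is None or s_col is None:
        raise ReflectionFormatError(
            f"{path}: no intensity (J) / sigma (Q) column pair found"
        )
    batch = lattice_column or ("BATCH" if "BATCH" in df.columns else None)
    refl = pd.DataFrame(
        {
            "h": df["H"].astype(np.int64),
            "k": df["K"].astype(np.int64),
            "l": df["L"].astype(np.int64),
            "lattice_id": (
                df[batch].astype(int).astype(str) if batch else "0"
            ),
            "intensity": df[i_col],
            "sigma": df[s_col],
        }
    )
    sig = refl["sigma"].to_numpy()
    good = np.isfinite(sig) & (sig > 0) & np.isfinite(refl["intensity"].to_numpy())
    n_dropped = int((~good).sum())
    refl = refl[good]
    lat = pd.DataFrame(
        {"lattice_id": sorted(refl["lattice_id"].unique()), "cc": 0.0}
    )
    return UnmergedReflectionTable(refl, lat), n_dropped
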