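"""Core crystallographic types and transforms.

Everything downstream (difference maps, extrapolation, density integrals)
is built on four objects: a triclinic :class:`UnitCell`, an
:class:`AtomicModel` holding fractional scattering positions, a
:class:`ReflectionSet` of indexed amplitudes (optionally with phases and
uncertainties), and a periodic real-space :class:`DensityMap`.

The scattering model is deliberately simple: each element contributes its
full electron count Z, damped by an isotropic Debye-Waller factor
exp(-B s^2 / 4) with s = 1/d.  This is a flat (point-atom) form factor,
not the 4/5-Gaussian parameterisations used in production refinement; it
keeps structure factors exactly invertible for verification while
preserving every property the difference-map arithmetic relies on.
All computation is in P1; merged amplitudes from higher-symmetry space
groups are treated as an expanded P1 set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "Atom",
    "AtomicModel",
    "ReflectionSet",
    "DensityMap",
    "AtomSelection",
    "ConstantMapError",
    "compute_structure_factors",
    "synthesize_map",
    "sigma_scale",
    "default_grid",
]


class ConstantMapError(ValueError):
    """Raised when a map with zero variance is sigma-scaled."""


# --------------------------------------------------------------------------
# Unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell, lengths in Angstrom, angles in degrees."""

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
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix M with cartesian = M @ fractional (a along x)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (self.a * self.b * sg)],
            ]
        )

    @property
    def recip_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G*; 1/d^2 = h . G* . h."""
        m = self.orthogonalization
        return np.linalg.inv(m.T @ m)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """d (A) for an (n,3) integer index array."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, self.recip_metric, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


# --------------------------------------------------------------------------
# Atomic model


def electron_count(element: str) -> int:
    el = gemmi.Element(element.strip().capitalize())
    z = el.atomic_number
    if z == 0:
        raise ValueError(f"unknown element {element!r}")
    return z


@dataclass
class Atom:
    serial: int
    chain: str
    resid: int
    resname: str
    name: str
    element: str
    frac: np.ndarray  # fractional, wrapped to [0, 1)
    occ: float = 1.0
    b: float = 10.0

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float) % 1.0
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b < 0:
            raise ValueError("B factor must be non-negative")
        electron_count(self.element)  # raises on unknown element


@dataclass
class AtomicModel:
    """A set of scattering atoms on a unit cell (P1)."""

    cell: UnitCell
    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def frac(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms]).reshape(-1, 3)

    @property
    def cart(self) -> np.ndarray:
        return self.cell.orthogonalize(self.frac)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.cell, [replace(a, frac=a.frac.copy()) for a in self.atoms])

    def select(self, pred, tag: str = "") -> "AtomSelection":
        idx = [i for i, a in enumerate(self.atoms) if pred(a)]
        ids = [self.atoms[i].serial for i in idx]
        cart = self.cart[idx] if idx else np.empty((0, 3))
        frac = self.frac[idx] if idx else np.empty((0, 3))
        return AtomSelection(ids=ids, cart=cart, frac=frac, cell=self.cell, tag=tag)


@dataclass
class AtomSelection:
    """Atoms (by id + position) used as integration / correlation probes."""

    ids: list[int]
    cart: np.ndarray  # (n, 3) Angstrom
    frac: np.ndarray  # (n, 3) fractional
    cell: UnitCell
    tag: str = ""

    def __len__(self) -> int:
        return len(self.ids)

    def require_nonempty(self) -> None:
        if len(self.ids) == 0:
            raise ValueError(f"empty atom selection (tag={self.tag!r})")


# --------------------------------------------------------------------------
# Reflections


@dataclass
class ReflectionSet:
    """Indexed structure-factor amplitudes on a cell.

    ``phase`` is in degrees when present.  ``label`` records the dataset
    role (light / dark / calc / extrapolated / apo).
    """

    cell: UnitCell
    hkl: np.ndarray  # (n, 3) int
    f: np.ndarray  # (n,) amplitudes, >= 0 for observed sets
    sigf: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float).reshape(-1)
        if self.sigf is not None:
            self.sigf = np.asarray(self.sigf, dtype=float).reshape(-1)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float).reshape(-1)
        n = len(self.f)
        if self.hkl.shape[0] != n:
            raise ValueError("hkl/f length mismatch")
        if self.sigf is not None and len(self.sigf) != n:
            raise ValueError("sigf length mismatch")
        if self.phase is not None and len(self.phase) != n:
            raise ValueError("phase length mismatch")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("non-finite amplitudes")
        keys = {tuple(h) for h in self.hkl}
        if len(keys) != n:
            raise ValueError("duplicate Miller indices")

    def __len__(self) -> int:
        return len(self.f)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def complex_f(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("reflection set has no phases")
        return self.f * np.exp(1j * np.radians(self.phase))

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(map(tuple, self.hkl))}

    @staticmethod
    def _hkl_keys(hkl: np.ndarray) -> np.ndarray:
        # pack (h,k,l) into one int64 key for fast joins
        h = hkl.astype(np.int64)
        return (h[:, 0] + 512) * 1048576 + (h[:, 1] + 512) * 1024 + (h[:, 2] + 512)

    def common(self, *others: "ReflectionSet") -> list[np.ndarray]:
        """Row indices aligning this set with each other set on shared hkl."""
        keys = [self._hkl_keys(self.hkl)] + [self._hkl_keys(o.hkl) for o in others]
        shared = keys[0]
        for k in keys[1:]:
            shared = shared[np.isin(shared, k, assume_unique=True)]
        rows = []
        for k in keys:
            order = np.argsort(k)
            rows.append(order[np.searchsorted(k, shared, sorter=order)])
        return rows

    def subset(self, idx: np.ndarray, label: Optional[str] = None) -> "ReflectionSet":
        return ReflectionSet(
            cell=self.cell,
            hkl=self.hkl[idx],
            f=self.f[idx],
            sigf=None if self.sigf is None else self.sigf[idx],
            phase=None if self.phase is None else self.phase[idx],
            label=self.label if label is None else label,
        )


# --------------------------------------------------------------------------
# Density map


@dataclass
class DensityMap:
    """Real scalar field on a periodic grid over the unit cell."""

    cell: UnitCell
    values: np.ndarray  # (nx, ny, nz) float
    sigma_scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with >= 2 points per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean((self.values - self.values.mean()) ** 2)))

    def grid_frac(self) -> np.ndarray:
        """Fractional coordinates of all grid points, shape (N, 3)."""
        nx, ny, nz = self.shape
        fx = np.arange(nx) / nx
        fy = np.arange(ny) / ny
        fz = np.arange(nz) / nz
        gx, gy, gz = np.meshgrid(fx, fy, fz, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def sigma_scale(dmap: DensityMap) -> DensityMap:
    """Return the map in sigma units: mean 0, rms 1.  Idempotent."""
    rms = dmap.rms
    if rms == 0:
        raise ConstantMapError("cannot sigma-scale a constant map")
    vals = (dmap.values - dmap.values.mean()) / rms
    return DensityMap(dmap.cell, vals, sigma_scaled=True)


# --------------------------------------------------------------------------
# Structure factors and Fourier synthesis


def hemisphere_indices(cell: UnitCell, dmin: float) -> np.ndarray:
    """Unique-half Miller indices with d >= dmin, excluding F(000).

    The retained half satisfies h > 0, or h = 0 and k > 0, or
    h = k = 0 and l > 0; the mate of every index is its Friedel conjugate.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    # conservative per-axis bounds from the reciprocal metric diagonal
    g = cell.recip_metric
    hmax = [int(math.floor(1.0 / (dmin * math.sqrt(g[i, i])))) for i in range(3)]
    h = np.arange(-hmax[0], hmax[0] + 1)
    k = np.arange(-hmax[1], hmax[1] + 1)
    l = np.arange(-hmax[2], hmax[2] + 1)
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    half = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[half]
    d = cell.d_spacing(hkl)
    return hkl[d >= dmin]


def structure_factors_at(model: AtomicModel, hkl: np.ndarray) -> np.ndarray:
    """Complex F(h) = sum_j occ_j Z_j exp(-B_j s^2/4) exp(2 pi i h.x_j)."""
    if len(model) == 0:
        raise ValueError("empty atomic model")
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    z = np.array([electron_count(a.element) for a in model.atoms], dtype=float)
    occ = np.array([a.occ for a in model.atoms])
    b = np.array([a.b for a in model.atoms])
    frac = model.frac
    inv_d2 = np.einsum("ni,ij,nj->n", hkl.astype(float), model.cell.recip_metric, hkl.astype(float))
    damp = np.exp(-np.outer(inv_d2, b) / 4.0)  # (n_hkl, n_atoms)
    phase = np.exp(2j * np.pi * (hkl @ frac.T))
    return (phase * damp * (occ * z)) @ np.ones(len(model))


def compute_structure_factors(model: AtomicModel, dmin: float, label: str = "calc") -> ReflectionSet:
    """Amplitudes and phases of the model to resolution dmin (F(000) excluded)."""
    hkl = hemisphere_indices(model.cell, dmin)
    fc = structure_factors_at(model, hkl)
    return ReflectionSet(
        cell=model.cell,
        hkl=hkl,
        f=np.abs(fc),
        phase=np.degrees(np.angle(fc)),
        label=label,
    )


def default_grid(cell: UnitCell, dmin: float) -> tuple[int, int, int]:
    """Smallest even grid dims giving spacing <= dmin/3 on each axis."""
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = int(math.ceil(3.0 * length / dmin))
        dims.append(n + (n % 2))
    return tuple(dims)  # type: ignore[return-value]


def synthesize_map(
    reflections: ReflectionSet,
    grid: tuple[int, int, int],
    check_sampling: bool = True,
) -> DensityMap:
    """Fourier synthesis rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    The input holds one reflection per Friedel pair; the conjugate mate
    F(-h) = F*(h) is supplied automatically, so the map is real.  F(000)
    is never included and the map mean is exactly zero.
    """
    nx, ny, nz = grid
    cell = reflections.cell
    if len(reflections) == 0:
        return DensityMap(cell, np.zeros(grid))
    if reflections.phase is None:
        raise ValueError("map synthesis requires phases")
    hkl = reflections.hkl
    if np.any(np.all(hkl == 0, axis=1)):
        raise ValueError("F(000) must not be included in synthesis")
    maxh = np.max(np.abs(hkl), axis=0)
    if maxh[0] * 2 >= nx or maxh[1] * 2 >= ny or maxh[2] * 2 >= nz:
        raise ValueError(
            f"grid {grid} too coarse for reflections with |h| up to {tuple(maxh)}"
        )
    if check_sampling:
        dmin = float(np.min(reflections.d))
        spacing = (cell.a / nx, cell.b / ny, cell.c / nz)
        if max(spacing) > dmin / 3.0 + 1e-9:
            raise ValueError(
                f"grid spacing {spacing} exceeds dmin/3 = {dmin / 3.0:.3f} A; "
                "pass a finer grid or check_sampling=False"
            )
    fgrid = np.zeros(grid, dtype=complex)
    coeff = reflections.complex_f
    seen = set(map(tuple, hkl))
    ih = hkl % np.array(grid)
    np.add.at(fgrid, (ih[:, 0], ih[:, 1], ih[:, 2]), coeff)
    # Friedel completion for indices whose mate is not explicitly present
    mate_missing = np.array([tuple(-h) not in seen for h in hkl])
    imate = (-hkl[mate_missing]) % np.array(grid)
    np.add.at(fgrid, (imate[:, 0], imate[:, 1], imate[:, 2]), np.conj(coeff[mate_missing]))
    rho = np.fft.fftn(fgrid).real / cell.volume
    return DensityMap(cell, rho)
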