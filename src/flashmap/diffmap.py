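"""Isomorphous difference maps.

A light (pumped) amplitude set is first brought onto the scale of the
dark (reference) set with an isotropic k/B model fitted by least squares
on log-ratios, after discarding weak amplitudes (F < n_sigma * sigmaF)
and restricting to a resolution window; difference-map coefficients
(F_light - F_dark) exp(i phi_dark) are then Fourier-synthesized with
phases from the refined dark model and reported on the sigma scale.

The scale model is F_dark ~ k * exp(-B s^2 / 4) * F_light, i.e. a
relative temperature factor B (A^2) on top of an overall scale k.  An
optional per-resolution-shell residual scale can be applied on top for
real data with non-isotropic systematics; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .core import (
    AtomicModel,
    ConstantMapError,
    DensityMap,
    ReflectionSet,
    compute_structure_factors,
    sigma_scale,
    synthesize_map,
)

__all__ = [
    "ScalingResult",
    "NullDifferenceError",
    "scale_amplitudes",
    "isomorphous_difference_map",
    "fcalc_difference_map",
]


class NullDifferenceError(ConstantMapError):
    """The difference map is identically constant (null difference)."""


@dataclass
class ScalingResult:
    k: float  # overall scale (unitless), > 0
    b: float  # relative temperature factor (A^2)
    n_used: int
    n_excluded: int
    res_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scale k must be positive")
        if self.n_used < 2:
            raise ValueError("scaling needs >= 2 reflections")


def scale_amplitudes(
    light: ReflectionSet,
    dark: ReflectionSet,
    res_window: tuple[float, float] = (6.0, 1.7),
    sigma_cutoff: float = 2.0,
    n_shells: int = 0,
) -> tuple[ReflectionSet, ScalingResult]:
    """Scale light amplitudes onto the dark set.

    Reflections used for the fit must be common to both sets, satisfy
    F >= sigma_cutoff * sigmaF in both (when sigmas are present), and lie
    inside ``res_window`` = (low, high) in Angstrom.  The returned set is
    the full light set with F and sigmaF multiplied by
    k * exp(-B s^2 / 4).  With ``n_shells`` > 0 an additional flat scale
    per resolution shell (fitted on the same reflections) is applied.
    """
    il, id_ = light.common(dark)
    if len(il) == 0:
        raise ValueError("light and dark share no Miller indices")
    fl, fd = light.f[il], dark.f[id_]
    d = light.cell.d_spacing(light.hkl[il])
    lo, hi = max(res_window), min(res_window)
    ok = (d <= lo) & (d >= hi) & (fl > 0) & (fd > 0)
    if light.sigf is not None:
        ok &= fl >= sigma_cutoff * light.sigf[il]
    if dark.sigf is not None:
        ok &= fd >= sigma_cutoff * dark.sigf[id_]
    n_used = int(ok.sum())
    if n_used < 2:
        raise ValueError(f"only {n_used} reflections survive the scaling filters")
    s2 = 1.0 / d[ok] ** 2
    # log(F_dark / F_light) = log k - B s^2 / 4
    y = np.log(fd[ok] / fl[ok])
    a = np.stack([np.ones_like(s2), -s2 / 4.0], axis=1)
    (logk, b), *_ = np.linalg.lstsq(a, y, rcond=None)
    k = float(np.exp(logk))

    s2_all = 1.0 / light.d**2
    fac = k * np.exp(-float(b) * s2_all / 4.0)
    if n_shells > 0:
        edges = np.quantile(s2[np.argsort(s2)], np.linspace(0, 1, n_shells + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        resid = fd[ok] / (fl[ok] * k * np.exp(-float(b) * s2 / 4.0))
        shell_of = np.clip(np.searchsorted(edges, s2, side="right") - 1, 0, n_shells - 1)
        shell_scale = np.array(
            [resid[shell_of == i].mean() if np.any(shell_of == i) else 1.0 for i in range(n_shells)]
        )
        shell_all = np.clip(np.searchsorted(edges, s2_all, side="right") - 1, 0, n_shells - 1)
        fac = fac * shell_scale[shell_all]
    scaled = ReflectionSet(
        cell=light.cell,
        hkl=light.hkl.copy(),
        f=light.f * fac,
        sigf=None if light.sigf is None else light.sigf * fac,
        phase=None if light.phase is None else light.phase.copy(),
        label=light.label or "light",
    )
    result = ScalingResult(
        k=k, b=float(b), n_used=n_used, n_excluded=int(len(il) - n_used),
        res_window=(lo, hi),
    )
    return scaled, result


def _difference_synthesis(
    delta_f: np.ndarray,
    hkl: np.ndarray,
    phases_deg: np.ndarray,
    cell,
    grid: tuple[int, int, int],
    weight: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    raw: bool = False,
) -> DensityMap:
    if weight is not None:
        delta_f = delta_f * weight(delta_f)
    coeffs = ReflectionSet(cell=cell, hkl=hkl, f=np.abs(delta_f), phase=phases_deg + 180.0 * (delta_f < 0), label="diff")
    out = synthesize_map(coeffs, grid, check_sampling=False)
    if raw:
        return out
    try:
        return sigma_scale(out)
    except ConstantMapError as exc:
        raise NullDifferenceError("null difference: identical amplitude sets") from exc


def isomorphous_difference_map(
    scaled_light: ReflectionSet,
    dark_obs: ReflectionSet,
    dark_phases: ReflectionSet,
    grid: tuple[int, int, int],
    weight: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    raw: bool = False,
) -> DensityMap:
    """Sigma-scaled (F_obs^light - F_obs^dark) exp(i phi_dark) map.

    ``dark_phases`` is typically the calculated set of the refined dark
    model.  Reflections missing from any of the three sets are omitted;
    no imputation is performed.  ``weight`` is an optional hook mapping
    the difference amplitudes to per-reflection weights (off by default).
    ``raw`` skips the sigma scaling (used when a series of maps is put
    on one common scale).
    """
    if dark_phases.phase is None:
        raise ValueError("dark phase set has no phases")
    il, id_, ip = scaled_light.common(dark_obs, dark_phases)
    if len(il) == 0:
        raise ValueError("no common Miller indices for the difference map")
    delta = scaled_light.f[il] - dark_obs.f[id_]
    return _difference_synthesis(
        delta, scaled_light.hkl[il], dark_phases.phase[ip], scaled_light.cell, grid, weight, raw
    )


def fcalc_difference_map(
    model_a: AtomicModel,
    model_b: AtomicModel,
    dmin: float,
    grid: tuple[int, int, int],
) -> DensityMap:
    """Sigma-scaled (F_calc^a - F_calc^b) map with phases of model_b (dark)."""
    fa = compute_structure_factors(model_a, dmin)
    fb = compute_structure_factors(model_b, dmin)
    ia, ib = fa.common(fb)
    delta = fa.f[ia] - fb.f[ib]
    return _difference_synthesis(delta, fa.hkl[ia], fb.phase[ib], fa.cell, grid)
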