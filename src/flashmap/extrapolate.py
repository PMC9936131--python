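"""Extrapolated structure factors and activation-level estimation.

With only a fraction A (percent) of molecules photoactivated, the
observed light amplitudes are a population average.  The linear
amplitude approximation estimates the fully activated state as

    F_extra = (100 / A) * (F_obs^light - F_obs^dark) + F_calc

where F_calc are the calculated amplitudes of the refined dark model.
Entries whose extrapolated amplitude is not positive are removed.
Maps use 2 F_extra - F_calc coefficients with dark-model phases: with
model phases a difference feature appears at roughly half height, and
the doubled difference restores it, so at the correct A the map shows
the activated state and the departed-ligand atoms carry no residual
density.

The activation level itself is estimated by scanning A downward:
negative density around reporter atoms (ligand nitrogens, which leave
their dark position) stays near zero while too little dark state is
subtracted (A above truth) and grows once the dark state is
over-subtracted (A below truth).  The elbow is located by an exhaustive
two-segment least-squares fit; A* is the abscissa where the two fitted
lines intersect.  A control estimator looks instead for the
re-appearance of dark-only features as positive density at A above
truth; both should agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import AtomSelection, DensityMap, ReflectionSet, sigma_scale, synthesize_map
from .density import integrate_density

__all__ = [
    "ActivationCurve",
    "BreakpointFit",
    "extrapolate_structure_factors",
    "extrapolated_map",
    "activation_scan",
    "activation_scan_multi",
    "estimate_activation",
    "dark_reappearance_estimate",
    "fit_breakpoint",
]


class FlatCurveError(ValueError):
    """No breakpoint: the scanned curve has no two-slope structure."""


@dataclass
class BreakpointFit:
    a_star: float  # abscissa of the two fitted lines' intersection
    left: tuple[float, float]  # slope, intercept for the low-A segment
    right: tuple[float, float]  # slope, intercept for the high-A segment
    split_a: float  # scanned abscissa at the chosen breakpoint
    sse: float
    at_boundary: bool = False


@dataclass
class ActivationCurve:
    a_values: np.ndarray  # percent, descending scan order
    density: np.ndarray  # integrated magnitude per A
    sign: str = "negative"
    fit: Optional[BreakpointFit] = None

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.a_values <= 0) or np.any(self.a_values > 100):
            raise ValueError("activation levels must lie in (0, 100]")
        if len(self.a_values) != len(self.density):
            raise ValueError("a/density length mismatch")


def extrapolate_structure_factors(
    light_scaled: ReflectionSet,
    dark_obs: ReflectionSet,
    fcalc_dark: ReflectionSet,
    a_percent: float,
) -> ReflectionSet:
    """Linear-approximation extrapolated amplitudes at activation level A.

    Works on the Miller indices common to all three sets; entries with
    F_extra <= 0 are removed.  sigma_extra = (100/A) sqrt(sl^2 + sd^2)
    treats F_calc as noiseless.
    """
    if not 0 < a_percent <= 100:
        raise ValueError("activation level A must lie in (0, 100]")
    il, id_, ic = light_scaled.common(dark_obs, fcalc_dark)
    if len(il) == 0:
        raise ValueError("no Miller indices common to light, dark and calc sets")
    mult = 100.0 / a_percent
    f_extra = mult * (light_scaled.f[il] - dark_obs.f[id_]) + fcalc_dark.f[ic]
    sig = None
    if light_scaled.sigf is not None and dark_obs.sigf is not None:
        sig = mult * np.sqrt(light_scaled.sigf[il] ** 2 + dark_obs.sigf[id_] ** 2)
    keep = f_extra > 0
    return ReflectionSet(
        cell=light_scaled.cell,
        hkl=light_scaled.hkl[il][keep],
        f=f_extra[keep],
        sigf=None if sig is None else sig[keep],
        phase=None if fcalc_dark.phase is None else fcalc_dark.phase[ic][keep],
        label="extrapolated",
    )


def extrapolated_map(
    extrapolated: ReflectionSet,
    fcalc_dark: ReflectionSet,
    grid: tuple[int, int, int],
    raw: bool = False,
) -> DensityMap:
    """Sigma-scaled 2 F_extra - F_calc map with dark-model phases.

    With ``raw`` the unscaled synthesis is returned; the activation scan
    uses this to keep every map of a scan on one common density scale
    (the sigma unit of the scan's reference map) so that
    over-subtracted density keeps growing linearly with the multiplier
    instead of being renormalized away map by map.
    """
    if fcalc_dark.phase is None:
        raise ValueError("dark calculated set has no phases")
    ie, ic = extrapolated.common(fcalc_dark)
    if len(ie) == 0:
        raise ValueError("extrapolated and calc sets share no indices")
    amp = 2.0 * extrapolated.f[ie] - fcalc_dark.f[ic]
    coeffs = ReflectionSet(
        cell=extrapolated.cell,
        hkl=extrapolated.hkl[ie],
        f=np.abs(amp),
        phase=fcalc_dark.phase[ic] + 180.0 * (amp < 0),
        label="2fextra-fcalc",
    )
    out = synthesize_map(coeffs, grid, check_sampling=False)
    return out if raw else sigma_scale(out)


def activation_scan(
    light_scaled: ReflectionSet,
    dark_obs: ReflectionSet,
    fcalc_dark: ReflectionSet,
    reporter_sel: AtomSelection,
    grid: tuple[int, int, int],
    a_grid: Optional[np.ndarray] = None,
    radius: float = 1.5,
    sigma_threshold: float = 3.0,
    sign: str = "negative",
) -> ActivationCurve:
    """Integrated reporter density on 2F_extra - F_calc maps vs A.

    ``sign='negative'`` probes over-subtraction at departed-ligand
    reporters; ``sign='positive'`` probes dark-feature re-appearance.
    """
    curves = activation_scan_multi(
        light_scaled, dark_obs, fcalc_dark, [(reporter_sel, sign)], grid,
        a_grid=a_grid, radius=radius, sigma_threshold=sigma_threshold,
    )
    return curves[0]


def activation_scan_multi(
    light_scaled: ReflectionSet,
    dark_obs: ReflectionSet,
    fcalc_dark: ReflectionSet,
    probes: list[tuple[AtomSelection, str]],
    grid: tuple[int, int, int],
    a_grid: Optional[np.ndarray] = None,
    radius: float = 1.5,
    sigma_threshold: float = 3.0,
) -> list[ActivationCurve]:
    """Scan once, integrate several (selection, sign) probes per map.

    All maps of the scan share one density scale: the sigma unit of the
    reference map at the largest scanned A.  Rescaling each map to its
    own sigma would cancel the multiplier-proportional growth of the
    over-subtracted density that the breakpoint estimate relies on.
    """
    for sel, _ in probes:
        sel.require_nonempty()
    if a_grid is None:
        a_grid = np.arange(100.0, 4.0, -1.0)
    a_grid = np.asarray(a_grid, dtype=float)
    if len(a_grid) < 2:
        raise ValueError("activation scan needs at least two A values")
    order = np.argsort(a_grid)[::-1]  # reference map first
    dens = np.empty((len(probes), len(a_grid)))
    sigma_ref: Optional[float] = None
    for i in order:
        extra = extrapolate_structure_factors(light_scaled, dark_obs, fcalc_dark, a_grid[i])
        emap = extrapolated_map(extra, fcalc_dark, grid, raw=True)
        if sigma_ref is None:
            if emap.rms == 0:
                raise ValueError("reference map is constant")
            sigma_ref = emap.rms
        scaled = DensityMap(emap.cell, (emap.values - emap.mean) / sigma_ref, sigma_scaled=True)
        for j, (sel, sign) in enumerate(probes):
            dens[j, i] = integrate_density(scaled, sel, radius, sigma_threshold, sign)
    return [
        ActivationCurve(a_values=a_grid.copy(), density=dens[j], sign=sign)
        for j, (_, sign) in enumerate(probes)
    ]


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept, SSE."""
    a = np.stack([x, np.ones_like(x)], axis=1)
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_breakpoint(x: np.ndarray, y: np.ndarray, min_seg: int = 2) -> BreakpointFit:
    """Broken-stick least squares: two lines meeting at a free knot.

    The model is continuous segmented regression,
    y = c + s_l (x - k) for x <= k and y = c + s_r (x - k) above, i.e.
    two linear parts whose intersection is the knot k.  For every
    candidate knot (each scanned abscissa and midpoint, with at least
    ``min_seg`` points per side) the conditionally linear parameters
    (c, s_l, s_r) are solved in closed form; the knot minimizing SSE
    wins, ties going to the smallest knot.  Raises
    :class:`FlatCurveError` when the two slopes are indistinguishable
    (no two-regime structure).
    """
    order = np.argsort(x)
    xs, ys = np.asarray(x, float)[order], np.asarray(y, float)[order]
    n = len(xs)
    if n < 2 * min_seg:
        raise ValueError(f"need >= {2 * min_seg} points spanning both regimes")
    lo, hi = xs[min_seg - 1], xs[n - min_seg]
    cand = np.unique(np.concatenate([xs, (xs[:-1] + xs[1:]) / 2.0]))
    cand = cand[(cand >= lo) & (cand <= hi)]
    best = None
    for k in cand:
        a = np.stack([np.ones(n), np.minimum(xs - k, 0.0), np.maximum(xs - k, 0.0)], axis=1)
        coef, *_ = np.linalg.lstsq(a, ys, rcond=None)
        resid = ys - a @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(k), coef)
    sse, knot, (c, sl, sr) = best  # type: ignore[misc]
    if abs(sl - sr) <= 1e-12 + 1e-6 * max(abs(sl), abs(sr)):
        raise FlatCurveError("no breakpoint: fitted segments are parallel")
    # refit each side as a free line and intersect them: the knot is a
    # robust locator of the regime change, the reported abscissa is the
    # analytic intersection of the two linear parts
    left_mask = xs <= knot
    if left_mask.sum() < 2 or (~left_mask).sum() < 2:
        left_mask = xs < knot if left_mask.sum() >= n - 1 else xs <= xs[min_seg - 1]
    sl2, il2, sse_l = _line_fit(xs[left_mask], ys[left_mask])
    sr2, ir2, sse_r = _line_fit(xs[~left_mask], ys[~left_mask])
    if abs(sl2 - sr2) > 1e-12 + 1e-6 * max(abs(sl2), abs(sr2)):
        x_star = (ir2 - il2) / (sl2 - sr2)
        left, right = (sl2, il2), (sr2, ir2)
    else:
        x_star = knot
        left = (float(sl), float(c - sl * knot))
        right = (float(sr), float(c - sr * knot))
    clamped = min(max(x_star, float(xs[0])), float(xs[-1]))
    return BreakpointFit(
        a_star=float(clamped),
        left=left,
        right=right,
        split_a=float(knot),
        sse=float(sse),
        at_boundary=bool(clamped != x_star or knot in (lo, hi)),
    )


def estimate_activation(curve: ActivationCurve) -> BreakpointFit:
    """Activation level from the intersection of the two linear regimes.

    The fit is performed against the extrapolation multiplier m = 100/A
    rather than A itself: the over-subtracted (or residual) occupancy is
    m * a_true - 1 (resp. 1 - m * a_true), so both regimes of the
    integrated density are linear in m and hyperbolic in A.  The
    intersection abscissa m* converts back to A* = 100/m*.  For the
    negative-density scan the small-m side is flat near zero and the
    density rises once dark is over-subtracted; the fit is sign-agnostic
    and works unchanged for the positive (re-appearance) control curve.
    """
    if np.ptp(curve.density) == 0:
        raise FlatCurveError("no breakpoint: curve is constant")
    m = 100.0 / curve.a_values
    fit = fit_breakpoint(m, curve.density)
    m_star = min(max(fit.a_star, float(m.min())), float(m.max()))
    fit.a_star = 100.0 / m_star
    fit.split_a = 100.0 / fit.split_a
    curve.fit = fit
    return fit


def dark_reappearance_estimate(
    light_scaled: ReflectionSet,
    dark_obs: ReflectionSet,
    fcalc_dark: ReflectionSet,
    dark_only_sel: AtomSelection,
    grid: tuple[int, int, int],
    a_grid: Optional[np.ndarray] = None,
    radius: float = 1.5,
    sigma_threshold: float = 3.0,
) -> tuple[ActivationCurve, BreakpointFit]:
    """Control estimate: A where dark-only features re-appear as positive.

    ``dark_only_sel`` are atoms occupied only in the dark state.  Their
    positive integral is ~0 for A at or below truth and grows above it.
    A constant curve (full conversion, nothing re-appears in the scanned
    range) yields a boundary fit at the largest scanned A.
    """
    curve = activation_scan(
        light_scaled, dark_obs, fcalc_dark, dark_only_sel, grid,
        a_grid=a_grid, radius=radius, sigma_threshold=sigma_threshold, sign="positive",
    )
    try:
        if np.ptp(curve.density) > 0 and curve.density.min() > 0.5 * curve.density.max():
            # positive density never vanishes anywhere in the scanned
            # range: the selection is occupied in both states and carries
            # no re-appearance signal
            raise FlatCurveError("uninformative dark-only selection")
        fit = estimate_activation(curve)
    except FlatCurveError:
        hi = float(curve.a_values.max())
        fit = BreakpointFit(
            a_star=hi, left=(0.0, 0.0), right=(0.0, 0.0),
            split_a=hi, sse=0.0, at_boundary=True,
        )
        curve.fit = fit
    return curve, fit
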