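"""Difference-density bookkeeping over a time series.

Three derived quantities drive the timeline analysis:

* signed density integrated in a sphere around selected atoms, with a
  sigma threshold (weak density ignored);
* the Pearson correlation matrix between per-atom integral vectors of
  all time-delay pairs, normalized to its largest entry — blocks of
  elevated correlation mark delays sharing one structural intermediate;
* the ligand-release curve: negative density around the ligand per
  delay, normalized so the (occupancy-rescaled) apo value is 1 and the
  smallest time-delay value is 0.

Distances are periodic (minimum image over the unit cell); each voxel is
counted once, assigned to its nearest selected atom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import AtomSelection, DensityMap

__all__ = [
    "DifferenceSeries",
    "CorrelationMatrix",
    "ReleaseCurve",
    "integrate_density",
    "per_atom_density_vector",
    "correlation_matrix",
    "equalize_multiplicity",
    "release_curve",
    "occupancy_snr_scale",
    "greedy_block_segmentation",
]


@dataclass
class DifferenceSeries:
    """Ordered per-delay sigma-scaled difference maps."""

    labels: list[str]
    times: np.ndarray  # seconds, strictly increasing
    maps: list[DensityMap]
    pattern_counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time delays must be strictly increasing")
        if not (len(self.labels) == len(self.times) == len(self.maps)):
            raise ValueError("labels/times/maps length mismatch")
        shapes = {m.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError("all maps in a series must share one grid")

    def __len__(self) -> int:
        return len(self.maps)


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: np.ndarray  # raw Pearson, n x n
    normalized: np.ndarray  # values / max
    display_mask: np.ndarray  # True where shown (normalized >= threshold)
    threshold: float
    selection_tag: str = ""


@dataclass
class ReleaseCurve:
    labels: list[str]
    times: np.ndarray
    raw: np.ndarray  # negative-density magnitudes, >= 0
    normalized: np.ndarray
    apo_raw: float
    apo_scale: float
    apo_normalized: float
    degenerate: bool = False


_D2_CACHE: dict[tuple, np.ndarray] = {}


def _voxel_distance_sq(dmap: DensityMap, sel: AtomSelection) -> np.ndarray:
    """Squared periodic distance (A^2) from each voxel to each atom, (N, n).

    Results are memoized on (grid shape, cell, atom positions): the same
    selection is probed against hundreds of maps during activation scans.
    """
    key = (
        dmap.shape,
        (dmap.cell.a, dmap.cell.b, dmap.cell.c, dmap.cell.alpha, dmap.cell.beta, dmap.cell.gamma),
        sel.frac.tobytes(),
    )
    hit = _D2_CACHE.get(key)
    if hit is not None:
        return hit
    gf = dmap.grid_frac()  # (N, 3)
    delta = gf[:, None, :] - sel.frac[None, :, :]
    delta -= np.round(delta)  # minimum image in fractional space
    m = dmap.cell.orthogonalization
    cart = np.einsum("ij,nkj->nki", m, delta)
    d2 = np.einsum("nki,nki->nk", cart, cart)
    if len(_D2_CACHE) > 32:
        _D2_CACHE.clear()
    _D2_CACHE[key] = d2
    return d2


def _thresholded(dmap: DensityMap, sigma_threshold: float, sign: str) -> np.ndarray:
    v = dmap.values.ravel()
    keep = np.abs(v) >= sigma_threshold
    if sign == "negative":
        keep &= v < 0
    elif sign == "positive":
        keep &= v > 0
    elif sign != "both":
        raise ValueError(f"sign must be negative/positive/both, got {sign!r}")
    return keep


def integrate_density(
    dmap: DensityMap,
    sel: AtomSelection,
    radius: float,
    sigma_threshold: float,
    sign: str = "both",
) -> float:
    """Sum |v| over voxels within ``radius`` of any selected atom.

    Only voxels with |v| >= sigma_threshold and the requested sign
    contribute; every voxel is counted once.  Returns a non-negative
    magnitude in sigma * voxel units.
    """
    sel.require_nonempty()
    if not dmap.sigma_scaled:
        raise ValueError("integrate_density expects a sigma-scaled map")
    if radius <= 0:
        raise ValueError("radius must be positive")
    d2 = _voxel_distance_sq(dmap, sel)
    in_sphere = (d2 <= radius * radius).any(axis=1)
    keep = in_sphere & _thresholded(dmap, sigma_threshold, sign)
    return float(np.abs(dmap.values.ravel()[keep]).sum())


def per_atom_density_vector(
    dmap: DensityMap,
    sel: AtomSelection,
    radius: float = 2.0,
    sigma_threshold: float = 1.5,
) -> np.ndarray:
    """Signed integral per selected atom (voxels go to their nearest atom)."""
    sel.require_nonempty()
    if not dmap.sigma_scaled:
        raise ValueError("per_atom_density_vector expects a sigma-scaled map")
    d2 = _voxel_distance_sq(dmap, sel)
    nearest = np.argmin(d2, axis=1)
    in_sphere = d2[np.arange(len(nearest)), nearest] <= radius * radius
    keep = in_sphere & _thresholded(dmap, sigma_threshold, "both")
    v = dmap.values.ravel()
    out = np.zeros(len(sel))
    np.add.at(out, nearest[keep], v[keep])
    return out


def correlation_matrix(
    series: DifferenceSeries,
    sel: AtomSelection,
    radius: float = 2.0,
    sigma_threshold: float = 1.5,
    threshold: float = 0.3,
) -> CorrelationMatrix:
    """Pearson correlations between per-atom density vectors of all delays.

    The matrix is normalized to its largest entry; entries whose
    normalized value falls below ``threshold`` are flagged for omission
    from display (the underlying values are kept).  A zero-variance
    vector yields NaN rows/columns (correlation undefined).
    """
    if len(series) < 2:
        raise ValueError("need at least two delays")
    vecs = np.array(
        [per_atom_density_vector(m, sel, radius, sigma_threshold) for m in series.maps]
    )
    n = len(series)
    corr = np.full((n, n), np.nan)
    sd = vecs.std(axis=1)
    good = sd > 0
    if good.sum() >= 2:
        sub = np.corrcoef(vecs[good])
        ix = np.where(good)[0]
        corr[np.ix_(ix, ix)] = sub
    cmax = np.nanmax(corr)
    normalized = corr / cmax
    mask = np.where(np.isnan(normalized), False, normalized >= threshold)
    return CorrelationMatrix(
        labels=list(series.labels),
        values=corr,
        normalized=normalized,
        display_mask=mask,
        threshold=threshold,
        selection_tag=sel.tag,
    )


def greedy_block_segmentation(cm: CorrelationMatrix) -> list[list[int]]:
    """Segment delays into contiguous blocks from the display mask.

    A delay joins the current block while its normalized correlation with
    every member stays at or above the display threshold; otherwise a new
    block starts.  This is the thresholded block reading of the
    correlation figure, not a general clustering algorithm.
    """
    blocks: list[list[int]] = [[0]]
    for i in range(1, len(cm.labels)):
        if all(cm.display_mask[i, j] for j in blocks[-1]):
            blocks[-1].append(i)
        else:
            blocks.append([i])
    return blocks


def equalize_multiplicity(
    pattern_counts: Sequence[int], seed: int = 0
) -> tuple[int, np.ndarray]:
    """Target pattern count and per-delay noise rescale factors.

    Subsampling every delay to the count of the worst-sampled one
    (min of counts) inflates merged-amplitude noise by
    sqrt(count / target) under the sqrt(N) law; the factors returned are
    exactly that.  ``seed`` fixes any downstream subsampling and is part
    of the contract for determinism.
    """
    counts = np.asarray(pattern_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("pattern counts must be positive")
    target = int(counts.min())
    return target, np.sqrt(counts / target)


def occupancy_snr_scale(occupancy_ratio: float) -> float:
    """Downscale factor for a dataset with ``occupancy_ratio``-fold signal.

    Signal-to-noise improves by sqrt(2) per doubling of observations, so
    a fourfold occupancy (treated like a fourfold multiplicity) is
    compensated by 1/sqrt(4) = 0.5.
    """
    if occupancy_ratio <= 0:
        raise ValueError("occupancy ratio must be positive")
    return 1.0 / math.sqrt(occupancy_ratio)


def release_curve(
    series: DifferenceSeries,
    ligand_sel: AtomSelection,
    apo_map: DensityMap,
    occupancy_ratio: float = 4.0,
    radius: float = 1.5,
    sigma_threshold: float = 3.0,
) -> ReleaseCurve:
    """Normalized negative-density (ligand release) curve over the delays.

    Negative density is integrated around the ligand atoms per delay and
    for the apo difference map; the apo value is rescaled by
    :func:`occupancy_snr_scale` and set to 1, the smallest time-delay
    value to 0.  If the rescaled apo value does not exceed every delay
    value the normalization is degenerate; raw values are still returned
    with the curve flagged.
    """
    ligand_sel.require_nonempty()
    raw = np.array(
        [integrate_density(m, ligand_sel, radius, sigma_threshold, "negative") for m in series.maps]
    )
    apo_raw = integrate_density(apo_map, ligand_sel, radius, sigma_threshold, "negative")
    scale = occupancy_snr_scale(occupancy_ratio)
    apo_eff = apo_raw * scale
    lo = raw.min()
    degenerate = apo_eff <= raw.max()
    if degenerate:
        span = raw.max() - lo if raw.max() > lo else 1.0
    else:
        span = apo_eff - lo
    normalized = (raw - lo) / span
    return ReleaseCurve(
        labels=list(series.labels),
        times=series.times.copy(),
        raw=raw,
        normalized=normalized,
        apo_raw=apo_raw,
        apo_scale=scale,
        apo_normalized=(apo_eff - lo) / span,
        degenerate=bool(degenerate),
    )
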