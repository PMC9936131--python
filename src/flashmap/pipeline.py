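"""End-to-end timeline analysis.

Order of stages, mirroring how the time-resolved datasets are consumed:

1. equalize per-delay multiplicity (noise inflated to the worst delay);
2. scale each light set onto dark (k/B on log-ratios, 2 sigma cutoff,
   6-1.7 A window) and build sigma-scaled isomorphous difference maps
   with dark-model phases;
3. Pearson correlation matrix of per-atom difference integrals over the
   delays (protein-wide and pocket selections) and its thresholded
   block segmentation;
4. ligand-release curve against the occupancy-rescaled apo map;
5. per-delay activation-level estimates (negative-density breakpoint
   plus the dark-feature re-appearance control) and their mean;
6. backbone displacement fields between the end-state models.

`run_timeline` works on an in-memory :class:`~flashmap.synth.SimulatedDataset`;
`load_manifest` assembles the same inputs from files referenced by a
YAML series manifest, so every stage can be re-run from persisted
intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as fio
from .core import AtomicModel, AtomSelection, DensityMap, ReflectionSet, default_grid
from .density import (
    CorrelationMatrix,
    DifferenceSeries,
    ReleaseCurve,
    correlation_matrix,
    greedy_block_segmentation,
    release_curve,
)
from .diffmap import ScalingResult, isomorphous_difference_map, scale_amplitudes
from .extrapolate import (
    ActivationCurve,
    FlatCurveError,
    activation_scan_multi,
    estimate_activation,
)
from .synth import SimulatedDataset, SyntheticScenario, equalize_series, simulate_dataset
from .vectors import DisplacementField, displacement_field, write_vectors

logger = logging.getLogger("flashmap")

__all__ = ["TimelineParams", "TimelineReport", "run_timeline", "load_manifest"]


@dataclass
class TimelineParams:
    res_window: tuple[float, float] = (6.0, 1.7)
    sigma_cutoff: float = 2.0
    corr_radius: float = 2.0
    corr_sigma: float = 1.5
    corr_threshold: float = 0.3
    release_radius: float = 1.5
    release_sigma: float = 3.0
    occupancy_ratio: float = 4.0
    a_grid: tuple[float, float, float] = (100.0, 5.0, 1.0)  # high, low, step
    vector_cutoff: float = 0.5
    vector_stride: int = 2
    vector_amplify: float = 6.0

    def a_values(self) -> np.ndarray:
        hi, lo, step = self.a_grid
        return np.arange(hi, lo - 0.5 * step, -step)


@dataclass
class TimelineReport:
    scaling: list[ScalingResult]
    series: DifferenceSeries
    apo_map: DensityMap
    corr_protein: CorrelationMatrix
    corr_pocket: CorrelationMatrix
    blocks: list[list[int]]
    release: Optional[ReleaseCurve]
    activation_per_delay: list[Optional[float]]
    activation_mean: Optional[float]
    reappearance_per_delay: list[Optional[float]]
    reappearance_mean: Optional[float]
    activation_curves: list[ActivationCurve]
    fields: dict[str, DisplacementField]
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_delays": len(self.series),
            "scaling_k": [round(s.k, 6) for s in self.scaling],
            "scaling_b": [round(s.b, 6) for s in self.scaling],
            "blocks": self.blocks,
            "release_normalized": None if self.release is None else [round(v, 6) for v in self.release.normalized],
            "activation_per_delay": [None if a is None else round(a, 3) for a in self.activation_per_delay],
            "activation_mean": None if self.activation_mean is None else round(self.activation_mean, 3),
            "reappearance_per_delay": [None if a is None else round(a, 3) for a in self.reappearance_per_delay],
            "reappearance_mean": None if self.reappearance_mean is None else round(self.reappearance_mean, 3),
            "n_vectors_shown": {k: len(v.shown) for k, v in self.fields.items()},
            "warnings": self.warnings,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.summary(), indent=2) + "\n")
        labels = self.series.labels
        with open(outdir / "correlation_protein.tsv", "w") as fh:
            fh.write("\t" + "\t".join(labels) + "\n")
            for i, lab in enumerate(labels):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in self.corr_protein.normalized[i]) + "\n")
        if self.release is not None:
            with open(outdir / "release.tsv", "w") as fh:
                fh.write("label\ttime_s\traw\tnormalized\n")
                for lab, t, r, n in zip(self.release.labels, self.release.times, self.release.raw, self.release.normalized):
                    fh.write(f"{lab}\t{t:g}\t{r:.6f}\t{n:.6f}\n")
        with open(outdir / "activation.tsv", "w") as fh:
            fh.write("label\tactivation_pct\treappearance_pct\n")
            for lab, a, r in zip(labels, self.activation_per_delay, self.reappearance_per_delay):
                fh.write(f"{lab}\t{'' if a is None else f'{a:.3f}'}\t{'' if r is None else f'{r:.3f}'}\n")
        for name, fld in self.fields.items():
            write_vectors(fld, outdir / f"vectors_{name}.tsv")


@dataclass
class TimelineInputs:
    """Everything `run_timeline` needs, from simulation or from files."""

    dark_obs: ReflectionSet
    apo_obs: Optional[ReflectionSet]
    delays: list[ReflectionSet]
    labels: list[str]
    times: np.ndarray
    pattern_counts: Optional[np.ndarray]
    fcalc_dark: ReflectionSet
    dark_model: AtomicModel
    protein_sel: AtomSelection
    ligand_sel: AtomSelection
    reporter_sel: AtomSelection
    pocket_sel: AtomSelection
    state_models: dict[str, AtomicModel]
    dmin: float


def _inputs_from_simulation(data: SimulatedDataset, seed: Optional[int]) -> TimelineInputs:
    sys_ = data.system
    return TimelineInputs(
        dark_obs=data.dark_obs,
        apo_obs=data.apo_obs,
        delays=equalize_series(data, seed=seed),
        labels=list(data.scenario.labels),
        times=np.array(data.scenario.times),
        pattern_counts=np.array(data.scenario.pattern_counts, dtype=float),
        fcalc_dark=data.fcalc_dark,
        dark_model=sys_.dark,
        protein_sel=sys_.selection("protein"),
        ligand_sel=sys_.selection("ligand"),
        reporter_sel=sys_.selection("ligand_N"),
        pocket_sel=sys_.selection("pocket"),
        state_models=dict(sys_.states),
        dmin=data.scenario.dmin,
    )


def load_manifest(path: str | Path, ligand_resname: str = "LIG") -> TimelineInputs:
    """Assemble timeline inputs from a YAML series manifest.

    The manifest references the dark/apo/per-delay reflection files, the
    dark model, and parameters; selections are derived from the model
    (ligand by residue name, waters and hydrogens excluded).
    """
    path = Path(path)
    man = yaml.safe_load(path.read_text())
    base = path.parent
    dark_model = fio.read_model(base / man["dark_model"])
    dmin = float(man.get("parameters", {}).get("dmin", 1.7))

    def not_water_h(a) -> bool:
        return a.resname not in ("HOH", "WAT") and a.element != "H"

    protein_sel = dark_model.select(
        lambda a: not_water_h(a) and a.resname != ligand_resname, tag="all protein non-H"
    )
    ligand_sel = dark_model.select(
        lambda a: a.resname == ligand_resname and a.element != "H", tag="ligand"
    )
    reporter_sel = dark_model.select(
        lambda a: a.resname == ligand_resname and a.element == "N", tag="ligand nitrogens"
    )
    lig_ids = set(ligand_sel.ids)
    cart = dark_model.cart
    lig_pos = np.array([cart[i] for i, a in enumerate(dark_model.atoms) if a.serial in lig_ids])
    near = set(lig_ids)
    if len(lig_pos):
        for i, a in enumerate(dark_model.atoms):
            if not_water_h(a) and np.min(np.linalg.norm(lig_pos - cart[i], axis=1)) <= 3.0:
                near.add(a.serial)
    pocket_sel = dark_model.select(lambda a: a.serial in near, tag="ligand+3A shell")

    delays, labels, times, counts = [], [], [], []
    for entry in man["delays"]:
        delays.append(fio.read_reflections(base / entry["file"], label=f"light:{entry['label']}"))
        labels.append(entry["label"])
        times.append(float(entry["time"]))
        counts.append(float(entry.get("patterns", 1)))
    fcalc = fio.read_reflections(base / man["fcalc"], label="calc")
    apo = None
    if man.get("apo"):
        apo = fio.read_reflections(base / man["apo"], label="apo")
    return TimelineInputs(
        dark_obs=fio.read_reflections(base / man["dark"], label="dark"),
        apo_obs=apo,
        delays=delays,
        labels=labels,
        times=np.array(times),
        pattern_counts=np.array(counts),
        fcalc_dark=fcalc,
        dark_model=dark_model,
        protein_sel=protein_sel,
        ligand_sel=ligand_sel,
        reporter_sel=reporter_sel,
        pocket_sel=pocket_sel,
        state_models={},
        dmin=dmin,
    )


def run_timeline(
    data: SimulatedDataset | TimelineInputs | SyntheticScenario,
    params: Optional[TimelineParams] = None,
    seed: Optional[int] = None,
) -> TimelineReport:
    """Run the full timeline analysis; see the module docstring."""
    params = params or TimelineParams()
    if isinstance(data, SyntheticScenario):
        data = simulate_dataset(data)
    if isinstance(data, SimulatedDataset):
        inputs = _inputs_from_simulation(data, seed)
    else:
        inputs = data
    warnings_: list[str] = []
    grid = default_grid(inputs.dark_obs.cell, inputs.dmin)

    scaling: list[ScalingResult] = []
    raw_maps: list[DensityMap] = []
    scaled_sets: list[ReflectionSet] = []
    for label, light in zip(inputs.labels, inputs.delays):
        scaled, res = scale_amplitudes(
            light, inputs.dark_obs, res_window=params.res_window, sigma_cutoff=params.sigma_cutoff
        )
        logger.info("scale %s: k=%.4f B=%.3f n=%d", label, res.k, res.b, res.n_used)
        scaling.append(res)
        scaled_sets.append(scaled)
        raw_maps.append(
            isomorphous_difference_map(scaled, inputs.dark_obs, inputs.fcalc_dark, grid, raw=True)
        )

    apo_raw = None
    if inputs.apo_obs is not None:
        apo_scaled, _apo_res = scale_amplitudes(
            inputs.apo_obs, inputs.dark_obs, res_window=params.res_window, sigma_cutoff=params.sigma_cutoff
        )
        apo_raw = isomorphous_difference_map(
            apo_scaled, inputs.dark_obs, inputs.fcalc_dark, grid, raw=True
        )

    # one sigma unit for the whole series (the strongest delay map):
    # every delay and the apo reference stay on one density scale, as
    # they are in real data where the map sigma is dominated by the
    # delay-independent merging noise
    sigma_ref = max(m.rms for m in raw_maps)
    if sigma_ref == 0:
        raise ValueError("reference difference map is constant")

    def on_ref_scale(m: DensityMap) -> DensityMap:
        return DensityMap(m.cell, (m.values - m.mean) / sigma_ref, sigma_scaled=True)

    maps = [on_ref_scale(m) for m in raw_maps]
    series = DifferenceSeries(
        labels=inputs.labels, times=inputs.times, maps=maps, pattern_counts=inputs.pattern_counts
    )

    corr_protein = correlation_matrix(
        series, inputs.protein_sel, params.corr_radius, params.corr_sigma, params.corr_threshold
    )
    corr_pocket = correlation_matrix(
        series, inputs.pocket_sel, params.corr_radius, params.corr_sigma, params.corr_threshold
    )
    blocks = greedy_block_segmentation(corr_protein)

    release = None
    apo_map = None
    if apo_raw is not None:
        apo_map = on_ref_scale(apo_raw)
        release = release_curve(
            series, inputs.ligand_sel, apo_map,
            occupancy_ratio=params.occupancy_ratio,
            radius=params.release_radius, sigma_threshold=params.release_sigma,
        )
    else:
        warnings_.append("no apo dataset in manifest: release stage skipped")
        logger.warning("no apo dataset: release stage skipped")

    a_values = params.a_values()
    act: list[Optional[float]] = []
    reap: list[Optional[float]] = []
    curves: list[ActivationCurve] = []
    probes = [(inputs.reporter_sel, "negative"), (inputs.reporter_sel, "positive")]
    for label, scaled in zip(inputs.labels, scaled_sets):
        curve, pos_curve = activation_scan_multi(
            scaled, inputs.dark_obs, inputs.fcalc_dark, probes, grid,
            a_grid=a_values, radius=params.release_radius, sigma_threshold=params.release_sigma,
        )
        curves.append(curve)
        try:
            act.append(estimate_activation(curve).a_star)
        except (FlatCurveError, ValueError) as exc:
            warnings_.append(f"activation estimate failed for {label}: {exc}")
            act.append(None)
        try:
            rfit = estimate_activation(pos_curve)
            reap.append(rfit.a_star)
        except (FlatCurveError, ValueError) as exc:
            warnings_.append(f"re-appearance estimate failed for {label}: {exc}")
            reap.append(None)

    def _mean(xs: list[Optional[float]]) -> Optional[float]:
        vals = [x for x in xs if x is not None]
        return float(np.mean(vals)) if vals else None

    fields: dict[str, DisplacementField] = {}
    for name, model in inputs.state_models.items():
        try:
            fields[name] = displacement_field(
                inputs.dark_model, model,
                cutoff=params.vector_cutoff, stride=params.vector_stride, amplify=params.vector_amplify,
            )
        except ValueError as exc:
            warnings_.append(f"vectors {name}: {exc}")

    if apo_map is None:
        apo_map = maps[-1]  # placeholder so the report stays writable
    return TimelineReport(
        scaling=scaling,
        series=series,
        apo_map=apo_map,
        corr_protein=corr_protein,
        corr_pocket=corr_pocket,
        blocks=blocks,
        release=release,
        activation_per_delay=act,
        activation_mean=_mean(act),
        reappearance_per_delay=reap,
        reappearance_mean=_mean(reap),
        activation_curves=curves,
        fields=fields,
        warnings=warnings_,
    )
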