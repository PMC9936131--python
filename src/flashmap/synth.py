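"""Seeded toy crystal systems with time-resolved mixed-population data.

The generator emulates the statistical structure of a pump-probe serial
crystallography experiment on a ligand-release system:

* a dark state: a pseudo-protein (~30 single-atom "residues", ten of
  which form a binding-pocket shell) plus an 8-atom ligand whose
  "A-ring" half carries two nitrogens (the reporter atoms);
* three photoproduct states visited in sequence — metastable (the
  A-ring relaxed ~2.5 A out of its dark pose), open (ligand still
  relaxed, the pocket gate atom rotated away plus smaller pocket
  shifts), and apo (ligand gone, pocket relaxed);
* per-delay light datasets over nine log-spaced delays (1 ns - 100 ms):
  complex structure factors of the states are population-mixed at
  activation fraction A, then amplitude noise is added with a sigma
  proportional to |F| and to sqrt(n_ref / n_patterns), so sparsely
  sampled delays are noisier (the sqrt-N merging law);
* a dark dataset, an apo dataset with higher multiplicity, and the
  noise-free calculated dark set used for phases.

Two population modes are provided.  The default crisp mode assigns the
whole activated fraction to one state per kinetic block (delays 1-3
metastable, 4-6 open, 7-9 apo) — the reference three-block scenario.
The smooth mode advances the activated population through the states
with stretched-exponential progress curves, giving a strictly monotone
decline of old-pose ligand occupancy over the delays (for release-curve
analyses).  Mixing is always done on complex structure factors, so the
pipeline's linear amplitude approximation is tested against physically
correct data, including its bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    Atom,
    AtomicModel,
    AtomSelection,
    ReflectionSet,
    UnitCell,
    compute_structure_factors,
    hemisphere_indices,
    structure_factors_at,
)
from .density import equalize_multiplicity

__all__ = [
    "SyntheticScenario",
    "KineticScheme",
    "ToySystem",
    "SimulatedDataset",
    "build_toy_system",
    "kinetic_populations",
    "simulate_dataset",
    "equalize_series",
    "write_scenario",
]

DELAY_LABELS = ["1ns", "10ns", "100ns", "1us", "10us", "100us", "1ms", "10ms", "100ms"]
DELAY_TIMES = np.array([1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1])

# uneven per-delay pattern counts; the minimum matches the study's
# worst-sampled delay (55,065 indexed patterns)
DEFAULT_PATTERN_COUNTS = (95382, 74551, 88210, 61023, 55065, 70128, 83407, 66894, 59712)

STATES = ("metastable", "open", "apo")

# pocket-gate displacements (A) on opening, and the relaxation shifts of
# other pocket-shell atoms in the apo state
GATE_SHIFTS = (2.2, 1.2, 1.0, 0.9, 0.8)
RELAX_SHIFTS = (1.2, 1.0, 0.9)


@dataclass
class KineticScheme:
    """Maps each delay to its dominant activated state (crisp blocks)."""

    blocks: tuple[tuple[int, int], ...] = ((0, 3), (3, 6), (6, 9))
    states: tuple[str, ...] = STATES

    def state_of(self, delay_index: int) -> str:
        for (lo, hi), st in zip(self.blocks, self.states):
            if lo <= delay_index < hi:
                return st
        raise ValueError(f"delay index {delay_index} outside the scheme")

    def block_of(self, delay_index: int) -> int:
        for b, (lo, hi) in enumerate(self.blocks):
            if lo <= delay_index < hi:
                return b
        raise ValueError(f"delay index {delay_index} outside the scheme")


@dataclass
class SyntheticScenario:
    seed: int = 1
    cell: UnitCell = field(default_factory=lambda: UnitCell(20.0, 24.0, 28.0))
    a_true: float = 22.0  # percent activated
    noise_frac: float = 0.02  # amplitude noise as a fraction of |F|
    dmin: float = 1.55
    labels: tuple[str, ...] = tuple(DELAY_LABELS)
    times: tuple[float, ...] = tuple(DELAY_TIMES)
    pattern_counts: tuple[int, ...] = DEFAULT_PATTERN_COUNTS
    dark_count: int = 150000
    apo_count: int = 4 * 55065  # ~fourfold the worst delay
    smooth: bool = False  # stretched-exponential state progression
    scheme: KineticScheme = field(default_factory=KineticScheme)

    def __post_init__(self) -> None:
        if not 0 <= self.a_true <= 100:
            raise ValueError("a_true must lie in [0, 100]")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be non-negative")
        if len(self.labels) != len(self.times) or len(self.labels) != len(self.pattern_counts):
            raise ValueError("labels/times/pattern_counts length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("delays must be strictly increasing")


@dataclass
class ToySystem:
    dark: AtomicModel
    states: dict[str, AtomicModel]  # metastable / open / apo
    reporter_serials: list[int]  # ligand nitrogens
    ligand_serials: list[int]
    gate_serials: list[int]  # pocket atoms that move on opening

    def selection(self, which: str) -> AtomSelection:
        """Named selections on the dark model.

        ``protein``: all pseudo-protein atoms; ``ligand``: ligand atoms;
        ``ligand_N``: the reporter nitrogens; ``pocket``: ligand plus
        every residue with an atom within 3 A of a ligand atom.
        """
        m = self.dark
        lig = set(self.ligand_serials)
        if which == "protein":
            return m.select(lambda a: a.serial not in lig, tag="all protein non-H")
        if which == "ligand":
            return m.select(lambda a: a.serial in lig, tag="ligand")
        if which == "ligand_N":
            rep = set(self.reporter_serials)
            return m.select(lambda a: a.serial in rep, tag="ligand nitrogens")
        if which == "pocket":
            cart = m.cart
            lig_pos = np.array([cart[i] for i, a in enumerate(m.atoms) if a.serial in lig])
            near: set[int] = set(lig)
            for i, a in enumerate(m.atoms):
                if np.min(np.linalg.norm(lig_pos - cart[i], axis=1)) <= 3.0:
                    near.add(a.serial)
            return m.select(lambda a: a.serial in near, tag="ligand+3A shell")
        raise ValueError(f"unknown selection {which!r}")


@dataclass
class PopulationTable:
    """Per-delay state fractions; rows sum to 1."""

    labels: list[str]
    dark: np.ndarray
    activated: dict[str, np.ndarray]  # state -> fraction of total

    def as_array(self) -> np.ndarray:
        cols = [self.dark] + [self.activated[s] for s in STATES]
        return np.stack(cols, axis=1)

    def old_pose_loss(self, a_ring_fraction: float = 0.5) -> np.ndarray:
        """Fraction of old-pose ligand occupancy lost per delay.

        The metastable and open states displace only the A-ring half of
        the ligand; apo removes all of it.
        """
        w_shift = self.activated["metastable"] + self.activated["open"]
        return a_ring_fraction * w_shift + self.activated["apo"]


@dataclass
class SimulatedDataset:
    scenario: SyntheticScenario
    system: ToySystem
    dark_obs: ReflectionSet
    apo_obs: ReflectionSet
    delays: list[ReflectionSet]
    fcalc_dark: ReflectionSet
    populations: PopulationTable


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def build_toy_system(seed: int = 1, cell: Optional[UnitCell] = None) -> ToySystem:
    """Deterministic toy crystal: dark model plus the three photoproducts.

    All non-moving atoms are bitwise identical across the four models.
    """
    cell = cell or UnitCell(20.0, 24.0, 28.0)
    rng = np.random.default_rng(seed)
    m = cell.orthogonalization
    minv = np.linalg.inv(m)
    center = np.array([cell.a / 2, cell.b / 2, cell.c / 2])

    # 8-atom ligand: A-ring (2 N + 2 C) and B-ring (4 C), ~1.4 A bonds
    a_off = np.array(
        [[0.0, 0.0, 0.0], [1.35, 0.4, 0.2], [0.5, 1.3, -0.4], [1.75, 1.6, -0.2]]
    )
    b_off = np.array(
        [[3.1, 0.1, 0.5], [4.3, 0.8, 0.3], [3.4, -1.2, 0.9], [4.6, -0.6, 0.7]]
    )
    lig_cart = np.vstack([center - 1.5 + a_off, center - 1.5 + b_off])
    lig_elements = ["N", "N", "C", "C", "C", "C", "C", "C"]
    lig_names = ["N1", "N2", "C1", "C2", "C3", "C4", "C5", "C6"]

    # ten pocket atoms on a shell ~4.5 A around the ligand centroid
    lig_centroid = lig_cart.mean(axis=0)
    pocket = []
    while len(pocket) < 10:
        pos = lig_centroid + 4.5 * _unit(rng) + rng.normal(scale=0.3, size=3)
        if np.min(np.linalg.norm(lig_cart - pos, axis=1)) < 2.4:
            continue
        if pocket and np.min(np.linalg.norm(np.array(pocket) - pos, axis=1)) < 2.4:
            continue
        pocket.append(pos)
    # twenty more scattered through the cell, away from everything placed
    scatter = []
    placed = np.vstack([lig_cart, pocket])
    min_sep, attempts = 3.0, 0
    while len(scatter) < 20:
        attempts += 1
        if attempts > 4000:  # ease the packing constraint if a seed packs badly
            min_sep, attempts = min_sep - 0.25, 0
        pos = rng.uniform(0, 1, 3) @ m.T
        frac_delta = (np.vstack([placed, scatter]) if scatter else placed) - pos
        frd = frac_delta @ minv.T
        frd -= np.round(frd)
        if np.min(np.linalg.norm(frd @ m.T, axis=1)) < min_sep:
            continue
        scatter.append(pos)
    prot_cart = np.vstack([pocket, scatter])
    # each pseudo-residue scatters like a calcium (Z = 20): a
    # coarse-grained stand-in for several light atoms, so the moving
    # ligand is a small fraction of the total scattering and the
    # light-dark phase changes stay small, as in a real protein crystal
    prot_elements = ["Ca"] * 30

    atoms: list[Atom] = []
    serial = 0
    for i in range(30):
        serial += 1
        atoms.append(
            Atom(
                serial=serial, chain="A", resid=i + 1, resname="ALA", name="CA",
                element=str(prot_elements[i]),
                frac=(minv @ prot_cart[i]), occ=1.0, b=float(rng.uniform(28, 32)),
            )
        )
    lig_serials, rep_serials = [], []
    for i in range(8):
        serial += 1
        lig_serials.append(serial)
        if lig_elements[i] == "N":
            rep_serials.append(serial)
        atoms.append(
            Atom(
                serial=serial, chain="L", resid=101, resname="LIG", name=lig_names[i],
                element=lig_elements[i],
                frac=(minv @ lig_cart[i]), occ=1.0, b=float(rng.uniform(4.6, 5.4)),
            )
        )
    dark = AtomicModel(cell, atoms)

    # state geometry.  Metastable: rigid 2.5 A shift of the A-ring
    # (echoing the ~2.6 A ring relocation of the relaxed pose).  Open:
    # the A-ring moves on to a second pose and the pocket gate opens
    # (five shell atoms displaced).  Apo: the ligand is gone, the gate
    # is back at its dark position and three other shell atoms relax.
    # Pose directions are drawn so relocated rings never collide with,
    # or sit on top of, old-pose or pocket atoms - each intermediate has
    # a distinct difference signature.
    old_aring = lig_cart[:4]

    def place_ring(shift: float, avoid: np.ndarray) -> np.ndarray:
        # rejection-sample a shift direction; relax the clearance
        # progressively so placement terminates for every seed
        best, best_clear = None, -1.0
        for clearance in (2.2, 2.0, 1.8, 1.6):
            for _ in range(400):
                new = old_aring + shift * _unit(rng)
                dmin_ = float(np.linalg.norm(new[:, None, :] - avoid[None, :, :], axis=2).min())
                if dmin_ >= clearance:
                    return new
                if dmin_ > best_clear:
                    best, best_clear = new, dmin_
        return best  # most-clear candidate seen

    obstacles = np.vstack([lig_cart, prot_cart[:10]])
    aring_meta = place_ring(2.5, obstacles)
    aring_open = place_ring(2.5, np.vstack([obstacles, aring_meta]))

    meta = dark.copy()
    for i in range(30, 34):  # A-ring atoms
        meta.atoms[i].frac = (minv @ aring_meta[i - 30]) % 1.0

    gate_idx = [0, 1, 2, 3, 4]  # pocket-shell atoms that move on opening
    open_ = dark.copy()
    for i in range(30, 34):
        open_.atoms[i].frac = (minv @ aring_open[i - 30]) % 1.0
    gate_dirs = [_unit(rng) for _ in gate_idx]
    for gi, gs, gd in zip(gate_idx, GATE_SHIFTS, gate_dirs):
        open_.atoms[gi].frac = (minv @ (prot_cart[gi] + gs * gd)) % 1.0

    relax_idx = [5, 6, 7]  # different shell atoms relax once the ligand left
    apo = AtomicModel(cell, [a for a in dark.copy().atoms if a.serial not in lig_serials])
    relax_dirs = [_unit(rng) for _ in relax_idx]
    for gi, rs, rd in zip(relax_idx, RELAX_SHIFTS, relax_dirs):
        apo.atoms[gi].frac = (minv @ (prot_cart[gi] + rs * rd)) % 1.0

    return ToySystem(
        dark=dark,
        states={"metastable": meta, "open": open_, "apo": apo},
        reporter_serials=rep_serials,
        ligand_serials=lig_serials,
        gate_serials=[gi + 1 for gi in gate_idx],
    )


def _smooth_weights(times: np.ndarray) -> dict[str, np.ndarray]:
    """Stretched-exponential progress through metastable -> open -> apo.

    The strongly stretched apo progress (beta 0.12, near log-uniform)
    spreads the release over the whole eight-decade delay range, so the
    old-pose ligand occupancy declines by a resolvable step at every
    delay.
    """
    t = np.asarray(times, dtype=float)
    w_apo = 1.0 - np.exp(-((t / 1e-4) ** 0.12))
    f_open = 1.0 - np.exp(-((t / 6e-7) ** 0.6))
    w_open = (1.0 - w_apo) * f_open
    w_meta = (1.0 - w_apo) * (1.0 - f_open)
    return {"metastable": w_meta, "open": w_open, "apo": w_apo}


def kinetic_populations(
    scheme: KineticScheme,
    a_true: float,
    times: np.ndarray,
    labels: Optional[list[str]] = None,
    smooth: bool = False,
) -> PopulationTable:
    """Per-delay state populations; dark is always 1 - A/100."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    labels = labels if labels is not None else [f"d{i}" for i in range(n)]
    a = a_true / 100.0
    dark = np.full(n, 1.0 - a)
    if smooth:
        w = _smooth_weights(times)
    else:
        w = {s: np.zeros(n) for s in STATES}
        for i in range(n):
            w[scheme.state_of(i)][i] = 1.0
    activated = {s: a * w[s] for s in STATES}
    total = dark + sum(activated.values())
    if not np.allclose(total, 1.0):
        raise ValueError("populations do not sum to 1")
    return PopulationTable(labels=list(labels), dark=dark, activated=activated)


def _noisy_amplitudes(
    f_complex: np.ndarray,
    noise_frac: float,
    count_factor: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    amp = np.abs(f_complex)
    sig = noise_frac * amp * count_factor
    obs = np.abs(amp + rng.normal(scale=np.where(sig > 0, sig, 1e-300), size=len(amp)) * (sig > 0))
    return obs, sig


def simulate_dataset(scenario: SyntheticScenario) -> SimulatedDataset:
    """Simulate dark, apo, and per-delay light reflection datasets.

    Complex structure factors of the states are mixed with the per-delay
    populations; observed amplitudes are | |F_mix| + eps | with
    eps ~ N(0, (noise_frac |F_mix| sqrt(n_ref / n_delay))^2), seeded.
    The sigmaF column records the true noise sd.
    """
    sys_ = build_toy_system(scenario.seed, scenario.cell)
    cell = scenario.cell
    hkl = hemisphere_indices(cell, scenario.dmin)
    f_states = {name: structure_factors_at(m, hkl) for name, m in sys_.states.items()}
    f_dark = structure_factors_at(sys_.dark, hkl)
    pops = kinetic_populations(
        scenario.scheme, scenario.a_true, np.array(scenario.times),
        labels=list(scenario.labels), smooth=scenario.smooth,
    )
    n_ref = float(max(scenario.pattern_counts))
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2**20]))

    def make_obs(fc: np.ndarray, count: float, label: str) -> ReflectionSet:
        factor = np.sqrt(n_ref / count)
        obs, sig = _noisy_amplitudes(fc, scenario.noise_frac, factor, rng)
        return ReflectionSet(cell=cell, hkl=hkl.copy(), f=obs, sigf=sig, label=label)

    dark_obs = make_obs(f_dark, scenario.dark_count, "dark")
    apo_obs = make_obs(f_states["apo"], scenario.apo_count, "apo")
    delays = []
    for i, label in enumerate(scenario.labels):
        f_mix = pops.dark[i] * f_dark
        for s in STATES:
            f_mix = f_mix + pops.activated[s][i] * f_states[s]
        delays.append(make_obs(f_mix, scenario.pattern_counts[i], f"light:{label}"))
    fcalc_dark = ReflectionSet(
        cell=cell, hkl=hkl.copy(), f=np.abs(f_dark),
        phase=np.degrees(np.angle(f_dark)), label="calc",
    )
    return SimulatedDataset(
        scenario=scenario, system=sys_, dark_obs=dark_obs, apo_obs=apo_obs,
        delays=delays, fcalc_dark=fcalc_dark, populations=pops,
    )


def equalize_series(data: SimulatedDataset, seed: Optional[int] = None) -> list[ReflectionSet]:
    """Per-delay sets with noise inflated to the worst-sampled delay.

    Mimics subsampling every delay to the smallest pattern count: extra
    Gaussian noise is added so each sigma reaches factor * sigma, with
    factor = sqrt(count / min_count).  Deterministic for a seed.
    """
    counts = data.scenario.pattern_counts
    _, factors = equalize_multiplicity(counts)
    rng = np.random.default_rng(
        np.random.SeedSequence([data.scenario.seed if seed is None else seed, 2**21])
    )
    out = []
    for refl, fac in zip(data.delays, factors):
        if fac == 1.0 or refl.sigf is None:
            out.append(refl)
            continue
        extra_sd = refl.sigf * np.sqrt(fac**2 - 1.0)
        f = np.abs(refl.f + rng.normal(size=len(refl)) * extra_sd)
        out.append(
            ReflectionSet(cell=refl.cell, hkl=refl.hkl.copy(), f=f,
                          sigf=refl.sigf * fac, label=refl.label)
        )
    return out


def write_scenario(data: SimulatedDataset, outdir: str | Path) -> Path:
    """Persist a simulated scenario: PDB models, MTZ data, truth, manifest."""
    from . import io as fio  # local import: io pulls in gemmi writers
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_model(data.system.dark, outdir / "dark.pdb")
    for name, m in data.system.states.items():
        fio.write_model(m, outdir / f"{name}.pdb")
    fio.write_reflections(data.dark_obs, outdir / "dark.mtz")
    fio.write_reflections(data.apo_obs, outdir / "apo.mtz")
    fio.write_reflections(data.fcalc_dark, outdir / "fcalc_dark.mtz")
    delay_files = []
    # persist the multiplicity-equalized sets: the files stand for data
    # already merged at matched pattern counts
    for label, refl in zip(data.scenario.labels, equalize_series(data)):
        fn = f"light_{label}.mtz"
        fio.write_reflections(refl, outdir / fn)
        delay_files.append(fn)
    truth = {
        "a_true": data.scenario.a_true,
        "seed": data.scenario.seed,
        "noise_frac": data.scenario.noise_frac,
        "reporter_serials": data.system.reporter_serials,
        "ligand_serials": data.system.ligand_serials,
        "populations": {
            "labels": data.populations.labels,
            "dark": data.populations.dark.tolist(),
            **{s: data.populations.activated[s].tolist() for s in STATES},
        },
        "old_pose_loss": data.populations.old_pose_loss().tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    manifest = {
        "dark": "dark.mtz",
        "apo": "apo.mtz",
        "fcalc": "fcalc_dark.mtz",
        "dark_model": "dark.pdb",
        "delays": [
            {"label": lab, "time": float(t), "file": fn, "patterns": int(c)}
            for lab, t, fn, c in zip(
                data.scenario.labels, data.scenario.times, delay_files,
                data.scenario.pattern_counts,
            )
        ],
        "parameters": {
            "dmin": data.scenario.dmin,
            "res_window": [6.0, 1.7],
            "sigma_cutoff": 2.0,
            "occupancy_ratio": 4.0,
        },
    }
    (outdir / "series.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir / "series.yaml"
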