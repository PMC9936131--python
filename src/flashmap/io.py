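"""Readers and writers for standard crystallographic formats.

Models: PDB / mmCIF in, PDB out.  Reflections: MTZ and structure-factor
mmCIF in, MTZ out (column roles F / SIGF / PHIC configurable).  Maps:
CCP4/MRC in and out.  All heavy lifting is delegated to gemmi; this layer
converts to and from the package's in-memory types and enforces the
invariants they promise (wrapped fractional coordinates, unique indices,
named errors for missing columns).

Space groups other than P1 are accepted on input but the data are used
as-is in P1: the downstream arithmetic consumes merged amplitudes and is
symmetry-agnostic.  A warning is emitted in that case.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .core import Atom, AtomicModel, DensityMap, ReflectionSet, UnitCell

__all__ = [
    "read_model",
    "write_model",
    "read_reflections",
    "write_reflections",
    "read_map",
    "write_map",
]


def _check_pdb_columns(path: Path) -> None:
    # PDB fixed columns: occupancy 55-60, B-factor 61-66.  A truncated
    # record means those fields are absent; name the missing column.
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line.rstrip()) < 60:
                raise ValueError(
                    f"{path.name}:{ln}: occupancy column missing from ATOM record"
                )
            if len(line.rstrip()) < 66:
                raise ValueError(
                    f"{path.name}:{ln}: temperature factor (B) column missing "
                    "from ATOM record"
                )


def read_model(path: str | Path, drop_altloc: bool = True) -> AtomicModel:
    """Read a PDB or mmCIF model into an :class:`AtomicModel`.

    Alternate conformers other than ''/'A' are dropped when
    ``drop_altloc`` (occupancies are kept as deposited).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".pdb":
        _check_pdb_columns(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    if st.spacegroup_hm and st.spacegroup_hm.replace(" ", "") not in ("P1", "P1"):
        warnings.warn(
            f"{path.name}: space group {st.spacegroup_hm!r} treated as P1 "
            "(merged-amplitude arithmetic is symmetry-agnostic)"
        )
    atoms: list[Atom] = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    if drop_altloc and at.altloc not in ("", "A", "\x00"):
                        continue
                    serial += 1
                    frac = st.cell.fractionalize(at.pos)
                    atoms.append(
                        Atom(
                            serial=serial,
                            chain=chain.name,
                            resid=res.seqid.num,
                            resname=res.name,
                            name=at.name,
                            element=at.element.name,
                            frac=np.array([frac.x, frac.y, frac.z]),
                            occ=min(max(at.occ, 0.0), 1.0),
                            b=max(at.b_iso, 0.0),
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(f"{path.name}: no atoms parsed")
    return AtomicModel(cell, atoms)


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write an :class:`AtomicModel` as a P1 PDB file."""
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != a.resid or ch[-1].name != a.resname:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            ch.add_residue(res)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.occ = a.occ
        at.b_iso = a.b
        at.pos = st.cell.orthogonalize(gemmi.Fractional(*a.frac))
        ch[-1].add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.write_pdb(str(path))


def read_reflections(
    path: str | Path,
    f_col: str = "F",
    sigf_col: Optional[str] = "SIGF",
    phase_col: Optional[str] = "PHIC",
    label: str = "",
) -> ReflectionSet:
    """Read amplitudes (and optional sigmas/phases) from MTZ or SF-mmCIF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mtz":
        mtz = gemmi.read_mtz_file(str(path))
        cols = {c.label for c in mtz.columns}
        if f_col not in cols:
            raise ValueError(f"{path.name}: required column {f_col!r} not found")
        hkl = np.array(
            [mtz.column_with_label(x).array for x in ("H", "K", "L")], dtype=int
        ).T
        f = np.asarray(mtz.column_with_label(f_col).array, dtype=float)
        sigf = None
        if sigf_col and sigf_col in cols:
            sigf = np.asarray(mtz.column_with_label(sigf_col).array, dtype=float)
        phase = None
        if phase_col and phase_col in cols:
            phase = np.asarray(mtz.column_with_label(phase_col).array, dtype=float)
        cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
        if mtz.spacegroup and mtz.spacegroup.number != 1:
            warnings.warn(
                f"{path.name}: space group {mtz.spacegroup.hm!r} treated as P1"
            )
    else:
        doc = gemmi.cif.read(str(path))
        rb = gemmi.as_refln_blocks(doc)[0]
        cell = UnitCell(rb.cell.a, rb.cell.b, rb.cell.c, rb.cell.alpha, rb.cell.beta, rb.cell.gamma)
        hkl = np.asarray(rb.make_miller_array(), dtype=int)
        f = np.asarray(rb.make_float_array(f_col), dtype=float)
        try:
            sigf = np.asarray(rb.make_float_array(sigf_col), dtype=float) if sigf_col else None
        except RuntimeError:
            sigf = None
        try:
            phase = np.asarray(rb.make_float_array(phase_col), dtype=float) if phase_col else None
        except RuntimeError:
            phase = None
    keep = np.isfinite(f)
    if sigf is not None:
        sigf = sigf[keep]
    if phase is not None:
        phase = phase[keep]
    return ReflectionSet(cell=cell, hkl=hkl[keep], f=f[keep], sigf=sigf, phase=phase, label=label)


def write_reflections(
    refl: ReflectionSet,
    path: str | Path,
    f_col: str = "F",
    sigf_col: str = "SIGF",
    phase_col: str = "PHIC",
) -> None:
    """Write a :class:`ReflectionSet` as a P1 MTZ file."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.cell = refl.cell.to_gemmi()
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    mtz.add_dataset("flashmap")
    mtz.add_column(f_col, "F")
    ncol = 4
    if refl.sigf is not None:
        mtz.add_column(sigf_col, "Q")
        ncol += 1
    if refl.phase is not None:
        mtz.add_column(phase_col, "P")
        ncol += 1
    data = np.zeros((len(refl), ncol))
    data[:, :3] = refl.hkl
    data[:, 3] = refl.f
    j = 4
    if refl.sigf is not None:
        data[:, j] = refl.sigf
        j += 1
    if refl.phase is not None:
        data[:, j] = refl.phase
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a :class:`DensityMap` as CCP4/MRC, cell and grid in the header."""
    grid = gemmi.FloatGrid(*dmap.shape)
    grid.set_unit_cell(dmap.cell.to_gemmi())
    grid.spacegroup = gemmi.SpaceGroup("P1")
    arr = np.asarray(grid.array)
    arr[...] = dmap.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path, sigma_scaled: bool = False) -> DensityMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))
    g = ccp4.grid
    cell = UnitCell(g.unit_cell.a, g.unit_cell.b, g.unit_cell.c, g.unit_cell.alpha, g.unit_cell.beta, g.unit_cell.gamma)
    return DensityMap(cell, np.array(g.array, dtype=float), sigma_scaled=sigma_scaled)
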