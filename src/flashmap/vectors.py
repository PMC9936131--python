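"""Backbone displacement fields between two structural states.

Per matched C-alpha the displacement vector (state B minus state A) is
computed in cartesian space; vectors are classified significant at a
magnitude cutoff (default 0.5 A), thinned to every ``stride``-th residue
for display and drawn at ``amplify`` times their true length.
Residues are matched by (chain, residue number); unmatched residues are
skipped and counted.  No superposition is applied by default (states
from one crystal form share a frame); an optional least-squares
superposition on matched C-alphas is available for pre-aligned inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AtomicModel

__all__ = ["DisplacementField", "displacement_field", "write_vectors", "read_vectors"]


@dataclass
class VectorEntry:
    chain: str
    resid: int
    origin: np.ndarray  # C-alpha position in state A (A)
    vector: np.ndarray  # displacement (A)
    magnitude: float
    shown: bool


@dataclass
class DisplacementField:
    entries: list[VectorEntry]
    cutoff: float
    stride: int
    amplify: float
    n_unmatched: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def shown(self) -> list[VectorEntry]:
        return [e for e in self.entries if e.shown]


def _ca_table(model: AtomicModel, atom_name: str) -> dict[tuple[str, int], np.ndarray]:
    out: dict[tuple[str, int], np.ndarray] = {}
    cart = model.cart
    for i, a in enumerate(model.atoms):
        if a.name.strip() == atom_name:
            out[(a.chain, a.resid)] = cart[i]
    return out


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing |R q + t - p|^2."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, pc - r @ qc


def displacement_field(
    model_a: AtomicModel,
    model_b: AtomicModel,
    cutoff: float = 0.5,
    stride: int = 2,
    amplify: float = 6.0,
    atom_name: str = "CA",
    superpose: bool = False,
) -> DisplacementField:
    """Per-residue C-alpha displacement field from state A to state B."""
    ta, tb = _ca_table(model_a, atom_name), _ca_table(model_b, atom_name)
    keys = sorted(set(ta) & set(tb))
    if not keys:
        raise ValueError(f"no matched {atom_name} pairs between the models")
    n_unmatched = len(set(ta) ^ set(tb))
    pa = np.array([ta[k] for k in keys])
    pb = np.array([tb[k] for k in keys])
    if superpose:
        r, t = _kabsch(pa, pb)
        pb = pb @ r.T + t
    entries = []
    for ordinal, key in enumerate(keys):
        vec = pb[ordinal] - pa[ordinal]
        mag = float(np.linalg.norm(vec))
        shown = mag >= cutoff and ordinal % stride == 0
        entries.append(
            VectorEntry(chain=key[0], resid=key[1], origin=pa[ordinal], vector=vec, magnitude=mag, shown=shown)
        )
    return DisplacementField(entries, cutoff=cutoff, stride=stride, amplify=amplify, n_unmatched=n_unmatched)


_TSV_HEADER = ["chain", "resid", "x", "y", "z", "dx", "dy", "dz", "magnitude", "shown"]


def write_vectors(field: DisplacementField, path: str | Path, pml: bool = True) -> None:
    """Write the field as TSV plus a PyMOL CGO-arrow viewer script."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_HEADER)
        for e in field.entries:
            w.writerow(
                [e.chain, e.resid]
                + [f"{v:.6f}" for v in (*e.origin, *e.vector, e.magnitude)]
                + [int(e.shown)]
            )
    if pml:
        lines = ["from pymol.cgo import CYLINDER", "arrows = []"]
        for e in field.shown:
            tip = e.origin + field.amplify * e.vector
            lines.append(
                "arrows += [CYLINDER, {:.3f},{:.3f},{:.3f}, {:.3f},{:.3f},{:.3f}, "
                "0.2, 1,0.5,0, 1,0.5,0]".format(*e.origin, *tip)
            )
        lines.append('cmd.load_cgo(arrows, "displacements")')
        path.with_suffix(".pml").write_text("\n".join(lines) + "\n")


def read_vectors(path: str | Path, cutoff: float = 0.5, stride: int = 2, amplify: float = 6.0) -> DisplacementField:
    """Round-trip reader for the TSV written by :func:`write_vectors`."""
    entries = []
    with open(path) as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd)
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected vector TSV header: {header}")
        for row in rd:
            entries.append(
                VectorEntry(
                    chain=row[0],
                    resid=int(row[1]),
                    origin=np.array([float(v) for v in row[2:5]]),
                    vector=np.array([float(v) for v in row[5:8]]),
                    magnitude=float(row[8]),
                    shown=bool(int(row[9])),
                )
            )
    return DisplacementField(entries, cutoff=cutoff, stride=stride, amplify=amplify)
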