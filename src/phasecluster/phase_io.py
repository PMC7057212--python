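"""Phase-set containers and I/O.

A *phase set* is the per-reflection record of one partial molecular-
replacement solution: Miller indices, amplitudes ``F``, figures of merit
``m`` (the per-reflection phase-reliability weights in [0, 1]) and phases
``phi`` in degrees.  The on-disk format is the whitespace-separated
``h k l F fom phi`` dialect written by SHELXE-style programs (``.phs``);
the file itself carries no cell or space group, so both are supplied by the
caller and attached at read time.

Phases can also be computed from a toy coordinate model by direct
structure-factor summation over the space-group operators.  The scattering
model is deliberately minimal — point atoms, unit weights, no thermal
motion — because every algorithm downstream depends on phase relationships,
not on amplitude realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .symmetry import SpaceGroupInfo, d_spacings, load_space_group

__all__ = [
    "PhaseSet",
    "ToyModel",
    "PhsParseError",
    "read_phs",
    "write_phs",
    "read_pdb_model",
    "generate_hkl",
    "structure_factors",
    "phases_from_model",
    "cut_resolution",
]


class PhsParseError(ValueError):
    """Raised when a .phs file cannot be parsed or fails validation."""


@dataclass
class PhaseSet:
    """Reflections, amplitudes, figures of merit and phases of one solution."""

    id: str
    cell: tuple[float, float, float, float, float, float]
    sg_symbol: str
    hkl: np.ndarray  # (n, 3) int
    F: np.ndarray  # (n,) float, >= 0
    fom: np.ndarray  # (n,) float in [0, 1]
    phi: np.ndarray  # (n,) float, degrees in [0, 360)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hkl = np.ascontiguousarray(np.asarray(self.hkl, dtype=int))
        self.F = np.asarray(self.F, dtype=float)
        self.fom = np.asarray(self.fom, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float) % 360.0
        self.cell = tuple(float(c) for c in self.cell)
        n = len(self.hkl)
        if not (len(self.F) == len(self.fom) == len(self.phi) == n):
            raise ValueError("per-reflection arrays must have equal length")
        if n and (self.fom.min() < 0.0 or self.fom.max() > 1.0):
            raise ValueError("figures of merit must lie in [0, 1]")
        if n and self.F.min() < 0.0:
            raise ValueError("amplitudes must be non-negative")
        if n and len(np.unique(self.hkl, axis=0)) != n:
            raise ValueError("duplicate Miller indices in phase set")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def n_reflections(self) -> int:
        return len(self.hkl)

    def d_spacings(self) -> np.ndarray:
        return d_spacings(self.hkl, self.cell)

    def replace(self, **changes) -> "PhaseSet":
        return dataclasses.replace(self, **changes)

    def copy(self) -> "PhaseSet":
        return PhaseSet(
            id=self.id,
            cell=self.cell,
            sg_symbol=self.sg_symbol,
            hkl=self.hkl.copy(),
            F=self.F.copy(),
            fom=self.fom.copy(),
            phi=self.phi.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ToyModel:
    """Point-atom model in fractional coordinates with per-atom weights."""

    cell: tuple[float, float, float, float, float, float]
    sg_symbol: str
    xyz: np.ndarray  # (n, 3) fractional, in [0, 1)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float) % 1.0
        self.cell = tuple(float(c) for c in self.cell)
        if self.weights is None:
            self.weights = np.ones(len(self.xyz))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.xyz):
            raise ValueError("weights and coordinates must have equal length")
        if len(self.xyz) and self.weights.min() <= 0.0:
            raise ValueError("atom weights must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)


def read_phs(
    path: str | Path,
    cell: Sequence[float],
    sg_symbol: str,
    id: str | None = None,
) -> PhaseSet:
    """Read a SHELXE-dialect .phs file (``h k l F fom phi`` records).

    Blank lines and an all-zero terminator record are skipped; a seventh
    column, if present, is ignored.  Cell and space group are attached from
    the arguments since the format does not carry them.
    """
    path = Path(path)
    hkl, F, fom, phi = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise PhsParseError(
                    f"{path.name}:{lineno}: expected >= 6 columns, got {len(fields)}"
                )
            try:
                h, k, l = int(fields[0]), int(fields[1]), int(fields[2])
                f_val, m_val, p_val = (float(v) for v in fields[3:6])
            except ValueError as exc:
                raise PhsParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
            if (h, k, l) == (0, 0, 0) and f_val == 0.0:
                continue  # terminator record
            if not 0.0 <= m_val <= 1.0:
                raise PhsParseError(
                    f"{path.name}:{lineno}: figure of merit {m_val} outside [0, 1]"
                )
            hkl.append((h, k, l))
            F.append(f_val)
            fom.append(m_val)
            phi.append(p_val)
    if not hkl:
        raise PhsParseError(f"{path.name}: no reflections found")
    return PhaseSet(
        id=id if id is not None else path.stem,
        cell=tuple(cell),
        sg_symbol=sg_symbol,
        hkl=np.array(hkl, dtype=int),
        F=np.array(F),
        fom=np.array(fom),
        phi=np.array(phi),
    )


def write_phs(ps: PhaseSet, path: str | Path) -> None:
    """Write fixed-width ``h k l F fom phi`` records, one per reflection."""
    if ps.n_reflections == 0:
        raise ValueError("refusing to write an empty phase set")
    with open(path, "w") as fh:
        for (h, k, l), f_val, m_val, p_val in zip(ps.hkl, ps.F, ps.fom, ps.phi):
            fh.write(f"{h:4d}{k:4d}{l:4d}{f_val:12.4f}{m_val:8.4f}{p_val:10.4f}\n")


def read_pdb_model(
    path: str | Path,
    cell: Sequence[float] | None = None,
    sg_symbol: str | None = None,
) -> ToyModel:
    """Read ATOM/HETATM records from a PDB file into a :class:`ToyModel`.

    Orthogonal coordinates are converted to fractional using the CRYST1 cell
    if present, otherwise the supplied cell.  Atoms get unit weights.
    """
    st = gemmi.read_structure(str(path))
    if cell is None:
        if st.cell.volume <= 0:
            raise ValueError("PDB file has no CRYST1 record and no cell was supplied")
        uc = st.cell
        cell6 = (uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma)
    else:
        cell6 = tuple(float(c) for c in cell)
        uc = gemmi.UnitCell(*cell6)
    if sg_symbol is None:
        sg_symbol = st.spacegroup_hm or "P1"
    frac = []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    fpos = uc.fractionalize(atom.pos)
                    frac.append((fpos.x, fpos.y, fpos.z))
        break  # first model only
    if not frac:
        raise ValueError(f"no atoms found in {path}")
    return ToyModel(cell=cell6, sg_symbol=sg_symbol, xyz=np.array(frac))


def _orbit_representative_mask(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """True where h is the lexicographically maximal member of its orbit.

    The orbit includes the images under all rotation parts and their Friedel
    mates; every phase set produced by this package uses the same convention,
    which is what makes reflection lists directly comparable.
    """
    rots = np.array([op.rot_array for op in sg.ops])  # (m, 3, 3)
    images = np.einsum("nj,mjk->mnk", hkl, rots)  # h' = h R
    images = np.concatenate([images, -images], axis=0)
    m = images.shape[0]
    best = images[0].copy()
    for i in range(1, m):
        cand = images[i]
        better = (
            (cand[:, 0] > best[:, 0])
            | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] > best[:, 1]))
            | (
                (cand[:, 0] == best[:, 0])
                & (cand[:, 1] == best[:, 1])
                & (cand[:, 2] > best[:, 2])
            )
        )
        best[better] = cand[better]
    return (hkl == best).all(axis=1)


def _systematic_absence_mask(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """True where the reflection is extinct (h R = h with non-integral h.t)."""
    absent = np.zeros(len(hkl), dtype=bool)
    for op in sg.ops:
        fixed = (hkl @ op.rot_array == hkl).all(axis=1)
        ht = hkl @ op.tran_array
        absent |= fixed & (np.abs(ht - np.round(ht)) > 1e-9)
    return absent


def generate_hkl(
    cell: Sequence[float], sg: SpaceGroupInfo | str, d_min: float
) -> np.ndarray:
    """Unique reflections with d >= d_min, one representative per orbit.

    The representative is the lexicographically maximal index among all
    symmetry images and Friedel mates; systematically absent reflections are
    removed.
    """
    if isinstance(sg, str):
        sg = load_space_group(sg)
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    a, b, c = cell[0], cell[1], cell[2]
    hmax = int(np.ceil(a / d_min)) + 1
    kmax = int(np.ceil(b / d_min)) + 1
    lmax = int(np.ceil(c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[(hkl != 0).any(axis=1)]
    d = d_spacings(hkl, cell)
    hkl = hkl[d >= d_min]
    if len(hkl) == 0:
        return hkl.reshape(0, 3)
    hkl = hkl[_orbit_representative_mask(hkl, sg)]
    hkl = hkl[~_systematic_absence_mask(hkl, sg)]
    # deterministic descending-d order
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], -d_spacings(hkl, cell)))
    return hkl[order]


def structure_factors(model: ToyModel, hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direct summation F(h), phi(h) over all symmetry copies of the model.

    F(h) = |sum_ops sum_atoms w_j exp(2 pi i h.(R x_j + t))|, phi in degrees.
    """
    sg = load_space_group(model.sg_symbol)
    hkl = np.asarray(hkl, dtype=int)
    sf = np.zeros(len(hkl), dtype=complex)
    for op in sg.ops:
        coords = model.xyz @ op.rot_array.T + op.tran_array  # (n_atoms, 3)
        phase = 2.0j * np.pi * (hkl @ coords.T)  # (n_hkl, n_atoms)
        sf += np.exp(phase) @ model.weights
    F = np.abs(sf)
    phi = np.degrees(np.angle(sf)) % 360.0
    return F, phi


def phases_from_model(
    model: ToyModel,
    d_min: float,
    hkl: np.ndarray | None = None,
    id: str = "model",
) -> PhaseSet:
    """Compute a phase set from a coordinate model by direct summation.

    All unique reflections with d >= d_min are used unless an explicit
    reflection list is given (callers comparing several models must share
    one list).  Figures of merit are set to 1.
    """
    if hkl is None:
        hkl = generate_hkl(model.cell, model.sg_symbol, d_min)
    if len(hkl) == 0:
        raise ValueError(
            f"no reflections at d >= {d_min} A for cell {model.cell}"
        )
    F, phi = structure_factors(model, hkl)
    return PhaseSet(
        id=id,
        cell=model.cell,
        sg_symbol=model.sg_symbol,
        hkl=hkl,
        F=F,
        fom=np.ones(len(hkl)),
        phi=phi,
    )


def cut_resolution(ps: PhaseSet, d_cut: float) -> PhaseSet:
    """Keep exactly the reflections with d >= d_cut, preserving order."""
    if d_cut <= 0:
        raise ValueError("d_cut must be positive")
    keep = ps.d_spacings() >= d_cut
    return ps.replace(
        hkl=ps.hkl[keep], F=ps.F[keep], fom=ps.fom[keep], phi=ps.phi[keep]
    )
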