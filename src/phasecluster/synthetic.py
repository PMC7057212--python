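"""Synthetic solution landscapes with ground truth.

Fragment-based molecular replacement produces "landscapes" of partial
solutions: a minority of correctly placed, incomplete, noisy sub-models and
a majority of wrong placements whose phases are essentially random, each
sitting on its own symmetry-allowed origin.  This module emulates that
statistical structure from a toy point-atom crystal so that every stage of
the comparison/clustering machinery can be exercised with known labels,
known origin shifts and a known true phase set.

Conventions chosen here (and documented in the methods note):

* every solution carries the *truth* amplitudes with its own model phases,
  as SHELXE-style .phs sets share the observed amplitudes;
* correct solutions derive from one common core subset of the structure
  (overlapping fragments share a consensus core), perturbed per solution by
  coordinate jitter and wrapped-Gaussian phase noise;
* wrong solutions are freshly drawn unrelated structures of the same size,
  which reproduces the ~90 degree phase-difference noise floor;
* figure-of-merit and score models are simple documented functions of the
  noise level, not fits to any real run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import gemmi
import numpy as np

from .core import apply_shift
from .phase_io import PhaseSet, ToyModel, phases_from_model, structure_factors
from .symmetry import SpaceGroupInfo, load_space_group

__all__ = [
    "SolutionLandscape",
    "DEFAULT_CELLS",
    "make_toy_structure",
    "make_partial_solution",
    "make_landscape",
]

# Default cells per supported group.  They are sized so that a few hundred
# unique reflections survive the 4.0 A comparison cutoff: with fewer, the
# wrapped-phase statistics of unrelated sets develop a heavy tail well below
# the 90-degree floor and chance admissions stop reflecting what happens at
# realistic reflection counts.
DEFAULT_CELLS: dict[str, tuple[float, float, float, float, float, float]] = {
    "P1": (18.0, 19.0, 21.0, 80.0, 95.0, 108.0),
    "P21": (20.0, 22.0, 24.0, 90.0, 100.0, 90.0),
    "C2": (36.0, 22.0, 26.0, 90.0, 105.0, 90.0),
    "P212121": (24.0, 27.0, 30.0, 90.0, 90.0, 90.0),
    "C2221": (26.0, 30.0, 34.0, 90.0, 90.0, 90.0),
    "F222": (34.0, 38.0, 42.0, 90.0, 90.0, 90.0),
    "F23": (40.0, 40.0, 40.0, 90.0, 90.0, 90.0),
    "P63": (26.0, 26.0, 30.0, 90.0, 90.0, 120.0),
}


@dataclass
class SolutionLandscape:
    """Labelled collection of synthetic partial solutions plus the truth."""

    truth: PhaseSet
    solutions: list[PhaseSet]
    labels: list[Literal["correct", "wrong"]]
    true_shifts: list[tuple[float, float, float]]
    params: dict = field(default_factory=dict)

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    def correct_ids(self) -> set[str]:
        return {s.id for s, lab in zip(self.solutions, self.labels) if lab == "correct"}


def _min_sym_distance(
    xyz: np.ndarray, new: np.ndarray, sg: SpaceGroupInfo, orth: np.ndarray
) -> float:
    """Minimum Cartesian distance from ``new`` to all symmetry images of the
    model (including its own images), over neighbouring cells."""
    pts = [xyz @ op.rot_array.T + op.tran_array for op in sg.ops]
    pts = np.concatenate(pts, axis=0) % 1.0
    diff = (pts - new + 0.5) % 1.0 - 0.5  # nearest-image fractional difference
    cart = diff @ orth.T
    dist = np.linalg.norm(cart, axis=1)
    return float(dist.min()) if len(dist) else np.inf


def make_toy_structure(
    sg_symbol: str,
    n_atoms: int,
    seed: int | np.random.Generator,
    cell: Sequence[float] | None = None,
    min_dist: float = 0.5,
) -> ToyModel:
    """Random point-atom structure with no special-position collisions.

    Atoms are drawn uniformly in the cell and rejected when any symmetry
    image (including self-images) comes within ``min_dist`` Angstrom.
    """
    sg = load_space_group(sg_symbol)
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    cell6 = tuple(cell) if cell is not None else DEFAULT_CELLS[sg.symbol]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    orth = np.array(gemmi.UnitCell(*cell6).orth.mat.tolist())
    xyz = np.empty((0, 3))
    attempts = 0
    while len(xyz) < n_atoms:
        attempts += 1
        if attempts > 2000 * n_atoms:
            raise RuntimeError(
                f"could not place {n_atoms} atoms at min_dist={min_dist} A in {sg.symbol}"
            )
        cand = rng.random(3)
        # check against existing atoms' images and the candidate's own images
        own = np.array([cand @ op.rot_array.T + op.tran_array for op in sg.ops[1:]]) % 1.0
        if len(own):
            diff = (own - cand + 0.5) % 1.0 - 0.5
            if np.linalg.norm(diff @ orth.T, axis=1).min() < min_dist:
                continue
        if len(xyz) and _min_sym_distance(xyz, cand, sg, orth) < min_dist:
            continue
        xyz = np.vstack([xyz, cand])
    return ToyModel(cell=cell6, sg_symbol=sg.symbol, xyz=xyz)


def _random_allowed_shift(
    sg: SpaceGroupInfo, rng: np.random.Generator
) -> tuple[float, float, float]:
    base = list(sg.discrete_shifts[rng.integers(len(sg.discrete_shifts))])
    for axis in sg.polar_axes:
        base[axis] = float(rng.random())
    return tuple(base)


def _fom_model(d: np.ndarray, sigma_eff: float) -> np.ndarray:
    """Luzzati-style resolution-dependent figure of merit.

    An effective coordinate error sigma_eff (Angstrom) attenuates phase
    reliability as exp(-0.5 (2 pi sigma_eff / d)^2), floored at 0.05.
    """
    return np.clip(np.exp(-0.5 * (2.0 * np.pi * sigma_eff / d) ** 2), 0.05, 1.0)


def make_partial_solution(
    model: ToyModel,
    fraction: float,
    coord_noise: float = 0.0,
    phase_noise: float = 0.0,
    shift_mode: Literal["none", "random_allowed"] = "random_allowed",
    seed: int | np.random.Generator = 0,
    truth: PhaseSet | None = None,
    d_min: float = 2.5,
    subset: np.ndarray | None = None,
    id: str = "partial",
) -> tuple[PhaseSet, tuple[float, float, float]]:
    """One noisy partial solution derived from a subset of a toy structure.

    A random atom subset of the given fraction is jittered by a Gaussian of
    ``coord_noise`` Angstrom, phased by direct summation on the truth's
    reflection list, degraded by wrapped-Gaussian phase noise
    (``phase_noise`` degrees) and finally moved to a random allowed origin.
    The applied shift is returned; comparing the solution against the
    unshifted truth recovers its negative (mod 1).  Amplitudes are the
    truth's; figures of merit follow the Luzzati-style model.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sg = load_space_group(model.sg_symbol)
    if truth is None:
        truth = phases_from_model(model, d_min, id="truth")
    if subset is None:
        n_keep = max(1, int(round(fraction * model.n_atoms)))
        subset = rng.choice(model.n_atoms, size=n_keep, replace=False)
    xyz = model.xyz[np.asarray(subset)]
    if coord_noise > 0:
        orth = np.array(gemmi.UnitCell(*model.cell).orth.mat.tolist())
        jitter_cart = rng.normal(0.0, coord_noise, size=xyz.shape)
        xyz = xyz + jitter_cart @ np.linalg.inv(orth).T
    sub_model = ToyModel(cell=model.cell, sg_symbol=model.sg_symbol, xyz=xyz)
    _, phi = structure_factors(sub_model, truth.hkl)
    if phase_noise > 0:
        phi = phi + rng.normal(0.0, phase_noise, size=phi.shape)
    d = truth.d_spacings()
    sigma_eff = coord_noise + 0.5 * (1.0 - fraction) + phase_noise / 240.0
    ps = PhaseSet(
        id=id,
        cell=model.cell,
        sg_symbol=model.sg_symbol,
        hkl=truth.hkl,
        F=truth.F.copy(),
        fom=_fom_model(d, sigma_eff),
        phi=phi % 360.0,
    )
    shift = (0.0, 0.0, 0.0)
    if shift_mode == "random_allowed":
        shift = _random_allowed_shift(sg, rng)
        ps = apply_shift(ps, shift)
    return ps, shift


def make_landscape(
    model: ToyModel,
    n_correct: int,
    n_wrong: int,
    fraction: float = 0.5,
    coord_noise: float = 0.1,
    phase_noise: float = 40.0,
    d_min: float = 2.5,
    seed: int = 0,
) -> SolutionLandscape:
    """Labelled landscape of correct and wrong partial solutions.

    Correct solutions share one randomly chosen core subset of the model
    (per-solution jitter and phase noise on top); wrong solutions are
    independent random structures of the same size.  Score metadata is drawn
    so that correct solutions have stochastically higher CC-like values with
    overlap between the two populations.
    """
    if n_correct + n_wrong < 2:
        raise ValueError("a landscape needs at least two solutions")
    rng = np.random.default_rng(seed)
    sg = load_space_group(model.sg_symbol)
    truth = phases_from_model(model, d_min, id="truth")
    n_keep = max(1, int(round(fraction * model.n_atoms)))
    core = rng.choice(model.n_atoms, size=n_keep, replace=False)
    solutions, labels, shifts = [], [], []
    for i in range(n_correct):
        ps, shift = make_partial_solution(
            model,
            fraction,
            coord_noise=coord_noise,
            phase_noise=phase_noise,
            seed=rng,
            truth=truth,
            subset=core,
            id=f"c{i:03d}",
        )
        ps.meta["CC"] = float(np.clip(rng.normal(30.0, 4.0), 5.0, 60.0))
        ps.meta["LLG"] = float(max(rng.normal(55.0, 12.0), 5.0))
        solutions.append(ps)
        labels.append("correct")
        shifts.append(shift)
    for i in range(n_wrong):
        decoy = make_toy_structure(
            model.sg_symbol, n_keep, rng, cell=model.cell
        )
        _, phi = structure_factors(decoy, truth.hkl)
        d = truth.d_spacings()
        ps = PhaseSet(
            id=f"w{i:03d}",
            cell=model.cell,
            sg_symbol=model.sg_symbol,
            hkl=truth.hkl,
            F=truth.F.copy(),
            fom=_fom_model(d, coord_noise + 0.5 * (1.0 - fraction)),
            phi=phi,
        )
        shift = _random_allowed_shift(sg, rng)
        ps = apply_shift(ps, shift)
        ps.meta["CC"] = float(np.clip(rng.normal(24.0, 4.0), 5.0, 60.0))
        ps.meta["LLG"] = float(max(rng.normal(40.0, 12.0), 5.0))
        solutions.append(ps)
        labels.append("wrong")
        shifts.append(shift)
    return SolutionLandscape(
        truth=truth,
        solutions=solutions,
        labels=labels,
        true_shifts=shifts,
        params={
            "n_atoms": model.n_atoms,
            "fraction": fraction,
            "coord_noise": coord_noise,
            "phase_noise": phase_noise,
            "d_min": d_min,
            "seed": seed,
        },
    )
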