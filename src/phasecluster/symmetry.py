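"""Space-group symmetry, polar directions and allowed origin shifts.

Phase sets coming from independent molecular-replacement solutions are only
comparable after referring them to a common origin.  Which origins are
equivalent is a property of the space group: a translation ``d`` of the whole
structure leaves the symmetry (and therefore every amplitude) unchanged
exactly when ``(R - I)·d`` is a lattice translation for every rotation part
``R`` of the group.  Along *polar* directions that condition holds for any
``d`` and the origin is continuously free; on the remaining axes only a small
discrete set of shifts survives.

Symmetry operators come from :mod:`gemmi`; the discrete-shift tables below
are hard coded for the supported groups and re-validated against the
normalizer condition the first time each group is loaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "SymOp",
    "SpaceGroupInfo",
    "UnsupportedSpaceGroupError",
    "load_space_group",
    "allowed_shift_generator",
    "resolution_of",
    "d_spacings",
    "shifts_equivalent",
    "SUPPORTED_SPACE_GROUPS",
]


class UnsupportedSpaceGroupError(ValueError):
    """Raised for space-group symbols outside the supported set."""


@dataclass(frozen=True)
class SymOp:
    """One symmetry operation in the fractional basis.

    ``rot`` is a 3x3 integer matrix with determinant +/-1, ``tran`` the
    translation part with components reduced to [0, 1).
    """

    rot: tuple[tuple[int, int, int], ...]
    tran: tuple[float, float, float]

    def __post_init__(self) -> None:
        det = round(float(np.linalg.det(np.asarray(self.rot, dtype=float))))
        if det not in (-1, 1):
            raise ValueError(f"rotation determinant must be +/-1, got {det}")
        if any(not (0.0 <= t < 1.0) for t in self.tran):
            raise ValueError("translations must be reduced mod 1")

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.asarray(self.tran, dtype=float)


@dataclass
class SpaceGroupInfo:
    """Symmetry context used by every origin-shift search.

    ``polar_mask`` marks axes along which the origin floats continuously;
    ``discrete_shifts`` lists the allowed discrete origin translations, with
    components on non-polar axes only (the zero shift is always present).
    """

    symbol: str
    ops: list[SymOp]
    polar_mask: tuple[bool, bool, bool]
    discrete_shifts: list[tuple[float, float, float]]
    centering: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def is_polar(self) -> bool:
        return any(self.polar_mask)

    @property
    def polar_axes(self) -> list[int]:
        return [i for i, p in enumerate(self.polar_mask) if p]

    @property
    def n_ops(self) -> int:
        return len(self.ops)


# Canonical short symbol -> (polar mask, discrete shift table).
# Shift components are given on the unit-cell torus; for centred lattices the
# table keeps the centring-equivalent copies (they produce identical phase
# changes on allowed reflections).
_HALF = (0.0, 0.5)
_QUARTERS = (0.0, 0.25, 0.5, 0.75)

_TABLES: dict[str, tuple[tuple[bool, bool, bool], list[tuple[float, float, float]]]] = {
    "P1": ((True, True, True), [(0.0, 0.0, 0.0)]),
    "P21": (
        (False, True, False),
        [(a, 0.0, c) for a in _HALF for c in _HALF],
    ),
    "C2": (
        (False, True, False),
        [(a, 0.0, c) for a in _HALF for c in _HALF],
    ),
    "P212121": (
        (False, False, False),
        [(a, b, c) for a in _HALF for b in _HALF for c in _HALF],
    ),
    "C2221": (
        (False, False, False),
        [(a, b, c) for a in _HALF for b in _HALF for c in _HALF],
    ),
    "F222": (
        (False, False, False),
        [(0.0, 0.0, 0.0), (0.0, 0.0, 0.5), (0.0, 0.5, 0.0), (0.0, 0.5, 0.5),
         (0.5, 0.0, 0.0), (0.5, 0.0, 0.5), (0.5, 0.5, 0.0), (0.5, 0.5, 0.5),
         (0.25, 0.25, 0.25), (0.25, 0.25, 0.75), (0.25, 0.75, 0.25),
         (0.25, 0.75, 0.75), (0.75, 0.25, 0.25), (0.75, 0.25, 0.75),
         (0.75, 0.75, 0.25), (0.75, 0.75, 0.75)],
    ),
    "F23": (
        (False, False, False),
        [(0.0, 0.0, 0.0), (0.0, 0.0, 0.5), (0.0, 0.5, 0.0), (0.0, 0.5, 0.5),
         (0.5, 0.0, 0.0), (0.5, 0.0, 0.5), (0.5, 0.5, 0.0), (0.5, 0.5, 0.5),
         (0.25, 0.25, 0.25), (0.25, 0.25, 0.75), (0.25, 0.75, 0.25),
         (0.25, 0.75, 0.75), (0.75, 0.25, 0.25), (0.75, 0.25, 0.75),
         (0.75, 0.75, 0.25), (0.75, 0.75, 0.75)],
    ),
    "P63": ((False, False, True), [(0.0, 0.0, 0.0)]),
}

SUPPORTED_SPACE_GROUPS = tuple(_TABLES)

# Unicode subscript digits occasionally used in screw-axis symbols.
_SUBSCRIPT_MAP = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def _normalize_symbol(symbol: str) -> str:
    """Map compact/spaced/subscripted HM dialects onto gemmi's spelling."""
    cleaned = symbol.strip().translate(_SUBSCRIPT_MAP)
    sg = gemmi.find_spacegroup_by_name(cleaned)
    if sg is None:
        # compact dialect without spaces, e.g. "P212121"
        sg = gemmi.find_spacegroup_by_name(" ".join(cleaned.split()).replace(" ", ""))
    if sg is None:
        raise UnsupportedSpaceGroupError(f"unknown space-group symbol: {symbol!r}")
    return sg.short_name()


def _gemmi_ops(symbol: str) -> tuple[list[SymOp], list[tuple[float, float, float]]]:
    gops = gemmi.find_spacegroup_by_name(symbol).operations()
    den = float(gemmi.Op.DEN)
    ops = []
    for op in gops:  # iterates sym x centring products
        rot = tuple(tuple(int(round(v / den)) for v in row) for row in op.rot)
        tran = tuple((t / den) % 1.0 for t in op.tran)
        ops.append(SymOp(rot, tran))
    cen = [tuple((c / den) % 1.0 for c in cv) for cv in gops.cen_ops]
    return ops, cen


def _derive_shift_set(
    ops: Sequence[SymOp],
    centering: Sequence[tuple[float, float, float]],
    polar_mask: tuple[bool, bool, bool],
    denom: int = 12,
) -> set[tuple[float, float, float]]:
    """All grid shifts satisfying the normalizer condition (R-I)d in lattice."""
    rots = {tuple(map(tuple, op.rot)) for op in ops}
    cen = np.asarray(list(centering) or [(0.0, 0.0, 0.0)], dtype=float)
    grid = np.arange(denom) / denom
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    for axis, polar in enumerate(polar_mask):
        if polar:
            cand = cand[cand[:, axis] == 0.0]
    keep = np.ones(len(cand), dtype=bool)
    for rot in rots:
        R = np.asarray(rot, dtype=float)
        v = (cand @ R.T - cand) % 1.0
        # congruent to some centring vector mod 1?
        diff = (v[:, None, :] - cen[None, :, :]) % 1.0
        diff = np.minimum(diff, 1.0 - diff)
        keep &= (diff.max(axis=2) < 1e-9).any(axis=1)
    return {tuple(np.round(row, 9)) for row in cand[keep]}


@lru_cache(maxsize=None)
def load_space_group(symbol: str) -> SpaceGroupInfo:
    """Build the :class:`SpaceGroupInfo` for a supported Hermann-Mauguin symbol.

    Both compact (``"P212121"``) and spaced (``"P 21 21 21"``) spellings are
    accepted, as are unicode subscripts.  The hard-coded shift table is
    checked against the normalizer condition on first load.
    """
    name = _normalize_symbol(symbol)
    if name not in _TABLES:
        raise UnsupportedSpaceGroupError(
            f"space group {symbol!r} ({name}) is not supported; "
            f"supported groups: {', '.join(SUPPORTED_SPACE_GROUPS)}"
        )
    polar_mask, shifts = _TABLES[name]
    ops, cen = _gemmi_ops(name)
    derived = _derive_shift_set(ops, cen, polar_mask)
    table = {tuple(np.round(s, 9)) for s in shifts}
    if table != derived:
        raise AssertionError(
            f"origin-shift table for {name} fails the normalizer condition: "
            f"table has {sorted(table)}, derivation gives {sorted(derived)}"
        )
    if (0.0, 0.0, 0.0) not in table:
        raise AssertionError(f"zero shift missing from table for {name}")
    return SpaceGroupInfo(
        symbol=name,
        ops=ops,
        polar_mask=polar_mask,
        discrete_shifts=[tuple(s) for s in sorted(table)],
        centering=cen,
    )


def allowed_shift_generator(
    sg: SpaceGroupInfo, polar_grid: int
) -> Iterator[tuple[float, float, float]]:
    """Yield every allowed origin shift, sampling polar axes on a grid.

    Discrete shifts are combined with ``polar_grid`` samples per polar axis;
    for nonpolar groups the generator yields exactly ``sg.discrete_shifts``.
    """
    if polar_grid < 1:
        raise ValueError("polar_grid must be >= 1")
    axes = sg.polar_axes
    if not axes:
        yield from (tuple(s) for s in sg.discrete_shifts)
        return
    samples = np.arange(polar_grid) / polar_grid
    for base in sg.discrete_shifts:
        grids = np.meshgrid(*[samples] * len(axes), indexing="ij")
        combos = np.column_stack([g.ravel() for g in grids])
        for combo in combos:
            shift = list(base)
            for axis, value in zip(axes, combo):
                shift[axis] = float(value)
            yield tuple(shift)


def _reciprocal_metric(cell: Sequence[float]) -> np.ndarray:
    uc = gemmi.UnitCell(*cell)
    orth = np.array(uc.orth.mat.tolist())
    return np.linalg.inv(orth.T @ orth)


def d_spacings(hkl: np.ndarray, cell: Sequence[float]) -> np.ndarray:
    """Vectorized triclinic d-spacing (Angstrom) for an (n, 3) index array."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    gstar = _reciprocal_metric(cell)
    inv_d2 = np.einsum("ij,jk,ik->i", hkl, gstar, hkl)
    return 1.0 / np.sqrt(inv_d2)


def shifts_equivalent(
    t1: Sequence[float],
    t2: Sequence[float],
    sg: SpaceGroupInfo,
    tol: float = 0.002,
) -> bool:
    """Whether two origin shifts act identically on allowed reflections.

    Shifts differing by a lattice translation (including centring vectors)
    change every allowed phase by a multiple of 360 degrees, so shift
    recovery is only defined modulo the centring translations.
    """
    diff = (np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float)) % 1.0
    cens = np.asarray(list(sg.centering) or [(0.0, 0.0, 0.0)], dtype=float)
    for c in cens:
        r = (diff - c) % 1.0
        r = np.minimum(r, 1.0 - r)
        if np.all(r <= tol):
            return True
    return False


def resolution_of(hkl: Sequence[int], cell: Sequence[float]) -> float:
    """d-spacing of a single reflection; (0,0,0) is not a reflection."""
    h = tuple(int(v) for v in hkl)
    if h == (0, 0, 0):
        raise ValueError("(0,0,0) is not a valid reflection")
    return float(d_spacings(np.array([h]), cell)[0])
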