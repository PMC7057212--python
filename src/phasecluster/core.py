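"""Phase-set comparison and merging engine.

Two phase sets are compared through the weighted mean phase difference
(wMPD) and the map correlation coefficient (mapCC), both computed in
reciprocal space:

    wMPD  = sum_h w_h |dphi_h|_wrapped / sum_h w_h ,   w_h = m1 m2 F^2
    mapCC = sum_h m1 m2 F1 F2 cos(dphi_h)
            / sqrt( sum_h (m1 F1)^2  *  sum_h (m2 F2)^2 )

wMPD is 0 for identical sets and converges to 90 degrees for uncorrelated
phases; mapCC is 1 and 0 respectively.  Because the space group leaves the
origin partially free, every comparison first resolves the relative origin
shift: exhaustive enumeration of the allowed discrete shifts for nonpolar
groups, and for polar groups either a layer-seeded estimate refined against
all reflections ("sparse") or an FFT translation search over the polar axes
followed by a local polish ("fft").

Consistent sets are merged into a weighted circular average whose combined
figure of merit measures the coherence of the contributing phases; the
merge is iterated, re-referencing against the running average, which is the
referential-clustering step the higher-level orchestration builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .phase_io import PhaseSet
from .symmetry import SpaceGroupInfo, load_space_group

__all__ = [
    "ComparisonResult",
    "MergeRecord",
    "MergedPhaseSet",
    "IndexingError",
    "DegenerateWeightError",
    "WrongAlgorithmError",
    "InsufficientLayerError",
    "delta_phi",
    "wmpd",
    "mapcc",
    "apply_shift",
    "best_shift_discrete",
    "best_shift_sparse",
    "best_shift_fft",
    "best_shift",
    "merge_sets",
    "referential_cluster",
]


class IndexingError(ValueError):
    """Phase sets do not share the same reflection list."""


class DegenerateWeightError(ValueError):
    """All comparison weights vanish."""


class WrongAlgorithmError(ValueError):
    """Shift-search algorithm does not apply to this space group."""


class InsufficientLayerError(ValueError):
    """The sparse search has no layer-1 reflections to seed from."""


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one ordered phase-set comparison at its best origin shift."""

    wmpd: float  # degrees, minimum over the shifts examined
    mapcc: float
    shift: tuple[float, float, float]
    n_common: int
    algorithm: Literal["discrete", "sparse", "fft"]


@dataclass(frozen=True)
class MergeRecord:
    member_id: str
    weight: float
    shift_applied: tuple[float, float, float]
    wmpd_to_reference: float


@dataclass
class MergedPhaseSet:
    """Averaged phase set plus the bookkeeping of its members."""

    phase_set: PhaseSet
    members: list[MergeRecord]
    cycles_run: int = 1

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


def delta_phi(a, b):
    """Wrapped absolute phase difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def _check_common(ps1: PhaseSet, ps2: PhaseSet) -> None:
    if ps1.hkl.shape != ps2.hkl.shape or not np.array_equal(ps1.hkl, ps2.hkl):
        raise IndexingError(
            f"phase sets {ps1.id!r} and {ps2.id!r} do not share the same "
            "reflection list (same indexing convention required)"
        )


def _weights(ps1: PhaseSet, ps2: PhaseSet) -> np.ndarray:
    # fom product times squared amplitude (sets share observed F in the
    # intended use; the geometric product covers slight divergence).
    w = ps1.fom * ps2.fom * ps1.F * ps2.F
    if not np.any(w > 0):
        raise DegenerateWeightError(
            f"all comparison weights are zero for {ps1.id!r} vs {ps2.id!r}"
        )
    return w


def wmpd(ps1: PhaseSet, ps2: PhaseSet) -> float:
    """Weighted mean phase difference in degrees (no shift search)."""
    _check_common(ps1, ps2)
    w = _weights(ps1, ps2)
    return float(np.sum(w * delta_phi(ps1.phi, ps2.phi)) / np.sum(w))


def mapcc(ps1: PhaseSet, ps2: PhaseSet) -> float:
    """Map correlation coefficient, computed in reciprocal space.

    Equals the real-space correlation of the two figure-of-merit-weighted
    Fourier syntheses (F000 excluded, means removed).
    """
    _check_common(ps1, ps2)
    e1 = ps1.fom * ps1.F
    e2 = ps2.fom * ps2.F
    denom = np.sqrt(np.sum(e1**2) * np.sum(e2**2))
    if denom == 0:
        raise DegenerateWeightError("zero-amplitude phase set in mapcc")
    dphi = np.radians(ps1.phi - ps2.phi)
    return float(np.sum(e1 * e2 * np.cos(dphi)) / denom)


def apply_shift(ps: PhaseSet, t: Sequence[float]) -> PhaseSet:
    """Move the origin of a phase set by fractional translation ``t``.

    A model moved by +t changes each phase as phi' = phi - 360 h.t.
    """
    t = np.asarray(t, dtype=float)
    phi = (ps.phi - 360.0 * (ps.hkl @ t)) % 360.0
    return ps.replace(phi=phi)


class _PairContext:
    """Precomputed quantities for scanning shifts between a fixed pair.

    Applying shift ``t`` to ps2 turns the phase difference into
    dphi(t) = (phi1 - phi2) + 360 h.t, so wMPD(t) needs only the cached
    raw difference and weights.
    """

    def __init__(self, ps1: PhaseSet, ps2: PhaseSet):
        _check_common(ps1, ps2)
        self.hkl = ps1.hkl
        self.w = _weights(ps1, ps2)
        self.wsum = float(np.sum(self.w))
        self.dphi0 = ps1.phi - ps2.phi  # degrees, unwrapped
        self.e1 = ps1.fom * ps1.F
        self.e2 = ps2.fom * ps2.F
        self.n = len(self.hkl)

    def wmpd_at(self, t: np.ndarray) -> float:
        d = self.dphi0 + 360.0 * (self.hkl @ t)
        d = np.abs((d + 180.0) % 360.0 - 180.0)
        return float(np.sum(self.w * d) / self.wsum)

    def mapcc_at(self, t: np.ndarray) -> float:
        d = np.radians(self.dphi0 + 360.0 * (self.hkl @ t))
        denom = np.sqrt(np.sum(self.e1**2) * np.sum(self.e2**2))
        return float(np.sum(self.e1 * self.e2 * np.cos(d)) / denom)


def _result(ctx: _PairContext, t: np.ndarray, algorithm: str) -> ComparisonResult:
    t = np.round(np.asarray(t, dtype=float) % 1.0, 9) % 1.0
    return ComparisonResult(
        wmpd=ctx.wmpd_at(t),
        mapcc=ctx.mapcc_at(t),
        shift=tuple(float(v) for v in t),
        n_common=ctx.n,
        algorithm=algorithm,  # type: ignore[arg-type]
    )


def best_shift_discrete(
    ps1: PhaseSet, ps2: PhaseSet, sg: SpaceGroupInfo
) -> ComparisonResult:
    """Exhaustive search over the allowed discrete origin shifts."""
    if sg.is_polar:
        raise WrongAlgorithmError(
            f"{sg.symbol} has polar axes; use the sparse or FFT search"
        )
    ctx = _PairContext(ps1, ps2)
    best_t, best_val = None, np.inf
    for d in sg.discrete_shifts:
        val = ctx.wmpd_at(np.asarray(d))
        if val < best_val - 1e-12:  # ties resolved to first in enumeration
            best_t, best_val = np.asarray(d), val
    return _result(ctx, best_t, "discrete")


def _refine_polar(
    ctx: _PairContext, t: np.ndarray, axes: list[int], halfwidth: float, sweeps: int = 2
) -> np.ndarray:
    """Coordinate-wise bounded minimization of wMPD around ``t``."""
    t = np.asarray(t, dtype=float).copy()
    for _ in range(sweeps):
        for axis in axes:
            def f(x, axis=axis):
                tt = t.copy()
                tt[axis] = x
                return ctx.wmpd_at(tt)

            res = minimize_scalar(
                f,
                bounds=(t[axis] - halfwidth, t[axis] + halfwidth),
                method="bounded",
                options={"xatol": 1e-6},
            )
            t[axis] = float(res.x)
    return t % 1.0


def best_shift_sparse(
    ps1: PhaseSet, ps2: PhaseSet, sg: SpaceGroupInfo
) -> ComparisonResult:
    """Layer-seeded polar shift search.

    For each allowed discrete shift the polar component is first estimated
    from the circular mean of the phase differences on the layer of polar
    index 1 (where the difference equals 360 t plus noise), then refined
    against all reflections by bounded 1-D minimization of the wMPD.
    """
    if not sg.is_polar:
        raise WrongAlgorithmError(f"{sg.symbol} is nonpolar; use the discrete search")
    ctx = _PairContext(ps1, ps2)
    axes = sg.polar_axes
    layers = {}
    for axis in axes:
        mask = ctx.hkl[:, axis] == 1
        for other in axes:
            if other != axis:
                mask &= ctx.hkl[:, other] == 0
        if not np.any(mask):
            raise InsufficientLayerError(
                f"no layer-1 reflections along axis {axis} in {sg.symbol}"
            )
        layers[axis] = mask
    best_t, best_val = None, np.inf
    for d in sg.discrete_shifts:
        t = np.asarray(d, dtype=float).copy()
        for axis in axes:
            mask = layers[axis]
            # want dphi0 + 360 h.t ~ 0 on the layer; h.t = (h.d) + t_axis there
            resid = np.radians(ctx.dphi0[mask] + 360.0 * (ctx.hkl[mask] @ t))
            mean = np.angle(np.sum(ctx.w[mask] * np.exp(1j * resid)))
            t[axis] = (-mean / (2.0 * np.pi)) % 1.0
        t = _refine_polar(ctx, t, axes, halfwidth=0.05)
        val = ctx.wmpd_at(t)
        if val < best_val - 1e-12:
            best_t, best_val = t, val
    return _result(ctx, best_t, "sparse")


def best_shift_fft(
    ps1: PhaseSet, ps2: PhaseSet, sg: SpaceGroupInfo, grid: int = 64
) -> ComparisonResult:
    """FFT translation search over the polar axes.

    For each discrete candidate the weighted phase-difference coefficients
    G_h = w_h exp(i dphi_h) are accumulated on a grid indexed by the polar
    components of h; the translation function T(t) = Re sum_h G_h
    exp(2 pi i h.t) is then evaluated on the whole polar grid by one inverse
    FFT, and the argmax is polished by a local 1-D refinement of the wMPD
    within one grid cell per axis.
    """
    if not sg.is_polar:
        raise WrongAlgorithmError(f"{sg.symbol} is nonpolar; use the discrete search")
    if grid < 32 or (grid & (grid - 1)) != 0:
        raise ValueError("grid must be a power of two >= 32")
    ctx = _PairContext(ps1, ps2)
    axes = sg.polar_axes
    best_t, best_val = None, np.inf
    for d in sg.discrete_shifts:
        dvec = np.asarray(d, dtype=float)
        g = ctx.w * np.exp(1j * np.radians(ctx.dphi0 + 360.0 * (ctx.hkl @ dvec)))
        shape = (grid,) * len(axes)
        acc = np.zeros(shape, dtype=complex)
        idx = tuple(np.mod(ctx.hkl[:, axis], grid) for axis in axes)
        np.add.at(acc, idx, g)
        tmap = np.fft.ifftn(acc).real  # T(j/grid) up to a positive factor
        argmax = np.unravel_index(int(np.argmax(tmap)), shape)
        t = dvec.copy()
        for axis, j in zip(axes, argmax):
            t[axis] = j / grid
        t = _refine_polar(ctx, t, axes, halfwidth=1.0 / grid)
        val = ctx.wmpd_at(t)
        if val < best_val - 1e-12:
            best_t, best_val = t, val
    return _result(ctx, best_t, "fft")


def best_shift(
    ps1: PhaseSet,
    ps2: PhaseSet,
    sg: SpaceGroupInfo | str,
    algorithm: Literal["auto", "discrete", "sparse", "fft"] = "auto",
    grid: int = 64,
) -> ComparisonResult:
    """Dispatch to the appropriate origin-shift search.

    Nonpolar groups always use the exhaustive discrete search; the
    ``algorithm`` argument selects the polar search: ``auto`` takes the FFT
    when every axis is polar (P1) and otherwise the sparse search with an
    FFT fallback when no seeding layer exists.
    """
    if isinstance(sg, str):
        sg = load_space_group(sg)
    if not sg.is_polar:
        return best_shift_discrete(ps1, ps2, sg)
    if algorithm == "discrete":
        return best_shift_discrete(ps1, ps2, sg)  # raises WrongAlgorithmError
    if algorithm == "sparse":
        return best_shift_sparse(ps1, ps2, sg)
    if algorithm == "fft":
        return best_shift_fft(ps1, ps2, sg, grid=grid)
    # auto, polar
    if all(sg.polar_mask):
        return best_shift_fft(ps1, ps2, sg, grid=grid)
    try:
        return best_shift_sparse(ps1, ps2, sg)
    except InsufficientLayerError:
        return best_shift_fft(ps1, ps2, sg, grid=grid)


def merge_sets(
    reference: PhaseSet,
    members: Sequence[tuple[PhaseSet, ComparisonResult]],
    tolerance: float,
    strict_amplitudes: bool = True,
) -> MergedPhaseSet:
    """Weighted circular average of a reference and its consistent members.

    Each member enters with weight (tolerance - wMPD)/tolerance after its
    origin shift is applied; the reference has weight 1.  The combined
    figure of merit is the resultant length of the weighted phase vectors —
    near 1 where members agree, near 0 where they cancel.  Amplitudes are
    taken from the reference (all sets share the observed amplitudes in the
    intended use; divergent amplitude arrays are rejected).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    records = [MergeRecord(reference.id, 1.0, (0.0, 0.0, 0.0), 0.0)]
    vec = reference.fom * np.exp(1j * np.radians(reference.phi))
    norm = reference.fom.copy()
    for ps, cmp_res in members:
        _check_common(reference, ps)
        if strict_amplitudes and not np.allclose(ps.F, reference.F, rtol=1e-6, atol=1e-8):
            raise ValueError(
                f"member {ps.id!r} has amplitudes diverging from the reference; "
                "merged sets must share observed amplitudes"
            )
        if cmp_res.wmpd > tolerance + 1e-9:
            raise ValueError(
                f"member {ps.id!r} has wMPD {cmp_res.wmpd:.2f} above tolerance"
            )
        shifted = apply_shift(ps, cmp_res.shift)
        weight = max((tolerance - cmp_res.wmpd) / tolerance, 1e-6)
        vec = vec + weight * shifted.fom * np.exp(1j * np.radians(shifted.phi))
        norm = norm + weight * shifted.fom
        records.append(MergeRecord(ps.id, weight, cmp_res.shift, cmp_res.wmpd))
    phi = np.degrees(np.angle(vec)) % 360.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fom = np.where(norm > 0, np.abs(vec) / np.where(norm > 0, norm, 1.0), 0.0)
    fom = np.clip(fom, 0.0, 1.0)
    merged = reference.replace(
        id=f"avg[{reference.id}]" if members else reference.id,
        phi=phi,
        fom=fom,
        meta=dict(reference.meta),
    )
    return MergedPhaseSet(phase_set=merged, members=records)


def _form_cluster(
    reference: PhaseSet,
    candidates: Sequence[PhaseSet],
    sg: SpaceGroupInfo,
    tolerance: float,
    cycles: int,
    algorithm: str = "auto",
    grid: int = 64,
    compare_fn=None,
) -> tuple[MergedPhaseSet, list[int]]:
    """Grow one cluster around a reference by iterated re-referencing.

    Cycle 1 compares every candidate to the raw reference; later cycles
    compare to the running weighted average.  Membership is re-decided from
    scratch each cycle; iteration stops early once it is stable.  Admission
    depends only on the (candidate, current reference) pair, so the
    comparison loop may be chunked/parallelized without changing the result.
    """
    if compare_fn is None:
        def compare_fn(ref, cands):
            return [best_shift(ref, ps, sg, algorithm=algorithm, grid=grid) for ps in cands]

    current_ref = reference
    admitted: list[int] = []
    merged = merge_sets(reference, [], tolerance)
    cycles_run = 0
    for _ in range(max(1, cycles)):
        cycles_run += 1
        results = compare_fn(current_ref, candidates)
        new_admitted = [i for i, r in enumerate(results) if r.wmpd <= tolerance]
        merged = merge_sets(
            reference, [(candidates[i], results[i]) for i in new_admitted], tolerance
        )
        stable = new_admitted == admitted
        admitted = new_admitted
        if stable:
            break
        current_ref = merged.phase_set
    merged.cycles_run = cycles_run
    return merged, admitted


def referential_cluster(
    inputs: Sequence[PhaseSet],
    sg: SpaceGroupInfo | str,
    tolerance: float,
    cycles: int = 3,
    seq_continue: bool = False,
    algorithm: str = "auto",
    grid: int = 64,
) -> tuple[list[MergedPhaseSet], list[str]]:
    """Referential clustering of an ordered list of phase sets.

    The head of the list seeds a cluster; all remaining sets whose
    shift-resolved wMPD to the (iteratively averaged) reference stays within
    the tolerance are merged and removed, and the procedure repeats on the
    remainder.  With ``seq_continue`` a reference that clusters nothing is
    set aside as a leftover and the next entry is tried, so single-member
    clusters are never emitted; without it they are kept as clusters of one.

    Returns the clusters in formation order plus the leftover ids.
    """
    if isinstance(sg, str):
        sg = load_space_group(sg)
    pool = list(inputs)
    clusters: list[MergedPhaseSet] = []
    leftovers: list[str] = []
    while pool:
        reference = pool.pop(0)
        merged, admitted = _form_cluster(
            reference, pool, sg, tolerance, cycles, algorithm=algorithm, grid=grid
        )
        if admitted:
            clusters.append(merged)
            pool = [ps for i, ps in enumerate(pool) if i not in set(admitted)]
        elif seq_continue:
            leftovers.append(reference.id)
        else:
            clusters.append(merged)
    return clusters, leftovers
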