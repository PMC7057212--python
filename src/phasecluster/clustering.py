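"""Clustering orchestration: sorting, chunked parallel rounds, sequential
fallback, resolution-limited comparison with full-resolution re-merging, and
the one-step / two-step protocols.

The orchestration sits on top of the referential-clustering engine in
:mod:`phasecluster.core`.  Solutions are sorted by their phasing figures of
merit, compared against a common reference at a reduced resolution (4.0 A by
default; 3.5 A in P1, where the fully unconstrained origin makes the shift
determination more error-prone), and the clusters found are re-merged at
full resolution.  While the pool is large, the comparison loop for each
reference is distributed over workers in contiguous chunks; admission
depends only on the (candidate, reference) pair, so chunking never changes
membership.  Once the pool shrinks below ``minchunk`` the sequential mode
takes over, advancing the reference through the remaining list until a
multi-member cluster forms.

Multi-copy asymmetric units are handled by the two-step protocol: clusters
are formed within each rotation group first, and the merged sets are then
combined across groups at a higher tolerance (87 degrees by default), since
solutions on different monomers carry complementary information and sit at
larger mutual phase differences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import (
    ComparisonResult,
    MergedPhaseSet,
    MergeRecord,
    best_shift,
    merge_sets,
    referential_cluster,
    _form_cluster,
    _PairContext,
)
from .phase_io import PhaseSet, cut_resolution
from .symmetry import SpaceGroupInfo, load_space_group

__all__ = [
    "ClusteringConfig",
    "ClusterEntry",
    "ClusterReport",
    "sort_solutions",
    "parallel_round",
    "sequential_round",
    "run_one_step",
    "run_two_step",
    "wmpe_table",
    "NONRANDOM_WMPE",
]

# Phase sets with a weighted mean phase error below this value carry real
# information about the target structure.
NONRANDOM_WMPE = 80.0


def _default_cores() -> int:
    n = os.cpu_count() or 1
    return max(1, min(n - 1, 10))


@dataclass
class ClusteringConfig:
    """Parameters of a clustering run.

    ``tolerance`` admits overlapping solutions (60 degrees); the second-round
    tolerance is looser (87 degrees) because round-1 averages from different
    monomers share less. Comparison runs at ``resolution_comparison``
    (defaulting to 4.0 A, or 3.5 A in P1 when left unset); merging of the
    final clusters uses all data.  ``minchunk`` is the pool size at which the
    parallel rounds hand over to the sequential algorithm.
    """

    tolerance: float = 60.0
    tolerance_round2: float = 87.0
    resolution_comparison: float | None = None
    cycles: int = 3
    minchunk: int | None = None
    n_cores: int = field(default_factory=_default_cores)
    polar_algorithm: Literal["fft", "sparse", "auto"] = "auto"
    grid: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tolerance <= self.tolerance_round2 <= 180:
            raise ValueError("need 0 < tolerance <= tolerance_round2 <= 180")
        if self.n_cores < 1:
            raise ValueError("n_cores must be >= 1")
        if self.minchunk is None:
            self.minchunk = 2 * self.n_cores

    def comparison_resolution(self, sg: SpaceGroupInfo) -> float:
        if self.resolution_comparison is not None:
            return self.resolution_comparison
        return 3.5 if all(sg.polar_mask) else 4.0


@dataclass
class ClusterEntry:
    """One cluster of a report: the merged set plus provenance."""

    merged: PhaseSet
    members: list[MergeRecord]
    round: int = 1
    reference_id: str = ""
    top_meta: dict = field(default_factory=dict)

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterReport:
    """Clusters plus leftovers; together they partition the input ids."""

    clusters: list[ClusterEntry]
    leftovers: list[str]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, entry in enumerate(self.clusters):
            for rec in entry.members:
                rows.append(
                    {
                        "cluster": i,
                        "size": entry.size,
                        "round": entry.round,
                        "reference": entry.reference_id,
                        "member": rec.member_id,
                        "weight": rec.weight,
                        "shift_x": rec.shift_applied[0],
                        "shift_y": rec.shift_applied[1],
                        "shift_z": rec.shift_applied[2],
                        "wmpd": rec.wmpd_to_reference,
                        **{f"top_{k}": v for k, v in entry.top_meta.items()},
                    }
                )
        for lid in self.leftovers:
            rows.append({"cluster": -1, "size": 1, "member": lid})
        return pd.DataFrame(rows)


def sort_solutions(inputs: Sequence[PhaseSet]) -> list[PhaseSet]:
    """Stable sort, best phasing scores first (CC, then LLG, then input order).

    Sets carrying scores precede sets without any.
    """
    def key(item):
        idx, ps = item
        cc = ps.meta.get("CC")
        llg = ps.meta.get("LLG")
        has_score = cc is not None or llg is not None
        return (
            0 if has_score else 1,
            -(cc if cc is not None else -np.inf),
            -(llg if llg is not None else -np.inf),
            idx,
        )

    return [ps for _, ps in sorted(enumerate(inputs), key=key)]


def _chunked_compare(cfg: ClusteringConfig, sg: SpaceGroupInfo):
    """Comparison callback distributing candidates over contiguous chunks."""

    def compare(reference: PhaseSet, candidates: Sequence[PhaseSet]) -> list[ComparisonResult]:
        if not candidates:
            return []
        n_jobs = min(cfg.n_cores, len(candidates))
        if n_jobs == 1:
            return [
                best_shift(reference, ps, sg, algorithm=cfg.polar_algorithm, grid=cfg.grid)
                for ps in candidates
            ]
        chunks = np.array_split(np.arange(len(candidates)), n_jobs)
        out = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(lambda idx: [
                best_shift(reference, candidates[i], sg,
                           algorithm=cfg.polar_algorithm, grid=cfg.grid)
                for i in idx
            ])(chunk)
            for chunk in chunks
        )
        results: list[ComparisonResult] = []
        for part in out:  # aggregation in chunk order keeps determinism
            results.extend(part)
        return results

    return compare


def parallel_round(
    pool: list[PhaseSet], cfg: ClusteringConfig, sg: SpaceGroupInfo
) -> tuple[list[MergedPhaseSet], list[str], list[PhaseSet]]:
    """Chunked clustering rounds against successive common references.

    The head of the pool is the common reference; all other sets are compared
    to it in parallel chunks, admitted sets are merged and removed, and the
    next head seeds a fresh round.  Runs while the pool is larger than
    ``minchunk``; references that cluster nothing become leftovers.
    """
    compare = _chunked_compare(cfg, sg)
    clusters: list[MergedPhaseSet] = []
    leftovers: list[str] = []
    pool = list(pool)
    while len(pool) > cfg.minchunk:
        reference = pool.pop(0)
        merged, admitted = _form_cluster(
            reference, pool, sg, cfg.tolerance, cfg.cycles, compare_fn=compare
        )
        if admitted:
            clusters.append(merged)
            admitted_set = set(admitted)
            pool = [ps for i, ps in enumerate(pool) if i not in admitted_set]
        else:
            leftovers.append(reference.id)
    return clusters, leftovers, pool


def sequential_round(
    pool: list[PhaseSet], cfg: ClusteringConfig, sg: SpaceGroupInfo
) -> tuple[list[MergedPhaseSet], list[str]]:
    """Sequential referential clustering of the remaining pool.

    Delegates to the engine with reference continuation: every entry is
    tried as a reference in turn and entries that cluster nothing end up as
    leftovers.
    """
    if not pool:
        return [], []
    clusters, leftovers = referential_cluster(
        pool,
        sg,
        cfg.tolerance,
        cycles=cfg.cycles,
        seq_continue=True,
        algorithm=cfg.polar_algorithm,
        grid=cfg.grid,
    )
    return clusters, leftovers


def _remerge_full_resolution(
    cluster: MergedPhaseSet,
    by_id: dict[str, PhaseSet],
    tolerance: float,
) -> tuple[PhaseSet, list[MergeRecord]]:
    """Rebuild a cluster from the full-resolution sets.

    Membership and origin shifts come from the comparison stage; the wMPD
    entering the merge weights is re-evaluated against the full data at the
    fixed shift.
    """
    ref_rec = cluster.members[0]
    reference = by_id[ref_rec.member_id]
    pairs = []
    for rec in cluster.members[1:]:
        ps = by_id[rec.member_id]
        ctx = _PairContext(reference, ps)
        t = np.asarray(rec.shift_applied)
        full_wmpd = ctx.wmpd_at(t)
        res = ComparisonResult(
            wmpd=min(full_wmpd, tolerance),  # keep admission from the comparison stage
            mapcc=ctx.mapcc_at(t),
            shift=rec.shift_applied,
            n_common=ctx.n,
            algorithm="discrete",
        )
        pairs.append((ps, res))
    merged = merge_sets(reference, pairs, tolerance)
    return merged.phase_set, merged.members


def run_one_step(
    inputs: Sequence[PhaseSet], cfg: ClusteringConfig | None = None
) -> ClusterReport:
    """Single round of phase clustering over one pool of solutions.

    Solutions are sorted by score, compared at the comparison resolution
    through parallel rounds and then the sequential stage, and the final
    clusters are re-merged with all reflections.
    """
    cfg = cfg or ClusteringConfig()
    inputs = list(inputs)
    if not inputs:
        return ClusterReport(clusters=[], leftovers=[])
    cells = {ps.cell for ps in inputs}
    sgs = {load_space_group(ps.sg_symbol).symbol for ps in inputs}
    if len(cells) > 1 or len(sgs) > 1:
        raise ValueError("all phase sets must share one cell and space group")
    sg = load_space_group(inputs[0].sg_symbol)
    ordered = sort_solutions(inputs)
    d_cmp = cfg.comparison_resolution(sg)
    cut = [cut_resolution(ps, d_cmp) for ps in ordered]
    cut = [c if len(c) else o for c, o in zip(cut, ordered)]  # guard tiny sets
    par_clusters, par_left, remaining = parallel_round(cut, cfg, sg)
    seq_clusters, seq_left = sequential_round(remaining, cfg, sg)
    by_id = {ps.id: ps for ps in inputs}
    entries = []
    for cl in par_clusters + seq_clusters:
        if cl.size == 1:
            # singleton cluster from the sequential stage edge cases
            entries.append(
                ClusterEntry(
                    merged=by_id[cl.members[0].member_id],
                    members=cl.members,
                    reference_id=cl.members[0].member_id,
                    top_meta=dict(by_id[cl.members[0].member_id].meta),
                )
            )
            continue
        merged_full, records = _remerge_full_resolution(cl, by_id, cfg.tolerance)
        metas = [by_id[m.member_id].meta for m in cl.members if by_id[m.member_id].meta]
        top = max(metas, key=lambda m: m.get("CC", m.get("LLG", 0.0)), default={})
        entries.append(
            ClusterEntry(
                merged=merged_full,
                members=records,
                reference_id=cl.members[0].member_id,
                top_meta=dict(top),
            )
        )
    return ClusterReport(clusters=entries, leftovers=par_left + seq_left)


def run_two_step(
    groups: Sequence[Sequence[PhaseSet]], cfg: ClusteringConfig | None = None
) -> ClusterReport:
    """Within-group clustering followed by a looser cross-group round.

    Round 1 applies :func:`run_one_step` to each group (rotation cluster) at
    the base tolerance; round 2 clusters the merged round-1 sets across all
    groups at ``tolerance_round2``.  Only round-1 clusters enter round 2;
    leftovers stay leftovers.
    """
    cfg = cfg or ClusteringConfig()
    if not groups:
        raise ValueError("need at least one group")
    round1: list[ClusterReport] = [run_one_step(group, cfg) for group in groups]
    merged_sets: list[PhaseSet] = []
    provenance: dict[str, ClusterEntry] = {}
    leftovers: list[str] = []
    for g, rep in enumerate(round1):
        for i, entry in enumerate(rep.clusters):
            tagged = entry.merged.replace(id=f"g{g}.c{i}")
            tagged.meta = dict(entry.top_meta)
            merged_sets.append(tagged)
            provenance[tagged.id] = entry
        leftovers.extend(rep.leftovers)
    if len(merged_sets) < 2:
        entries = [
            ClusterEntry(
                merged=ps,
                members=provenance[ps.id].members,
                round=2,
                reference_id=provenance[ps.id].reference_id,
                top_meta=provenance[ps.id].top_meta,
            )
            for ps in merged_sets
        ]
        return ClusterReport(clusters=entries, leftovers=leftovers)
    sg = load_space_group(merged_sets[0].sg_symbol)
    cfg2 = ClusteringConfig(
        tolerance=cfg.tolerance_round2,
        tolerance_round2=cfg.tolerance_round2,
        resolution_comparison=cfg.resolution_comparison,
        cycles=cfg.cycles,
        minchunk=cfg.minchunk,
        n_cores=cfg.n_cores,
        polar_algorithm=cfg.polar_algorithm,
        grid=cfg.grid,
        seed=cfg.seed,
    )
    clusters2, left2 = referential_cluster(
        merged_sets,
        sg,
        cfg2.tolerance,
        cycles=cfg2.cycles,
        seq_continue=False,
        algorithm=cfg2.polar_algorithm,
        grid=cfg2.grid,
    )
    entries = []
    for cl in clusters2:
        expanded: list[MergeRecord] = []
        for rec in cl.members:
            for sub in provenance[rec.member_id].members:
                expanded.append(
                    MergeRecord(
                        member_id=sub.member_id,
                        weight=sub.weight * rec.weight,
                        shift_applied=sub.shift_applied,
                        wmpd_to_reference=sub.wmpd_to_reference,
                    )
                )
        metas = [provenance[rec.member_id].top_meta for rec in cl.members]
        top = max(
            (m for m in metas if m), key=lambda m: m.get("CC", m.get("LLG", 0.0)), default={}
        )
        entries.append(
            ClusterEntry(
                merged=cl.phase_set,
                members=expanded,
                round=2,
                reference_id=cl.members[0].member_id,
                top_meta=dict(top),
            )
        )
    # round-1 clusters that stayed alone in round 2 keep their identity
    return ClusterReport(clusters=entries, leftovers=leftovers + left2)


def wmpe_table(
    solutions: Sequence[PhaseSet],
    truth: PhaseSet,
    sg: SpaceGroupInfo | str | None = None,
    algorithm: str = "auto",
    grid: int = 64,
) -> pd.DataFrame:
    """Weighted mean phase error of each solution against the true phases.

    The error is evaluated at the best allowed origin shift; solutions with
    wMPE below 80 degrees are flagged as nonrandom.
    """
    if sg is None:
        sg = truth.sg_symbol
    if isinstance(sg, str):
        sg = load_space_group(sg)
    rows = []
    for ps in solutions:
        res = best_shift(truth, ps, sg, algorithm=algorithm, grid=grid)
        rows.append(
            {
                "id": ps.id,
                "wmpe": res.wmpd,
                "mapcc": res.mapcc,
                "shift_x": res.shift[0],
                "shift_y": res.shift[1],
                "shift_z": res.shift[2],
                "nonrandom": res.wmpd < NONRANDOM_WMPE,
            }
        )
    return pd.DataFrame(rows)
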