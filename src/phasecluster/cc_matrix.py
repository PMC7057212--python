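"""Pairwise map-correlation matrices and their eigen-embedding.

Beyond greedy referential clustering, the full pairwise structure of a
solution landscape is informative: the matrix of map correlation
coefficients between all phase sets (each evaluated at the pair's best
origin shift) can be fed to an external multidimensional-scaling analysis,
or embedded directly via its eigendecomposition.  In such an embedding each
solution becomes a vector whose pairwise dot products approximate the CCs;
solutions with random phases correlate with nothing and collapse to short
vectors near the origin, while mutually consistent (correct) solutions
acquire long vectors pointing the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .core import best_shift
from .phase_io import PhaseSet, cut_resolution
from .symmetry import SpaceGroupInfo, load_space_group

__all__ = ["CCMatrix", "pairwise_mapcc", "write_cc_input", "read_cc_input", "embed"]


@dataclass
class CCMatrix:
    """Upper-triangle list of pairwise CCs with 1-based indices."""

    n: int
    entries: list[tuple[int, int, float]]  # (i, j, cc), i < j, 1-based
    labels: list[str]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, cc in self.entries:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"bad index pair ({i}, {j}) for n={self.n}")
            if not -1.0 <= cc <= 1.0:
                raise ValueError(f"cc {cc} outside [-1, 1] for pair ({i}, {j})")
            if (i, j) in seen:
                raise ValueError(f"duplicate entry ({i}, {j})")
            seen.add((i, j))
        if len(self.labels) != self.n:
            raise ValueError("labels length must equal n")

    def dense(self) -> np.ndarray:
        m = np.eye(self.n)
        for i, j, cc in self.entries:
            m[i - 1, j - 1] = m[j - 1, i - 1] = cc
        return m


def pairwise_mapcc(
    solutions: Sequence[PhaseSet],
    sg: SpaceGroupInfo | str,
    n_cores: int = 1,
    algorithm: str = "auto",
    grid: int = 64,
    d_cut: float | None = 4.0,
) -> CCMatrix:
    """Map CC at the best origin shift for every unordered pair.

    The comparisons are independent, so they parallelize trivially; results
    are assembled in pair order, making the parallel result identical to the
    serial one.  By default pairs are compared at 4.0 A; pass ``d_cut=None``
    for full resolution.
    """
    if len(solutions) < 2:
        raise ValueError("need at least two solutions for a CC matrix")
    if isinstance(sg, str):
        sg = load_space_group(sg)
    if d_cut is not None:
        work = [cut_resolution(ps, d_cut) for ps in solutions]
        work = [w if len(w) else ps for w, ps in zip(work, solutions)]
    else:
        work = list(solutions)
    pairs = [(i, j) for i in range(len(work)) for j in range(i + 1, len(work))]

    def one(i: int, j: int) -> tuple[int, int, float]:
        res = best_shift(work[i], work[j], sg, algorithm=algorithm, grid=grid)
        return (i + 1, j + 1, float(np.clip(res.mapcc, -1.0, 1.0)))

    if n_cores > 1:
        entries = Parallel(n_jobs=n_cores, prefer="threads")(
            delayed(one)(i, j) for i, j in pairs
        )
    else:
        entries = [one(i, j) for i, j in pairs]
    return CCMatrix(n=len(work), entries=list(entries), labels=[ps.id for ps in solutions])


def write_cc_input(m: CCMatrix, path: str | Path) -> Path:
    """Write ``i j cc`` lines (1-based, fixed precision) plus an id sidecar.

    Returns the sidecar path (``<path>.labels.tsv``), a two-column table
    mapping indices to solution ids.
    """
    if not m.entries:
        raise ValueError("refusing to write an empty CC matrix")
    path = Path(path)
    with open(path, "w") as fh:
        for i, j, cc in m.entries:
            fh.write(f"{i:6d} {j:6d} {cc:8.4f}\n")
    sidecar = path.with_suffix(path.suffix + ".labels.tsv")
    with open(sidecar, "w") as fh:
        for idx, label in enumerate(m.labels, start=1):
            fh.write(f"{idx}\t{label}\n")
    return sidecar


def read_cc_input(path: str | Path, labels: Sequence[str] | None = None) -> CCMatrix:
    """Parse an ``i j cc`` file written by :func:`write_cc_input`."""
    entries = []
    n = 0
    for line in open(path):
        fields = line.split()
        if not fields:
            continue
        i, j, cc = int(fields[0]), int(fields[1]), float(fields[2])
        entries.append((i, j, cc))
        n = max(n, i, j)
    if labels is None:
        labels = [str(k) for k in range(1, n + 1)]
    return CCMatrix(n=n, entries=entries, labels=list(labels))


def embed(m: CCMatrix, ndim: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Spectral embedding of the CC matrix.

    The top-``ndim`` eigenpairs of the symmetric CC matrix (negative
    eigenvalues clipped to zero) give coordinates ``V sqrt(lambda)`` whose
    dot products approximate the CCs in the least-squares sense.  Returns
    ``(coords, norms)`` with one row / entry per solution; vector norms near
    zero mark solutions that correlate with nothing.
    """
    if ndim < 2:
        raise ValueError("ndim must be >= 2")
    dense = m.dense()
    evals, evecs = np.linalg.eigh(dense)
    order = np.argsort(evals)[::-1][:ndim]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    norms = np.linalg.norm(coords, axis=1)
    return coords, norms
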