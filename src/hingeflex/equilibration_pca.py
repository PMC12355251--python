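"""Coordinate PCA and the cosine-content equilibration diagnostic.

The cosine content of a principal-component projection measures how much
the projection resembles a half-cosine — the signature of random diffusion
rather than equilibrated sampling (Hess's diagnostic).  Values above the
customary 0.7 threshold flag an unequilibrated segment.  The progressive
scan evaluates the diagnostic on growing trajectory prefixes, the way one
checks whether discarding more initial sampling changes the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import ParameterError, StructureError, Trajectory
from .superposition_metrics import _aligned_frames, _as_selection

__all__ = [
    "PCAResult",
    "CosineContentReport",
    "pca_coords",
    "cosine_content",
    "equilibration_scan",
]

#: Customary critical cosine-content value separating equilibrated from
#: diffusive sampling.
CC_THRESHOLD = 0.7


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the coordinate covariance.

    ``components`` are orthonormal rows (3N-dimensional directions),
    ``eigenvalues`` the variances (Angstrom^2) in non-increasing order,
    ``projections`` the centered per-frame scores, shape (n_frames, k).
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    projections: np.ndarray


@dataclass(frozen=True)
class CosineContentReport:
    """Cosine content per (segment length, PC) plus per-segment verdicts."""

    table: pd.DataFrame           # columns: t_f, pc, cc, equilibrated
    threshold: float
    trend: float | None           # cc(PC1) change between the two shortest t_f

    def segment_equilibrated(self, t_f: int) -> bool:
        rows = self.table[self.table["t_f"] == t_f]
        if rows.empty:
            raise ParameterError(f"no segment of length {t_f} in the report")
        return bool(rows["equilibrated"].all())


def pca_coords(traj: Trajectory, selection=None, align: bool = True
               ) -> PCAResult:
    """PCA of (aligned) Cartesian coordinates over a selection.

    Frames are superposed onto their mean (two-pass) before the
    decomposition unless ``align=False``; projections are centered.
    """
    if traj.n_frames < 2:
        raise ParameterError("PCA needs at least 2 frames")
    n = traj.topology.n_atoms
    sel = (_as_selection(selection, n) if selection is not None
           else np.arange(n))
    if sel.size == 0:
        raise StructureError("empty selection")
    frames = traj.frames[:, sel, :]
    if align:
        frames = _aligned_frames(frames, selection=np.arange(sel.size))
    X = frames.reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data matrix: eigenvalues = s^2 / n_frames
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = (s ** 2) / traj.n_frames
    projections = Xc @ vt.T
    return PCAResult(mean=mean, components=vt, eigenvalues=eigenvalues,
                     projections=projections)


def cosine_content(projection: np.ndarray, pc_index: int = 0,
                   t_f: int | None = None) -> float:
    """Cosine content of a PC projection over its first ``t_f`` frames.

    With time rescaled to [0, 1] over the segment and the cosine frequency
    set to ``pc_index + 1`` (0-based PC indexing), the discrete Riemann-sum
    evaluation is::

        cc = 2 * (sum_t cos((i+1) pi t / t_f) p(t))^2
               / (t_f * sum_t p(t)^2)

    The result is clipped to [0, 1] against round-off.  The continuous
    integral form omits the time normalisation at face value; it is
    restored here (t mapped to [0, 1]) so that cc is invariant to the
    segment length units, matching the scale-free original diagnostic.
    """
    p = np.asarray(projection, dtype=float).ravel()
    if t_f is None:
        t_f = p.size
    if t_f < 2 or t_f > p.size:
        raise ParameterError(
            f"t_f must be in [2, {p.size}] (got {t_f})")
    if pc_index < 0:
        raise ParameterError("pc_index is 0-based and must be >= 0")
    p = p[:t_f]
    denom = float(np.sum(p * p))
    if denom == 0.0:
        raise ParameterError("all-zero projection: cosine content undefined")
    t = np.arange(t_f)
    cos = np.cos((pc_index + 1) * np.pi * t / t_f)
    cc = 2.0 * float(np.sum(cos * p)) ** 2 / (t_f * denom)
    return float(np.clip(cc, 0.0, 1.0))


def equilibration_scan(traj: Trajectory, t_f_list, n_components: int = 2,
                       threshold: float = CC_THRESHOLD, selection=None
                       ) -> CosineContentReport:
    """Cosine-content scan over progressively longer trajectory prefixes.

    A segment is flagged not-equilibrated when any of the first
    ``n_components`` PCs exceeds the threshold.  The PCA is recomputed on
    each prefix (the diagnostic is about the segment's own dominant
    modes).  ``trend`` reports cc(PC1) of the second-shortest segment
    minus that of the shortest — a decreasing trend supports convergence.
    """
    t_f_list = sorted(int(t) for t in t_f_list)
    if not t_f_list:
        raise ParameterError("empty t_f list")
    if t_f_list[-1] > traj.n_frames:
        raise ParameterError(
            f"t_f {t_f_list[-1]} exceeds the trajectory length "
            f"{traj.n_frames}")
    rows = []
    cc_pc1 = {}
    for t_f in t_f_list:
        sub = Trajectory(topology=traj.topology, frames=traj.frames[:t_f],
                         timestep_ns=traj.timestep_ns)
        pca = pca_coords(sub, selection=selection)
        k = min(n_components, pca.projections.shape[1])
        ccs = [cosine_content(pca.projections[:, i], pc_index=i)
               for i in range(k)]
        flag = all(c <= threshold for c in ccs)
        for i, c in enumerate(ccs):
            rows.append({"t_f": t_f, "pc": i, "cc": c, "equilibrated": flag})
        cc_pc1[t_f] = ccs[0]
    trend = None
    if len(t_f_list) >= 2:
        trend = cc_pc1[t_f_list[1]] - cc_pc1[t_f_list[0]]
    return CosineContentReport(table=pd.DataFrame(rows), threshold=threshold,
                               trend=trend)
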