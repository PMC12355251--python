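"""Rigid-body superposition and trajectory metrics.

RMSD against a reference frame, per-residue RMSF over (optionally
concatenated) replicas, radius of gyration, the interdomain angle theta at
the central domain's center of mass, and the region-wise RMSF classifier
that summarises how a variant's fluctuations differ from wild type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model_io import (
    DomainMap,
    ParameterError,
    Structure,
    StructureError,
    Trajectory,
)

__all__ = [
    "SuperpositionResult",
    "RegionVerdict",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "interdomain_angle",
    "interdomain_angle_series",
    "classify_regions",
    "verdict_table",
]

#: ASCII serialization of the region symbols for machine-readable reports.
SYMBOL_ASCII = {"∼": "~", "×": "x", "↑": "up", "↓": "down"}


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation and the resulting RMSD.

    The transform maps mobile coordinates onto the reference:
    ``x -> rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0,
                            abs_tol=1e-6):
            raise StructureError("rotation must be proper (det = +1)")


@dataclass(frozen=True)
class RegionVerdict:
    """Region-wise comparison symbol: ~ (comparable), x (mixed higher and
    lower), up (higher), down (lower), with the mean RMSF difference."""

    region: str
    symbol: str
    mean_delta: float


def _as_selection(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    idx = np.asarray(selection, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
        raise StructureError("selection indices out of range")
    return idx


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection=None) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch) over a selection.

    Requires at least 3 non-collinear selected points; the returned RMSD is
    computed over the selection after applying the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise StructureError("mobile and reference shapes differ")
    sel = _as_selection(selection, mobile.shape[0])
    if sel.size < 3:
        raise StructureError("need >= 3 points for a rigid superposition")
    mob = mobile[sel]
    ref = reference[sel]
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise StructureError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    diff = (mob_c @ R.T) - ref_c
    rmsd = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray,
                        result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def _batch_superpose(frames: np.ndarray, reference: np.ndarray,
                     align: np.ndarray) -> np.ndarray:
    """Superpose every frame onto the reference over ``align`` at once.

    Batched Kabsch via stacked SVD; returns the transformed frames (all
    atoms moved, fit computed on the align selection).
    """
    mob = frames[:, align, :]
    mob_mean = mob.mean(axis=1, keepdims=True)
    ref = reference[align]
    ref_mean = ref.mean(axis=0)
    H = np.einsum("fni,nj->fij", mob - mob_mean, ref - ref_mean)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik",
                                        Vt.transpose(0, 2, 1),
                                        U.transpose(0, 2, 1))))
    D = np.repeat(np.eye(3)[None], frames.shape[0], axis=0)
    D[:, 2, 2] = d
    # rotation mapping mobile -> reference: R = V D U^T
    R = np.einsum("fij,fjk,fkl->fil", Vt.transpose(0, 2, 1), D,
                  U.transpose(0, 2, 1))
    centered = frames - mob_mean
    return np.einsum("fni,fji->fnj", centered, R) + ref_mean


def rmsd_series(traj: Trajectory, reference: Structure,
                align_selection=None, measure_selection=None) -> np.ndarray:
    """Per-frame RMSD (Angstrom) against a reference structure.

    Each frame is superposed on ``align_selection`` (default: all atoms)
    and the RMSD is evaluated over ``measure_selection``; passing one
    domain's Calpha indices as the measure selection yields per-domain
    RMSD curves.
    """
    n = traj.topology.n_atoms
    if reference.n_atoms != n:
        raise StructureError("reference and trajectory topologies differ")
    align = _as_selection(align_selection, n)
    measure = _as_selection(measure_selection, n)
    if measure.size == 0:
        raise StructureError("empty measure selection")
    moved = _batch_superpose(traj.frames, reference.coords, align)
    d = moved[:, measure, :] - reference.coords[measure]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def _aligned_frames(frames: np.ndarray, selection: np.ndarray,
                    n_passes: int = 2) -> np.ndarray:
    """Superpose every frame onto the running mean structure.

    Two passes (align to frame-0, take the mean, re-align to the mean) fix
    the "average configuration" convention used for fluctuation analyses.
    """
    aligned = frames
    target = aligned[0]
    for _ in range(n_passes):
        aligned = _batch_superpose(aligned, target, selection)
        target = aligned.mean(axis=0)
    return aligned


def rmsf_per_residue(trajs, selection=None, equilibration_offset=0.0,
                     align_selection=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF over one or more replicas.

    Replicas are concatenated after discarding an equilibration offset
    (fraction of frames when < 1, absolute frame count otherwise) from
    each; frames are superposed onto the mean structure by two-pass
    iterative alignment.  Returns ``(res_ids, rmsf)`` for the selected
    (Calpha by default) atoms.

    ``align_selection`` restricts the superposition fit to a subset of
    atoms (e.g. a rigid core domain) while fluctuations are still
    reported for the full selection; the default fits on all selected
    atoms.  Core-domain alignment attributes each hinge arm's swing to
    its own residues instead of letting the least-squares fit
    redistribute it over the whole molecule.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ParameterError("need at least one trajectory")
    topo = trajs[0].topology
    sel = (_as_selection(selection, topo.n_atoms) if selection is not None
           else topo.ca_indices())
    if sel.size == 0:
        raise StructureError("empty atom selection")
    chunks = []
    for tr in trajs:
        if tr.topology.n_atoms != topo.n_atoms:
            raise StructureError("replicas must share one topology")
        off = (int(round(equilibration_offset * tr.n_frames))
               if 0 < equilibration_offset < 1 else int(equilibration_offset))
        chunk = tr.frames[off:]
        if chunk.shape[0] == 0:
            raise ParameterError(
                "equilibration offset leaves no frames in a replica")
        chunks.append(chunk[:, sel, :])
    frames = np.concatenate(chunks, axis=0)
    if align_selection is None:
        fit_idx = np.arange(sel.size)
    else:
        align_set = set(np.asarray(align_selection, dtype=int).tolist())
        fit_idx = np.array([i for i, a in enumerate(sel)
                            if int(a) in align_set], dtype=int)
        if fit_idx.size < 3:
            raise StructureError(
                "align_selection must overlap the analysed selection in "
                ">= 3 atoms")
    aligned = _aligned_frames(frames, selection=fit_idx)
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return topo.res_ids[sel], rmsf


def radius_of_gyration(coords: np.ndarray, weights=None) -> float:
    """Weighted radius of gyration: sqrt(sum w |x - xbar_w|^2 / sum w)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ParameterError("need at least one atom")
    if weights is None:
        w = np.ones(coords.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ParameterError("weights must be non-negative")
        if w.sum() == 0:
            raise ParameterError("weights must not all be zero")
    centroid = (w[:, None] * coords).sum(axis=0) / w.sum()
    d2 = np.sum((coords - centroid) ** 2, axis=1)
    return math.sqrt(float((w * d2).sum() / w.sum()))


def _domain_center(structure: Structure, coords: np.ndarray, dmap: DomainMap,
                   name: str, mass_weighted: bool) -> np.ndarray:
    idx = dmap.domain_atom_indices(structure, name)
    ca = [i for i in idx if structure.atom_names[i].strip() == "CA"]
    idx = np.array(ca, dtype=int) if ca else idx
    if mass_weighted:
        w = structure.masses[idx]
        return (w[:, None] * coords[idx]).sum(axis=0) / w.sum()
    return coords[idx].mean(axis=0)


def interdomain_angle(structure: Structure, dmap: DomainMap,
                      coords: np.ndarray | None = None,
                      mass_weighted: bool = False) -> float:
    """Angle (degrees, in [0, 180]) at domain II's center of mass subtended
    by the domain-I and domain-III centers of mass.

    Centers use Calpha atoms with equal weights by default; pass
    ``mass_weighted=True`` for mass-weighted centers.
    """
    for name in ("I", "II", "III"):
        if name not in dmap.domains:
            raise StructureError(
                f"domain {name!r} missing from the map; the interdomain "
                "angle needs all three domains")
    c = structure.coords if coords is None else np.asarray(coords, dtype=float)
    p1 = _domain_center(structure, c, dmap, "I", mass_weighted)
    p2 = _domain_center(structure, c, dmap, "II", mass_weighted)
    p3 = _domain_center(structure, c, dmap, "III", mass_weighted)
    v1, v3 = p1 - p2, p3 - p2
    n1, n3 = np.linalg.norm(v1), np.linalg.norm(v3)
    if n1 < 1e-9 or n3 < 1e-9:
        raise StructureError("coincident domain centers: angle undefined")
    cosang = float(np.clip(np.dot(v1, v3) / (n1 * n3), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def interdomain_angle_series(traj: Trajectory, dmap: DomainMap,
                             mass_weighted: bool = False) -> np.ndarray:
    return np.array([interdomain_angle(traj.topology, dmap, coords=f,
                                       mass_weighted=mass_weighted)
                     for f in traj.frames])


def classify_regions(rmsf_variant: tuple[np.ndarray, np.ndarray],
                     rmsf_wt: tuple[np.ndarray, np.ndarray],
                     dmap: DomainMap, threshold: float = 1.0
                     ) -> list[RegionVerdict]:
    """Region-wise fluctuation comparison of a variant against wild type.

    Per region the residue-wise difference Delta = variant - WT is reduced
    to a symbol: ``x`` when some residue rises and some falls by at least
    the threshold, ``up``/``down`` when the regional mean crosses
    +/-threshold, and ``~`` otherwise.  The default 1 Angstrom threshold is
    the convention used for fluctuation-discrepancy tables.
    """
    ids_v, vals_v = np.asarray(rmsf_variant[0]), np.asarray(rmsf_variant[1])
    ids_w, vals_w = np.asarray(rmsf_wt[0]), np.asarray(rmsf_wt[1])
    var = dict(zip(ids_v.tolist(), vals_v.tolist()))
    wt = dict(zip(ids_w.tolist(), vals_w.tolist()))
    verdicts = []
    for region in dmap.region_order:
        residues = dmap.region_residues(region)
        missing = [int(r) for r in residues if r not in var or r not in wt]
        if missing:
            raise StructureError(
                f"region {region!r}: no RMSF value for residues {missing[:5]}")
        delta = np.array([var[int(r)] - wt[int(r)] for r in residues])
        if np.any(delta >= threshold) and np.any(delta <= -threshold):
            symbol = "x"
        elif delta.mean() >= threshold:
            symbol = "up"
        elif delta.mean() <= -threshold:
            symbol = "down"
        else:
            symbol = "~"
        verdicts.append(RegionVerdict(region=region, symbol=symbol,
                                      mean_delta=float(delta.mean())))
    return verdicts


def verdict_table(verdicts_by_system: dict[str, list[RegionVerdict]]
                  ) -> pd.DataFrame:
    """Variant x region symbol matrix (rows in insertion order)."""
    rows = {}
    for system, verdicts in verdicts_by_system.items():
        rows[system] = {v.region: v.symbol for v in verdicts}
    return pd.DataFrame.from_dict(rows, orient="index")
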