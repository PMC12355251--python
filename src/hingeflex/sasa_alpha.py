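"""Solvent-accessible surface area along trajectories and the
charge-weighted binding-affinity estimator alpha.

Per-residue SASA is computed with the Shrake–Rupley rolling-probe method
(probe radius 1.4 Angstrom, 960 sphere points by default; hydrogens
excluded so heavy-atom-only inputs are first class).  alpha sums each
charged residue's time-averaged SASA weighted by its formal charge over a
chosen domain — for a nucleic-acid-binding domain, exposed positive
residues favour binding to the phosphate backbone and exposed negative
residues disfavour it, so alpha serves as a cheap electrostatic
complementarity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc

from .model_io import (
    DomainMap,
    ParameterError,
    Structure,
    StructureError,
    Trajectory,
)
from .model_io import _atom_array_from_structure, _guess_element

__all__ = [
    "SASATrace",
    "AlphaResult",
    "VDW_RADII",
    "sasa_frame",
    "mean_sasa",
    "alpha_estimator",
    "delta_sasa",
]

#: Bondi-style van der Waals radii (Angstrom) for heavy elements; the
#: fallback covers coarse bead atoms without an explicit radius.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
    "H": 1.20,
}
_DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class SASATrace:
    """Per-residue SASA statistics over a trajectory.

    ``per_frame`` has shape (n_frames, n_residues); ``mean`` and ``sd``
    are the per-residue time statistics (SD, not SEM, mirroring how
    difference tables are usually reported).
    """

    res_ids: np.ndarray
    per_frame: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"res_id": self.res_ids, "mean_sasa": self.mean,
                             "sd_sasa": self.sd})


@dataclass(frozen=True)
class AlphaResult:
    """Charge-weighted SASA sum over one domain.

    ``alpha`` (signed, Angstrom^2) equals the exact sum of the per-residue
    contributions q_r * <SASA>_r; neutral residues contribute zero.
    """

    alpha: float
    contributions: pd.DataFrame   # res_id, charge, mean_sasa, contribution
    domain: str

    def __post_init__(self):
        total = float(self.contributions["contribution"].sum())
        if not np.isclose(total, self.alpha, atol=1e-9):
            raise StructureError("alpha must equal the sum of contributions")


def _atom_radii(structure: Structure) -> np.ndarray:
    if structure.radii is not None:
        return np.asarray(structure.radii, dtype=float)
    return np.array([VDW_RADII.get(_guess_element(a), _DEFAULT_RADIUS)
                     for a in structure.atom_names])


def sasa_frame(structure: Structure, probe_radius: float = 1.4,
               n_sphere_points: int = 960,
               coords: np.ndarray | None = None) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Shrake–Rupley SASA of one conformation, summed per residue.

    Returns ``(res_ids, per_residue_area)`` in Angstrom^2.  Hydrogens are
    excluded; atomic radii come from the structure's own radii when set
    (coarse bead models) and from a bundled vdW table otherwise.
    """
    if probe_radius <= 0:
        raise ParameterError("probe radius must be positive")
    if n_sphere_points < 10:
        raise ParameterError("n_sphere_points must be >= 10")
    radii = _atom_radii(structure)
    if np.any(radii <= 0):
        raise ParameterError("atomic radii must be positive")
    s = structure if coords is None else structure.with_coords(coords)
    arr = _atom_array_from_structure(s)
    heavy = arr.element != "H"
    atom_sasa = struc.sasa(arr, probe_radius=probe_radius,
                           atom_filter=heavy, ignore_ions=False,
                           point_number=n_sphere_points,
                           vdw_radii=radii)
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    res_ids = structure.unique_residues()
    per_res = np.array([atom_sasa[structure.res_ids == r].sum()
                        for r in res_ids])
    return res_ids, per_res


def mean_sasa(traj: Trajectory, probe_radius: float = 1.4,
              n_sphere_points: int = 960, stride: int = 1) -> SASATrace:
    """Per-residue SASA mean and SD over the frames of a trajectory.

    ``stride`` subsamples frames (SASA is the costly step of the
    pipeline); statistics are over the evaluated frames.
    """
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    frames = traj.frames[::stride]
    res_ids = traj.topology.unique_residues()
    per_frame = np.empty((frames.shape[0], res_ids.size))
    for f in range(frames.shape[0]):
        _, per_frame[f] = sasa_frame(traj.topology, probe_radius,
                                     n_sphere_points, coords=frames[f])
    return SASATrace(res_ids=res_ids, per_frame=per_frame,
                     mean=per_frame.mean(axis=0), sd=per_frame.std(axis=0))


def alpha_estimator(trace: SASATrace, charges: dict[int, int],
                    dmap: DomainMap, domain: str = "I") -> AlphaResult:
    """Charge-weighted mean-SASA sum over one domain's residues.

    ``charges`` maps residue number to formal charge and must cover every
    residue of the domain.
    """
    if domain not in dmap.domains:
        raise StructureError(f"unknown domain {domain!r}")
    lo, hi = dmap.domains[domain]
    by_res = dict(zip(trace.res_ids.tolist(), trace.mean.tolist()))
    rows = []
    for r in range(lo, hi + 1):
        if r not in by_res:
            raise StructureError(
                f"no SASA trace for residue {r} of domain {domain!r}")
        if r not in charges:
            raise StructureError(
                f"no charge assignment for residue {r} of domain {domain!r}")
        q = int(charges[r])
        rows.append({"res_id": r, "charge": q, "mean_sasa": by_res[r],
                     "contribution": q * by_res[r]})
    table = pd.DataFrame(rows)
    return AlphaResult(alpha=float(table["contribution"].sum()),
                       contributions=table, domain=domain)


def delta_sasa(variant: SASATrace, wt: SASATrace,
               charges: dict[int, int] | None = None,
               charged_only: bool = False) -> pd.DataFrame:
    """Per-residue mean-SASA difference (variant - WT) with pooled SD.

    The pooled SD is sqrt(SD_variant^2 + SD_wt^2).  With
    ``charged_only=True`` (requires ``charges``) the table is restricted
    to residues of formal charge +/-1.
    """
    if not np.array_equal(variant.res_ids, wt.res_ids):
        raise StructureError("variant and WT traces cover different residues")
    delta = variant.mean - wt.mean
    pooled = np.sqrt(variant.sd ** 2 + wt.sd ** 2)
    table = pd.DataFrame({"res_id": variant.res_ids, "delta_mean": delta,
                          "pooled_sd": pooled})
    if charged_only:
        if charges is None:
            raise ParameterError("charged_only requires a charge map")
        keep = table["res_id"].map(lambda r: abs(charges.get(int(r), 0)) == 1)
        table = table[keep].reset_index(drop=True)
    return table
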