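"""SAXS flexibility analysis: Debye profiles, Guinier and dimensionless
Kratky analysis, model-based P(r)/Dmax, hinge-rotation conformer pools,
multistate ensemble fitting, and domain rotation/displacement geometry.

The forward model is the Debye equation with uniform per-bead form
factors (coarse bead systems; atomic form-factor tables are injectable).
Ensemble fitting searches n-member subsets of a conformer pool and solves
non-negative weights plus a global scale against an experimental-style
profile under the reduced chi score — the standard minimal-ensemble
approach for flexible multidomain scatterers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.transform import Rotation

from .model_io import (
    DomainMap,
    ParameterError,
    SAXSProfile,
    Structure,
    StructureError,
)
from .superposition_metrics import (
    apply_superposition,
    interdomain_angle,
    kabsch_superpose,
    radius_of_gyration,
)

__all__ = [
    "ConformerPool",
    "EnsembleModel",
    "DisplacementReport",
    "debye_profile",
    "guinier_fit",
    "kratky_dimensionless",
    "pr_from_model",
    "generate_pool",
    "multistate_fit",
    "domain_displacement",
    "ensemble_table",
]

#: Default q-grid (1/Angstrom) for pool profiles.
DEFAULT_Q_GRID = np.linspace(0.005, 0.35, 80)

#: Exhaustive subset search is used while C(pool, n) stays below this.
EXHAUSTIVE_LIMIT = 200_000

#: Minimum interdomain Calpha distance accepted by the pool generator.
CLASH_DISTANCE = 3.5


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def debye_profile(structure: Structure, q_grid=None,
                  form_factors=None) -> SAXSProfile:
    """Scattering profile of a structure by the Debye equation.

    I(q) = sum_ij f_i f_j sinc(q r_ij), with sinc(0) = 1, so
    I(0) = (sum f)^2.  Uniform f = 1 by default (coarse beads).
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ParameterError("q must be non-negative")
    coords = structure.coords
    n = coords.shape[0]
    if n == 0:
        raise ParameterError("empty structure")
    f = (np.ones(n) if form_factors is None
         else np.asarray(form_factors, dtype=float))
    if f.shape != (n,):
        raise ParameterError("one form factor per atom required")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    ff = f[:, None] * f[None, :]
    qr = q[:, None, None] * d[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    inten = np.einsum("ij,qij->q", ff, sinc)
    # strictly increasing grid is required by SAXSProfile; a q=0 point is fine
    return SAXSProfile(q=q, I=inten)


# ---------------------------------------------------------------------------
# Guinier / Kratky / P(r)
# ---------------------------------------------------------------------------

def guinier_fit(profile: SAXSProfile, max_iter: int = 20
                ) -> tuple[float, float, tuple[int, int]]:
    """Guinier analysis: returns (I0, Rg, (i_lo, i_hi)) of the final window.

    Fits ln I vs q^2 on a low-q window iterated self-consistently so that
    q_max <= 1/Rg (the customary Guinier validity range), starting from
    the lowest fifth of the grid.  Raises on a non-decaying profile
    (positive slope: no Guinier regime).
    """
    q, inten = profile.q, profile.I
    n = q.size
    if n < 5:
        raise ParameterError("need at least 5 points for a Guinier fit")
    hi = max(5, n // 5)
    window = (0, hi)
    rg = None
    for _ in range(max_iter):
        lo, hi = window
        qq, ii = q[lo:hi], inten[lo:hi]
        if np.any(ii <= 0):
            raise ParameterError(
                "non-positive intensities inside the Guinier window")
        slope, intercept = np.polyfit(qq ** 2, np.log(ii), 1)
        if slope >= -1e-12:
            raise ParameterError(
                "non-negative Guinier slope: no Guinier regime (Rg ~ 0?)")
        rg = math.sqrt(-3.0 * slope)
        new_hi = int(np.searchsorted(q, 1.0 / rg, side="right"))
        new_hi = max(new_hi, lo + 5)
        new_hi = min(new_hi, n)
        if (lo, new_hi) == window:
            break
        window = (lo, new_hi)
    return float(math.exp(intercept)), float(rg), window


def kratky_dimensionless(profile: SAXSProfile, rg: float, i0: float
                         ) -> tuple[pd.DataFrame, float, float]:
    """Dimensionless Kratky transform (qRg, (qRg)^2 I/I0).

    Returns the curve plus the peak location and height over qRg in
    (0, 3].  A globular scatterer peaks at (sqrt(3), ~1.1); flexible
    chains plateau above that level.  A warning is issued when the grid
    is coarser than 0.05 in qRg near the expected peak.
    """
    if rg <= 0 or i0 <= 0:
        raise ParameterError("Rg and I0 must be positive")
    x = profile.q * rg
    y = x ** 2 * profile.I / i0
    curve = pd.DataFrame({"qRg": x, "kratky": y})
    sel = (x > 0) & (x <= 3.0)
    if not np.any(sel):
        raise ParameterError("no grid points with qRg in (0, 3]")
    xs = x[sel]
    if np.max(np.diff(xs)) > 0.05:
        warnings.warn("q-grid coarser than 0.05 in qRg: peak location is "
                      "resolution-limited", stacklevel=2)
    k = int(np.argmax(y[sel]))
    peak_x, peak_y = float(xs[k]), float(y[sel][k])
    if k == xs.size - 1:
        warnings.warn("Kratky transform still rising at qRg = 3 (peak at "
                      "grid edge): non-globular profile", stacklevel=2)
    return curve, peak_x, peak_y


def pr_from_model(structure: Structure, n_bins: int = 200,
                  form_factors=None) -> tuple[pd.DataFrame, float, float]:
    """Pair-distance distribution from coordinates.

    Returns (P(r) table with bin centers, Dmax, Rg).  P(r) histograms the
    f_i f_j weighted pair distances (i < j); Dmax is the largest pair
    distance, and Rg uses the exact (sum f)^2 normalisation so it matches
    the coordinate radius of gyration up to binning.
    """
    coords = structure.coords
    n = coords.shape[0]
    if n < 2:
        raise ParameterError("P(r) needs at least two atoms")
    f = (np.ones(n) if form_factors is None
         else np.asarray(form_factors, dtype=float))
    iu = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    w = f[iu[0]] * f[iu[1]]
    dmax = float(d.max())
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, dmax), weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    table = pd.DataFrame({"r": centers, "P": counts})
    rg2 = float(np.sum(centers ** 2 * counts)) / float(np.sum(f)) ** 2
    return table, dmax, math.sqrt(max(rg2, 0.0))


# ---------------------------------------------------------------------------
# conformer pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformerPool:
    """Conformers sharing one topology with precomputed Debye profiles."""

    conformers: tuple[Structure, ...]
    q_grid: np.ndarray
    profiles: np.ndarray          # (n_conformers, n_q)
    hinge_residues: tuple[int, ...] = ()
    angle_range: float = 0.0
    seed: int = 0
    member_rg: tuple[float, ...] = ()
    member_dmax: tuple[float, ...] = ()
    member_theta: tuple[float, ...] = ()

    def __post_init__(self):
        if len(self.conformers) < 1:
            raise ParameterError("pool must contain at least one conformer")
        if self.profiles.shape != (len(self.conformers), self.q_grid.size):
            raise StructureError("profiles do not match pool/q-grid shape")


def _hinge_pivot(structure: Structure, dmap: DomainMap, hinge: str
                 ) -> np.ndarray:
    """Calpha position of the hinge's middle residue (the pivot)."""
    lo, hi = dmap.hinges[hinge]
    mid = (lo + hi) // 2
    idx = structure.residue_indices(mid, mid)
    ca = [i for i in idx if structure.atom_names[i].strip() == "CA"]
    if not ca and idx.size == 0:
        raise StructureError(f"hinge {hinge!r} residue {mid} not in structure")
    return structure.coords[ca[0] if ca else idx[0]]


def generate_pool(structure: Structure, dmap: DomainMap,
                  n_conformers: int = 200, angle_range: float = 60.0,
                  seed: int = 0, q_grid=None,
                  form_factors=None) -> ConformerPool:
    """Hinge-rotation conformer pool.

    Each conformer rotates domain I about a random axis through the
    hinge-I-II pivot Calpha and domain III about the hinge-II-III pivot,
    with angles uniform in +/-angle_range degrees; clashing conformers
    (interdomain Calpha contact below 3.5 Angstrom) are rejected and
    resampled.  Profiles are precomputed on a shared q-grid.
    """
    if n_conformers < 1:
        raise ParameterError("n_conformers must be >= 1")
    for hinge in ("I-II", "II-III"):
        if hinge not in dmap.hinges:
            raise StructureError(f"domain map lacks hinge {hinge!r}")
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    idx_I = dmap.domain_atom_indices(structure, "I")
    idx_III = dmap.domain_atom_indices(structure, "III")
    others = np.setdiff1d(np.arange(structure.n_atoms),
                          np.concatenate([idx_I, idx_III]))
    pivots = {"I": _hinge_pivot(structure, dmap, "I-II"),
              "III": _hinge_pivot(structure, dmap, "II-III")}

    def rotate(coords, idx, pivot):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(-angle_range, angle_range))
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        out = coords.copy()
        out[idx] = (coords[idx] - pivot) @ R.T + pivot
        return out

    conformers: list[Structure] = []
    attempts = 0
    while len(conformers) < n_conformers:
        attempts += 1
        if attempts > max(100 * n_conformers, 1000):
            raise StructureError(
                "pool rejection rate above 99%: reduce angle_range or open "
                "the starting structure")
        coords = rotate(structure.coords, idx_I, pivots["I"])
        coords = rotate(coords, idx_III, pivots["III"])
        d_I = np.linalg.norm(coords[idx_I][:, None] - coords[others][None],
                             axis=2).min() if others.size else np.inf
        d_III = np.linalg.norm(coords[idx_III][:, None] - coords[others][None],
                               axis=2).min() if others.size else np.inf
        d_I_III = np.linalg.norm(coords[idx_I][:, None] - coords[idx_III][None],
                                 axis=2).min()
        if min(d_I, d_III, d_I_III) < CLASH_DISTANCE and angle_range > 0:
            continue
        conformers.append(structure.with_coords(coords))
    profiles = np.stack([debye_profile(c, q, form_factors).I
                         for c in conformers])
    rgs, dmaxs, thetas = [], [], []
    for c in conformers:
        rg, dmax, _ = _member_geometry(c)
        rgs.append(rg)
        dmaxs.append(dmax)
        try:
            thetas.append(interdomain_angle(c, dmap))
        except StructureError:
            thetas.append(math.nan)
    return ConformerPool(conformers=tuple(conformers), q_grid=q,
                         profiles=profiles,
                         hinge_residues=tuple((lo + hi) // 2
                                              for lo, hi in
                                              dmap.hinges.values()),
                         angle_range=angle_range, seed=seed,
                         member_rg=tuple(rgs), member_dmax=tuple(dmaxs),
                         member_theta=tuple(thetas))


# ---------------------------------------------------------------------------
# multistate fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleModel:
    """An n-state mixture model fitted to a profile.

    ``chi`` is the square root of the reduced chi-square
    (1/M) sum_q ((I_exp - c sum_k w_k I_k)/sigma)^2; ``chi2`` is the
    reduced chi-square itself (the convention printed in ensemble
    tables).
    """

    n_states: int
    members: tuple[int, ...]
    weights: np.ndarray
    scale: float
    chi: float
    member_rg: tuple[float, ...] = ()
    member_dmax: tuple[float, ...] = ()
    member_theta: tuple[float, ...] = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(self.members) != self.n_states or w.size != self.n_states:
            raise StructureError("member/weight counts must equal n_states")
        if np.any(w < -1e-12) or not math.isclose(w.sum(), 1.0, abs_tol=1e-6):
            raise StructureError("weights must be a simplex")
        if self.chi < 0:
            raise StructureError("chi must be non-negative")

    @property
    def chi2(self) -> float:
        return self.chi ** 2


def _resample_pool(pool: ConformerPool, q: np.ndarray) -> np.ndarray:
    """Pool profiles linearly interpolated onto the experimental grid.

    sigma is never interpolated: fitting is restricted to experimental
    points that fall inside the pool's native q range.
    """
    if q.size == pool.q_grid.size and np.allclose(q, pool.q_grid):
        return pool.profiles
    inside = (q >= pool.q_grid[0]) & (q <= pool.q_grid[-1])
    if not np.all(inside):
        raise ParameterError(
            "experimental q extends beyond the pool grid; regenerate the "
            "pool on a wider grid")
    return np.stack([np.interp(q, pool.q_grid, p) for p in pool.profiles])


def _score_subset(A: np.ndarray, y: np.ndarray, subset: tuple[int, ...]
                  ) -> tuple[float, np.ndarray, float]:
    """Weighted NNLS fit of one subset: returns (chi, weights, scale)."""
    coeff, _ = nnls(A[:, subset], y)
    resid = y - A[:, subset] @ coeff
    m = y.size
    chi = math.sqrt(float(resid @ resid) / m)
    total = coeff.sum()
    if total <= 0:
        return chi, np.full(len(subset), 1.0 / len(subset)), 0.0
    return chi, coeff / total, float(total)


def multistate_fit(profile: SAXSProfile, pool: ConformerPool,
                   n_states=(1, 2, 3), top_k: int = 100
                   ) -> dict[int, list[EnsembleModel]]:
    """Minimal-ensemble search: best n-member mixtures of pool conformers.

    For each n, every subset (exhaustive while C(pool, n) stays below
    2e5, greedy add-and-swap refinement beyond that) is scored by
    sigma-weighted non-negative least squares with a free global scale;
    the ``top_k`` models per n are returned sorted by chi, ties broken by
    member indices.
    """
    if profile.sigma is None:
        raise ParameterError("chi is undefined without per-point sigma")
    if len(pool.conformers) == 0:
        raise ParameterError("empty conformer pool")
    profiles = _resample_pool(pool, profile.q)
    A = (profiles / profile.sigma).T          # (M, n_pool)
    y = profile.I / profile.sigma
    n_pool = profiles.shape[0]
    results: dict[int, list[EnsembleModel]] = {}

    if pool.member_rg:
        geometry = [(pool.member_rg[i], pool.member_dmax[i],
                     pool.member_theta[i]) for i in range(n_pool)]
    else:
        geometry = [_member_geometry(c) for c in pool.conformers]

    for n in sorted(set(int(k) for k in n_states)):
        if n < 1 or n > n_pool:
            raise ParameterError(f"n_states {n} outside [1, {n_pool}]")
        scored: list[tuple[float, tuple[int, ...], np.ndarray, float]] = []
        if math.comb(n_pool, n) <= EXHAUSTIVE_LIMIT:
            for subset in itertools.combinations(range(n_pool), n):
                chi, w, c = _score_subset(A, y, subset)
                scored.append((chi, subset, w, c))
        else:
            scored = _greedy_search(A, y, n, results, n_pool, top_k)
        scored.sort(key=lambda t: (t[0], t[1]))
        models = []
        for chi, subset, w, c in scored[:top_k]:
            rg = tuple(geometry[i][0] for i in subset)
            dmax = tuple(geometry[i][1] for i in subset)
            theta = tuple(geometry[i][2] for i in subset)
            models.append(EnsembleModel(n_states=n, members=subset,
                                        weights=w, scale=c, chi=chi,
                                        member_rg=rg, member_dmax=dmax,
                                        member_theta=theta))
        results[n] = models
    return results


def _member_geometry(conformer: Structure) -> tuple[float, float, float]:
    """(Rg, Dmax, theta-or-nan) of one pool member."""
    rg = radius_of_gyration(conformer.coords)
    d = np.linalg.norm(conformer.coords[:, None] - conformer.coords[None],
                       axis=2)
    dmax = float(d.max())
    return rg, dmax, math.nan


def _greedy_search(A, y, n, previous, n_pool, top_k):
    """Greedy add-and-swap refinement seeded from the best (n-1)-state
    models (or the best singles when unavailable)."""
    singles = sorted(range(n_pool),
                     key=lambda i: _score_subset(A, y, (i,))[0])
    seeds: list[tuple[int, ...]] = []
    if (n - 1) in previous and previous[n - 1]:
        seeds = [m.members for m in previous[n - 1][:top_k // 2]]
    seeds = seeds or [(i,) for i in singles[:top_k // 2]]
    scored = {}
    for seed_subset in seeds:
        subset = tuple(sorted(seed_subset))
        while len(subset) < n:
            best = None
            for cand in singles:
                if cand in subset:
                    continue
                trial = tuple(sorted(subset + (cand,)))
                chi, w, c = _score_subset(A, y, trial)
                if best is None or chi < best[0]:
                    best = (chi, trial, w, c)
            subset = best[1]
        chi, w, c = _score_subset(A, y, subset)
        # swap passes until no single replacement improves chi
        improved = True
        while improved:
            improved = False
            for pos in range(n):
                for cand in singles:
                    if cand in subset:
                        continue
                    trial = tuple(sorted(subset[:pos] + (cand,)
                                         + subset[pos + 1:]))
                    t_chi, t_w, t_c = _score_subset(A, y, trial)
                    if t_chi < chi - 1e-15:
                        subset, chi, w, c = trial, t_chi, t_w, t_c
                        improved = True
        scored[subset] = (chi, subset, w, c)
    return list(scored.values())


def ensemble_table(results: dict[int, list[EnsembleModel]],
                   best_only: bool = True) -> pd.DataFrame:
    """Flat table of fitted ensembles (state, member, fraction, Rg, Dmax,
    theta, chi2) mirroring the usual multistate-fit report layout."""
    rows = []
    for n, models in sorted(results.items()):
        chosen = models[:1] if best_only else models
        for model in chosen:
            for k in range(model.n_states):
                rows.append({
                    "state": n,
                    "member": model.members[k],
                    "fraction": float(model.weights[k]),
                    "rg": model.member_rg[k] if model.member_rg else math.nan,
                    "dmax": (model.member_dmax[k] if model.member_dmax
                             else math.nan),
                    "theta": (model.member_theta[k] if model.member_theta
                              else math.nan),
                    "chi": model.chi,
                    "chi2": model.chi2,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# domain rotation / displacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacementReport:
    """Per-domain rigid-motion summary after aligning on the hub domain."""

    rotations_deg: dict[str, float]
    displacements: dict[str, float]
    reference: str = "reference"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "domain": list(self.rotations_deg),
            "rotation_deg": list(self.rotations_deg.values()),
            "displacement_A": list(self.displacements.values()),
        })


def domain_displacement(conformer: Structure, reference: Structure,
                        dmap: DomainMap) -> DisplacementReport:
    """Rotation angle and center-of-mass displacement of domains I and III
    relative to a reference, after superposing both on domain II.

    The rotation angle is the axis-angle magnitude of the optimal rotation
    carrying the conformer's domain onto the reference's; displacement is
    the distance between domain centers of mass in the aligned frame.
    Identical structures give (0 deg, 0 Angstrom); any global rigid motion
    of the conformer is removed by the domain-II alignment.
    """
    if conformer.n_atoms != reference.n_atoms:
        raise StructureError("conformer and reference topologies differ")
    idx_II = dmap.domain_atom_indices(reference, "II")
    ca_II = np.array([i for i in idx_II
                      if reference.atom_names[i].strip() == "CA"], dtype=int)
    sel = ca_II if ca_II.size >= 3 else idx_II
    sup = kabsch_superpose(conformer.coords, reference.coords, selection=sel)
    moved = apply_superposition(conformer.coords, sup)

    rotations, displacements = {}, {}
    for name in ("I", "III"):
        idx = dmap.domain_atom_indices(reference, name)
        mob = moved[idx]
        ref = reference.coords[idx]
        mob_c = mob - mob.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)
        if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
            raise StructureError(
                f"domain {name!r} is degenerate (collinear atoms)")
        rot, _ = Rotation.align_vectors(ref_c, mob_c)
        rotations[name] = float(np.degrees(np.linalg.norm(rot.as_rotvec())))
        displacements[name] = float(np.linalg.norm(mob.mean(axis=0)
                                                   - ref.mean(axis=0)))
    return DisplacementReport(rotations_deg=rotations,
                              displacements=displacements)
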