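"""Synthetic hinged multidomain proteins and their dynamics.

This module produces everything the analysis stages need without any real
simulation data: a coarse bead model of a three-domain protein connected
by two hinges, overdamped Langevin dynamics of the hinge angles with an
exactly known stationary law, variant perturbations (stiffness scaling,
equilibrium-angle shifts, charge edits) standing in for point mutations,
and noisy synthetic SAXS curves built as weighted mixtures of conformer
profiles.

Geometry.  Domain II sits at the origin; domains I and III are rigid bead
blobs carried on two "arms" whose in-plane orientation angles are the two
hinge degrees of freedom.  The interdomain angle theta (at the domain-II
center of mass) therefore equals the difference of the two arm angles, and
each arm angle is an independent Ornstein-Uhlenbeck process with the
equilibrium distribution Normal(rest, kB*T/kappa) - the closed form every
equipartition test checks against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import (
    KB_KCAL_MOL_K,
    ParameterError,
    SAXSProfile,
    Structure,
    StructureError,
    Trajectory,
    DomainMap,
    residue_charge,
)

__all__ = [
    "ToyProteinSpec",
    "VariantPerturbation",
    "build_toy_protein",
    "toy_domain_map",
    "simulate_hinge_langevin",
    "apply_variant",
    "synthesize_saxs_profile",
]

_HINGE_NAMES = ("I-II", "II-III")

# residue names used to realise integer charge labels as bead residues
_NAME_FOR_CHARGE = {1: "LYS", -1: "GLU", 0: "GLY"}


def _default_charges(n_residues: int) -> tuple[int, ...]:
    """A fixed, deterministic charge pattern: every 5th bead charged,
    alternating +1/-1 (~20% charged residues, roughly net neutral)."""
    charges = []
    sign = 1
    for r in range(n_residues):
        if r % 5 == 2:
            charges.append(sign)
            sign = -sign
        else:
            charges.append(0)
    return tuple(charges)


@dataclass(frozen=True)
class ToyProteinSpec:
    """Parameters of the synthetic hinged protein.

    ``hinge_rest_angles`` maps each starting state to the equilibrium
    interdomain angle theta0 (degrees); ``hinge_stiffness`` gives the
    harmonic constant kappa (kcal/mol/rad^2) of each hinge.  ``charges``
    holds the per-residue formal charges the binding estimator weights by;
    when ``None`` a fixed default pattern is generated.
    """

    n_domains: int = 3
    beads_per_domain: int = 30
    beads_per_hinge: int = 4
    bead_radius: float = 1.9          # Angstrom, Calpha-bead scale
    domain_blob_radius: float = 8.0   # Angstrom
    arm_length: float = 30.0          # domain-II center to arm-domain center
    hinge_rest_angles: dict[str, float] = field(
        default_factory=lambda: {"open": 122.0, "closed": 75.0})
    hinge_stiffness: dict[str, float] = field(
        default_factory=lambda: {h: 8.0 for h in _HINGE_NAMES})
    charges: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.n_domains not in (2, 3):
            raise ParameterError("n_domains must be 2 or 3")
        if self.beads_per_domain < 3:
            raise ParameterError("beads_per_domain must be >= 3")
        for state, ang in self.hinge_rest_angles.items():
            if not 0.0 < ang < 180.0:
                raise ParameterError(
                    f"rest angle for state {state!r} must lie in (0, 180) deg")
        for h, k in self.hinge_stiffness.items():
            if k <= 0:
                raise ParameterError(f"hinge {h!r} stiffness must be positive")

    @property
    def n_hinges(self) -> int:
        return self.n_domains - 1

    @property
    def n_residues(self) -> int:
        return (self.n_domains * self.beads_per_domain
                + self.n_hinges * self.beads_per_hinge)

    def charge_vector(self) -> np.ndarray:
        if self.charges is not None:
            if len(self.charges) != self.n_residues:
                raise ParameterError(
                    f"charges has {len(self.charges)} entries for "
                    f"{self.n_residues} residues")
            return np.asarray(self.charges, dtype=int)
        return np.asarray(_default_charges(self.n_residues), dtype=int)


@dataclass(frozen=True)
class VariantPerturbation:
    """A named perturbation standing in for a point mutation.

    ``stiffness_scale`` multiplies hinge constants, ``rest_angle_shift``
    adds to the equilibrium angles (degrees, applied to every state),
    ``charge_edits`` rewrites individual residue charges.  The identity
    perturbation (empty fields) leaves a spec unchanged.
    """

    name: str = "WT"
    stiffness_scale: dict[str, float] = field(default_factory=dict)
    rest_angle_shift: dict[str, float] = field(default_factory=dict)
    charge_edits: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        for h, s in self.stiffness_scale.items():
            if s <= 0:
                raise ParameterError(
                    f"stiffness scale for hinge {h!r} must be positive")


def apply_variant(spec: ToyProteinSpec, v: VariantPerturbation) -> ToyProteinSpec:
    """Return a new spec with the perturbation applied; the input is unchanged."""
    stiffness = dict(spec.hinge_stiffness)
    for h, s in v.stiffness_scale.items():
        if h not in stiffness:
            raise ParameterError(f"unknown hinge {h!r}")
        stiffness[h] = stiffness[h] * s
    shift = sum(v.rest_angle_shift.values())
    rest = {state: ang + shift for state, ang in spec.hinge_rest_angles.items()}
    charges = list(spec.charge_vector())
    for res_num, new_q in v.charge_edits:
        if not 1 <= res_num <= spec.n_residues:
            raise ParameterError(
                f"charge edit references residue {res_num}, but the spec has "
                f"residues 1..{spec.n_residues}")
        charges[res_num - 1] = int(new_q)
    return replace(spec, hinge_stiffness=stiffness, hinge_rest_angles=rest,
                   charges=tuple(charges))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _sample_blob(rng: np.random.Generator, n: int, radius: float,
                 min_sep: float, max_tries: int = 100) -> np.ndarray:
    """Zero-mean rigid blob of n beads inside a ball, pairwise >= min_sep."""
    for _ in range(max_tries):
        pts = np.empty((0, 3))
        attempts = 0
        while pts.shape[0] < n and attempts < 200 * n:
            cand = rng.uniform(-radius, radius, size=3)
            attempts += 1
            if np.linalg.norm(cand) > radius:
                continue
            if pts.size and np.min(np.linalg.norm(pts - cand, axis=1)) < min_sep:
                continue
            pts = np.vstack([pts, cand])
        if pts.shape[0] == n:
            return pts - pts.mean(axis=0)
    raise StructureError(
        f"could not place {n} beads of min separation {min_sep:.2f} A inside "
        f"a {radius:.1f} A blob after {max_tries} resamples")


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _domain_templates(spec: ToyProteinSpec, seed: int):
    """Seeded rigid bead templates (zero-mean) for each domain."""
    rng = np.random.default_rng(seed)
    min_sep = 0.9 * 2.0 * spec.bead_radius
    return [_sample_blob(rng, spec.beads_per_domain, spec.domain_blob_radius,
                         min_sep) for _ in range(spec.n_domains)]


def _arm_angles(theta_deg: float, n_hinges: int) -> list[float]:
    """Arm orientation angles (radians from +x) realising interdomain angle
    theta.  Three domains: arms at +theta/2 and -theta/2; two domains: one
    arm along theta."""
    theta = math.radians(theta_deg)
    if n_hinges == 2:
        return [theta / 2.0, -theta / 2.0]
    return [theta]


def _assemble(spec: ToyProteinSpec, templates: list[np.ndarray],
              arm_angles: list[float]) -> np.ndarray:
    """Coordinates in chain order: domain I, hinge I-II, domain II,
    [hinge II-III, domain III]."""
    hub = templates[min(1, spec.n_domains - 1)]
    L = spec.arm_length
    pieces: list[np.ndarray] = []

    def arm_pieces(template: np.ndarray, angle: float):
        rot = _rot_z(angle)
        center = L * np.array([math.cos(angle), math.sin(angle), 0.0])
        domain = template @ rot.T + center
        fracs = np.linspace(0.30, 0.70, spec.beads_per_hinge)
        hinge = fracs[:, None] * center[None, :]
        return domain, hinge

    if spec.n_domains == 3:
        dom1, hinge1 = arm_pieces(templates[0], arm_angles[0])
        dom3, hinge3 = arm_pieces(templates[2], arm_angles[1])
        pieces = [dom1, hinge1, templates[1], hinge3, dom3]
    else:
        dom1, hinge1 = arm_pieces(templates[0], arm_angles[0])
        pieces = [dom1, hinge1, templates[1]]
    return np.vstack(pieces)


def toy_domain_map(spec: ToyProteinSpec) -> DomainMap:
    """Domain/hinge residue ranges matching the chain order of the builder."""
    bpd, bph = spec.beads_per_domain, spec.beads_per_hinge
    pos = 1
    domains: dict[str, tuple[int, int]] = {}
    hinges: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    names = ["I", "II", "III"][:spec.n_domains]
    for i, name in enumerate(names):
        domains[name] = (pos, pos + bpd - 1)
        order.append(name)
        pos += bpd
        if i < spec.n_hinges:
            hname = f"{names[i]}-{names[i + 1]}"
            hinges[hname] = (pos, pos + bph - 1)
            order.append(hname)
            pos += bph
    return DomainMap(domains=domains, hinges=hinges, region_order=tuple(order))


def _check_clashes(spec: ToyProteinSpec, coords: np.ndarray,
                   dmap: DomainMap, res_ids: np.ndarray) -> bool:
    """True when no two beads of different domains come closer than
    0.8 * (2 * bead_radius)."""
    tol = 0.8 * 2.0 * spec.bead_radius
    groups = []
    for name in dmap.domains:
        lo, hi = dmap.domains[name]
        groups.append(coords[(res_ids >= lo) & (res_ids <= hi)])
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i][:, None, :] - groups[j][None, :, :],
                               axis=2)
            if d.min() < tol:
                return False
    return True


def build_toy_protein(spec: ToyProteinSpec, state: str = "open",
                      seed: int = 0) -> Structure:
    """Build the bead structure of one starting state.

    The interdomain angle of the built structure equals the state's rest
    angle exactly (domain blobs are zero-mean, so blob centers coincide
    with centers of mass).  Deterministic for a fixed seed.
    """
    if state not in spec.hinge_rest_angles:
        raise ParameterError(
            f"unknown state {state!r}; spec defines "
            f"{sorted(spec.hinge_rest_angles)}")
    dmap = toy_domain_map(spec)
    charges = spec.charge_vector()
    res_ids = np.arange(1, spec.n_residues + 1)
    angles = _arm_angles(spec.hinge_rest_angles[state], spec.n_hinges)
    for attempt in range(100):
        templates = _domain_templates(spec, seed + 7919 * attempt)
        coords = _assemble(spec, templates, angles)
        if _check_clashes(spec, coords, dmap, res_ids):
            break
    else:
        raise StructureError(
            "steric overlap between domains persists after 100 resamples; "
            "increase arm_length or reduce domain_blob_radius")
    res_names = tuple(_NAME_FOR_CHARGE[int(q)] for q in charges)
    return Structure(
        atom_names=tuple("CA" for _ in res_ids),
        res_names=res_names,
        res_ids=res_ids,
        coords=coords,
        masses=np.full(spec.n_residues, 110.0),  # one-bead-per-residue, ~aa mass
        radii=np.full(spec.n_residues, spec.bead_radius),
    )


# ---------------------------------------------------------------------------
# hinge Langevin dynamics
# ---------------------------------------------------------------------------

def _infer_arm_angles(structure: Structure, dmap: DomainMap) -> list[float]:
    """Current in-plane arm angles from domain centers of mass."""
    hub_name = "II" if "II" in dmap.domains else list(dmap.domains)[-1]
    hub_idx = dmap.domain_atom_indices(structure, hub_name)
    hub = structure.coords[hub_idx].mean(axis=0)
    angles = []
    for name in dmap.domains:
        if name == hub_name:
            continue
        idx = dmap.domain_atom_indices(structure, name)
        v = structure.coords[idx].mean(axis=0) - hub
        angles.append(math.atan2(v[1], v[0]))
    return angles


def simulate_hinge_langevin(structure: Structure, spec: ToyProteinSpec,
                            n_frames: int, temperature: float = 310.0,
                            seed: int = 0,
                            dt_over_gamma: float | None = None) -> Trajectory:
    """Overdamped Langevin dynamics of the hinge angles.

    Each arm angle a follows Euler-Maruyama updates of the OU process
    ``da = -(dt/gamma) kappa (a - a0) + sqrt(2 kB T dt/gamma) xi``, with the
    rest angle a0 taken from the input structure (which the builder places
    at the state's equilibrium).  Domains are rigid; the stationary law of
    each hinge angle is Normal(a0, kB*T/kappa).

    ``dt_over_gamma`` is the per-step mobility; the default makes the
    stiffest hinge relax over 100 steps (discretisation bias on the
    stationary variance < 1%).
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    dmap = toy_domain_map(spec)
    kappas = np.array([spec.hinge_stiffness[h]
                       for h in _HINGE_NAMES[:spec.n_hinges]])
    if np.any(kappas <= 0):
        raise ParameterError("hinge stiffness must be positive")
    if dt_over_gamma is None:
        dt_over_gamma = 1.0 / (100.0 * float(kappas.max()))
    if dt_over_gamma * kappas.max() >= 2.0:
        raise ParameterError("dt_over_gamma too large: the Euler scheme is unstable")

    a0 = np.array(_infer_arm_angles(structure, dmap))
    rng = np.random.default_rng(seed)
    drift = dt_over_gamma * kappas
    noise_sd = math.sqrt(2.0 * KB_KCAL_MOL_K * temperature * dt_over_gamma)

    # regenerate the rigid templates used by the builder geometry: recover
    # them from the structure itself so the trajectory is consistent with
    # any (possibly resampled) build
    res_ids = structure.res_ids
    names = list(dmap.domains)
    hub_name = "II" if "II" in names else names[-1]
    hub_idx = dmap.domain_atom_indices(structure, hub_name)
    hub_center = structure.coords[hub_idx].mean(axis=0)

    arm_info = []  # per arm: (domain idx, hinge idx, template, arm length)
    arm_i = 0
    for name in names:
        if name == hub_name:
            continue
        didx = dmap.domain_atom_indices(structure, name)
        center = structure.coords[didx].mean(axis=0) - hub_center
        angle = a0[arm_i]
        template = (structure.coords[didx] - hub_center - center) @ _rot_z(angle)
        hinge_name = [h for h in dmap.hinges
                      if name in h.split("-")][0]
        hidx = dmap.domain_atom_indices(structure, hinge_name)
        hinge_fracs = (np.linalg.norm(structure.coords[hidx] - hub_center, axis=1)
                       / np.linalg.norm(center))
        arm_info.append((didx, hidx, template, np.linalg.norm(center),
                         hinge_fracs))
        arm_i += 1

    a = a0.copy()
    frames = np.empty((n_frames, structure.n_atoms, 3))
    base = structure.coords.copy()
    for t in range(n_frames):
        a = a - drift * (a - a0) + noise_sd * rng.standard_normal(a.size)
        coords = base.copy()
        for k, (didx, hidx, template, L, fracs) in enumerate(arm_info):
            rot = _rot_z(a[k])
            center = L * np.array([math.cos(a[k]), math.sin(a[k]), 0.0])
            coords[didx] = template @ rot.T + center + hub_center
            coords[hidx] = fracs[:, None] * center[None, :] + hub_center
        frames[t] = coords
    return Trajectory(topology=structure, frames=frames)


# ---------------------------------------------------------------------------
# synthetic SAXS mixtures
# ---------------------------------------------------------------------------

def synthesize_saxs_profile(component_profiles: list[SAXSProfile],
                            weights, noise_level: float = 0.0,
                            seed: int = 0) -> SAXSProfile:
    """Weighted mixture of conformer profiles with multiplicative Gaussian
    noise: I(q) = sum_k w_k I_k(q) + eps(q), eps ~ N(0, noise_level*I(q)).

    The sigma column is populated with the noise model's standard deviation
    (a small floor avoids zero sigma for noise-free synthesis).
    """
    if not component_profiles:
        raise ParameterError("need at least one component profile")
    w = np.asarray(weights, dtype=float)
    if w.size != len(component_profiles):
        raise ParameterError("one weight per component profile required")
    if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ParameterError("weights must be >= 0 and sum to 1")
    q = component_profiles[0].q
    for p in component_profiles[1:]:
        if p.q.shape != q.shape or not np.allclose(p.q, q):
            raise StructureError("component profiles must share one q-grid")
    mixture = sum(wk * p.I for wk, p in zip(w, component_profiles))
    sigma = noise_level * np.abs(mixture)
    rng = np.random.default_rng(seed)
    noisy = mixture + sigma * rng.standard_normal(q.size)
    sigma_out = np.where(sigma > 0, sigma, 1e-12 + 1e-6 * np.abs(mixture))
    return SAXSProfile(q=q, I=noisy, sigma=sigma_out)
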