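# hingeflex

Comparative conformational-dynamics and SAXS flexibility analysis for
hinged multidomain proteins.

Multidomain proteins such as the three-domain ribosome-maturation factor
SBDS work by swinging rigid domains about short hinge linkers.  Point
variants can stiffen or soften those hinges, shift the equilibrium
interdomain geometry, or rewire surface charges — and each of those
changes leaves a different fingerprint in trajectory metrics and in
small-angle X-ray scattering.  `hingeflex` packages the full comparative
workflow for such systems:

* **Trajectory metrics** — Kabsch superposition, RMSD series, per-residue
  RMSF over concatenated replicas, radius of gyration R_g, and the
  interdomain angle θ at the central domain's centre of mass, plus a
  region-wise RMSF classifier (`~`/`x`/`up`/`down` at a 1 Å threshold).
* **Equilibration diagnostics** — coordinate PCA and Hess's cosine
  content cc[p_i; t_f] with the 0.7 criterion, scanned over progressive
  trajectory prefixes.
* **Free-energy surfaces** — F = −k_B T ln ρ(R_g, θ) + F₀ at 310 K, and
  base-2 Jensen–Shannon comparison of sampled distributions (range
  exactly [0, 1]) with average-linkage dendrograms.
* **Charge-weighted SASA estimator** — α = Σ_r q_r ⟨SASA_r⟩ over a
  binding domain's residues: an electrostatic-complementarity proxy for
  nucleic-acid binding, built on Shrake–Rupley accessible areas.
* **SAXS flexibility suite** — Debye-equation profiles, self-consistent
  Guinier fits, dimensionless Kratky analysis (globular reference: peak
  1.1 at qR_g = √3), model-based P(r)/D_max, hinge-rotation conformer
  pools, n-state ensemble fitting under the reduced-χ score, and domain
  rotation/displacement geometry after hub-domain alignment.
* **A synthetic hinged-protein generator** — rigid bead domains on
  Langevin hinge angles with the exact stationary law
  Normal(θ₀, k_B T/κ), variant perturbations, and noisy synthetic SAXS
  mixtures — so the entire pipeline is testable end to end with no
  external data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
import hingeflex as hf

spec = hf.ToyProteinSpec()                      # 3 domains, 2 hinges
dmap = hf.toy_domain_map(spec)
wt = hf.build_toy_protein(spec, state="open", seed=1)
print(round(hf.interdomain_angle(wt, dmap), 1))  # -> 122.0

traj = hf.simulate_hinge_langevin(wt, spec, n_frames=2000,
                                  temperature=310.0, seed=1)
scan = hf.equilibration_scan(traj, t_f_list=[400, 800, 1200, 1600, 2000])
print(bool(scan.table["equilibrated"].iloc[-1]))  # -> True (cc(PC1)=0.02)

eq = hf.Trajectory(topology=traj.topology, frames=traj.frames[400:])
rg = np.array([hf.radius_of_gyration(f) for f in eq.frames])
th = hf.interdomain_angle_series(eq, dmap)
print(round(rg.mean(), 1), round(th.mean(), 1))   # -> 22.7  124.3

trace = hf.mean_sasa(eq, stride=20, n_sphere_points=240)
charges = {int(r): hf.residue_charge(wt.res_names[i])
           for i, r in enumerate(wt.res_ids)}
print(round(hf.alpha_estimator(trace, charges, dmap).alpha, 1))  # -> -67.3
```

The trajectory equilibrates (cosine content 0.02 ≪ 0.7), samples R_g
around 22.7 Å and θ around its 122° rest angle, and the open wild type
scores α ≈ −67 Å² — the signed, charge-weighted exposed area of
domain I.

Ensemble fitting recovers a planted conformational mixture exactly in
the noise-free limit:

```python
pool = hf.generate_pool(wt, dmap, n_conformers=60, angle_range=50.0, seed=2)
idx = np.argsort(pool.member_rg)
picks = [int(idx[6]), int(idx[30]), int(idx[54])]   # compact/mid/extended
comps = [hf.SAXSProfile(q=pool.q_grid, I=pool.profiles[m]) for m in picks]
target = hf.synthesize_saxs_profile(comps, [0.08, 0.77, 0.15],
                                    noise_level=0.0, seed=3)
best = hf.multistate_fit(target, pool, n_states=(3,))[3][0]
for m, w in zip(best.members, best.weights):
    print(f"member {m}: Rg {pool.member_rg[m]:.1f} A, weight {w:.3f}")
print(f"chi = {best.chi:.2e}")
```

```
member 13: Rg 22.0 A, weight 0.770
member 47: Rg 23.2 A, weight 0.150
member 52: Rg 20.3 A, weight 0.080
chi = 1.46e-10
```

The three planted members (weights 0.08/0.77/0.15) are identified with
their weights reproduced to solver precision and χ ≈ 0.  With realistic
noise the member identities blur (smooth scattering profiles are nearly
collinear) but the weight structure remains recoverable — see the
methods note.

## Command line

The full comparative study (13 variants × open/closed = 26 systems by
default) runs from the shell:

```bash
hingeflex report --seed 7 --out study/          # everything, all tables
hingeflex generate --out trajs/ --format xyz    # just the trajectories
hingeflex analyze --variant R175W --state closed --out one/
hingeflex saxs-fit --variant WT --out fits/
```

Reports are TSV/Newick/JSON: per-system metrics, region-verdict
matrices per state, JS divergence matrices with dendrograms, the α
panel, and ensemble tables (state, member, fraction, R_g, D_max, θ,
χ²).  Runs are bit-reproducible per seed; a YAML config (see
`hingeflex.pipeline_cli.StudyConfig` for keys) overrides any default.

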