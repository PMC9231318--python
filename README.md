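# poreform

Trajectory analysis for peptide pore formation on lipid membranes.

Amyloid peptides bound to a membrane diffuse laterally, aggregate, and can
anneal into membrane-spanning pores that conduct water and ions — a leading
mechanism for the cytotoxicity of amyloid-beta oligomers.  `poreform`
implements the analysis pipeline used to characterise that process in
molecular simulations, for people who have trajectories (or want controlled
synthetic ones) and need the standard observables:

* **Aggregation kinetics** — peptide chains *i*, *j* belong to one cluster
  when a path of pairs connects them with centre-of-mass distances
  d(COM_i, COM_j) < 1.5 nm under the minimum-image convention; the cluster
  count per frame tracks aggregation.
* **Conformation metrics** — radius of gyration
  R_g = sqrt(Σ m_i |r_i − r_com|² / Σ m_i) and Shrake–Rupley
  solvent-accessible surface area (probe 0.14 nm, deterministic
  Fibonacci-lattice sphere points).
* **Free-energy landscape** — over X = SASA and Y = R_g,
  P(X,Y) = Z⁻¹ exp[−βW(X,Y)], inverted as W = −RT ln P (min-shifted to 0);
  local minima are the metastable pore-like and fiber-like aggregates, and
  the barrier between them is the minimax saddle over occupied bins:
  ΔG‡ = min over paths of max W − W(basin).
* **Channel order** — nematic order parameter S, the largest eigenvalue of
  Q = ⟨(3ûûᵀ − I)/2⟩ over per-chain backbone principal axes (1 = parallel
  bundle, ≈0 = isotropic).
* **Pore permeation** — axial number density ρ(z) of water/ions in a
  channel-centred cylinder, the density-based potential of mean force
  ΔG_PMF(z) = −k_B T ln(ρ_z/ρ_bulk), lumen radius from the enclosed pore
  area (r = sqrt(A/π)), direct contacts (< 0.4 nm), and complete
  face-to-face permeation events.

Because microsecond membrane trajectories are expensive, the package ships
first-class synthetic generators with known ground truth: an aggregating
bead-chain scenario (25 chains of 28 beads in a 20 × 20 × 11 nm box at
310 K), exact Boltzmann samplers ρ(z) ∝ exp(−U(z)/RT) for prescribed axial
potentials, static pore/fiber scenes, and an analytic two-basin (SASA, R_g)
surface.  Every analysis is validated by recovering what the generators
prescribe.

## Worked example

```python
import poreform as pf

surface = pf.TwoBasinSurface()          # depth difference 1.0, barrier 2.5
x, y = surface.sample(1_000_000, temperature=310.0, seed=11)
landscape = pf.landscape_from_series((x, y), temperature=310.0, bins=(50, 50),
                                     ranges=[surface.x_range, surface.y_range])
basins = pf.find_basins(landscape, max_w=2.0)
barrier = pf.barrier_height(landscape, basins[0], basins[1])
```

prints (`python examples/02_free_energy_landscape.py`):

```
pore-like  basin: SASA =  427.0 nm^2, Rg = 3.59 nm, W = 0.00 kcal/mol
fiber-like basin: SASA =  428.0 nm^2, Rg = 4.11 nm, W = 0.96 kcal/mol
recovered depth difference: 0.96 kcal/mol (constructed: 1.00)
barrier deeper->shallower: 2.38 kcal/mol (constructed: 2.50)
```

The sampler drew a million conformational points from the Boltzmann
distribution of a surface with a compact pore-like well and an extended
fiber-like well; histogramming and inverting those samples recovers the
basin positions, their 1 kcal/mol stability difference and the ~2.5
kcal/mol ridge between them — the same computation one runs on real
(SASA, R_g) series from a trajectory, where the deeper pore-like basin
means pores are the favoured aggregate.

The other `examples/` scripts demonstrate each capability on small inputs:
aggregation kinetics (`01`), the density-based PMF (`03`, recovering a
2.5 kcal/mol water barrier from particle positions alone), pore radius and
order parameter of pore vs fiber scenes (`04`, lumen radius 0.554 nm for a
ring built at 0.550 nm), and permeation counting (`05`).

A thin CLI mirrors the library:

```sh
poreform generate --scenario aggregation --n-frames 100 --seed 1 --out-dir run
poreform pipeline run/topology.gro run/frames.gro --out-dir run/analysis
```

`pipeline` runs every stage in order and writes tidy CSVs plus a JSON
summary; individual subcommands (`clusters`, `metrics`, `fel`,
`density-pmf`, `permeation`, `pore-radius`) run one stage each.

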