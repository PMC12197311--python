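# thschain

Monte Carlo simulation and nematic-order analysis of semi-flexible
polymers modelled as linear chains of **tangent hard spheres**, in bulk
and between flat hard walls.

Athermal, rod-like polymers order entropically: past a critical packing
density φ they trade orientational freedom for packing room and align
along a common director — the isotropic-to-nematic (I–N) transition of
lyotropic liquid crystals. This package provides the complete
simulation-and-analysis chain used to study how that transition depends
on chain length, stiffness, and confinement:

* the hard-sphere chain model (diameter σ = 1, tangent bonds within a
  tolerance dl = 6.5×10⁻⁴, harmonic bending potential
  U(θ) = k_θ·θ², no torsional potential, k_BT = 1);
* a semigrand Metropolis Monte Carlo engine with conventional moves
  (reptation, end-mer rotation, flip, intermolecular reptation,
  end-group rotation) and chain-connectivity-altering moves
  (simplified end bridging and its intramolecular variant), with
  configurational-bias regrowth; chain lengths fluctuate uniformly in
  [N_min, N_max] at fixed total sphere count;
* preparation protocols: dilute self-avoiding growth at φ = 0.001,
  stratified chain deletion, wall insertion (dconf = 0…3 confined
  axes), stepwise isotropic compression, and density scans;
* the long-range order descriptor: per-chain long axes from the
  inertia tensor, the traceless order tensor
  **Q** = ⟨**u u**ᵀ⟩ − **δ**/3, the scalar order parameter
  q = (3/2)λ₁ (λ₁ the eigenvalue of largest magnitude; q = 1 ideal
  prolate nematic, 0 isotropic, −0.5 ideal oblate), the director
  **n**, and end-to-end statistics;
* transition analysis: φ_I−N as the lowest density with q ≥ 0.5, and
  nonlinear fits of the empirical laws
  φ_I−N = a + b·N_av + c·r^N_av (chain length),
  φ_I−N = a·e^(b·k_θ) + c (stiffness), and
  φ_eff,I−N = a − b·c^d_wall (confinement);
* synthetic fixtures (ideal prolate/oblate/isotropic rod systems, toy
  law curves) so every analysis stage is testable without simulation.

Geometry bookkeeping follows the standard definitions
φ = (π/6)·N_at·σ³/L³ for the cubic cell and, under confinement, the
effective density φ_eff = (π/6)·N_at·σ³/((d_wall−σ)^dconf·L^(3−dconf))
that refers to the wall-accessible volume (sphere centres keep σ/2 off
each wall).

See `docs/methods.md` for the algorithms, defaults, and the reduced
problem sizes the test suite runs at.

## Worked example

Build the reference system (100 chains, N ∈ [6,18], N_av = 12,
k_θ = 9) at φ = 0.001, compute its nematic order, and evaluate the
chain-length law at the reference length:

```python
>>> from thschain import (ModelParams, MCState, initialize_dilute,
...                       nematic_order_of_system, evaluate_model)
>>> params = ModelParams()          # k_bend=9, window [6, 18]
>>> system, cell = initialize_dilute(100, params, phi0=0.001, seed=1)
>>> system.n_atoms, round(cell.L, 2)
(1200, 85.65)
>>> round(nematic_order_of_system(system, cell).q, 3)
-0.056
>>> law = {"a": 0.076, "b": -1.236e-5, "c": 0.257, "r": 0.936}
>>> round(evaluate_model("length", law, 12), 3)
0.192
```

The dilute system is isotropic — q is near zero, at the finite-sample
level expected for 100 chains — and the fitted chain-length law places
the bulk transition of the N_av = 12 system at φ_I−N ≈ 0.192. A
density scan of a reduced (20-chain) replica of this system,

```python
>>> from thschain import ScanPlan, density_scan
>>> st = MCState(system, cell, params, seed=1)
>>> curve = density_scan(st, ScanPlan(grid=(0.05, 0.15, 0.25)))
```

shows q rising from the isotropic baseline toward 1 as φ crosses the
transition region.

The same functionality is available from the shell:

```sh
thschain fixture --kind ideal_prolate --nch 10 --n 12 --out pro.xyz
thschain analyze pro.xyz            # prints q=1.000000 ...
thschain init --nch 100 --nav 12 --phi 0.001 --seed 1 --out sys.xyz
thschain scan --config run.toml     # density scan -> scan.csv
thschain fit --model confinement --points points.csv
```

Configurations are exchanged as extended XYZ (exact round-trip, cell
and density metadata in the comment line, per-sphere chain tags), with
an optional PDB export for molecular viewers.

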