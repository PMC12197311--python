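# Methods

## Model

Polymers are linear chains of tangent hard spheres of uniform diameter
σ, which is the unit of length; temperature is fixed at k_BT = 1.
Non-bonded sphere pairs interact through the hard-sphere potential —
overlap (r < σ) is forbidden, contact (r = σ) and anything beyond are
free. Bonded neighbours must lie in the thin shell [σ, σ + dl] with
dl = 6.5×10⁻⁴ σ, i.e. the spheres are tangent up to a numerical
tolerance. Chain stiffness enters through a harmonic bending potential
U(θ) = k_bend·θ² on the angle θ between successive bond vectors
(θ = 0 is a straight triplet); there is no torsional potential. The
default k_bend = 9 k_BT·rad⁻² produces rod-like chains whose residual
flexibility is dominated by the hard 1–3 constraint, which truncates θ
at 120°.

Chain lengths fluctuate in a semigrand ensemble over the window
[N_min, N_max] (default [6, 18], average N_av = 12) under a
chemical-potential spectrum μ(N). The default spectrum is flat: with
symmetric length-transfer moves a flat μ makes the stationary length
distribution uniform over the window, which is the targeted spectrum.
A per-class μ hook exists for calibration but is not needed in any
test. The total sphere count and the chain count are exactly conserved
by every move, so N_at = N_ch·N_av holds identically when the system
is initialized that way (see below).

The simulation cell is cubic with edge L. `dconf` ∈ {0,1,2,3} counts
the confined axes: 0 is fully periodic bulk, 1 a slit pore, 2 a
rectangular channel, 3 a closed box. Confinement is a pair of flat
impenetrable walls per axis at 0 and L (so d_wall = L), and sphere
centres must stay within [σ/2, L − σ/2]; the convention is that
confinement is applied from the z-axis backwards (dconf=1 → z,
dconf=2 → y,z). The packing density is φ = (π/6)·N_at/L³; under
confinement the effective packing density
φ_eff = (π/6)·N_at/((L−σ)^dconf·L^(3−dconf)) refers the occupied
volume to the wall-accessible volume.

## Monte Carlo engine

One sweep is N_at attempted moves, each drawn from the move mix.
Conventional moves: reptation (delete one chain end, regrow at the
other), end rotation (resample a terminal sphere about its anchor),
flip (rotate an interior sphere about the axis through its bonded
neighbours; all adjacent bond lengths are preserved exactly),
intermolecular reptation (transfer a terminal sphere between chain
ends, changing both lengths by one), and end-group rotation (rigid
rotation of a terminal segment of m ∈ {2,3,4} spheres about the bond
connecting it to the rest of the chain — this preserves every bond
length and every bending angle, so it is accepted whenever it creates
no hard violation).

Chain-connectivity-altering moves displace no spheres: simplified end
bridging (sEB) bonds a chain end to an interior monomer of another
chain that happens to lie inside the bond window [σ, σ+dl], severs the
victim there, and grafts the freed segment onto the attacker;
simplified intramolecular end bridging (sIEB) does the same within one
chain, relocating the chain end. Both conserve N_at and N_ch; sEB
changes two chain lengths (window-checked a priori), sIEB none.
Acceptance uses the bending-energy change of the four affected angles,
the chemical-potential change, and the forward/reverse ratio of
admissible (victim, severed-side) candidate counts. Because the
capture shell is only dl wide, bridging fires at an appreciable rate
only in dense systems — which is where it is needed; at dilute
conditions the length spectrum is mixed by intermolecular reptation.

Single-bead regrowth uses an orientational configurational-bias
scheme: trial orientations are drawn directly from the bending
Boltzmann density p(θ) ∝ sinθ·exp(−k_bend θ²) (inverse-CDF table,
4096 nodes), the bond length uniformly from [σ, σ+dl]. The bending
factor then cancels between proposal and target, so the Rosenbluth
trial weights reduce to 0/1 hard-constraint indicators and the
acceptance ratio is the ratio of admissible trial counts. New and old
weights are both evaluated in the environment with the shuttling bead
removed, which makes the scheme exactly balanced. The trial count
n_trial(φ) is 1 below φ = 0.1 and ⌈30φ⌉ (capped at 20) above; a single
trial already accepts ≈85–100 % of moves at dilute conditions.

The default move mix assigns 0.8 to the conventional moves (equal
split) and 0.15/0.05 to sEB/sIEB; it is freely configurable and the
statistical tests use mixes emphasising the moves that matter for the
property under test (e.g. intermolecular reptation for the length
spectrum). A null proposal — no eligible geometry, e.g. a flip on a
dimer — counts as attempted-and-rejected, which keeps the per-kind
bookkeeping consistent with detailed balance. All randomness flows
from one PCG64 generator with an explicit 64-bit seed; identical seed
and configuration reproduce the trajectory bit for bit.

Numerical tolerances: pair distances ≥ σ(1 − 10⁻¹²) count as
non-overlapping (contact is legal); minimum-image displacements are
applied on periodic axes only. Geometry that can span more than one
bond (rotation segments, unwrapped chains) is accumulated bond by
bond, never through a single minimum-image difference, so small cells
(L down to ~3σ) are handled exactly.

## Preparation protocols

Initial configurations are grown at φ = 0.001 as self-avoiding tangent
walks with bending-Boltzmann-biased growth directions (20 direction
trials per bead, chain regrown from scratch on a dead end). Chain
lengths are drawn uniformly over the window *conditioned on the exact
total* N_ch·N_av, by repairing an unconstrained draw with random ±1
adjustments and then randomising with symmetric pair transfers. The
conditioning matters: with the total left free, the fixed-total
ensemble reached after initialization has a genuinely tilted length
marginal and the uniform-spectrum property would fail for physical
reasons.

Chain deletion removes a prescribed fraction of chains at fixed cell
size, stratified by length class (largest-remainder apportionment of
the survivor counts), so the length spectrum and hence N_av are
preserved to integer resolution.

Compression is isotropic and stepwise: each step multiplies the cell
edge by a shrink factor and moves every chain rigidly so that its
centre of mass follows the compression map — a literal affine map of
sphere coordinates would compress the tangent bonds below contact at
the first step. On periodic axes the centre scales affinely; on
confined axes it is mapped through the wall-accessible slab
[σ/2, L − σ/2], so walls move with the cell without systematically
pushing wall-adjacent chains into the forbidden shell. A step that would create
any violation is reverted and retried after a few MC relaxation sweeps
(default 10; the scans use 3). The step size adapts: it grows
geometrically (exponent 1.5, floor 0.97) while steps succeed and
resets to the schedule's fine step (default 0.999) after a rejection.
The final step lands on the target density to 10⁻⁶. Targets above
φ = 0.60 are refused (random-close-packing guard for rod-like chains).

Confinement of a periodic configuration chooses, per newly confined
axis, a wall position on the periodic circle that no chain's padded
arc covers (padding σ/2 per side), then re-anchors every chain rigidly
in the wall frame. If no uncovered point exists at the current density
the operation raises — confinement is intended to be applied at dilute
conditions.

Density scans compress progressively along an increasing grid.
Equilibration at each point is a fixed minimum number of sweeps plus a
stationarity check on q (three consecutive block means within 0.01,
capped by a maximum); production samples q every `snapshot_stride`
sweeps and the curve records mean and naive standard error of the
per-snapshot values. Confined scans report φ_eff, bulk scans φ.

## Orientational order

Each chain is unwrapped (bond-by-bond minimum image), centred, and
reduced to the eigenvector of the smallest eigenvalue of its inertia
tensor I = Σ(|x|²δ − xxᵀ) with unit masses — the chain's long axis.
(The tensor is computed with centred coordinates throughout; an
uncentred dyadic term would break translation invariance.) The order
tensor Q = ⟨uuᵀ⟩ − δ/3 over chains is symmetric and traceless; its
eigenvalues are sorted by decreasing absolute value and the scalar
order parameter is q = (3/2)λ₁, the director the matching eigenvector
(reported with the first-nonzero-component-positive convention;
physically n ≡ −n). Magnitude sorting is the reading that assigns the
ideal oblate phase q = −0.5; sorting by signed value would assign it
+0.25. q = 1 for the ideal prolate phase, 0 for an isotropic system up
to a finite-sample bias of order N_ch^(−1/2) (≈0.09 mean |q| at
N_ch = 100, ≈0.2 at N_ch = 20 — the reduced-scan thresholds below are
set with this bias in mind). Scans report the production-window mean
of per-snapshot q.

## Transition analysis

The transition density φ_I−N of a scan is the smallest grid density
with mean q ≥ 0.5 (grid-resolution criterion; linear interpolation is
available but never the default). Curves that never reach the
threshold yield an undefined transition, which propagates into fits as
a dropped point. Three empirical laws are fitted by nonlinear least
squares (scipy `curve_fit`, up to 10 restarts with jittered initial
guesses, R² = 1 − SS_res/SS_tot):

* chain length: φ_I−N = a + b·N_av + c·r^N_av
* stiffness:    φ_I−N = a·e^(b·k_bend) + c
* confinement:  φ_eff,I−N = a − b·c^d_wall (a is the bulk limit
  d_wall → ∞)

Noise-free synthetic data reproduce all published coefficient sets to
R² = 1; parameter recovery from data with Gaussian noise σ = 0.002
returns a and c within 10 %.

## Synthetic fixtures

Ideal-phase fixtures use straight rods because they realize the
reference order tensors exactly: all-parallel rods on a square lattice
(prolate, q = 1), rods with axes equally spaced over a half-circle in
the xy-plane stacked at distinct heights (oblate, q = −0.5 for any
N_ch ≥ 3 by the exactness of the planar average), and rods with axes
uniform on the sphere placed by rejection (isotropic; valid to
φ = 0.05). Toy curves evaluate a transition law on a grid and add
i.i.d. Gaussian noise, seeded.

## Problem sizes and what the tests show

The statistical and phenomenological tests run at reduced scale,
chosen so the full suite completes on a single CPU:

* trimer angle law: 10⁴–3×10⁴ sweeps, thinned to ≈1500–2000 samples
  (thinning matters: at k_bend = 9 consecutive sweeps are strongly
  correlated and an unthinned KS test rejects a correct sampler);
* length spectrum: the N_ch = 100 reference system at φ = 0.001,
  ≈140 sweeps, 25 pooled snapshots;
* bulk scan: N_ch = 20, grid 0.05–0.30 in two legs. The isotropic leg
  (0.05–0.15) uses a short budget (250 sweeps per point). Through the
  transition region (0.20–0.30) relaxation slows by orders of
  magnitude — nematic order has to nucleate — so that leg uses slower
  compression with ten relaxation sweeps per rejected step (the
  annealing during gradual compression is where order predominantly
  develops), a deep trial count (n_trial = 16 rather than the density
  schedule's 9; the extra insertion trials roughly triple move
  acceptance in the dense regime) and progressively longer
  equilibration, up to 2000 sweeps at φ = 0.30. At this size the
  isotropic baseline |q| is ≈0.2 and the box edge at φ = 0.30 (7.5σ)
  is shorter than an extended 18-mer, so rods must tilt off the box
  axes to avoid their own periodic images; the scan checks the
  qualitative transition (crossing q = 0.5 on the grid between 0.1 and
  0.3), not the full-size transition density. Even with this protocol,
  nucleation within the budget is not guaranteed for every random
  stream — roughly one trajectory in three stays trapped isotropic at
  φ = 0.30; the test's fixed-seed trajectory is one that equilibrates.
  The monotonicity check allows two combined standard errors plus the
  0.2 isotropic noise floor, because a kinetically delayed
  intermediate point can sit anywhere inside that band;
* fully confined scan: N_ch = 30 started at φ = 0.005, grid 0.05–0.15
  (φ_eff up to ≈0.20, the density scale at which the bulk system is
  already nematic), where the signed production mean |q| stays below
  0.2 — the suppression of long-range order by full confinement.
  Compression under walls maps chain centres through the accessible
  slab (see above) — without that, nearly every step strands a sphere
  inside the shrinking wall shell and compression stalls.

What passing these tests does and does not show: the analytic
bookkeeping (densities, descriptor identities, law evaluation) is
exact at any scale; the sampler is statistically correct against
closed-form oracles; the phase phenomenology is reproduced in
direction and order of magnitude. The quantitative full-scale
transition points (φ_I−N = 0.192 at N_at = 1200, 0.063 at
N_at = 10⁴) require equilibration budgets far beyond this suite and
are reached here only through the published law coefficients, which
the fitting machinery recovers exactly from noise-free data.

## Known limitations

* Bridging moves rely on chance partners in a dl-wide shell; their
  acceptance at dilute conditions is essentially zero, so semigrand
  mixing there rests on intermolecular reptation alone.
* The equilibration criterion (block stationarity of q) is a
  heuristic; deeply metastable states at high density can pass it.
* Compression near φ ≈ 0.3 of isotropic rod systems is slow (many
  reject–relax cycles); the adaptive step mitigates but does not
  remove this.
* No cluster or collective rotation moves: orientational
  decorrelation at high density proceeds through reptation, which is
  slow for long chains.
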