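# Model and numerical methods

`matesim` simulates mating between budding-yeast cells in two dimensions.
Each haploid cell is a deformable disc (initial radius 1 µm, the 2D
abstraction of a ~2 µm yeast cell confined to a filter surface) whose shape
responds to the pheromone secreted by cells of the opposite mating type.
One model time unit corresponds to 100 s, matching the order of magnitude of
observed projection growth; all lengths are in micrometres.

## Cell shapes: level sets

Every cell carries its own level-set function φ(x, t) on a shared uniform
grid, with φ < 0 inside, φ > 0 outside, and the membrane Γ = {φ = 0}.  The
membrane moves with outward normal speed V by the Hamilton–Jacobi equation
φ_t + V|∇φ| = 0, discretized with first-order Godunov upwinding.  The speeds
here are ~10⁻³ µm/s against a mesh of 0.04–0.08 µm, so the CFL number per
membrane step is ~10⁻², and first order is ample; the step refuses to run if
the CFL constraint is violated.

Signed-distance character is restored every 10 membrane steps by geometric
reinitialization: the zero contour is extracted by marching squares (exact
to the bilinear interpolant, so the interface moves ≪ h/2), densified to
h/6 segments, and node distances are recomputed with a KD-tree, keeping the
inherited sign.  Inside the simulation loop only the nodes in a padded
bounding box of the contour are refreshed — every consumer of φ (sources,
masks, normals, contact tests) reads it near an interface.

Membrane-bound quantities live on N markers (default 400; 200 at the batch
resolution) resampled to equal arc length from the contour at every
reinitialization; between resamplings markers are advected with V along the
outward normal (∇φ/|∇φ| interpolated at the markers).  Species are
transported to the new markers by projecting each new marker onto the
nearest segment of the old polyline; per-resampling mass drift is < 0.5%
(tested).

## Extracellular fields

α-factor (sensed by **a**-cells), **a**-factor (sensed by α-cells), and the
protease Bar1 (secreted by Bar1+ **a**-cells) obey

    ∂f/∂t = D Δf + S(x, t) − k_eff(x) f + κ₁ f ηᵢ(x, t)

on the exterior nodes, with no-flux conditions at the outer rectangle and
at every membrane (cell bodies exclude ligand; mass is conserved up to decay
— tested to 10⁻⁶).  Secretion is a membrane-localized Gaussian in the
level-set function, S = A·exp(−100 φ²) with A = 1000/√(2π); in polarized
mode it is additionally confined to the projection tip by the factor
exp(−20 (1 − u₂/u₂max)²), with u₂ read from the nearest marker.  Before a
cell polarizes, secretion is isotropic.  Bar1 is co-secreted with a-factor
at the fixed ratio S_B = S_a/50 and enhances α-factor degradation:

    k_eff(x) = k_α + k_bar1 · B(x)/(max B + 10⁻⁶).

A uniform background production rate C can be added to the α-factor source
(modeling pheromone from cells outside the simulated patch).

Two integrators are provided.  The explicit Euler–Maruyama integrator
(`solver_mode='explicit'`) implements the equation literally, with
multiplicative noise increments N(0, dt) i.i.d. per node and negative
undershoots clamped (and counted; < 0.1% of node-steps at the default noise,
tested).  Because the fields relax on the 1/k ≈ 0.1–1 s timescale — far
below the membrane motion timescale — the default mode (`'qss'`) solves the
quasi-steady state D Δf − k_eff f + S = 0 by a sparse LU factorization that
is cached while the exterior mask and decay field are unchanged.  The two
routes agree to < 1% at steady state (tested).

In QSS mode the field noise is applied to the membrane-sampled values at
its stationary amplitude: linearizing the SPDE about the QSS, the relative
fluctuation of f is an Ornstein–Uhlenbeck process with stationary standard
deviation κ₁/√(2k) and correlation time 1/k ≪ one membrane step, so each
sampled marker value is multiplied by (1 + κ₁/√(2k)·ξ), ξ ~ N(0,1),
independently per membrane step.  Using the raw per-step variance instead
would overstate the noise the explicit integrator actually delivers, since
decay and diffusion erase increments older than ~1/k.

Membrane sampling is bilinear using exterior-side nodes only, followed by
the adaptive-range normalization f̃ = f / max_membrane(f) + 0.1, which keeps
the input in [0.1, 1.1] regardless of the absolute pheromone level — the
model's stand-in for the dose-adaptation machinery of the pathway.  The
sensing domain of the max is the cell's own membrane.

## Membrane polarity

Each cell runs a two-stage cascade on its markers: u₁ (free Gβγ) is driven
by f̃ through a saturating Hill term with sensitivity β₁ and by cooperative
positive feedback; u₂ (active Cdc42) is driven by u₁ with the same
structure.  The auxiliary species v₁, v₂ multiply the degradation rates and
integrate the difference between the membrane mean and a setpoint
(k1ss, k2ss) — integral feedback that confers adaptation and pins the total
amount of polarity factor.  Multiplicative noise (κ₂ on u₁, κ₃ on v₁; none
in the second stage) uses N(0, dt) increments per marker.  Reactions and
noise step with Euler–Maruyama at dt = 0.01 time units; the lateral surface
diffusion (Laplace–Beltrami reduced to the 1D periodic Laplacian in arc
length) is applied implicitly in Fourier space, which is exact for the
periodic stencil and unconditionally stable.

The default β₁ = 0.92 places the f̃ working range on the steep part of the
activation curve; the supersensitive genotype raises β₁ to 2.5, saturating
the term so that spatial differences in pheromone no longer translate into
activation differences (tested as a strict inequality of relative spans).

The rate constants of the cascade and the field decay rates are not printed
in the source study (they live in unavailable supplementary material), so
they are calibration parameters of this package.  They were fixed — before
any batch statistics were collected — by requiring, in order: (i) a uniform
noise-free membrane holds its setpoints (mean u₁ → k1ss, mean u₂ → k2ss
within 1%); (ii) a noise-free two-cell scenario polarizes within ~150 s,
tracks the partner direction, and mates around 650 s, with half the boundary
speed roughly doubling the mating time; (iii) the qualitative noise table is
reproduced (κ₂ ∈ {0, 3, 5} gives high/intermediate/low mating success,
κ₁ = 50 abolishes polarization); (iv) the supersensitive genotype fails to
mate; (v) Bar1 visibly steepens the sensed α-factor gradient at high
background.  The frozen values are the defaults of `PolarityParams` and
`ScenarioConfig`.  Two choices deserve comment:

* γ₂ = 0.02 keeps the u₂ positive feedback negligible at the setpoint
  (where a larger value drives the u₂/v₂ integral loop through a Hopf
  bifurcation into a limit cycle) while remaining saturated at the
  polarized peak.
* The Bar1 parameters (k_bar1 = 3·k_α, D_B = 30 µm²/s) give a smooth
  degradation halo around the a-cell.  A much stronger, tightly localized
  choice lets the polarized Bar1 secretion carve a degradation hole exactly
  at the cell's own tip — the cell blinds itself to the gradient it is
  trying to read — and Bar1+ cells then mate *worse* than bar1Δ, contrary
  to observation.

Decay lengths implied by the defaults: λ_α = √(D_α/k_α) ≈ 3.2 µm and
λ_a ≈ 2.2 µm at the default D_a = 10 µm²/s, so both pheromones form
informative gradients over the 2–4 µm cell spacing; at D_a = 0.1 µm²/s the
a-factor decay length (0.22 µm) is too short to reach the partner and
mating degrades, while at D_a = 100 µm²/s the field is nearly homogeneous
and only the f̃ normalization preserves directionality.

## Polarisome, velocity, growth

The polarisome is the midpoint of the minimum-arc-length membrane window
containing at least τ = 0.4 of the total u₂ mass, found by an exact
windowed scan (equivalent to the O(N²) brute force, tested).  On a marker
grid the minimal window count is degenerate, so ties are broken by the
largest contained mass — which recovers the peak-centered continuum
interval — then by the smallest start index (a uniform profile yields the
window at marker 0).

The boundary speed is V = V_amp · ũ₂ · max(0, ⟨n, d_max⟩), where d_max is
the outward normal at the polarisome and ũ₂ is u₂ filtered by a circular
moving average over 5% of the membrane plus an exponential filter with a
15-step time constant — without filtering, the noisy u₂ makes d_max jitter
and the tip fragments.  Growth activates once max(ũ₂)/mean(ũ₂) > 1.5 (the
polarization criterion; secretion switches from isotropic to polarized at
the same moment).  V is extended from the markers to a 6h narrow band by
nearest-marker lookup before the level-set step.

Growth is frozen locally where a membrane comes within h/2 of another cell
(no interpenetration — the success criterion fires on polarisome proximity
first) and within 3h of the domain wall.

## Mating detection and assays

Every 50 s the polarisome positions, angles, pairwise polarisome distances
and projection lengths are recorded.  A mating succeeds at the first sample
where the distance between the polarisomes of an **a**/α pair falls below
the mesh size (0.04 µm at the reference resolution; max(0.04, h) in
general) *and* the distance has decreased on average over the trailing five
samples — projections that merely pass close by do not count.

Mating efficiency is successes/replicates.  Projection directions are
measured per sample as the angle of the polarisome about the initial cell
center relative to the partner axis — counterclockwise-positive for the
α-cell and clockwise-positive for the **a**-cell, clipped to [−π/2, π/2] —
so partners pointing at each other give equal angles; a simulation's
direction pair is the per-cell time average, and a batch's diagonal
deviation is the mean perpendicular distance of the pairs from the identity
line (the coordinate difference |θ_a − θ_α| is an alternative reading of
"distance from the diagonal"; the perpendicular convention is used
throughout and implemented in one place).  Mating discrimination is the
fraction of successful matings whose partner is the pheromone-producing
α-cell; mating competition tallies which of two **a**-cell genotypes
reaches the shared α-cell.  Group comparisons use Fisher's exact test
(SciPy), one-sided where the hypothesis is directional (Bar1+ efficiency
exceeding bar1Δ), two-sided otherwise.

## Operating resolutions and problem sizes

The reference configuration is the printed geometry at h = 0.04 µm with 400
markers.  Batch assays and the acceptance script run at the package's
standard operating resolution — h = 0.08 µm, 200 markers, QSS solves every
5 membrane steps (0.05 time units, still ≫ faster than any field change) —
where a two-cell simulation of 1800 s takes a few seconds and resolution
studies showed the same qualitative behavior; the success threshold follows
the mesh (0.08 µm).  Stochastic batches use 20 replicates with seeds
spawned deterministically from a root seed, one independent stream per
noise source per cell.

## What the simulations do and do not show

The generator of all test data is the simulator itself; no external data is
read.  The model is generic: it abstracts receptor/G-protein kinetics into
two saturating stages, replaces dose adaptation with an explicit
normalization, omits advection/dilution of membrane species by membrane
growth (the integral feedback largely compensates; dropping them permits a
much larger time step), stops at polarisome contact (no fusion), and is
two-dimensional.  Conclusions about relative effects — polarized versus
isotropic secretion, supersensitivity, Bar1, background pheromone — are the
intended use; absolute times and rates are order-of-magnitude only, and the
noise amplitudes κ map onto physical fluctuation sizes only through the
calibration choices described above.

Known quantitative limitations at the frozen calibration: supersensitive
cells form a weak, non-growing Cdc42 bump rather than a full noise-driven
projection, so their direction-pair deviation (~0.2 rad) understates the
fully random ~0.7 rad of projecting supersensitive cells (the bump is still
weakly guided by the ~3% residual activation differential, and without
growth there is no random tip lock-in); Bar1+ rescue of mating at
background C = 100 is partial (~30–50% versus ~80%), because within the
no-flux / basal-decay field model a background of that size exceeds what
the calibrated Bar1 sink can clear without blinding the cell to its own
gradient; and very slow a-factor diffusion (0.1 µm²/s) impairs rather than
abolishes mating under noise, because the multiplicative sampling noise is
scale-invariant and the f̃ normalization rescales even a vanishing signal.
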