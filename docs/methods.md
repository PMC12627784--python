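# Methods

`idpscale` quantifies how compact an intrinsically disordered protein (IDP)
segment is — summarised by the apparent Flory exponent ν of the scaling law
R_E = ρ₀·N_res^ν — from four kinds of data: single-molecule FRET bursts,
donor fluorescence-lifetime decays, FCS diffusion measurements, and
residue-level coarse-grained simulations. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Gaussian-chain distance model and efficiency inversion

The donor–acceptor distance r of a disordered segment is modelled as a
Gaussian chain,

    P(r) = 4πr² (3/2π⟨r²⟩)^{3/2} exp(−3r²/2⟨r²⟩),

parameterised by the mean-squared distance ⟨r²⟩ alone (R_E = √⟨r²⟩). The
measured mean transfer efficiency is ⟨E⟩ = ∫E(r)P(r)dr with
E(r) = R₀⁶/(R₀⁶+r⁶). Because ⟨E⟩ is strictly decreasing in R_E, the
inversion ⟨E⟩ → R_E is unique.

* Quadrature: adaptive Gauss–Kronrod on (0, 12·R_E) with breakpoints at R₀
  and R_E; the truncated tail is bounded by exp(−3·12²/2) of the integrand
  scale, far below the 1e-10 tolerance.
* Root finding: Brent's bracketed method on log R_E over
  [10⁻³·R₀, 10³·R₀]; monotonicity guarantees the bracket.
* No contour-length cap is applied to P(r): the Gaussian chain deliberately
  admits distances beyond the physical contour length. This is a property of
  the model, kept for consistency with its closed form.
* Förster radii used throughout: 5.6 nm (Alexa488/Alexa594) and 7.7 nm
  (AF594/LD655).
* Scaling fits use nonlinear least squares on R_E = ρ₀N^ν (log–log OLS as
  the seed), weighted when per-point uncertainties are given
  (`absolute_sigma` in that case); the reported error of ν is the square
  root of the ν-diagonal of the fit covariance. N_res is taken as the
  label-site index difference and is supplied by the caller, never inferred.

## Burst analysis

The all-photon burst search tests each photon against a centred window
(default 1000 µs, threshold 5 photons) and merges maximal runs of
qualifying photons, with one refinement: runs are split where successive
qualifying photons are further apart than one window, since such photons
share no window. Bursts with fewer than 50 photons are discarded.
Background is estimated as constant per-channel rates from the inter-burst
photons and subtracted as rate × burst duration (clipped at zero).

Corrected efficiency and stoichiometry per burst:

    E = I_A^D / (γ·I_D^D + I_A^D),   S = (γ·I_D^D + I_A^D) / (… + I_A^A),

where I_A^D is first corrected for donor leakage (α, default 0.086) and
acceptor direct excitation (δ, default 0.046), and γ (default 0.323)
rescales the donor channel. E and S are clipped to [−0.1, 1.1] before
histogramming because shot noise can carry corrected values outside [0, 1].
Population structure in the (E, S) plane is fitted either with a seeded
maximum-likelihood Gaussian mixture (diagonal covariances) or, when
selection boxes are given (the nanocluster workflow, where acceptor
quenching pushes S below 0.5), with independent single Gaussians per box.

## Lifetime model and MLE distance extraction

The donor-channel decay over one laser period T is a three-population
model convolved with the instrument response function (IRF):

    I(t) = {A_D e^{−t/τ_D} + A_FRET ∫P(r) e^{−(t/τ_D)[1+(R₀/r)⁶]} dr
            + A_bg Σᵢ αᵢ e^{−t/τ_bg,i}} ⊗ IRF,   A_D + A_FRET + A_bg = 1.

Numerical choices:

* Periodicity: every exponential is wrapped over preceding excitation
  periods (division by 1 − e^{−T/τ}) and the IRF convolution is circular —
  appropriate for 25/40 MHz repetition where decays do not complete between
  pulses.
* The distance integral uses 400 log-spaced nodes on [0.05, 8]·R_E with
  trapezoid weights renormalised to 1 (so the FRET amplitude is exactly the
  t = 0 fraction); validated bin-wise against a 2000-node direct summation.
* The likelihood is per-bin Poisson conditioned on the total count
  (multinomial), so only the decay *shape* is fitted; a 1e-9 uniform floor
  on bin probabilities keeps the surface smooth where a trial model
  predicts empty bins.
* With amplitudes fixed by the workflow, R_E is found by bounded scalar
  minimisation on log R_E; free amplitude subsets are re-mixed by softmax
  over the unclaimed probability mass, preserving the sum rule. A fit with
  A_FRET = 0 is flagged unidentifiable rather than fitted. Optional
  profile-likelihood confidence intervals use the 1.92 log-likelihood rise.
* The time origin is shared between decay and IRF; no shift parameter is
  fitted by default.

Background decays (acceptor-free condition) are fitted as an N-exponential
model (default 4) on pooled counts — pooling and fitting-the-sum are
identical under Poisson statistics. Acceptor photobleaching collapses the
FRET term into the donor exponential; the post-bleach fit supplies τ_D and
A_bg, and equality of pre/post apparent donor lifetimes (5% tolerance) is
the no-intermolecular-FRET control.

The global scaling fit shares (log ρ₀, ν) across labelling variants through
R_E(N) = ρ₀N^ν inside the decay model, with a free FRET amplitude per
variant. Bootstrap rounds resample 70% of cells per variant without
replacement (cell-level resampling, seeded), sum the sampled histograms and
refit; ten rounds by default. The optimiser is a nested scheme: outer
Nelder–Mead over (log ρ₀, ν), inner bounded 1-d amplitude MLE per variant
operating on pre-convolved component shapes (convolution is linear in the
amplitudes, so the IRF convolution is done once per shape).

## Phasor analysis

Phasor coordinates are the normalised cosine/sine Fourier coefficients of
the decay at the repetition frequency ω = 2π/T, computed as discrete sums
over bin centres. Calibration divides the complex phasor by the IRF's
phasor, mapping the IRF to the zero-lifetime point (1, 0). Binning biases
the phasor of a sampled exponential inward from the universal semicircle by
about 2π²(τ/T)/n_bins, so semicircle geometry should be checked on finely
sampled decays; with ~8·10⁶ bins the deviation is below 1e-6 (this is the
condition exercised in the validation suite). Outlier rejection is a
single-pass mean ± 3 SD cut applied to g and s separately.

## FCS

Photon streams are binned and correlated with a multi-tau scheme (16 lags
per level, bin width doubling per level, symmetric normalisation), which
equals a direct correlator on the same coarsened traces by construction.
Fits use the single-component 3D diffusion model with the structure
parameter fixed at a calibration value (default 0.2) unless freed; the
heterogeneity readout is the *distribution* of per-window diffusion
coefficients over repeated short acquisitions, not multi-component fits.
Converting τ_D to D = w₀²/4τ_D requires the lateral beam waist w₀
(instrument calibration, default 0.3 µm); the Stokes–Einstein relation
r = k_BT/6πηD then gives a hydrodynamic radius.

The Brownian-walker generator emits photons with a 3D-Gaussian detection
weight from walkers in a periodic box. The box truncates the slowest
diffusive relaxation at τ_box ≈ L²/4π²D, so recoveries fit only lags well
below τ_box; defaults (L = 3.2 µm, w₀ = 0.3 µm, w_z = 0.9 µm) keep the
residual bias near 5%.

## Coarse-grained simulator

One bead per residue; nonbonded energetics are the Urry-scale
hydrophobicity-scaled Lennard-Jones split (Ashbaugh–Hatch, ε = 0.8368
kJ/mol, 20 Å cutoff, pair λ and σ arithmetic means) plus a screened-Coulomb
term (Debye length 10 Å, dielectric 80, 35 Å cutoff). Harmonic bonds
(r₀ = 3.8 Å, k = 10 kJ/mol/Å², energy ½k(r−r₀)²) connect backbone
neighbours; folded domains are held by an elastic network joining all
structured-residue pairs closer than 12 Å at their input-coordinate
distances with the same rigidity. Histidine is neutral by default.

Dynamics: BAOAB-split Langevin at 300 K with drag 10 u/ps and a 10 fs
timestep; internal units Å/ps/u. Nonbonded pairs come from a Verlet list
(2 Å skin, rebuilt on a half-skin displacement) built by direct scan — at
the few-hundred-bead scale this package targets, a cell grid would not pay
for itself. 1-2 bonded pairs are excluded from nonbonded terms; pair
truncation is plain (unshifted). Bead overlap below 0.1 Å or a non-finite
potential aborts the run with the last stable state, and a pathological
start is handled by re-seeding rather than by topology surgery.

Equilibration is staged: nonbonded interactions ramp 0 → 1 at 150 K with a
soft-core distance clamp and a 10× reduced timestep, then temperature ramps
to 300 K, then the timestep ramps back, then a final relaxation at full
settings during which the spherical confining wall (used in multi-chain
runs to nucleate a single cluster quickly) is removed. Single-chain runs
pin the first bead and use no wall. Stage durations are configurable and
default to desk-scale values.

Desk-scale problem sizes: the shipped validation runs use a 42-residue
amphiphilic diblock — a 32-residue aromatic-rich (W/Y, mean λ ≈ 0.84)
hydrophobic block and a 10-residue +5e hydrophilic block. The aromatic
composition is deliberate: at 32 residues a natural FG-motif composition
(λ̄ ≈ 0.56–0.65) sits on its single-chain collapse transition and flips
between compact and expanded states run-to-run, whereas long FG domains at
native hydrophobicity collapse decisively; raising λ̄ restores that
decisive collapse at desk length. The dilute state is sampled as six
pinned, non-interacting copies in one box (the sparse-lattice setup);
clusters of 5 and 10 chains assemble under a temporary spherical wall
during equilibration. Runs use ~19 k staged equilibration steps, then
2.5 ns (single) or 4 ns (cluster) production with frames every 5 ps. These
conditions resolve trend-level questions (chain expansion with cluster
size; charged block at the cluster surface); they are far below the
multi-microsecond, 50-chain scale needed for converged absolute ν values
of ~500-residue constructs, and the absolute exponents from these runs
should be read as qualitative.

## Trajectory analysis

Chains belong to one cluster when any interchain bead pair is closer than
7 Å (minimum image); clusters are connected components of that graph.
Density profiles histogram bead distances from the mass-weighted centre of
mass of the largest cluster (unwrapped by walking bonds through the
minimum image, then shifting whole chains), convert with shell volumes to
mol amino acids/L, and scale each block by n_chain/n_block so blocks of
different lengths are comparable; bin width defaults to 5 Å. Contact maps
count interchain residue pairs within 1.5·σ̄ (σ̄ the mean bead diameter of
the pair), normalised by mean chain count × frames.

Frame correlation is folded into error bars through an effective sample
size: the distance autocorrelation (averaged over chains) is fitted with a
stretched exponential A·exp(−(t/τ₀)^β), summarised by the integrated
relaxation time τ = (τ₀/β)Γ(1/β); n_eff = n_frames/τ, clamped to
[1, n_frames], with τ < 1 frame treated as fully independent sampling; then
SEM = SD/√(n_eff·n_chains). A frame-static series is assigned one
effective frame so its SEM is carried by the chain count alone. Inter-label
distances are reported as mean distances (the convention used when
comparing simulations with the FRET-derived scaling), and the Flory fit of
mean distance vs sequence separation delegates to the shared power-law
fitter with the SEMs as weights.

## Synthetic-data generators

Every generator draws from the same forward model its analysis inverts and
returns a truth record with all parameters; recovery tests read truth only
from that record, and all generators are bit-reproducible given a seed.

* Decays: multinomial allocation of a fixed photon budget over bins
  (fixed-acquisition convention; per-bin Poisson available). Default
  conditions mirror the lifetime workflows: τ_D = 3.6 ns, R₀ = 7.7 nm,
  30% background amplitude, four-component background, Gaussian IRF of
  0.2 ns FWHM at 25 ns period.
* Burst streams: square-profile molecule transits on Poisson background;
  donor-excitation photons split DA/DD by the true E; a donor-only species
  reproduces the near-zero-efficiency peak. No photophysics beyond constant
  brightness (no blinking or in-burst bleaching).
* FCS traces: periodic-box Brownian walkers as above.
* Conformer ensembles: fractional Brownian motion along the chain index
  (Hurst = ν) sampled by Cholesky factorisation, so ⟨R²(N)⟩ = (ρ₀N^ν)²
  holds exactly in expectation; ν = 1/2 reduces to an ideal random walk.
* Planted micelles: core-block beads at small radii, shell-block beads at
  larger radii, per-frame jitter — structure without dynamics, for testing
  the density-profile and cluster machinery against known geometry.

What passing tests on these generators show: that the estimators invert
their own forward models without bias at realistic counting statistics,
and that the analysis stages compose correctly. What they do not show:
robustness to instrument artefacts absent from the generators (detector
afterpulsing, IRF drift, dye photophysics, chromatic aberration) or to
model misspecification of real chains (non-Gaussian distance
distributions, dye–linker dynamics).

## Known limitations

* The lifetime fit conditions on total counts; absolute intensities are not
  used, so components whose shape contribution vanishes (e.g. an
  ultra-short background lifetime) are not identifiable.
* The phasor transform's binning bias (above) makes coarse-binned
  monoexponential phasors sit slightly inside the semicircle.
* The simulator is desk-scale by design: no GPU path, no replica exchange,
  no slab coexistence geometry; entanglement through elastic-network
  triangles is handled by re-seeding, not detected geometrically.
* Burst analysis implements no PIE lifetime filtering or two-channel
  variance analysis; FCS has no triplet or anomalous-diffusion terms.
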