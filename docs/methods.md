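# Methods

## Model and estimators

**MBAR.** All frames from all umbrella windows are pooled; because every
window shares the same underlying low-level Hamiltonian, the unbiased energy
cancels from the weight denominators and only the analytic harmonic biases
enter. The reduced window free energies `f_k = βf_k^(b)` solve

    exp(−f_k) = Σ_n exp(−u_k(x_n)) / Σ_t N_t exp(f_t − u_t(x_n)),  u_k = βW_k,

anchored at `f_1 = 0` (the equations determine f only up to a constant). The
per-frame unbiased weight is `w⁰(x_n) = 1/Σ_k N_k exp(f_k − u_k(x_n))`, kept
as a log-weight throughout.

*Solver.* The default is a hybrid: five self-consistent sweeps, then L-BFGS
on the convex MBAR objective `Σ_n ln Σ_k N_k e^{f_k−u_nk} − Σ_k N_k f_k`
(whose gradient costs the same single O(N·S) pass as one sweep), then
self-consistent polishing until the residual — the maximum absolute change of
any `f_k` over one sweep — falls below the tolerance (default 1e-8, budget
10 000 iterations). A full Newton step would require an O(N·S²) Hessian pass,
which is not affordable at S ≈ 400+; limited-memory quasi-Newton achieves the
same superlinear behaviour at first-order cost. A pure `scf` mode exists for
cross-checking; the two agree to the tolerance.

*Kronecker fast path.* When the window centers form a full Cartesian product
grid and the force constants depend only on the per-axis center (the standard
2D umbrella setup), the reduced bias splits as
`u[n,(i,j)] = A[n,i] + B[n,j]`. Every sum over windows then factorizes into
two thin matrix products, `(N×n₁)·(n₁×n₂)`, so one sweep over 882 000 frames
and 441 windows takes ~0.15 s instead of ~4 s, with per-frame row-minimum
shifts for overflow safety. Irregular window sets fall back to a chunked
dense path (≤ 4×10⁷ bias-matrix entries in memory at once); the two paths
agree to machine precision and a unit test asserts it.

**Surfaces and wTP.** Histogram bins are half-open rectangles centered on a
regular grid; the default bin width equals the window spacing (the
conventional choice — the bin geometry is otherwise a free parameter).
Boundary points belong to the higher-index bin. Frames outside the grid are
counted and excluded from surfaces but participate fully in the MBAR
normalization. `F_L` is reported relative to an anchor bin (configurable;
default: the occupied bin of lowest free energy, i.e. the most stable basin
carries zero free energy, matching the product-state-as-reference
convention). The wTP correction `ΔF(η)` is reported raw (un-anchored): it is
a physical per-bin free-energy difference between Hamiltonians, so a constant
energy offset `U_H = U_L + c` must surface as `ΔF = c` exactly — this also
fixes the convention `F_H = F_L(anchored) + ΔF(raw)`, asserted bin-by-bin.
All exponential sums use log-sum-exp.

*Per-bin uncertainty.* `F_L` carries the first-order importance-sampling
variance `1/(β² n_eff)` with `n_eff = (Σw)²/Σw²`; `ΔF` carries a delta-method
variance from the weighted spread of `e^{−βΔU}`. Both treat frames as
independent — with a Metropolis generator this requires a decorrelating
stride (tests use stride 10 where standard errors are asserted). The full
MBAR covariance Θ over the S window states plus M bin-restricted unbiased
states is available separately: Θ = [ (WᵀW)⁺ − N + 1·1ᵀ/N_total ]⁺ with
Moore–Penrose pseudo-inverses (relative cutoff 1e-12; the inner matrix is
singular by construction), and δ²ΔF(a,b) = Θ_aa − 2Θ_ab + Θ_bb. A replicate
test confirms the predicted variance is within a factor of 2 of the spread
over 20 independent simulations.

**Reweighting entropy.** Within each bin, with normalized perturbation
weights `p_l ∝ w⁰_l e^{−βΔU_l}`, `S = −(1/ln n) Σ p_l ln p_l ∈ [0, 1]`
(`S = 1` for n = 1 by convention). The 1/ln n normalization is chosen so that
the GP noise `σ_n² = e^{−S}` lies in [e⁻¹, 1] — a bounded, dimensionless
reliability score; the effective sample size `1/Σp²` is reported alongside,
and bins where one frame carries > 99.9 % of the weight are flagged.

**GPR.** Zero-mean GP with kernel
`k(η,η′) = σ_f² exp(−|η−η′|²/2l²) + α σ_n²(η) δ(η,η′)`; a single isotropic
length scale is shared by both RC dimensions, and the Kronecker delta applies
only to identical training indices (two distinct observations at the same
location are not noise-correlated). Observations are centered before fitting
and the mean restored on prediction, since the posterior-mean formula assumes
a zero prior mean. Hyperparameters {l, σ_f, α} maximize the log marginal
likelihood by L-BFGS on log-parameters with analytic gradients, 8 starts (one
heuristic: median pairwise distance and value spread; 7 seeded log-uniform
restarts), bounds l ∈ [0.01, 10] Å, σ_f ∈ [1e-3, 1e3] kcal/mol,
α ∈ [1e-6, 1e3]. The kernel system is solved by Cholesky; diagonal jitter
1e-10, escalated ×10 up to 1e-6, is added only if factorization fails.
Predictive variance is clipped at zero (a warning fires below −1e-8). The
homoscedastic special case is cross-checked against scikit-learn's
RBF + WhiteKernel GP in the test suite; what is smoothed is the corrected
surface `F_H` (ΔF smoothing can be had by passing `delta_f` instead).

**Stationary points.** Central differences with step h = 0.025 Å by default
(half the conventional window spacing; halving h moves smooth-surface
saddles by < 1e-3 Å). Candidates come from a coarse scan for cells whose
corners bracket sign changes in both gradient components; damped Newton
(step capped at 4h) refines until the gradient norm is below
1e-4 kcal/mol/Å. Duplicates within 0.02 Å merge; classification is by
Hessian eigenvalues with |λ| < 1e-6 reported as "degenerate", never silently
assigned. A saddle-free surface yields an empty result plus a warning, not an
exception. ΔG‡ and ΔG are anchor-invariant differences; their uncertainties
combine per-bin variances assuming independence.

**Electrostatics.** Fields are evaluated with positions converted Å → bohr
(1 bohr = 0.529177 Å) so charges in e give fields in atomic units, summed
over all charges with no cutoff. The dipole–field energy uses the explicit
unit chain e · Å · (a.u. → 51.42 V/Å) → eV → kcal/mol (× 23.0605); negative
values stabilize the transition state. Ensemble averages of field projections
go through the same perturbation-reweighted bin average as any observable.

## Synthetic data

The generator emulates the reference umbrella protocol: windows on a regular
RC grid (default 1.50–4.00 Å in 0.05 Å steps), identical harmonic restraints,
Boltzmann sampling at 298.15 K by Metropolis Monte Carlo (Gaussian proposals,
default step `(βk)^{-1/2}`, acceptance rate logged with a warning outside
[0.1, 0.9]), burn-in then strided recording. The restraint strength is not
stated by the protocol; the default 100 kcal/mol/Å² puts the restrained RC
spread (~0.077 Å) on the order of the window spacing so neighbors overlap
well. All randomness flows from one named seed; per-window chains are
advanced in lockstep so large window sets sample in seconds.

The default validation system is a double well along η₁,
`U = h((η₁/a)² − 1)² + ½k η₂²` with barrier h = 5 kcal/mol and wells at
a = ±0.8 — chosen so every stationary point lies strictly inside a [−1, 1]
window range — plus a smooth Gaussian-bump high-level offset (max 2 kcal/mol)
that keeps the two Hamiltonians well-overlapped while shifting the high-level
saddle measurably (to (0, −0.202), barrier 5.80 kcal/mol, both known
analytically). An optional orthogonal harmonic coordinate with
position-dependent stiffness exercises the nontrivial-marginal case; its
Gaussian integral is closed-form, so the oracle stays exact.

Oracles: the analytic surface is the per-bin Boltzmann average of the
marginal free energy by tensor Gauss–Legendre quadrature (default order 7,
refined in tests), which is exactly what the histogram estimator converges
to; window free energies come from dense trapezoidal quadrature of the
biased partition functions; the wTP correction from the ratio of high/low
bin integrals.

*What the toy does not emulate:* correlated MD dynamics (Metropolis with a
stride gives nearly independent frames, so the variance model is cleaner
than for real trajectories), many-atom energy noise, QM convergence failures,
and anharmonic solvent coupling. Passing tests therefore demonstrate
estimator correctness and calibration under the stated sampling model, not
robustness to every pathology of production QM/MM data.

## Problem sizes used in the test suite

The full-scale validation uses 21×21 windows × 2000 frames (882 000 frames,
441 windows) for surface recovery and end-to-end transition-state location —
the largest size at which the whole battery stays comfortably interactive
(~2 min) — and smaller, strided systems (5×5 windows × 500 frames; 3×3 × 300
× 20 replicates) where per-bin standard errors or replicate spreads are the
quantity under test. The two worked dipole–field examples are exact
arithmetic and run instantly.

## Known limitations

- Single temperature only; no multi-temperature or replica-exchange
  reweighting.
- One shared GP length scale for both RC dimensions; no Matérn or
  anisotropic kernels, no sparse approximations (n ≈ 2600 bins is the
  practical ceiling for the dense Cholesky).
- wTP requires `u_high` on every frame of every occupied bin and refuses
  bins with missing values rather than silently dropping frames.
- The per-bin delta-method errors assume independent frames; feed
  decorrelated (strided) data or treat them as lower bounds.
- No minimum free-energy path tracing; only point-wise stationary analysis.
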