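# Methods

## Model and conventions

The generative model is a stable multivariate Ornstein–Uhlenbeck (OU)
process, `dx/dt = W x + σ ξ(t)`, with uncorrelated unit-variance white noise
per channel and a single noise amplitude σ (default 1) for all channels.
All eigenvalues of `W` must have negative real part (stability); complex
eigenvalues occur in conjugate pairs because `W` is real.

Internally all rates are in rad/s; every user-facing frequency is in Hz. A
spectral peak (f_peak, hwhm) in Hz corresponds to the eigenvalue pair
`−2π·hwhm ± i·2π·f_peak` rad/s. Fixing one internal convention matters
because the same matrix is consumed by the spectral, simulation and
covariance code; the Hz↔rad/s mapping appears exactly once, in
`spectra.eigenvalues_from_prescription`.

The analytic channel-averaged power spectrum is evaluated in trace form,
`P(f) = (σ²/N)·‖(i2πf I − W)⁻¹‖²_F`, which is identical to the mean diagonal
of the cross-spectral matrix `S(f) = σ² R R†`, `R = (i2πf I − W)⁻¹` (asserted
to machine precision in the tests). A Lorentzian-superposition form computed
from the eigenvalues alone is also provided; the two coincide exactly for
normal matrices and are both useful: the Lorentzian form previews a
prescription before any matrix exists, the trace form evaluates a realized
(generally non-normal) matrix.

## Spectral prescriptions

* **Normal** — `n_peaks` peaks in geometric progression from `base_freq`
  with ratio `ratio` (defaults 6, 2 Hz, 2.6: evenly spaced on a log axis,
  top peak ≈ 238 Hz, keeping significant power between 0 and 300 Hz).
  Peak HWHM is `hwhm_factor · f_peak` (default 0.2); the exact published
  peak table exists only as a figure, so these defaults are configurable
  stand-ins with the right qualitative layout.
* **Entrained** — peaks at exact small-integer ratios, default 2.7 and
  8.1 Hz (1:3), producing cross-frequency phase locking.
* **Incomplete** — the Normal sequence with its `incomplete_removed`
  (default 2) highest peaks dropped.
* **Background** — no peaks; pure 1/f² spectrum.
* **Random** — the Normal peak count drawn uniformly on the log-frequency
  axis over the Normal span, fresh per seed.

The real eigenvalues (the background) are drawn uniformly from
`real_eig_bounds`. The default bounds are the min and max real parts of the
*Normal* group's complex pairs under the same configuration, and all groups
reuse them, so the non-oscillatory background is conserved across scenarios.
For a reduced configuration (e.g. 2 peaks) the bounds come from those two
pairs, which keeps the eigenvalue scale of desk-size studies homogeneous.

## The inverse eigenvalue problem

The flow parametrises candidates as `X(V) = V Λ_b V⁻¹`, where `Λ_b` is the
real block-diagonal form of the prescription (2×2 rotation–scaling blocks
`[[a, b], [−b, a]]` for pairs a ± ib, scalars for real eigenvalues). Real
arithmetic throughout guarantees a real `W` and exact closure under
conjugation. The misfit is `J(V) = ½‖R‖²_F` with `R = X − Π(X)`, where Π
overwrites the prescribed positions (a random 35% of the off-diagonal
entries, drawn with a seed of its own) with their prescribed value 0. The
diagonal is never constrained. From `dX = [dV·V⁻¹, X]` the exact gradient is

    ∇_V J = (X Rᵀ − Rᵀ X)ᵀ V⁻ᵀ,

validated against central finite differences (relative error < 1e−5 over 20
random instances in the suite, observed ~1e−10). The commutator structure is
the least-squares gradient flow consistent with similarity-parametrised
isospectral descent.

Numerical choices:

* **Start** `V(0)`: i.i.d. uniform entries on a width-one interval whose
  center is itself uniform on [−0.5, 0.5]; candidates are redrawn until the
  condition number is below 200. This makes the start bounded in (−1, 1) but
  almost never symmetric about zero.
* **Integrator**: LSODA (stiff-capable, adaptive), rtol 1e−6 / atol 1e−8,
  run in geometrically growing flow-time chunks (first chunk sized from the
  initial decay rate `dJ/dt = −‖∇J‖²`, then ×3 per chunk). A terminal event
  stops integration the moment the residual crosses the threshold.
* **Stopping rule**: the reference residual 10 holds for the 80-node, 35%
  reference problem; it is rescaled linearly by the number of prescribed
  entries (the residual is a Frobenius norm over exactly those entries).
  For 20 nodes / 35% the threshold is 0.601.
* **Stall rule**: if the relative residual decrease over a chunk falls below
  1e−4 (after the first few chunks), the flow is declared stalled and the
  current matrix is returned with `converged=False` and a warning —
  convergence below the threshold is empirically extremely slow, so further
  integration does not improve the solution notably.
* Whatever the stopping point, `W = V Λ_b V⁻¹` carries the prescribed
  eigenvalues to numerical precision; only the prescribed-entry misfit is
  approximate. An ill-conditioned `V` (which would degrade eigenvalue
  accuracy) is flagged.
* Determinism: a fixed seed fixes `V(0)` and the constraint mask, and the
  integrator is deterministic, so identical calls return numerically
  identical matrices.

## Forward simulation

Euler–Maruyama, `x ← x + dt·W·x + √dt·σ·η`, from a zero state with 2 s of
discarded burn-in. Defaults dt = 2·10⁻⁴ s and 60 s duration resolve the
default band layout; the step is rejected unless `dt ≤ 0.1/ρ(W)`. An exact
one-step OU update is not needed at these step sizes (the Welch spectrum of
a simulated reconstruction matches the analytic curve to mean
|Δlog₁₀P| < 0.15 over 1–100 Hz in the suite). The optional colored drive
replaces η with a one-pole exponentially filtered process (time constant τ,
default experiment value 10 ms) rescaled to unit variance; it steepens the
high-frequency drop-off from 1/f² to 1/f⁴.

Welch estimation uses 2 s Hann segments with 50% overlap and is reported in
the *two-sided* density convention so that it is directly comparable to the
analytic spectra; spectrograms use 0.5 s windows. Connectivity recovery from
traces regresses forward differences `(x(t+dt)−x(t))/dt` on `x(t)` by least
squares; forward differencing biases the estimate by O(dt·W²), which is
negligible at the default step and documented rather than corrected.

## Covariance and complexity

The stationary covariance solves `W C + C Wᵀ = −σ² I`. The closed form via
the eigendecomposition `W = L D L⁻¹` (`C̃_ij = −Q̃_ij/(λ_i + λ̄_j)`) is used
when `cond(L)` is moderate; otherwise the Lyapunov equation is solved
directly (scipy) and a warning is issued. Both routes agree to < 1e−7 on
random stable instances (tested on 100).

TSE complexity is computed from Gaussian subset entropies of C:
`C_N = Σ_k [⟨H(size-k subset)⟩ − (k/N)·H(all)]`. Subsets are enumerated
exactly for N ≤ 12 and sampled (200 subsets per size, seeded) above; the
Monte-Carlo standard error is available on request. Singular submatrices are
regularized with a 1e−12 jitter on the log-determinant. The measure is zero
for independent channels and invariant to channel permutation and uniform
rescaling.

## Hierarchy, node removal, motifs, bootstrap

**TNS** of node i sums the absolute off-diagonal input and output weights.
Self-connections are excluded: they are (almost) uniformly inhibitory and
would mask hub structure if included. Ranks descend with TNS (rank 1 =
strongest). The hierarchy curve is TNS versus rank normalized to the rank-1
value; the *half rank* is the smallest rank whose cumulative TNS reaches half
the total. Excitatory/inhibitory input totals sum the positive/|negative|
row entries (diagonal included, matching the row-sum definition of net
input); net input/output are the raw row/column sums.

**Node removal** deletes one node (row and column), recomputes the analytic
spectrum and scores `error_i = Σ_f |log₁₀P⁽ⁱ⁾ − log₁₀P| / Σ_f |log₁₀P|`
(normalization by the unperturbed log-spectrum magnitude; one convention
fixed, stated with the result). The Pearson correlation of error with the
removed node's rank summarizes how strongly hubs dominate the rhythms;
Spearman is available. A removal that destabilizes the submatrix (possible
for non-normal W) is reported per node and excluded from the correlation.

**Motif census.** Hub set = nodes at or below the half rank. Connections are
thresholded at 5% of the largest off-diagonal magnitude within the hub set —
the underlying matrices have no exact zeros, so a presence threshold is
unavoidable; it is a parameter and is reported with every census. Two
families are enumerated exhaustively for sizes 2–5: directed cycles (single
or reciprocal connections) and radial stars (center reciprocally linked to
leaves; leaf–leaf connections ignored). Occurrences are presence-based:
extra edges among the chosen nodes never disqualify a placement. Equivalence
rules: within a reciprocal loop the direction of excitation vs inhibition is
not distinguished (loop classes EE, EI, II), and reciprocal loops may be
permuted; single-connection cycles are canonical up to rotation. The
probability of a class is `P = 100·F/M` with M the number of placements of
that topology and size; group-level censuses sum F and M over the group's
matrices. The census is exhaustive by design and refuses oversized hub sets
rather than silently sampling.

**Bootstrap.** Group comparison pools both samples, re-splits at random into
the original sizes and accumulates the null distribution of the mean
difference; the p-value integrates the null from the left end up to the
observed value (a two-sided variant doubles the smaller tail). The study
driver defaults to 10⁴ iterations (the reference analysis used 10⁶; the
p-value granularity 1/n_iter is the only difference).

## Desk scale and what the tests show

The suite and the acceptance script run the pipeline at desk scale: 20-node
networks with 2-peak prescriptions (and the 2.7/8.1 Hz Entrained bands),
3–5 matrices per group, 10³–10⁵ bootstrap iterations. This preserves every
qualitative contrast of the full 80-node, 20-matrix study — Background
lowest in TSE complexity, flatter hierarchy and weaker rank–removal
correlation than peaked groups, counterbalanced (EI) reciprocal pairs
dominant among hubs, quarter-cycle high-frequency lags in Background
networks — and the tests assert exactly those directional statements plus
the exact oracles (gradient, covariance, isospectrality, equivalence rules).
Synthetic prescriptions are the *only* inputs: the generator emulates the
band layout of real EEG/MEG spectra but none of their nonstationarity,
measurement noise, volume conduction or non-Gaussian features, so passing
tests validate the reconstruction/analysis machinery, not fits to any
recording.

## Known limitations

* The IEP solution is non-unique by construction; only ensemble properties
  are meaningful, not individual entries of one reconstruction.
* The flow may stall above threshold for unlucky starts on hard instances;
  the result is still exactly isospectral and is returned flagged.
* Sub-peak spectral structure (peak skew from the 1/f² background) shifts
  recovered Welch peak locations slightly below the prescribed frequency;
  at the default bands the shift is well inside the reported tolerances.
* The linear Gaussian model cannot produce bistable or otherwise
  non-Gaussian dynamics; spindle- and sharp-wave-like transients it does
  produce are chance excursions of a stationary Gaussian field.
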