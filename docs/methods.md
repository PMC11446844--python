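# Methods

## The model

Whole-brain activity is approximated as a first-order vector autoregression
(VAR(1)):

    r_t = W r_{t-1} + W_lx L_t + eps_t

where `r_t` is the D-vector of neural activity, `W` the D x D dynamics
("effectome") matrix of direct causal weights, `L_t` a vector of
independent white-noise laser powers driving opsin-expressing source
neurons through `W_lx`, and `eps_t` additive noise of arbitrary bounded
covariance — including slow unobserved common inputs. One model tick
corresponds to the timescale of monosynaptic interaction (nominally 1 ms;
recorded as metadata only, nothing in the estimators depends on it). The
laser enters at the same tick as the noise, so its first-order effect on
downstream neurons appears one step later.

The anatomical stand-in for `W` is the signed synaptic-count matrix: entry
(i, j) is the aggregate synapse count from presynaptic neuron j to
postsynaptic neuron i, positive for acetylcholine and dopamine, negative
for GABA, serotonin, glutamate and octopamine, with aggregated connections
below 5 synapses discarded (below that count reconstructions are not
proofread). Rows are postsynaptic and columns presynaptic throughout, so
`r_{t+1} = W r_t` reads with the standard matrix-vector action.

### Construction details

* Duplicate (pre, post) rows in a synapse table are summed **before**
  thresholding. The threshold keeps aggregated counts `>= 5` by default;
  the comparison operator is configurable (`>` reproduces the stricter
  reading).
* One sign per presynaptic neuron (Dale's law). When a table carries
  conflicting neurotransmitter labels for one neuron, the count-weighted
  majority decides; unknown labels are a hard error unless coercion to a
  configured default sign is explicitly requested (and then logged).
* Autapses, if present after thresholding, are kept as diagonal entries.
* Neurons with no surviving incoming or outgoing connection are pruned.
* `scale_spectral` multiplies the matrix by `target / rho(W)` (spectral
  radius rho); the cumulative factor is stored so raw counts are
  recoverable. Whole-brain simulation uses target 0.99 (strictly stable);
  eigencircuit analysis tolerates 1.0.

## Estimators

Let `X_t` be the stimulated-and-observed sources, `Y_{t+1}` the observed
targets. Since the laser has known diagonal covariance,
`Cov[X_t, L_t] = W_lx` and `Cov[Y_{t+1}, L_t] = W_xy W_lx`, so

    W_xy = Cov[Y_{t+1}, L_t] (Cov[X_t, L_t])^+

identifies the causal submatrix under arbitrary noise correlation that is
independent of the laser. `iv_2sls` implements this covariance form and the
equivalent two-stage regression (L -> X, then X-hat -> Y); the two agree
exactly when the laser count matches the source count and the first stage
is full rank. Sample cross-covariances are mean-removed by default
(robustness to drift) — closed-form textbook examples can disable this
with `demean=False`. The pseudo-inverse drops singular values below
1e-10 of the largest; a first stage whose effective rank cannot identify
the requested sources raises an error naming the rank.

`iv_bayes_map` replaces the second stage with the per-target MAP solution
of the Gaussian model

    (Xh' Xh / sigma^2 + V^{-1}) w = (Xh' y / sigma^2 + V^{-1} mu)

with prior mean `mu = s c` (s a scale hyperparameter, c the signed counts)
and diagonal prior variance `V = |s c| + c0`. The constant `c0 > 0`
(default 0.01 s) keeps every prior variance positive so the estimator
remains consistent even where the anatomy is wrong; an isotropic variance
recovers the classic ridge-toward-mu form exactly. When `sigma^2` is not
supplied it is plugged in from per-target second-stage residuals of the
plain 2SLS fit. Regressions are per-target (row-wise), which keeps memory
linear in the number of targets and permits sparse storage.

Hyperparameters can be chosen by closed-form evidence maximization
(`y ~ N(X mu, sigma^2 I + X V X')`, evaluated with the Woodbury identity)
or by held-out grid search; both return the full score surface.

Recovery is scored by RSS = sum (w-hat - w)^2 and by R^2 with the variance
of the true weights about their mean as denominator. With nearly-all-zero
true weights this denominator approximates sum w^2; the convention is
stated here because R^2 over a weight set has no single standard
definition. A constant truth leaves R^2 undefined (reported as missing).

## Synthetic study conditions

The generator emulates the statistical features of the fly connectome that
drive estimation difficulty, and nothing else (no neuropil structure,
degree heterogeneity, or cell types):

* extreme sparsity — default 1e-4 (~0.01% of ordered pairs connected);
* integer counts `5 + Geometric(p = 0.3)` (heavy-ish tail, support at the
  threshold, one parameter);
* per-presynaptic-neuron sign, 35% inhibitory (the approximate fraction of
  GABAergic/glutamatergic neurons);
* seed-deterministic output.

Ground-truth effectomes are drawn entrywise from the connectome prior
`N(s c, |s c|)` **without** the `c0` constant, so anatomical zeros stay
exactly zero and the prior mean is never equal to the realized truth —
each replicate estimates under a misspecified prior.

The confounded two-neuron scenario is `X_t = L_t + Z_t + e_x`,
`Y_t = beta X_{t-1} + Z_t + e_y`, with Z an AR(1) process
(`z_t = phi z_{t-1} + a eta_t`, default persistence 0.995, innovation
amplitude 0.2 in units of the private-noise s.d., i.e. stationary s.d.
about 2). A boxcar-smoothed-noise alternative with matched stationary
variance is provided.

### Scaled-down convergence experiment

The estimator-efficiency study runs at D = 2000 with density 6e-3. That
density matches the fly's **per-neuron** synaptic partner count (~12)
rather than its raw pair density; matching the 1e-4 pair density at
D = 2000 would leave the average neuron with 0.2 partners and the
single-source estimand nearly empty. The stimulated source is the neuron
with the largest out-degree (the interesting regime: many true downstream
weights). SNR is laser power over noise power, l/c = 10/1. The weight
scale s = 5e-6 is set by an explicit signal-to-noise calculation: the
per-weight IV error s.d. at n = 1e5 is about sqrt(Var(r)/(n l)) ~ 1e-3,
and s is chosen so a typical nonzero weight sqrt(s c-bar) ~ 6e-3 sits
several error s.d. above it while the summed power of the ~25 true
weights stays below the accumulated error over all 2000 candidate weights
— the regime in which the prior matters: raw IV drowns in the zero-weight
noise while IV-Bayes suppresses it. Ladder 1e3 / 1e4 / 1e5 samples
(nested prefixes of one recording), 10 replicates with ground truth and
noise redrawn from split seeds. The problem sizes keep a full run in the
low minutes on one CPU.

## Eigenmodes and eigencircuits

`top_modes` computes the k largest-magnitude eigenpairs with seeded ARPACK
(subspace `max(2k + 10, 40)`, fixed start vector) or densely below
D = 300, sorts by |lambda| with ties broken by descending real then
imaginary part, fixes each vector's phase (largest-magnitude entry real
positive), pairs conjugates exactly, and verifies residuals
`||W v - lambda v|| <= tol |lambda_1|`.

The spectrum summary folds angles into [0, 180] degrees (0 = monotonic
decay, 180 = sign flip each step) and fits log10 |lambda| against log10
rank by ordinary least squares over all retained ranks. Eigenvector
"correlation" is implemented as absolute cosine similarity of normalized
real/imaginary parts without mean removal (loadings are already near zero
mean at realistic sparsity); parts with norm below 1e-8 of the vector are
dropped, so real modes contribute one vector and complex pairs two.

A mode's eigencircuit is the smallest set of neurons whose squared-modulus
loadings ("power" = |v_i|^2) reach 75% of the total, capped at 100 members
with the cap flagged. Anatomical localization is scored as the fraction of
within-circuit synapse counts per annotated region.

## Circuit simulation

A circuit matrix W describes one discrete interaction step of T = 10 ms.
Sampling at Delta = 1 ms uses the principal fractional power:

    r_{t+Delta} = W^(Delta/T) f(r_t + u_t),      f = rectification

Three numerical choices deserve explanation:

* **Rotation-preserving state (default).** For inhibitory circuits the
  dominant eigenvalues are negative or complex, so `W^(Delta/T)` is
  genuinely complex. Projecting it to its real part entrywise yields a
  *nonnegative* matrix whenever Delta/T < 1/2 (the principal power of a
  negative eigenvalue has positive real part), which makes the rectified
  dynamics monotone: no suppression can ever occur and winner-take-all
  competition is impossible. The simulator therefore keeps the complex
  state, rectifies on its real part (an entry whose real part is negative
  is zeroed entirely), and reports real parts as activity. Composing
  Delta-steps over one T recovers W exactly in the linear regime, and the
  linear evolution from an eigenvector matches lambda^(t/T) v to machine
  precision. `build_propagator` still returns the real-part matrix for
  inspection, together with the discarded imaginary residual and the
  reconstruction residual ||P^(T/Delta) - W||/||W||; a "real" state mode
  runs the projected dynamics for comparison.
* **Scaling to maximum eigenvalue 1 (default).** A complete
  mutual-inhibition circuit has spectrum {-(n-1) w, +w}: its *competition*
  subspace (differences between neurons) carries the positive eigenvalue.
  Normalizing the largest eigenvalue (real part) to 1 makes that subspace
  marginally stable, which is what lets the winning neuron sustain its
  response for the entire 150 ms stimulus. Normalizing the spectral
  radius instead puts the competition mode at 1/(n-1), which decays to
  nothing within a few interaction steps; it remains available as the
  "radius" option (and is the right choice for stability of whole-brain
  VAR(1) simulation, where 0.99 is used).
* **Membrane leak off by default in the protocols.** An explicit
  per-sample leak exp(-Delta/tau) with tau = 0.5 ms multiplies the state
  by e^-20 over one 10 ms interaction step, erasing the rotation memory
  that drives both the winner-take-all suppression and the
  opponent-motion ordering. The 0.5 ms membrane time constant is instead
  regarded as folded into the count-to-weight scaling; the leak remains a
  separable flag on `build_propagator` and `CircuitProtocol` for
  sensitivity analysis.

Matrices are required to be diagonalizable within an eigenvector-condition
tolerance of 1e12; a defective matrix raises an error recommending a small
jitter. Stimuli are step inputs (onset, duration, amplitude per neuron
set); protocol defaults follow the stimulation conventions used for these
circuits: 150 ms steps, amplitude 0.01 (opponent motion and the
winner-take-all winner), 0.006 to winner-take-all losers.

Two in-package fixtures let the protocols run without any connectome
download, with **synthetic** magnitudes (placeholders shaped by the
published topology, not measured counts): an all-inhibitory
opponent-motion circuit (VCH/DCH not mutually inhibiting; both inhibited
by Am1 and LPi15; Am1 — but not LPi15 — reciprocally inhibited by
VCH/DCH; a fifth unnamed member with weak reciprocal couplings that keeps
the matrix diagonalizable) and a complete mutual-inhibition ring of nine
neurons.

## What passing tests do and do not show

The synthetic generator reproduces sparsity, count scale, sign structure
and confounding — not the fly's degree distribution, cell-type structure,
or anatomical organization. Estimator results on it demonstrate
*statistical* properties (consistency, efficiency gain from the prior
under misspecification) that carry over to any VAR(1) system with
laser-independent noise; they do not validate the linear model itself
against a real nervous system. Whole-brain figures that depend on the
actual connectome download (the 121,327-neuron construction count, the
|lambda_1000|/|lambda_1| ~ 0.1 spectrum ratio, the 75%-power sparsity
ceiling) are represented here by the exact machinery plus synthetic-scale
checks, not by their fly-scale values.

## Degenerate inputs and tie-breaking

Empty synapse tables produce empty connectomes; all-zero matrices pass
through spectral scaling unchanged with a warning; zero eigenvectors are
rejected by power counts; constant true weights leave R^2 undefined but
keep RSS; conjugate pairs are deduplicated keeping the nonnegative
imaginary part; |lambda| ties are broken by descending real then imaginary
part; equal winner-take-all inputs on a symmetric circuit produce exactly
symmetric output (no spurious winner).
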