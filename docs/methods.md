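# Methods

## Model family

Two discretized chemical-kinetics motifs are fitted, each with a single
output species observed on a shared, uniformly spaced time grid
t₁ < … < t_q (days). Rates are expressed **per grid interval**: the
one-step recursion absorbs Δt, so a reported γ of 0.2 means 20% decay per
interval. The grid spacing is recorded with every fit.

* **TI (translation inhibition).** Output p (protein), inputs g (mRNA) and
  m₁..m_k (miRNAs): `p_{j+1} − p_j = −γ p_j + λ g_j H_j` with the
  commitment `H = ∏ᵢ (1 + uᵢ mᵢ)^{−Sᵢ}` ∈ (0, 1]. Parameters
  w = [γ, λ, u₁, S₁, …], n_par = 2 + 2k.
* **TD (transcription degradation).** Output g (mRNA), inputs m (miRNA)
  and TF proteins: `g_{j+1} − g_j = −β g_j − v g_j m_j + κ F_j` with
  `F = REP·(1 − ACT)`, REP/ACT products of Hill factors over
  repressors/activators. n_par = 3 + 2(n_rep + n_act).

Structural consequence worth flagging: with **no activators the empty ACT
product equals 1 and F ≡ 0** — a TD gene without modeled activators cannot
be transcribed. The model warns and κ is then unidentifiable; synthetic TD
datasets always carry at least one activator.

Summing the recursion telescopes into cumulative-sum predictors, e.g. for
TI: `p̂(t_{j+1}) = p(t₁) − γ Q(t_j) + λ L(t_j)` with `Q = Σ p`, `L = Σ gH`.
The running sum in the γ term is over the *output* p — the one-step
recursion forces this under summation. Residuals are defined for
j = 1..q−1 (coefficients at t_j predict t_{j+1}), so each inner LP has
2(q−1) residual constraints plus the sign constraints. Forward simulation
and the telescoped predictor agree to machine precision by construction;
this identity is asserted in the tests.

## Estimation

`ERR(w) = max_j |f(t_{j+1}) − f̂(t_{j+1})|` is minimized in two layers:

1. **Outer exhaustive search** over a finite set of Hill parameters. For
   each regulator, every S ∈ {1..S_max} (default 5, reflecting how few
   mRNAs carry many functional sites) is crossed with s median fractions
   h_j = j/(s+1), j = 1..s, equally spaced in the open interval (0, 1) —
   the open placement avoids the singular endpoints of the inversion.
   Reading h as the median of the regulator's Hill factor and knowing the
   regulator's median level m̄ gives the closed-form affinity
   `u = (1/m̄)((1/h)^{1/S} − 1)`. Defaults: s = 99 (k = 1), 60 (k = 2),
   20 (k = 3); k ≥ 4 has no canonical size and defaults to 20. The total
   combination count is capped at N_max = 10⁵ (error, with a suggestion to
   shrink s). The same construction is used for TD repressors and
   activators, applied to each regulator's own median level.
2. **Inner minimax LP** per combination: minimize z subject to
   z ≥ ±residual_j and rates ≥ 0, solved with HiGHS. The paper-level
   strict positivity (γ > 0 etc.) is relaxed to ≥ 0 because LP feasible
   sets must be closed; a rate returned exactly at 0 is surfaced in
   `results.boundary_rates`. When the optimal rate face is not a single
   vertex the solver's vertex is accepted — the optimal objective z* is
   unique regardless, and the robustness study quantifies the resulting
   parameter spread.

Enumeration order is fixed (S ascending, h ascending, regulators in motif
order, first regulator slowest) and ties in z* keep the first combination
encountered, so fits are bit-reproducible.

**Parsimony gate.** With p time points the data provide p−1 one-step
equations; the fit refuses motifs with n_par > (p−1)/4 (overridable
explicitly). On the default 19-point grid this admits exactly one TI
inhibitor (n_par = 4). The minimal transcribable TD motif (one activator,
n_par = 5) needs q ≥ 21, which is why TD recovery studies run on a
21-point grid.

## Affine invariance, distance, clustering

Microarray intensities are treated as unknown affine maps a·c(t) + b of
concentrations, with coefficients varying by species. The CKE family is
form-invariant under such maps, so fitting recorded intensities is
legitimate; correspondingly all profile comparison uses
`D(r₁, r₂) = √(2 − 2 corr(r₁, r₂))`.

Two deliberate conventions:

* **corr is the Pearson correlation** — the inner product of normalized
  profiles divided by q. An un-normalized inner product would range in
  [−q, q] and make D² negative; dividing by q is the only reading under
  which D is a metric on [0, 2] (it equals the Euclidean distance between
  the unit vectors nor(r)/√q).
* **Variance uses the population 1/q convention**, not the 1/(q−1) sample
  convention, matching the definition D is built on.

Affine maps are restricted to **a > 0**: a negative scale flips nor(r) and
invariance fails. Constant profiles are rejected with an explicit error —
callers decide the filtering policy, nothing is dropped silently.

Minimal-net clustering seeds with the farthest pair (so n ≥ 2 always
yields at least two clusters, even when one ball would cover the set),
promotes the farthest-from-net point while that distance exceeds ε, then
assigns every profile to its nearest representative. Guarantees: coverage
≤ ε, representatives pairwise > ε apart beyond the seed pair, diameters
≤ 2ε. The construction is greedy — no minimum-cardinality claim. All ties
break by input order, which is therefore part of the reproducibility
contract. The "representative" of a cluster is the net point that seeded
it; no medoid is recomputed. A singleton input returns one trivial cluster
rather than erroring on the farthest-pair step.

## Fit quality

`SRE(t) = |f−f̂|/f(t)` when `f(t) > 0.15·f̄` (strict), else `|f−f̂|/f̄`;
`MODER = max_t SRE(t)`. Both branches are invariant under joint positive
scaling. The f̄ used for a fit is the mean of the full observed output
profile; SRE is evaluated at the q−1 predicted points. A motif is
"validated" when MODER ≤ threshold. **No canonical threshold exists**; the
default 0.15 is a free choice of this package (same order as the displayed
fit errors and the clustering radius), always echoed in reports and fully
configurable.

Observation from the end-to-end screen on synthetic data: with two free
rates plus a 495-point Hill grid, the TI model is flexible enough to fit
smooth *unrelated* miRNA profiles to MODER ≈ 0.08–0.12, while the planted
(true) motif fits one to two orders of magnitude better (≲ 0.01 even under
modest noise). A 0.15 cutoff therefore over-validates on smooth synthetic
data; the planted motif is reliably the *best* fit. The pipeline reports
per-cluster MODER so users can apply a stricter cutoff; the test suite
demonstrates exact selection at 0.02 on its fixture.

## Positive-shift normalization

Before screening, miRNA profiles are mapped to
`m̂ = (m − m̄)/‖m − m̄‖₂ + 1` (the denominator is the root of the
*un-divided* centered sum of squares). The output has mean exactly 1, unit
centered norm, lies in [0, 2], and is invariant under positive scaling —
it also guarantees the positive medians the affinity-grid inversion needs
and the positive mean SRE needs.

## Robustness study

Given a completed fit: perturb the miRNA inputs with independent zero-mean
noise of prescribed per-point sd (Gaussian by default; matched-sd uniform
available), push the perturbed inputs through the fitted forward recursion
to get a simulated downstream profile, re-run the full estimator on that
profile **with the original upstream inputs**, and record the re-estimated
vector; repeat (default 100 replicates, per-replicate seeds spawned from
one master seed). Perturbed levels are not truncated at zero — truncation
would bias the injected sd — they are floored at 0 only where a Hill
factor is evaluated. At sd = 0 the ensemble collapses onto the original
estimates exactly (the estimator is consistent on self-generated data).

Identifiability caveat: when the fitted commitment H(t) is nearly constant
over the course, λ enters the dynamics only through the product λ·H̄, and
the parameter-space spread of the ensemble is dominated by grid-hopping
along that degenerate ray rather than by estimator noise. Stability
studies therefore target motifs whose commitment varies materially
(max/min ≥ 1.5 over the course is the working criterion) — the regime a
validated, dynamically informative motif lives in. On such fixtures the
ensemble spread is zero at sd = 0 and grows monotonically through sd ∈
{0.5%, 1%, 2%} of the median level. More broadly, minimax (L∞) estimation
fits the extreme residuals and can jump between distant near-optimal grid
points under noise; the study surfaces exactly this.

## Sequence vs expression analysis

All n(n−1)/2 unordered miRNA pairs are scored by Needleman–Wunsch global
alignment (linear gaps) and by the Euclidean distance between
positive-shift-normalized profiles (raw-profile option available). The
scoring scheme is not canonical; the default match +1 / mismatch −1 /
gap −2 makes thresholds of 10–15 meaningful for ~22-nt sequences, and the
threshold splits pairs strictly: High iff NWA > threshold. Distance
distributions of the two groups are compared by the asymptotic two-sample
KS test and by quantile curves. Alignment is delegated to Biopython's
`PairwiseAligner`; an independent quadratic DP serves as the test oracle.

## Synthetic data

The generator emulates the *shape* of differentiation day-course data —
strictly positive, smooth profiles (sums of 2–4 logistic/sine components
over a positive baseline) on the 19-point grid over days 0–6 — with
downstream outputs produced by the exact forward recursions and optional
Gaussian noise scaled to each profile's median. Default rate ranges
(γ ∈ [0.05, 0.5), λ ∈ [0.1, 0.8), β ∈ [0.05, 0.3), v ∈ [0.01, 0.1),
κ ∈ [0.2, 0.8) per interval) keep trajectories positive and dynamics
visible over 19 points. "Exact-recovery mode" (default) draws true
affinities on the estimator's own median-inversion grid so recovery tests
can demand equality. What passing these tests does *not* show: anything
about probe-level microarray artifacts, missing values, non-affine
saturation effects, or the true kinetic rates of any organism — the
generator is a correctness harness, not a biological simulator.

The clustering fixture plants affine images (a ∈ [0.5, 2], b ∈ [−1, 1]) of
well-separated templates (pairwise D > 1 by rejection sampling) with noise
shrunk until each member lies within the requested spread of its template,
so recovery of the planted partition is guaranteed by construction for
ε between the within-spread and half the separation.

## Problem sizes and numerical choices

Test and acceptance runs use the study sizes the method targets: q = 19
(TI) / 21 (TD) grids, 20 + 10 noiseless recovery instances, 25 LP-vs-
lattice instances at 2000² resolution, 1000 affine-invariance draws, 50
clustering instances, and robustness ensembles of 10–100 replicates per
noise level. Noiseless "zero" residuals are asserted below 1e−9 (LP
tolerance), the simulation/predictor identity below 1e−10 relative, and
metric invariance below 1e−12. Degenerate inputs (constant profiles, empty
clusters, h ∉ (0,1), non-positive medians) raise errors naming the
offending quantity rather than being repaired silently.

## Known limitations

* The greedy net is not a minimum-cardinality ε-net.
* λ (TI) and κ (TD) are weakly identified when the commitment function is
  nearly constant; the robustness module is the diagnostic.
* The MODER validation threshold is a reporting convention, not a test
  with error control; no multiplicity correction is applied across motifs.
* Continuous-time integration, stochastic kinetics, missing-value
  handling and raw-intensity preprocessing are out of scope.
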