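# mirmotif

Chemical-kinetics validation of repressive miRNA–mRNA interactions from
time-course expression data.

## The problem

miRNAs repress gene expression in two ways: by degrading their target mRNA,
or — more often — by inhibiting its translation into protein. Given
time-course expression profiles (e.g. microarray day courses of a
differentiating cell population), the question is which of the hundreds of
candidate miRNAs actually repress a given target. Linear correlation
screens answer this only qualitatively; `mirmotif` instead fits explicit
chemical-kinetics models of two interaction architectures and validates a
candidate only when the optimally parameterized model reproduces the
observed output profile.

## Models and method

Both motifs are discretized first-order kinetics on a uniform time grid
(rates per grid interval), with Hill-type commitment functions built from
factors `1/(1 + u·x(t))^S` (affinity `u > 0`, integer binding sites
`1 ≤ S ≤ 5`):

**Translation-Inhibition (TI)** — miRNAs M₁..M_k inhibit translation of
protein P from mRNA G:

    p(t_{j+1}) − p(t_j) = −γ·p(t_j) + λ·g(t_j)·H(t_j),
    H(t) = ∏ᵢ 1/(1 + uᵢ·mᵢ(t))^{Sᵢ}

**Transcription-Degradation (TD)** — miRNA M degrades mRNA G whose
transcription is driven by repressor/activator TFs:

    g(t_{j+1}) − g(t_j) = −β·g(t_j) − v·g(t_j)·m(t_j) + κ·F(t_j),
    F(t) = REP(t)·(1 − ACT(t))

Summing the recursion telescopes into a predictor that is *linear* in the
rates, so the minimax estimation problem

    min_w ERR(w) = min_w max_j |f(t_{j+1}) − f̂(t_{j+1})|

splits into an exhaustive search over a finite affinity grid (built by
inverting each regulator's Hill factor at its median level) with an inner
linear program per grid point. Fit quality is judged by the scale-free
smoothed relative error, summarized by `MODER = max_t SRE(t)`; a parsimony
gate `n_par ≤ (p−1)/4` rejects motifs the data cannot support.

Because microarray intensities are unknown affine transformations of
concentrations, all profile comparison uses the affine-invariant distance
`D = √(2 − 2·corr)`, and the miRNA pool is condensed by greedy minimal-net
clustering, which bounds every cluster diameter by `2ε`. The model family
is form-invariant under affine recalibration, so a validated cluster
representative flags every cluster member.

The package also ships a perturb-and-refit robustness study, a
mature-sequence vs expression-distance analysis (Needleman–Wunsch scores,
two-sample Kolmogorov–Smirnov test), and a synthetic-data generator with
known ground truth.

## Worked example

```python
import mirmotif as mm

# a TI motif with one inhibitor on the 19-point day grid 0, 1/3, ..., 6
motif = mm.TIMotif("P", "G", ("M1",))
profiles, truth = mm.generate_ti_dataset(mm.SyntheticSpec(motif=motif, seed=3))

model = mm.TranslationInhibitionModel(motif, profiles)
res = model.fit()
print(res.summary())
```

prints

```
Translation-Inhibition Motif Fit (minimax grid + LP)
====================================================
Output: protein P    mRNA: G    inhibitors: M1
Time points: 19    n_par: 4    grid points searched: 495
  gamma    = 0.184281
  lambda   = 0.31979
  u_1      = 0.437865
  S_1      = 4
ERR(w*) = 5.55112e-16
MODER   = 1.47542e-15  [VALIDATED at threshold 0.15]
```

The search enumerated all 495 = 5 × 99 binding-site/affinity combinations,
solved one minimax LP per combination, and recovered the generating
parameters (here `truth.gamma = 0.184281…`, `truth.lam = 0.319790…`,
`u = 0.437865…`, `S = 4`) exactly, with a minimax residual at machine
precision — on noiseless model-generated data the telescoped predictor can
be zeroed, and the grid contains the true affinity.

The same objects drive the full screen (normalize → cluster → fit each
representative → propagate validation), e.g.

```python
report = mm.run_screen(profiles, "P", "G", epsilon=0.15)
print(report.table())
```

A thin CLI mirrors the library: `mirmotif simulate|cluster|fit-ti|fit-td|
screen|robustness|seqsim` (see `mirmotif --help`).

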