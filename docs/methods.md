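# Methods

## The model

Feature selection is cast as the minimization problem argmin f(S) over
subsets S ⊆ X of the n features, with the wrapper objective

    f(S) = β (1 − Acc) + (1 − β) |S| / n,

where Acc is the stratified 5-fold cross-validation accuracy of a K=5
nearest-neighbor classifier restricted to S on the training split, and
β ∈ (0,1) trades accuracy against compactness. f maps into [0,1]; it is
strictly decreasing in Acc and strictly increasing in |S|.

Candidate subsets are represented as real vectors x ∈ [0,1]^n
(genotype) and decoded by the inclusive threshold rule S = {j : x_j ≥ θ}
(phenotype). The population loop is the generic bio-inspired scheme —
initialize, evaluate, then per generation modify / evaluate trials /
select survivors / track the global best — so any population algorithm
can plug in; jDE, DE/rand/1/bin, PSO and random search are built in.

## Threshold control

θ is governed by one of six mechanisms, all confined to
[θmin, θmax] = [0.1, 0.9] by the projection Π:

- **STATIC** — θ fixed (baseline 0.5).
- **LR** — θ_t = θmin + (t/T)(θmax − θmin); T is the generation horizon.
- **CR** — θ_t = θmin + (θmax − θmin)/2 · (1 − cos(πt/T)); same endpoints
  as LR, slow at both ends.
- **PC** — θ_{t+1} = Π(θ_t + η(ρ_t − ρ★)) with learning rate η = 0.05 and
  target selection rate ρ★; ρ_t is the population-mean fraction of
  selected features. Selecting too much raises θ; the fixed point is
  ρ_t = ρ★.
- **SRA** — multiplicative: ×0.85 when the success rate SR_t (fraction of
  population slots whose fitness strictly improved this generation)
  exceeds SR★ = 0.15, ×1.15 otherwise. The equal-to-target case takes the
  increase branch. Improvement is a strict *decrease* of the minimized
  fitness; a `literal_increase` switch counts strict increases instead,
  for replicating setups that applied the comparison verbatim to a
  maximized score.
- **SA** — each genome carries one extra gene θ_i ∈ [θmin, θmax],
  initialized uniformly, passed through the variation operators exactly
  like a problem variable, then projected into the θ bounds (problem
  genes are independently projected into [0,1]).

Global controllers update exactly once per generation, after all trial
evaluations of that generation, from that generation's population summary;
θ is frozen within a generation. Fitness values are never retro-actively
recomputed when a global θ moves (stale-best policy) — PSO personal/global
bests in particular keep the fitness they were evaluated with.

## Protocol parameters

| parameter | default | meaning |
|---|---|---|
| Np | 30 | population size |
| budget | 3000 | fitness evaluations per run, the initial population included |
| T | budget // Np = 100 | schedule horizon in generations |
| n_runs | 30 | independent repetitions per cell |
| split | 70/30 | stratified train/test fraction, re-drawn per run seed |
| K, folds | 5, 5 | KNN neighbors and CV folds |
| β | {0.9, 0.7, 0.5} | accuracy-vs-size weight |
| θmin, θmax | 0.1, 0.9 | threshold bounds |
| η, SR★ | 0.05, 0.15 | PC learning rate, SRA target |
| ρ★ | 0.2 | PC target selection rate (configuration default; no canonical value exists) |
| θ0 (PC, SRA) | 0.5 | adaptive controllers start from the static baseline value |
| jDE | Fl=0.1, Fu=0.9, τ1=τ2=0.1 | strategy-parameter regeneration constants |
| PSO | w=0.7, c1=c2=1.5 | inertia / cognitive / social weights |

Run r of an experiment uses seed = base_seed + r for the split, the CV
fold assignment and the optimizer; the optimizer's root seed is split
into independent substreams for initialization and variation, so every
run replays byte-identically. Evaluation counting: every fitness
computation (initial or trial) consumes budget; survivor selection does
not. If the remaining budget cannot cover a full generation, the
generation stops at the last affordable trial.

## Numerical and tie-break choices

- **Stratified split** uses largest-remainder apportionment of the train
  quota across classes: deterministic, and every class train fraction is
  within one instance of the global fraction.
- **Normalization** is min-max per feature, fitted on the training rows
  only; zero-variance features map to 0; out-of-range test values are
  clipped into [0,1] so KNN distances stay bounded. Whether to fit on the
  full data or the training split was an open choice; the training-only
  contract avoids test-set leakage.
- **KNN** uses Euclidean distance on the normalized features (one GEMM per
  fold). Neighbor-distance ties break by ascending training-row index
  (stable sort); vote ties by the tied class whose nearest member is
  closest; residual ties by the smallest encoded label. Fully
  deterministic, which the replay guarantee requires.
- **CV accuracy** is the unweighted mean of fold accuracies (folds are
  near-equal in size), and fold assignment is fixed once per run so every
  candidate is scored on identical partitions.
- **Empty subsets** are reachable at high θ. Default policy assigns the
  worst fitness f = 1 (accuracy recorded as 0); the alternative `repair`
  policy keeps the single strongest gene.
- **DE selection** favors the trial on ties (≤), promoting drift across
  fitness plateaus.
- **GTC** (generation to convergence) is the first generation index at
  which the run's final best fitness was attained; generation 0 is the
  evaluated initial population.
- **Schedules past the horizon** hold θmax (only reachable when the budget
  exceeds T generations).

## Statistical comparison

Methods are compared across datasets with within-row ranks (ties
averaged, best = 1). The Friedman statistic is the classic χ² form
χ²_F = 12N/(k(k+1))·[Σ R̄_j² − k(k+1)²/4] with k−1 degrees of freedom
(the Iman–Davenport F correction is a switch, off by default). The
paired-observation matrix takes two summary statistics — mean and median
of the per-run scores — per dataset, ranked jointly in one matrix, so 15
datasets yield N = 30 rows. Post hoc analysis runs only when the Friedman
null is rejected at α = 0.05: the Nemenyi critical difference
CD = q_α(k)·√(k(k+1)/6N), with q_α evaluated from scipy's studentized-range
distribution (df → ∞, divided by √2) rather than a transcribed table, and
Wilcoxon signed-rank tests of every method against the control (lowest
average rank). Wilcoxon drops zero differences, uses the exact
enumeration distribution for ≤ 25 untied pairs and a tie-corrected normal
approximation otherwise; p-values are two-sided and reported raw (a Holm
step-down option exists, off by default).

## Synthetic data

The generator emulates the benchmark shapes (19–12,600 features, 70–2,600
instances, 2–26 classes): `n_informative` columns are class-conditional
Gaussians (unit within-class SD) whose class means sit at the vertices of
a regular simplex scaled so every pair of means is `class_separation`
apart — one parameter, symmetric multi-class separation; when the
informative dimension cannot hold the simplex the means fall back to
collinear placement with adjacent-class spacing `class_separation`.
`n_redundant` columns are linear mixtures of the informative block with
uniform[−1,1] weights renormalized to unit norm, plus Gaussian noise of
SD `redundancy_noise_sd`; `n_noise` columns are standard Gaussian,
independent of the class. The ground-truth mask marks informative ∪
redundant.

What the generator does *not* emulate: heteroscedastic or heavy-tailed
noise, batch effects, correlated noise blocks, class imbalance beyond
remainder effects, and missing values. Tests passing on this data show
the mechanisms behave as designed under clean planted structure, not that
they rank identically on real microarray data.

## Problem sizes in the test suite

The behavioral checks run a reduced-scale cell chosen to keep the suite
fast while preserving the high-dimensional character of the benchmarks:
300 samples × 500 features (20 informative, 30 redundant, 450 noise,
2 classes, class_separation = 2.0 — moderately separable), jDE with
Np = 30 and 1500 evaluations, β = 0.5, 10 seed-paired runs per
controller. At this scale the self-adaptive controller reliably finds
smaller subsets than the static baseline, and proportional control holds
the final selection rate near its target.

## Known limitations

- GA, ABC and LSHADE are accepted through the optimizer registry but not
  implemented; published results involving them cannot be reproduced here.
- Only overall accuracy is supported as the wrapper metric; balanced
  accuracy / F1 / AUC and classifiers other than KNN are out of scope.
- The wrapper cost is one KNN CV per evaluation; for very large feature
  counts the column gather dominates and runs scale linearly in |S|.
- ρ★ has no canonical published value; results with PC depend on it and
  the 0.2 default is a repository choice.
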