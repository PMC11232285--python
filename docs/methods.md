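# Methods

## The model

`ctgansurv` trains a cycle-consistent adversarial network on tabular
cohort data. A sample is the concatenation of its selected-gene
expression vector (log2(FPKM + 1) scale) and one extra feature,
log2(survival days + 1); the survival time enters the network exactly
like a gene, with no separate head. Two generators map this vector
between cohorts A and B, two least-squares discriminators judge domain
membership, and the objective is the unit-weight sum of the two
adversarial terms, an L1 cycle-consistency term and an L1 identity term
(weights `lam_cycle`, `lam_identity` are exposed; setting
`lam_identity = 0` reproduces the identity-loss ablation). The L1 norms
are summed over features and averaged over the minibatch, so minibatch
means estimate the population expectations.

Architecture. Generator: dense+BatchNorm+ReLU ×2 → three residual
blocks → dense+BatchNorm+ReLU ×2 → linear dense back to the input
dimension. A residual block is `y = x + BN(dense(ReLU(BN(dense(x)))))`;
there is deliberately no activation after the skip addition, and the
final generator layer is linear — log-scale features are unbounded above
and a saturating output would throttle gradients. Negative generated
expression is clipped to zero only at export, never during training.
Discriminator: three dense+LeakyReLU(0.2) layers and a scalar linear
output (least-squares GANs need an unsquashed critic). Hidden widths
default to 256 for the generator and (256, 128, 64) for the
discriminator; all are configuration knobs, and the tests use narrower
networks (see "Problem sizes").

Training. Adam (lr 2e-4, β₁ 0.5, β₂ 0.999), batch 64, and a stabilising
schedule: within each minibatch the generators take
`g_steps_per_d_step = 3` updates with the discriminators frozen for each
single discriminator update, and the whole epoch schedule is executed
`n_repeats = 3` times consecutively on the same data without
re-initialisation (a `restart` mode and a whole-epoch interleaving are
selectable). Unequal cohort sizes are handled by iterating the larger
domain once per epoch and cycling a reshuffled permutation of the
smaller. Epochs are driven by the larger domain: ceil(n_large / batch)
minibatches per epoch. BatchNorm uses batch statistics during training
and running averages (momentum 0.1, eps 1e-5) for generation, so
generated output is independent of batch composition. Everything is
deterministic under the config seed.

The networks are implemented in a compact numpy reverse-mode engine
(`nn.py`): layers expose `forward -> (output, cache)` and
`backward(cache, grad)`, which lets the several generator passes of one
update (translation, cycle, identity) coexist before a single backward
sweep. Gradients flow through a frozen discriminator to the generator;
the discriminator's own accumulated gradients are discarded in that
step.

## Survival-time handling

Times are kept in days for every survival statistic; the log2(t + 1)
value exists only as the model-facing feature, assembled on the fly.
Generated times are back-transformed as `max(2^y − 1, 1)` day — the
1-day floor mirrors the upstream removal of 0-day samples and keeps
augmented data valid for Cox/KM. Generated times are left real-valued
(no rounding to whole days). Event indicators are never generated;
censoring status travels with the source patient, so event counts are
conserved by construction. In `expression_only` mode the generated time
is discarded and the source patient's real time is kept.

## Gene selection

Each gene is fitted alone in a Cox proportional-hazards model (Breslow
ties, no penalisation, Newton–Raphson with oscillation damping and a
±50 coefficient cap; monotone-likelihood fits that walk to the cap are
accepted as boundary fits, genuinely failed fits score 0.5) and ranked
by the Harrell C-index of its fitted risk on the same data. Ranking is
by raw C descending — not |C − 0.5| — so strongly protective genes rank
low; ties break lexicographically by gene ID. Only the *target* cohort's
survival drives the ranking, and the resulting list is applied to both
domains. Scoring uses the full target dataset before any train/test
split; the CV benchmark's folds re-use this list (an option to re-score
within training folds would avoid this mild leakage but is not the
default workflow). The per-gene Newton solver is vectorised across genes
(risk-set sums via reversed cumulative sums), which makes screening a
whole catalogue a few passes over the matrix; it is verified against
lifelines' `CoxPHFitter` on tie-free data in the tests.

## SuperPC

Standardise genes with training means/SDs; compute per-gene univariate
Cox Wald z; choose the screening threshold from a quantile grid
(0, 0.25, 0.5, 0.75, 0.9 of |z|) by internal 3-fold cross-validation
maximising validation C-index (ties prefer the stricter screen, at least
one gene is always retained); take the first principal component of the
retained standardised submatrix (unit-norm loadings, sign fixed by the
largest-magnitude loading); fit a univariate Cox model on the centred
PC1 score. Prediction standardises with the *training* parameters,
projects, and exponentiates — partial hazards on new data use nothing
estimated from that data. Risk stratification thresholds at the median
partial hazard of the training set, with strict `>` for the high-risk
group, so all-tied hazards yield an all-low-risk split and p = 1.

## The benchmark

`run_cv_benchmark` repeatedly splits the *real* target cohort
(default 100 rounds; round r uses seed base+r), trains SuperPC per
condition on the real training fold — plus, for augmented conditions,
the generated samples (IDs prefixed `gen:`) — and scores the untouched
real test fold with Harrell's C. Generated samples never enter a test
fold. Conditions share identical splits within a round; the paired
two-sided Wilcoxon signed-rank test compares each augmented condition
with the real-only baseline. The "chronological order" 7:3 split used
for the Kaplan–Meier illustration is the dataset's stored sample order
(deterministic after the sorted-ID reading convention).

Harrell's C is implemented with the strict convention: a pair is
comparable iff the two observed times differ and the shorter one is an
event; risk ties count 1/2; no comparable pairs returns 0.5 with a
warning. Kaplan–Meier and the two-group log-rank test delegate to
lifelines.

## Evaluation metrics

Points are selected-gene expression vectors (the time feature is
excluded from clustering but included in reconstruction error), pooled
from real A, real B, and — in the model condition — generated samples
labelled by their *target* style. KNN purity (k = 10, Euclidean,
distance ties broken by index order) reads domain separation directly.
A two-component full-covariance Gaussian mixture (5 initialisations,
fixed seed, ridge 1e-6 fallback for singular covariances) provides
cluster assignments; NMI (arithmetic-mean normalisation) and ARI compare
them to the domain labels, silhouette (singletons and the 0/0 case
contribute 0) and the Dunn index (single-linkage inter-cluster distance
over maximum diameter) score internal quality. The mixture is fitted on
a canonically sorted copy of the points and applied pointwise, so all
metrics are invariant to input order. Reconstruction MSE and R² compare
real versus round-tripped (A→B→A) samples entry-wise over expression
plus the log-time feature, R² about the pooled mean of the real entries;
they are reported as absent ("NA") when no reconstruction exists.

## Synthetic cohorts

`simulate_pair` emulates the statistical skeleton the workflow assumes,
not TCGA's gene-wise marginals. Latent factors z ~ N(0, I_4) per sample;
expression = softplus(W_d z + μ_d + ε), ε ~ N(0, noise_sd²), already on
the log2 scale (softplus keeps it smooth and nonnegative — a
differentiable target for the GAN). The first `n_informative` genes load
positively (≈1.5) on z₁ in both domains; z₁ also sets the hazard:
event times are exponential with rate exp(effect_size · z₁)/1500 days,
censoring times exponential with the rate solved numerically so the
expected censored fraction equals `censor_rate` exactly under the
sampled hazards. μ_B − μ_A is `domain_shift` × a standard normal draw
per gene, so the true cross-domain map is a known affine transform
through the latent space; `known_map_transfer` applies it (softplus
inverse → pseudo-inverse projection → re-emission) as an oracle
generator for plumbing tests and upper bounds. Exponential survival with
a log-linear hazard matches the proportional-hazards assumption, so
SuperPC recovery is well-posed. Defaults: 400 samples per domain, 300
genes, 20 informative, effect size 1.0, censor rate 0.3, domain shift
2.0, noise SD 0.3.

What the generator does *not* emulate: heavy-tailed and zero-inflated
expression marginals, gene–gene correlation beyond a 4-factor structure,
batch effects, and non-proportional hazards. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure, not performance on real cohorts.

## Problem sizes in tests and the acceptance script

All stochastic checks run at sizes chosen for single-CPU minutes:
generator width 64 and discriminator (128, 64, 32) with 60 epochs × 3
repeats for training-sanity checks (50 genes, 400 samples per domain;
3-seed medians); width 128 with 100 epochs × 3 repeats for the
augmentation benchmark, where transfer quality is the binding
constraint; 300-gene catalogues for gene-selection recovery; 20 rounds
for the benchmark. The checked properties (cycle-loss collapse,
generated samples landing in the target cloud, recovery fractions,
benchmark direction) are size-independent statements; package defaults
remain at the full-scale values.

The augmentation-benefit check runs in an information-starved regime —
267 target samples of which 80 train, observation noise 1.5, ten
informative genes — because that is the regime augmentation targets.
With the default low-noise fixture, SuperPC on 80 real samples already
attains the concordance ceiling of the data-generating process (the C
of the true risk factor itself), leaving augmentation nothing to add;
an oracle check with the true cross-domain map confirms the ceiling.
This is a known property of the benchmark design, not of the model.

## Numerical choices

- Cox Newton: step clip ±2, damping halved on sign-flip oscillation,
  convergence at |step| < 1e-9 (steps below 1e-4 accepted as
  near-converged), coefficient cap ±50. Zero-variance genes score 0.5.
- C-index: O(n²) vectorised enumeration — exact, no approximation.
- PCA: SVD of the centred screened submatrix; deterministic sign.
- GMM singular covariances: refit with reg_covar 1e-6, logged.
- Censoring-rate calibration: bisection on the mean censored
  probability, 200 iterations over [1e-12, 1e12].
- TSV I/O: floats written as %.17g and parsed with round-trip precision,
  so read → write → read is bit-identical.

## Known limitations

- The adversarial objective at unit weights gives the cycle and identity
  terms (sums over hundreds of features) much more initial weight than
  the GAN terms; the model first learns reconstruction, then style. The
  paper's weighting is followed as stated; `lam_*` knobs allow the
  CycleGAN-style λ = 10 convention instead.
- Hidden widths, optimiser, learning rate and epoch counts are not
  pinned by the source method description; the defaults here are the
  conventional CycleGAN/LSGAN choices and everything is config-exposed.
- Gene scoring before the CV split mirrors the original workflow and
  carries mild selection leakage into the benchmark's absolute C values;
  condition *differences* are unaffected since all conditions share it.
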