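# Methods

## Model

The framework treats cross-tissue expression prediction as a conditional
translation problem.  All profiles are standardized per tissue and gene
(Z-scores), so the networks operate on unbounded reals and the tissue
condition carries the tissue-specific location/scale information that
standardization removed from the data itself.

A Tissue Conditioning Module (TCM) computes
`LeakyReLU(γ_t ⊙ (Wx + b) + β_t)`: the dense map (W, b) is shared across
tissues, and one learnable scale/shift pair (γ_t, β_t) exists per declared
tissue per block, applied element-wise to every sample ("instance-level" —
no batch statistics are involved).  Initialization is γ = 1, β = 0, so a
freshly built model is tissue-agnostic and conditioning structure is learned
entirely during training.  Encoder, generator and discriminator are TCM
stacks; the generator's hidden widths are the reverse of the encoder's, and
the final layers of the generator (into gene space) and discriminator (into
a scalar score) are plain linear maps.  The mapping network is an
unconditioned dense stack with leaky ReLU hidden layers.

Default architecture: encoder gene→512→256→latent 128, generator mirrored,
discriminator gene→512→256→1, mapper noise 64→128→latent.  These defaults
target cohorts with 10⁴-scale gene counts; the desk-scale experiments in
the tests and acceptance script use proportionally smaller widths (stated
where used), which is sufficient for cohorts of 10²-scale genes.  Leaky
ReLU slope is 0.2 throughout (the conventional value for hinge-loss
adversarial training).  Weights are fan-in-scaled normal, drawn from a
seeded generator.  No spectral normalization or other Lipschitz control is
applied to the discriminator by default.

## Objectives and gradient routing

Four terms (all L1 terms use mean reduction over batch *and* feature
dimensions, keeping the weights λ comparable across gene counts):

- hinge discriminator loss on real target profiles versus generated
  profiles from mapped noise codes; fakes are gradient-detached so the
  discriminator update cannot alter the generator;
- generator adversarial loss −E[D(G(M(z)|t)|t)];
- latent reconstruction ‖E(G(c̃|t)|t) − c̃‖₁ for c̃ = M(z);
- individualized loss ‖G(E(x_s|s)|t) − x_t‖₁ on same-individual pairs;
- cycle consistency ‖G(E(G(E(x_s|s)|t)|t)|s) − x_s‖₁ with full backprop
  through both passes (no detachment inside the cycle).

Routing: the adversarial generator term and the latent reconstruction
update G and M only (the reconstruction path crosses E, but E's gradient
from it is discarded); the individualized and cycle terms update E and G;
the discriminator is updated only by its hinge loss.  This mirrors the
alternating scheme of conditional style-transfer GANs and makes the
division of labor testable: with λ_I = λ_C = 0 the encoder provably never
moves.

Default weights are λ_R = 1, λ_I = 10, λ_C = 1 — the individualized
prediction is the headline task and dominates.  A scalar `adv_weight`
multiplies both adversarial terms; setting it small (or 0) yields an almost
purely reconstructive model, which is the right regime when the goal is
per-gene accuracy on small cohorts rather than distribution matching.

Training pairs are all ordered within-individual sample pairs (both
directions; self-pairs excluded by default).  One noise vector is drawn per
pair and generated under the pair's target tissue, keeping the real and
fake tissue marginals matched.  An epoch is one shuffled pass over the pair
set; Adam uses lr 5e-4, β₁ = 0.5, β₂ = 0.9 by default.  The best-validation
checkpoint (by held-out individualized L1) is restored when a validation
split is supplied.

## Numerical engine

The networks run on a compact reverse-mode autograd engine over float64
numpy arrays (`mtm._autograd`).  Everything is single-threaded and double
precision, so a seeded run — simulation, training, evaluation — is
bit-reproducible; the test suite asserts this at the level of loss
histories and prediction matrices.  Scaler fitting extracts contiguous
arrays before reducing, so refits are bit-identical regardless of the
caller's memory layout.

## Preprocessing protocol

Tissues with ≤ 50 samples are dropped, then individuals with fewer than two
remaining samples, iterated to a fixed point.  Splits and cross-validation
folds partition *individuals*, never samples, so no person spans train and
test.  Z-scoring uses per-tissue per-gene mean and sample sd (ddof = 1 —
the convention is recorded on the scaler object and configurable) computed
from training individuals only; the recorded factors are applied to
held-out data.  Genes with zero training variance standardize to 0 (not
NaN) to keep matrix shapes fixed, and are flagged.  By default values are
log2(TPM+1)-transformed before Z-scoring — raw TPM is heavy-tailed enough
to destabilize L1 training — with a `log=False` path for Z-scoring the raw
values (both paths are tested).  External cohorts are aligned by matching
each gene's per-tissue mean/sd to the reference scalers.

## Synthetic cohorts

The simulator generates the structure the model assumes.  Individual *i*
carries a latent vector u_i (a static block, standing for the shared
genetic component across tissues, and a dynamic block for physiological
state), shared by all of that individual's samples.  Tissue *k* maps u_i
through loadings A_k and intercept b_k; A_k interpolates toward a common
matrix with per-tissue weight r_k (default r linearly spaced 0.9→0.1),
which plants a ground-truth tissue-similarity ordering (similarity of
tissues k, l tracks r_k·r_l).  Gaussian noise with sd `noise_sd` is added
on the log2 scale.  The default non-negativity transform is
TPM = 2^(signal/τ) with τ = 1, giving TPM-like right-skewed values;
`shifted-linear` instead shifts each gene to be non-negative and keeps the
values exactly linear in the latents — the regime used for noiseless
recoverability checks.  Trait-correlated genes receive an additive
`trait_effect × trait` term (trait ~ N(0,1), age-like); per tissue, `n_deg`
genes get a ± `deg_log2fc` shift in case individuals (cases drawn with
probability `case_fraction`).  Samples are dropped independently at
`missing_rate`, but every individual keeps at least two samples.
`resample_expression` redraws only the noise, producing an independent
realization of the same truth — used to test whether planted trait and DE
signals are recoverable and reproducible.

What the simulator does **not** emulate: count noise (negative binomial,
library-size variation), zero inflation, genotype/eQTL structure, and
batch effects.  Passing tests therefore demonstrate that the machinery
recovers the assumed latent structure, not that it handles the full
complexity of real RNA-seq cohorts.

Default study conditions in the tests: 40–120 individuals, 2–5 tissues,
100–300 genes, noise sd 0.2–1.5 — small enough for minutes-scale CPU runs,
large enough for the planted effects to be statistically identifiable.

## Evaluation and downstream choices

- pGenes use a strict inequality (ρ > 0.3); undefined correlations
  (constant vectors) are excluded rather than zero-filled and can never
  qualify.
- Cross-validation concatenates per-fold predictions and scores once; the
  suite checks this equals a full-matrix bookkeeping oracle.
- Gene-wise ρ is computed on standardized data; Pearson correlation is
  invariant to the per-gene affine standardization, so raw and standardized
  versions coincide.
- Wilcoxon rank-sum uses the exact null distribution for tie-free groups of
  up to 25, the normal approximation with tie correction otherwise.  FDR is
  Benjamini–Hochberg.  log2 fold changes use a pseudocount of 1 on the
  TPM-like scale.  Sign consistency excludes genes with a zero fold change
  in either arm.  The minimum group size defaults to 10 at desk scale (50
  per group is the documented full-scale convention).
- Empty reference DEG sets make overlap/F1 undefined (NaN), not zero.
- Trait-association preservation restricts both arms to the supplied gene
  set (typically pGenes or planted trait genes).
- Tissue similarity uses log2(TPM+1) mean profiles (the pseudocount choice
  is exposed); pairwise-matrix agreement uses Spearman on the flattened
  upper triangles with average ranks on ties.

## Interpretation of the noiseless-recoverability check

On a noiseless `shifted-linear` cohort the blood→tissue map is exactly
linear and a least-squares oracle recovers it perfectly even on held-out
individuals.  An MLP trained on ~50 individuals approaches but does not
reach that oracle out-of-sample (gene-wise ρ ≈ 0.91 minimum): the function
class is richer than the target and desk-scale cohorts cannot pin it down
everywhere.  The recoverability test therefore measures whether the
architectures and optimizer can represent and recover the deterministic
map on the cohort they were fitted to (all-individual fit, minimum
gene-wise ρ ≥ 0.99), which isolates optimization from small-sample
generalization; the multi-task-benefit test handles held-out
generalization separately.

## Untrained-model control for latent individuality

A trained encoder separates individuals in latent space (intra- versus
inter-individual code similarity, rank-sum p far below 0.01).  The matched
control re-draws a fresh cohort *and* a fresh untrained model per
replicate: with a single fixed cohort, the realized loading matrices leave
a small trace-level alignment between same-individual profiles that even a
random encoder transmits, so replicating over cohorts is what makes the
null honest.  Five replicates must show no significant positive gap.

## Known limitations

- The adversarial component is kept deliberately weak in the desk-scale
  experiments; hinge-GAN dynamics on 10⁴-gene cohorts are not exercised.
- Linear baselines are simplified versions of the published per-gene
  feature-selected Bayesian ridge and PCA+LASSO pipelines: feature count,
  PC count and penalties are config keys rather than tuned per gene.
- Checkpoints are JSON (exact float64 round-trip, human-readable); for
  very large models a binary format would be preferable.
- The training loop holds the full standardized matrix in memory; cohorts
  far beyond 10⁵ samples × 10⁴ genes would need batched I/O.
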