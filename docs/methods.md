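# Methods

## Model

Known miRNA–disease associations form a binary matrix R ∈ {0,1}^(Nm×Nd).
The model assigns each miRNA a latent vector Mᵤ ∈ ℝ^Nl and each disease a
latent vector Dᵢ ∈ ℝ^Nl, and scores the pair through the logistic link
g(x) = 1/(1+e^(−x)).  The fitted objective is

L = ½ ΣᵤΣᵢ Wᵤᵢ (Rᵤᵢ − g(MᵤᵀDᵢ))²
  + (λM/2)‖M‖²_F + (λD/2)‖D‖²_F
  + (λS/2) Σᵤ ‖Mᵤ − Σ_{v∈Eᵤ} Sᵤᵥ Mᵥ‖².

This is the MAP problem of a probabilistic model with (i) Gaussian
observation noise around g(MᵤᵀDᵢ) on every cell, weighted by Wᵤᵢ, (ii)
zero-mean isotropic Gaussian priors on M and D, and (iii) an additional
Gaussian prior on each Mᵤ centered at the neighbor-weighted average of its
network neighbors.  The λs are the noise-to-prior variance ratios; they are
exposed directly because the variances never appear separately in the loss.

Assumptions worth stating explicitly:

* associations are generated by a low-rank bilinear form through a logistic
  link — the model cannot represent associations that are not expressible
  at rank Nl;
* unobserved cells are *weak* negatives whose influence is proportional to
  the expression-derived weight, not hard negatives;
* network similarity is informative about latent proximity, i.e.
  functionally similar miRNAs have similar disease profiles;
* only the miRNA side is network-regularized; diseases carry a plain ridge.

## Weight matrix

Expression values (arbitrary units, non-negative) are min-max scaled to
[0,1] over all provided values — one global scaling, so relative expression
differences across miRNAs are preserved.  Cells with a known association get
weight exactly 1.  In `per_mirna` mode (default) one value per miRNA is
broadcast across its row; `per_pair` mode uses pair-specific values where
present.  miRNAs without expression fall back to weight 1 with a logged
warning, which degrades that row to ordinary weighted MF rather than
discarding it.  If all expression values are identical the scaling is
undefined and construction fails with an instruction to use constant
weights.  The `WeightMatrix` also keeps the *background* (expression-derived)
weight of every cell, which leave-one-out evaluation uses to demote a
held-out positive back to its unobserved weight.

## Similarity network

* Interaction profile IPᵤ = row u of R.
* GIP kernel GS(u,v) = exp(−rm‖IPᵤ−IPᵥ‖²).  The printed form of the
  bandwidth rule is ambiguous between multiplying and dividing by the mean
  squared profile norm; the default divides — rm = rm′ / (mean ‖IP‖²) — the
  standard construction for this kernel family, making the kernel scale
  invariant to annotation density.  The multiplicative reading is available
  via `convention="multiply"`.  Default rm′ = 1.0 (dimensionless).
* The kernel is computed from R before any latent vectors exist; it cannot
  depend on them.
* Integration: S = FS where functional similarity is defined, GS elsewhere.
  "Defined" means finite and strictly positive — FS exports encode absent
  pairs as 0 (or NaN in memory), which the mask distinguishes from a true
  zero score.
* Row normalization: the diagonal is zeroed (a miRNA is not its own
  neighbor; a self-loop would satisfy the regularizer vacuously), then each
  row is divided by its off-diagonal sum, so the neighbor weights over
  Eᵤ = {v : Sᵤᵥ > 0} form a convex combination and the neighbor average is a
  proper weighted mean.  Σᵥ Sᵤᵥ normalization was chosen over |Eᵤ| because
  the prior mean must be a convex combination of neighbor vectors.  Isolated
  rows stay zero: an isolated miRNA feels no network pull.

## Training

Full-batch gradient descent on M and D simultaneously.  Gradients:

∂L/∂Mᵤ = Σᵢ Wᵤᵢ Dᵢ g′(MᵤᵀDᵢ)(g(MᵤᵀDᵢ)−Rᵤᵢ) + λM Mᵤ
       + λS (Mᵤ − Σᵥ Sᵤᵥ Mᵥ) − λS Σ_{v:u∈Eᵥ} Sᵥᵤ (Mᵥ − Σ_w Sᵥw M_w)

∂L/∂Dᵢ = Σᵤ Wᵤᵢ Mᵤ g′(MᵤᵀDᵢ)(g(MᵤᵀDᵢ)−Rᵤᵢ) + λD Dᵢ.

The fourth M-term back-propagates the network pull from every miRNA that
counts u among its neighbors; dropping it is a common bug and is caught by
the finite-difference tests.

Numerical choices:

* **Initialization** i.i.d. N(0, init_scale²) with init_scale = 0.1, from a
  seeded generator.  Zero initialization is a saddle point of the data term
  (all scores 0.5, zero gradient through D), so it is avoided.
* **Step guard.**  If a step would increase the loss, the learning rate is
  halved and the step retried.  The recorded loss history is therefore
  non-increasing — a testable invariant — and a too-large learning rate
  degrades gracefully instead of diverging.  If the loss is non-finite even
  at a vanishing step the run aborts advising a smaller rate.
* **Stopping**: relative loss change < tol (default 1e-6), max_epochs
  (default 2000), or learning-rate underflow.
* **Stability**: the logistic link is evaluated in its two-branch form, so
  it never overflows for |x| ≤ 700.

Defaults — Nl = 10, λM = λD = 0.01, λS = 0.1, learning rate 0.05,
2000 epochs — are this package's own: they converge in seconds at the
synthetic scales below and every one is exposed in `ModelConfig`.

## Evaluation

* **roc_auc** is the Mann–Whitney rank statistic with mid-rank ties —
  identical to integrating sensitivity over 1−specificity.
* **pr_auc** uses the step-wise rectangular rule over descending unique
  score thresholds.
* **Global LOOCV** removes each known association in turn (and demotes its
  weight to the expression background), retrains, and ranks the held-out
  pair against all unknown cells.  **Local LOOCV** ranks only within the
  held-out pair's disease; per-disease AUCs are combined by unweighted mean
  (the aggregation is not dictated by the protocol; unweighted mean treats
  every disease equally regardless of annotation count).  Diseases lacking
  a positive or a negative miRNA are skipped with a warning.
* **Repeats** re-randomize the model initialization; folds are exhaustive
  by definition of leave-one-out.  Per-repeat AUCs are averaged.
* **Fast mode** trains once per repeat on the full data and ranks every
  positive without refitting.  It is an approximation — the model has seen
  each "held-out" positive during training, which inflates absolute AUC
  (dramatically so when the model can interpolate the training data) — and
  is therefore off by default; it is appropriate for scorer-calibration
  checks and for relative comparisons at fixed capacity.
* **AUPRC pooling**: positives contribute their fold scores; negative
  scores are averaged across folds (they differ per fold only under
  refitting).  This is one defensible pooling among several; the per-fold
  ranks in `EvalResult` allow any other summary.
* **top_k_candidates** sorts non-associated miRNAs by descending score with
  lexicographic ID tie-break, so reports are deterministic.

## Synthetic worlds

`generate_world` draws M_true, D_true i.i.d. N(0,1) (matching the model's
prior), sets Rᵤᵢ = 1 iff g(M_trueᵤ·D_trueᵢ) > τ, then flips an η-fraction
of cells.  Defaults Nm = 80, Nd = 60, Nl = 5, τ = 0.9 give ≈12% density —
large enough for stable LOOCV statistics, small enough that the full test
suite runs in well under a minute.  Functional similarity is the cosine of
true miRNA factors rescaled to [0,1], observed on a random ρ-fraction of
unordered pairs (ρ = 0.5 default) with symmetric N(0, ε²) noise, clipped.
Expression mixes the (scaled) association row count with uniform noise at
ratio expr_assoc = 0.7, so weights are plausible but not trivially
informative.  A held-out tenth of the positives supports recovery
experiments.  All draws come from one seeded generator; worlds are
bit-reproducible.

What the generator does *not* emulate: the long-tailed degree distributions
of curated databases, disease-side correlation structure, block structure
of miRNA families, or realistic expression distributions.  Passing the
recovery tests therefore shows the estimator recovers the model's own
generative structure — a necessary correctness property — not that it
reaches any particular accuracy on real curated data.

`recovery_experiment` trains on R minus the held-out positives, builds the
network from the training matrix only (no leakage), and ranks held-out
positives against true negatives, with the network term on and off, across
seeds.  `shuffle_fs=True` permutes the miRNA labels of FS — preserving its
marginal distribution while destroying its information — as a negative
control.

### A caveat on the network ablation

With the cosine-based FS, similarity values are dense and relatively
uniform, so after row normalization the neighbor average is close to the
population mean of the latent vectors.  The network term then acts partly
as *mean-centering shrinkage*, which improves generalization regardless of
whether the network is informative; the shuffled-network control quantifies
this share, and the informative-minus-shuffled gap isolates the genuinely
relational contribution.  Ablation comparisons on dense similarity networks
should always be read against such a control.

## Problem sizes

The acceptance script uses 5 worlds at the default 80 × 60 scale for
recovery/ablation (single-fit per arm), and one 40 × 30 world for the exact
per-fold-retrained global and local LOOCV — chosen so the full recomputation
stays in the minutes range on a single CPU while keeping ≈90 folds for the
rank statistics.

## Known limitations

* Only the miRNA side carries a network regularizer; a disease semantic
  similarity network is out of scope.
* Full-batch gradient descent is adequate at desk scale; the quadratic
  per-epoch cost in Nm·Nd would need mini-batching or specialized solvers at
  database scale (hundreds of thousands of cells are fine; tens of millions
  are not).
* LOOCV with per-fold retraining is O(#positives) trainings; fast mode
  exists but changes the meaning of the numbers (see above).
* The ID normalizer is a deterministic string canonicalization (lower-case,
  trimmed); it does not resolve miRNA synonyms or MeSH disease terms.
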