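# Methods

## Overview

`cellmatch` couples three components: (i) network smoothing of binary DNA
alteration matrices, (ii) a semi-supervised variational autoencoder (VAE)
with an entropy-regularised objective, and (iii) downstream geometry on the
learnt latent space — cosine fidelity scoring, a multidimensional-scaling
reference map, and centroid-based latent perturbation. This note records
the modelling assumptions, the defaults and why they were chosen, and what
the synthetic benchmark does and does not demonstrate.

## Network smoothing of DNA views

Binary mutation and CNV matrices are extremely sparse; two samples rarely
share an altered gene even when they hit the same pathway. Smoothing
propagates each sample's alteration signal over a gene-interaction network
with the random-walk-with-restart iteration

    F_{k+1} = alpha * F_k @ W + (1 - alpha) * F0,
    W = D^(-1/2) A D^(-1/2),

run to its fixed point (1 − α) F₀ (I − αW)^{−1}. Because the spectral
radius of W is at most 1, the iteration converges for any α ∈ (0, 1).

Defaults: **α = 0.5** (equal weight to network context and original
signal, the common middle ground in network-propagation practice),
**tol = 1e−6** on the element-wise change, **max_iter = 1000** (reached
only for α near 1; a warning then reports the residual). Mutation and CNV
are smoothed independently and concatenated downstream — they carry
different biology and their scales should not mix.

Gene handling: diffusion runs over the full network (unmeasured network
genes carry zero seed mass but conduct signal); measured genes absent from
the network pass through unsmoothed by default so no data is silently
discarded (`off_network="drop"` gives the strict behaviour). After
smoothing, each gene is min-max rescaled to [0, 1] across samples; constant
columns map to 0. The per-gene extrema are persisted so query cohorts are
scaled against the training extrema (clamped), never refit.

## Feature assembly

Profiles are x = (x_DNA, x_RNA) with features namespaced `rna:`, `mut:`,
`cnv:` in that fixed order. Expression preprocessing upstream of min-max
scaling (log transformation, normalisation) is the caller's responsibility;
the package accepts any numeric matrix. Genes present in one DNA modality
but not the other are zero-filled (absence of evidence of alteration).
Train/test splitting of the labelled cohort is stratified by subtype so
rare subtypes appear in both partitions; subtypes with a single sample stay
in training with a warning.

## The semi-supervised VAE

Generative model: p(z) = N(0, I), p(y|z) = Cat(π_θ(z)),
p(x|z) = ∏_i Bernoulli(x_i | f_θ(z)_i). A Bernoulli likelihood over
[0,1]-scaled features treats each decoder output as the probability that
the corresponding feature is "active" (e.g. that a gene is expressed); the
cross-entropy form of the reconstruction loss is well defined for
fractional inputs. Bernoulli is the only implemented likelihood; a Gaussian
decoder would be the natural extension for unscaled features.

Inference model: q(z|x) = N(μ(x), diag(σ²(x))) with
(μ, log σ) = g_φ(x); q(y|z) shares the classifier network with the
generative side. One reparameterised sample per datum per step approximates
the expectation under q, and the entropy and classification terms are
evaluated on that same draw so each step does a single forward pass.

Losses (sums over mini-batches, all four terms with weight one, exactly as
the objective is defined):

    U(x)    = recon + KL + H[p(y|z)]
    S(x, y) = recon + KL + H[p(y|z)] - log pi_y(z)

The entropy regulariser penalises uncertain classifications, pushing
decision boundaries into low-density latent regions — the standard
semi-supervised argument — and empirically is what lets one model achieve
both good classification and good generation.

Architecture: encoder and decoder are mirrored ReLU multilayer perceptrons,
default hidden widths **(128, 64)**, chosen for the few-hundred-feature
cohorts this package targets; all widths are config-exposed. Hidden layers
use He initialisation, output heads a smaller 1/sqrt(n) scale so the
untrained posterior starts near N(0, 1) and the decoder near 0.5. No batch
normalisation: plain stacks keep inference deterministic, simplify the
hand-written backward pass, and train these shallow models without trouble.
The classifier is a single affine layer + softmax on z — keeping it linear
in z is what makes individual latent components interpretable as subtype
axes. The latent dimension defaults to d = h.

Numerical guards: decoder probabilities are clamped to
[1e−7, 1 − 1e−7] so Bernoulli log-likelihoods stay finite; the raw
log σ head is clipped to [−8, 5] (gradients masked outside); softmax and
sigmoid use the usual max-shift / sign-split stable forms.

Optimisation: Adam, learning rate 1e−3, 300 epochs by default (the
synthetic benchmark uses 200, which is past convergence there). Each step
pairs one labelled batch (default 64) with one unlabelled batch (default
32, recycled when the unlabelled stream is shorter). Because no autodiff
framework is used, all gradients are derived analytically; the test suite
checks them against central finite differences at ~1e−4 relative
tolerance. Determinism contract: a single seed drives initialisation,
shuffling and all latent draws, and runs are bit-reproducible on one
thread.

Inference uses the posterior mean μ(x) — for subtype prediction, latent
embedding, fidelity scores and the reference map — so all published
artefacts are deterministic. Argmax ties break to the lowest class index.

## Fidelity scoring

d(c, t) = 1 − cos(z_c, z_t), bounded in [0, 2]; zero-norm latent vectors
are rejected by name rather than silently producing NaN. Heatmap orders
come from average-linkage hierarchical clustering of the rows (and,
separately, columns) of the dissimilarity matrix under cosine distance of
their profiles; average linkage is a deliberate choice for visual block
structure and is deterministic. Ranked queries sort ascending with ties
broken by identifier.

## Reference map

Component-to-component distances are Euclidean distances between z-scored
component profiles across the training tumours (constant components skip
standardisation with a warning); `1 − Pearson` is available as a
config-exposed alternative. Corners are placed by classical (Torgerson)
MDS — deterministic, unlike stress-minimising iterative MDS — centred,
with a fixed sign convention (corner 1 non-negative x, corner 2
non-negative y) so repeated fits are identical. The reported stress is
sqrt(Σ(d_fit − d)² / Σd²).

Sample projection: per-sample min-max of the latent vector to [0, 1],
sharpened by power p = 2, normalised to sum one, then a weighted sum of
corner positions. Min-max makes weights non-negative (raw latent values can
be negative, for which a "magnitude-weighted superposition" is ill
defined); the square sharpens assignment toward dominant components. Both
are config-exposed. All-equal latent vectors land on the corner centroid.
Corners are fit once on tumours and never refit when query samples (cell
lines) are projected.

## Latent perturbation

δ = centroid(target) − centroid(source) in latent space; decoded feature
scores before/after are decoder means (deterministic), with Bernoulli
sampling available. The before/after comparison for selected features uses
a paired sign-flip permutation test (10⁴ permutations, seeded, two-sided)
— boxplots alone do not quantify the shift.

## Synthetic cohort generator

The generator emulates the joint structure the matcher assumes:

- **h = 4 subtypes**, each an expression prototype drawn
  N(0, separation²) per gene with **separation = 1.5** and i.i.d. sample
  noise **noise_sd = 1.0** — clearly separated clusters, comparable to the
  strong subtype signal of well-characterised cancer cohorts;
- **150 tumours and 10 cell lines per subtype** (600 labelled / 40
  unlabelled) — the same order of magnitude as a single-cancer cohort in
  public tumour/cell-line compendia, and small enough that the full
  pipeline runs in seconds;
- **100 expression genes, 80 DNA genes** on a seeded scale-free
  (Barabási–Albert) network, with a two-block stochastic block model as
  alternative;
- per subtype, **8 driver genes per modality** altered at
  background 0.02 + enrichment 0.30; all other genes at background — sparse
  subtype-informative binary signals that only become usable after
  smoothing;
- cell lines drawn from the *same* prototypes plus a **shared random shift
  direction of magnitude 1.0** before logistic squashing, modelling a
  systematic culture effect rather than per-line noise;
- expression mapped through a logistic squash into (0, 1).

What the generator does **not** model: count-distributed RNA noise,
library-size effects, batch structure within a cohort, copy-number segment
correlation along chromosomes, or subtype imbalance. Passing the synthetic
benchmark therefore demonstrates that the machinery recovers planted
structure under the stated assumptions — it does not certify performance
on real tumour/cell-line data, where signal is weaker and confounding
richer.

## Benchmark experiments and sizes

The test suite runs the full pipeline (smooth → scale → assemble → train →
evaluate) on the default cohort for seeds 0–4 (200 epochs each, ~8 s per
run on one CPU) and checks: median held-out tumour weighted F1 ≥ 0.95;
median hidden cell-line label accuracy ≥ 0.90; median per-sample
reconstruction correlation (decoder means) ≥ 0.8; within-subtype cell-line
→ tumour dissimilarity strictly below cross-subtype in every run; centroid
perturbation moving ≥ 80 % of source samples into the target class with
feature shifts signed consistently with the prototype difference. A null
cohort (separation and enrichment zero, seed 123) verifies held-out
accuracy stays inside the 95 % binomial interval around 1/h — a guard
against label leakage anywhere in the pipeline. Reconstruction correlations
are reported for both decoder means and Bernoulli draws; the means variant
is the headline number because draw-based correlations are attenuated by
Bernoulli sampling noise against continuous inputs.

## Known limitations

- No autodiff backend: architectures are limited to the implemented dense
  ReLU stacks; adding convolutional or attention encoders would require a
  framework.
- Bernoulli decoding treats features as independent given z; correlated
  noise across genes is not modelled.
- The entropy term's weight is fixed at 1 (matching the objective's
  definition); no annealing schedule is implemented.
- Classical MDS reflects large distances faithfully but can shrink small
  ones when the component metric is far from 2-embeddable; the stress value
  is reported so users can judge.
- Training is single-threaded numpy; wall time scales linearly in D and
  cohort size, which is fine at desk scale but not for tens of thousands of
  features without feature selection upstream.
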