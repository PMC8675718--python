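# cellmatch

Semi-supervised deep generative matching of cancer cell lines to tumours
and cancer subtypes.

## The problem

Tumour-derived cell lines are the workhorse models of experimental cancer
biology, but not every line is a faithful model of the tumours — or even the
subtype — it is meant to represent. `cellmatch` addresses the selection
problem: given molecular profiles of a labelled tumour cohort (subtypes
known) and an unlabelled cell-line panel, it simultaneously

1. **predicts the cancer subtype of each cell line**, and
2. **scores how similar each cell line is to each individual tumour**,

so that a researcher can pick the best in-vitro model for a given tumour or
subtype, or conversely find the patient sub-cohort a promising in-vitro
result is most likely to translate to.

## The model

Each sample is a feature vector **x** = (**x**_DNA, **x**_RNA) in [0,1]^D:
gene expression plus *network-smoothed* binary mutation and copy-number
profiles. Sparse per-gene alteration indicators are diffused over a
gene-interaction network by a random walk with restart,
F_{k+1} = α F_k W + (1−α) F₀ with W = D^{−1/2} A D^{−1/2}, whose fixed
point is (1−α) F₀ (I − αW)^{−1}; this turns near-disjoint binary events
into dense neighbourhood-informed scores.

The core is a semi-supervised variational autoencoder with three networks:

- **encoder** g_φ(x) → (μ, log σ), a diagonal-Gaussian posterior
  q(z|x) = N(μ(x), diag(σ²(x))) over a latent z ∈ R^d with d = h (one
  latent component per subtype);
- **classifier** π_θ(z), a categorical subtype distribution p(y|z);
- **decoder** f_θ(z), factorised Bernoulli probabilities for all D features.

Training minimises, over mixed mini-batches,

    Σ_cells U(x)  +  Σ_tumours S(x, y),

where U(x) = recon + KL + H[p(y|z)] is the negative unsupervised ELBO plus
an entropy regulariser (pushing class boundaries into low-density latent
regions), and S(x, y) = U-terms − log π_y(z) adds the classification term.
All terms are evaluated on a single reparameterised draw z = μ + σ ⊙ ε.

Fidelity between a cell line c and tumour t is the cosine dissimilarity of
their latent means,

    d(c, t) = 1 − z_c·z_t / (‖z_c‖‖z_t‖)  ∈ [0, 2],

with 0 = perfectly aligned, 1 = orthogonal, 2 = antipodal. The package also
builds a 2-D **reference map** (corners = latent components placed by
classical multidimensional scaling; samples = corner-weighted
superpositions) and supports **latent arithmetic**: the centroid difference
δ = z̄_target − z̄_source transforms samples between subtypes in silico.

## Worked example

The built-in generator draws a synthetic cohort with the structure the
method assumes: 4 subtype clusters, 600 labelled tumours, 40 unlabelled
cell lines (hidden truth retained for evaluation), subtype-enriched
alterations on a scale-free gene network.

```python
import numpy as np
from cellmatch import SynthSpec, generate_cohort, best_cell_lines
from cellmatch.pipeline import run_pipeline

cohort = generate_cohort(SynthSpec(seed=0))
result = run_pipeline(cohort, seed=0)

print(f"held-out tumour accuracy:    {result.report.accuracy:.3f}")
print(f"held-out weighted F1:        {result.report.weighted_f1:.3f}")
print(f"cell-line label accuracy:    {result.cell_line_accuracy:.3f}")
print(f"median reconstruction corr:  "
      f"{np.nanmedian(result.reconstruction['corr_mean']):.3f}")
print(best_cell_lines(result.dissimilarity, 'TU0001', k=3))
```

prints (about ten seconds on one CPU):

```
held-out tumour accuracy:    1.000
held-out weighted F1:        1.000
cell-line label accuracy:    0.975
median reconstruction corr:  0.836
           dissimilarity
sample_id
CL0009          0.040305
CL0006          0.083243
CL0010          0.159028
```

Held-out metrics are computed on the 20 % tumour test split; cell-line
accuracy compares predicted subtypes against the generator's hidden truth;
the reconstruction number is the median per-sample Pearson correlation
between input features and decoder means; the ranked table lists the three
cell lines with the smallest latent dissimilarity to tumour TU0001.

The same workflow is available from the shell:

```bash
cellmatch simulate --out fixtures/ --seed 0
cellmatch train --rna fixtures/rna.tsv --mutations fixtures/mutations.tsv \
    --cnv fixtures/cnv.tsv --network fixtures/network.tsv \
    --labels fixtures/labels.tsv --out run/
cellmatch predict --checkpoint run/checkpoint.npz --rna ... --out preds.tsv
```

plus `smooth`, `dissimilarity`, `refmap` and `perturb` subcommands.

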