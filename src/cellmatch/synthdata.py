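"""Synthetic cohort generator.

Emulates the statistical structure the matching problem assumes: h subtype
clusters in expression space, sparse subtype-enriched binary alterations on
a gene network, and an unlabelled cell-line cohort drawn from the same
subtype prototypes plus a shared systematic shift (a stand-in for culture
effects). Expression values are logistic-squashed into [0, 1]; alterations
are emitted as binary matrices, ready for network smoothing. Everything is
deterministic given the seed.

The generator does not model count-level RNA noise (negative binomial
libraries etc.): downstream features are min-max scaled anyway, so a
squashed-Gaussian cluster model carries the relevant structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .netsmooth import GeneNetwork

__all__ = ["SynthSpec", "SynthCohort", "generate_network", "generate_cohort"]


@dataclass
class SynthSpec:
    """Study conditions for the synthetic cohort.

    Defaults describe a well-separated four-subtype cohort of 600 tumours
    and 40 cell lines — large enough to train on, small enough to run in
    seconds.
    """

    h: int = 4
    n_tumours_per_subtype: int = 150
    n_cell_lines_per_subtype: int = 10
    n_rna_genes: int = 100
    n_dna_genes: int = 80
    network_model: str = "scale-free"
    prototype_separation: float = 1.5
    alteration_enrichment: float = 0.3
    background_rate: float = 0.02
    n_driver_genes: int = 8
    cell_line_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("h", "n_tumours_per_subtype", "n_cell_lines_per_subtype",
                     "n_rna_genes", "n_dna_genes", "n_driver_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("prototype_separation", "alteration_enrichment",
                     "cell_line_shift", "noise_sd", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.network_model not in ("scale-free", "block"):
            raise ValueError("network_model must be 'scale-free' or 'block'")
        if self.h * self.n_driver_genes > self.n_dna_genes:
            raise ValueError("not enough DNA genes for disjoint driver sets")


@dataclass
class SynthCohort:
    rna: pd.DataFrame              # all samples x rna genes, in [0, 1]
    mutations: pd.DataFrame        # all samples x dna genes, binary
    cnv: pd.DataFrame              # all samples x dna genes, binary
    network: GeneNetwork
    tumour_labels: pd.Series       # training labels (public)
    cell_line_labels: pd.Series    # hidden truth, evaluation only
    prototypes: pd.DataFrame       # subtype x rna gene, pre-squash means
    driver_genes: dict             # subtype -> {"mutation": [...], "cnv": [...]}
    shift_vector: np.ndarray
    spec: SynthSpec

    @property
    def tumour_ids(self) -> pd.Index:
        return self.tumour_labels.index

    @property
    def cell_line_ids(self) -> pd.Index:
        return self.cell_line_labels.index

    def to_tsv(self, outdir: str | Path) -> None:
        """Write the TSV fixtures the pipeline reads, plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rna.to_csv(outdir / "rna.tsv", sep="\t")
        self.mutations.astype(int).to_csv(outdir / "mutations.tsv", sep="\t")
        self.cnv.astype(int).to_csv(outdir / "cnv.tsv", sep="\t")
        self.tumour_labels.rename("subtype").to_csv(
            outdir / "labels.tsv", sep="\t")
        edges = [f"{u}\t{v}" for u, v in
                 sorted(tuple(sorted(e)) for e in self.network.graph.edges)]
        (outdir / "network.tsv").write_text("\n".join(edges) + "\n")
        truth = {
            "cell_line_labels": self.cell_line_labels.to_dict(),
            "driver_genes": self.driver_genes,
            "spec": {k: getattr(self.spec, k) for k in vars(self.spec)},
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def generate_network(spec: SynthSpec) -> GeneNetwork:
    """Seeded scale-free (Barabasi-Albert) or two-block gene graph."""
    n = spec.n_dna_genes
    if n < 3:
        raise ValueError("need at least 3 DNA genes for a network")
    if spec.network_model == "scale-free":
        g = nx.barabasi_albert_graph(n, 2, seed=spec.seed)
    else:
        sizes = [n // 2, n - n // 2]
        p_in = min(1.0, 10.0 / n)
        p_out = min(1.0, 0.5 / n)
        g = nx.stochastic_block_model(
            sizes, [[p_in, p_out], [p_out, p_in]], seed=spec.seed)
    names = _gene_names(n)
    g = nx.relabel_nodes(g, {i: names[i] for i in range(n)})
    plain = nx.Graph()
    plain.add_nodes_from(names)
    plain.add_edges_from(g.edges)
    return GeneNetwork(plain)


def _draw_samples(rng, prototypes, subtype_sizes, noise_sd, shift=None):
    rows = []
    labels = []
    for s, (subtype, proto) in enumerate(prototypes.iterrows()):
        n = subtype_sizes[s]
        x = proto.to_numpy() + rng.normal(0.0, noise_sd,
                                          size=(n, len(proto)))
        if shift is not None:
            x = x + shift
        rows.append(x)
        labels.extend([subtype] * n)
    return np.vstack(rows), labels


def _draw_alterations(rng, sample_labels, genes, drivers, background, enriched):
    mat = (rng.random((len(sample_labels), len(genes))) < background)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for subtype, gene_list in drivers.items():
        rows = np.asarray([lab == subtype for lab in sample_labels])
        cols = [gene_pos[g] for g in gene_list]
        hits = rng.random((rows.sum(), len(cols))) < enriched
        sub = mat[rows]
        sub[:, cols] = hits
        mat[rows] = sub
    return mat.astype(int)


def generate_cohort(spec: SynthSpec | None = None) -> SynthCohort:
    """Draw a full labelled tumour + unlabelled cell-line cohort."""
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    subtypes = [f"S{i + 1}" for i in range(spec.h)]
    rna_genes = [f"R{i:04d}" for i in range(1, spec.n_rna_genes + 1)]
    dna_genes = _gene_names(spec.n_dna_genes)
    network = generate_network(spec)

    prototypes = pd.DataFrame(
        rng.normal(0.0, spec.prototype_separation,
                   size=(spec.h, spec.n_rna_genes)),
        index=subtypes, columns=rna_genes)

    # disjoint driver sets per modality
    drivers: dict[str, dict[str, list[str]]] = {s: {} for s in subtypes}
    for modality in ("mutation", "cnv"):
        perm = rng.permutation(dna_genes)
        for i, s in enumerate(subtypes):
            block = perm[i * spec.n_driver_genes:(i + 1) * spec.n_driver_genes]
            drivers[s][modality] = sorted(block.tolist())

    n_tu = spec.h * spec.n_tumours_per_subtype
    n_cl = spec.h * spec.n_cell_lines_per_subtype
    tumour_ids = [f"TU{i:04d}" for i in range(1, n_tu + 1)]
    cell_ids = [f"CL{i:04d}" for i in range(1, n_cl + 1)]

    X_tu, lab_tu = _draw_samples(
        rng, prototypes, [spec.n_tumours_per_subtype] * spec.h, spec.noise_sd)
    direction = rng.standard_normal(spec.n_rna_genes)
    direction /= np.linalg.norm(direction)
    shift = spec.cell_line_shift * direction
    X_cl, lab_cl = _draw_samples(
        rng, prototypes, [spec.n_cell_lines_per_subtype] * spec.h,
        spec.noise_sd, shift=shift)

    rna = pd.DataFrame(expit(np.vstack([X_tu, X_cl])),
                       index=tumour_ids + cell_ids, columns=rna_genes)

    enriched = min(1.0, spec.background_rate + spec.alteration_enrichment)
    all_labels = lab_tu + lab_cl
    mut = _draw_alterations(
        rng, all_labels, dna_genes,
        {s: drivers[s]["mutation"] for s in subtypes},
        spec.background_rate, enriched)
    cnv = _draw_alterations(
        rng, all_labels, dna_genes,
        {s: drivers[s]["cnv"] for s in subtypes},
        spec.background_rate, enriched)

    index = pd.Index(tumour_ids + cell_ids, name="sample_id")
    return SynthCohort(
        rna=rna.set_axis(index, axis=0),
        mutations=pd.DataFrame(mut, index=index, columns=dna_genes),
        cnv=pd.DataFrame(cnv, index=index, columns=dna_genes),
        network=network,
        tumour_labels=pd.Series(lab_tu, index=pd.Index(tumour_ids,
                                                       name="sample_id")),
        cell_line_labels=pd.Series(lab_cl, index=pd.Index(cell_ids,
                                                          name="sample_id")),
        prototypes=prototypes, driver_genes=drivers, shift_vector=shift,
        spec=spec)
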