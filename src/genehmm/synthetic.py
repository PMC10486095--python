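"""Ground-truth simulator: models, binarized multi-cell-type tracks, covariates.

Everything downstream of raw data can be exercised against a known truth: a
mixture model is sampled with a guaranteed emission separation between
components (and between states within a component, so states are identifiable
too), per-(gene, cell type) component labels are drawn from the model prior
with an optional replicate-concordance structure, mark observations are
simulated from each gene's component HMM over its flank-extended bins, and
covariates (expression, pLI, planted gene sets) are drawn conditionally on
the true labels.

A single integer seed drives every draw through ``numpy.random.SeedSequence``
spawning (model, dataset, covariates in that order), so fixtures are
bit-reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (BinarizedChromosome, GeneInterval, compute_extended_bins,
                   write_input_files)
from .model import GeneMixtureModel

__all__ = [
    "GroundTruth",
    "sample_ground_truth_model",
    "simulate_dataset",
    "simulate_covariates",
    "default_ci_dataset",
    "write_dataset",
]


@dataclass
class GroundTruth:
    model: GeneMixtureModel
    true_assignment: np.ndarray          # (G, C) component labels
    genes: list
    cell_types: list
    replicate_pairs: list
    genes_by_chrom: dict = field(default_factory=dict)
    tracks: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        G, C = self.true_assignment.shape
        if G != len(self.genes) or C != len(self.cell_types):
            raise ValueError("true_assignment shape inconsistent with genes/cell types")
        M = self.model.M
        if np.any((self.true_assignment < 0) | (self.true_assignment >= M)):
            raise ValueError("labels out of range")


def sample_ground_truth_model(M: int, S: int, E: int, separation: float = 2.0,
                              seed: int = 0, *, exit_mass: float = 0.05,
                              state_separation: float = 1.0,
                              self_weight: float = 0.6,
                              max_tries: int = 1000) -> GeneMixtureModel:
    """Sample a mixture whose components differ by >= ``separation``.

    Separation is the L1 distance between component mean-emission profiles
    (states averaged); states within a component are additionally kept at
    least ``state_separation`` apart so that multi-state structure is
    recoverable.  Transition rows mix a ``self_weight`` self-transition with a
    Dirichlet(1) draw, giving the within-gene mark domains some persistence.
    """
    if separation > E:
        raise ValueError(f"separation {separation} infeasible: the maximum L1 "
                         f"distance between emission profiles is E = {E}")
    rng = np.random.default_rng(seed)
    emit = np.empty((M, S, E))
    means = []
    for m in range(M):
        for attempt in range(max_tries):
            # anchor each component at a binary presence pattern; states flip a
            # few marks of the anchor so they are distinct but thematically alike
            anchor = rng.integers(0, 2, size=E).astype(float)
            flips = rng.random((S, E)) < 0.25
            patterns = np.where(flips, 1.0 - anchor, anchor)
            cand = np.clip(0.1 + 0.8 * patterns
                           + rng.uniform(-0.08, 0.08, size=(S, E)), 0.02, 0.98)
            if S > 1:
                ok = all(np.abs(cand[i] - cand[j]).sum() >= state_separation
                         for i in range(S) for j in range(i + 1, S))
                if not ok:
                    continue
            mean = cand.mean(axis=0)
            if all(np.abs(mean - mu).sum() >= separation for mu in means):
                emit[m] = cand
                means.append(mean)
                break
        else:
            raise RuntimeError(
                f"could not find a component {m} separated by {separation} after "
                f"{max_tries} tries; use more marks (E) or a smaller separation")

    comp_prior = rng.dirichlet(np.full(M, 5.0))
    tau = np.stack([rng.dirichlet(np.ones(S)) * comp_prior[m] for m in range(M)])
    trans = np.empty((M, S, S))
    for m in range(M):
        for s in range(S):
            row = self_weight * np.eye(S)[s] + (1 - self_weight) * rng.dirichlet(np.ones(S))
            trans[m, s] = row * (1.0 - exit_mass)
    exit_prob = np.full((M, S), exit_mass)
    return GeneMixtureModel(tau=tau, trans=trans, emit=emit, exit_prob=exit_prob)


def _sample_gene_observation(model: GeneMixtureModel, m: int, T: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Simulate T bins of marks from component m's HMM (length conditioned)."""
    S, E = model.S, model.E
    tau = model.tau[m] / model.tau[m].sum()
    P = model.trans[m] / model.trans[m].sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(S, p=tau)
    u = rng.random(T)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return (rng.random((T, E)) < model.emit[m, states]).astype(np.int8)


def simulate_dataset(truth_model: GeneMixtureModel, n_genes: int = 200,
                     n_cell_types: int = 4, replicate_pairs=((0, 1),),
                     *, length_median: float = 30000.0,
                     length_log10_sd: float = 0.35,
                     length_min: float = 2000.0, length_max: float = 60000.0,
                     flip_noise: float = 0.02, concordance: float = 1.0,
                     seed: int = 0, bin_width: int = 200, flank_bp: int = 2000,
                     n_chrom: int = 4) -> GroundTruth:
    """Simulate binarized tracks for a panel of cell types with known labels.

    Gene lengths are log-normal (median ``length_median``, clipped to
    [length_min, length_max]); genes are laid out on ``n_chrom`` synthetic
    chromosomes with non-overlapping flanks and random strands.  Each
    (gene, cell type) pair draws a component from the model prior; the second
    member of each replicate pair copies its partner's label with probability
    ``concordance``.  Observations are component-HMM simulations with
    symmetric per-bin flip noise.
    """
    if not (0.0 <= flip_noise < 0.5):
        raise ValueError("flip_noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    M, E = truth_model.M, truth_model.E
    cell_types = [f"ct{c:02d}" for c in range(n_cell_types)]
    rep_pairs = [(cell_types[a], cell_types[b]) for a, b in replicate_pairs]

    # gene layout
    lengths = 10 ** rng.normal(np.log10(length_median), length_log10_sd, size=n_genes)
    lengths = np.clip(lengths, length_min, length_max).astype(int)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    cursors = {c: flank_bp + bin_width for c in chrom_names}
    genes = []
    genes_by_chrom = {c: [] for c in chrom_names}
    for g in range(n_genes):
        chrom = chrom_names[g % n_chrom]
        start = cursors[chrom] + int(rng.integers(bin_width))
        end = start + int(lengths[g])
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneInterval(chrom=chrom, start=start, end=end, strand=strand,
                            gene_id=f"g{g:04d}", gene_symbol=f"G{g:04d}")
        genes.append(gene)
        genes_by_chrom[chrom].append(gene)
        cursors[chrom] = end + 2 * flank_bp + 2 * bin_width

    # labels: independent prior draws; replicates copy with given concordance
    prior = truth_model.component_prior
    labels = rng.choice(M, size=(n_genes, n_cell_types), p=prior / prior.sum())
    cidx = {c: i for i, c in enumerate(cell_types)}
    for a, b in rep_pairs:
        ia, ib = cidx[a], cidx[b]
        copy = rng.random(n_genes) < concordance
        labels[copy, ib] = labels[copy, ia]

    # tracks: background noise, then simulated genes written genomically
    chrom_bins = {c: -(-(cursors[c] + flank_bp) // bin_width) for c in chrom_names}
    tracks = {}
    for ct in cell_types:
        for chrom in chrom_names:
            bg = (rng.random((chrom_bins[chrom], E)) < flip_noise).astype(np.int8)
            tracks[(ct, chrom)] = BinarizedChromosome(
                cell_type=ct, chrom=chrom, bins=bg, bin_width=bin_width,
                mark_names=list(truth_model.mark_names))
    for g, gene in enumerate(genes):
        ext_start, ext_end, T = compute_extended_bins(gene, flank_bp, bin_width)
        lo, hi = ext_start // bin_width, ext_end // bin_width
        for c, ct in enumerate(cell_types):
            obs = _sample_gene_observation(truth_model, labels[g, c], T, rng)
            if flip_noise > 0:
                flip = rng.random(obs.shape) < flip_noise
                obs = obs ^ flip
            if gene.strand == "-":
                obs = obs[::-1]
            tracks[(ct, gene.chrom)].bins[lo:hi] = obs

    return GroundTruth(model=truth_model, true_assignment=labels, genes=genes,
                       cell_types=cell_types, replicate_pairs=rep_pairs,
                       genes_by_chrom=genes_by_chrom, tracks=tracks)


def simulate_covariates(truth: GroundTruth, *, expr_log10_mean=None,
                        expr_log10_sd: float = 0.3, high_pli_rate=None,
                        planted_sets=None, base_set_rate: float = 0.1,
                        seed: int = 0) -> dict:
    """Draw expression, pLI and gene-set tables linked to the true labels.

    RPKM per (gene, cell type) is log-normal around its true component's
    mean (defaults spread the M components evenly over log10 RPKM [-1, 2]);
    pLI is drawn per gene from its modal component's high-pLI rate (high
    scores uniform on [0.9, 1], others uniform on [0, 0.9)); each planted set
    ``(name, target_component, odds_ratio)`` over-samples genes whose modal
    component matches the target.
    """
    rng = np.random.default_rng(seed)
    M = truth.model.M
    G, C = truth.true_assignment.shape
    if expr_log10_mean is None:
        expr_log10_mean = np.linspace(-1.0, 2.0, M)
    expr_log10_mean = np.asarray(expr_log10_mean, dtype=float)
    if high_pli_rate is None:
        high_pli_rate = np.linspace(0.05, 0.5, M)
    high_pli_rate = np.asarray(high_pli_rate, dtype=float)
    if planted_sets is None:
        planted_sets = [("set_a", 0, 8.0), ("set_b", min(1, M - 1), 8.0)]

    gene_ids = [g.gene_id for g in truth.genes]
    mu = expr_log10_mean[truth.true_assignment]
    rpkm = 10 ** rng.normal(mu, expr_log10_sd)
    expression = pd.DataFrame(rpkm, index=pd.Index(gene_ids, name="gene_id"),
                              columns=truth.cell_types)

    modal = np.array([np.bincount(row, minlength=M).argmax()
                      for row in truth.true_assignment])
    is_high = rng.random(G) < high_pli_rate[modal]
    pli = pd.Series(np.where(is_high, rng.uniform(0.9, 1.0, G),
                             rng.uniform(0.0, 0.9, G)),
                    index=pd.Index(gene_ids, name="gene_id"), name="pli")

    gene_sets = {}
    for name, target, odds in planted_sets:
        p_in = base_set_rate * odds
        if p_in >= 1.0:
            p_in = 0.95
        prob = np.where(modal == target, p_in, base_set_rate)
        members = np.array(gene_ids)[rng.random(G) < prob]
        gene_sets[name] = members.tolist()

    lengths = pd.Series([g.length for g in truth.genes],
                        index=pd.Index(gene_ids, name="gene_id"), name="length")
    covariates = {"expression": expression, "pli": pli,
                  "gene_sets": gene_sets, "lengths": lengths}
    truth.covariates = covariates
    return covariates


def default_ci_dataset(seed: int = 0, *, n_genes: int = 200, M: int = 4,
                       S: int = 2, E: int = 6, separation: float = 2.0,
                       flip_noise: float = 0.02,
                       length_median: float = 8000.0) -> GroundTruth:
    """The small standard fixture: n_genes x 4 cell types (1 replicate pair),
    6 marks, lengths 2-60 kb, component separation 2.0, 2% flip noise."""
    ss = np.random.SeedSequence(seed).spawn(3)
    model = sample_ground_truth_model(M=M, S=S, E=E, separation=separation,
                                      seed=ss[0])
    truth = simulate_dataset(model, n_genes=n_genes, n_cell_types=4,
                             replicate_pairs=((0, 1),), flip_noise=flip_noise,
                             length_median=length_median, seed=ss[1])
    simulate_covariates(truth, seed=ss[2])
    return truth


def write_dataset(truth: GroundTruth, out_dir, flank_bp: int = 2000,
                  bin_width: int = 200) -> pd.DataFrame:
    """Write a self-contained fixture directory: input files + manifest,
    gene BED, covariate TSVs and a truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = write_input_files(truth.genes_by_chrom, truth.tracks, out_dir,
                                 flank_bp=flank_bp, bin_width=bin_width)
    with open(os.path.join(out_dir, "genes.bed"), "w") as fh:
        for g in truth.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    if truth.covariates:
        truth.covariates["expression"].to_csv(
            os.path.join(out_dir, "expression.tsv"), sep="\t")
        truth.covariates["pli"].to_csv(os.path.join(out_dir, "pli.tsv"), sep="\t")
        with open(os.path.join(out_dir, "gene_sets.json"), "w") as fh:
            json.dump(truth.covariates["gene_sets"], fh, indent=1)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump({"labels": truth.true_assignment.tolist(),
                   "gene_ids": [g.gene_id for g in truth.genes],
                   "cell_types": truth.cell_types,
                   "replicate_pairs": [list(p) for p in truth.replicate_pairs]},
                  fh, indent=1)
    return manifest
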