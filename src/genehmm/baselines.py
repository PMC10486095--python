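"""Comparison models: TSS-only, gene-average, and collapsed.

The TSS model clusters genes on the single 200-bp bin overlapping the
transcription start site.  The gene-average model is exactly the main
pipeline run with one state per component (no separate code path).  The
collapsed model averages each trained component's states into one —
prior-weighted by empirical state usage — and is never trained further; it
isolates how much of the full model's behaviour comes from spatial modeling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import data as _data
from .assign import posteriors_for_file
from .inference import batch_estep, em_train, load_file_segments
from .model import (ComponentUsage, GeneMixtureModel, collapse_model,
                    expand_to_single_hmm, initialize_model)

__all__ = [
    "make_tss_inputs",
    "train_baseline",
    "compute_component_usage",
    "build_collapsed_baseline",
]

logger = logging.getLogger(__name__)


def tss_bin(gene: _data.GeneInterval, bin_width: int = 200) -> int:
    """Start coordinate of the bin containing the TSS (strand-aware).

    For a negative-strand gene the TSS is the last covered coordinate,
    ``end - 1`` under the half-open convention.
    """
    tss = gene.start if gene.strand == "+" else gene.end - 1
    return (tss // bin_width) * bin_width


def make_tss_inputs(genes_by_chrom: dict, tracks: dict, out_dir,
                    bin_width: int = 200) -> pd.DataFrame:
    """Write dummy-separated input files with exactly one row per gene."""
    observations = {}
    for (cell_type, chrom), track in tracks.items():
        genes = genes_by_chrom.get(chrom, [])
        obs_list = []
        for gene in genes:
            b = tss_bin(gene, bin_width)
            if b >= track.chrom_len:
                raise ValueError(f"{gene.gene_id}: TSS bin outside track")
            obs_list.append(track.bins[b // bin_width: b // bin_width + 1])
        observations[(cell_type, chrom)] = obs_list
    return _data.write_input_files(genes_by_chrom, tracks, out_dir,
                                   bin_width=bin_width, observations=observations)


def train_baseline(kind: str, data, files, M: int = 12, seed: int = 0,
                   iterations: int = 200, subsample_files: int = 100,
                   n_restarts: int = 1, mark_names=None) -> tuple[GeneMixtureModel, object]:
    """Train an S=1 mixture on TSS or whole-gene inputs.

    ``kind`` selects the input convention only ('tss' inputs come from
    :func:`make_tss_inputs`, 'gene_average' uses the standard files); the
    model itself is the main pipeline with a single state per component.
    ``n_restarts > 1`` selects the best of several random starts by dataset
    log-likelihood before full training.
    """
    if kind not in ("tss", "gene_average"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    if n_restarts > 1:
        from .inference import em_train_restarts
        return em_train_restarts(data, files, M=M, S=1, iterations=iterations,
                                 n_restarts=n_restarts,
                                 subsample_files=subsample_files, seed=seed,
                                 mark_names=mark_names)
    model0 = initialize_model(data, M=M, S=1, seed=seed, mark_names=mark_names)
    return em_train(model0, files, iterations=iterations,
                    subsample_files=subsample_files, seed=seed)


def compute_component_usage(model: GeneMixtureModel, files,
                            manifest: pd.DataFrame) -> ComponentUsage:
    """Hard state/gene assignment counts, aggregated over all cell types.

    Each gene is hard-assigned to its posterior-argmax component; each of its
    bins to the maximum-posterior state within that component.  ``x_m`` counts
    bins, ``n_m`` genes, ``state_counts[m, s]`` bins per state.
    """
    M, S = model.M, model.S
    hmm = expand_to_single_hmm(model)
    x = np.zeros(M)
    n = np.zeros(M)
    state_counts = np.zeros((M, S))
    for fname, sub in manifest.groupby("file", sort=True):
        sub = sub.sort_values("index")
        if isinstance(files, dict):
            source = files[fname]
        else:
            import os
            source = os.path.join(files, fname)
        segments = load_file_segments(source, mark_names=model.mark_names)
        _, _, _, _, gammas = batch_estep(hmm.trans_full, hmm.emit_full,
                                         hmm.initial, segments)
        for gamma in gammas:
            gene_rows = gamma[1:-1, : M * S].reshape(-1, M, S)
            comp = int(np.argmax(gene_rows.sum(axis=2)[0]))
            states = np.argmax(gene_rows[:, comp, :], axis=1)
            n[comp] += 1
            x[comp] += len(states)
            state_counts[comp] += np.bincount(states, minlength=S)
    return ComponentUsage(x=x, n=n, state_counts=state_counts)


def build_collapsed_baseline(full_model: GeneMixtureModel, files,
                             manifest: pd.DataFrame) -> GeneMixtureModel:
    """Collapse a trained multi-state model using its own hard assignments."""
    usage = compute_component_usage(full_model, files, manifest)
    return collapse_model(full_model, usage)
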