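"""Per-gene component posteriors, hard assignments and the assignment table.

Because transitions between mixture components are disallowed, the component
posterior P(m | X) = sum_s p(H_{m,s} | X) is the same at every position of a
gene; the code asserts this rather than assuming it, since a violation means
the transition mask is broken.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneInterval
from .inference import batch_estep, load_file_segments
from .model import GeneMixtureModel, expand_to_single_hmm

__all__ = [
    "GenePosterior",
    "AssignmentMatrix",
    "MISSING",
    "gene_component_posteriors",
    "assign_all",
    "write_assignment_table",
    "read_assignment_table",
]

logger = logging.getLogger(__name__)

#: sentinel for a gene absent from a cell type's input
MISSING = -1

_CONSTANCY_TOL = 1e-9


@dataclass
class GenePosterior:
    gene_id: str
    cell_type: str
    component_posterior: np.ndarray
    hard_component: int

    def __post_init__(self):
        p = np.asarray(self.component_posterior, dtype=float)
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"{self.gene_id}: component posterior sums to {p.sum()}")
        self.component_posterior = p


@dataclass
class AssignmentMatrix:
    """Genes x cell types hard component assignments with gene metadata."""

    assignments: np.ndarray                # (G, C) ints, MISSING where absent
    gene_meta: pd.DataFrame                # chrom, start, end, symbol, strand per gene
    cell_types: list = field(default_factory=list)

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.shape != (len(self.gene_meta), len(self.cell_types)):
            raise ValueError("assignment matrix shape does not match metadata")

    @property
    def gene_ids(self) -> list:
        return list(self.gene_meta.index)

    def column(self, cell_type: str) -> np.ndarray:
        return self.assignments[:, self.cell_types.index(cell_type)]


def _component_posterior_from_gamma(gamma_rows: np.ndarray, M: int, S: int) -> np.ndarray:
    """Reduce per-position state posteriors (gene rows only) to one component vector."""
    per_pos = gamma_rows[:, : M * S].reshape(gamma_rows.shape[0], M, S).sum(axis=2)
    dev = np.max(np.abs(per_pos - per_pos[0]))
    if dev > _CONSTANCY_TOL:
        raise RuntimeError(
            f"component posterior varies along the gene (max dev {dev:.3g}); "
            "this indicates a broken cross-component transition mask")
    p = per_pos[0]
    return p / p.sum()


def gene_component_posteriors(fb, gene_row_ranges, M: int, S: int, *,
                              gene_ids=None, cell_type: str = "") -> list[GenePosterior]:
    """Component posteriors for each gene of a concatenated-file FB result.

    ``gene_row_ranges`` are half-open row spans of each gene within the file
    matrix (from the manifest or from splitting on dummy rows).  Ties at the
    argmax go to the lowest component index.
    """
    out = []
    for k, (lo, hi) in enumerate(gene_row_ranges):
        p = _component_posterior_from_gamma(fb.state_posteriors[lo:hi], M, S)
        gid = gene_ids[k] if gene_ids is not None else str(k)
        out.append(GenePosterior(gene_id=gid, cell_type=cell_type,
                                 component_posterior=p,
                                 hard_component=int(np.argmax(p))))
    return out


def posteriors_for_file(model: GeneMixtureModel, source, *,
                        gene_ids=None, cell_type: str = "") -> list[GenePosterior]:
    """Batched per-gene component posteriors for one input file."""
    hmm = expand_to_single_hmm(model)
    segments = load_file_segments(source, mark_names=model.mark_names)
    _, _, _, _, gammas = batch_estep(hmm.trans_full, hmm.emit_full,
                                     hmm.initial, segments)
    out = []
    for k, gamma in enumerate(gammas):
        p = _component_posterior_from_gamma(gamma[1:-1], model.M, model.S)
        gid = gene_ids[k] if gene_ids is not None else str(k)
        out.append(GenePosterior(gene_id=gid, cell_type=cell_type,
                                 component_posterior=p,
                                 hard_component=int(np.argmax(p))))
    return out


def per_bin_states(model: GeneMixtureModel, source, *, gene_ids=None,
                   cell_type: str = "") -> list[np.ndarray]:
    """Per-bin maximum-posterior states within each gene's assigned component.

    Returns one integer state vector (values in [0, S)) per gene of the file.
    States index positions *within* the gene's component and are not
    comparable across components; they are a visualization aid, not an
    analysis quantity.
    """
    hmm = expand_to_single_hmm(model)
    segments = load_file_segments(source, mark_names=model.mark_names)
    *_, gammas = batch_estep(hmm.trans_full, hmm.emit_full, hmm.initial,
                             segments)
    M, S = model.M, model.S
    out = []
    for gamma in gammas:
        rows = gamma[1:-1, : M * S].reshape(-1, M, S)
        comp = int(np.argmax(rows.sum(axis=2)[0]))
        out.append(np.argmax(rows[:, comp, :], axis=1))
    logger.info("per-bin states computed for %d genes; states are not "
                "comparable across components", len(out))
    return out


def assign_all(model: GeneMixtureModel, files, manifest: pd.DataFrame,
               gene_meta: pd.DataFrame | None = None,
               return_posteriors: bool = False):
    """Hard assignments for every (gene, cell type) covered by the manifest.

    ``files`` maps file name -> path or matrix.  Genes missing from a cell
    type are flagged :data:`MISSING`, never dropped.  Optionally also returns
    the full posterior array (G, C, M).
    """
    cell_types = sorted(manifest["cell_type"].unique())
    gene_order: list = []
    for gid in manifest.sort_values(["chrom", "index"])["gene_id"]:
        if gid not in gene_order:
            gene_order.append(gid)
    gidx = {g: i for i, g in enumerate(gene_order)}
    cidx = {c: j for j, c in enumerate(cell_types)}

    G, C = len(gene_order), len(cell_types)
    assignments = np.full((G, C), MISSING, dtype=int)
    post = np.full((G, C, model.M), np.nan) if return_posteriors else None

    for fname, sub in manifest.groupby("file", sort=True):
        sub = sub.sort_values("index")
        if isinstance(files, dict):
            source = files[fname]
        elif isinstance(files, (str, os.PathLike)):
            source = os.path.join(files, fname)
        else:
            raise TypeError("files must be a dict or an input directory path")
        cell_type = sub["cell_type"].iloc[0]
        gps = posteriors_for_file(model, source,
                                  gene_ids=list(sub["gene_id"]), cell_type=cell_type)
        for gp in gps:
            i, j = gidx[gp.gene_id], cidx[gp.cell_type]
            assignments[i, j] = gp.hard_component
            if post is not None:
                post[i, j] = gp.component_posterior

    n_missing = int((assignments == MISSING).sum())
    if n_missing:
        logger.warning("%d (gene, cell type) entries missing from inputs", n_missing)

    if gene_meta is None:
        gene_meta = pd.DataFrame(index=pd.Index(gene_order, name="gene_id"),
                                 columns=["chrom", "start", "end", "symbol", "strand"])
    else:
        gene_meta = gene_meta.loc[gene_order]
    mat = AssignmentMatrix(assignments=assignments, gene_meta=gene_meta,
                           cell_types=cell_types)
    return (mat, post) if return_posteriors else mat


def gene_meta_frame(genes: list[GeneInterval]) -> pd.DataFrame:
    """Metadata table (chrom, start, end, symbol, strand) indexed by gene_id."""
    return pd.DataFrame(
        {"chrom": [g.chrom for g in genes],
         "start": [g.start for g in genes],
         "end": [g.end for g in genes],
         "symbol": [g.gene_symbol or g.gene_id for g in genes],
         "strand": [g.strand for g in genes]},
        index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def write_assignment_table(matrix: AssignmentMatrix, path) -> None:
    """Write the published table layout: chrom, start, end, symbol, strand,
    then one component column per cell type; missing entries written as NA."""
    meta = matrix.gene_meta
    df = pd.DataFrame({
        "chrom": meta["chrom"].values,
        "start": meta["start"].values,
        "end": meta["end"].values,
        "symbol": meta["symbol"].values,
        "strand": meta["strand"].values,
    }, index=meta.index)
    for j, ct in enumerate(matrix.cell_types):
        col = matrix.assignments[:, j].astype(object)
        col[matrix.assignments[:, j] == MISSING] = "NA"
        df[ct] = col
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_assignment_table(path) -> AssignmentMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    meta_cols = ["chrom", "start", "end", "symbol", "strand"]
    cell_types = [c for c in df.columns if c not in meta_cols]
    assignments = (df[cell_types].replace("NA", MISSING)
                   .astype(int).to_numpy())
    return AssignmentMatrix(assignments=assignments, gene_meta=df[meta_cols],
                            cell_types=cell_types)
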