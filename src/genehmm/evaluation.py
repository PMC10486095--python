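"""Statistics for characterizing and comparing gene-level annotations.

All operations consume hard assignment matrices (genes x cell types) and
return plain arrays / DataFrames.  Thresholds default to the standard values
used throughout: RPKM >= 1 for "expressed", RPKM > 100 for "highly
expressed", pLI >= 0.9 for constrained genes, adjusted p < 0.01 for
enrichment significance, and a pseudocount of 0.1 before log10-transforming
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .assign import MISSING, AssignmentMatrix

__all__ = [
    "PairedCellTypes",
    "EnrichmentResult",
    "expression_prediction_eval",
    "compare_methods_binomial",
    "mutual_information_with_length",
    "confusion_and_contingency",
    "coassignment_enrichment",
    "gene_set_enrichment",
    "bonferroni",
    "random_split_enrichment_comparison",
    "variance_permutation_test",
    "expression_change_matrix",
    "pli_analysis",
    "hyperparameter_metrics",
    "assignment_distance_matrix",
    "cluster_assignment_rows",
]

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.1
EXPRESSED_RPKM = 1.0
HIGH_PLI = 0.9


@dataclass
class PairedCellTypes:
    """Replicate structure over the cell-type panel."""

    replicate_pairs: list
    cell_types: list

    def __post_init__(self):
        names = set(self.cell_types)
        for a, b in self.replicate_pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            if a not in names or b not in names:
                raise ValueError(f"replicate pair ({a!r}, {b!r}) not in cell types")

    @property
    def replicate_index_pairs(self) -> list:
        idx = {c: i for i, c in enumerate(self.cell_types)}
        return [(idx[a], idx[b]) for a, b in self.replicate_pairs]

    @property
    def nonreplicate_index_pairs(self) -> list:
        """All unordered non-replicate pairs of cell types."""
        rep = {frozenset(p) for p in self.replicate_pairs}
        n = len(self.cell_types)
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((self.cell_types[i], self.cell_types[j])) not in rep:
                    out.append((i, j))
        return out


@dataclass
class EnrichmentResult:
    cell_type: str
    fold: float
    p_value: float
    overlap: int
    set_size: int
    component_size: int
    universe: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.fold < 0:
            raise ValueError("fold must be >= 0")


def _labels(matrix) -> np.ndarray:
    if isinstance(matrix, AssignmentMatrix):
        return matrix.assignments
    return np.asarray(matrix, dtype=int)


def _n_components(labels: np.ndarray) -> int:
    return int(labels[labels != MISSING].max()) + 1


# ---------------------------------------------------------------------------
# expression prediction

def tie_aware_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC (ties count one half) via midranks."""
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        logger.warning("AUROC undefined with a single class; returning nan")
        return np.nan
    ranks = stats.rankdata(scores)
    return (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def expression_prediction_eval(matrix, expression: pd.DataFrame,
                               gene_chroms: pd.Series,
                               expressed_rpkm: float = EXPRESSED_RPKM) -> pd.DataFrame:
    """Leave-one-chromosome-out expression prediction from annotations.

    For each cell type and each held-out chromosome, the training genes'
    per-annotation median log10(RPKM + 0.1) is the prediction for held-out
    genes of that annotation.  Returns per-cell-type AUROC (expressed vs
    unexpressed, predictions as scores), MSE and Pearson r of the pooled
    held-out predictions.
    """
    labels = _labels(matrix)
    cell_types = (matrix.cell_types if isinstance(matrix, AssignmentMatrix)
                  else list(expression.columns))
    gene_ids = (matrix.gene_ids if isinstance(matrix, AssignmentMatrix)
                else list(expression.index))
    expr = expression.loc[gene_ids, cell_types]
    chroms = np.asarray(gene_chroms.loc[gene_ids])
    if len(np.unique(chroms)) < 2:
        raise ValueError("leave-one-chromosome-out needs >= 2 chromosomes")
    M = _n_components(labels)

    rows = []
    for j, ct in enumerate(cell_types):
        y = np.log10(expr[ct].to_numpy(dtype=float) + PSEUDOCOUNT)
        lab = labels[:, j]
        ok = lab != MISSING
        preds = np.full(y.shape, np.nan)
        for chrom in np.unique(chroms):
            held = (chroms == chrom) & ok
            train = (chroms != chrom) & ok
            global_med = np.median(y[train])
            med = np.full(M, global_med)
            for m in range(M):
                tm = train & (lab == m)
                if tm.any():
                    med[m] = np.median(y[tm])
                elif (held & (lab == m)).any():
                    logger.warning("cell type %s, chromosome %s: annotation %d has "
                                   "no training genes; using global median", ct, chrom, m)
            preds[held] = med[lab[held]]
        expressed = expr[ct].to_numpy(dtype=float)[ok] >= expressed_rpkm
        auroc = tie_aware_auroc(expressed, preds[ok])
        mse = float(np.mean((preds[ok] - y[ok]) ** 2))
        if np.ptp(preds[ok]) == 0 or np.ptp(y[ok]) == 0:
            logger.warning("cell type %s: constant values, Pearson r reported as 0", ct)
            r = 0.0
        else:
            r = float(stats.pearsonr(preds[ok], y[ok]).statistic)
        rows.append({"cell_type": ct, "auroc": auroc, "mse": mse, "pearson_r": r})
    return pd.DataFrame(rows).set_index("cell_type")


def compare_methods_binomial(metric_a, metric_b) -> float:
    """One-sided binomial test that method a beats method b across cell types.

    k = #{a > b} strict wins (ties count against a); p = P(Bin(n, 1/2) >= k).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("metric vectors must be 1-D and equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty metric vectors")
    k = int(np.sum(a > b))
    return float(stats.binom.sf(k - 1, n, 0.5))


# ---------------------------------------------------------------------------
# gene length

def length_bins(lengths, width: float = 0.05) -> np.ndarray:
    """Discretize log10(length in bp) into fixed-width intervals."""
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    return np.floor(np.log10(lengths) / width).astype(int)


def mutual_information(x, y) -> float:
    """MI in bits between two discrete label vectors, from the empirical joint."""
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def mutual_information_with_length(matrix, lengths, bin_width: float = 0.05) -> pd.Series:
    """Per-cell-type MI (bits) between annotation and binned log10 gene length."""
    labels = _labels(matrix)
    cell_types = (matrix.cell_types if isinstance(matrix, AssignmentMatrix)
                  else list(range(labels.shape[1])))
    lbins = length_bins(np.asarray(lengths, dtype=float), bin_width)
    out = {}
    for j, ct in enumerate(cell_types):
        ok = labels[:, j] != MISSING
        out[ct] = mutual_information(labels[ok, j], lbins[ok])
    return pd.Series(out, name="mutual_information_bits")


# ---------------------------------------------------------------------------
# replicate structure

def _conditional_matrix(labels: np.ndarray, index_pairs, M: int) -> np.ndarray:
    counts = np.zeros((M, M))
    for i, j in index_pairs:
        a, b = labels[:, i], labels[:, j]
        ok = (a != MISSING) & (b != MISSING)
        np.add.at(counts, (a[ok], b[ok]), 1)
        np.add.at(counts, (b[ok], a[ok]), 1)
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, counts / tot, np.nan)


def confusion_and_contingency(matrix, pairs: PairedCellTypes):
    """Replicate confusion matrix, non-replicate contingency table, specificity.

    Both matrices are row-stochastic conditionals P(component in c' = j |
    component in c = i), accumulated over genes and over both orientations of
    each pair.  The cell-type specificity of annotation i is
    ``1 - contingency_ii / confusion_ii``.
    """
    labels = _labels(matrix)
    M = _n_components(labels)
    confusion = _conditional_matrix(labels, pairs.replicate_index_pairs, M)
    contingency = _conditional_matrix(labels, pairs.nonreplicate_index_pairs, M)
    conf_diag = np.diag(confusion)
    cont_diag = np.diag(contingency)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = np.where(conf_diag > 0, 1.0 - cont_diag / conf_diag, np.nan)
    return confusion, contingency, specificity


def overall_concordance(labels: np.ndarray, index_pairs) -> float:
    """Fraction of identical assignments across the given cell-type pairs."""
    same = total = 0
    for i, j in index_pairs:
        a, b = labels[:, i], labels[:, j]
        ok = (a != MISSING) & (b != MISSING)
        same += int(np.sum(a[ok] == b[ok]))
        total += int(ok.sum())
    return same / total if total else np.nan


def coassignment_enrichment(matrix, pairs: PairedCellTypes) -> np.ndarray:
    """log2(observed / expected) co-assignment over non-replicate pairs.

    Expected assumes independent draws from the empirical annotation priors;
    observed is symmetrized over unordered non-replicate pairs and normalized
    to sum to 1.  Never-observed combinations come back as NaN.
    """
    labels = _labels(matrix)
    M = _n_components(labels)
    flat = labels[labels != MISSING]
    priors = np.bincount(flat, minlength=M) / flat.size
    expected = np.outer(priors, priors)

    index_pairs = pairs.nonreplicate_index_pairs
    if not index_pairs:
        raise ValueError("need at least one non-replicate pair")
    observed = np.zeros((M, M))
    for i, j in index_pairs:
        a, b = labels[:, i], labels[:, j]
        ok = (a != MISSING) & (b != MISSING)
        np.add.at(observed, (a[ok], b[ok]), 1)
        np.add.at(observed, (b[ok], a[ok]), 1)
    observed /= observed.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.log2(observed / expected)
    n_zero = int(np.sum(observed == 0))
    if n_zero:
        logger.info("%d co-assignment combinations never observed; reported as NaN",
                    n_zero)
        enr[observed == 0] = np.nan
    return enr


# ---------------------------------------------------------------------------
# gene-set enrichment

def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni adjustment with the caller's correction universe, capped at 1."""
    return min(1.0, p * n_tests)


def gene_set_enrichment(matrix, gene_set, component: int,
                        universe=None):
    """Hypergeometric enrichment of a gene set in one annotation.

    Per cell type: upper-tail hypergeometric p-value with parameters
    (universe size, set size, component size, overlap).  The summary fold is
    the mean over cell types of the proportion of set genes assigned to the
    annotation, divided by the annotation's empirical prior over the whole
    matrix — so a set that coincides with the universe has fold 1.  The
    summary p is the median over cell types.  Returns
    ``(results, fold, median_p)``.
    """
    labels = _labels(matrix)
    gene_ids = (matrix.gene_ids if isinstance(matrix, AssignmentMatrix)
                else list(range(labels.shape[0])))
    cell_types = (matrix.cell_types if isinstance(matrix, AssignmentMatrix)
                  else list(range(labels.shape[1])))
    if universe is None:
        universe = gene_ids
    universe = list(universe)
    gene_set = set(gene_set)
    if not gene_set <= set(universe):
        raise ValueError("gene_set must be a subset of the universe")
    gpos = {g: i for i, g in enumerate(gene_ids)}
    sel = np.array([gpos[g] for g in universe], dtype=int)
    in_set = np.array([g in gene_set for g in universe])

    flat = labels[labels != MISSING]
    prior = np.mean(flat == component)

    results = []
    props = []
    for j, ct in enumerate(cell_types):
        lab = labels[sel, j]
        ok = lab != MISSING
        in_comp = (lab == component) & ok
        N_univ = int(ok.sum())
        n_set = int((in_set & ok).sum())
        n_comp = int(in_comp.sum())
        overlap = int((in_set & in_comp).sum())
        if n_comp == 0 or n_set == 0:
            logger.info("cell type %s: empty annotation %d or gene set; skipped",
                        ct, component)
            continue
        p = float(stats.hypergeom.sf(overlap - 1, N_univ, n_set, n_comp))
        results.append(EnrichmentResult(cell_type=str(ct), fold=np.nan, p_value=p,
                                        overlap=overlap, set_size=n_set,
                                        component_size=n_comp, universe=N_univ))
        props.append(overlap / n_set)
    if not results:
        raise ValueError(f"annotation {component} empty in every cell type")
    fold = float(np.mean(props) / prior) if prior > 0 else np.nan
    median_p = float(np.median([r.p_value for r in results]))
    for r in results:
        r.fold = fold
    return results, fold, median_p


def _count_significant(groups: dict, gene_sets: dict, universe: list,
                       n_tests: int, alpha: float) -> int:
    """(gene set, group) combinations significant after Bonferroni adjustment."""
    universe_set = list(universe)
    N = len(universe_set)
    count = 0
    for _, members in groups.items():
        members = set(members)
        n_comp = len(members)
        if n_comp == 0:
            continue
        for _, gset in gene_sets.items():
            gset = set(gset) & set(universe_set)
            overlap = len(gset & members)
            p = float(stats.hypergeom.sf(overlap - 1, N, len(gset), n_comp))
            if bonferroni(p, n_tests) < alpha:
                count += 1
    return count


def random_split_enrichment_comparison(assignment_labels: pd.Series,
                                       tested_genes, gene_sets: dict,
                                       annotation_order, n_rand: int = 100,
                                       seed: int = 0, alpha: float = 0.01,
                                       coverage: float = 0.75,
                                       universe=None):
    """Enrichment counts for annotation-defined vs random same-size gene splits.

    ``assignment_labels`` maps gene id -> annotation for one cell type;
    ``tested_genes`` is the expression-filtered set; ``annotation_order`` lists
    annotations by expression (lowest first for unexpressed genes, highest
    first for highly expressed ones).  The minimal prefix of that order
    covering at least ``coverage`` of the tested genes defines the groups.
    Returns ``(n_significant_true, mean_n_significant_random)``.
    """
    tested = [g for g in tested_genes if g in assignment_labels.index]
    if universe is None:
        universe = list(assignment_labels.index)
    lab = assignment_labels.loc[tested]

    chosen = []
    covered = 0
    for m in annotation_order:
        chosen.append(m)
        covered += int((lab == m).sum())
        if covered >= coverage * len(tested):
            break
    groups = {m: [g for g in tested if lab.loc[g] == m] for m in chosen}
    sizes = [len(v) for v in groups.values()]
    n_tests = len(gene_sets) * len(chosen)

    n_true = _count_significant(groups, gene_sets, universe, n_tests, alpha)

    rng = np.random.default_rng(seed)
    pool = list(tested)
    rand_counts = []
    for _ in range(n_rand):
        perm = rng.permutation(pool)
        rgroups = {}
        pos = 0
        for m, size in zip(chosen, sizes):
            rgroups[m] = perm[pos: pos + size].tolist()
            pos += size
        rand_counts.append(_count_significant(rgroups, gene_sets, universe,
                                              n_tests, alpha))
    return n_true, float(np.mean(rand_counts))


# ---------------------------------------------------------------------------
# expression structure

@dataclass
class PermutationResult:
    p_value: float
    observed: float
    n_perm: int
    below_resolution: bool

    def __str__(self):
        if self.below_resolution:
            return f"p < {1.0 / self.n_perm:g}"
        return f"p = {self.p_value:g}"


def variance_permutation_test(median_expr: np.ndarray, n_perm: int = 10000,
                              seed: int = 0) -> PermutationResult:
    """Are within-annotation variances of median expression small?

    ``median_expr`` is annotations x cell types.  The statistic is the mean
    within-annotation variance; the null permutes the pooled cell-type medians
    over annotations, keeping the per-annotation counts.  p is the fraction of
    permutations whose statistic does not exceed the observed one; an
    observation more extreme than every permutation is flagged as below the
    1/n_perm resolution.
    """
    vals = np.asarray(median_expr, dtype=float)
    M, C = vals.shape
    observed = float(np.mean(np.var(vals, axis=1, ddof=1)))
    rng = np.random.default_rng(seed)
    flat = vals.reshape(-1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(flat).reshape(M, C)
        if np.mean(np.var(perm, axis=1, ddof=1)) <= observed:
            count += 1
    p = count / n_perm
    return PermutationResult(p_value=p, observed=observed, n_perm=n_perm,
                             below_resolution=count == 0)


def expression_change_matrix(matrix, expression: pd.DataFrame,
                             cell_type_pairs=None) -> np.ndarray:
    """Mean log2 expression ratio binned by (annotation in i, annotation in j).

    For every ordered pair of distinct cell types and every gene, the log2
    ratio (pseudocount 0.1 on both sides) lands in the bin indexed by the
    gene's annotations in the two cell types; the returned M x M matrix holds
    per-bin means (NaN where a bin is empty).
    """
    labels = _labels(matrix)
    cell_types = (matrix.cell_types if isinstance(matrix, AssignmentMatrix)
                  else list(expression.columns))
    gene_ids = (matrix.gene_ids if isinstance(matrix, AssignmentMatrix)
                else list(expression.index))
    expr = expression.loc[gene_ids, cell_types].to_numpy(dtype=float) + PSEUDOCOUNT
    M = _n_components(labels)
    if cell_type_pairs is None:
        C = len(cell_types)
        cell_type_pairs = [(i, j) for i in range(C) for j in range(C) if i != j]
    sums = np.zeros((M, M))
    counts = np.zeros((M, M))
    for i, j in cell_type_pairs:
        a, b = labels[:, i], labels[:, j]
        ok = (a != MISSING) & (b != MISSING)
        ratios = np.log2(expr[ok, j] / expr[ok, i])
        np.add.at(sums, (a[ok], b[ok]), ratios)
        np.add.at(counts, (a[ok], b[ok]), 1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


# ---------------------------------------------------------------------------
# pLI

@dataclass
class PliResult:
    high_pli_proportion: np.ndarray            # (M,)
    length_normalized_proportion: np.ndarray   # (M,)
    length_bin_proportions: np.ndarray         # (M, n_length_bins)
    reference_length_density: np.ndarray       # (n_length_bins,)
    expression_curve_proportion: np.ndarray    # (n_expr_bins,)
    expression_curve_mean_pli: np.ndarray      # (n_expr_bins,)
    expression_bin_centers: np.ndarray
    spearman_by_cell_type: pd.Series


def pli_analysis(matrix, pli: pd.Series, lengths: pd.Series,
                 expression: pd.DataFrame, high_pli: float = HIGH_PLI,
                 length_range=(3.0, 6.0), n_length_bins: int = 15,
                 expr_range=(-1.0, 2.0), n_expr_bins: int = 30) -> PliResult:
    """Loss-of-function constraint by annotation, with a length correction.

    Components: (i) per annotation, the fraction of assigned (gene, cell type)
    entries with pLI >= 0.9; (ii) the same proportion within 0.2-wide log10
    length bins on [3, 6] (genes outside discarded), summed against the
    all-gene length density to give a length-normalized proportion; (iii)
    high-pLI proportion and mean pLI in 30 bins of log10(RPKM + 0.1) on
    [-1, 2], pooled over cell types; (iv) Spearman correlation of expression
    with pLI per cell type.
    """
    labels = _labels(matrix)
    gene_ids = (matrix.gene_ids if isinstance(matrix, AssignmentMatrix)
                else list(pli.index))
    cell_types = (matrix.cell_types if isinstance(matrix, AssignmentMatrix)
                  else list(expression.columns))
    M = _n_components(labels)
    pli_v = pli.loc[gene_ids].to_numpy(dtype=float)
    if np.any((pli_v < 0) | (pli_v > 1)):
        raise ValueError("pLI scores must lie in [0, 1]")
    high = pli_v >= high_pli
    len_v = lengths.loc[gene_ids].to_numpy(dtype=float)

    # (i) overall proportion per annotation over (gene, cell type) entries
    high_prop = np.full(M, np.nan)
    high_bc = np.broadcast_to(high[:, None], labels.shape)
    for m in range(M):
        mask = labels == m
        if mask.any():
            high_prop[m] = float(np.mean(high_bc[mask]))

    # (ii) length-normalized proportion
    lo, hi = length_range
    width = (hi - lo) / n_length_bins
    loglen = np.log10(len_v)
    in_range = (loglen >= lo) & (loglen < hi)
    lbin = np.clip(((loglen - lo) / width).astype(int), 0, n_length_bins - 1)
    ref_counts = np.bincount(lbin[in_range], minlength=n_length_bins).astype(float)
    ref_density = ref_counts / ref_counts.sum()
    length_bin_prop = np.full((M, n_length_bins), np.nan)
    length_norm = np.full(M, np.nan)
    for m in range(M):
        assigned = (labels == m)  # (G, C)
        gene_w = assigned.sum(axis=1).astype(float)  # entries per gene in m
        for b in range(n_length_bins):
            sel = in_range & (lbin == b) & (gene_w > 0)
            if sel.any():
                length_bin_prop[m, b] = float(
                    np.sum(gene_w[sel] * high[sel]) / np.sum(gene_w[sel]))
        valid = ~np.isnan(length_bin_prop[m])
        if valid.any():
            length_norm[m] = float(np.nansum(
                np.where(valid, length_bin_prop[m] * ref_density, 0.0)))

    # (iii) expression curves pooled over cell types
    elo, ehi = expr_range
    ewidth = (ehi - elo) / n_expr_bins
    expr = expression.loc[gene_ids, cell_types].to_numpy(dtype=float)
    tx = np.log10(expr + PSEUDOCOUNT)
    in_erange = (tx >= elo) & (tx < ehi)
    ebin = np.clip(((tx - elo) / ewidth).astype(int), 0, n_expr_bins - 1)
    curve_prop = np.full(n_expr_bins, np.nan)
    curve_mean = np.full(n_expr_bins, np.nan)
    high_gc = np.broadcast_to(high[:, None], tx.shape)
    pli_gc = np.broadcast_to(pli_v[:, None], tx.shape)
    for b in range(n_expr_bins):
        sel = in_erange & (ebin == b)
        if sel.any():
            curve_prop[b] = float(np.mean(high_gc[sel]))
            curve_mean[b] = float(np.mean(pli_gc[sel]))
    centers = elo + (np.arange(n_expr_bins) + 0.5) * ewidth

    # (iv) Spearman per cell type
    rho = {}
    for j, ct in enumerate(cell_types):
        rho[ct] = float(stats.spearmanr(expr[:, j], pli_v).statistic)

    return PliResult(high_pli_proportion=high_prop,
                     length_normalized_proportion=length_norm,
                     length_bin_proportions=length_bin_prop,
                     reference_length_density=ref_density,
                     expression_curve_proportion=curve_prop,
                     expression_curve_mean_pli=curve_mean,
                     expression_bin_centers=centers,
                     spearman_by_cell_type=pd.Series(rho, name="spearman_r"))


# ---------------------------------------------------------------------------
# hyperparameters & visualization

def closest_state_distance(model) -> float:
    """Mean over components of the min pairwise L1 distance between state emissions."""
    if model.S < 2:
        return np.nan
    per_comp = []
    for m in range(model.M):
        dists = pdist(model.emit[m], metric="cityblock")
        per_comp.append(dists.min())
    return float(np.mean(per_comp))


def hyperparameter_metrics(models: dict, assignments: dict,
                           pairs: PairedCellTypes) -> pd.DataFrame:
    """Reproducibility and state-redundancy metrics over an (M, S) grid.

    ``models`` and ``assignments`` map (M, S) -> trained model / assignment
    matrix.  Reproducibility is the replicate concordance (fraction of
    identical assignments across replicate pairs); redundancy is the mean
    closest-state Manhattan distance (NaN for S = 1).
    """
    rows = []
    for key, model in models.items():
        labels = _labels(assignments[key])
        rows.append({"M": key[0], "S": key[1],
                     "reproducibility":
                         overall_concordance(labels, pairs.replicate_index_pairs),
                     "closest_state_distance": closest_state_distance(model)})
    return pd.DataFrame(rows).set_index(["M", "S"])


def assignment_distance_matrix(matrix, n_sample: int = 2000,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Condensed gene-gene distances 1 - mean_c I(assignment equal).

    Samples up to ``n_sample`` genes; the distance is the hamming fraction of
    discordant cell types, suitable for UPGMA clustering.  Returns
    ``(condensed_distances, sampled_gene_indices)``.
    """
    labels = _labels(matrix)
    G = labels.shape[0]
    if G < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(G, size=min(n_sample, G), replace=False))
    return pdist(labels[idx], metric="hamming"), idx


def cluster_assignment_rows(condensed: np.ndarray) -> np.ndarray:
    """UPGMA linkage with optimal leaf ordering; returns the leaf order."""
    Z = hierarchy.linkage(condensed, method="average")
    Z = hierarchy.optimal_leaf_ordering(Z, condensed)
    return np.asarray(hierarchy.leaves_list(Z))
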