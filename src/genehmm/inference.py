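"""Scaled forward-backward and Baum-Welch EM on the expanded HMM.

The recursions run in scaled (not log) space: forward variables are rescaled
at each position by the sum of the forward variables, and backward variables
— independently — by the sum of the backward variables.  After scaling, any
backward variable below 1e-300 is floored to 1e-300; forward variables are
floored the same way unless the state's emission product at that position is
exactly 0, in which case the 0 is kept.  This combination is what keeps the
procedure finite when one mixture component dominates the forward pass and a
different one dominates the backward pass, which is the regime a mixture of
HMMs routinely produces and plain single-HMM scaling does not survive.

The log-likelihood of a sequence is the sum of the logs of the forward scale
factors.  State posteriors are formed per position from the product of the
scaled forward and backward variables, renormalized.

Training follows fixed-iteration Baum-Welch: a fresh uniform subsample of
input files is drawn each iteration, so the per-iteration log-likelihood is
recorded for monitoring but is not comparable across iterations and is never
used for early stopping.  Parameters that are exactly 0 or 1 when training
starts (the structural zeros and the dummy bookkeeping entries, plus any
saturated emission) are held fixed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import read_binarized_file, split_concatenated
from .model import (ExpandedHMM, GeneMixtureModel, contract_to_mixture,
                    expand_to_single_hmm)

__all__ = [
    "FBResult",
    "EMTrace",
    "ImpossibleSequenceError",
    "forward_backward",
    "em_train",
    "em_train_restarts",
    "dataset_log_likelihood",
    "load_file_segments",
]

logger = logging.getLogger(__name__)

FLOOR = 1e-300


class ImpossibleSequenceError(ValueError):
    """The observation sequence has probability 0 under the model."""


@dataclass
class FBResult:
    """Output of one forward-backward pass over a sequence."""

    log_likelihood: float
    state_posteriors: np.ndarray      # (T, n_states) gamma
    pairwise_expectations: np.ndarray  # (n_states, n_states) summed xi
    forward_scales: np.ndarray
    backward_scales: np.ndarray


@dataclass
class EMTrace:
    """Per-iteration record of a training run.

    Log-likelihoods are evaluated on each iteration's own file subsample and
    are therefore not comparable across iterations unless subsampling covers
    all files.
    """

    log_likelihoods: list = field(default_factory=list)
    subsample_indices: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.log_likelihoods)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"iteration": np.arange(self.n_iterations),
                             "log_likelihood": self.log_likelihoods})


def emission_products(emit_full: np.ndarray, seq: np.ndarray) -> np.ndarray:
    """Per-position Bernoulli-product emission probabilities.

    ``seq`` has shape (..., T, E+1); returns shape (..., T, n_states).
    Computed by an exact product over marks (no logs), so parameters that are
    exactly 0 or 1 give exact 0/1 factors.
    """
    seq = np.asarray(seq, dtype=float)
    n_states, n_marks = emit_full.shape
    if seq.shape[-1] != n_marks:
        raise ValueError(f"sequence has {seq.shape[-1]} mark columns, "
                         f"model expects {n_marks}")
    B = np.ones(seq.shape[:-1] + (n_states,))
    for e in range(n_marks):
        x = seq[..., e: e + 1]
        B *= x * emit_full[:, e] + (1.0 - x) * (1.0 - emit_full[:, e])
    return B


def _floor_forward(alpha: np.ndarray, B_t: np.ndarray) -> np.ndarray:
    # keep exact zeros where the emission product is zero
    return np.where(B_t > 0, np.maximum(alpha, FLOOR), alpha)


def forward_backward(hmm: ExpandedHMM, seq: np.ndarray) -> FBResult:
    """Scaled forward-backward over one concatenated sequence.

    ``seq`` is a T x (E+1) binary matrix (last column the dummy mark).
    Raises :class:`ImpossibleSequenceError` rather than dividing by zero if
    the sequence is impossible under the model.
    """
    seq = np.asarray(seq)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("seq must be a T x (E+1) matrix with T >= 1")
    A = hmm.trans_full
    B = emission_products(hmm.emit_full, seq)
    T, n = B.shape

    alpha_hat = np.empty((T, n))
    fscales = np.empty(T)
    a = hmm.initial * B[0]
    for t in range(T):
        if t > 0:
            a = (a @ A) * B[t]
        s = a.sum()
        if s <= 0.0 or not np.isfinite(s):
            raise ImpossibleSequenceError(
                f"all forward variables vanished at position {t}")
        a = a / s
        a = _floor_forward(a, B[t])
        alpha_hat[t] = a
        fscales[t] = s

    beta_hat = np.empty((T, n))
    bscales = np.empty(T)
    b = np.ones(n)
    for t in range(T - 1, -1, -1):
        if t < T - 1:
            b = A @ (B[t + 1] * beta_hat[t + 1])
        s = b.sum()
        if s <= 0.0 or not np.isfinite(s):
            raise ImpossibleSequenceError(
                f"all backward variables vanished at position {t}")
        b = b / s
        b = np.maximum(b, FLOOR)
        beta_hat[t] = b
        bscales[t] = s

    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.zeros((n, n))
    for t in range(T - 1):
        num = alpha_hat[t][:, None] * A * (B[t + 1] * beta_hat[t + 1])[None, :]
        z = num.sum()
        if z <= 0.0:
            raise ImpossibleSequenceError(
                f"no transition mass between positions {t} and {t + 1}")
        xi += num / z

    return FBResult(log_likelihood=float(np.log(fscales).sum()),
                    state_posteriors=gamma, pairwise_expectations=xi,
                    forward_scales=fscales, backward_scales=bscales)


# ---------------------------------------------------------------------------
# batched E-step over per-gene segments

def load_file_segments(source, mark_names=None) -> list[np.ndarray]:
    """Per-gene sequences of a concatenated input file.

    ``source`` is a path to a binarized input file or an in-memory matrix with
    the dummy column.  Each returned segment is a (T + 2) x (E + 1) matrix:
    the gene's rows bracketed by one dummy row on each side, which is exactly
    the context the gene has inside the concatenated file.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        _, _, names, matrix = read_binarized_file(source)
        if mark_names is not None and names[:-1] != list(mark_names):
            raise ValueError(f"{source}: mark columns {names[:-1]} do not match "
                             f"the model's marks {list(mark_names)}")
    else:
        matrix = np.asarray(source)
    blocks = split_concatenated(matrix)
    E = matrix.shape[1] - 1
    segments = []
    for block in blocks:
        seg = np.zeros((block.shape[0] + 2, E + 1))
        seg[1:-1, :E] = block
        seg[0, E] = 1.0
        seg[-1, E] = 1.0
        segments.append(seg)
    return segments


def _group_by_length(segments):
    groups = {}
    for i, seg in enumerate(segments):
        groups.setdefault(seg.shape[0], []).append(i)
    return groups


def _batched_forward(A, initial, B):
    """Forward pass over a (N, T, n) emission tensor; returns alpha_hat, scales."""
    N, T, n = B.shape
    alpha_hat = np.empty((N, T, n))
    scales = np.empty((N, T))
    a = initial * B[:, 0]
    for t in range(T):
        if t > 0:
            a = (a @ A) * B[:, t]
        s = a.sum(axis=1)
        if np.any(s <= 0.0) or not np.all(np.isfinite(s)):
            raise ImpossibleSequenceError(
                f"forward variables vanished at position {t}")
        a = a / s[:, None]
        a = np.where(B[:, t] > 0, np.maximum(a, FLOOR), a)
        alpha_hat[:, t] = a
        scales[:, t] = s
    return alpha_hat, scales


def _batched_backward(A, B):
    N, T, n = B.shape
    beta_hat = np.empty((N, T, n))
    b = np.ones((N, n))
    for t in range(T - 1, -1, -1):
        if t < T - 1:
            b = (B[:, t + 1] * beta_hat[:, t + 1]) @ A.T
        s = b.sum(axis=1)
        if np.any(s <= 0.0) or not np.all(np.isfinite(s)):
            raise ImpossibleSequenceError(
                f"backward variables vanished at position {t}")
        b = np.maximum(b / s[:, None], FLOOR)
        beta_hat[:, t] = b
    return beta_hat


def batch_estep(A, emit_full, initial, segments):
    """Expectations for a set of per-gene segments, grouped by length.

    Returns ``(loglik_per_segment, xi_sum, emit_num, emit_den,
    gamma_by_segment)`` where ``xi_sum`` accumulates normalized pairwise
    expectations over all segments and positions, ``emit_num[k, e]`` the
    gamma-weighted observed-mark counts and ``emit_den[k]`` the total gamma
    mass per state.  Results are independent of the grouping because all
    accumulators are plain sums.
    """
    n = A.shape[0]
    n_marks = emit_full.shape[1]
    logliks = np.empty(len(segments))
    xi_sum = np.zeros((n, n))
    emit_num = np.zeros((n, n_marks))
    emit_den = np.zeros(n)
    gammas: list = [None] * len(segments)

    for T, idxs in sorted(_group_by_length(segments).items()):
        X = np.stack([segments[i] for i in idxs]).astype(float)  # (N, T, E+1)
        B = emission_products(emit_full, X)
        alpha_hat, scales = _batched_forward(A, initial, B)
        beta_hat = _batched_backward(A, B)
        gamma = alpha_hat * beta_hat
        gamma /= gamma.sum(axis=2, keepdims=True)
        logliks[idxs] = np.log(scales).sum(axis=1)
        for t in range(T - 1):
            num = np.einsum("ni,nj->nij", alpha_hat[:, t],
                            B[:, t + 1] * beta_hat[:, t + 1]) * A
            z = num.sum(axis=(1, 2))
            if np.any(z <= 0.0):
                raise ImpossibleSequenceError(
                    f"no transition mass between positions {t} and {t + 1}")
            xi_sum += (num / z[:, None, None]).sum(axis=0)
        emit_num += np.einsum("ntk,nte->ke", gamma, X)
        emit_den += gamma.sum(axis=(0, 1))
        for j, i in enumerate(idxs):
            gammas[i] = gamma[j]
    return logliks, xi_sum, emit_num, emit_den, gammas


def _resolve_files(files):
    if hasattr(files, "itertuples"):  # manifest DataFrame: unique file column
        raise TypeError("pass a list of file paths or matrices, not a manifest")
    return list(files)


def em_train(model: GeneMixtureModel, files, iterations: int = 200,
             subsample_files: int = 100, seed: int = 0) -> tuple[GeneMixtureModel, EMTrace]:
    """Baum-Welch training of the mixture on concatenated input files.

    Each iteration draws ``min(subsample_files, len(files))`` files uniformly
    without replacement (a fresh seeded draw per iteration), runs the E-step
    over their per-gene segments, and re-estimates initial probabilities (from
    dummy-row transition expectations), within-component transitions and exit
    probabilities, and emissions.  Runs a fixed number of iterations with no
    convergence stopping.
    """
    files = _resolve_files(files)
    if not files:
        raise ValueError("files must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    segment_cache = [load_file_segments(f, mark_names=model.mark_names)
                     for f in files]

    hmm = expand_to_single_hmm(model)
    A = hmm.trans_full.copy()
    Emat = hmm.emit_full.copy()
    trans_zero = A == 0.0
    trans_one = A == 1.0
    emit_zero = Emat == 0.0
    emit_one = Emat == 1.0

    rng = np.random.default_rng(seed)
    trace = EMTrace(seed=seed)
    k = min(subsample_files, len(files))
    for _ in range(iterations):
        sel = np.sort(rng.choice(len(files), size=k, replace=False))
        segments = [seg for i in sel for seg in segment_cache[i]]
        logliks, xi_sum, emit_num, emit_den, _ = batch_estep(
            A, Emat, hmm.initial, segments)

        row_tot = xi_sum.sum(axis=1)
        visited = row_tot > 0
        A_new = A.copy()
        A_new[visited] = xi_sum[visited] / row_tot[visited, None]
        A_new[trans_zero] = 0.0
        A_new[trans_one] = 1.0
        A = A_new

        E_new = Emat.copy()
        seen = emit_den > 0
        if not np.all(seen[:-1]):
            logger.warning("state(s) %s received zero expected mass; emissions "
                           "left unchanged this iteration",
                           np.nonzero(~seen)[0].tolist())
        E_new[seen] = emit_num[seen] / emit_den[seen, None]
        E_new[emit_zero] = 0.0
        E_new[emit_one] = 1.0
        Emat = E_new

        trace.log_likelihoods.append(float(logliks.sum()))
        trace.subsample_indices.append(sel.tolist())

    hmm.trans_full = A
    hmm.emit_full = Emat
    hmm.validate()
    return contract_to_mixture(hmm), trace


def em_train_restarts(data, files, M: int, S: int, *, iterations: int = 200,
                      n_restarts: int = 3, restart_iterations: int = 10,
                      subsample_files: int = 100, seed: int = 0,
                      mark_names=None) -> tuple[GeneMixtureModel, EMTrace]:
    """Multi-start Baum-Welch: short runs from different random initializations,
    then full training from the start with the best dataset log-likelihood.

    Mixture EM is multimodal — a single random start can merge two components
    — so the usual remedy is a handful of restarts scored on the data
    likelihood.  ``data`` is the per-gene observation collection used to seed
    emissions (as in :func:`genehmm.model.initialize_model`); restart r uses
    ``seed + r`` throughout.
    """
    from .model import initialize_model

    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best_ll = -np.inf
    best_model = None
    best_seed = seed
    for r in range(n_restarts):
        m0 = initialize_model(data, M=M, S=S, seed=seed + r,
                              mark_names=mark_names)
        mr, _ = em_train(m0, files, iterations=restart_iterations,
                         subsample_files=subsample_files, seed=seed + r)
        ll = dataset_log_likelihood(mr, files)
        logger.info("restart %d: dataset log-likelihood %.2f", r, ll)
        if ll > best_ll:
            best_ll, best_model, best_seed = ll, mr, seed + r
    remaining = max(iterations - restart_iterations, 1)
    return em_train(best_model, files, iterations=remaining,
                    subsample_files=subsample_files, seed=best_seed)


def dataset_log_likelihood(model: GeneMixtureModel, files) -> float:
    """Sum of per-file sequence log-likelihoods under the expanded HMM."""
    files = _resolve_files(files)
    hmm = expand_to_single_hmm(model)
    total = 0.0
    for f in files:
        segments = load_file_segments(f, mark_names=model.mark_names)
        for T, idxs in sorted(_group_by_length(segments).items()):
            X = np.stack([segments[i] for i in idxs]).astype(float)
            B = emission_products(hmm.emit_full, X)
            try:
                _, scales = _batched_forward(A=hmm.trans_full,
                                             initial=hmm.initial, B=B)
            except ImpossibleSequenceError as exc:
                raise ImpossibleSequenceError(f"{f}: {exc}") from exc
            total += float(np.log(scales).sum())
    return total
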