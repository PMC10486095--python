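"""Mixture-of-HMMs parameter containers and constructions.

A gene-level annotation model is a mixture of ``M`` hidden Markov models, each
with ``S`` states, over ``E`` binary epigenomic marks.  Component ``m`` is a
fully connected HMM with initial probabilities ``tau[m, s]``, within-component
transitions ``trans[m, s, s']`` and Bernoulli emission parameters
``emit[m, s, e]``.  Transitions between components are disallowed.  The mixture
is trained and decoded as a single larger HMM of ``M * S + 1`` states in which
the extra "dummy" state separates genes and emits only a "dummy" mark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneMixtureModel",
    "ExpandedHMM",
    "ComponentUsage",
    "initialize_model",
    "expand_to_single_hmm",
    "contract_to_mixture",
    "collapse_model",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_ATOL = 1e-9


@dataclass
class GeneMixtureModel:
    """Parameters of an ``M``-component, ``S``-states-per-component mixture.

    Attributes
    ----------
    tau : (M, S) array
        Initial-state probabilities; sums to 1 over all M*S states.  The
        component prior ``pi_m`` is ``tau[m].sum()``.
    trans : (M, S, S) array
        Within-component transition probabilities.  Row ``(m, s)`` plus
        ``exit_prob[m, s]`` sums to 1.
    emit : (M, S, E) array
        Bernoulli probability of observing each mark in each state.
    exit_prob : (M, S) array
        Probability of leaving the gene (transition to the dummy state).
    mark_names : list of str
        Ordered labels of the E marks.
    """

    tau: np.ndarray
    trans: np.ndarray
    emit: np.ndarray
    exit_prob: np.ndarray
    mark_names: list = field(default_factory=list)

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.emit = np.asarray(self.emit, dtype=float)
        self.exit_prob = np.asarray(self.exit_prob, dtype=float)
        if not self.mark_names:
            self.mark_names = [f"mark{e}" for e in range(self.E)]
        self.validate()

    @property
    def M(self) -> int:
        return self.tau.shape[0]

    @property
    def S(self) -> int:
        return self.tau.shape[1]

    @property
    def E(self) -> int:
        return self.emit.shape[2]

    @property
    def component_prior(self) -> np.ndarray:
        """pi_m: prior probability that a random gene belongs to component m."""
        return self.tau.sum(axis=1)

    def validate(self) -> None:
        M, S = self.tau.shape
        if self.trans.shape != (M, S, S):
            raise ValueError(f"trans shape {self.trans.shape}, expected {(M, S, S)}")
        if self.exit_prob.shape != (M, S):
            raise ValueError(f"exit_prob shape {self.exit_prob.shape}, expected {(M, S)}")
        if self.emit.ndim != 3 or self.emit.shape[:2] != (M, S):
            raise ValueError(f"emit shape {self.emit.shape}, expected ({M}, {S}, E)")
        if len(self.mark_names) != self.E:
            raise ValueError("mark_names length does not match E")
        if abs(self.tau.sum() - 1.0) > _ATOL:
            raise ValueError(f"tau sums to {self.tau.sum()!r}, expected 1")
        row_tot = self.trans.sum(axis=2) + self.exit_prob
        if np.max(np.abs(row_tot - 1.0)) > _ATOL:
            raise ValueError("transition rows plus exit probability must sum to 1")
        if np.any(self.emit < 0) or np.any(self.emit > 1):
            raise ValueError("emission parameters must lie in [0, 1]")
        if np.any(self.tau < 0) or np.any(self.trans < 0) or np.any(self.exit_prob < 0):
            raise ValueError("probabilities must be non-negative")


@dataclass
class ExpandedHMM:
    """The mixture written as one HMM of ``M * S + 1`` states.

    State ordering is ``(m, s)`` flattened row-major with the dummy state
    last.  Emissions have ``E + 1`` columns, the last being the dummy mark.
    ``zero_mask`` marks structurally disallowed transitions (cross-component
    moves and dummy->dummy); those entries are exactly 0 and stay 0 through
    training.
    """

    M: int
    S: int
    initial: np.ndarray
    trans_full: np.ndarray
    emit_full: np.ndarray
    zero_mask: np.ndarray
    mark_names: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.M * self.S + 1

    @property
    def dummy(self) -> int:
        return self.n_states - 1

    @property
    def E(self) -> int:
        return self.emit_full.shape[1] - 1

    def validate(self) -> None:
        n = self.n_states
        if self.trans_full.shape != (n, n):
            raise ValueError("trans_full has wrong shape")
        if np.max(np.abs(self.trans_full.sum(axis=1) - 1.0)) > _ATOL:
            raise ValueError("trans_full rows must sum to 1")
        if np.any(self.trans_full[self.zero_mask] != 0.0):
            raise ValueError("structural zeros violated")
        d = self.dummy
        if self.emit_full[d, self.E] != 1.0 or np.any(self.emit_full[d, : self.E] != 0.0):
            raise ValueError("dummy state must emit exactly the dummy mark")
        if np.any(self.emit_full[:d, self.E] != 0.0):
            raise ValueError("real states must never emit the dummy mark")


@dataclass
class ComponentUsage:
    """Hard-assignment counts needed to collapse a trained model.

    ``x``: number of 200-bp positions assigned to each component's states;
    ``n``: number of genes assigned to each component;
    ``state_counts``: positions per (component, state).
    """

    x: np.ndarray
    n: np.ndarray
    state_counts: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.state_counts = np.asarray(self.state_counts, dtype=float)
        if np.any(self.x < self.n):
            raise ValueError("cannot have more genes than positions in a component")

    @property
    def state_prior(self) -> np.ndarray:
        """pi_{m,s}: within-component empirical fraction of bins per state."""
        tot = self.state_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.state_counts / tot, np.nan)


def _as_matrix(obs) -> np.ndarray:
    return np.asarray(getattr(obs, "obs", obs), dtype=float)


def initialize_model(data, M: int, S: int, seed: int, *,
                     exit_mass: float = 0.05, mark_names=None) -> GeneMixtureModel:
    """Randomly initialize mixture parameters from a collection of gene observations.

    ``tau`` is a single Dirichlet(1) draw over all M*S states.  Emissions are
    seeded empirically: each gene is assigned uniformly to a component, each of
    its bins uniformly to one of that component's states, and ``emit[m, s, e]``
    is the observed mark frequency over the bins landing in ``(m, s)``.
    Each within-component transition row is a Dirichlet(1) draw scaled to sum
    to ``1 - exit_mass``; the remaining ``exit_mass`` goes to the dummy state.
    Deterministic given ``seed``.
    """
    if M < 1 or S < 1:
        raise ValueError("M and S must be >= 1")
    mats = [_as_matrix(d) for d in data]
    if not mats:
        raise ValueError("data must be non-empty")
    E = mats[0].shape[1]
    if E == 0:
        raise ValueError("observations must have at least one mark")
    if any(m.shape[1] != E for m in mats):
        raise ValueError("all observations must share the same number of marks")

    rng = np.random.default_rng(seed)
    tau = rng.dirichlet(np.ones(M * S)).reshape(M, S)
    trans = np.empty((M, S, S))
    for m in range(M):
        for s in range(S):
            trans[m, s] = rng.dirichlet(np.ones(S)) * (1.0 - exit_mass)
    exit_prob = np.full((M, S), exit_mass)

    present = np.zeros((M, S, E))
    counts = np.zeros((M, S))
    total_present = np.zeros(E)
    total_bins = 0
    for mat in mats:
        comp = rng.integers(M)
        states = rng.integers(S, size=mat.shape[0])
        for s in range(S):
            rows = mat[states == s]
            if rows.size:
                present[comp, s] += rows.sum(axis=0)
                counts[comp, s] += rows.shape[0]
        total_present += mat.sum(axis=0)
        total_bins += mat.shape[0]

    global_freq = total_present / total_bins
    emit = np.empty((M, S, E))
    for m in range(M):
        for s in range(S):
            if counts[m, s] > 0:
                emit[m, s] = present[m, s] / counts[m, s]
            else:
                logger.info("no bins assigned to component %d state %d at "
                            "initialization; using global mark frequencies", m, s)
                emit[m, s] = global_freq

    names = list(mark_names) if mark_names else [f"mark{e}" for e in range(E)]
    return GeneMixtureModel(tau=tau, trans=trans, emit=emit, exit_prob=exit_prob,
                            mark_names=names)


def expand_to_single_hmm(model: GeneMixtureModel) -> ExpandedHMM:
    """Embed the mixture into one HMM with a dummy state and dummy mark.

    Non-dummy rows carry the within-component block and the exit probability
    in the dummy column; the dummy row is the flattened ``tau`` (so a dummy
    position re-draws the component); all cross-component entries are
    structural zeros, as is dummy->dummy.
    """
    M, S, E = model.M, model.S, model.E
    n = M * S + 1
    d = n - 1

    trans_full = np.zeros((n, n))
    zero_mask = np.ones((n, n), dtype=bool)
    for m in range(M):
        lo, hi = m * S, (m + 1) * S
        trans_full[lo:hi, lo:hi] = model.trans[m]
        zero_mask[lo:hi, lo:hi] = False
    trans_full[:d, d] = model.exit_prob.reshape(-1)
    trans_full[d, :d] = model.tau.reshape(-1)
    zero_mask[:d, d] = False
    zero_mask[d, :d] = False
    # dummy -> dummy stays structurally zero

    emit_full = np.zeros((n, E + 1))
    emit_full[:d, :E] = model.emit.reshape(M * S, E)
    emit_full[d, E] = 1.0

    initial = np.zeros(n)
    initial[d] = 1.0

    hmm = ExpandedHMM(M=M, S=S, initial=initial, trans_full=trans_full,
                      emit_full=emit_full, zero_mask=zero_mask,
                      mark_names=list(model.mark_names))
    hmm.validate()
    return hmm


def contract_to_mixture(hmm: ExpandedHMM) -> GeneMixtureModel:
    """Inverse of :func:`expand_to_single_hmm` (bit-identical round trip)."""
    M, S, E = hmm.M, hmm.S, hmm.E
    d = hmm.dummy
    tau = hmm.trans_full[d, :d].reshape(M, S).copy()
    exit_prob = hmm.trans_full[:d, d].reshape(M, S).copy()
    trans = np.empty((M, S, S))
    for m in range(M):
        lo, hi = m * S, (m + 1) * S
        trans[m] = hmm.trans_full[lo:hi, lo:hi]
    emit = hmm.emit_full[:d, :E].reshape(M, S, E).copy()
    return GeneMixtureModel(tau=tau, trans=trans, emit=emit, exit_prob=exit_prob,
                            mark_names=list(hmm.mark_names))


def collapse_model(model: GeneMixtureModel, usage: ComponentUsage) -> GeneMixtureModel:
    """Average each component's states into one, weighted by empirical state use.

    The collapsed emission for component m is ``sum_s pi_{m,s} * emit[m,s]``
    with ``pi_{m,s}`` the fraction of bins hard-assigned to state s among bins
    in component m; the collapsed initial probability is the component prior;
    the self-transition is ``(x_m - n_m) / x_m`` and the exit ``n_m / x_m``.
    The result is used as-is, never trained further.
    """
    M = model.M
    if usage.x.shape != (M,) or usage.state_counts.shape != (M, model.S):
        raise ValueError("usage dimensions do not match the model")
    empty = np.nonzero(usage.x == 0)[0]
    if empty.size:
        raise ValueError(f"component(s) {empty.tolist()} have no assigned positions; "
                         "cannot collapse")
    pi_ms = usage.state_prior  # (M, S)
    emit = (pi_ms[:, :, None] * model.emit).sum(axis=1)[:, None, :]  # (M, 1, E)
    tau = model.component_prior[:, None]  # (M, 1)
    self_trans = ((usage.x - usage.n) / usage.x)[:, None, None]
    exit_prob = (usage.n / usage.x)[:, None]
    return GeneMixtureModel(tau=tau, trans=self_trans, emit=emit,
                            exit_prob=exit_prob, mark_names=list(model.mark_names))


# ---------------------------------------------------------------------------
# plain-text serialization

def save_model(model: GeneMixtureModel, path) -> None:
    """Write a model to the package's tab-separated text format."""
    with open(path, "w") as fh:
        fh.write(f"M\t{model.M}\n")
        fh.write(f"S\t{model.S}\n")
        fh.write(f"E\t{model.E}\n")
        fh.write("marks\t" + "\t".join(model.mark_names) + "\n")
        fh.write("INIT\n")
        for m in range(model.M):
            for s in range(model.S):
                fh.write(f"{m}\t{s}\t{model.tau[m, s]:.17g}\n")
        fh.write("TRANSITION\n")
        for m in range(model.M):
            for s in range(model.S):
                for s2 in range(model.S):
                    fh.write(f"{m}\t{s}\t{s2}\t{model.trans[m, s, s2]:.17g}\n")
                fh.write(f"{m}\t{s}\texit\t{model.exit_prob[m, s]:.17g}\n")
        fh.write("EMISSION\n")
        for m in range(model.M):
            for s in range(model.S):
                for e in range(model.E):
                    fh.write(f"{m}\t{s}\t{model.mark_names[e]}\t{model.emit[m, s, e]:.17g}\n")


def load_model(path) -> GeneMixtureModel:
    """Read a model written by :func:`save_model`; rejects inconsistent dimensions."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    try:
        M = int(lines[0].split("\t")[1])
        S = int(lines[1].split("\t")[1])
        E = int(lines[2].split("\t")[1])
        mark_names = lines[3].split("\t")[1:]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed model header in {path}") from exc
    if len(mark_names) != E:
        raise ValueError(f"header declares E={E} but lists {len(mark_names)} marks")

    tau = np.full((M, S), np.nan)
    trans = np.full((M, S, S), np.nan)
    exit_prob = np.full((M, S), np.nan)
    emit = np.full((M, S, E), np.nan)
    mark_index = {name: e for e, name in enumerate(mark_names)}

    section = None
    for ln in lines[4:]:
        if ln in ("INIT", "TRANSITION", "EMISSION"):
            section = ln
            continue
        if not ln.strip():
            continue
        parts = ln.split("\t")
        m, s = int(parts[0]), int(parts[1])
        if not (0 <= m < M and 0 <= s < S):
            raise ValueError(f"state index out of range in line: {ln!r}")
        if section == "INIT":
            tau[m, s] = float(parts[2])
        elif section == "TRANSITION":
            if parts[2] == "exit":
                exit_prob[m, s] = float(parts[3])
            else:
                trans[m, s, int(parts[2])] = float(parts[3])
        elif section == "EMISSION":
            emit[m, s, mark_index[parts[2]]] = float(parts[3])
        else:
            raise ValueError(f"data line before any section: {ln!r}")
    arrays = (tau, trans, exit_prob, emit)
    if any(np.isnan(a).any() for a in arrays):
        raise ValueError(f"model file {path} is missing parameter entries")
    return GeneMixtureModel(tau=tau, trans=trans, emit=emit, exit_prob=exit_prob,
                            mark_names=mark_names)
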