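import os
from types import SimpleNamespace

import numpy as np
import pytest

from genehmm.model import GeneMixtureModel


@pytest.fixture(scope="session")
def ci_dataset(tmp_path_factory):
    """The standard small synthetic fixture, written to disk once per session."""
    from genehmm import synthetic
    from genehmm.data import read_binarized_file, split_concatenated

    truth = synthetic.default_ci_dataset(seed=1)
    d = tmp_path_factory.mktemp("ci_fixture")
    manifest = synthetic.write_dataset(truth, d)
    paths = [os.path.join(d, f) for f in sorted(manifest["file"].unique())]
    obs = [b for p in paths
           for b in split_concatenated(read_binarized_file(p)[3])]
    return SimpleNamespace(truth=truth, dir=str(d), manifest=manifest,
                           paths=paths, obs=obs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mixture(M, S, E, rng, exit_mass=0.05):
    """A valid random mixture model for oracle tests."""
    tau = rng.dirichlet(np.ones(M * S)).reshape(M, S)
    trans = np.stack([
        np.stack([rng.dirichlet(np.ones(S)) * (1 - exit_mass) for _ in range(S)])
        for _ in range(M)])
    emit = rng.uniform(0.05, 0.95, size=(M, S, E))
    exit_prob = np.full((M, S), exit_mass)
    return GeneMixtureModel(tau=tau, trans=trans, emit=emit, exit_prob=exit_prob)


@pytest.fixture
def small_model(rng):
    return random_mixture(2, 2, 3, rng)


def make_gene_segment(obs):
    """Wrap a T x E gene observation in dummy rows / dummy column."""
    obs = np.asarray(obs, dtype=float)
    T, E = obs.shape
    seg = np.zeros((T + 2, E + 1))
    seg[1:-1, :E] = obs
    seg[0, E] = 1.0
    seg[-1, E] = 1.0
    return seg


def brute_force_loglik(hmm, seq):
    """Exhaustive sum over all state paths; independent oracle for T <= ~7."""
    import itertools
    from genehmm.inference import emission_products

    seq = np.asarray(seq, dtype=float)
    B = emission_products(hmm.emit_full, seq)
    T, n = B.shape
    total = 0.0
    for path in itertools.product(range(n), repeat=T):
        p = hmm.initial[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= hmm.trans_full[path[t - 1], path[t]] * B[t, path[t]]
        total += p
    return np.log(total)


def logspace_forward_loglik(hmm, seq):
    """Log-space forward recursion (logsumexp); independent of the scaled path."""
    from scipy.special import logsumexp
    from genehmm.inference import emission_products

    seq = np.asarray(seq, dtype=float)
    B = emission_products(hmm.emit_full, seq)
    with np.errstate(divide="ignore"):
        logB = np.log(B)
        logA = np.log(hmm.trans_full)
        la = np.log(hmm.initial) + logB[0]
    for t in range(1, seq.shape[0]):
        la = logsumexp(la[:, None] + logA, axis=0) + logB[t]
    return logsumexp(la)
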