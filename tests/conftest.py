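import numpy as np
import pytest

from gscpipe import HMMParams


@pytest.fixture
def well_separated_params() -> HMMParams:
    """Three clearly separated emission states, uniform chain."""
    u = np.full(3, 1 / 3)
    return HMMParams(u, np.tile(u, (3, 1)), [-0.5, 0.0, 0.5], [0.05] * 3)


def random_hmm_params(rng: np.random.Generator) -> HMMParams:
    """A random valid 3-state parameter set for oracle suites."""
    pi = rng.dirichlet(np.ones(3))
    trans = rng.dirichlet(np.ones(3), size=3)
    means = np.sort(rng.normal(0, 1, size=3))
    means += np.arange(3) * 1e-3          # enforce strict ordering
    sds = rng.uniform(0.05, 1.0, size=3)
    return HMMParams(pi, trans, means, sds)


def brute_force_viterbi(values, params: HMMParams, boundaries=None):
    """Exhaustive maximization over all 3**n state paths.

    Independent oracle for Viterbi decoding: scores every path by direct
    summation of log initial/transition/emission terms and returns the
    best.  Paths are enumerated in lexicographic order, so among exact
    ties the lowest-index path wins.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if boundaries is None:
        boundaries = [0]
    starts = set(int(b) for b in boundaries)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial_probs)
        log_a = np.log(params.transition_matrix)
    # all 3**n paths, lexicographic, one row each
    paths = np.stack(np.unravel_index(np.arange(3 ** n), (3,) * n), axis=1)
    z = (values[None, :] - params.emission_means[:, None]) \
        / params.emission_sds[:, None]
    log_b = (-0.5 * z ** 2 - np.log(params.emission_sds)[:, None]
             - 0.5 * np.log(2 * np.pi))            # (state, t)
    scores = np.zeros(len(paths))
    for t in range(n):
        scores += log_b[paths[:, t], t]
        if t in starts:
            scores += log_pi[paths[:, t]]
        else:
            scores += log_a[paths[:, t - 1], paths[:, t]]
    best = int(np.argmax(scores))
    return paths[best].copy(), float(scores[best])
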