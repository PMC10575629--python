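"""Three-state Gaussian HMM segmentation of log10 fold-change tracks.

A hidden Markov model with states (depleted, no-difference, enriched) and
Gaussian emissions on the log10 normalized ChIP/Input fold-change is
initialized semi-informedly (uniform initial and transition probabilities;
emission means at the 10th/50th/90th percentiles of the signal), decoded
with the Viterbi algorithm, and fit by Viterbi training (segmental
k-means): alternate best-path decoding with parameter re-estimation from
the decoded path until the path log-likelihood converges.  The final state
path, merged into maximal same-state runs of retained bins, is the domain
segmentation.

Chromosomes are independent chains: the model restarts at each chromosome
boundary.  All decoding is in log space; ties break toward the lowest
state index (depleted first), which makes decoding deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tracks import BinnedTrack, GenomeBins

logger = logging.getLogger("gscpipe")

STATE_LABELS = ("depleted", "nodiff", "enriched")
N_STATES = 3

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HMMParams:
    """Parameters of the three-state Gaussian HMM.

    Emission means are in log10 fold-change units and must be strictly
    increasing so that state 0/1/2 is always depleted/nodiff/enriched.
    """

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    emission_means: np.ndarray
    emission_sds: np.ndarray
    state_labels: tuple[str, ...] = STATE_LABELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial_probs",
                           np.asarray(self.initial_probs, dtype=float))
        object.__setattr__(self, "transition_matrix",
                           np.asarray(self.transition_matrix, dtype=float))
        object.__setattr__(self, "emission_means",
                           np.asarray(self.emission_means, dtype=float))
        object.__setattr__(self, "emission_sds",
                           np.asarray(self.emission_sds, dtype=float))
        if self.initial_probs.shape != (N_STATES,):
            raise ValueError(
                f"expected 3 states, got {self.initial_probs.shape[0]} "
                "initial probabilities")
        if self.transition_matrix.shape != (N_STATES, N_STATES):
            raise ValueError(
                f"expected a 3x3 transition matrix, got shape "
                f"{self.transition_matrix.shape}")
        if self.emission_means.shape != (N_STATES,) or \
                self.emission_sds.shape != (N_STATES,):
            raise ValueError("emission parameters must have 3 entries")
        if np.any(self.initial_probs < 0) or np.any(self.transition_matrix < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.initial_probs.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diff(self.emission_means) <= 0):
            raise ValueError("emission means must be strictly increasing "
                             "(depleted < nodiff < enriched)")
        if np.any(self.emission_sds <= 0):
            raise ValueError("emission sds must be positive")


@dataclass
class StatePath:
    """A per-retained-bin state labelling and its path log-likelihood."""

    states: np.ndarray                     # int in {0,1,2} per retained bin
    boundaries: np.ndarray                 # chromosome start indices
    log_likelihood: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.states.size and not np.isin(self.states, [0, 1, 2]).all():
            raise ValueError("state labels must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(STATE_LABELS, dtype=object)[self.states]


@dataclass
class DomainSet:
    """Merged same-state genomic intervals (the final segmentation)."""

    intervals: pd.DataFrame     # chrom, start, end, state

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_semi_informed(values: np.ndarray, epsilon: float = 1e-3) -> HMMParams:
    """Semi-informed starting parameters from the signal itself.

    Uniform initial and transition probabilities; emission means at the
    10th/50th/90th percentiles of the values; a shared emission SD equal
    to the overall SD (floored at 1e-3).  Degenerate (non-increasing)
    percentiles are nudged apart by ``epsilon`` with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError(f"need at least 3 finite values, got {values.size}")
    means = np.percentile(values, [10, 50, 90]).astype(float)
    if np.any(np.diff(means) <= 0):
        warnings.warn("degenerate signal: percentile emission means are not "
                      "strictly increasing; nudging them apart")
        means = np.array([means[1] - epsilon, means[1], means[1] + epsilon])
    sd = max(float(np.std(values)), 1e-3)
    uniform = np.full(N_STATES, 1.0 / N_STATES)
    return HMMParams(uniform, np.tile(uniform, (N_STATES, 1)), means,
                     np.full(N_STATES, sd))


# ---------------------------------------------------------------------------
# Decoding and likelihood
# ---------------------------------------------------------------------------

def _check_boundaries(n: int, boundaries) -> np.ndarray:
    if boundaries is None:
        return np.array([0], dtype=int) if n else np.array([], dtype=int)
    b = np.asarray(boundaries, dtype=int)
    if n and (b.size == 0 or b[0] != 0):
        raise ValueError("boundaries must start at index 0")
    if np.any(np.diff(b) <= 0) or (b.size and b[-1] >= n):
        raise ValueError("boundaries must be strictly increasing and < n")
    return b


def _log_emissions(values: np.ndarray, params: HMMParams) -> np.ndarray:
    """(n, 3) matrix of log Gaussian emission densities."""
    z = (values[:, None] - params.emission_means[None, :]) / params.emission_sds
    return -0.5 * (z ** 2) - np.log(params.emission_sds) - 0.5 * _LOG_2PI


def viterbi_decode(values: np.ndarray, params: HMMParams,
                   boundaries=None) -> StatePath:
    """Maximum-probability state path, decoded per chromosome.

    The chain restarts with the initial distribution at every boundary
    index.  Ties break toward the lowest state index.
    """
    values = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite value at bin index {bad[0]}")
    boundaries = _check_boundaries(len(values), boundaries)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial_probs)
        log_a = np.log(params.transition_matrix)
    log_b = _log_emissions(values, params)

    states = np.empty(len(values), dtype=int)
    total = 0.0
    edges = np.append(boundaries, len(values))
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = hi - lo
        delta = np.empty((n, N_STATES))
        psi = np.empty((n, N_STATES), dtype=int)
        delta[0] = log_pi + log_b[lo]
        for t in range(1, n):
            cand = delta[t - 1][:, None] + log_a          # (from, to)
            psi[t] = np.argmax(cand, axis=0)              # argmax -> lowest index on ties
            delta[t] = cand[psi[t], np.arange(N_STATES)] + log_b[lo + t]
        last = int(np.argmax(delta[n - 1]))
        total += float(delta[n - 1, last])
        path = np.empty(n, dtype=int)
        path[-1] = last
        for t in range(n - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        states[lo:hi] = path
    return StatePath(states, boundaries, total)


def statepath_loglik(values: np.ndarray, params: HMMParams,
                     path: StatePath | np.ndarray,
                     boundaries=None) -> float:
    """Joint log-likelihood of (values, state path) under the model.

    Sum of log initial, log transition and log Gaussian emission terms
    along the path, with the chain restarting at each boundary.
    """
    if np.any(params.emission_sds <= 0):
        raise ValueError("emission sds must be positive")
    values = np.asarray(values, dtype=float)
    if isinstance(path, StatePath):
        states = path.states
        if boundaries is None:
            boundaries = path.boundaries
    else:
        states = np.asarray(path, dtype=int)
    if len(states) != len(values):
        raise ValueError("path length must equal number of values")
    boundaries = _check_boundaries(len(values), boundaries)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial_probs)
        log_a = np.log(params.transition_matrix)
    log_b = _log_emissions(values, params)
    total = float(log_b[np.arange(len(values)), states].sum())
    is_start = np.zeros(len(values), dtype=bool)
    is_start[boundaries] = True
    total += float(log_pi[states[is_start]].sum())
    prev_ok = ~is_start
    total += float(log_a[states[np.flatnonzero(prev_ok) - 1],
                         states[prev_ok]].sum())
    return total


# ---------------------------------------------------------------------------
# Viterbi training (segmental k-means)
# ---------------------------------------------------------------------------

def _reestimate(values: np.ndarray, states: np.ndarray,
                boundaries: np.ndarray, sd_floor: float = 1e-4) -> HMMParams:
    """Parameter re-estimation from a decoded path.

    Initial probabilities come from the path starts, transitions from the
    path bigram frequencies, emission mean/SD from the values assigned to
    each state.  A state with no assigned bins is re-seeded to the
    corresponding extreme quantile with the global SD.
    """
    n = len(values)
    starts = states[boundaries]
    pi = np.bincount(starts, minlength=N_STATES).astype(float)
    if pi.sum() == 0:
        pi = np.ones(N_STATES)
    pi /= pi.sum()

    is_start = np.zeros(n, dtype=bool)
    is_start[boundaries] = True
    frm = states[np.flatnonzero(~is_start) - 1]
    to = states[~is_start]
    trans = np.zeros((N_STATES, N_STATES))
    np.add.at(trans, (frm, to), 1.0)
    rowsum = trans.sum(axis=1, keepdims=True)
    # a state never left keeps a uniform outgoing row
    trans = np.where(rowsum > 0, trans / np.where(rowsum == 0, 1, rowsum),
                     1.0 / N_STATES)

    global_sd = max(float(np.std(values)), sd_floor)
    seed_quantiles = (10.0, 50.0, 90.0)
    means = np.empty(N_STATES)
    sds = np.empty(N_STATES)
    for s in range(N_STATES):
        assigned = values[states == s]
        if assigned.size == 0:
            means[s] = float(np.percentile(values, seed_quantiles[s]))
            sds[s] = global_sd
            logger.info("viterbi_train: state %s had no assigned bins; "
                        "re-seeded to the %g%% quantile", STATE_LABELS[s],
                        seed_quantiles[s])
        else:
            means[s] = float(assigned.mean())
            sds[s] = max(float(assigned.std()), sd_floor)

    order = np.argsort(means, kind="stable")
    if not np.array_equal(order, np.arange(N_STATES)):
        logger.info("viterbi_train: re-sorting states by emission mean")
        means, sds, pi = means[order], sds[order], pi[order]
        trans = trans[order][:, order]
    # collapsed means are nudged minimally to keep the ordering invariant
    for s in (1, 2):
        if means[s] <= means[s - 1]:
            means[s] = means[s - 1] + 1e-6
    return HMMParams(pi, trans, means, sds)


def viterbi_train(values: np.ndarray, boundaries=None,
                  init: HMMParams | None = None, max_iter: int = 1000,
                  tol: float = 1e-6) -> tuple[HMMParams, StatePath, pd.DataFrame]:
    """Fit by Viterbi training: decode, re-estimate, repeat to convergence.

    Stops when the path log-likelihood changes by less than ``tol``, the
    path stops changing, or ``max_iter`` is reached.  Returns the final
    parameters, the final path, and a per-iteration log (iteration,
    log-likelihood, path changed).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    values = np.asarray(values, dtype=float)
    boundaries = _check_boundaries(len(values), boundaries)
    params = init if init is not None else init_semi_informed(values)
    prev_ll = -np.inf
    prev_states: np.ndarray | None = None
    log_rows = []
    path = viterbi_decode(values, params, boundaries)
    for it in range(1, max_iter + 1):
        changed = prev_states is None or not np.array_equal(path.states,
                                                            prev_states)
        log_rows.append({"iteration": it, "log_likelihood": path.log_likelihood,
                         "path_changed": changed})
        if (not changed) or abs(path.log_likelihood - prev_ll) < tol:
            break
        prev_ll = path.log_likelihood
        prev_states = path.states
        params = _reestimate(values, path.states, boundaries)
        path = viterbi_decode(values, params, boundaries)
    return params, path, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

def domains_from_statepath(path: StatePath, retained_bins: GenomeBins) -> DomainSet:
    """Merge maximal runs of same-state retained bins into intervals.

    A discarded bin between two same-state bins breaks the run (the
    retained bins are not coordinate-adjacent there), yielding two
    domains.
    """
    if len(path) != len(retained_bins):
        raise ValueError("state path and retained bins are inconsistent "
                         f"({len(path)} states vs {len(retained_bins)} bins)")
    if len(path) == 0:
        return DomainSet(pd.DataFrame(columns=["chrom", "start", "end", "state"]))
    chroms = retained_bins.chroms
    starts = retained_bins.starts
    ends = retained_bins.ends
    states = path.states
    # a new domain starts where state, chromosome, or coordinate adjacency breaks
    brk = np.ones(len(path), dtype=bool)
    brk[1:] = ((states[1:] != states[:-1])
               | (chroms[1:] != chroms[:-1])
               | (starts[1:] != ends[:-1]))
    run_start = np.flatnonzero(brk)
    run_end = np.append(run_start[1:], len(path)) - 1
    df = pd.DataFrame({
        "chrom": chroms[run_start],
        "start": starts[run_start],
        "end": ends[run_end],
        "state": np.asarray(STATE_LABELS, dtype=object)[states[run_start]],
    })
    return DomainSet(df)


def statepath_from_domains(domains: DomainSet,
                           retained_bins: GenomeBins) -> np.ndarray:
    """Re-label retained bins from a DomainSet (inverse of domain building)."""
    label_to_idx = {lab: i for i, lab in enumerate(STATE_LABELS)}
    states = np.full(len(retained_bins), -1, dtype=int)
    for row in domains.intervals.itertuples(index=False):
        sel = ((retained_bins.chroms == row.chrom)
               & (retained_bins.starts >= row.start)
               & (retained_bins.ends <= row.end))
        states[sel] = label_to_idx[row.state]
    if np.any(states < 0):
        raise ValueError("domains do not cover every retained bin")
    return states


def segment_track(fc_track: BinnedTrack, max_iter: int = 1000,
                  tol: float = 1e-6) -> tuple[DomainSet, HMMParams, StatePath,
                                              pd.DataFrame]:
    """End-to-end segmentation of a log10 normalized fold-change track."""
    if fc_track.value_kind != "log10_norm_fc":
        raise ValueError("segment_track expects a log10_norm_fc track")
    boundaries = fc_track.bins.chromosome_boundaries()
    params, path, log = viterbi_train(fc_track.values, boundaries,
                                      max_iter=max_iter, tol=tol)
    return domains_from_statepath(path, fc_track.bins), params, path, log
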