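"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of study input — state-structured
ChIP/Input count tracks, stage-series coarse coverage with elevated
centric signal, repeat-element count tables, follicle volumes from the
piecewise allometric growth model, and replicate TPM tables — and emits a
truth record sufficient for parameter-recovery tests downstream.  All
generators are deterministic given their seed.

Noise models: Input read counts are Poisson with the requested mean
depth; ChIP counts are Poisson with mean = Input mean x 10**e where e is
the hidden state's Gaussian log10 fold-change emission (so the expected
log10 FC per bin equals the state's emission mean at moderate depth).
TPM replicates are log-normal parameterized by (mean, CV), which keeps
them nonnegative with a directly controllable CV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthFit, predict_log_volume, REFERENCE_COEFFICIENTS
from .het_profile import COARSE_BIN_WIDTH, StageProfile
from .hmm_segment import HMMParams, N_STATES, STATE_LABELS
from .lineage_sim import Lineage
from .tracks import BinnedTrack, GenomeBins, make_bins

#: Default stage -> log2 DNA sampling ranges.  Ranges overlap within each
#: condition segment, which keeps the slope/intercept design identifiable.
DEFAULT_STAGE_DNA_RANGES: dict[int, tuple[float, float]] = {
    **{s: (0.0, 4.0) for s in range(1, 6)},
    **{s: (3.0, 7.0) for s in (6, 7)},
    **{s: (6.0, 10.0) for s in (8, 9, 10)},
}


# ---------------------------------------------------------------------------
# ChIP/Input pair with hidden three-state structure
# ---------------------------------------------------------------------------

@dataclass
class SynthChipTruth:
    """Ground truth of a generated ChIP/Input pair."""

    genome: list[tuple[str, int]]
    bin_width: int
    true_statepath: np.ndarray      # int state per bin
    true_params: HMMParams
    seed: int

    @property
    def state_labels(self) -> np.ndarray:
        return np.asarray(STATE_LABELS, dtype=object)[self.true_statepath]


def gen_chip_pair(genome: Mapping[str, int] | Sequence[tuple[str, int]],
                  bin_width: int, params: HMMParams, mean_depth: float,
                  seed: int) -> tuple[BinnedTrack, BinnedTrack, SynthChipTruth]:
    """Generate a ChIP/Input count pair over genome bins with hidden
    three-state structure.

    The hidden state path is sampled per chromosome from ``params``'s
    Markov chain; Input counts are Poisson(``mean_depth``); ChIP counts
    are Poisson(``mean_depth`` x 10**e) with e drawn from the state's
    Gaussian emission.
    """
    if len(params.initial_probs) != N_STATES:
        raise ValueError(f"params must have exactly {N_STATES} states, got "
                         f"{len(params.initial_probs)}")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    genome_items = list(genome.items()) if isinstance(genome, Mapping) \
        else [(str(c), int(l)) for c, l in genome]
    if not genome_items:
        raise ValueError("zero-length genome")
    bins = make_bins(dict(genome_items), bin_width)
    rng = np.random.default_rng(seed)

    states = np.empty(len(bins), dtype=int)
    boundaries = bins.chromosome_boundaries()
    edges = np.append(boundaries, len(bins))
    for lo, hi in zip(edges[:-1], edges[1:]):
        s = rng.choice(N_STATES, p=params.initial_probs)
        for t in range(lo, hi):
            states[t] = s
            s = rng.choice(N_STATES, p=params.transition_matrix[s])
    emissions = rng.normal(params.emission_means[states],
                           params.emission_sds[states])
    input_counts = rng.poisson(mean_depth, size=len(bins))
    chip_counts = rng.poisson(mean_depth * 10.0 ** emissions)
    chip = BinnedTrack(bins, chip_counts, "raw_count")
    inp = BinnedTrack(bins, input_counts, "raw_count")
    truth = SynthChipTruth(genome_items, bin_width, states, params, seed)
    return chip, inp, truth


# ---------------------------------------------------------------------------
# Stage-series coarse heterochromatin profiles
# ---------------------------------------------------------------------------

def gen_het_profiles(genome: Mapping[str, int],
                     centric_spans: Mapping[str, list[tuple[int, int]]],
                     stage_enrichments: Mapping[str, float],
                     bin_width: int = COARSE_BIN_WIDTH,
                     seed: int = 0,
                     euchromatic_signal: float = 100.0,
                     background: float = 20.0
                     ) -> dict[str, StageProfile]:
    """Stage-series coarse count profiles with elevated centric signal.

    Euchromatic bins of every stage carry the same expected ChIP signal
    (``background + euchromatic_signal`` reads); bins inside a centric
    span carry ``background + ratio * euchromatic_signal`` where ratio is
    the stage's centric/euchromatic enrichment.  Input tracks are flat at
    ``background``.  Counts are Poisson; after background elimination and
    cross-stage euchromatin normalization the centric mean recovers the
    stage's ratio.
    """
    for stage, ratio in stage_enrichments.items():
        if ratio < 1:
            raise ValueError(f"stage {stage!r}: enrichment ratio must be >= 1")
    for chrom, spans in centric_spans.items():
        if chrom not in genome:
            raise ValueError(f"centric span on unknown chromosome {chrom!r}")
        spans = sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping centric spans on {chrom!r}")
        for s, e in spans:
            if s < 0 or e > genome[chrom]:
                raise ValueError(f"centric span ({s}, {e}) outside "
                                 f"{chrom!r} bounds")
    bins = make_bins(genome, bin_width)
    centric = np.zeros(len(bins), dtype=bool)
    for i, (c, s, e) in enumerate(zip(bins.chroms, bins.starts, bins.ends)):
        for lo, hi in centric_spans.get(c, []):
            if s >= lo and e <= hi:
                centric[i] = True
    rng = np.random.default_rng(seed)
    profiles: dict[str, StageProfile] = {}
    for stage, ratio in stage_enrichments.items():
        mean_chip = np.where(centric,
                             background + ratio * euchromatic_signal,
                             background + euchromatic_signal)
        chip = rng.poisson(mean_chip)
        inp = rng.poisson(np.full(len(bins), background))
        # counts are generated at matched ChIP/Input sequencing depth, so the
        # nominal depth is 1e6 for both and CPM equals the raw count scale
        profiles[stage] = StageProfile(
            stage=stage,
            track=BinnedTrack(bins, chip, "raw_count"),
            input_track=BinnedTrack(bins, inp, "raw_count"),
            depth=1e6,
            input_depth=1e6,
        )
    return profiles


# ---------------------------------------------------------------------------
# Follicle volumes from the growth model
# ---------------------------------------------------------------------------

def gen_follicle_volumes(n: int,
                         coefficients: GrowthFit | Mapping[str, float] = None,
                         noise_sd: float = 0.15,
                         stage_dna_ranges: Mapping[int, tuple[float, float]]
                         = None,
                         seed: int = 0,
                         stages: Sequence[int] | None = None) -> pd.DataFrame:
    """Follicle table (stage, log2_dna, log10_volume) from the piecewise
    allometric model plus Gaussian noise.

    Stages are drawn uniformly from 1-10 (or given explicitly); log2 DNA
    content is uniform on the stage's range.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if coefficients is None:
        coefficients = REFERENCE_COEFFICIENTS
    ranges = dict(DEFAULT_STAGE_DNA_RANGES if stage_dna_ranges is None
                  else stage_dna_ranges)
    for s in range(1, 11):
        if s not in ranges:
            raise ValueError(f"missing log2 DNA range for stage {s}")
    if any(s < 1 or s > 10 for s in ranges):
        raise ValueError("stage outside 1-10 in stage_dna_ranges")
    rng = np.random.default_rng(seed)
    if stages is None:
        stage_arr = rng.integers(1, 11, size=n)
    else:
        stage_arr = np.asarray(stages, dtype=int)
        if len(stage_arr) != n:
            raise ValueError("stages must have length n")
        if np.any((stage_arr < 1) | (stage_arr > 10)):
            raise ValueError("stage outside 1-10")
    lo = np.array([ranges[s][0] for s in stage_arr])
    hi = np.array([ranges[s][1] for s in stage_arr])
    log2_dna = rng.uniform(lo, hi)
    vol = predict_log_volume(coefficients, stage_arr, log2_dna)
    vol = np.asarray(vol, dtype=float)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"stage": stage_arr, "log2_dna": log2_dna,
                         "log10_volume": vol})


# ---------------------------------------------------------------------------
# Replicate TPM tables
# ---------------------------------------------------------------------------

def gen_expression_table(n_genes: int,
                         group_means: Mapping[str, float],
                         cv: Mapping[str, float] | float,
                         n_reps: int, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate TPM table with per-class mean and CV, plus truth labels.

    ``group_means`` maps class label -> mean TPM; ``cv`` is a matching
    mapping (or one shared value).  ``n_genes`` is the total, split as
    evenly as possible across classes.  Values are log-normal with the
    requested mean and CV (a zero mean gives exact zeros).  Returns the
    genes x replicates table and the per-gene class labels.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    classes = list(group_means)
    cvs = {c: (cv if np.isscalar(cv) else cv[c]) for c in classes}
    for c in classes:
        if group_means[c] < 0:
            raise ValueError(f"class {c!r}: mean must be nonnegative")
        if cvs[c] < 0:
            raise ValueError(f"class {c!r}: cv must be nonnegative")
    rng = np.random.default_rng(seed)
    base = n_genes // len(classes) if classes else 0
    sizes = [base + (1 if i < n_genes - base * len(classes) else 0)
             for i in range(len(classes))]
    rows, labels, names = [], [], []
    gene_i = 0
    for c, size in zip(classes, sizes):
        m, v = group_means[c], cvs[c]
        for _ in range(size):
            if m == 0:
                vals = np.zeros(n_reps)
            elif v == 0:
                vals = np.full(n_reps, m)
            else:
                sigma2 = np.log1p(v ** 2)
                mu = np.log(m) - sigma2 / 2.0
                vals = rng.lognormal(mu, np.sqrt(sigma2), size=n_reps)
            rows.append(vals)
            labels.append(c)
            names.append(f"gene_{gene_i:05d}")
            gene_i += 1
    table = pd.DataFrame(rows, index=names,
                         columns=[f"rep{r + 1}" for r in range(n_reps)])
    return table, pd.Series(labels, index=names, name="true_class")


# ---------------------------------------------------------------------------
# Repeat-element count tables
# ---------------------------------------------------------------------------

def gen_repeat_counts(repeat_names: Sequence[str],
                      stage_factors: Mapping[str, Mapping[str, float]],
                      base_counts: Mapping[str, float],
                      seed: int | None = 0,
                      repeat_classes: Mapping[str, str] | None = None,
                      background: float = 50.0,
                      stages: Sequence[str] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage repeat count table with known enrichment factors.

    Expected ChIP count for repeat r at stage s is
    ``background + base_counts[r] * stage_factors[s][r]`` (factor 1 where
    unspecified); input counts are flat at ``background``.  With
    ``seed=None`` counts are exact expectations (deterministic mode) and
    downstream enrichment ratios equal the factors exactly; otherwise
    counts are Poisson.  Returns (table, truth factor table).
    """
    if stages is None:
        stages = list(stage_factors)
    for stage in stage_factors:
        if stage not in stages:
            raise ValueError(f"unknown stage {stage!r} in stage_factors")
    for r in repeat_names:
        if base_counts.get(r, 0) <= 0:
            raise ValueError(f"repeat {r!r}: base count must be positive")
    factors = pd.DataFrame(1.0, index=list(repeat_names), columns=list(stages))
    for stage, per_repeat in stage_factors.items():
        for r, f in per_repeat.items():
            if r not in factors.index:
                raise ValueError(f"unknown repeat {r!r} in stage_factors")
            if f <= 0:
                raise ValueError(f"factor for {r!r}@{stage!r} must be positive")
            factors.loc[r, stage] = f
    rng = np.random.default_rng(seed) if seed is not None else None
    table = pd.DataFrame({"repeat": list(repeat_names)})
    table["class"] = [repeat_classes.get(r, "TE") if repeat_classes else "TE"
                      for r in repeat_names]
    for stage in stages:
        expected = background + np.array(
            [base_counts[r] * factors.loc[r, stage] for r in repeat_names])
        table[f"count_{stage}"] = (rng.poisson(expected) if rng is not None
                                   else expected)
        table[f"input_count_{stage}"] = (
            rng.poisson(np.full(len(repeat_names), background))
            if rng is not None else np.full(len(repeat_names), background))
    return table, factors
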