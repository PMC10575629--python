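"""Chromosome-scale H3K9me3 profiling and repeat-element enrichment.

Pericentromeric heterochromatin growth across germline stages is measured
on a coarse (250 kb) bin grid: reads are scaled by sequencing depth (CPM),
the matching input control is subtracted to eliminate background, and each
stage's profile is normalized to its own mean over the euchromatic
chromosome arms so that stages are directly comparable (euchromatic mean
= 1 everywhere; centric bins then read out fold-enrichment over arms).

Repeat-element enrichment compares depth-scaled, background-eliminated
counts on individual repeats (transposons and satellites) between a stage
and a reference stage (usually the germline stem cell sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .tracks import (BinnedTrack, EuchromatinLimits, EUCHROMATIN_COARSE_250KB)

logger = logging.getLogger("gscpipe")

COARSE_BIN_WIDTH = 250_000


@dataclass
class StageProfile:
    """Coverage of one developmental stage (GSC, 4C NC, 8C NC, ...)."""

    stage: str
    track: BinnedTrack
    input_track: BinnedTrack | None = None
    depth: float = 1.0           # total mapped reads, ChIP
    input_depth: float = 1.0     # total mapped reads, Input

    def __post_init__(self) -> None:
        if self.input_track is not None and \
                len(self.input_track) != len(self.track):
            raise ValueError("track and input must share bins")


def _cpm(values: np.ndarray, depth: float) -> np.ndarray:
    if depth <= 0:
        raise ValueError(f"sequencing depth must be positive, got {depth}")
    return np.asarray(values, dtype=float) * 1e6 / depth


def coarse_profile(counts: BinnedTrack, input_: BinnedTrack | None,
                   depth_chip: float, depth_input: float = 1.0,
                   mode: str = "subtract") -> BinnedTrack:
    """Depth-scale and background-eliminate one stage's coarse counts.

    Per-bin value is ``max(0, CPM_chip - CPM_input)`` in the default
    subtractive mode, or ``CPM_chip / CPM_input`` (zero-input bins -> 0)
    in ratio mode.  Without an input control the background step is
    skipped with a warning and the CPM track returned.
    """
    chip_cpm = _cpm(counts.values, depth_chip)
    if input_ is None:
        logger.warning("coarse_profile: no input control; background "
                       "elimination skipped")
        return BinnedTrack(counts.bins, chip_cpm, "coverage")
    if len(input_) != len(counts):
        raise ValueError("ChIP and input tracks must share bins")
    input_cpm = _cpm(input_.values, depth_input)
    if mode == "subtract":
        values = np.maximum(0.0, chip_cpm - input_cpm)
    elif mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(input_cpm > 0, chip_cpm / input_cpm, 0.0)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return BinnedTrack(counts.bins, values, "coverage")


def normalize_across_stages(tracks: Mapping[str, BinnedTrack],
                            limits: EuchromatinLimits = EUCHROMATIN_COARSE_250KB,
                            statistic: str = "mean"
                            ) -> dict[str, BinnedTrack]:
    """Normalize each stage's coverage to its euchromatic-arm level.

    Each track is divided by the mean (or median) of its bins lying fully
    inside the euchromatin limits, so after normalization every stage's
    euchromatic mean is 1 and bins elsewhere read out relative
    enrichment.  Bins straddling a limit boundary are excluded from the
    denominator.
    """
    if not tracks:
        raise ValueError("need at least one stage profile")
    out: dict[str, BinnedTrack] = {}
    for stage, track in tracks.items():
        mask = limits.bin_mask(track.bins)
        if not mask.any():
            raise ValueError(f"stage {stage!r} has no bins inside the "
                             f"euchromatin limits {limits.name!r}")
        eu = track.values[mask]
        denom = float(np.mean(eu)) if statistic == "mean" else float(np.median(eu))
        if denom <= 0:
            raise ValueError(f"stage {stage!r} has non-positive euchromatic "
                             f"{statistic}; cannot normalize")
        out[stage] = BinnedTrack(track.bins, track.values / denom, "coverage")
    return out


def repeat_enrichment(table: pd.DataFrame, reference_stage: str,
                      stages: list[str] | None = None,
                      depths: Mapping[str, float] | None = None,
                      input_depths: Mapping[str, float] | None = None
                      ) -> pd.DataFrame:
    """Per-repeat enrichment of each stage relative to a reference stage.

    ``table`` has one row per repeat with columns ``repeat``, ``class``
    (TE or satellite), ``count_<stage>`` and optionally
    ``input_count_<stage>``.  The per-stage signal is the depth-scaled,
    background-eliminated count; the ratio divides it by the same
    quantity in the reference stage.  Repeats whose reference signal is
    zero are reported with ``missing=True`` and NaN ratios rather than
    infinities.
    """
    count_cols = [c for c in table.columns if c.startswith("count_")]
    all_stages = [c[len("count_"):] for c in count_cols]
    if reference_stage not in all_stages:
        raise ValueError(f"reference stage {reference_stage!r} not in table")
    if stages is None:
        stages = [s for s in all_stages if s != reference_stage]

    def signal(stage: str) -> np.ndarray:
        chip = table[f"count_{stage}"].to_numpy(dtype=float)
        d = depths.get(stage, 1.0) if depths else 1.0
        sig = _cpm(chip, d) if depths else chip
        icol = f"input_count_{stage}"
        if icol in table.columns:
            inp = table[icol].to_numpy(dtype=float)
            di = input_depths.get(stage, 1.0) if input_depths else 1.0
            sig = np.maximum(0.0, sig - (_cpm(inp, di) if input_depths else inp))
        return sig

    ref = signal(reference_stage)
    if not np.any(ref > 0):
        raise ValueError(f"all-zero reference column for stage "
                         f"{reference_stage!r}")
    out = table[["repeat", "class"]].copy() if "class" in table.columns \
        else table[["repeat"]].copy()
    out["missing"] = ref <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for stage in stages:
            out[f"ratio_{stage}"] = np.where(ref > 0, signal(stage) / ref,
                                             np.nan)
    n_missing = int(out["missing"].sum())
    if n_missing:
        logger.info("repeat_enrichment: %d repeats with zero reference "
                    "signal flagged missing", n_missing)
    return out


def profile_stages(profiles: Mapping[str, StageProfile],
                   limits: EuchromatinLimits = EUCHROMATIN_COARSE_250KB,
                   mode: str = "subtract") -> dict[str, BinnedTrack]:
    """Full coarse pipeline: CPM + background elimination + cross-stage
    euchromatin normalization for a set of stage profiles."""
    coverage = {
        stage: coarse_profile(p.track, p.input_track, p.depth,
                              p.input_depth, mode=mode)
        for stage, p in profiles.items()
    }
    return normalize_across_stages(coverage, limits)
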