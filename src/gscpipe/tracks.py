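"""Per-bin genomic signal tracks and the normalized log10 fold-change transform.

ChIP-seq domain calling starts from read counts over a fixed genome
partition (500 bp non-overlapping bins by default).  For each ChIP/Input
pair, bins with zero reads in either sample are discarded from both, the
per-bin fold-change ChIP/Input is taken, fold-changes are normalized to
the sample's median fold-change, and the result is log10-transformed.
The normalized track is the substrate for HMM segmentation.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gscpipe")

VALUE_KINDS = ("raw_count", "fold_change", "log10_norm_fc", "coverage")


# ---------------------------------------------------------------------------
# Genome bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBins:
    """A sorted, non-overlapping tiling of a genome by fixed-width bins.

    The last bin of each chromosome may be shorter than ``bin_width``
    (truncated at the chromosome end).
    """

    chroms: np.ndarray          # per-bin chromosome name
    starts: np.ndarray          # per-bin start, bp
    ends: np.ndarray            # per-bin end, bp (half-open)
    bin_width: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms, starts and ends must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("every bin must have end > start")

    def __len__(self) -> int:
        return len(self.starts)

    def subset(self, mask: np.ndarray) -> "GenomeBins":
        return GenomeBins(self.chroms[mask], self.starts[mask],
                          self.ends[mask], self.bin_width)

    def chromosome_boundaries(self) -> np.ndarray:
        """Indices where a new chromosome starts (first index included)."""
        if len(self) == 0:
            return np.array([], dtype=int)
        change = np.flatnonzero(self.chroms[1:] != self.chroms[:-1]) + 1
        return np.concatenate([[0], change])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts,
                             "end": self.ends})


@dataclass
class BinnedTrack:
    """One numeric value per genome bin."""

    bins: GenomeBins
    values: np.ndarray
    value_kind: str = "raw_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if len(self.values) != len(self.bins):
            raise ValueError(
                f"{len(self.values)} values for {len(self.bins)} bins")
        if self.value_kind == "raw_count":
            if np.any(self.values < 0) or np.any(self.values != np.floor(self.values)):
                raise ValueError("raw_count values must be nonnegative integers")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_frame()
        df["value"] = self.values
        return df


def make_bins(chrom_sizes: Mapping[str, int] | pd.Series, bin_width: int) -> GenomeBins:
    """Tile each chromosome from 0 with ``bin_width`` bins.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    bin_width
        Bin width in bp (> 0).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if isinstance(chrom_sizes, pd.Series):
        if chrom_sizes.index.has_duplicates:
            raise ValueError("duplicate chromosome names in chrom_sizes")
        chrom_sizes = chrom_sizes.to_dict()
    names = list(chrom_sizes)
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in chrom_sizes")
    chroms, starts, ends = [], [], []
    for name in names:
        length = int(chrom_sizes[name])
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        s = np.arange(0, length, bin_width)
        e = np.minimum(s + bin_width, length)
        chroms.append(np.full(len(s), name, dtype=object))
        starts.append(s)
        ends.append(e)
    return GenomeBins(np.concatenate(chroms), np.concatenate(starts),
                      np.concatenate(ends), bin_width)


def count_intervals_in_bins(intervals: pd.DataFrame, bins: GenomeBins) -> BinnedTrack:
    """Count intervals per bin; an interval overlapping k bins is counted in all k.

    ``intervals`` needs columns chrom/start/end, 0-based half-open.
    Intervals on chromosomes absent from ``bins`` are ignored (count logged).
    """
    if len(intervals) and (np.any(intervals["start"].to_numpy() < 0)
                           or np.any(intervals["end"].to_numpy() < 0)):
        raise ValueError("negative interval coordinates")
    counts = np.zeros(len(bins), dtype=np.int64)
    # bins are contiguous from 0 per chromosome, so bin index is coordinate // width
    offsets: dict[str, tuple[int, int]] = {}
    bnd = bins.chromosome_boundaries()
    for i, b in enumerate(bnd):
        stop = bnd[i + 1] if i + 1 < len(bnd) else len(bins)
        offsets[bins.chroms[b]] = (b, stop)
    skipped = 0
    for chrom, sub in intervals.groupby("chrom", sort=False):
        if chrom not in offsets:
            skipped += len(sub)
            continue
        base, stop = offsets[chrom]
        n_bins = stop - base
        first = sub["start"].to_numpy() // bins.bin_width
        last = (sub["end"].to_numpy() - 1) // bins.bin_width
        first = np.clip(first, 0, n_bins - 1)
        last = np.clip(last, 0, n_bins - 1)
        # difference-array trick: +1 at first bin, -1 after last bin
        delta = np.zeros(n_bins + 1, dtype=np.int64)
        np.add.at(delta, first, 1)
        np.add.at(delta, last + 1, -1)
        counts[base:stop] += np.cumsum(delta[:-1])
    if skipped:
        logger.info("count_intervals_in_bins: ignored %d intervals on "
                    "chromosomes absent from the bin set", skipped)
    return BinnedTrack(bins, counts, "raw_count")


# ---------------------------------------------------------------------------
# Normalized log10 fold-change
# ---------------------------------------------------------------------------

def fold_change_track(chip: BinnedTrack, input_: BinnedTrack
                      ) -> tuple[BinnedTrack, np.ndarray]:
    """Build the log10 median-normalized ChIP/Input fold-change track.

    Bins with zero reads in either sample are discarded from both; the
    fold-change of each retained bin is divided by the median fold-change
    and log10-transformed, so the median of 10**value is exactly 1.

    Returns the track over the retained bins and a boolean mask (over the
    original bins) of the retained bins.
    """
    if len(chip.bins) != len(input_.bins) or \
            np.any(chip.bins.starts != input_.bins.starts) or \
            np.any(chip.bins.chroms != input_.bins.chroms):
        raise ValueError("ChIP and Input tracks must share identical bins")
    c = np.asarray(chip.values, dtype=float)
    i = np.asarray(input_.values, dtype=float)
    mask = (c > 0) & (i > 0)
    if not mask.any():
        raise ValueError("no usable bins: every bin has zero reads in at "
                         "least one sample")
    fc = c[mask] / i[mask]
    fc /= np.median(fc)
    track = BinnedTrack(chip.bins.subset(mask), np.log10(fc), "log10_norm_fc")
    return track, mask


def median_of_ratios_factors(fc_matrix: np.ndarray) -> np.ndarray:
    """Per-sample size factors for several samples sharing bins.

    Each column is one sample's per-bin fold-change; the factor is the
    median of a sample's ratios to the per-bin geometric mean across
    samples (the DESeq-style median-of-ratios estimator).
    """
    fc = np.asarray(fc_matrix, dtype=float)
    if fc.ndim != 2:
        raise ValueError("fc_matrix must be 2-D (bins x samples)")
    if np.any(fc <= 0):
        raise ValueError("fold-changes must be positive (discard zero bins first)")
    log_geo = np.mean(np.log(fc), axis=1, keepdims=True)
    return np.exp(np.median(np.log(fc) - log_geo, axis=0))


# ---------------------------------------------------------------------------
# Euchromatin limits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EuchromatinLimits:
    """Per-chromosome coordinate bounds delimiting the gene-rich arms.

    A position x on chromosome c is euchromatic iff ``lo <= x < hi`` for
    that chromosome's ``(lo, hi)``; ``hi=None`` means the chromosome end.
    Chromosomes absent from the table (chr4, chrY, ...) are never
    euchromatic.
    """

    name: str
    bounds: Mapping[str, tuple[int, int | None]] = field(default_factory=dict)

    def contains_bin(self, chrom: str, start: int, end: int) -> bool:
        """True iff the whole [start, end) span lies inside the limits."""
        if chrom not in self.bounds:
            return False
        lo, hi = self.bounds[chrom]
        return start >= lo and (hi is None or end <= hi)

    def bin_mask(self, bins: GenomeBins) -> np.ndarray:
        return np.fromiter(
            (self.contains_bin(c, s, e)
             for c, s, e in zip(bins.chroms, bins.starts, bins.ends)),
            dtype=bool, count=len(bins))


#: Arm limits used for fine-scale euchromatin/heterochromatin assignment
#: (a 500 bp bin is euchromatic when its start satisfies the bound).
EUCHROMATIN_FINE = EuchromatinLimits("fine", {
    "chr2L": (0, 21_400_000),
    "chr2R": (5_970_000, None),
    "chr3L": (0, 22_270_000),
    "chr3R": (4_191_000, None),
    "chrX": (0, 21_400_000),
})

#: Arm limits rounded to the 250 kb bin grid for chromosome-scale profiling.
EUCHROMATIN_COARSE_250KB = EuchromatinLimits("coarse250kb", {
    "chr2L": (0, 21_500_000),
    "chr2R": (5_500_000, 25_286_936),
    "chr3L": (0, 23_000_000),
    "chr3R": (4_250_000, 32_079_331),
    "chrX": (0, 21_500_000),
})

EUCHROMATIN_PRESETS = {p.name: p for p in (EUCHROMATIN_FINE,
                                           EUCHROMATIN_COARSE_250KB)}


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column chromosome-sizes TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_bedgraph(path, bin_width: int, value_kind: str = "raw_count") -> BinnedTrack:
    """Read a 4-column bedGraph (chrom, start, end, value) as a BinnedTrack."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    bins = GenomeBins(df["chrom"].to_numpy(dtype=object),
                      df["start"].to_numpy(dtype=np.int64),
                      df["end"].to_numpy(dtype=np.int64), bin_width)
    values = df["value"].to_numpy()
    if value_kind == "raw_count":
        values = values.astype(np.int64)
    return BinnedTrack(bins, values, value_kind)


def write_bedgraph(track: BinnedTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


def write_bed_mask(bins: GenomeBins, mask: np.ndarray, path) -> None:
    """Write the retained-bin mask as a 3-column BED of retained bins."""
    bins.subset(np.asarray(mask, dtype=bool)).to_frame().to_csv(
        path, sep="\t", header=False, index=False)
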