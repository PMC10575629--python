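"""Germline-cyst transposition cluster model and single-male screen simulator.

A transposable-element insertion is heritable: an insertion arising in one
cell of a germline cyst is copied to both daughters at every subsequent
division, so the number of gametes sharing an identical insertion encodes
*when* the insertion happened.  In a male lineage with ``c`` synchronous
cyst divisions and ``m`` meiotic divisions (2**(c+m) gametes per cyst), an
insertion immediately after cyst division ``k`` is shared by
``2**(c - k + m)`` gametes; a post-meiotic insertion is unique to one
gamete.  An insertion already present in the stem cell marks every gamete
that stem cell produces, i.e. roughly ``1/n_gscs`` of a male's progeny
when the 10-20 stem cells contribute equally.

``simulate_screen`` is a Monte-Carlo model of a single-male transposition
screen: each male's progeny (100-200) are sampled from the surviving sperm
(25-50% random survival) of cysts produced by its stem cells, insertions
are placed per stage at configurable per-cell rates, and progeny sharing
an identical insertion are grouped into clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

POST_MEIOTIC = "post_meiotic"
PRE_ADULT = "pre_adult"
GSC_STAGE = "gsc"


@dataclass(frozen=True)
class Lineage:
    """Cyst-division structure of a germline lineage.

    The illustrative male lineage has two cyst divisions and a single
    meiotic division, giving eight sperm per cyst; real spermatogenesis
    uses two meiotic divisions (set ``n_meiotic_divisions=2``).
    """

    n_cyst_divisions: int = 2
    n_meiotic_divisions: int = 1

    def __post_init__(self) -> None:
        if self.n_cyst_divisions < 0 or self.n_meiotic_divisions < 0:
            raise ValueError("division counts must be nonnegative")

    @property
    def total_gametes(self) -> int:
        return 2 ** (self.n_cyst_divisions + self.n_meiotic_divisions)


def cluster_size(lineage: Lineage, insertion_stage) -> int:
    """Number of gametes of one cyst sharing an insertion made at a stage.

    ``insertion_stage`` is the cyst-division index k (0 = in the
    cystoblast before any division, so all gametes carry it) or
    ``"post_meiotic"`` (one unique gamete).
    """
    if insertion_stage == POST_MEIOTIC:
        return 1
    k = int(insertion_stage)
    if k < 0 or k > lineage.n_cyst_divisions:
        raise ValueError(
            f"cyst division index {k} outside 0..{lineage.n_cyst_divisions}")
    return 2 ** (lineage.n_cyst_divisions - k + lineage.n_meiotic_divisions)


def lineage_cluster_table(lineage: Lineage) -> pd.DataFrame:
    """Cluster size per insertion stage, one row per stage.

    ``cells_at_stage`` times ``cluster_size`` equals the gamete total for
    every pre-meiotic stage (each of the 2**k cells present after
    division k founds one cluster-sized block of gametes).
    """
    rows = []
    for k in range(lineage.n_cyst_divisions + 1):
        rows.append({"stage": f"cyst_division_{k}", "cells_at_stage": 2 ** k,
                     "cluster_size": cluster_size(lineage, k)})
    rows.append({"stage": POST_MEIOTIC,
                 "cells_at_stage": lineage.total_gametes,
                 "cluster_size": 1})
    return pd.DataFrame(rows)


def expected_cluster_fraction(n_gscs: int) -> float:
    """Fraction of a male's progeny descending from one stem cell,
    assuming the stem cells contribute equally."""
    if n_gscs < 1:
        raise ValueError("n_gscs must be >= 1")
    return 1.0 / n_gscs


@dataclass
class ScreenConfig:
    """Parameters of the single-male transposition screen simulation.

    ``insertion_rates`` maps stage names to per-cell(-cycle) insertion
    probabilities.  Recognized stages: ``pre_adult`` (the founding germ
    cell, hence all stem cells), ``gsc`` (one stem cell, carried for the
    whole sampling period), ``cyst_<k>`` (each of the 2**k cells present
    after cyst division k, per cyst), ``post_meiotic`` (each gamete).
    ``detection_efficiency`` is the probability a transposed progeny is
    recognized at all (enhancer trapping / insertion sequencing are not
    exhaustive).
    """

    n_males: int = 15_000
    progeny_range: tuple[int, int] = (100, 200)
    gsc_range: tuple[int, int] = (10, 20)
    sperm_survival: tuple[float, float] = (0.25, 0.50)
    insertion_rates: Mapping[str, float] = field(default_factory=dict)
    lineage: Lineage = field(default_factory=Lineage)
    detection_efficiency: float = 1.0
    cysts_per_gsc: int | None = None     # None: sized from progeny demand
    seed: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.progeny_range, self.gsc_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be nonempty with lo >= 1")
        lo, hi = self.sperm_survival
        if not (0 < lo <= hi <= 1):
            raise ValueError("sperm_survival must lie in (0, 1]")
        for stage, rate in self.insertion_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"rate for {stage!r} must be in [0, 1]")
            if stage not in (PRE_ADULT, GSC_STAGE, POST_MEIOTIC) and \
                    not stage.startswith("cyst_"):
                raise ValueError(f"unknown insertion stage {stage!r}")
        per_cyst = sum(r * 2 ** int(s.split("_")[1])
                       for s, r in self.insertion_rates.items()
                       if s.startswith("cyst_"))
        if per_cyst > 1:
            warnings.warn("insertion rates give >1 expected insertion per "
                          "cyst; the model assumes rare events")


@dataclass
class ScreenResult:
    """Output of ``simulate_screen``."""

    clusters: pd.DataFrame          # male, stage, size, surviving_carriers
    males_without_events: int
    per_male_cluster_counts: pd.DataFrame   # male -> number of transposed progeny
    summary: dict

    def cluster_size_histogram(self) -> pd.Series:
        return self.clusters["size"].value_counts().sort_index()


def _place_insertions(rng: np.random.Generator, cfg: ScreenConfig,
                      n_gsc: int, cysts_per_gsc: int, gametes: int
                      ) -> list[tuple[str, int, int]]:
    """Sample insertion events as contiguous carrier index ranges.

    Sperm are indexed stem-cell-major, then cyst, then position within the
    cyst, so every insertion's carriers form one contiguous block
    [start, stop).  Returns (stage, start, stop) per event.
    """
    lineage = cfg.lineage
    n_cysts = n_gsc * cysts_per_gsc
    total = n_cysts * gametes
    events: list[tuple[str, int, int]] = []
    rates = cfg.insertion_rates
    if rates.get(PRE_ADULT, 0) > 0 and rng.random() < rates[PRE_ADULT]:
        events.append((PRE_ADULT, 0, total))
    r = rates.get(GSC_STAGE, 0)
    if r > 0:
        for g in np.flatnonzero(rng.random(n_gsc) < r):
            block = cysts_per_gsc * gametes
            events.append((GSC_STAGE, g * block, (g + 1) * block))
    for stage, rate in rates.items():
        if not stage.startswith("cyst_") or rate <= 0:
            continue
        k = int(stage.split("_")[1])
        size = cluster_size(lineage, k)      # gametes per carrier cell
        cells = 2 ** k                       # cells per cyst at this stage
        hits = np.flatnonzero(rng.random(n_cysts * cells) < rate)
        for h in hits:
            start = (h // cells) * gametes + (h % cells) * size
            events.append((stage, start, start + size))
    r = rates.get(POST_MEIOTIC, 0)
    if r > 0:
        for h in np.flatnonzero(rng.random(total) < r):
            events.append((POST_MEIOTIC, int(h), int(h) + 1))
    return events


def simulate_screen(config: ScreenConfig) -> ScreenResult:
    """Monte-Carlo simulation of the single-male transposition screen.

    Per male: stem-cell count, progeny count and sperm survival are drawn
    uniformly from their ranges; insertions are placed per stage; each
    sperm survives independently; surviving sperm are subsampled (without
    replacement) to the progeny count; progeny sharing an identical
    insertion form a cluster.  Survival uniforms are drawn before the
    survival probability is applied, so under a fixed seed lowering
    survival can only remove carriers (never add them) — the invariant is
    exact on ``surviving_carriers``, before progeny subsampling.
    """
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_males)
    lineage = config.lineage
    gametes = lineage.total_gametes
    rows = []
    per_male = np.zeros(config.n_males, dtype=int)
    males_without = 0
    for male in range(config.n_males):
        # independent stream per male: downstream draws of one male never
        # shift another male's draws
        rng = np.random.default_rng(child_seeds[male])
        n_gsc = int(rng.integers(config.gsc_range[0], config.gsc_range[1] + 1))
        n_prog = int(rng.integers(config.progeny_range[0],
                                  config.progeny_range[1] + 1))
        surv = rng.uniform(*config.sperm_survival)
        # enough cysts that survivors almost surely cover the progeny demand
        cysts_per_gsc = config.cysts_per_gsc if config.cysts_per_gsc else \
            max(1, math.ceil(1.5 * n_prog / (surv * gametes * n_gsc)) + 1)
        total = n_gsc * cysts_per_gsc * gametes
        events = _place_insertions(rng, config, n_gsc, cysts_per_gsc, gametes)
        u = rng.random(total)
        survivors = np.flatnonzero(u < surv)
        if survivors.size == 0:
            males_without += 1
            continue
        chosen = survivors if survivors.size <= n_prog else \
            rng.choice(survivors, size=n_prog, replace=False)
        chosen.sort()
        had_event = False
        for stage, start, stop in events:
            n_carriers_alive = int(np.searchsorted(survivors, stop)
                                   - np.searchsorted(survivors, start))
            size = int(np.searchsorted(chosen, stop)
                       - np.searchsorted(chosen, start))
            if config.detection_efficiency < 1 and size > 0:
                size = int(rng.binomial(size, config.detection_efficiency))
            if size > 0:
                had_event = True
                per_male[male] += size
                rows.append({"male": male, "stage": stage, "size": size,
                             "surviving_carriers": n_carriers_alive})
        if not had_event:
            males_without += 1
    clusters = pd.DataFrame(rows, columns=["male", "stage", "size",
                                           "surviving_carriers"])
    sizes = clusters["size"]
    n_clusters = len(clusters)
    summary = {
        "n_males": config.n_males,
        "n_clusters": n_clusters,
        "fraction_singletons": float((sizes == 1).mean()) if n_clusters else 0.0,
        "fraction_doublets": float((sizes == 2).mean()) if n_clusters else 0.0,
        "fraction_3plus": float((sizes >= 3).mean()) if n_clusters else 0.0,
        "mean_cluster_size": float(sizes.mean()) if n_clusters else 0.0,
    }
    per_male_df = pd.DataFrame({"male": np.arange(config.n_males),
                                "transposed_progeny": per_male})
    return ScreenResult(clusters, males_without, per_male_df, summary)
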