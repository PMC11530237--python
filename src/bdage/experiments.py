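"""Scripted computational experiments and their summary statistics.

Three experiment families are provided, each a thin driver over the
stochastic engine:

* **Competition cell** — replicated mixed simulations of a Lansing and a
  non-Lansing sub-population with Malthusian-matched founder traits
  ((1.5, 1.3) Lansing vs (1.5, 0.83) non-Lansing at ``i_b = i_d = 1``),
  global logistic competition and an event budget; summarized by the
  collapse-count ratio, the pooled progeny ratio and the mean final Lansing
  share.
* **Lansing-magnitude sweep** — the same mixed setup across a grid of
  Lansing magnitudes in [0, 1], reporting the final-window gap distribution
  per lineage.
* **Uniform start** — both lineages founded with genes drawn uniformly on a
  wide interval (classically [-10, 10]); extreme gaps are counter-selected
  early and each lineage branches toward its own theoretical gap limit.

Per-time-point decile curves (gap, lifespan, or per-individual Malthusian
parameter) can be extracted from any simulation log.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    LANSING,
    NON_LANSING,
    Individual,
    SimulationResult,
    founders,
    simulate,
)
from .fitness import malthusian
from .model import Intensities, LansingRule, ModelParams, MutationKernel, Trait

__all__ = [
    "CompetitionConfig",
    "CompetitionSummary",
    "DecileCurves",
    "run_competition_cell",
    "run_magnitude_sweep",
    "run_uniform_start",
    "summarize_deciles",
]


@dataclass(frozen=True)
class CompetitionConfig:
    """Configuration of one replicated Lansing vs non-Lansing competition cell.

    Defaults follow the canonical matched-fitness setup: 500 age-0 founders
    per lineage with traits (1.5, 1.3) / (1.5, 0.83), ``i_b = i_d = 1``,
    mutation width 0.05, a 2e5 birth-or-death event budget per replicate.
    """

    p: float = 0.1
    c: float = 9e-4
    replicates: int = 100
    n_founders: int = 500
    lansing_trait: Trait = Trait(1.5, 1.3)
    non_lansing_trait: Trait = Trait(1.5, 0.83)
    intensities: Intensities = field(default_factory=lambda: Intensities(1.0, 1.0))
    sigma: float = 0.05
    magnitude: float = 1.0
    event_budget: int = 200_000
    seed_base: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")
        if self.n_founders < 1:
            raise ValueError("founders per lineage must be positive")
        if self.event_budget <= 0:
            raise ValueError("event budget must be positive")

    def model_params(self, magnitude: Optional[float] = None) -> ModelParams:
        mag = self.magnitude if magnitude is None else magnitude
        return ModelParams(
            intensities=self.intensities,
            c=self.c,
            kernel=MutationKernel(self.p, self.sigma),
            lansing=LansingRule(True, mag),
        )

    def founder_population(self) -> list[Individual]:
        return founders(self.n_founders, self.lansing_trait, LANSING) + founders(
            self.n_founders, self.non_lansing_trait, NON_LANSING, id_start=self.n_founders
        )

    def fitness_mismatch(self) -> float:
        """|lambda_Lansing - lambda_non-Lansing| of the founder traits."""
        lam_l = malthusian(self.lansing_trait, self.intensities, LANSING).lambda_
        lam_n = malthusian(self.non_lansing_trait, self.intensities, NON_LANSING).lambda_
        return abs(lam_l - lam_n)


@dataclass(frozen=True)
class CompetitionSummary:
    """Replicate-level records and the three competition indexes.

    * ``collapse_ratio`` — Lansing collapses / non-Lansing collapses
      (``None`` when no population of either type collapsed, the printed
      "-"; ``inf`` when only non-Lansing never collapsed).
    * ``progeny_ratio`` — total Lansing births / total non-Lansing births,
      pooled over replicates.
    * ``lansing_share`` — mean final Lansing fraction over replicates with
      any survivor (``None`` if every replicate went fully extinct).
    """

    per_replicate: pd.DataFrame
    collapse_ratio: Optional[float]
    progeny_ratio: float
    lansing_share: Optional[float]
    lansing_collapses: int
    non_lansing_collapses: int

    def to_csv(self, path) -> None:
        self.per_replicate.to_csv(path, index=False)


def _lineage_counts(result: SimulationResult) -> dict[str, int]:
    counts = {LANSING: 0, NON_LANSING: 0}
    for ind in result.initial:
        counts[ind.lineage] += 1
    for kind, lin in zip(result.kinds, result.lineages):
        counts[lin] += 1 if kind == "birth" else -1
    return counts


def _replicate_record(rep: int, result: SimulationResult) -> dict:
    births = {LANSING: 0, NON_LANSING: 0}
    alive = {LANSING: 0, NON_LANSING: 0}
    for ind in result.initial:
        alive[ind.lineage] += 1
    collapse_time = {LANSING: math.nan, NON_LANSING: math.nan}
    for t, kind, lin in zip(result.times, result.kinds, result.lineages):
        if kind == "birth":
            births[lin] += 1
            alive[lin] += 1
        else:
            alive[lin] -= 1
            if alive[lin] == 0:
                collapse_time[lin] = t
    # a lineage cannot recover once extinct (no migration), so the first
    # zero crossing is the collapse time
    return {
        "replicate": rep,
        "births_lansing": births[LANSING],
        "births_non_lansing": births[NON_LANSING],
        "final_lansing": alive[LANSING],
        "final_non_lansing": alive[NON_LANSING],
        "lansing_collapsed": alive[LANSING] == 0,
        "non_lansing_collapsed": alive[NON_LANSING] == 0,
        "collapse_time_lansing": collapse_time[LANSING],
        "collapse_time_non_lansing": collapse_time[NON_LANSING],
        "final_time": result.final_time,
        "n_events": result.n_events,
    }


def run_competition_cell(cfg: CompetitionConfig) -> CompetitionSummary:
    """Replicated mixed competition; replicate ``r`` uses seed ``seed_base + r``."""
    for trait in (cfg.lansing_trait, cfg.non_lansing_trait):
        if malthusian(trait, cfg.intensities, NON_LANSING).lambda_ == -math.inf:
            raise ValueError(f"founder trait {trait} is sterile")
    params = cfg.model_params()
    records = []
    for rep in range(cfg.replicates):
        result = simulate(
            cfg.founder_population(),
            params,
            max_events=cfg.event_budget,
            seed=cfg.seed_base + rep,
        )
        records.append(_replicate_record(rep, result))
    per_rep = pd.DataFrame.from_records(records)

    n_col_l = int(per_rep["lansing_collapsed"].sum())
    n_col_n = int(per_rep["non_lansing_collapsed"].sum())
    if n_col_n == 0:
        collapse_ratio = None if n_col_l == 0 else math.inf
    else:
        collapse_ratio = n_col_l / n_col_n
    births_n = int(per_rep["births_non_lansing"].sum())
    progeny_ratio = (
        math.inf if births_n == 0 else float(per_rep["births_lansing"].sum()) / births_n
    )
    final_total = per_rep["final_lansing"] + per_rep["final_non_lansing"]
    surv = per_rep[final_total > 0]
    lansing_share = (
        None
        if surv.empty
        else float(
            (surv["final_lansing"] / (surv["final_lansing"] + surv["final_non_lansing"])).mean()
        )
    )
    return CompetitionSummary(
        per_replicate=per_rep,
        collapse_ratio=collapse_ratio,
        progeny_ratio=progeny_ratio,
        lansing_share=lansing_share,
        lansing_collapses=n_col_l,
        non_lansing_collapses=n_col_n,
    )


def _final_window_gaps(
    result: SimulationResult, window: float
) -> pd.DataFrame:
    """Gap ``x_b - x_d`` of individuals born in the terminal time window."""
    t1 = result.final_time
    t0 = t1 - window
    rows = []
    for t, kind, xb, xd, lin in zip(
        result.times, result.kinds, result.x_bs, result.x_ds, result.lineages
    ):
        if kind == "birth" and t >= t0:
            rows.append((lin, xb, xd, xb - xd))
    return pd.DataFrame(rows, columns=["lineage", "x_b", "x_d", "gap"])


def run_magnitude_sweep(
    magnitudes: Sequence[float],
    cfg: CompetitionConfig,
    window: float = 10.0,
) -> dict[float, pd.DataFrame]:
    """Final-window gap distributions per lineage across Lansing magnitudes.

    For each magnitude, ``cfg.replicates`` mixed simulations are pooled; the
    returned frames carry one row per terminal-window birth (lineage, trait,
    gap).
    """
    if any(not 0.0 <= m <= 1.0 for m in magnitudes):
        raise ValueError("magnitudes must lie in [0, 1]")
    out: dict[float, pd.DataFrame] = {}
    for mi, mag in enumerate(magnitudes):
        params = cfg.model_params(magnitude=mag)
        frames = []
        for rep in range(cfg.replicates):
            result = simulate(
                cfg.founder_population(),
                params,
                max_events=cfg.event_budget,
                seed=cfg.seed_base + 1000 * mi + rep,
            )
            frames.append(_final_window_gaps(result, window))
        out[mag] = pd.concat(frames, ignore_index=True)
    return out


@dataclass(frozen=True)
class UniformStartResult:
    """Outcome of a wide uniform-start run."""

    result: SimulationResult
    final_window: pd.DataFrame  # births in the terminal window (lineage, trait, gap)

    def positive_gap_fraction(self) -> float:
        """Fraction of all individuals ever born with ``x_b - x_d > 0``."""
        df = self.result.individuals()
        return float((df["x_b"] - df["x_d"] > 0).mean())

    def gap_mode(self, lineage: str, bin_width: float = 0.2) -> float:
        """Histogram mode of the final-window gap for one lineage."""
        gaps = self.final_window.loc[self.final_window["lineage"] == lineage, "gap"]
        if gaps.empty:
            raise ValueError(f"no terminal-window births for lineage {lineage}")
        lo, hi = gaps.min(), gaps.max()
        nbins = max(1, int(math.ceil((hi - lo) / bin_width)))
        counts, edges = np.histogram(gaps, bins=nbins)
        k = int(np.argmax(counts))
        return float(0.5 * (edges[k] + edges[k + 1]))


def run_uniform_start(
    n_per_lineage: int,
    params: ModelParams,
    trait_range: tuple[float, float] = (-10.0, 10.0),
    horizon: float = 1000.0,
    window: float = 10.0,
    seed: int = 0,
) -> UniformStartResult:
    """Mixed run founded by traits with genes uniform on ``trait_range``.

    Both genes of every founder are drawn independently; both lineages get
    ``n_per_lineage`` age-0 founders.  Returns the full log plus the gap
    distribution of individuals born in the terminal ``window``.
    """
    lo, hi = trait_range
    if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
        raise ValueError("trait_range must be a finite nonempty interval")
    rng = random.Random(seed)
    init = []
    for k in range(n_per_lineage):
        init.append(
            Individual(k, Trait(rng.uniform(lo, hi), rng.uniform(lo, hi)), 0.0, LANSING)
        )
    for k in range(n_per_lineage):
        init.append(
            Individual(
                n_per_lineage + k,
                Trait(rng.uniform(lo, hi), rng.uniform(lo, hi)),
                0.0,
                NON_LANSING,
            )
        )
    result = simulate(init, params, time_horizon=horizon, rng=rng)
    return UniformStartResult(result, _final_window_gaps(result, window))


@dataclass(frozen=True)
class DecileCurves:
    """Deciles 1/5/9 of a per-individual statistic over time, per lineage.

    ``curves[lineage]`` is a (len(times), 3) array with columns d1, d5, d9;
    NaN rows mark time points where the statistic is undefined (no living
    individual of that lineage, or no completed lifespans yet).
    """

    times: np.ndarray
    statistic: str
    curves: dict[str, np.ndarray]


def summarize_deciles(
    result: SimulationResult,
    statistic: str,
    times: Sequence[float],
) -> DecileCurves:
    """Decile curves of ``gap``, ``lifespan`` or ``malthusian`` over time.

    ``gap`` and ``malthusian`` are evaluated over individuals alive at each
    time point (the Malthusian parameter is each individual's own-trait,
    own-lineage growth rate); ``lifespan`` over individuals already dead by
    then (realized death time minus birth time).
    """
    if statistic not in ("gap", "lifespan", "malthusian"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if result.n_events == 0 and not result.initial:
        raise ValueError("empty simulation log")
    df = result.individuals()
    t_grid = np.asarray(list(times), dtype=float)

    if statistic == "gap":
        values = (df["x_b"] - df["x_d"]).to_numpy()
    elif statistic == "lifespan":
        values = (df["death_time"] - df["birth_time"]).to_numpy()
    else:
        ints = result.params.intensities
        cache: dict[tuple[float, float, str], float] = {}
        vals = []
        for xb, xd, lin in zip(df["x_b"], df["x_d"], df["lineage"]):
            key = (xb, xd, lin)
            if key not in cache:
                cache[key] = malthusian(Trait(xb, xd), ints, lin).lambda_
            vals.append(cache[key])
        values = np.asarray(vals)

    birth = df["birth_time"].to_numpy()
    death = df["death_time"].to_numpy()
    lineages = df["lineage"].to_numpy()
    curves: dict[str, np.ndarray] = {}
    for lin in (LANSING, NON_LANSING):
        sel = lineages == lin
        out = np.full((t_grid.size, 3), math.nan)
        for i, t in enumerate(t_grid):
            if statistic == "lifespan":
                mask = sel & (death <= t) & ~np.isnan(death)
            else:
                mask = sel & (birth <= t) & (np.isnan(death) | (death > t))
            v = values[mask]
            v = v[np.isfinite(v)]
            if v.size:
                out[i] = np.quantile(v, [0.1, 0.5, 0.9])
        curves[lin] = out
    return DecileCurves(t_grid, statistic, curves)
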