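"""Exact stochastic simulation of the birth-death-mutation-competition process.

The population is age-structured with piecewise-constant individual rates, so
the next event is generated by thinning (acceptance-rejection): every living
individual is dominated by the constant bound ``i_b + i_d + c (N - 1)``,
which is refreshed whenever the population size changes.  A candidate event
time is drawn from the total bound rate, a candidate individual uniformly,
and the candidate is accepted as a birth or a death with probability equal
to the true age-dependent rate over the bound — this reproduces the exact
law of the process without discretization bias at the hazard steps ``x_b``
and ``x_d``.

Runs are driven by a single explicit integer seed (``random.Random``); two
runs with the same seed produce bit-identical event logs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import ModelParams, Trait, apply_lansing, mutate

__all__ = [
    "LANSING",
    "NON_LANSING",
    "Individual",
    "EventRecord",
    "SimulationResult",
    "founders",
    "simulate",
]

LANSING = "lansing"
NON_LANSING = "non_lansing"
_LINEAGES = (NON_LANSING, LANSING)  # integer codes 0 / 1


@dataclass(frozen=True)
class Individual:
    """A living agent: identity, heritable trait, birth time and lineage."""

    id: int
    trait: Trait
    birth_time: float = 0.0
    lineage: str = NON_LANSING
    parent_id: Optional[int] = None


@dataclass(frozen=True)
class EventRecord:
    time: float
    kind: str  # "birth" | "death"
    individual_id: int
    parent_id: Optional[int]
    trait: Trait
    lineage: str


def founders(
    n: int,
    trait: Trait,
    lineage: str = NON_LANSING,
    birth_time: float = 0.0,
    id_start: int = 0,
) -> list[Individual]:
    """Convenience constructor: ``n`` age-0 clones of one trait and lineage."""
    return [
        Individual(id_start + k, trait, birth_time, lineage) for k in range(n)
    ]


@dataclass
class SimulationResult:
    """Complete event log of one run plus enough context to replay it."""

    initial: list[Individual]
    params: ModelParams
    seed: Optional[int]
    termination: str  # "event_budget" | "time_horizon" | "extinction"
    final_time: float
    # columnar event log (parallel lists, chronological order)
    times: list[float] = field(repr=False, default_factory=list)
    kinds: list[str] = field(repr=False, default_factory=list)
    ids: list[int] = field(repr=False, default_factory=list)
    parent_ids: list[Optional[int]] = field(repr=False, default_factory=list)
    x_bs: list[float] = field(repr=False, default_factory=list)
    x_ds: list[float] = field(repr=False, default_factory=list)
    lineages: list[str] = field(repr=False, default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def events(self) -> pd.DataFrame:
        """Event log as a DataFrame (time, kind, id, parent_id, x_b, x_d, lineage)."""
        return pd.DataFrame(
            {
                "time": self.times,
                "kind": self.kinds,
                "id": self.ids,
                "parent_id": self.parent_ids,
                "x_b": self.x_bs,
                "x_d": self.x_ds,
                "lineage": self.lineages,
            }
        )

    def individuals(self) -> pd.DataFrame:
        """One row per individual ever alive: birth, death (NaN if censored), trait.

        Derived purely from the initial listing and the event log.
        """
        rows = {
            ind.id: [ind.id, ind.parent_id, ind.birth_time, math.nan,
                     ind.trait.x_b, ind.trait.x_d, ind.lineage]
            for ind in self.initial
        }
        for t, kind, iid, pid, xb, xd, lin in zip(
            self.times, self.kinds, self.ids, self.parent_ids,
            self.x_bs, self.x_ds, self.lineages,
        ):
            if kind == "birth":
                rows[iid] = [iid, pid, t, math.nan, xb, xd, lin]
            else:
                rows[iid][3] = t
        df = pd.DataFrame(
            list(rows.values()),
            columns=["id", "parent_id", "birth_time", "death_time", "x_b", "x_d", "lineage"],
        )
        return df

    def snapshot(self, t: float) -> pd.DataFrame:
        """Individuals alive at time ``t``, reconstructed from the event log.

        Past an extinction the listing is empty; past any other termination
        time the state is unknown and the query is an error.
        """
        if t > self.final_time and self.termination != "extinction":
            raise ValueError(f"t={t} beyond termination time {self.final_time}")
        df = self.individuals()
        alive = (df["birth_time"] <= t) & (df["death_time"].isna() | (df["death_time"] > t))
        return df.loc[alive, ["id", "x_b", "x_d", "birth_time", "lineage"]].reset_index(
            drop=True
        )

    def population_size(self, t: float) -> int:
        born = sum(1 for tt, k in zip(self.times, self.kinds) if k == "birth" and tt <= t)
        died = sum(1 for tt, k in zip(self.times, self.kinds) if k == "death" and tt <= t)
        return len(self.initial) + born - died

    def write_events_csv(self, path) -> None:
        write_csv(self.events(), path)


def write_csv(df: pd.DataFrame, path) -> None:
    """CSV with shortest round-trip float representation (exact replay)."""
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def simulate(
    initial: Iterable[Individual],
    params: ModelParams,
    *,
    max_events: Optional[int] = None,
    time_horizon: Optional[float] = None,
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
) -> SimulationResult:
    """Run the individual-based process until a stop criterion fires.

    ``max_events`` counts accepted births plus deaths; ``time_horizon`` stops
    the clock at a fixed time (events proposed beyond it are discarded).  At
    least one criterion must be given.  Randomness comes from ``rng`` or a
    fresh ``random.Random(seed)``; one of the two must be supplied so every
    run is explicitly seeded.
    """
    if max_events is None and time_horizon is None:
        raise ValueError("provide max_events and/or time_horizon")
    if max_events is not None and max_events <= 0:
        raise ValueError("max_events must be positive")
    if time_horizon is not None and time_horizon <= 0:
        raise ValueError("time_horizon must be positive")
    if rng is None:
        if seed is None:
            raise ValueError("simulations must be explicitly seeded (seed= or rng=)")
        rng = random.Random(seed)

    ints = params.intensities
    i_b, i_d, c = ints.i_b, ints.i_d, params.c
    kernel, lansing_rule = params.kernel, params.lansing
    for v in (i_b, i_d, c):
        if not math.isfinite(v):
            raise ValueError("rates must be finite")

    init_list = list(initial)
    # live-population state, columnar for speed (swap-remove on death)
    ids: list[int] = []
    bts: list[float] = []
    xbs: list[float] = []
    xds: list[float] = []  # hazard onset, pre-clamped at 0
    xds_raw: list[float] = []
    lins: list[int] = []
    for ind in init_list:
        ids.append(ind.id)
        bts.append(ind.birth_time)
        xbs.append(ind.trait.x_b)
        xds_raw.append(ind.trait.x_d)
        xds.append(max(ind.trait.x_d, 0.0))
        lins.append(_LINEAGES.index(ind.lineage))

    res = SimulationResult(
        initial=init_list,
        params=params,
        seed=seed,
        termination="extinction",
        final_time=0.0,
    )
    ev_t, ev_k, ev_i, ev_p = res.times, res.kinds, res.ids, res.parent_ids
    ev_xb, ev_xd, ev_l = res.x_bs, res.x_ds, res.lineages

    n = len(ids)
    if n == 0:
        res.termination = "extinction"
        return res

    t = min(bts) if bts else 0.0
    t = max(t, 0.0)
    next_id = max(ids) + 1
    n_events = 0
    uniform = rng.random
    expovariate = rng.expovariate

    while True:
        if max_events is not None and n_events >= max_events:
            res.termination = "event_budget"
            break
        if n == 0:
            res.termination = "extinction"
            break
        bound = i_b + i_d + c * (n - 1)
        total = bound * n
        if total <= 0:
            # no individual can ever do anything again
            res.termination = "time_horizon" if time_horizon is not None else "event_budget"
            t = time_horizon if time_horizon is not None else t
            break
        t = t + expovariate(total)
        if time_horizon is not None and t > time_horizon:
            t = time_horizon
            res.termination = "time_horizon"
            break
        k = int(uniform() * n)
        a = t - bts[k]
        rb = i_b if a < xbs[k] else 0.0
        rd = (i_d if a >= xds[k] else 0.0) + c * (n - 1)
        u = uniform() * bound
        if u < rb:
            # accepted birth
            parent_trait = Trait(xbs[k], xds_raw[k])
            child = mutate(parent_trait, kernel, rng)
            if lins[k] == 1:
                child = apply_lansing(child, parent_trait, a, lansing_rule)
            ids.append(next_id)
            bts.append(t)
            xbs.append(child.x_b)
            xds_raw.append(child.x_d)
            xds.append(max(child.x_d, 0.0))
            lins.append(lins[k])
            ev_t.append(t)
            ev_k.append("birth")
            ev_i.append(next_id)
            ev_p.append(ids[k])
            ev_xb.append(child.x_b)
            ev_xd.append(child.x_d)
            ev_l.append(_LINEAGES[lins[k]])
            next_id += 1
            n += 1
            n_events += 1
        elif u < rb + rd:
            # accepted death: log, then swap-remove index k
            ev_t.append(t)
            ev_k.append("death")
            ev_i.append(ids[k])
            ev_p.append(None)
            ev_xb.append(xbs[k])
            ev_xd.append(xds_raw[k])
            ev_l.append(_LINEAGES[lins[k]])
            last = n - 1
            if k != last:
                ids[k] = ids[last]
                bts[k] = bts[last]
                xbs[k] = xbs[last]
                xds[k] = xds[last]
                xds_raw[k] = xds_raw[last]
                lins[k] = lins[last]
            del ids[last], bts[last], xbs[last], xds[last], xds_raw[last], lins[last]
            n -= 1
            n_events += 1
        # else: thinned proposal, clock still advances

    res.final_time = t
    return res
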