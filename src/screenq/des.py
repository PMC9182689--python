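"""Discrete-event simulation oracle for infinite-server networks.

Because every queue has infinitely many servers, agents never interact:
each agent's path through the network (queue visit sequence and
per-visit durations) can be drawn independently and the network state
is the superposition of those paths.  The simulator therefore
propagates whole *waves* of agents with vectorized draws instead of
maintaining a global event heap — exact for this network class, and
fast enough to estimate stationary laws with tens of thousands of
decorrelated occupancy samples on one CPU.

All draws come from a single PCG64 stream seeded by the caller and are
made in a fixed order (wave by wave, queue index order within a wave),
so identical seed and configuration give bit-identical event logs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import QueueNetwork, require_valid

__all__ = [
    "SimulationResult",
    "EmpiricalStationary",
    "simulate_network",
    "queue_lengths_at",
    "empirical_stationary",
]

_MAX_WAVES = 100_000


@dataclass(frozen=True)
class SimulationResult:
    """Flat event log of one simulation run.

    One row per queue visit: ``agent_id``, ``queue`` (0-based),
    ``entry`` and ``exit`` times in months.  Transitions are
    instantaneous, so an agent's network sojourn is its last exit minus
    its first entry.
    """

    agent_id: np.ndarray
    queue: np.ndarray
    entry: np.ndarray
    exit: np.ndarray
    n_agents: int
    horizon: float
    seed: int
    network: QueueNetwork

    @property
    def sojourns(self) -> np.ndarray:
        """Per-agent total time in the network, in months."""
        first = np.full(self.n_agents, np.inf)
        last = np.zeros(self.n_agents)
        np.minimum.at(first, self.agent_id, self.entry)
        np.maximum.at(last, self.agent_id, self.exit)
        return last - first

    @property
    def arrival_times(self) -> np.ndarray:
        first = np.full(self.n_agents, np.inf)
        np.minimum.at(first, self.agent_id, self.entry)
        return first

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "agent_id": self.agent_id,
                "queue": self.queue,
                "entry_time": self.entry,
                "exit_time": self.exit,
            }
        )


@dataclass(frozen=True)
class EmpiricalStationary:
    """Empirical occupancy distribution per queue.

    ``pmfs[j][k]`` estimates ``P(N_j* = k)``; each pmf sums to one.
    ``counts`` holds the raw histogram (``counts[j].sum() ==
    n_samples``) for tests that need sample sizes.
    """

    pmfs: tuple
    counts: tuple
    n_samples: int


def _route(rng: np.random.Generator, row: np.ndarray, n: int) -> np.ndarray:
    """Vectorized routing draw; destination J means network exit."""
    J = len(row)
    cum = np.cumsum(np.append(row, max(0.0, 1.0 - row.sum())))
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right").clip(0, J)


def simulate_network(
    net: QueueNetwork, horizon: float, seed: int, max_waves: int = _MAX_WAVES
) -> SimulationResult:
    """Simulate the network over ``[0, horizon]`` months.

    Exogenous arrivals are homogeneous Poisson at the network's rates;
    every arriving agent's path is followed to its exit even past the
    horizon, so occupancy sampled at any epoch in ``[0, horizon]`` is
    unbiased (no truncation at the boundary).
    """
    require_valid(net)
    if horizon <= 0:
        raise ValueError("horizon must be > 0 months")
    max_mean = float(net.service_means.max())
    if horizon < 5.0 * max_mean:
        warnings.warn(
            f"horizon {horizon:g} mo is shorter than the default burn-in "
            f"({5 * max_mean:g} mo); stationary estimates will be biased",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    J = net.n_queues
    R = net.routing.entries

    # exogenous arrivals, queue index order
    arr_queues, arr_times = [], []
    for j in range(J):
        rate = net.exogenous_rates[j]
        if rate > 0:
            n_j = rng.poisson(rate * horizon)
            t = np.sort(rng.uniform(0.0, horizon, n_j))
            arr_queues.append(np.full(n_j, j, dtype=np.int32))
            arr_times.append(t)
    if arr_queues:
        cur_queue = np.concatenate(arr_queues)
        cur_time = np.concatenate(arr_times)
    else:
        cur_queue = np.empty(0, dtype=np.int32)
        cur_time = np.empty(0)
    n_agents = len(cur_queue)
    cur_agent = np.arange(n_agents, dtype=np.int64)

    log_agent, log_queue, log_entry, log_exit = [], [], [], []
    for _ in range(max_waves):
        if len(cur_queue) == 0:
            break
        next_agent, next_queue, next_time = [], [], []
        for j in range(J):
            mask = cur_queue == j
            n = int(mask.sum())
            if n == 0:
                continue
            entry = cur_time[mask]
            service = net.services[j].sample(rng, n)
            exit_t = entry + service
            log_agent.append(cur_agent[mask])
            log_queue.append(np.full(n, j, dtype=np.int32))
            log_entry.append(entry)
            log_exit.append(exit_t)
            dest = _route(rng, R[j], n)
            stay = dest < J
            if stay.any():
                next_agent.append(cur_agent[mask][stay])
                next_queue.append(dest[stay].astype(np.int32))
                next_time.append(exit_t[stay])
        if next_agent:
            cur_agent = np.concatenate(next_agent)
            cur_queue = np.concatenate(next_queue)
            cur_time = np.concatenate(next_time)
        else:
            cur_agent = np.empty(0, dtype=np.int64)
            cur_queue = np.empty(0, dtype=np.int32)
            cur_time = np.empty(0)
    else:
        raise RuntimeError("routing did not terminate within the wave cap")

    cat = lambda parts, dtype: (
        np.concatenate(parts) if parts else np.empty(0, dtype=dtype)
    )
    return SimulationResult(
        agent_id=cat(log_agent, np.int64),
        queue=cat(log_queue, np.int32),
        entry=cat(log_entry, float),
        exit=cat(log_exit, float),
        n_agents=n_agents,
        horizon=float(horizon),
        seed=int(seed),
        network=net,
    )


def queue_lengths_at(sim: SimulationResult, epochs: np.ndarray) -> np.ndarray:
    """Occupancy matrix (len(epochs) x J): agents present per queue.

    An agent occupies a queue on ``[entry, exit)``; counts come from
    two sorted searches per queue, so sampling is cheap even for
    multi-million-row logs.
    """
    epochs = np.asarray(epochs, dtype=float)
    J = sim.network.n_queues
    out = np.empty((len(epochs), J), dtype=np.int64)
    for j in range(J):
        mask = sim.queue == j
        entries = np.sort(sim.entry[mask])
        exits = np.sort(sim.exit[mask])
        out[:, j] = np.searchsorted(entries, epochs, side="right") - np.searchsorted(
            exits, epochs, side="right"
        )
    return out


def empirical_stationary(
    sim: SimulationResult,
    burn_in: float | None = None,
    spacing: float | None = None,
) -> EmpiricalStationary:
    """Empirical stationary pmf per queue from spaced occupancy samples.

    Defaults: burn-in of five times the largest mean service time,
    sample spacing of one largest mean service time — enough to
    decorrelate successive occupancy samples without wasting horizon.
    """
    max_mean = float(sim.network.service_means.max())
    if burn_in is None:
        burn_in = 5.0 * max_mean
    if spacing is None:
        spacing = max_mean
    if sim.horizon - burn_in < 10.0 * spacing:
        raise ValueError(
            "too few samples: horizon - burn_in must cover >= 10 spacings"
        )
    epochs = np.arange(burn_in, sim.horizon, spacing)
    lengths = queue_lengths_at(sim, epochs)
    counts, pmfs = [], []
    for j in range(lengths.shape[1]):
        hist = np.bincount(lengths[:, j])
        counts.append(hist)
        pmfs.append(hist / hist.sum())
    return EmpiricalStationary(
        pmfs=tuple(pmfs), counts=tuple(counts), n_samples=len(epochs)
    )
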