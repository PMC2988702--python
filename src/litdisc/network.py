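"""Connectivity significance of a gene set in an interaction network.

If a target list is genuinely coherent (its members act in shared pathways),
its members should interact with each other more than a random gene set of
the same size would.  Four connectivity statistics summarise a target set:
how many targets have any interaction at all, how many interact with another
target, the edge count of the target-induced subgraph, and its maximum
degree.  The null distribution is obtained by drawing equal-size gene sets
uniformly from a gene universe (ids absent from the network count as
isolated) and recomputing the statistics; the observed set is compared to
the null by a Z-test, a one-sample t-test (the null values form the sample,
the observation is the reference, so t is negative when the observed value
exceeds the null mean), and an add-one empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .stats import StatsDomainError, TestResult, one_sample_t, z_test

logger = logging.getLogger(__name__)

STAT_NAMES = ("n_any_interaction", "n_interacting_within",
              "n_edges_within", "max_degree_within")


@dataclass
class InteractionNetwork:
    """Undirected interaction graph (no self-loops, no duplicate edges)."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dropped = 0
        for u, v in edges:
            if u == v:
                dropped += 1
                continue
            g.add_edge(u, v)
        if dropped:
            logger.info("dropped %d self-loop(s)", dropped)
        return cls(graph=g)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionNetwork) and \
            self.nodes == other.nodes and self.edges == other.edges


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a 2-column TSV edge list; self-loops dropped, duplicates collapsed."""
    path = Path(path)
    edges = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            edges.append((fields[0], fields[1]))
    return InteractionNetwork.from_edges(edges)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\n")


@dataclass(frozen=True)
class NetworkStatsVector:
    """The four connectivity statistics of a target set in a network."""

    n_any_interaction: int
    n_interacting_within: int
    n_edges_within: int
    max_degree_within: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in STAT_NAMES], dtype=float)


def target_network_stats(network: InteractionNetwork, targets: set) -> NetworkStatsVector:
    """Connectivity statistics of ``targets`` (ids absent from the network are isolated)."""
    adj = network.graph.adj
    present = [t for t in targets if t in adj]
    target_set = set(targets)
    n_any = sum(1 for t in present if len(adj[t]) > 0)
    within_degrees = [sum(1 for nb in adj[t] if nb in target_set) for t in present]
    n_within = sum(1 for d in within_degrees if d > 0)
    edges_within = sum(within_degrees) // 2
    max_deg = max(within_degrees, default=0)
    return NetworkStatsVector(n_any, n_within, edges_within, max_deg)


def sample_null_distribution(
    network: InteractionNetwork,
    universe: set,
    set_size: int,
    n_iterations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Null connectivity statistics of random equal-size gene sets.

    Each iteration draws ``set_size`` ids uniformly without replacement from
    ``universe`` (which may include ids absent from the network — these count
    as isolated genes) and records the four statistics.
    """
    universe_list = sorted(universe)
    if set_size > len(universe_list):
        raise StatsDomainError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_iterations, 4))
    for i in range(n_iterations):
        draw = rng.choice(len(universe_list), size=set_size, replace=False)
        stats = target_network_stats(network, {universe_list[j] for j in draw})
        rows[i] = stats.as_array()
    return pd.DataFrame(rows, columns=list(STAT_NAMES))


@dataclass
class NullComparison:
    """Observed statistics against the random-set null, per statistic."""

    observed: NetworkStatsVector
    null_mean: pd.Series
    null_sd: pd.Series
    z: pd.Series
    p_z: pd.Series
    log10_p_z: pd.Series
    t: pd.Series
    p_t: pd.Series
    log10_p_t: pd.Series
    empirical_p: pd.Series
    n_iterations: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Report table: rows = quantity, columns = the four statistics."""
        obs = pd.Series(self.observed.as_array(), index=list(STAT_NAMES))
        return pd.DataFrame(
            {
                "observed": obs,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "p_z": self.p_z,
                "log10_p_z": self.log10_p_z,
                "t": self.t,
                "p_t": self.p_t,
                "log10_p_t": self.log10_p_t,
                "empirical_p": self.empirical_p,
            }
        ).T


def compare_to_null(
    observed: NetworkStatsVector,
    samples: pd.DataFrame,
    seed: int | None = None,
) -> NullComparison:
    """Z, one-sample t and empirical p of the observed statistics vs the null.

    The t-test treats the null draws as the sample and the observed value as
    the reference mean, so t < 0 whenever the observation exceeds the null
    mean; the empirical p uses the add-one estimator
    (1 + #{null >= observed}) / (n + 1).
    """
    n = len(samples)
    if n < 2:
        raise StatsDomainError("need at least 2 null samples per statistic")
    mean = samples.mean()
    sd = samples.std(ddof=1)
    obs = pd.Series(observed.as_array(), index=list(STAT_NAMES))
    z, pz, lpz, t, pt, lpt, emp = ({} for _ in range(7))
    for s in STAT_NAMES:
        if sd[s] > 0:
            zr: TestResult = z_test(obs[s], mean[s], sd[s])
            tr: TestResult = one_sample_t(mean[s], sd[s], n, obs[s])
            z[s], pz[s], lpz[s] = zr.statistic, zr.p_value, zr.log10_p
            t[s], pt[s], lpt[s] = tr.statistic, tr.p_value, tr.log10_p
        else:
            degenerate_equal = obs[s] == mean[s]
            z[s] = 0.0 if degenerate_equal else np.inf
            pz[s] = 1.0 if degenerate_equal else 0.0
            lpz[s] = 0.0 if degenerate_equal else -np.inf
            t[s], pt[s], lpt[s] = (0.0, 1.0, 0.0) if degenerate_equal else (-np.inf, 0.0, -np.inf)
        emp[s] = (1 + int((samples[s] >= obs[s]).sum())) / (n + 1)
    return NullComparison(
        observed=observed,
        null_mean=mean, null_sd=sd,
        z=pd.Series(z), p_z=pd.Series(pz), log10_p_z=pd.Series(lpz),
        t=pd.Series(t), p_t=pd.Series(pt), log10_p_t=pd.Series(lpt),
        empirical_p=pd.Series(emp),
        n_iterations=n, seed=seed,
    )


def null_histogram_table(samples: pd.DataFrame, observed: NetworkStatsVector,
                         bins: int = 20) -> pd.DataFrame:
    """Binned null distributions with the observed value marked per statistic.

    Structure-only export for rendering observed-vs-null histograms.
    """
    frames = []
    obs = pd.Series(observed.as_array(), index=list(STAT_NAMES))
    for s in STAT_NAMES:
        counts, edges = np.histogram(samples[s].to_numpy(), bins=bins)
        frames.append(pd.DataFrame({
            "statistic": s,
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "observed": obs[s],
        }))
    return pd.concat(frames, ignore_index=True)
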