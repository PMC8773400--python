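"""Directed-network reciprocity: dyad census, r, Garlaschelli-Loffredo rho.

A day of contact data is a directed network: nodes are participants (or
cards), and an edge i -> j means i reported (or i's card detected) a
contact with j.  Internal consistency is measured by how often the reverse
edge exists.

Two estimators are provided:

* the classical reciprocity ``r`` — the proportion of directed edges whose
  reverse edge also exists, r = 2 m / (2 m + a) with m mutual and a
  asymmetric dyads, with binomial standard error sqrt(r (1 - r) / n);
* the Garlaschelli-Loffredo correlation ``rho = (r - abar) / (1 - abar)``,
  which discounts the reciprocity expected from a random placement of the
  same number of edges (``abar`` is the density over an *explicit* node
  set, which may exceed the active nodes).

Uncertainty for rho uses the leave-one-dyad-out jackknife
``sigma_rho = sqrt(sum_{i<j} (rho_{-(ij)} - rho)^2)``, where the (i, j)
term zeroes both directions of that dyad.  Null dyads leave rho unchanged
and contribute nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .card_pipeline import CLASS_MIN_COLS

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class DailyDirectedNetwork:
    """One day's directed contact network over an explicit node set.

    ``nodes`` may exceed the nodes with incident edges: densities (and hence
    rho) are defined relative to the full roster, e.g. all 65 retained
    interviewees even when fewer appear in reciprocity edges.
    """

    day: object
    nodes: frozenset
    edges: frozenset  # of (i, j) tuples, i != j

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise NetworkError(f"self-loop {i}->{j}")
            if i not in self.nodes or j not in self.nodes:
                raise NetworkError(f"edge ({i}, {j}) outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def replace_edges(self, edges) -> "DailyDirectedNetwork":
        return DailyDirectedNetwork(self.day, self.nodes, frozenset(edges))


@dataclass(frozen=True)
class DyadCensus:
    mutual: int
    asymmetric: int
    null: int

    @property
    def n_dyads(self) -> int:
        return self.mutual + self.asymmetric + self.null

    @property
    def n_edges(self) -> int:
        return 2 * self.mutual + self.asymmetric


@dataclass(frozen=True)
class ReciprocityEstimate:
    day: object
    r: float
    sigma_r: float
    rho_hat: float
    sigma_rho: float | None
    a_bar: float
    n_edges: int


def dyad_census(net: DailyDirectedNetwork) -> DyadCensus:
    """Classify every unordered node pair as mutual, asymmetric or null."""
    n = net.n_nodes
    if n < 2:
        raise NetworkError("dyad census undefined for fewer than 2 nodes")
    mutual = asymmetric = 0
    seen = set()
    for i, j in net.edges:
        key = (i, j) if i <= j else (j, i)
        if key in seen:
            continue
        seen.add(key)
        if (j, i) in net.edges and (i, j) in net.edges:
            mutual += 1
        else:
            asymmetric += 1
    null = n * (n - 1) // 2 - mutual - asymmetric
    return DyadCensus(mutual, asymmetric, null)


def reciprocity_r(census: DyadCensus) -> tuple[float, float]:
    """Classical reciprocity and its binomial standard error.

    Returns (r, sigma_r) with r = 2m / (2m + a) and
    sigma_r = sqrt(r (1 - r) / n_edges).
    """
    n = census.n_edges
    if n == 0:
        raise NetworkError("reciprocity undefined with zero edges")
    r = 2 * census.mutual / n
    return r, math.sqrt(r * (1 - r) / n)


def network_density(net: DailyDirectedNetwork) -> float:
    """Edge density abar = |edges| / (N (N - 1)) over the explicit node set."""
    n = net.n_nodes
    if n < 2:
        raise NetworkError("density undefined for fewer than 2 nodes")
    return len(net.edges) / (n * (n - 1))


def rho_hat(r: float, a_bar: float) -> float:
    """Garlaschelli-Loffredo reciprocity correlation (r - abar)/(1 - abar)."""
    if a_bar >= 1:
        raise NetworkError("rho undefined at density 1")
    return (r - a_bar) / (1 - a_bar)


def _rho_from_counts(mutual: int, asymmetric: int, n_possible: int) -> float:
    n_edges = 2 * mutual + asymmetric
    r = 2 * mutual / n_edges
    a_bar = n_edges / n_possible
    return (r - a_bar) / (1 - a_bar)


def jackknife_sigma_rho(net: DailyDirectedNetwork) -> float:
    """Leave-one-dyad-out jackknife SE of rho.

    Each non-null dyad's term recomputes rho with both directions of that
    dyad zeroed; null dyads are skipped since removing nothing leaves rho
    unchanged.  Deleting a mutual dyad drops one mutual pair and two edges,
    an asymmetric dyad one pair and one edge, so the N^2 loop reduces to
    two closed-form terms weighted by the census counts.
    """
    census = dyad_census(net)
    m, a = census.mutual, census.asymmetric
    if m + a < 2:
        raise NetworkError("jackknife needs at least 2 non-null dyads")
    n_possible = net.n_nodes * (net.n_nodes - 1)
    rho_full = _rho_from_counts(m, a, n_possible)
    ss = 0.0
    if m:
        if 2 * (m - 1) + a == 0:
            raise NetworkError("jackknife degenerate: all edges in one dyad")
        ss += m * (_rho_from_counts(m - 1, a, n_possible) - rho_full) ** 2
    if a:
        ss += a * (_rho_from_counts(m, a - 1, n_possible) - rho_full) ** 2
    return math.sqrt(ss)


def estimate_reciprocity(
    net: DailyDirectedNetwork, jackknife: bool = True
) -> ReciprocityEstimate:
    """All per-day reciprocity statistics for one network."""
    census = dyad_census(net)
    r, sigma_r = reciprocity_r(census)
    a_bar = network_density(net)
    sigma_rho = jackknife_sigma_rho(net) if jackknife else None
    return ReciprocityEstimate(
        day=net.day,
        r=r,
        sigma_r=sigma_r,
        rho_hat=rho_hat(r, a_bar),
        sigma_rho=sigma_rho,
        a_bar=a_bar,
        n_edges=census.n_edges,
    )


@dataclass(frozen=True)
class PooledReciprocity:
    r: float
    n_reciprocated: int
    n_edges: int
    wald_ci: tuple[float, float]
    agresti_coull_ci: tuple[float, float]


def pooled_reciprocity(censuses) -> PooledReciprocity:
    """Pool daily dyad censuses into one reciprocity proportion.

    r = sum_d 2 m_d / sum_d (2 m_d + a_d), with a Wald interval
    r +/- z sqrt(r(1-r)/n) and an Agresti-Coull interval from the
    z^2-augmented counts (the latter behaves better at small n).
    """
    x = sum(2 * c.mutual for c in censuses)
    n = sum(c.n_edges for c in censuses)
    if n == 0:
        raise NetworkError("pooled reciprocity undefined with zero edges")
    r = x / n
    half = Z_95 * math.sqrt(r * (1 - r) / n)
    n_t = n + Z_95**2
    p_t = (x + Z_95**2 / 2) / n_t
    half_ac = Z_95 * math.sqrt(p_t * (1 - p_t) / n_t)
    return PooledReciprocity(
        r=r,
        n_reciprocated=x,
        n_edges=n,
        wald_ci=(r - half, r + half),
        agresti_coull_ci=(p_t - half_ac, p_t + half_ac),
    )


# ---------------------------------------------------------------------------
# Substrate builders

def network_from_census(
    n_nodes: int, mutual: int, asymmetric: int, day=1
) -> DailyDirectedNetwork:
    """Realise an exact dyad census as a concrete directed network.

    Unordered pairs are enumerated lexicographically; the first ``mutual``
    pairs receive both directed edges, the next ``asymmetric`` pairs one.
    Useful for reconstructing a day's network from published census counts:
    every census-determined statistic (r, density, rho, jackknife SE) is
    invariant to which particular pairs carry the edges.
    """
    pairs = ((i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes))
    edges = set()
    for t, (i, j) in zip(range(mutual + asymmetric), pairs):
        edges.add((i, j))
        if t < mutual:
            edges.add((j, i))
    if len(edges) != 2 * mutual + asymmetric:
        raise NetworkError(
            f"{n_nodes} nodes cannot host {mutual} mutual + {asymmetric} asymmetric dyads"
        )
    return DailyDirectedNetwork(day, frozenset(range(n_nodes)), frozenset(edges))

def networks_from_daily(
    daily: pd.DataFrame,
    nodes,
    class_set=(0, 1, 2),
    day_col: str = "date",
) -> dict:
    """Day-indexed directed networks from daily card dyad records.

    An edge observer -> observed exists on a day iff the dyad logged any
    minutes at a class in ``class_set``.  ``nodes`` is the explicit roster
    used for densities.
    """
    nodes = frozenset(nodes)
    mins = [CLASS_MIN_COLS[c] for c in sorted(class_set)]
    active = daily[daily[mins].sum(axis=1) > 0]
    nets = {}
    for day, sub in active.groupby(day_col):
        edges = frozenset(zip(sub["observer_id"], sub["observed_id"]))
        nets[day] = DailyDirectedNetwork(day, nodes, edges)
    return nets


def daily_reciprocity_table(networks: dict, jackknife: bool = True) -> pd.DataFrame:
    """Per-day summary table: day, r, sigma_r, rho_hat, sigma_rho, a_bar, n."""
    rows = [
        estimate_reciprocity(networks[day], jackknife=jackknife)
        for day in sorted(networks)
    ]
    return pd.DataFrame(
        {
            "day": [e.day for e in rows],
            "r": [e.r for e in rows],
            "sigma_r": [e.sigma_r for e in rows],
            "rho_hat": [e.rho_hat for e in rows],
            "sigma_rho": [e.sigma_rho for e in rows],
            "a_bar": [e.a_bar for e in rows],
            "n_edges": [e.n_edges for e in rows],
        }
    )
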