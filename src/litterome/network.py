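"""Co-occurrence networks: construction, modules, keystone roles, robustness, cohesion.

Construction follows the conservative two-gate recipe: taxa are first
prevalence-filtered (mean relative abundance ≥ 0.01% and occupancy ≥ 80% of
samples, both boundaries inclusive), then pairwise Spearman correlations are
kept only when |ρ| ≥ 0.8 and the Benjamini–Hochberg adjusted p-value is
below 0.01.  The result is an undirected signed weighted graph.

Node roles use the within-module degree z-score Zi and the among-module
participation coefficient Pi = 1 − Σ_s (k_is/k_i)², with the classical
thresholds Zi 2.5 and Pi 0.62: non-peripheral nodes (connectors, module
hubs, network hubs) are keystone taxa.

Robustness is probed by removing edges or nodes (randomly, or strongest
edge / highest degree first) and tracking three measures: network
efficiency Eff (mean inverse shortest-path length over pairs, unweighted),
natural connectivity Eigen = ln(Σ e^λi / N) of the adjacency spectrum, and
the Molloy–Reed critical fraction Pcr = 1 − 1/(⟨k²⟩/⟨k⟩ − 1) clamped to
[0, 1].

Cohesion quantifies per-sample community connectivity: each taxon's
connectedness is its average positive (or negative) null-corrected
correlation with all other taxa, and a sample's cohesion is the abundance-
weighted sum of connectedness values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CommunityTable
from .diversity import relative_abundance

__all__ = [
    "prevalence_filter",
    "correlation_network",
    "detect_modules",
    "node_roles",
    "keystone_taxa",
    "efficiency",
    "natural_connectivity",
    "molloy_reed_fraction",
    "robustness",
    "RobustnessCurve",
    "cohesion",
]

ROLE_ZI = 2.5
ROLE_PI = 0.62


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: CommunityTable,
    min_abundance: float = 1e-4,
    min_occupancy: float = 0.8,
) -> CommunityTable:
    """Drop rare and patchy taxa before correlation analysis.

    Retains taxa whose mean relative abundance is at least ``min_abundance``
    (default 0.01%) and which occur in at least ``min_occupancy`` of samples
    (default 80%); both boundaries are kept.
    """
    if table.n_samples < 5:
        raise ValueError("prevalence filtering needs at least 5 samples")
    rel = relative_abundance(table)
    mean_ok = rel.mean(axis=0) >= min_abundance
    occ_ok = (table.counts > 0).mean(axis=0) >= min_occupancy
    keep = table.counts.columns[mean_ok & occ_ok]
    if len(keep) == 0:
        raise ValueError("no taxa survive the prevalence filter")
    return table.copy_with(table.counts[keep])


def correlation_network(
    table: CommunityTable,
    rho_min: float = 0.8,
    q_max: float = 0.01,
) -> nx.Graph:
    """Spearman co-occurrence graph with |ρ| and FDR gates.

    Correlations use mid-rank ties and two-sided p-values;
    Benjamini–Hochberg adjustment runs across all taxon pairs.  Pairs
    involving a constant taxon (undefined ρ) are skipped with a warning.
    Node attributes carry taxonomy and mean relative abundance; edge
    attributes carry ``rho``, ``q`` and ``weight`` = |ρ|.
    """
    if table.n_samples < 5:
        raise ValueError("correlation network needs at least 5 samples")
    rel = relative_abundance(table)
    taxa = list(rel.columns)
    values = rel.to_numpy()
    n_taxa = len(taxa)
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa to build a network")

    constant = np.ptp(values, axis=0) == 0
    if constant.any():
        bad = [taxa[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"correlations undefined for constant taxa {bad}; their pairs were skipped"
        )
    usable = np.flatnonzero(~constant)
    rho = np.full((n_taxa, n_taxa), np.nan)
    pval = np.full((n_taxa, n_taxa), np.nan)
    if len(usable) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho_sub, p_sub = stats.spearmanr(values[:, usable], axis=0)
        if len(usable) == 2:
            rho_sub = np.array([[1.0, rho_sub], [rho_sub, 1.0]])
            p_sub = np.array([[0.0, p_sub], [p_sub, 0.0]])
        rho[np.ix_(usable, usable)] = rho_sub
        pval[np.ix_(usable, usable)] = p_sub

    iu = np.triu_indices(n_taxa, k=1)
    rho_flat, p_flat = rho[iu], pval[iu]
    valid = np.isfinite(rho_flat) & np.isfinite(p_flat)

    q_flat = np.full_like(p_flat, np.nan)
    if valid.any():
        q_flat[valid] = multipletests(p_flat[valid], method="fdr_bh")[1]

    graph = nx.Graph()
    mean_rel = rel.mean(axis=0)
    for t in taxa:
        lineage = "" if table.taxonomy is None else table.taxonomy.get(t, "")
        graph.add_node(t, taxonomy=lineage, abundance=float(mean_rel[t]))
    for (i, j), r, q in zip(zip(*iu), rho_flat, q_flat):
        if not np.isfinite(r) or not np.isfinite(q):
            continue
        if abs(r) >= rho_min and q < q_max:
            graph.add_edge(taxa[i], taxa[j], rho=float(r), q=float(q), weight=float(abs(r)))
    return graph


# ---------------------------------------------------------------------------
# modules and node roles
# ---------------------------------------------------------------------------

def detect_modules(graph: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Louvain modularity partition; module ids ranked by decreasing size.

    An edgeless graph places every node in its own module (with a warning).
    """
    if graph.number_of_edges() == 0:
        warnings.warn("edgeless network: every node is its own module")
        return {node: i for i, node in enumerate(graph.nodes())}
    communities = nx.community.louvain_communities(graph, seed=seed, weight="weight")
    ordered = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    assignment: dict[str, int] = {}
    for module_id, members in enumerate(ordered):
        for node in members:
            assignment[node] = module_id
    return assignment


def node_roles(graph: nx.Graph, modules: dict[str, int]) -> pd.DataFrame:
    """Zi/Pi topological role per node.

    Zi is the z-score of the node's within-module degree over its module
    (0 for zero-variance or singleton modules); Pi = 1 − Σ_s (k_is/k_i)².
    Roles: peripheral (Zi<2.5, Pi<0.62), connector (Zi<2.5, Pi≥0.62),
    module hub (Zi≥2.5, Pi<0.62), network hub (Zi≥2.5, Pi≥0.62).
    """
    missing = set(graph.nodes()) - set(modules)
    if missing:
        raise ValueError(f"modules do not cover nodes: {sorted(missing)}")
    nodes = list(graph.nodes())
    within = {
        node: sum(1 for nb in graph.neighbors(node) if modules[nb] == modules[node])
        for node in nodes
    }
    by_module: dict[int, list[str]] = {}
    for node in nodes:
        by_module.setdefault(modules[node], []).append(node)

    rows = []
    for node in nodes:
        members = by_module[modules[node]]
        kw = np.array([within[m] for m in members], dtype=float)
        sd = kw.std(ddof=0)
        zi = 0.0 if sd == 0 else (within[node] - kw.mean()) / sd
        k = graph.degree(node)
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[int, int] = {}
            for nb in graph.neighbors(node):
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        if zi >= ROLE_ZI:
            role = "network_hub" if pi >= ROLE_PI else "module_hub"
        else:
            role = "connector" if pi >= ROLE_PI else "peripheral"
        rows.append(
            {"node": node, "module": modules[node], "degree": k,
             "zi": zi, "pi": pi, "role": role, "keystone": role != "peripheral"}
        )
    return pd.DataFrame(rows).set_index("node")


def keystone_taxa(roles: pd.DataFrame) -> list[str]:
    """Non-peripheral nodes (connectors, module hubs, network hubs)."""
    return list(roles.index[roles["keystone"]])


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def efficiency(graph: nx.Graph) -> float:
    """Mean inverse shortest-path length over node pairs (unweighted)."""
    if graph.number_of_nodes() < 2:
        return 0.0
    return nx.global_efficiency(graph)


def natural_connectivity(graph: nx.Graph) -> float:
    """ln of the average adjacency-spectrum exponential, ln(Σ e^λi / N)."""
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    eigvals = np.linalg.eigvalsh(nx.to_numpy_array(graph, weight=None))
    return float(np.log(np.exp(eigvals).mean()))


def molloy_reed_fraction(graph: nx.Graph) -> float:
    """Molloy–Reed critical removal fraction 1 − 1/(⟨k²⟩/⟨k⟩ − 1), in [0, 1]."""
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    if len(degrees) == 0 or degrees.sum() == 0:
        return 0.0
    kappa = (degrees**2).mean() / degrees.mean()
    if kappa <= 1:
        return 0.0
    return float(np.clip(1.0 - 1.0 / (kappa - 1.0), 0.0, 1.0))


_MEASURES = {
    "Eff": efficiency,
    "Eigen": natural_connectivity,
    "Pcr": molloy_reed_fraction,
}

STRATEGIES = ("edge_rand", "edge_strong", "node_rand", "node_degree_high")


@dataclass
class RobustnessCurve:
    strategy: str
    measure: str
    removal_fractions: np.ndarray
    values: np.ndarray
    n_reps: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "measure": self.measure,
                "removal_fraction": self.removal_fractions,
                "value": self.values,
            }
        )


def _removal_order(graph: nx.Graph, strategy: str, rng: np.random.Generator):
    if strategy == "edge_rand":
        edges = list(graph.edges())
        rng.shuffle(edges)
        return "edge", edges
    if strategy == "edge_strong":
        edges = sorted(
            graph.edges(data=True),
            key=lambda e: (-e[2].get("weight", 1.0), e[0], e[1]),
        )
        return "edge", [(u, v) for u, v, _ in edges]
    if strategy == "node_rand":
        nodes = list(graph.nodes())
        rng.shuffle(nodes)
        return "node", nodes
    if strategy == "node_degree_high":
        nodes = sorted(graph.nodes(), key=lambda n: (-graph.degree(n), n))
        return "node", nodes
    raise ValueError(f"unknown removal strategy {strategy!r}; expected one of {STRATEGIES}")


def robustness(
    graph: nx.Graph,
    strategy: str,
    measure: str,
    grid: np.ndarray | None = None,
    n_reps: int = 20,
    seed: int = 0,
) -> RobustnessCurve:
    """Measure degradation under progressive edge/node removal.

    ``grid`` is the strictly increasing sequence of removal fractions in
    [0, 0.99]; random strategies are averaged over ``n_reps`` seeded
    replicates, deterministic ones run once.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {tuple(_MEASURES)}")
    if grid is None:
        grid = np.linspace(0.0, 0.9, 10)
    grid = np.asarray(grid, dtype=float)
    if (np.diff(grid) <= 0).any() or grid.min() < 0 or grid.max() > 0.99:
        raise ValueError("grid must be strictly increasing within [0, 0.99]")
    fn = _MEASURES[measure]
    deterministic = strategy in ("edge_strong", "node_degree_high")
    reps = 1 if deterministic else n_reps

    curves = np.zeros((reps, len(grid)))
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        kind, order = _removal_order(graph, strategy, rng)
        total = len(order)
        for gi, frac in enumerate(grid):
            g = graph.copy()
            n_remove = int(round(frac * total))
            if kind == "edge":
                g.remove_edges_from(order[:n_remove])
            else:
                g.remove_nodes_from(order[:n_remove])
            curves[rep, gi] = fn(g)
    return RobustnessCurve(
        strategy=strategy,
        measure=measure,
        removal_fractions=grid,
        values=curves.mean(axis=0),
        n_reps=reps,
    )


# ---------------------------------------------------------------------------
# cohesion
# ---------------------------------------------------------------------------

def cohesion(
    abundances: pd.DataFrame,
    n_null: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample positive and negative cohesion.

    Pairwise Pearson correlations of relative abundances are corrected by a
    taxon-shuffle null (each sample's abundance vector permuted across taxa,
    ``n_null`` reps); a taxon's connectedness± is the mean of its positive
    (negative) corrected correlations and cohesion± per sample is the
    abundance-weighted sum, so cohesion⁺ ≥ 0 ≥ cohesion⁻.
    """
    if abundances.shape[0] < 5:
        raise ValueError("cohesion needs at least 5 samples")
    x = abundances.to_numpy(dtype=float)
    n_samples, n_taxa = x.shape

    def corr(mat: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.corrcoef(mat, rowvar=False)
        return np.nan_to_num(c, nan=0.0)

    obs = corr(x)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(n_null):
        shuffled = np.empty_like(x)
        for i in range(n_samples):
            shuffled[i] = x[i, rng.permutation(n_taxa)]
        null_sum += corr(shuffled)
    corrected = obs - null_sum / n_null
    np.fill_diagonal(corrected, 0.0)

    pos = np.where(corrected > 0, corrected, 0.0)
    neg = np.where(corrected < 0, corrected, 0.0)
    denom = max(n_taxa - 1, 1)
    conn_pos = pos.sum(axis=0) / denom
    conn_neg = neg.sum(axis=0) / denom
    return pd.DataFrame(
        {
            "positive_cohesion": x @ conn_pos,
            "negative_cohesion": x @ conn_neg,
        },
        index=abundances.index,
    )
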