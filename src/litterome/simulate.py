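"""Synthetic communities with known assembly regimes, plus enzyme and FTIR tables.

The generator emulates the shape of a 6-treatment x 5-replicate litter-bag
microcosm: a shared species pool with a skewed (lognormal-ranked) abundance
distribution, a pure-birth phylogeny over the pool, and local communities
assembled under one of four controllable regimes:

``neutral``
    repeated multinomial resampling (Wright–Fisher-style drift) with a
    migration pull toward the shared metacommunity — drift-dominated.
``homogeneous_selection``
    sampling weights multiplied by a Gaussian fitness kernel on phylogenetic
    proximity to a focal optimum taxon (a perfectly conserved niche trait),
    with one optimum shared by every sample; communities converge on a
    phylogenetically clustered subset of taxa.
``variable_selection``
    as above but with a different focal optimum per treatment group.
``dispersal_limited``
    disjoint regional pools per group and near-zero migration.

Because selection acts on proximity measured on the same tree used by the
phylogenetic null models, selection regimes produce phylogenetically
autocorrelated abundance shifts, which is what makes βNTI respond in the
theoretically expected direction.  A Brownian trait per taxon is still
simulated and reported in the ground truth for downstream use.

Every function threads an explicit seed; no global random state is touched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .containers import CommunityTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "brownian_traits",
    "cophenetic_matrix",
    "simulate_metacommunity",
    "simulate_communities",
    "simulate_enzymes",
    "simulate_bands",
    "ENZYMES",
    "BAND_NAMES",
    "DEFAULT_GROUPS",
]

REGIMES = ("neutral", "homogeneous_selection", "variable_selection", "dispersal_limited")
DEFAULT_GROUPS = ("CK", "Np10", "Np100", "Pb", "Pb_Np10", "Pb_Np100")

#: enzyme panel: C-acquiring (BG, C1, Cx), N-acquiring (NAG, LAP),
#: P-acquiring (AP) and ligninolytic (laccase, peroxidase) activities
ENZYMES = ("BG", "NAG", "LAP", "AP", "C1", "Cx", "laccase", "peroxidase")

#: typical litter activity scales, µmol g⁻¹ dry litter h⁻¹
_ENZYME_MEANS = {
    "BG": 20.0, "NAG": 8.0, "LAP": 5.0, "AP": 15.0,
    "C1": 2.0, "Cx": 4.0, "laccase": 1.0, "peroxidase": 1.5,
}

BAND_NAMES = ("polysaccharide_CO", "aliphatic_CH", "aromatic_CC", "aromatic_CH")

#: fresh plant litter is polysaccharide-dominated; concentrations give mean
#: relative areas ≈ (0.59, 0.24, 0.12, 0.06)
_DEFAULT_BAND_CONCENTRATION = (10.0, 4.0, 2.0, 1.0)


@dataclass
class SimulationConfig:
    """Knobs for one synthetic community dataset.

    ``selection_strength`` is the inverse squared width of the Gaussian
    fitness kernel on the standardized Brownian trait (0 = no selection);
    ``migration_rate`` in [0, 1] is the per-generation fraction of the local
    community replenished from the regional pool (1 = fully mixed, no drift
    accumulation).
    """

    n_taxa: int = 60
    n_samples_per_group: int = 5
    groups: tuple[str, ...] = DEFAULT_GROUPS
    depth: int = 5000
    assembly_regime: str = "neutral"
    selection_strength: float = 0.0
    migration_rate: float = 0.9
    seed: int = 0
    sad_sigma: float = 1.5
    n_generations: int = 10

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_samples_per_group < 1 or self.depth < 1:
            raise ValueError("n_taxa, n_samples_per_group and depth must be positive")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        if self.assembly_regime not in REGIMES:
            raise ValueError(
                f"unknown assembly regime {self.assembly_regime!r}; expected one of {REGIMES}"
            )
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis has to recover."""

    regime: str
    group_per_sample: pd.Series
    traits: pd.Series  # standardized Brownian trait per taxon
    metacommunity: pd.Series  # shared-pool relative abundances, sums to 1
    optima: dict[str, str] = field(default_factory=dict)  # group -> focal optimum taxon

    def expected_category(self, sample_a: str, sample_b: str) -> str:
        """Dominant assembly category expected for a sample pair."""
        same = self.group_per_sample[sample_a] == self.group_per_sample[sample_b]
        if self.regime == "neutral":
            return "drift"
        if self.regime == "homogeneous_selection":
            return "homogeneous_selection"
        if self.regime == "variable_selection":
            return "homogeneous_selection" if same else "heterogeneous_selection"
        return "drift" if same else "dispersal_limitation"


# ---------------------------------------------------------------------------
# phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Rooted ultrametric pure-birth (Yule) tree with ``n_taxa`` tips.

    Tips are labelled ``OTU1..OTUn`` in a seed-determined order.  Terminal
    branches are extended by one extra exponential waiting time so that every
    branch length is strictly positive (the birth process otherwise stops
    exactly at the final speciation, leaving two zero-length tips).
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be at least 3")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, rng=rng
    )
    extension = rng.expovariate(float(n_taxa))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    # deterministic relabel in leaf-iteration order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1}"
    tree.seed_node.edge.length = None
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def cophenetic_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Pairwise patristic (cophenetic) distances between tips."""
    if taxa is None:
        taxa = tip_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(by_label[taxa[i]], by_label[taxa[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=taxa, columns=taxa)


def brownian_traits(tree: dendropy.Tree, seed: int) -> pd.Series:
    """Brownian-motion trait per tip, standardized to zero mean / unit sd.

    The trait evolves along the same tree later used for the phylogenetic
    null models, so selection on it is phylogenetically autocorrelated.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(max(node.edge.length, 0.0)))
    traits = pd.Series(
        {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    )
    sd = traits.std(ddof=0)
    if sd > 0:
        traits = (traits - traits.mean()) / sd
    return traits


# ---------------------------------------------------------------------------
# metacommunity and local communities
# ---------------------------------------------------------------------------

def simulate_metacommunity(n_taxa: int, seed: int, sigma: float = 1.5) -> np.ndarray:
    """Lognormal-ranked relative abundances (skewed SAD), summing to 1."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be positive")
    rng = np.random.default_rng(seed)
    raw = np.sort(rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa))[::-1]
    return raw / raw.sum()


def _selection_weights(dist_to_focal: np.ndarray, height: float, strength: float) -> np.ndarray:
    """Gaussian fitness kernel on phylogenetic proximity to a focal taxon.

    Models habitat filtering on a perfectly conserved niche trait: fitness
    decays with the (tree-height-normalized) cophenetic distance to the
    focal optimum taxon.  A single Brownian trait realization on a small
    tree shows too much convergent similarity across clades for selection
    on it to confine communities phylogenetically, so the conserved-trait
    limit is used instead.
    """
    return np.exp(-strength * (dist_to_focal / height) ** 2 / 2.0)


def simulate_communities(
    config: SimulationConfig,
    tree: dendropy.Tree | None = None,
    metacommunity: np.ndarray | None = None,
) -> tuple[CommunityTable, GroundTruth]:
    """Assemble local communities under the configured regime.

    Each sample drifts for ``n_generations`` Wright–Fisher steps of size
    ``depth``: at every step the sampling probabilities are a mixture of the
    current local composition (weight ``1 - migration_rate``) and the
    regime-specific source pool (weight ``migration_rate``).  Selection
    regimes tilt the source pool by the Gaussian trait kernel before any
    resampling happens.
    """
    if tree is None:
        tree = simulate_tree(config.n_taxa, config.seed)
    taxa = tip_labels(tree)
    if metacommunity is None:
        metacommunity = simulate_metacommunity(len(taxa), config.seed + 1, config.sad_sigma)
    metacommunity = np.asarray(metacommunity, dtype=float)
    if len(taxa) < len(metacommunity):
        raise ValueError("tree tips must cover all metacommunity taxa")
    rng = np.random.default_rng(config.seed + 2)
    # assign SAD values to tips in random order: a rank-sorted SAD laid onto
    # the tip iteration order would correlate abundance with the phylogeny
    # and bias the neutral regime away from the tip-shuffle null
    metacommunity = metacommunity[rng.permutation(len(metacommunity))]
    traits = brownian_traits(tree, config.seed + 3)
    trait_values = traits.loc[taxa].to_numpy()

    groups = list(config.groups)
    optima: dict[str, str] = {}
    pools: dict[str, np.ndarray] = {}
    if config.assembly_regime == "neutral":
        pools = {g: metacommunity for g in groups}
    elif config.assembly_regime in ("homogeneous_selection", "variable_selection"):
        d = cophenetic_matrix(tree, taxa).to_numpy()
        height = d.max() / 2.0
        shared_focal = int(rng.integers(len(taxa)))
        for g in groups:
            focal = (
                shared_focal
                if config.assembly_regime == "homogeneous_selection"
                else int(rng.integers(len(taxa)))
            )
            optima[g] = taxa[focal]
            w = _selection_weights(d[focal], height, config.selection_strength)
            pools[g] = metacommunity * w / (metacommunity * w).sum()
    else:  # dispersal_limited: disjoint regional pools per group
        order = rng.permutation(len(taxa))
        blocks = np.array_split(order, len(groups))
        for g, block in zip(groups, blocks):
            mask = np.zeros(len(taxa))
            mask[block] = 1.0
            pool = metacommunity * mask
            if pool.sum() == 0:
                pool = mask
            pools[g] = pool / pool.sum()

    rows, sample_ids, labels = [], [], []
    for g in groups:
        pool = pools[g]
        for rep in range(config.n_samples_per_group):
            local = pool.copy()
            counts = None
            for _ in range(config.n_generations):
                probs = (1.0 - config.migration_rate) * local + config.migration_rate * pool
                probs = probs / probs.sum()
                counts = rng.multinomial(config.depth, probs)
                local = counts / config.depth
            rows.append(counts)
            sample_ids.append(f"{g}_{rep + 1}")
            labels.append(g)

    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa)
    metadata = pd.Series(labels, index=sample_ids, name="group")
    taxonomy = _synthetic_taxonomy(taxa)
    table = CommunityTable(counts=counts, taxonomy=taxonomy, metadata=metadata)
    truth = GroundTruth(
        regime=config.assembly_regime,
        group_per_sample=metadata,
        traits=traits,
        metacommunity=pd.Series(metacommunity, index=taxa),
        optima=optima,
    )
    return table, truth


def _synthetic_taxonomy(taxa: list[str], n_phyla: int = 3) -> pd.Series:
    """QIIME-style lineages partitioning taxa into nested clades.

    Taxa are assigned in tip order, so adjacent tips (which tend to be close
    on the tree) share lineage prefixes — a rough phylogenetic signal that is
    enough for clade roll-up analyses.
    """
    n = len(taxa)
    lineages = []
    for i in range(n):
        p = i * n_phyla // n + 1
        c = i * (n_phyla * 2) // n + 1
        f = i * (n_phyla * 4) // n + 1
        g = i * (n_phyla * 8) // n + 1
        lineages.append(
            f"k__Microbia;p__Phylum{p};c__Class{c};f__Family{f};g__Genus{g}"
        )
    return pd.Series(lineages, index=taxa, name="taxonomy")


# ---------------------------------------------------------------------------
# enzyme activities and FTIR band areas
# ---------------------------------------------------------------------------

def simulate_enzymes(
    groups: list[str],
    n_reps: int,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    sigma: float = 0.3,
) -> pd.DataFrame:
    """Lognormal enzyme activities per sample (strictly positive).

    ``effects`` maps group -> enzyme -> multiplicative factor on that group's
    mean activity; unlisted enzymes default to factor 1.  The log-scale sd
    ``sigma`` sets replicate noise; lognormal means are corrected by
    ``exp(-sigma²/2)`` so the arithmetic group mean scales exactly with the
    stated factor.
    """
    effects = effects or {}
    for g, facs in effects.items():
        for enz, f in facs.items():
            if f <= 0:
                raise ValueError(f"non-positive effect factor {f} for {g}/{enz}")
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], []
    for g in groups:
        facs = effects.get(g, {})
        for rep in range(n_reps):
            row = {}
            for enz in ENZYMES:
                mean = _ENZYME_MEANS[enz] * facs.get(enz, 1.0)
                mu = np.log(mean) - sigma**2 / 2.0
                row[enz] = float(rng.lognormal(mu, sigma))
            rows.append(row)
            ids.append(f"{g}_{rep + 1}")
            labels.append(g)
    out = pd.DataFrame(rows, index=ids)
    out.insert(0, "group", labels)
    return out


def simulate_bands(
    n_samples: int,
    concentration: tuple[float, float, float, float] = _DEFAULT_BAND_CONCENTRATION,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet-distributed relative infrared band areas; rows sum to 1."""
    conc = np.asarray(concentration, dtype=float)
    if conc.shape != (4,) or (conc <= 0).any():
        raise ValueError("concentration must be 4 positive reals")
    rng = np.random.default_rng(seed)
    areas = rng.dirichlet(conc, size=n_samples)
    return pd.DataFrame(
        areas, index=[f"S{i + 1}" for i in range(n_samples)], columns=list(BAND_NAMES)
    )
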