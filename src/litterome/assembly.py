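"""Null-model quantification of community assembly processes.

For every pair of samples we compute the abundance-weighted beta mean
nearest taxon distance

    βMNTD(k, m) = ½ [ Σ_i f_ik · min_{j ∈ m} d_ij  +  Σ_j f_jm · min_{i ∈ k} d_ij ]

with f relative abundances and d cophenetic tree distances, then standardize
it against a tip-shuffle null (taxa permuted across the tips of the
phylogeny, abundances held fixed) to obtain the beta nearest taxon index
βNTI = (βMNTD_obs − mean_null) / sd_null.  A second, taxonomic null gives
the Raup–Crick metric on Bray–Curtis (RC_bray): null communities preserve
each sample's richness and total abundance, drawing taxa with probability
proportional to their occupancy and filling abundances proportionally to
regional relative abundance, with RC rescaled to [−1, 1].

Pairs are then classified into the five assembly categories:

    βNTI < −2                         homogeneous selection
    βNTI > +2                         heterogeneous selection
    |βNTI| < 2 and RC_bray < −0.95    homogenizing dispersal
    |βNTI| < 2 and RC_bray > +0.95    dispersal limitation
    |βNTI| < 2 and |RC_bray| < 0.95   drift

Boundary values (|βNTI| = 2, |RC| = 0.95) do not exceed the thresholds.
Pairs whose null standard deviation is zero (e.g. identical communities,
where every taxon's nearest neighbour is itself under any tip shuffle) have
undefined βNTI; they are reported as NaN and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .containers import CommunityTable
from .simulate import cophenetic_matrix

__all__ = [
    "CATEGORIES",
    "STOCHASTIC_CATEGORIES",
    "BntiResult",
    "beta_mntd",
    "bnti",
    "rc_bray",
    "classify",
    "assembly_pairs",
    "summarize",
]

CATEGORIES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)
STOCHASTIC_CATEGORIES = ("homogenizing_dispersal", "dispersal_limitation", "drift")


@dataclass
class BntiResult:
    bnti: pd.DataFrame
    beta_mntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame


def _distance_frame(
    table: CommunityTable, tree: dendropy.Tree | pd.DataFrame
) -> np.ndarray:
    """Cophenetic distances ordered like the table's taxa."""
    taxa = table.taxon_ids
    if isinstance(tree, pd.DataFrame):
        dmat = tree
    else:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        present = set(
            table.counts.columns[(table.counts.to_numpy() > 0).any(axis=0)]
        )
        missing = sorted(present - tips)
        if missing:
            raise ValueError(f"taxa missing from tree tips: {missing}")
        dmat = cophenetic_matrix(tree, [t for t in taxa if t in tips])
    dmat = dmat.reindex(index=taxa, columns=taxa)
    if dmat.isna().to_numpy().any():
        bad = [t for t in taxa if t not in dmat.index or dmat.loc[t].isna().all()]
        raise ValueError(f"taxa missing from distance matrix: {bad}")
    return dmat.to_numpy(dtype=float)


def _abundance_weights(table: CommunityTable, weighted: bool) -> np.ndarray:
    counts = table.counts.to_numpy(dtype=float)
    if not weighted:
        counts = (counts > 0).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("empty samples have no defined βMNTD")
    return counts / totals


def _beta_mntd_matrix(weights: np.ndarray, d: np.ndarray, supports: list[np.ndarray]) -> np.ndarray:
    n_samples, n_taxa = weights.shape
    mins = np.empty((n_samples, n_taxa))
    for m, supp in enumerate(supports):
        mins[m] = d[:, supp].min(axis=1)
    a = weights @ mins.T  # a[k, m] = Σ_i f_ik · min_{j∈m} d_ij
    return 0.5 * (a + a.T)


def beta_mntd(
    table: CommunityTable,
    tree: dendropy.Tree | pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted (or presence-based) βMNTD for all sample pairs."""
    d = _distance_frame(table, tree)
    weights = _abundance_weights(table, weighted)
    supports = [np.flatnonzero(row > 0) for row in weights]
    mat = _beta_mntd_matrix(weights, d, supports)
    np.fill_diagonal(mat, 0.0)
    ids = table.sample_ids
    return pd.DataFrame(mat, index=ids, columns=ids)


def bnti(
    table: CommunityTable,
    tree: dendropy.Tree | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> BntiResult:
    """βNTI z-scores against the tip-shuffle null.

    Each null draw permutes taxa across the tips of the phylogeny (one joint
    permutation of the cophenetic matrix) and recomputes βMNTD for every
    pair.  Pairs with zero null standard deviation get NaN.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    d = _distance_frame(table, tree)
    weights = _abundance_weights(table, weighted)
    supports = [np.flatnonzero(row > 0) for row in weights]
    obs = _beta_mntd_matrix(weights, d, supports)

    rng = np.random.default_rng(seed)
    n_taxa = d.shape[0]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_matrix(weights, d[np.ix_(perm, perm)], supports)
        total += null
        total_sq += null**2
    mean = total / n_null
    var = (total_sq - n_null * mean**2) / (n_null - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    np.fill_diagonal(z, np.nan)
    ids = table.sample_ids
    frame = lambda m: pd.DataFrame(m, index=ids, columns=ids)  # noqa: E731
    return BntiResult(
        bnti=frame(z), beta_mntd_obs=frame(obs), null_mean=frame(mean), null_sd=frame(sd)
    )


# ---------------------------------------------------------------------------
# Raup–Crick on Bray–Curtis
# ---------------------------------------------------------------------------

def _null_communities(
    counts: np.ndarray, n_null: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per sample: n_null null count vectors preserving richness and total.

    Taxa enter a null community with probability proportional to their
    occupancy across samples (weighted sampling without replacement via the
    Gumbel-max trick); one individual seeds each chosen taxon and the
    remaining individuals are distributed multinomially with probabilities
    proportional to regional relative abundance.
    """
    n_samples, n_taxa = counts.shape
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore"):
        log_occ = np.log(occupancy)

    nulls = []
    for k in range(n_samples):
        richness = int((counts[k] > 0).sum())
        total = int(counts[k].sum())
        keys = rng.gumbel(size=(n_null, n_taxa)) + log_occ
        chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
        null_k = np.zeros((n_null, n_taxa), dtype=np.int64)
        extra = total - richness
        for r in range(n_null):
            sel = chosen[r]
            null_k[r, sel] = 1
            if extra > 0:
                p = regional[sel]
                null_k[r, sel] += rng.multinomial(extra, p / p.sum())
        nulls.append(null_k)
    return nulls


def _bray_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.abs(x - y).sum(axis=-1) / (x + y).sum(axis=-1)


def rc_bray(
    table: CommunityTable,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Raup–Crick metric on Bray–Curtis, rescaled to [−1, 1].

    RC = 2 · [ #(null < obs) + ½ · #(null = obs) ] / n_null − 1, where the
    null Bray–Curtis distribution comes from richness/abundance-preserving
    random communities.  RC < −0.95 flags homogenizing dispersal, RC > +0.95
    dispersal limitation.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    if table.n_samples < 2:
        raise ValueError("RC_bray needs at least two samples")
    counts = table.counts.to_numpy(dtype=np.int64)
    rng = np.random.default_rng(seed)
    nulls = _null_communities(counts, n_null, rng)

    n = table.n_samples
    out = np.zeros((n, n))
    for k, m in combinations(range(n), 2):
        obs = _bray_counts(counts[k].astype(float), counts[m].astype(float))
        null_d = _bray_counts(nulls[k].astype(float), nulls[m].astype(float))
        below = (null_d < obs - 1e-12).sum()
        ties = (np.abs(null_d - obs) <= 1e-12).sum()
        rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
        out[k, m] = out[m, k] = rc
    ids = table.sample_ids
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------

def classify(bnti_value: float, rc_value: float) -> str:
    """Five-category assembly classification with strict thresholds."""
    if not (np.isfinite(bnti_value) and np.isfinite(rc_value)):
        raise ValueError("classify requires finite βNTI and RC_bray values")
    if bnti_value < -2:
        return "homogeneous_selection"
    if bnti_value > 2:
        return "heterogeneous_selection"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    if rc_value > 0.95:
        return "dispersal_limitation"
    return "drift"


def assembly_pairs(
    table: CommunityTable,
    tree: dendropy.Tree | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    pairs: str = "within-group",
) -> pd.DataFrame:
    """Per-pair βNTI, RC_bray and assembly category.

    ``pairs`` selects the pair universe: ``within-group`` (default, requires
    sample metadata) or ``all``.  Pairs with undefined βNTI (zero-variance
    null) carry NaN and an ``unclassified`` category.
    """
    if pairs not in ("within-group", "all"):
        raise ValueError("pairs must be 'within-group' or 'all'")
    res = bnti(table, tree, n_null=n_null, seed=seed)
    rc = rc_bray(table, n_null=n_null, seed=seed + 1)
    bray = pd.DataFrame(
        np.nan, index=table.counts.index, columns=table.counts.index
    )
    counts = table.counts.to_numpy(dtype=float)
    groups = table.metadata if table.metadata is not None else None

    records = []
    ids = table.sample_ids
    for i, j in combinations(range(len(ids)), 2):
        a, b = ids[i], ids[j]
        if pairs == "within-group":
            if groups is None:
                raise ValueError("within-group pairs need sample metadata")
            if groups[a] != groups[b]:
                continue
        z = res.bnti.iat[i, j]
        r = rc.iat[i, j]
        category = classify(z, r) if np.isfinite(z) else "unclassified"
        records.append(
            {
                "sample_a": a,
                "sample_b": b,
                "group_a": None if groups is None else groups[a],
                "group_b": None if groups is None else groups[b],
                "beta_mntd_obs": res.beta_mntd_obs.iat[i, j],
                "null_mean": res.null_mean.iat[i, j],
                "null_sd": res.null_sd.iat[i, j],
                "bnti": z,
                "bray_obs": _bray_counts(counts[i], counts[j]),
                "rc_bray": r,
                "category": category,
            }
        )
    return pd.DataFrame(records)


def summarize(pairs: pd.DataFrame, by: str = "group_a") -> pd.DataFrame:
    """Per-group fractions of assembly categories plus the stochastic total.

    Unclassified pairs (undefined βNTI) are excluded; category fractions sum
    to 1 within each group.
    """
    usable = pairs[pairs["category"] != "unclassified"]
    rows = []
    keys = usable[by].unique() if by in usable.columns else ["all"]
    for key in keys:
        sub = usable if key == "all" else usable[usable[by] == key]
        if len(sub) == 0:
            continue
        fracs = {c: float((sub["category"] == c).mean()) for c in CATEGORIES}
        fracs["stochastic"] = sum(fracs[c] for c in STOCHASTIC_CATEGORIES)
        fracs[by] = key
        fracs["n_pairs"] = len(sub)
        rows.append(fracs)
    return pd.DataFrame(rows).set_index(by)
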