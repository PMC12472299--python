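"""Normalization, alpha diversity, Bray–Curtis, PCoA, PERMANOVA, PERMDISP.

Conventions: Shannon in nats (base e); Simpson is the Gini–Simpson form
1 − Σp²; Chao1 is the classic estimator with the bias-corrected fallback when
no doubletons exist; ACE uses the standard rare-taxon cutoff of 10.  Bray–
Curtis is a semimetric (the triangle inequality is not guaranteed), so PCoA
on it can produce negative eigenvalues; these are reported but their axes are
excluded from the coordinates.

PERMANOVA and PERMDISP are computed from the distance matrix directly
(Anderson's partition of squared inter-point distances), with label
permutations evaluated in a single vectorized pass so large permutation
counts and repeated calibration runs stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _alpha

from .containers import CommunityTable

__all__ = [
    "OrdinationResult",
    "PermutationTestResult",
    "rarefy",
    "relative_abundance",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "permdisp",
]


@dataclass
class OrdinationResult:
    """PCoA output: coordinates on positive-eigenvalue axes only."""

    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues


@dataclass
class PermutationTestResult:
    statistic: float  # pseudo-F
    r2: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int | None = None, seed: int = 0) -> CommunityTable:
    """Subsample every sample without replacement to a common depth.

    Default depth is the minimum sample total (the usual rarefaction choice).
    Subsampling is multivariate-hypergeometric, i.e. drawing ``depth`` reads
    from the sample's observed reads without replacement.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    too_shallow = totals[totals < depth]
    if len(too_shallow):
        raise ValueError(
            f"depth {depth} exceeds totals of samples: {list(too_shallow.index)}"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().astype(np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return table.copy_with(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Row-normalize counts to relative abundances (rows sum to 1)."""
    totals = table.sample_totals()
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"empty samples cannot be normalized: {list(empty.index)}")
    return table.counts.div(totals, axis=0)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Chao1, ACE, Shannon (nats) and Gini–Simpson per sample."""
    rows = {}
    for sid, row in table.counts.iterrows():
        counts = row.to_numpy().astype(np.int64)
        if counts.sum() == 0:
            raise ValueError(f"sample {sid} has no counts")
        rows[sid] = {
            "chao1": float(_alpha.chao1(counts, bias_corrected=False)),
            "ace": float(_alpha.ace(counts, rare_threshold=10)),
            "shannon": float(_alpha.shannon(counts, base=np.e)),
            "simpson": float(_alpha.simpson(counts)),
            "observed": int((counts > 0).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity, Σ|x−y| / Σ(x+y)."""
    values = abundances.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray–Curtis undefined between two all-zero samples")
    dm = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dm, index=abundances.index, columns=abundances.index)


def _gower_center(dm: np.ndarray) -> np.ndarray:
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def pcoa(dm: pd.DataFrame) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix; axes with negative
    eigenvalues are excluded from the returned coordinates but the
    eigenvalues themselves are reported.
    """
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    values = dm.to_numpy(dtype=float)
    eigvals, eigvecs = np.linalg.eigh(_gower_center(values))
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    coordinates = pd.DataFrame(
        coords, index=dm.index, columns=[f"PCo{i + 1}" for i in range(pos.sum())]
    )
    prop = eigvals[pos] / eigvals[pos].sum()
    return OrdinationResult(
        coordinates=coordinates, eigenvalues=eigvals, proportion_explained=prop
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _check_grouping(groups: pd.Series, index: pd.Index) -> np.ndarray:
    groups = groups.reindex(index)
    if groups.isna().any():
        raise ValueError("grouping does not cover all samples")
    labels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [labels[i] for i in np.where(sizes < 2)[0]]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    return codes


def _ss_within(d2: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """SS_within for each row of a (P, n) matrix of group codes."""
    n_groups = codes.max() + 1
    ss = np.zeros(codes.shape[0])
    for g in range(n_groups):
        member = (codes == g).astype(float)  # (P, n)
        pair_sums = ((member @ d2) * member).sum(axis=1) / 2.0
        ss += pair_sums / member.sum(axis=1)
    return ss


def permanova(
    dm: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix (Anderson's pseudo-F).

    p-value uses the add-one smoothing p = (1 + #{F* ≥ F}) / (1 + n_perm);
    permutations shuffle sample labels with an explicitly seeded generator.
    """
    codes = _check_grouping(groups, dm.index)
    d2 = dm.to_numpy(dtype=float) ** 2
    n = len(codes)
    a = codes.max() + 1
    ss_total = d2.sum() / (2.0 * n)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=np.int64)
    perms[0] = codes
    for i in range(1, n_perm + 1):
        perms[i] = codes[rng.permutation(n)]
    ss_w = _ss_within(d2, perms)
    f_all = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
    f_obs = f_all[0]
    p = (1 + int((f_all[1:] >= f_obs).sum())) / (1 + n_perm)
    r2 = (ss_total - ss_w[0]) / ss_total
    return PermutationTestResult(
        statistic=float(f_obs), r2=float(r2), p_value=float(p), n_permutations=n_perm
    )


def _signed_pcoa_axes(dm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full PCoA coordinates plus a ±1 sign per axis.

    Negative-eigenvalue axes (semimetric inputs) contribute with a minus
    sign to squared distances — the standard correction.
    """
    eigvals, eigvecs = np.linalg.eigh(_gower_center(dm))
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    signs = np.where(eigvals > tol, 1.0, np.where(eigvals < -tol, -1.0, 0.0))
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    return coords, signs


def _centroid_distances(coords: np.ndarray, signs: np.ndarray, codes: np.ndarray) -> np.ndarray:
    z2 = np.zeros(len(codes))
    for g in range(codes.max() + 1):
        members = codes == g
        centroid = coords[members].mean(axis=0)
        diff2 = (coords[members] - centroid) ** 2
        z2[members] = (diff2 * signs).sum(axis=1)
    return np.sqrt(np.clip(z2, 0.0, None))


def dispersion_distances(dm: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Distance of each sample to its group centroid in PCoA space."""
    codes = _check_grouping(groups, dm.index)
    coords, signs = _signed_pcoa_axes(dm.to_numpy(dtype=float))
    return pd.Series(
        _centroid_distances(coords, signs, codes), index=dm.index, name="dist_to_centroid"
    )


def permdisp(
    dm: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions (centroid variant).

    ANOVA F on the per-sample distances to the group centroid.  The
    permutation p-value re-assigns samples to groups and recomputes the
    centroids and distances for every permutation; keeping the centroids
    fixed and shuffling only the distances runs noticeably anticonservative
    at small group sizes.
    """
    codes = _check_grouping(groups, dm.index)
    coords, signs = _signed_pcoa_axes(dm.to_numpy(dtype=float))
    n = len(codes)
    a = codes.max() + 1

    def f_stat(codes_row: np.ndarray) -> float:
        z = _centroid_distances(coords, signs, codes_row)
        grand = z.mean()
        ss_b = ss_w = 0.0
        for g in range(a):
            zg = z[codes_row == g]
            ss_b += len(zg) * (zg.mean() - grand) ** 2
            ss_w += ((zg - zg.mean()) ** 2).sum()
        if ss_w == 0:
            return np.inf
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if f_stat(codes[rng.permutation(n)]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    z = _centroid_distances(coords, signs, codes)
    ss_total = ((z - z.mean()) ** 2).sum()
    ss_w = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum() for g in range(a))
    r2 = 0.0 if ss_total == 0 else (ss_total - ss_w) / ss_total
    return PermutationTestResult(
        statistic=float(f_obs), r2=float(r2), p_value=float(p), n_permutations=n_perm
    )
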