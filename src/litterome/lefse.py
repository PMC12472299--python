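"""Biomarker discovery: clade roll-up + Kruskal–Wallis / Wilcoxon / LDA gates.

The procedure mirrors the classical three-step biomarker recipe:

1. roll taxa up into clade features at every taxonomic rank (a clade's
   abundance is the sum of its members' relative abundances);
2. keep features whose abundance differs across groups by Kruskal–Wallis at
   p < 0.01, then require the candidate (highest-mean) group to beat every
   other group in one-sided Wilcoxon rank-sum comparisons (α = 0.05);
3. score surviving features with a bootstrap-averaged linear-discriminant
   effect size on the enriched-vs-rest contrast: abundances are rescaled by
   10⁶ and the score is log10 of the averaged absolute class-mean
   discriminant difference (floored at 1), which lands scores on the
   familiar 2–5 range.  Biomarkers are features with |LDA score| above the
   threshold (default 3.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CommunityTable
from .diversity import relative_abundance

__all__ = ["build_clade_features", "lda_effect_size", "lefse"]

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_RANK_NAMES = {
    "k": "kingdom", "p": "phylum", "c": "class", "o": "order",
    "f": "family", "g": "genus", "s": "species",
}


def build_clade_features(table: CommunityTable) -> pd.DataFrame:
    """Cumulative relative abundance per lineage prefix (clade), per sample.

    Every distinct lineage prefix (kingdom, kingdom;phylum, ...) becomes one
    feature whose abundance is the summed relative abundance of its member
    taxa.  Taxa with malformed lineages contribute only to the ranks that
    parse; a warning is emitted for them.
    """
    if table.taxonomy is None:
        raise ValueError("clade features need taxonomy lineages")
    rel = relative_abundance(table)
    features: dict[str, np.ndarray] = {}
    malformed = []
    for taxon in rel.columns:
        lineage = str(table.taxonomy.get(taxon, "") or "")
        parts = [p.strip() for p in lineage.split(";") if p.strip()]
        clean = []
        for part in parts:
            if len(part) >= 3 and part[1:3] == "__" and part[:1].isalpha() and part[3:]:
                clean.append(part)
            else:
                malformed.append(taxon)
                break
        for depth in range(1, len(clean) + 1):
            clade = ";".join(clean[:depth])
            vec = rel[taxon].to_numpy()
            features[clade] = features.get(clade, 0.0) + vec
    if malformed:
        warnings.warn(
            f"{len(set(malformed))} taxa had malformed lineages; "
            "assigned only to parsed ranks"
        )
    if not features:
        raise ValueError("no parseable lineages")
    return pd.DataFrame(features, index=rel.index)


def clade_rank(clade: str) -> str:
    """Name of the deepest rank of a clade id (phylum/class/.../species)."""
    last = str(clade).split(";")[-1]
    return _RANK_NAMES.get(last[:1], "unknown")


def lda_effect_size(
    values: np.ndarray,
    enriched_mask: np.ndarray,
    n_boot: int = 30,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap-averaged one-feature LDA effect size, log10 scale.

    Per bootstrap, two-thirds of each class is subsampled and the absolute
    difference of class means of the 10⁶-rescaled feature is recorded; the
    score is log10 of the bootstrap mean, floored at 1 (score 0).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    scaled = values * 1e6
    a, b = scaled[enriched_mask], scaled[~enriched_mask]
    diffs = []
    for _ in range(n_boot):
        sa = rng.choice(a, size=max(2, int(np.ceil(len(a) * 2 / 3))), replace=False)
        sb = rng.choice(b, size=max(2, int(np.ceil(len(b) * 2 / 3))), replace=False)
        diffs.append(abs(sa.mean() - sb.mean()))
    return float(np.log10(max(np.mean(diffs), 1.0)))


@dataclass
class LefseResult:
    biomarkers: pd.DataFrame  # clade, rank, group, kw_p, lda_score
    all_features: pd.DataFrame  # per-feature kw_p, candidate group, pass flags


def lefse(
    features: pd.DataFrame,
    groups: pd.Series,
    kw_alpha: float = 0.01,
    lda_min: float = 3.0,
    wilcoxon_alpha: float = 0.05,
    n_boot: int = 30,
    seed: int = 0,
) -> LefseResult:
    """Run the three-gate biomarker procedure on a feature table.

    ``features``: samples x clade-features (relative abundances);
    ``groups``: group label per sample.  Constant features are skipped with
    a reported Kruskal–Wallis p of 1.
    """
    groups = groups.reindex(features.index)
    if groups.isna().any():
        raise ValueError("groups do not cover all samples")
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 3).any():
        raise ValueError("every group needs at least 3 samples")
    rng = np.random.default_rng(seed)

    rows, markers = [], []
    for clade in features.columns:
        vec = features[clade]
        by_group = [vec[groups == g].to_numpy() for g in labels]
        if np.ptp(vec.to_numpy()) == 0:
            rows.append({"clade": clade, "kw_p": 1.0, "group": None,
                         "consistent": False, "lda_score": np.nan})
            continue
        kw_p = stats.kruskal(*by_group).pvalue
        candidate = labels[int(np.argmax([v.mean() for v in by_group]))]
        row = {"clade": clade, "kw_p": float(kw_p), "group": candidate,
               "consistent": False, "lda_score": np.nan}
        if kw_p < kw_alpha:
            cand_vals = vec[groups == candidate].to_numpy()
            consistent = True
            for g in labels:
                if g == candidate:
                    continue
                other = vec[groups == g].to_numpy()
                p = stats.mannwhitneyu(cand_vals, other, alternative="greater").pvalue
                if p >= wilcoxon_alpha:
                    consistent = False
                    break
            row["consistent"] = consistent
            if consistent:
                score = lda_effect_size(
                    vec.to_numpy(), (groups == candidate).to_numpy(),
                    n_boot=n_boot, rng=rng,
                )
                row["lda_score"] = score
                if abs(score) > lda_min:
                    markers.append(
                        {"clade": clade, "rank": clade_rank(clade),
                         "group": candidate, "kw_p": float(kw_p), "lda_score": score}
                    )
        rows.append(row)
    biomarkers = pd.DataFrame(
        markers, columns=["clade", "rank", "group", "kw_p", "lda_score"]
    )
    return LefseResult(
        biomarkers=biomarkers, all_features=pd.DataFrame(rows).set_index("clade")
    )
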