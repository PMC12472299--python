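"""Biomarker stage: clade roll-up and the KW + Wilcoxon + LDA double gate.

Runs on the variable-selection dataset, where per-treatment trait optima
enrich different clades per group; the neutral kingdoms serve as the
negative control (no biomarkers expected).  Writes results/biomarkers/.
"""

import sys
from pathlib import Path

from litterome import diversity, io, lefse

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "biomarkers"
OUT.mkdir(parents=True, exist_ok=True)

for label, prefix in (("selection", "selection"), ("neutral-control", "bacteria")):
    metadata = io.read_metadata(BASE / "data" / f"{prefix}_metadata.csv")
    table = io.read_community(BASE / "data" / f"{prefix}_community.tsv", metadata=metadata)
    rarefied = diversity.rarefy(table, seed=SEED)
    features = lefse.build_clade_features(rarefied)
    result = lefse.lefse(features, rarefied.groups(), seed=SEED)
    result.biomarkers.to_csv(OUT / f"{label}_biomarkers.csv", index=False)
    print(f"{label}: {features.shape[1]} clade features -> "
          f"{len(result.biomarkers)} biomarkers (KW p<0.01, |LDA|>3.0)")
    if len(result.biomarkers):
        top = result.biomarkers.nlargest(3, "lda_score")
        for _, row in top.iterrows():
            print(f"  {row['clade']} ({row['rank']}) enriched in {row['group']}, "
                  f"LDA {row['lda_score']:.2f}")
print(f"tables under {OUT}")
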