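"""Substrate-quality metrics: mass loss, enzyme stoichiometry, FTIR indices.

Enzyme stoichiometry follows the log-ratio vector framework: with BG the
C-acquiring, NAG+LAP the N-acquiring and AP the P-acquiring activities,

    x = ln(BG) / ln(AP)           y = ln(BG) / ln(NAG + LAP)
    length = sqrt(x² + y²)        angle = degrees(atan2(y, x))

Vector length increases with microbial C limitation; angles above 45°
indicate P limitation, below 45° N limitation.

FTIR quality indices use relative areas of infrared absorption bands (RAISB):
Index I = (aromatic C=C + aromatic C–H) / aliphatic C–H tracks decomposition
extent; Index II = (aliphatic C–H + aromatic C=C + aromatic C–H) /
polysaccharide C–O tracks recalcitrance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StoichiometryVector",
    "QualityIndices",
    "mass_loss",
    "enzyme_vector_point",
    "vector_length",
    "vector_angle",
    "quality_indices",
    "stoichiometry_table",
    "indices_table",
]


@dataclass(frozen=True)
class StoichiometryVector:
    length: float  # dimensionless
    angle: float  # degrees


@dataclass(frozen=True)
class QualityIndices:
    index_I: float
    index_II: float


def mass_loss(initial_dry_mass: float, final_dry_mass: float) -> float:
    """Percentage reduction from the initial dry mass."""
    if initial_dry_mass <= 0:
        raise ValueError("initial dry mass must be positive")
    if final_dry_mass < 0 or final_dry_mass > initial_dry_mass:
        raise ValueError("final dry mass must lie in [0, initial]; mass gain is not modeled")
    return 100.0 * (initial_dry_mass - final_dry_mass) / initial_dry_mass


def enzyme_vector_point(bg: float, nag: float, lap: float, ap: float) -> tuple[float, float]:
    """The (x, y) log-ratio point underlying both length and angle.

    x = ln(BG)/ln(AP), y = ln(BG)/ln(NAG+LAP).  Activities must be positive;
    a denominator activity exactly 1 (ln = 0) is degenerate.
    """
    for name, v in (("BG", bg), ("NAG", nag), ("LAP", lap), ("AP", ap)):
        if v <= 0:
            raise ValueError(f"enzyme activity {name} must be positive, got {v}")
    ln_n = math.log(nag + lap)
    ln_p = math.log(ap)
    if ln_n == 0.0 or ln_p == 0.0:
        raise ValueError("degenerate input: ln(NAG+LAP) or ln(AP) is zero")
    return math.log(bg) / ln_p, math.log(bg) / ln_n


def vector_length(bg: float, nag: float, lap: float, ap: float) -> float:
    """Euclidean norm of the two enzyme log-ratios (degree of C limitation)."""
    x, y = enzyme_vector_point(bg, nag, lap, ap)
    return math.hypot(x, y)


def vector_angle(bg: float, nag: float, lap: float, ap: float) -> float:
    """Angle in degrees of the log-ratio point; >45° P-limited, <45° N-limited."""
    x, y = enzyme_vector_point(bg, nag, lap, ap)
    return math.degrees(math.atan2(y, x))


def quality_indices(
    polysaccharide_CO: float,
    aliphatic_CH: float,
    aromatic_CC: float,
    aromatic_CH: float,
) -> QualityIndices:
    """FTIR band-ratio indices of decomposition extent (I) and recalcitrance (II)."""
    for name, v in (
        ("polysaccharide_CO", polysaccharide_CO),
        ("aliphatic_CH", aliphatic_CH),
        ("aromatic_CC", aromatic_CC),
        ("aromatic_CH", aromatic_CH),
    ):
        if v <= 0:
            raise ValueError(f"band area {name} must be positive, got {v}")
    index_i = (aromatic_CC + aromatic_CH) / aliphatic_CH
    index_ii = (aliphatic_CH + aromatic_CC + aromatic_CH) / polysaccharide_CO
    return QualityIndices(index_I=index_i, index_II=index_ii)


# ---------------------------------------------------------------------------
# table-level wrappers
# ---------------------------------------------------------------------------

def stoichiometry_table(enzymes: pd.DataFrame) -> pd.DataFrame:
    """Per-sample vector length and angle from an enzyme activity table.

    Expects columns BG, NAG, LAP, AP (extra columns are ignored).
    """
    out = []
    for sid, row in enzymes.iterrows():
        out.append(
            {
                "sample_id": sid,
                "vector_length": vector_length(row["BG"], row["NAG"], row["LAP"], row["AP"]),
                "vector_angle": vector_angle(row["BG"], row["NAG"], row["LAP"], row["AP"]),
            }
        )
    result = pd.DataFrame(out).set_index("sample_id")
    result["limitation"] = np.where(result["vector_angle"] > 45.0, "P", "N")
    return result


def indices_table(bands: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Index I / Index II from an FTIR band-area table."""
    out = []
    for sid, row in bands.iterrows():
        qi = quality_indices(
            row["polysaccharide_CO"], row["aliphatic_CH"],
            row["aromatic_CC"], row["aromatic_CH"],
        )
        out.append({"sample_id": sid, "index_I": qi.index_I, "index_II": qi.index_II})
    return pd.DataFrame(out).set_index("sample_id")
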