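"""Expression-based functional support calls.

Two quantitative rules: (1) where a variant carrier's myocardial mRNA
level falls against the rest of the cohort (below the 25th percentile
supports a loss-of-expression effect, above the 75th a gain), and
(2) relative qPCR abundance by the 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMeasurement",
    "summarize_ct",
    "carrier_percentile",
    "ddct_fold_change",
]

LOW_PCTL = 25.0
HIGH_PCTL = 75.0


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    target_ct: float
    reference_ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("Ct cycles must be positive")


def summarize_ct(measurements: Sequence[CtMeasurement]) -> tuple[float, float]:
    """Replicate means of (target, reference) Ct."""
    if not measurements:
        raise ValueError("no Ct measurements")
    return (
        float(np.mean([m.target_ct for m in measurements])),
        float(np.mean([m.reference_ct for m in measurements])),
    )


def carrier_percentile(
    expr: pd.DataFrame, gene: str, carrier: str
) -> tuple[float, Optional[str]]:
    """Percentile rank of a carrier's expression against the remaining cohort.

    ``expr`` is genes x samples (scaled RPKM). The carrier is excluded from
    the reference distribution; ties take mid-ranks:
    ``100 * (#strictly_below + 0.5 * #ties) / (n - 1)``. Returns the
    percentile and a flag: ``"low"`` below the 25th, ``"high"`` above the
    75th, else ``None``.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    if carrier not in expr.columns:
        raise KeyError(f"sample {carrier!r} not in expression matrix")
    if expr.shape[1] < 4:
        raise ValueError("cohort too small for percentile placement (need >= 4 samples)")
    row = expr.loc[gene]
    value = float(row[carrier])
    others = row.drop(carrier).to_numpy(dtype=float)
    below = int(np.sum(others < value))
    ties = int(np.sum(others == value))
    pct = 100.0 * (below + 0.5 * ties) / len(others)
    flag = "low" if pct < LOW_PCTL else "high" if pct > HIGH_PCTL else None
    return pct, flag


def ddct_fold_change(
    case: tuple[float, float], control: tuple[float, float]
) -> float:
    """Relative abundance 2^-ddCt from (target, reference) Ct means.

    dCt = target - reference per group; ddCt = dCt_case - dCt_control.
    A one-cycle deficit halves apparent abundance.
    """
    dct_case = case[0] - case[1]
    dct_control = control[0] - control[1]
    return float(2.0 ** (-(dct_case - dct_control)))
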