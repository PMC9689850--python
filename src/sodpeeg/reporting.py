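"""Descriptive statistics over features and selection results.

One-way ANOVA group comparisons (the two-group case reduces to the
classical F = MSB/MSW with (k-1, N-k) degrees of freedom), [0,1]
display normalization, and the occurrence statistics of selected
features across optimization trials: how often each feature enters the
best mask, and how the selected bits distribute over frequency bands.
Significance is reported at p < 0.01 (two-sided), with no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .selection import SelectionResult
from .sodp_features import GEO_FEATURE_NAMES

__all__ = [
    "anova_oneway",
    "normalize01",
    "key_feature_frequency",
    "band_contribution",
]

P_SIGNIFICANT = 0.01


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    ``F = MSB / MSW`` with ``(k - 1, N - k)`` degrees of freedom.  When
    the within-group variance vanishes and the group means agree, F is
    defined as 0 (identical groups carry no evidence of a difference).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("anova_oneway needs >= 2 groups with >= 2 values each")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def normalize01(values: Sequence[float]) -> np.ndarray:
    """Affine map of ``values`` onto [0, 1]; a constant input maps to 0.

    Display-only convenience (feature plots); never used in the
    classification path.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class OccurrenceTable:
    """Per-feature selection frequencies across the trials of one result."""

    bands: tuple[str, ...]
    n_trials: int
    #: (bands*10,) fraction of trials whose best mask set each bit
    fractions: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, frac in enumerate(self.fractions):
            rows.append(
                {
                    "band": self.bands[i // 10],
                    "feature": GEO_FEATURE_NAMES[i % 10],
                    "fraction": float(frac),
                }
            )
        return pd.DataFrame(rows)

    def top_k(self, k: int = 4) -> pd.DataFrame:
        """Top ``k`` most frequently selected features per band."""
        frame = self.as_frame()
        return (
            frame.sort_values(["band", "fraction"], ascending=[True, False], kind="stable")
            .groupby("band", sort=False)
            .head(k)
            .reset_index(drop=True)
        )


def key_feature_frequency(result: SelectionResult) -> OccurrenceTable:
    """Fraction of trials in which each feature entered the best mask."""
    if not result.trial_masks:
        raise ValueError("result holds no trials")
    bits = np.array([m.bits for m in result.trial_masks], dtype=float)
    return OccurrenceTable(
        bands=result.bands,
        n_trials=len(result.trial_masks),
        fractions=bits.mean(axis=0),
    )


def band_contribution(result: SelectionResult) -> dict[str, float]:
    """Share (percent) of all selected bits falling in each band.

    Pooled over trials; the shares sum to 100 whenever any bit was
    selected at all.
    """
    counts = {band: 0 for band in result.bands}
    total = 0
    for mask in result.trial_masks:
        for i, bit in enumerate(mask.bits):
            if bit:
                counts[result.bands[i // 10]] += 1
                total += 1
    if total == 0:
        return {band: 0.0 for band in result.bands}
    return {band: 100.0 * c / total for band, c in counts.items()}
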