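"""Between-sample similarity index from shared-subcluster composition.

Two tumors of one patient are jointly clustered; each sample's fractional
abundance over the joint subclusters forms a composition vector, and the
similarity index is SI = sum_k min(a_k, b_k), equivalently 1 minus half the
L1 distance. SI < 0.35 is low and SI > 0.67 high, with the band between
intermediate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOW_BAND = 0.35
HIGH_BAND = 0.67


def _check_composition(v: np.ndarray, name: str) -> None:
    if (v < 0).any():
        raise ValueError(f"{name}: fractions must be non-negative")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name}: fractions must sum to 1 (got {v.sum()})")


def similarity_index(a, b) -> float:
    """SI = sum of the minimal fractional abundance per joint subcluster."""
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if set(a.index) != set(b.index):
            raise ValueError("composition vectors use different subcluster sets")
        b = b.reindex(a.index)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("composition vectors use different subcluster sets")
    _check_composition(a, "a")
    _check_composition(b, "b")
    return float(np.minimum(a, b).sum())


def classify_si(si: float) -> str:
    """Band label: low below 0.35, high above 0.67, else intermediate."""
    if not (0.0 <= si <= 1.0):
        raise ValueError(f"SI must lie in [0, 1], got {si}")
    if si < LOW_BAND:
        return "low"
    if si > HIGH_BAND:
        return "high"
    return "intermediate"


def composition_vectors(labels: pd.Series, samples: pd.Series) -> pd.DataFrame:
    """Per-sample fractional abundance over joint clusters (rows sum to 1)."""
    tab = pd.crosstab(samples, labels)
    return tab.div(tab.sum(axis=1), axis=0)


def pairwise_si(labels: pd.Series, samples: pd.Series) -> pd.DataFrame:
    """SI matrix (with band labels accessible via classify_si) for a cohort."""
    comp = composition_vectors(labels, samples)
    ids = list(comp.index)
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            si = similarity_index(comp.loc[a], comp.loc[ids[j]])
            out.iloc[i, j] = out.iloc[j, i] = si
    return out
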