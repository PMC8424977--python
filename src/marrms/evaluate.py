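"""Aggregate per-pair reproducibility calls into study-level summaries.

A layer's results form an M x J binary matrix: rows are metabolites, columns
are replicate sample pairs, entries are the per-pair MaRR calls. Data-driven
filtering then flags a metabolite reproducible when strictly more than a
fraction c_s of its pairs call it so, and a pair reproducible when strictly
more than a fraction c_m of metabolites are called within it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReproMatrix",
    "FilterThresholds",
    "metabolite_reproducibility",
    "pair_reproducibility",
    "summary_table",
    "histogram_data",
    "subset_reproducible",
]


@dataclass
class ReproMatrix:
    """M x J binary matrix of reproducibility calls for one design layer."""

    calls: pd.DataFrame  # index metabolite ids, columns pair ids, values 0/1
    layer: str = ""

    def __post_init__(self) -> None:
        x = self.calls.to_numpy()
        if not np.isin(x, (0, 1)).all():
            raise ValueError("call matrix entries must be 0 or 1")

    @property
    def m_features(self) -> int:
        return int(self.calls.shape[0])

    @property
    def n_pairs(self) -> int:
        return int(self.calls.shape[1])


@dataclass(frozen=True)
class FilterThresholds:
    """User cut-offs c_s (per metabolite) and c_m (per pair), both in (0,1)."""

    c_s: float = 0.7
    c_m: float = 0.7

    def __post_init__(self) -> None:
        for name, v in (("c_s", self.c_s), ("c_m", self.c_m)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")


def metabolite_reproducibility(matrix: ReproMatrix, c_s: float) -> pd.Series:
    """Flag metabolite m iff its reproducible-pair fraction strictly exceeds c_s."""
    if matrix.n_pairs < 1:
        raise ValueError("need at least one pair")
    frac = matrix.calls.mean(axis=1)
    return (frac > c_s).astype(np.int8)


def pair_reproducibility(matrix: ReproMatrix, c_m: float) -> pd.Series:
    """Flag pair (i,i') iff its reproducible-metabolite fraction strictly exceeds c_m."""
    if matrix.m_features < 1:
        raise ValueError("need at least one metabolite")
    frac = matrix.calls.mean(axis=0)
    return (frac > c_m).astype(np.int8)


def summary_table(
    matrix: ReproMatrix, thresholds: tuple[float, ...] = (0.7, 0.8, 0.9)
) -> pd.DataFrame:
    """Percent of pairs / metabolites exceeding each reproducibility threshold.

    For each threshold t the table reports the percentage of sample pairs
    whose reproducible-metabolite fraction strictly exceeds t, and the
    percentage of metabolites whose reproducible-pair fraction strictly
    exceeds t, both rounded to two decimals.
    """
    pair_frac = matrix.calls.mean(axis=0)
    met_frac = matrix.calls.mean(axis=1)
    rows = {}
    for t in thresholds:
        rows[f">{int(round(t * 100))}%"] = {
            "pct_pairs": round(float((pair_frac > t).mean() * 100), 2),
            "pct_metabolites": round(float((met_frac > t).mean() * 100), 2),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "threshold"
    return out


def histogram_data(
    matrix: ReproMatrix, margin: str = "pairs", n_bins: int = 20
) -> dict:
    """Percent-scale reproducibility fractions plus fixed-width bin counts.

    ``margin='pairs'`` summarises each sample pair by its percent of
    reproducible metabolites; ``margin='metabolites'`` summarises each
    metabolite by its percent of reproducible pairs. Bins cover [0, 100].
    """
    if margin == "pairs":
        pct = matrix.calls.mean(axis=0) * 100
    elif margin == "metabolites":
        pct = matrix.calls.mean(axis=1) * 100
    else:
        raise ValueError("margin must be 'pairs' or 'metabolites'")
    edges = np.linspace(0, 100, n_bins + 1)
    counts, _ = np.histogram(pct.to_numpy(), bins=edges)
    return {
        "margin": margin,
        "unit_ids": pct.index.astype(str).tolist(),
        "percent": pct.round(6).tolist(),
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }


def subset_reproducible(
    values: pd.DataFrame, matrix: ReproMatrix, c_s: float
) -> pd.DataFrame:
    """Restrict an abundance matrix to metabolites flagged reproducible."""
    flags = metabolite_reproducibility(matrix, c_s)
    keep = flags.index[flags.astype(bool)]
    return values.loc[values.index.intersection(keep)]
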