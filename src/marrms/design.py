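"""Nested replicate study designs and abundance tables.

MS-metabolomics experiments are often hierarchical: e.g. batch operators at
the top, spike-in controls in the middle, technical replicates at the bottom.
This module represents such strictly nested D-layer designs, enumerates the
within-group replicate pairs that reproducibility is assessed on, and pools
(sums) abundances over lower layers so that upper-layer units can be
compared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LayerDesign",
    "AbundanceTable",
    "ReplicatePair",
    "enumerate_pairs",
    "count_pairs",
    "pool_lower_layers",
]


@dataclass(frozen=True)
class LayerDesign:
    """A strictly nested design: layer_names ordered top -> bottom."""

    layer_names: tuple[str, ...]
    level_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_names", tuple(self.layer_names))
        object.__setattr__(self, "level_counts", tuple(self.level_counts))
        if len(self.layer_names) < 1:
            raise ValueError("a design needs at least one layer")
        if len(self.layer_names) != len(self.level_counts):
            raise ValueError("layer_names and level_counts differ in length")
        if any(c < 1 for c in self.level_counts):
            raise ValueError("every layer needs at least one level")

    @property
    def depth(self) -> int:
        return len(self.layer_names)

    @property
    def n_samples(self) -> int:
        return int(np.prod(self.level_counts))


@dataclass
class AbundanceTable:
    """Features x samples abundance matrix with per-sample layer coordinates.

    ``values`` is a DataFrame with feature ids as the index and sample ids as
    columns (missing entries as NaN); ``coordinates`` is indexed by sample id
    with one column per design layer, top layer first.
    """

    values: pd.DataFrame
    coordinates: pd.DataFrame

    def __post_init__(self) -> None:
        v, c = self.values, self.coordinates
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in abundance matrix")
        missing = v.columns.difference(c.index)
        if len(missing):
            raise ValueError(
                f"samples absent from metadata: {missing.tolist()[:5]}"
            )
        extra = c.index.difference(v.columns)
        if len(extra):
            raise ValueError(
                f"metadata samples absent from matrix: {extra.tolist()[:5]}"
            )
        self.coordinates = c.loc[v.columns]
        if self.coordinates.apply(tuple, axis=1).duplicated().any():
            raise ValueError("two samples share identical layer coordinates")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def layers(self) -> list[str]:
        return list(self.coordinates.columns)

    @property
    def m_features(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])

    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())


@dataclass(frozen=True)
class ReplicatePair:
    """An unordered pair of samples compared within one upper-layer group."""

    group: tuple
    sample_a: str
    sample_b: str

    @property
    def pair_id(self) -> str:
        return f"{self.sample_a}|{self.sample_b}"


def _upper_layers(table: AbundanceTable, layer: str) -> list[str]:
    layers = table.layers
    if layer not in layers:
        raise KeyError(f"unknown layer {layer!r}; design layers: {layers}")
    return layers[: layers.index(layer)]


def enumerate_pairs(table: AbundanceTable, layer: str) -> list[ReplicatePair]:
    """All C(n, 2) replicate pairs at ``layer`` within each upper-layer group.

    Samples are grouped by their coordinates on the layers above ``layer``;
    within each group every unordered pair of units is returned, giving
    J = sum over groups of C(n_group, 2) pairs in total.
    """
    upper = _upper_layers(table, layer)
    coords = table.coordinates
    if upper:
        groups = coords.groupby(upper, sort=True, observed=True).groups
    else:
        groups = {(): coords.index}
    pairs: list[ReplicatePair] = []
    for key, samples in sorted(groups.items(), key=lambda kv: str(kv[0])):
        key_t = key if isinstance(key, tuple) else (key,)
        ids = sorted(map(str, samples))
        if len(ids) < 2:
            raise ValueError(
                f"group {key_t} has a single unit at layer {layer!r}; "
                "pairing needs >= 2 replicates — pool lower layers instead"
            )
        for a, b in itertools.combinations(ids, 2):
            pairs.append(ReplicatePair(group=key_t, sample_a=a, sample_b=b))
    return pairs


def count_pairs(table: AbundanceTable, layer: str) -> int:
    """Closed-form pair count sum_groups C(n, 2) without materialising pairs."""
    upper = _upper_layers(table, layer)
    coords = table.coordinates
    if upper:
        sizes = coords.groupby(upper, observed=True).size().to_numpy()
    else:
        sizes = np.array([len(coords)])
    return int((sizes * (sizes - 1) // 2).sum())


def pool_lower_layers(table: AbundanceTable, target_layer: str) -> AbundanceTable:
    """Sum abundances over all samples below each unit of ``target_layer``.

    Produces one pooled sample per combination of coordinates on the layers
    at and above ``target_layer``; layers below it are dropped. Pooling
    requires complete data (impute first), since a missing entry would make
    the sum undefined.
    """
    if table.has_missing():
        raise ValueError("pooling requires complete data; impute first")
    upper = _upper_layers(table, target_layer)
    keep = upper + [target_layer]
    coords = table.coordinates
    key = coords[keep].astype(str).agg("/".join, axis=1)
    pooled = table.values.T.groupby(key, sort=True).sum().T
    new_coords = (
        coords[keep]
        .astype(str)
        .assign(__key=key)
        .drop_duplicates()
        .set_index("__key")
        .rename_axis(index=None)
        .loc[pooled.columns]
    )
    return AbundanceTable(values=pooled, coordinates=new_coords)
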