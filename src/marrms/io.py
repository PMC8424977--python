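"""Reading and writing abundance tables, metadata, and synthetic fixtures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import AbundanceTable, LayerDesign

__all__ = [
    "read_abundance",
    "write_abundance",
    "generate_fixture",
]

_NA_VALUES = ["", "NA"]


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_abundance(path, metadata_path) -> AbundanceTable:
    """Load a features x samples matrix plus its sample metadata.

    The matrix is delimited text (TSV/CSV by extension) with a header row of
    sample ids and feature ids in the first column; empty cells and "NA" are
    missing. Metadata has a ``sample_id`` column plus one column per design
    layer. Sample ids must match exactly between the two files.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    values = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=_NA_VALUES,
        keep_default_na=False,
    )
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    non_numeric = values.dtypes[
        ~values.dtypes.apply(pd.api.types.is_numeric_dtype)
    ]
    if len(non_numeric):
        col = non_numeric.index[0]
        raise ValueError(
            f"non-numeric cells in sample column {col!r} of {path.name}"
        )
    meta = pd.read_csv(
        metadata_path,
        sep=_sep_for(metadata_path),
        na_values=_NA_VALUES,
        keep_default_na=False,
        dtype=str,
    )
    if "sample_id" not in meta.columns:
        raise ValueError(f"{metadata_path.name} lacks a 'sample_id' column")
    meta = meta.set_index("sample_id")
    missing = values.columns.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"metadata is missing sample ids: {missing.tolist()[:5]}"
        )
    return AbundanceTable(values=values, coordinates=meta.loc[values.columns])


def write_abundance(table: AbundanceTable, path, metadata_path=None) -> None:
    """Write a table (and optionally its metadata) as delimited text."""
    path = Path(path)
    table.values.to_csv(path, sep=_sep_for(path), na_rep="NA")
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        out = table.coordinates.copy()
        out.index.name = "sample_id"
        out.to_csv(metadata_path, sep=_sep_for(metadata_path))


def generate_fixture(
    design: LayerDesign,
    n_features: int = 200,
    pi1: float = 0.75,
    mu_r: float = 4.13,
    sigma_r: float = 0.17,
    rho_r: float = 0.99,
    mu_ir: float = 3.2,
    sigma_ir: float = 0.05,
    missing_fraction: float = 0.0,
    seed: int | None = None,
    out_dir=None,
    prefix: str = "fixture",
) -> tuple[AbundanceTable, pd.Series]:
    """Synthesise a nested-design abundance table with planted truth.

    Reproducible features share an equicorrelated signal across all samples
    (pairwise correlation ``rho_r`` around mean ``mu_r``); irreproducible
    features are drawn independently per sample at a lower mean. Values are
    exponentiated (base 2) so they look like raw positive abundances and are
    suitable for the full filter/impute/normalize/log pipeline. Optionally a
    completely-at-random fraction of cells is blanked.

    Returns the table and a 0/1 truth series; when ``out_dir`` is given the
    matrix, metadata, and truth are also written as ``<prefix>_*.csv``.
    """
    rng = np.random.default_rng(seed)
    coords = pd.DataFrame(
        [
            {
                design.layer_names[d]: f"{design.layer_names[d][:2]}{ix + 1}"
                for d, ix in enumerate(combo)
            }
            for combo in np.ndindex(*design.level_counts)
        ]
    )
    coords.index = pd.Index(
        ["s" + "_".join(row) for row in coords.to_numpy()], name="sample_id"
    )
    n_samples = len(coords)
    k = int(round(pi1 * n_features))
    # equicorrelated draws: z shared per feature, e idiosyncratic per sample
    z = rng.standard_normal((k, 1))
    e = rng.standard_normal((k, n_samples))
    rep = mu_r + sigma_r * (
        np.sqrt(rho_r) * z + np.sqrt(1.0 - rho_r) * e
    )
    irr = rng.normal(mu_ir, sigma_ir, size=(n_features - k, n_samples))
    log_values = np.vstack([rep, irr])
    values = np.power(2.0, log_values)
    if missing_fraction > 0:
        blank = rng.random(values.shape) < missing_fraction
        values = np.where(blank, np.nan, values)
    feature_ids = [f"met{i + 1}" for i in range(n_features)]
    table = AbundanceTable(
        values=pd.DataFrame(values, index=feature_ids, columns=coords.index),
        coordinates=coords,
    )
    truth = pd.Series(
        np.r_[np.ones(k, dtype=np.int8), np.zeros(n_features - k, dtype=np.int8)],
        index=feature_ids,
        name="reproducible",
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_abundance(
            table,
            out_dir / f"{prefix}_abundance.csv",
            out_dir / f"{prefix}_metadata.csv",
        )
        truth.rename_axis("feature_id").to_csv(out_dir / f"{prefix}_truth.csv")
    return table, truth
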