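"""End-to-end data-driven reproducibility pipeline.

Order of operations: filter -> impute -> normalize -> (pool per layer) ->
log transform -> pairwise MaRR per layer -> reproducibility matrix ->
data-driven filtering and summaries -> subset of reproducible features.
Pooling happens on the normalized (pre-log) scale; every tie-break seed is
derived deterministically from the master seed and the pair identity so a
run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import AbundanceTable, enumerate_pairs, pool_lower_layers
from .evaluate import (
    ReproMatrix,
    histogram_data,
    metabolite_reproducibility,
    pair_reproducibility,
    subset_reproducible,
    summary_table,
)
from .marr import marr_pair
from .preprocess import PreprocessConfig, log_transform, preprocess

__all__ = ["RunConfig", "LayerResult", "pair_tie_seed", "run_layer", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All user-settable knobs of a pipeline run."""

    preprocess: PreprocessConfig = PreprocessConfig()
    alpha: float = 0.01
    lam: float = 0.9
    c_s: float = 0.7
    c_m: float = 0.7
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        for name, v in (("c_s", self.c_s), ("c_m", self.c_m)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1)")


@dataclass
class LayerResult:
    """Per-layer outputs: call matrix, per-pair estimates, summaries."""

    layer: str
    matrix: ReproMatrix
    pair_stats: pd.DataFrame  # pi1_hat, k_hat, n_hat, n_calls per pair
    summary: pd.DataFrame
    metabolite_flags: pd.Series
    pair_flags: pd.Series


def pair_tie_seed(master_seed: int, pair_id: str) -> int:
    """Deterministic per-pair tie-break seed below 2^31."""
    h = zlib.crc32(pair_id.encode())
    ss = np.random.SeedSequence([int(master_seed), h])
    return int(ss.generate_state(1)[0] % (2**31))


def run_layer(
    table: AbundanceTable, layer: str, config: RunConfig
) -> LayerResult:
    """Pairwise MaRR at one design layer of a complete, log-scale table."""
    pairs = enumerate_pairs(table, layer)
    x = table.values
    calls = {}
    stats_rows = []
    for pair in pairs:
        res = marr_pair(
            x[pair.sample_a].to_numpy(),
            x[pair.sample_b].to_numpy(),
            alpha=config.alpha,
            lam=config.lam,
            tie_seed=pair_tie_seed(config.master_seed, pair.pair_id),
            pair_id=(pair.sample_a, pair.sample_b),
        )
        calls[pair.pair_id] = res.calls
        stats_rows.append(
            {
                "pair_id": pair.pair_id,
                "group": "/".join(map(str, pair.group)),
                "k_hat": res.pi1.k_hat,
                "pi1_hat": res.pi1.pi1_hat,
                "n_hat": res.n_hat,
                "n_calls": res.n_reproducible,
            }
        )
    matrix = ReproMatrix(
        calls=pd.DataFrame(calls, index=table.feature_ids, dtype=np.int8),
        layer=layer,
    )
    return LayerResult(
        layer=layer,
        matrix=matrix,
        pair_stats=pd.DataFrame(stats_rows).set_index("pair_id"),
        summary=summary_table(matrix),
        metabolite_flags=metabolite_reproducibility(matrix, config.c_s),
        pair_flags=pair_reproducibility(matrix, config.c_m),
    )


def run_pipeline(
    table: AbundanceTable,
    config: RunConfig = RunConfig(),
    layers: list[str] | None = None,
    runday: pd.Series | None = None,
    out_dir=None,
) -> dict[str, LayerResult]:
    """Preprocess a table and assess reproducibility at each design layer.

    The bottom layer is analysed on the preprocessed per-sample table; each
    upper layer is analysed after pooling (summing) all samples beneath its
    units. When ``out_dir`` is given, every artifact is written there: the
    call matrix, per-margin flags, the threshold summary table, histogram
    JSON, the reproducible-feature subset, and a plain-text log with stage
    counts and the master seed.
    """
    log_lines: list[str] = []
    say = log_lines.append
    say(f"marrms {__version__} | master_seed={config.master_seed}")
    say(
        f"alpha={config.alpha} lambda={config.lam} "
        f"c_s={config.c_s} c_m={config.c_m}"
    )
    pp = PreprocessConfig(
        **{
            **config.preprocess.__dict__,
            "log_transform": False,  # defer: pooling happens pre-log
        }
    )
    clean = preprocess(table, pp, runday=runday, log=say)
    layers = layers or clean.layers
    results: dict[str, LayerResult] = {}
    for layer in reversed(layers):  # bottom layer first
        layer_table = clean
        if layer != clean.layers[-1]:
            layer_table = pool_lower_layers(clean, layer)
            say(
                f"pool -> layer {layer!r}: {layer_table.n_samples} pooled samples"
            )
        if config.preprocess.log_transform:
            layer_table = log_transform(
                layer_table, config.preprocess.log_base
            )
        result = run_layer(layer_table, layer, config)
        results[layer] = result
        say(
            f"layer {layer!r}: {result.matrix.n_pairs} pairs, "
            f"median pi1_hat={result.pair_stats.pi1_hat.median():.3f}, "
            f"{int(result.metabolite_flags.sum())} reproducible features "
            f"(c_s={config.c_s}), {int(result.pair_flags.sum())} reproducible "
            f"pairs (c_m={config.c_m})"
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for layer, res in results.items():
            stem = out_dir / f"layer_{layer}"
            res.matrix.calls.rename_axis("feature_id").to_csv(
                f"{stem}_calls.csv"
            )
            res.pair_stats.to_csv(f"{stem}_pairs.csv")
            res.summary.to_csv(f"{stem}_summary.csv")
            res.metabolite_flags.rename("reproducible").rename_axis(
                "feature_id"
            ).to_csv(f"{stem}_metabolite_flags.csv")
            res.pair_flags.rename("reproducible").rename_axis(
                "pair_id"
            ).to_csv(f"{stem}_pair_flags.csv")
            hist = {
                margin: histogram_data(res.matrix, margin)
                for margin in ("pairs", "metabolites")
            }
            Path(f"{stem}_histograms.json").write_text(
                json.dumps(hist, indent=1)
            )
            subset = subset_reproducible(clean.values, res.matrix, config.c_s)
            subset.to_csv(f"{stem}_reproducible_subset.csv")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
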