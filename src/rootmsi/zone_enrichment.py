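"""Meristem-vs-differentiation expression enrichment from a zone FPKM table.

Root zonation RNA-seq quantifies each gene's expression (FPKM) separately
in the meristem, elongation zone and differentiation zone. A gene's
meristem enrichment is the ratio of its average transformed expression,
log10(3 x FPKM), in the meristem to that in the differentiation zone;
values above 1 mark meristem-enriched biosynthesis. The transform floors
FPKM at 1/3 so that absent genes map to exactly 0 and the log never takes a
non-positive argument; a raw-FPKM ratio mode is available since the ratio
of logs and the log of ratios are materially different conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ZONES",
    "EnrichmentScore",
    "load_expression_table",
    "transform_expression",
    "enrichment",
    "enrichment_table",
]

ZONES = ("meristem", "elongation", "differentiation")
DEFAULT_FLOOR_FPKM = 1.0 / 3.0


def load_expression_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a delimited zone x gene FPKM table.

    Expected columns: gene_id, zone (meristem | elongation |
    differentiation), replicate, fpkm. (gene_id, zone, replicate) must be
    unique and FPKM non-negative.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    return validate_expression_table(table)


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "zone", "replicate", "fpkm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    bad_zones = set(table["zone"]) - set(ZONES)
    if bad_zones:
        raise ValueError(f"unknown zones {sorted(bad_zones)}; expected {ZONES}")
    if (table["fpkm"] < 0).any():
        raise ValueError("negative FPKM values")
    dup = table.duplicated(subset=["gene_id", "zone", "replicate"])
    if dup.any():
        raise ValueError(
            f"duplicate (gene_id, zone, replicate) rows: {table[dup].head()}"
        )
    return table


def transform_expression(
    fpkm, floor_fpkm: float = DEFAULT_FLOOR_FPKM, base: float = 10.0
):
    """log(3 x max(FPKM, floor)) in the given base (default log10, floor 1/3
    so the transformed floor is exactly 0). Accepts scalars or arrays."""
    arr = np.asarray(fpkm, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("FPKM must be non-negative")
    out = np.log(3.0 * np.maximum(arr, floor_fpkm)) / math.log(base)
    return float(out) if np.isscalar(fpkm) or arr.ndim == 0 else out


@dataclass(frozen=True)
class EnrichmentScore:
    """Meristem/differentiation expression ratio for one gene."""

    gene_id: str
    meristem_expr: float
    differentiation_expr: float
    enrichment: float
    undefined: bool = False


def enrichment(
    table: pd.DataFrame,
    gene: str,
    transformed: bool = True,
    floor_fpkm: float = DEFAULT_FLOOR_FPKM,
    base: float = 10.0,
) -> EnrichmentScore:
    """Average expression per zone for one gene, then meristem /
    differentiation.

    With ``transformed=True`` (default) the ratio is taken on
    log(3 x FPKM)-transformed replicate values; ``transformed=False`` uses
    raw FPKM means. A zero differentiation-zone mean flags the score
    undefined (enrichment NaN) rather than raising.
    """
    rows = table[table["gene_id"] == gene]
    means = {}
    for zone in ("meristem", "differentiation"):
        vals = rows.loc[rows["zone"] == zone, "fpkm"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"gene {gene!r} has no replicates in zone {zone!r}")
        if transformed:
            vals = transform_expression(vals, floor_fpkm=floor_fpkm, base=base)
        means[zone] = float(np.mean(vals))
    m, d = means["meristem"], means["differentiation"]
    if d == 0:
        return EnrichmentScore(gene, m, d, float("nan"), undefined=True)
    return EnrichmentScore(gene, m, d, m / d)


def enrichment_table(
    table: pd.DataFrame,
    genes: Iterable[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Enrichment scores for a gene list (default: every gene in the table)."""
    if genes is None:
        genes = sorted(table["gene_id"].unique())
    scores = [enrichment(table, g, **kwargs) for g in genes]
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "meristem_expr": [s.meristem_expr for s in scores],
            "differentiation_expr": [s.differentiation_expr for s in scores],
            "enrichment": [s.enrichment for s in scores],
            "undefined": [s.undefined for s in scores],
        }
    )
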