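"""Positionally weighted average poly(A) site (wPAS).

Most genes use several poly(A) addition sites; anchoring 3'-end metagenes on
any single site blurs the aggregate. The wPAS of a gene is the
intensity-weighted mean of its site positions,

    wPAS = sum_i pos_i * w_i / sum_i w_i ,

with raw intensities used as weights. The anchor coordinate is the wPAS
rounded half away from zero to the nearest integer position.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model import CracflowError, PolyASiteTable

WPAS_COLUMNS = ("gene_id", "wpas_real", "wpas_anchor", "n_sites", "total_weight")


def round_half_away(x: float) -> float:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def compute_wpas(pa_table: PolyASiteTable) -> pd.DataFrame:
    """Weighted-average poly(A) site per gene.

    Returns a DataFrame indexed by gene_id with columns wpas_real,
    wpas_anchor, n_sites and total_weight. Raises on zero total weight or a
    negative weight (naming the gene).
    """
    rows = []
    for gene_id, sites in pa_table.sites.items():
        pos = np.array([p for p, _ in sites], dtype=float)
        w = np.array([wt for _, wt in sites], dtype=float)
        if np.any(w < 0):
            raise CracflowError(f"gene {gene_id!r}: negative poly(A) weight")
        total = float(w.sum())
        if total <= 0:
            raise CracflowError(f"gene {gene_id!r}: total poly(A) weight is zero")
        real = float((pos * w).sum() / total)
        rows.append({
            "gene_id": gene_id,
            "wpas_real": real,
            "wpas_anchor": int(round_half_away(real)),
            "n_sites": len(sites),
            "total_weight": total,
        })
    return pd.DataFrame(rows, columns=list(WPAS_COLUMNS)).set_index("gene_id")
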