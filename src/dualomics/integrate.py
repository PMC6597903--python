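"""Dual-omics integration: compression correction and the significance cascade.

The two layers and two timepoints are merged into one gene-level table by a
strict significance-priority cascade: if a gene's protein is significantly
differential at 35 DIV that row is used; otherwise the 56 DIV protein row if
significant; otherwise the 35 DIV RNA row if significant; otherwise the 56 DIV
RNA row if significant. Protein-sourced log2 fold changes are multiplied by the
ratio-compression correction factor (default 1.4) to compensate for TMT
reporter-ion compression. Genes significant nowhere are either excluded or
carried through from the RNA layer (flagged non-significant) so enrichment has
a defined gene universe.

Significance in the cascade means FDR-adjusted p below ``alpha`` (RNA rows must
also pass the detection filter); the fold-change gate applies only to the
enrichment input signature, selected by :func:`signature_filter`.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .core import PROTEIN, RNA
from .errors import ConsistencyError, ValidationError

logger = logging.getLogger(__name__)

#: cascade priority: (layer, timepoint), highest first
CASCADE_PRIORITY = ((PROTEIN, 35), (PROTEIN, 56), (RNA, 35), (RNA, 56))

#: fallback carry order when no source is significant
FALLBACK_ORDER = ((RNA, 35), (RNA, 56), (PROTEIN, 35), (PROTEIN, 56))

INTEGRATED_COLUMNS = (
    "gene_symbol",
    "source_layer",
    "source_timepoint",
    "log2fc_integrated",
    "p_adj_integrated",
    "significant_any",
    "in_signature",
    "direction",
)


def compression_correct(log2fc_protein, factor: float = 1.4):
    """Rescale a protein-layer log2 fold change by the compression factor.

    TMT reporter ratios underestimate true fold changes; multiplying the log2
    fold change by ``factor`` (default 1.4) restores the attenuated effect.
    Exactly linear and sign-preserving.
    """
    if factor <= 0:
        raise ValidationError(f"compression factor must be > 0, got {factor}")
    arr = np.asarray(log2fc_protein, dtype=float) * factor
    return float(arr) if np.isscalar(log2fc_protein) else arr


def _prep(table: pd.DataFrame, layer: str, timepoint: int) -> pd.DataFrame:
    t = table[(table["layer"] == layer) & (table["timepoint"] == int(timepoint))]
    if t.empty:
        t = table
    sym = t["feature"].astype(str).str.upper()
    if sym.duplicated().any():
        dups = sorted(sym[sym.duplicated()].unique()[:5])
        raise ConsistencyError(
            f"duplicate gene symbols in {layer}/{timepoint} table: {dups}"
        )
    out = t.set_index(pd.Index(sym, name="gene_symbol"))[["log2fc", "p_adj", "detected"]]
    return out


def cascade_merge(
    prot35: pd.DataFrame,
    prot56: pd.DataFrame,
    rna35: pd.DataFrame,
    rna56: pd.DataFrame,
    alpha: float = 0.05,
    fallback: str = "carry_gene35",
    factor: float = 1.4,
) -> pd.DataFrame:
    """Merge the four differential tables by significance priority.

    Returns one row per gene symbol with the chosen source's (corrected) log2
    fold change and adjusted p. ``fallback`` handles genes significant in no
    table: ``"carry_gene35"`` keeps them (sourced from the first table that
    quantified them, in RNA-35-first order, with ``significant_any = False``);
    ``"exclude"`` drops them.
    """
    if fallback not in ("carry_gene35", "exclude"):
        raise ValidationError(f"unknown fallback mode {fallback!r}")
    tables = {
        (PROTEIN, 35): _prep(prot35, PROTEIN, 35),
        (PROTEIN, 56): _prep(prot56, PROTEIN, 56),
        (RNA, 35): _prep(rna35, RNA, 35),
        (RNA, 56): _prep(rna56, RNA, 56),
    }
    universe = sorted(set().union(*(t.index for t in tables.values())))
    idx = pd.Index(universe, name="gene_symbol")

    aligned = {}
    for key, t in tables.items():
        a = t.reindex(idx)
        n_missing = int(a["log2fc"].isna().sum())
        if n_missing:
            logger.info(
                "%s/%s table missing %d of %d symbols (treated as non-significant)",
                key[0], key[1], n_missing, len(idx),
            )
        sig = (a["p_adj"] < alpha).fillna(False).to_numpy()
        if key[0] == RNA:
            det = a["detected"].to_numpy()
            sig &= np.array([bool(v) and v == v for v in det])
        aligned[key] = (a, sig)

    n = len(idx)
    chosen_layer = np.full(n, None, dtype=object)
    chosen_tp = np.zeros(n, dtype=int)
    lfc = np.full(n, np.nan)
    padj = np.full(n, np.nan)
    sig_any = np.zeros(n, dtype=bool)

    unassigned = np.ones(n, dtype=bool)
    for layer, tp in CASCADE_PRIORITY:
        a, sig = aligned[(layer, tp)]
        take = unassigned & sig
        if not take.any():
            continue
        chosen_layer[take] = layer
        chosen_tp[take] = tp
        val = a["log2fc"].to_numpy()[take]
        lfc[take] = compression_correct(val, factor) if layer == PROTEIN else val
        padj[take] = a["p_adj"].to_numpy()[take]
        sig_any[take] = True
        unassigned &= ~take

    if fallback == "carry_gene35":
        still = unassigned.copy()
        for layer, tp in FALLBACK_ORDER:
            a, _ = aligned[(layer, tp)]
            present = a["log2fc"].notna().to_numpy()
            take = still & present
            if not take.any():
                continue
            chosen_layer[take] = layer
            chosen_tp[take] = tp
            val = a["log2fc"].to_numpy()[take]
            lfc[take] = compression_correct(val, factor) if layer == PROTEIN else val
            padj[take] = a["p_adj"].to_numpy()[take]
            still &= ~take
        keep = np.ones(n, dtype=bool)
    else:
        keep = sig_any

    out = pd.DataFrame(
        {
            "gene_symbol": np.asarray(universe, dtype=object)[keep],
            "source_layer": chosen_layer[keep],
            "source_timepoint": chosen_tp[keep],
            "log2fc_integrated": lfc[keep],
            "p_adj_integrated": padj[keep],
            "significant_any": sig_any[keep],
        }
    )
    return out.reset_index(drop=True)


def signature_filter(
    integrated: pd.DataFrame, p_max: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Flag the enrichment input signature on an integrated table.

    ``in_signature = (p_adj_integrated < p_max) and (|FC| > fc_min)``, the
    fold-change gate applied on the linear scale in either direction
    (equivalently ``|log2fc_integrated| > log2(fc_min)``). Adds ``direction``
    ("up"/"down") from the sign of the integrated log2 fold change.
    """
    if p_max <= 0 or fc_min <= 0:
        raise ValidationError("p_max and fc_min must be > 0")
    out = integrated.copy()
    lfc = out["log2fc_integrated"].to_numpy(dtype=float)
    padj = out["p_adj_integrated"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["in_signature"] = (padj < p_max) & (np.abs(lfc) > math.log2(fc_min))
    out["in_signature"] = out["in_signature"].fillna(False).astype(bool)
    out["direction"] = np.where(lfc < 0, "down", "up")
    return out[list(INTEGRATED_COLUMNS)]
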