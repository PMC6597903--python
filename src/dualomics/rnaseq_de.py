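"""RNA layer: normalization, detection filtering and NB differential expression.

Counts are normalized with median-of-ratios size factors (each sample's factor
is the median, over genes expressed in every sample, of that sample's counts
divided by the gene's geometric-mean pseudo-reference). Expression is reported
in FPKM for detection filtering (robustly detected = mean FPKM strictly above
0.5), and two-group differential expression is tested per gene with a Wald
statistic on the log2 ratio of normalized group means under a negative-binomial
model with variance ``mu + alpha * mu**2``; the gene-wise dispersion ``alpha``
is a pooled method-of-moments estimate. Benjamini–Hochberg adjustment is
applied over the detected genes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CONTROL, DIFF_COLUMNS, GENOTYPES, MUTANT, RNA, TIMEPOINTS
from .errors import EstimationError, ValidationError
from .proteomics_de import bh_adjust

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Genes × samples integer counts with gene lengths and sample metadata."""

    counts: pd.DataFrame
    lengths_bp: pd.Series
    samples: pd.DataFrame  # index = sample id; columns genotype, timepoint

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if not self.counts.columns.equals(self.samples.index):
            raise ValidationError("count columns do not match sample sheet")
        if not self.counts.index.equals(self.lengths_bp.index):
            raise ValidationError("lengths index does not match feature ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integral")
        if (self.lengths_bp.to_numpy() < 1).any():
            raise ValidationError("gene lengths must be >= 1 bp")
        bad = {g for g in self.samples["genotype"] if g not in GENOTYPES}
        if bad:
            raise ValidationError(f"unknown genotype labels: {sorted(bad)}")
        bad_tp = {t for t in self.samples["timepoint"] if int(t) not in TIMEPOINTS}
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")

    def subset_timepoint(self, timepoint: int) -> "CountMatrix":
        keep = self.samples.index[self.samples["timepoint"] == int(timepoint)]
        if len(keep) == 0:
            raise ValidationError(f"no samples at timepoint {timepoint}")
        return CountMatrix(
            self.counts[keep].copy(), self.lengths_bp.copy(), self.samples.loc[keep].copy()
        )


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with a positive geometric mean across samples (i.e. expressed in
    every sample), ``s_j = median_i(k_ij / geomean_i)``.
    """
    k = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = k.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "cannot estimate size factors: no gene has nonzero counts in all samples"
        )
    logk = np.log(vals[positive])
    log_geomean = logk.mean(axis=1)
    s = np.exp(np.median(logk - log_geomean[:, None], axis=0))
    return pd.Series(s, index=k.columns, name="size_factor")


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM_ij = counts_ij * 1e9 / (length_i * total_counts_j)``.
    """
    totals = cm.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = list(cm.counts.columns[totals <= 0])
        raise EstimationError(f"zero library total in sample(s): {bad}")
    vals = cm.counts.to_numpy(dtype=float) * 1e9
    vals /= cm.lengths_bp.to_numpy(dtype=float)[:, None]
    vals /= totals[None, :]
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def detection_filter(mean_fpkm, fpkm_min: float = 0.5) -> np.ndarray:
    """Robust-detection flag: mean FPKM strictly above the threshold."""
    return np.asarray(mean_fpkm, dtype=float) > fpkm_min


def log_normalized(cm: CountMatrix) -> pd.DataFrame:
    """``log2(normalized count + 1)`` matrix for QC ordination (PCA)."""
    s = size_factors(cm)
    return np.log2(cm.counts.div(s, axis=1) + 1.0)


def nb_differential(
    cm: CountMatrix, timepoint: int, fpkm_min: float = 0.5
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test at one timepoint.

    Per gene: normalized counts ``k_ij / s_j``; group means; pooled
    method-of-moments dispersion (floored at 1e-8); ``log2fc`` of the shifted
    group means with pseudocount ``eps = 0.5 / median(s)``; delta-method
    standard error of the log2 ratio; two-sided p from a Student t reference
    with ``n_c + n_m - 2`` degrees of freedom (which accounts for the
    estimated dispersion at small group sizes). BH adjustment is computed over
    detected genes only; undetected genes carry ``p_adj = NaN``.
    """
    sub = cm.subset_timepoint(timepoint)
    geno = sub.samples["genotype"]
    is_c = (geno == CONTROL).to_numpy()
    is_m = (geno == MUTANT).to_numpy()
    n_c, n_m = int(is_c.sum()), int(is_m.sum())
    if n_c < 2 or n_m < 2:
        raise EstimationError(
            f"need >= 2 samples per genotype at timepoint {timepoint} "
            f"(control={n_c}, mutant={n_m})"
        )
    k = sub.counts.to_numpy(dtype=float)
    for mask, label in ((is_c, CONTROL), (is_m, MUTANT)):
        if k[:, mask].sum() == 0:
            raise EstimationError(f"{label} group has all-zero counts at {timepoint}")

    s = size_factors(sub).to_numpy()
    kn = k / s[None, :]
    kc, km = kn[:, is_c], kn[:, is_m]
    mu_c, mu_m = kc.mean(axis=1), km.mean(axis=1)
    v_c = kc.var(axis=1, ddof=1)
    v_m = km.var(axis=1, ddof=1)
    # mean Poisson ("shot") variance of k/s within each group
    shot_c = float(np.mean(1.0 / s[is_c]))
    shot_m = float(np.mean(1.0 / s[is_m]))

    # pooled method-of-moments dispersion: E[v_g] = mu_g*shot_g + alpha*mu_g^2
    num = (n_c - 1) * (v_c - mu_c * shot_c) + (n_m - 1) * (v_m - mu_m * shot_m)
    den = (n_c - 1) * mu_c**2 + (n_m - 1) * mu_m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    eps = 0.5 / float(np.median(s))
    log2fc = np.log2((mu_m + eps) / (mu_c + eps))

    var_mu_c = (mu_c * shot_c + alpha * mu_c**2) / n_c
    var_mu_m = (mu_m * shot_m + alpha * mu_m**2) / n_m
    se = np.sqrt(var_mu_c / (mu_c + eps) ** 2 + var_mu_m / (mu_m + eps) ** 2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p_raw = np.where(se > 0, 2.0 * stats.t.sf(np.abs(wald), n_c + n_m - 2), 1.0)

    mean_fpkm = fpkm(sub).mean(axis=1).to_numpy()
    detected = detection_filter(mean_fpkm, fpkm_min)
    p_adj = np.full(p_raw.shape, np.nan)
    if detected.any():
        p_adj[detected] = bh_adjust(p_raw[detected])

    table = pd.DataFrame(
        {
            "feature": sub.counts.index.astype(str).str.upper(),
            "layer": RNA,
            "timepoint": int(timepoint),
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "mean_fpkm": mean_fpkm,
            "detected": detected,
        }
    )
    return table[list(DIFF_COLUMNS)].reset_index(drop=True)
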