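"""TMT-10plex proteomics: normalization and moderated-t differential abundance.

Reporter-ion intensities from an isobaric 10-plex experiment are normalized in
two steps — equalize channel medians (preserving the global scale), then divide
each protein by its own across-channel mean so every protein is expressed as a
relative ratio — and differential abundance between genotypes is tested with an
empirical-Bayes moderated t-statistic on log2 ratios: per-protein residual
variances are shrunk toward a common prior variance ``s2_0`` with prior degrees
of freedom ``d0`` estimated from the whole ensemble of proteins, and the
t reference gains those ``d0`` degrees of freedom.

Also hosts :func:`bh_adjust`, the Benjamini–Hochberg step-up procedure used by
every stage that corrects for multiple testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import CONTROL, DIFF_COLUMNS, GENOTYPES, MUTANT, PROTEIN, TIMEPOINTS
from .errors import EstimationError, ValidationError

logger = logging.getLogger(__name__)

MAX_CHANNELS_PER_SET = 10


# ---------------------------------------------------------------------------
# container


@dataclass
class IntensityMatrix:
    """Proteins × TMT channels reporter intensities with channel metadata.

    Parameters
    ----------
    intensities
        Positive reals, proteins in rows, channels in columns. Zeros are
        treated as missing and stored as NaN.
    gene_symbols
        Mapping protein_id → gene symbol, indexed like ``intensities``.
    channels
        One row per channel (index = channel id, matching the intensity
        columns) with columns ``genotype``, ``timepoint`` and ``tmt_set``.
    """

    intensities: pd.DataFrame
    gene_symbols: pd.Series
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValidationError("duplicate protein ids in intensity matrix")
        if not self.intensities.columns.equals(self.channels.index):
            raise ValidationError("intensity columns do not match channel metadata")
        if not self.intensities.index.equals(self.gene_symbols.index):
            raise ValidationError("gene_symbols index does not match protein ids")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValidationError("intensities must be positive")
        if (vals == 0).any():
            logger.warning("zero intensities found; treating them as missing")
            self.intensities = self.intensities.replace(0.0, np.nan)
        bad = {g for g in self.channels["genotype"] if g not in GENOTYPES}
        if bad:
            raise ValidationError(f"unknown genotype labels: {sorted(bad)}")
        bad_tp = {t for t in self.channels["timepoint"] if int(t) not in TIMEPOINTS}
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        for set_id, grp in self.channels.groupby("tmt_set"):
            if len(grp) > MAX_CHANNELS_PER_SET:
                raise ValidationError(
                    f"TMT set {set_id!r} has {len(grp)} channels (max 10)"
                )

    def subset_timepoint(self, timepoint: int) -> "IntensityMatrix":
        keep = self.channels.index[self.channels["timepoint"] == int(timepoint)]
        if len(keep) == 0:
            raise ValidationError(f"no channels at timepoint {timepoint}")
        return IntensityMatrix(
            self.intensities[keep].copy(), self.gene_symbols.copy(), self.channels.loc[keep].copy()
        )


# ---------------------------------------------------------------------------
# normalization


def channel_median_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Equalize channel medians while preserving the global intensity scale.

    Each channel is divided by its own median over all quantified proteins and
    multiplied by the mean of the original channel medians, so post-hoc the
    channel medians are all equal to that grand mean.
    """
    med = m.intensities.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise EstimationError(f"channel(s) with no finite intensities: {bad}")
    grand = float(med.mean())
    norm = m.intensities.div(med, axis=1) * grand
    return IntensityMatrix(norm, m.gene_symbols.copy(), m.channels.copy())


def relative_ratio(m: IntensityMatrix) -> pd.DataFrame:
    """Divide every protein row by its across-channel mean (row means → 1)."""
    row_mean = m.intensities.mean(axis=1, skipna=True)
    return m.intensities.div(row_mean, axis=0)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    ``adj_(i) = min_{j>=i} p_(j) * m / j`` over the sorted p-values, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0), by bracketed root finding."""
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-6, 1e8
    if f(lo) < 0:  # y above trigamma(1e-6): essentially x -> 0
        return lo
    if f(hi) > 0:  # y below trigamma(1e8): essentially x -> inf
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match the scaled-F model for residual variances.

    Under the hierarchical model ``s2 ~ s2_0 * F(df, d0)``, ``log s2`` has mean
    ``log s2_0 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)`` and
    excess variance ``trigamma(d0/2)`` beyond its sampling variance
    ``trigamma(df/2)``. Matching the first two moments of ``log s2`` yields
    ``(d0, s2_0)``; when the empirical spread does not exceed the sampling
    variance the prior is degenerate (``d0 = +inf``).
    """
    ok = (df > 0) & (s2 > 0)
    if ok.sum() < 2:
        raise EstimationError("need >= 2 positive residual variances to fit a prior")
    z = np.log(s2[ok])
    half_df = df[ok] / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1) - special.polygamma(1, half_df).mean())
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s2_0 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s2_0


def moderated_t(
    ratios: pd.DataFrame,
    design: pd.Series,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test on log2 relative ratios.

    Parameters
    ----------
    ratios
        Proteins × channels relative-ratio matrix (positive; NaN = missing).
    design
        Genotype label per channel (``control``/``mutant``), indexed by the
        ratio columns.
    d0_override
        Force the prior degrees of freedom: ``0`` reduces the statistic to the
        ordinary pooled two-sample t; ``None`` (default) estimates ``d0`` from
        the variance ensemble.

    Returns
    -------
    DataFrame indexed by protein with columns ``log2fc``, ``s2``, ``df``,
    ``s2_0``, ``d0``, ``s2_post``, ``t_mod``, ``p_raw``, ``p_adj``. Proteins
    quantified in fewer than two channels of either group are excluded.
    """
    design = design.reindex(ratios.columns)
    if design.isna().any():
        raise ValidationError("design labels missing for some channels")
    x = np.log2(ratios.to_numpy(dtype=float))
    is_m = (design == MUTANT).to_numpy()
    is_c = (design == CONTROL).to_numpy()
    if is_m.sum() < 2 or is_c.sum() < 2:
        raise EstimationError("need >= 2 channels per genotype group")

    fin = np.isfinite(x)
    nc = (fin & is_c).sum(axis=1)
    nm = (fin & is_m).sum(axis=1)
    usable = (nc >= 2) & (nm >= 2)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "excluding %d protein(s) quantified in <2 channels of a group", n_dropped
        )
    x = x[usable]
    fin = fin[usable]
    nc, nm = nc[usable].astype(float), nm[usable].astype(float)

    xc = np.where(fin & is_c, x, 0.0)
    xm = np.where(fin & is_m, x, 0.0)
    mean_c = xc.sum(axis=1) / nc
    mean_m = xm.sum(axis=1) / nm
    rss_c = np.where(fin & is_c, (x - mean_c[:, None]) ** 2, 0.0).sum(axis=1)
    rss_m = np.where(fin & is_m, (x - mean_m[:, None]) ** 2, 0.0).sum(axis=1)
    df = nc + nm - 2.0
    s2 = (rss_c + rss_m) / df

    if d0_override is None:
        d0, s2_0 = estimate_prior(s2, df)
    elif d0_override == 0:
        d0, s2_0 = 0.0, float("nan")
    else:
        d0 = float(d0_override)
        _, s2_0 = estimate_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s2_0)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s2_0 + df * s2) / (d0 + df)

    log2fc = mean_m - mean_c
    se = np.sqrt(s2_post * (1.0 / nc + 1.0 / nm))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    df_total = df + d0
    if np.isinf(d0):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.where(se > 0, p_raw, 1.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "df": df,
            "s2_0": s2_0,
            "d0": d0,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        },
        index=ratios.index[usable],
    )
    return out


# ---------------------------------------------------------------------------
# layer driver


def protein_differential(
    m: IntensityMatrix,
    timepoint: int,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Full protein-layer differential table for one timepoint.

    Normalize channel medians, form relative ratios, run the moderated t, and
    collapse to gene level: where several protein ids map to one gene symbol
    the protein with the highest mean normalized intensity is kept. Returns the
    shared differential-table schema (``mean_fpkm`` NaN, ``detected`` True).
    """
    sub = m.subset_timepoint(timepoint)
    norm = channel_median_normalize(sub)
    ratios = relative_ratio(norm)
    fit = moderated_t(ratios, norm.channels["genotype"], d0_override=d0_override)

    mean_int = norm.intensities.loc[fit.index].mean(axis=1, skipna=True)
    genes = norm.gene_symbols.loc[fit.index].astype(str).str.upper()
    keep = (
        pd.DataFrame({"gene": genes, "mean_int": mean_int})
        .sort_values(["gene", "mean_int"], ascending=[True, False], kind="stable")
        .drop_duplicates("gene", keep="first")
        .index
    )
    fit = fit.loc[keep]

    table = pd.DataFrame(
        {
            "feature": genes.loc[keep].to_numpy(),
            "layer": PROTEIN,
            "timepoint": int(timepoint),
            "log2fc": fit["log2fc"].to_numpy(),
            "p_raw": fit["p_raw"].to_numpy(),
            "p_adj": bh_adjust(fit["p_raw"].to_numpy()),
            "mean_fpkm": np.nan,
            "detected": True,
        }
    )
    table = table.sort_values("feature", kind="stable", ignore_index=True)
    return table[list(DIFF_COLUMNS)]
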