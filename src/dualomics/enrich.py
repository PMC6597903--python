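"""Ensemble gene-set enrichment on the integrated signature.

Three complementary base statistics are computed per gene set — an
over-representation (hypergeometric tail) test of the set's overlap with the
significant-gene signature, a competitive Wilcoxon rank-sum test comparing
in-set against out-of-set gene scores, and a self-contained permutation test of
the set's mean score — spanning the over-representation / competitive /
self-contained taxonomy that ensemble enrichment methods combine. Per-set
p-values are combined by Fisher's method (chi-square with 6 df), sets are
ordered by the median of their ranks under the three methods, the combined
p-values are BH-adjusted across sets, and a signed mean of member fold changes
labels each set up- or down-regulated.

The gene-level score is ``-log10`` of the integrated adjusted p-value; the gene
universe is every symbol in the integrated table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .proteomics_de import bh_adjust

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

ENRICHMENT_COLUMNS = (
    "set_name",
    "n_members_in_universe",
    "n_members_in_signature",
    "p_ora",
    "p_rank",
    "p_perm",
    "p_combined",
    "p_adj",
    "median_rank",
    "direction_score",
    "direction",
    "reported",
)


@dataclass
class GeneSetCollection:
    """Named gene sets (name → member symbols) with per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")
        self.descriptions = {n: self.descriptions.get(n, "") for n in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {n: sorted(m) for n, m in self.sets.items()} == {
            n: sorted(m) for n, m in other.sets.items()
        }


def gene_scores(integrated: pd.DataFrame) -> pd.Series:
    """Two-sided gene-level scores: ``-log10(p_adj_integrated)`` (NaN → 0)."""
    p = integrated["p_adj_integrated"].to_numpy(dtype=float)
    p = np.where(np.isfinite(p), np.clip(p, P_FLOOR, 1.0), 1.0)
    idx = pd.Index(integrated["gene_symbol"].astype(str), name="gene_symbol")
    return pd.Series(-np.log10(p), index=idx, name="score")


def ora_test(set_members, signature, universe) -> float:
    """Hypergeometric upper-tail over-representation p-value.

    ``P(X >= k)`` for k = |set ∩ signature| under drawing n = |signature|
    genes from a universe of N containing K = |set ∩ universe| set members.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    signature = set(signature) & universe
    members = set(set_members) & universe
    N, K, n, k = len(universe), len(members), len(signature), len(members & signature)
    if K == 0 or n == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rank_test(set_members, gene_stats: pd.Series, method: str = "auto") -> float:
    """Competitive two-sided Wilcoxon rank-sum p: in-set vs out-of-set scores.

    ``method`` is passed to scipy's Mann–Whitney U ("auto" uses the exact
    distribution for small tie-free samples, otherwise the normal
    approximation with tie and continuity corrections).
    """
    in_mask = gene_stats.index.isin(set(set_members))
    x = gene_stats.to_numpy(dtype=float)[in_mask]
    y = gene_stats.to_numpy(dtype=float)[~in_mask]
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank test needs >= 1 in-set and >= 1 out-of-set gene")
    xy = np.concatenate([x, y])
    if np.all(xy == xy[0]):
        logger.warning("all gene scores tied; rank-sum p set to 1")
        return 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def _perm_null(
    scores: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of the mean score of a uniform size-``set_size`` subset."""
    n = scores.size
    # random keys + argpartition = n_perm uniform subsets without replacement
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return scores[idx].mean(axis=1)


def perm_test(
    set_members,
    gene_stats: pd.Series,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Self-contained permutation p for the set's mean gene score.

    Observed statistic = mean score of set members; null = the same statistic
    on ``n_perm`` uniform random same-size subsets of the universe;
    ``p = (1 + #{T_perm >= T_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if len(set(set_members)) > gene_stats.size:
        raise ValidationError("set larger than universe")
    in_mask = gene_stats.index.isin(set(set_members))
    m = int(in_mask.sum())
    if m == 0:
        return 1.0
    scores = gene_stats.to_numpy(dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = scores[in_mask].mean()
    t_null = _perm_null(scores, m, n_perm, rng)
    return float((1 + np.sum(t_null >= t_obs)) / (n_perm + 1))


def ensemble_combine(p_ora, p_rank, p_perm):
    """Fisher-combine the three per-set p-values (chi-square, 6 df).

    Returns the combined p-value array; zeros are clamped to 1e-300 before the
    logarithm.
    """
    ps = np.column_stack([
        np.asarray(p_ora, dtype=float),
        np.asarray(p_rank, dtype=float),
        np.asarray(p_perm, dtype=float),
    ])
    if (ps < 0).any() or (ps > 1).any() or np.isnan(ps).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if (ps == 0).any():
        logger.warning("zero p-value(s) clamped to %g before Fisher combination", P_FLOOR)
        ps = np.clip(ps, P_FLOOR, 1.0)
    x = -2.0 * np.log(ps).sum(axis=1)
    return stats.chi2.sf(x, df=6)


def enrich_all(
    integrated: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full enrichment ensemble over a gene-set collection.

    Per set: over-representation, rank-sum and permutation p-values; Fisher
    combination; ranks per method (ties share the best rank) and their median;
    BH adjustment of the combined p across sets. Sets with ``p_adj < alpha``
    are flagged ``reported``. Output is ordered by median rank, ties broken by
    combined p then name. Permutation nulls are shared across sets of equal
    size (one null ensemble per size), drawn from ``seed``.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 gene sets")
    scores = gene_scores(integrated)
    universe = list(scores.index)
    signature = set(integrated.loc[integrated["in_signature"].astype(bool), "gene_symbol"])
    if not signature:
        logger.warning("empty signature: all over-representation p-values are 1")
    lfc = pd.Series(
        integrated["log2fc_integrated"].to_numpy(dtype=float),
        index=pd.Index(integrated["gene_symbol"].astype(str)),
    )

    names = sorted(sets.sets)
    arr = scores.to_numpy(dtype=float)
    member_masks = {n: scores.index.isin(set(sets.sets[n])) for n in names}
    sizes = {n: int(member_masks[n].sum()) for n in names}

    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    for m in sorted({s for s in sizes.values() if s > 0}):
        nulls[m] = np.sort(_perm_null(arr, m, n_perm, rng))

    rows = []
    for name in names:
        members = set(sets.sets[name])
        mask = member_masks[name]
        m = sizes[name]
        p_o = ora_test(members, signature, universe)
        if m == 0 or m == len(universe):
            p_r = 1.0
            logger.warning("set %r degenerate in universe; rank p set to 1", name)
        else:
            p_r = rank_test(members, scores)
        if m == 0:
            p_p = 1.0
        else:
            t_obs = arr[mask].mean()
            null = nulls[m]
            # count of null >= t_obs via sorted null
            n_ge = n_perm - np.searchsorted(null, t_obs, side="left")
            p_p = float((1 + n_ge) / (n_perm + 1))
        dscore = float(lfc[list(members & set(universe))].mean()) if m else 0.0
        rows.append((name, m, len(members & signature), p_o, p_r, p_p, dscore))

    df = pd.DataFrame(
        rows,
        columns=[
            "set_name", "n_members_in_universe", "n_members_in_signature",
            "p_ora", "p_rank", "p_perm", "direction_score",
        ],
    )
    df["p_combined"] = ensemble_combine(df["p_ora"], df["p_rank"], df["p_perm"])
    ranks = np.column_stack([
        stats.rankdata(df[c], method="min") for c in ("p_ora", "p_rank", "p_perm")
    ])
    df["median_rank"] = np.median(ranks, axis=1)
    df["p_adj"] = bh_adjust(df["p_combined"].to_numpy())
    df["direction"] = np.where(df["direction_score"] < 0, "down", "up")
    df["reported"] = df["p_adj"] < alpha
    df = df.sort_values(
        ["median_rank", "p_combined", "set_name"], kind="stable", ignore_index=True
    )
    return df[list(ENRICHMENT_COLUMNS)]
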