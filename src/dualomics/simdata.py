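"""Seeded synthetic two-genotype × two-timepoint dual-omics data.

Emulates the statistical structure the downstream analysis assumes for iPSC
neuron cultures sampled at 35 and 56 days in vitro: negative-binomial RNA
counts with library-size variation, log-normal TMT reporter intensities with
per-channel offsets and fold-change (ratio) compression, and differential
effects planted in known features so that every stage can be validated against
ground truth. Proteins are a deterministic subset of the gene symbols (the
first ``n_proteins`` genes) so gene↔protein joins are reproducible, and the
same true effects are planted at both timepoints and shared across layers for
protein-mapped genes.

All randomness flows from ``SimConfig.seed``; each layer draws from its own
stream derived from the master seed by a fixed offset, so adding a layer never
perturbs another layer's draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CONTROL, MUTANT, PROTEIN, RNA, TIMEPOINTS
from .errors import ConfigurationError, ConsistencyError
from .proteomics_de import IntensityMatrix
from .rnaseq_de import CountMatrix

logger = logging.getLogger(__name__)

# stream offsets: one independent generator per layer / purpose
_STREAM_RNA = 1
_STREAM_PROTEIN = 2
_STREAM_SETS = 3

GENE_LENGTH_RANGE_BP = (500, 20_000)
#: planted effects are restricted to genes whose baseline mean count is at
#: least this value — effects in essentially unexpressed genes are not
#: recoverable by any method and would not survive detection filtering.
MIN_PLANTED_BASELINE = 5.0


@dataclass
class SimConfig:
    """Parameters of the synthetic dual-omics experiment.

    Defaults mirror the study design the pipeline targets: ~16k detected genes
    and ~10.5k proteins per timepoint, 5 samples per genotype per timepoint
    (one TMT 10-plex set per timepoint), moderate NB overdispersion, ~20%
    library-size variation, and protein-layer fold changes attenuated by the
    TMT ratio-compression factor 1/1.4.
    """

    n_genes: int = 16_000
    n_proteins: int = 10_500
    n_per_group: int = 5
    frac_de: float = 0.1
    planted_sets: tuple[str, ...] = ()
    effect_log2fc: float = 1.0
    nb_dispersion: float = 0.05
    compression_factor: float = 1.0 / 1.4
    libsize_cv: float = 0.2
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_proteins <= 0 or self.n_per_group <= 0:
            raise ConfigurationError("n_genes, n_proteins and n_per_group must be > 0")
        if self.n_proteins > self.n_genes:
            raise ConfigurationError("n_proteins cannot exceed n_genes")
        if not 0 <= self.frac_de < 1:
            raise ConfigurationError("frac_de must lie in [0, 1)")
        if not 0 < self.compression_factor <= 1:
            raise ConfigurationError("compression_factor must lie in (0, 1]")
        if self.nb_dispersion < 0 or self.libsize_cv < 0 or self.noise_sd < 0:
            raise ConfigurationError("dispersion, libsize_cv and noise_sd must be >= 0")
        if 2 * self.n_per_group > 10:
            raise ConfigurationError(
                "a TMT 10-plex set holds at most 10 channels: n_per_group <= 5"
            )
        self.planted_sets = tuple(self.planted_sets)


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``de_features[layer][timepoint]`` maps feature → true log2 fold change
    (mutant over control, before any compression); ``size_factors[layer]``
    holds the true per-sample (or per-channel) multiplicative scaling.
    """

    genes: list[str]
    de_features: dict[str, dict[int, dict[str, float]]]
    enriched_sets: set[str] = field(default_factory=set)
    size_factors: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "de_features": {
                layer: {str(tp): dict(d) for tp, d in per_tp.items()}
                for layer, per_tp in self.de_features.items()
            },
            "enriched_sets": sorted(self.enriched_sets),
            "size_factors": {k: dict(v) for k, v in self.size_factors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            genes=list(d["genes"]),
            de_features={
                layer: {int(tp): {k: float(v) for k, v in sub.items()} for tp, sub in per_tp.items()}
                for layer, per_tp in d["de_features"].items()
            },
            enriched_sets=set(d.get("enriched_sets", [])),
            size_factors={k: dict(v) for k, v in d.get("size_factors", {}).items()},
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate the RNA layer for both timepoints and its ground truth.

    Counts are negative binomial with mean
    ``baseline_i * size_factor_j * 2**(log2fc_i * I[mutant])`` and variance
    ``mu + nb_dispersion * mu**2`` (gamma–Poisson mixture). Baseline means are
    log-normal (log2 scale: N(5, 2)), gene lengths log-uniform in
    [500, 20000] bp, library size factors log-normal with the configured CV.
    """
    rng = _rng(cfg, _STREAM_RNA)
    genes = _gene_ids(cfg.n_genes)

    lo, hi = GENE_LENGTH_RANGE_BP
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), cfg.n_genes)).round().astype(int)
    baseline = 2.0 ** rng.normal(5.0, 2.0, cfg.n_genes)

    lfc = np.zeros(cfg.n_genes)
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    if n_de > 0:
        eligible = np.flatnonzero(baseline >= MIN_PLANTED_BASELINE)
        if n_de > eligible.size:
            raise ConfigurationError(
                f"cannot plant {n_de} effects: only {eligible.size} genes pass the "
                f"baseline floor of {MIN_PLANTED_BASELINE} counts"
            )
        de_idx = rng.choice(eligible, n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], n_de)
        lfc[de_idx] = signs * cfg.effect_log2fc

    # sample sheet: both timepoints, control then mutant within each
    rows, cols = [], []
    for tp in TIMEPOINTS:
        for geno in (CONTROL, MUTANT):
            for i in range(1, cfg.n_per_group + 1):
                cols.append(f"rna_{geno[:3]}{tp}_{i}")
                rows.append((geno, tp))
    samples = pd.DataFrame(rows, index=pd.Index(cols, name="sample_id"),
                           columns=["genotype", "timepoint"])

    sigma = math.sqrt(math.log(1.0 + cfg.libsize_cv**2))
    sf = np.exp(rng.normal(0.0, sigma, len(cols)))
    sf /= np.exp(np.mean(np.log(sf)))  # geometric mean 1 for identifiability

    is_mut = (samples["genotype"] == MUTANT).to_numpy()
    mu = baseline[:, None] * sf[None, :] * 2.0 ** (lfc[:, None] * is_mut[None, :])
    if cfg.nb_dispersion > 0:
        lam = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=cols),
        lengths_bp=pd.Series(lengths, index=pd.Index(genes, name="gene_id"), name="length_bp"),
        samples=samples,
    )

    de_map = {genes[i]: float(lfc[i]) for i in np.flatnonzero(lfc != 0)}
    protein_genes = set(genes[: cfg.n_proteins])
    de_prot = {g: v for g, v in de_map.items() if g in protein_genes}
    truth = SimTruth(
        genes=genes,
        de_features={
            RNA: {tp: dict(de_map) for tp in TIMEPOINTS},
            PROTEIN: {tp: dict(de_prot) for tp in TIMEPOINTS},
        },
        size_factors={RNA: {c: float(v) for c, v in zip(cols, sf)}},
    )
    return cm, truth


def simulate_intensities(cfg: SimConfig, truth: SimTruth) -> IntensityMatrix:
    """Simulate TMT reporter intensities for both timepoints (one 10-plex each).

    ``log2 intensity = baseline + channel_effect
    + compression_factor * true_log2fc * I[mutant] + N(0, noise_sd)``.
    Channel effects are distinct per channel, so median normalization is
    non-trivial; the compression factor attenuates the planted effects the way
    reporter-ion co-isolation attenuates observed TMT ratios.
    """
    if len(truth.genes) != cfg.n_genes:
        raise ConsistencyError(
            f"truth carries {len(truth.genes)} genes but cfg.n_genes={cfg.n_genes}"
        )
    rng = _rng(cfg, _STREAM_PROTEIN)
    genes = truth.genes[: cfg.n_proteins]
    proteins = [g.replace("GENE", "PROT", 1) for g in genes]

    baseline = rng.normal(18.0, 1.5, cfg.n_proteins)

    rows, cols, tp_of, geno_of, set_of = [], [], [], [], []
    for tp in TIMEPOINTS:
        for geno in (CONTROL, MUTANT):
            for i in range(1, cfg.n_per_group + 1):
                cols.append(f"tmt_{geno[:3]}{tp}_{i}")
                tp_of.append(tp)
                geno_of.append(geno)
                set_of.append(f"TMT{tp}")
    channels = pd.DataFrame(
        {"genotype": geno_of, "timepoint": tp_of, "tmt_set": set_of},
        index=pd.Index(cols, name="channel_id"),
    )
    chan_eff = rng.normal(0.0, 0.25, len(cols))

    lfc = np.zeros((cfg.n_proteins, len(cols)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, (tp, geno) in enumerate(zip(tp_of, geno_of)):
        if geno != MUTANT:
            continue
        for g, v in truth.de_features[PROTEIN][tp].items():
            if g not in gene_pos:
                raise ConsistencyError(f"truth feature {g!r} not among simulated proteins")
            lfc[gene_pos[g], j] = v

    log2i = (
        baseline[:, None]
        + chan_eff[None, :]
        + cfg.compression_factor * lfc
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_proteins, len(cols)))
    )
    truth.size_factors[PROTEIN] = {c: float(2.0**e) for c, e in zip(cols, chan_eff)}

    return IntensityMatrix(
        intensities=pd.DataFrame(2.0**log2i, index=pd.Index(proteins, name="protein_id"), columns=cols),
        gene_symbols=pd.Series(genes, index=pd.Index(proteins, name="protein_id"), name="gene_symbol"),
        channels=channels,
    )


def build_genesets(
    cfg: SimConfig,
    truth: SimTruth,
    n_sets: int = 51,
    set_size_range: tuple[int, int] = (10, 30),
    planted_frac: float = 0.6,
):
    """Build a gene-set collection with enrichment planted in known sets.

    Sets named in ``cfg.planted_sets`` draw at least ``planted_frac`` of their
    members from the truly differential features; the remaining sets are
    decoys sampled uniformly from all genes. Marks the planted sets in
    ``truth.enriched_sets``.
    """
    from .enrich import GeneSetCollection  # deferred: avoid import cycle at module load

    if n_sets < 2:
        raise ConfigurationError("need at least 2 gene sets")
    if len(cfg.planted_sets) > n_sets:
        raise ConfigurationError("more planted sets than total sets")
    lo, hi = int(set_size_range[0]), int(set_size_range[1])
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid set_size_range {set_size_range}")
    if hi > cfg.n_genes:
        raise ConfigurationError("set size exceeds number of genes")

    rng = _rng(cfg, _STREAM_SETS)
    genes = np.array(truth.genes)
    de_pool = np.array(sorted(truth.de_features[RNA][TIMEPOINTS[0]]))
    non_de_pool = np.array(sorted(set(truth.genes) - set(de_pool)))

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_decoys = n_sets - len(cfg.planted_sets)
    width = max(3, len(str(n_decoys)))

    for name in cfg.planted_sets:
        size = int(rng.integers(lo, hi + 1))
        n_planted = int(math.ceil(planted_frac * size))
        if n_planted > de_pool.size:
            raise ConfigurationError(
                f"planted set {name!r} needs {n_planted} differential members but "
                f"truth has only {de_pool.size}"
            )
        members = list(rng.choice(de_pool, n_planted, replace=False))
        n_rest = size - n_planted
        if n_rest > non_de_pool.size:
            raise ConfigurationError("not enough non-differential genes for set filler")
        members += list(rng.choice(non_de_pool, n_rest, replace=False))
        sets[name] = sorted(members)
        descriptions[name] = "planted dysregulated set"

    for i in range(1, n_decoys + 1):
        name = f"DECOY_{i:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        sets[name] = sorted(rng.choice(genes, size, replace=False))
        descriptions[name] = "decoy set"

    truth.enriched_sets = set(cfg.planted_sets)
    return GeneSetCollection(sets=sets, descriptions=descriptions)
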