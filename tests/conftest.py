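import numpy as np
import pandas as pd
import pytest

import dualomics as d


@pytest.fixture(scope="session")
def small_cfg() -> d.SimConfig:
    return d.SimConfig(
        n_genes=400,
        n_proteins=250,
        n_per_group=5,
        frac_de=0.1,
        effect_log2fc=1.0,
        planted_sets=("PLANTED",),
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_data(small_cfg):
    cm, truth = d.simulate_counts(small_cfg)
    im = d.simulate_intensities(small_cfg, truth)
    return cm, truth, im


@pytest.fixture(scope="session")
def integrated_small(sim_data):
    cm, truth, im = sim_data
    tables = {
        (layer, tp): (
            d.nb_differential(cm, tp) if layer == d.RNA else d.protein_differential(im, tp)
        )
        for layer in (d.RNA, d.PROTEIN)
        for tp in d.TIMEPOINTS
    }
    merged = d.cascade_merge(
        tables[(d.PROTEIN, 35)], tables[(d.PROTEIN, 56)],
        tables[(d.RNA, 35)], tables[(d.RNA, 56)],
    )
    return d.signature_filter(merged)


def make_diff_table(rows) -> pd.DataFrame:
    """Build a differential table from (feature, layer, tp, log2fc, p_adj, detected)."""
    recs = [
        {
            "feature": f, "layer": layer, "timepoint": tp, "log2fc": lfc,
            "p_raw": p, "p_adj": p, "mean_fpkm": np.nan, "detected": det,
        }
        for f, layer, tp, lfc, p, det in rows
    ]
    return pd.DataFrame(recs, columns=list(d.DIFF_COLUMNS))


@pytest.fixture
def make_intensity_matrix():
    def _make(values, genotypes, timepoints=None, tmt_sets=None, gene_symbols=None):
        values = np.asarray(values, dtype=float)
        n_prot, n_chan = values.shape
        prots = [f"PROT{i:05d}" for i in range(1, n_prot + 1)]
        chans = [f"ch{i}" for i in range(1, n_chan + 1)]
        timepoints = timepoints or [35] * n_chan
        tmt_sets = tmt_sets or ["TMT35"] * n_chan
        genes = gene_symbols or [p.replace("PROT", "GENE") for p in prots]
        return d.IntensityMatrix(
            intensities=pd.DataFrame(values, index=pd.Index(prots, name="protein_id"), columns=chans),
            gene_symbols=pd.Series(genes, index=pd.Index(prots, name="protein_id")),
            channels=pd.DataFrame(
                {"genotype": genotypes, "timepoint": timepoints, "tmt_set": tmt_sets},
                index=pd.Index(chans, name="channel_id"),
            ),
        )

    return _make
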