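"""Shared vocabulary for the pipeline stages.

Genotype labels, the two culture ages (days in vitro) at which samples are
collected, and the column schema of the per-layer differential tables that
every downstream stage consumes.
"""

CONTROL = "control"
MUTANT = "mutant"
GENOTYPES = (CONTROL, MUTANT)

#: Culture ages in days in vitro at which both omics layers are assayed.
TIMEPOINTS = (35, 56)

RNA = "rna"
PROTEIN = "protein"
LAYERS = (RNA, PROTEIN)

#: Column schema of a differential table (one row per feature, one table per
#: (layer, timepoint)). ``mean_fpkm``/``detected`` are RNA-layer concepts;
#: protein rows carry NaN / True there.
DIFF_COLUMNS = (
    "feature",
    "layer",
    "timepoint",
    "log2fc",
    "p_raw",
    "p_adj",
    "mean_fpkm",
    "detected",
)
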