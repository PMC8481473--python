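"""Small curated reference tables bundled with the package.

These are the published summary-level results of the bleomycin lung-fibrosis
meta-analysis that the pipeline re-derives: the 18-gene overlap between
longevity-associated genes and fibrosis-related genes, the evidence
consistency tallies, and the interactome summary statistics.  They serve as
worked inputs for the arithmetic the package implements (contingency
analysis, consistency percentages, interconnectivity and Z-scores) without
any external download.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "longevity_fibrosis_overlap",
    "ipf_consistency_counts",
    "manipulation_consistency_counts",
    "interactome_summary",
]

# Genes whose manipulation affects both mouse lifespan and bleomycin-induced
# lung fibrosis.  Tert's longevity annotation is flagged uncertain in the
# source curation but is carried as pro-longevity; Rps6kb1 has no clear
# fibrosis effect.
_LAG_PFRG_OVERLAP = [
    ("Akt1", "anti_longevity", "pro_fibrotic"),
    ("Akt2", "anti_longevity", "pro_fibrotic"),
    ("Cav1", "pro_longevity", "anti_fibrotic"),
    ("Fgf2", "pro_longevity", "anti_fibrotic"),
    ("Foxm1", "pro_longevity", "anti_fibrotic"),
    ("Kl", "pro_longevity", "anti_fibrotic"),
    ("Mtor", "anti_longevity", "pro_fibrotic"),
    ("Nos3", "pro_longevity", "anti_fibrotic"),
    ("Parp1", "anti_longevity", "pro_fibrotic"),
    ("Plau", "pro_longevity", "anti_fibrotic"),
    ("Pparg", "pro_longevity", "anti_fibrotic"),
    ("Rps6kb1", "anti_longevity", "unclear"),
    ("Serpine1", "anti_longevity", "pro_fibrotic"),
    ("Sirt1", "pro_longevity", "anti_fibrotic"),
    ("Sod3", "pro_longevity", "anti_fibrotic"),
    ("Tert", "pro_longevity", "pro_fibrotic"),
    ("Txn1", "pro_longevity", "anti_fibrotic"),
    ("Zmpste24", "pro_longevity", "anti_fibrotic"),
]


def longevity_fibrosis_overlap() -> pd.DataFrame:
    """The 18 genes with curated effects on both longevity and lung fibrosis
    (columns gene_id, longevity_effect, fibrosis_call)."""
    return pd.DataFrame(
        _LAG_PFRG_OVERLAP, columns=["gene_id", "longevity_effect", "fibrosis_call"]
    )


def ipf_consistency_counts() -> dict:
    """Published tally of agreement between bleomycin-model manipulation
    effects and gene-expression direction in human IPF, by manipulation."""
    return {"full": 93, "partial": 2, "inconsistent": 10, "not_clear": 12}


def manipulation_consistency_counts() -> dict:
    """Published tally of agreement between different manipulations of the
    same gene."""
    return {"full": 54, "partial": 7, "not_clear": 2}


def interactome_summary() -> dict:
    """Published interactome statistics of the fibrosis gene set: in-graph
    set size, largest-connected-component sizes (whole set and its anti-/
    pro-fibrotic subsets), and the resampling-null moments with the observed
    interconnectivity percentage."""
    return {
        "n_set_in_graph": 190,
        "lcc_size": 107,
        "anti_fibrotic_lcc": 26,
        "pro_fibrotic_lcc": 42,
        "observed_fraction": 56.31,
        "null_mean": 13.9,
        "null_sd": 7.9,
        "null_samples": 1000,
        "set_mean_degree": 64.4,
        "background_mean_degree": 45.5,
        "degree_enrichment_score": 0.6,
    }
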