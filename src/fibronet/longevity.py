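"""Links between fibrosis-related genes and longevity.

Two complementary analyses: (i) cross-classification of pro-/anti-fibrotic
calls against pro-/anti-longevity annotations of longevity-associated genes
(LAGs) with Fisher's exact inference; (ii) per-gene ordinary least squares
of species-level lung expression on (log10) maximum lifespan (MLS) across
mammals, with Benjamini-Hochberg correction, plus the fold-enrichment of
significant correlations in a gene set over the genome-wide background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .curation import FibrosisCall, GeneFibrosisCall

__all__ = [
    "LAGAnnotation",
    "ContingencyTable",
    "MLSDataset",
    "EnrichmentFold",
    "lag_fibrosis_contingency",
    "fit_mls_models",
    "mls_enrichment",
    "read_lag_annotations",
]


@dataclass(frozen=True)
class LAGAnnotation:
    gene_id: str
    longevity_effect: str  # pro_longevity | anti_longevity | unclear


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 longevity-effect x fibrosis-call table with Fisher inference.

    Rows: pro-longevity, anti-longevity.  Columns: anti-fibrotic,
    pro-fibrotic.  ``a``..``d`` in reading order.
    """

    a: int  # pro-longevity & anti-fibrotic
    b: int  # pro-longevity & pro-fibrotic
    c: int  # anti-longevity & anti-fibrotic
    d: int  # anti-longevity & pro-fibrotic
    fisher_p: float
    odds_ratio: float

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class MLSDataset:
    """Species-level expression with per-species maximum lifespan.

    ``expression``: genes x species (one aggregated value per species);
    ``mls``: maximum lifespan in years, indexed by species, all positive,
    aligned with the expression columns.
    """

    expression: pd.DataFrame
    mls: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.expression.columns if s not in self.mls.index]
        if missing:
            raise ValueError(f"species missing lifespan data: {missing}")
        self.mls = self.mls.loc[self.expression.columns].astype(float)
        if (self.mls <= 0).any():
            raise ValueError("maximum lifespan must be positive")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix must be orthology-complete (no NaNs)")

    @classmethod
    def from_samples(
        cls,
        sample_expression: pd.DataFrame,
        sample_to_species: pd.Series,
        mls: pd.Series,
        aggregate: Literal["median", "mean"] = "median",
    ) -> "MLSDataset":
        """Aggregate a genes x samples matrix to one value per species."""
        mapped = sample_to_species.loc[sample_expression.columns]
        grouped = sample_expression.T.groupby(mapped.values)
        agg = grouped.median() if aggregate == "median" else grouped.mean()
        return cls(expression=agg.T, mls=mls)


@dataclass(frozen=True)
class EnrichmentFold:
    observed_rate: float
    expected_rate: float
    fold: float
    fisher_p: float


def read_lag_annotations(path) -> list[LAGAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate genes in LAG annotation table")
    return [
        LAGAnnotation(gene_id=g, longevity_effect=e.lower())
        for g, e in zip(df["gene_id"], df["longevity_effect"])
    ]


def lag_fibrosis_contingency(
    lags: list[LAGAnnotation],
    calls: list[GeneFibrosisCall],
    drop_unclear: bool = True,
) -> ContingencyTable:
    """Cross-classify longevity effect against fibrosis call.

    Genes unclear on either axis (or with no fibrosis effect) are dropped
    when ``drop_unclear`` is set.  Two-sided Fisher exact p (the sum over
    tables with probability not exceeding the observed one at fixed
    margins).
    """
    call_by_gene = {c.gene_id: c.call for c in calls}
    cells = np.zeros((2, 2), dtype=int)
    row_of = {"pro_longevity": 0, "anti_longevity": 1}
    col_of = {FibrosisCall.ANTI_FIBROTIC: 0, FibrosisCall.PRO_FIBROTIC: 1}
    for lag in lags:
        call = call_by_gene.get(lag.gene_id)
        if call is None:
            continue
        if lag.longevity_effect not in row_of or call not in col_of:
            if drop_unclear:
                continue
            raise ValueError(
                f"unclear annotation for {lag.gene_id} with drop_unclear=False"
            )
        cells[row_of[lag.longevity_effect], col_of[call]] += 1
    if cells.sum() == 0:
        raise ValueError("no genes shared between LAG annotations and fibrosis calls")
    if (cells.sum(axis=0) == 0).any() or (cells.sum(axis=1) == 0).any():
        warnings.warn("a margin of the contingency table is zero; Fisher p is 1")
    odds, p = stats.fisher_exact(cells, alternative="two-sided")
    return ContingencyTable(
        a=int(cells[0, 0]),
        b=int(cells[0, 1]),
        c=int(cells[1, 0]),
        d=int(cells[1, 1]),
        fisher_p=float(p),
        odds_ratio=float(odds),
    )


def fit_mls_models(
    data: MLSDataset,
    gene_subset=None,
    mls_transform: Literal["log10", "identity"] = "log10",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of species-level expression on (transformed) maximum
    lifespan.

    P-values come from the slope t-test; Benjamini-Hochberg correction is
    applied across exactly the genes tested in this call.  Genes with
    constant expression are degenerate: slope 0, p 1, flagged.  Returns a
    DataFrame indexed by gene with columns slope, intercept, r_squared,
    p_value, p_adjusted, significant, degenerate.
    """
    if gene_subset is None:
        genes = list(data.expression.index)
    else:
        unknown = [g for g in gene_subset if g not in data.expression.index]
        if unknown:
            raise KeyError(f"genes not in dataset: {unknown[:5]}")
        genes = list(dict.fromkeys(gene_subset))
    if data.expression.shape[1] < 4:
        raise ValueError("at least 4 species are required to fit lifespan models")
    x = data.mls.to_numpy()
    if mls_transform == "log10":
        x = np.log10(x)
    if np.ptp(x) == 0:
        raise ValueError("maximum lifespan is constant across species")
    design = sm.add_constant(x)

    rows = []
    for gene in genes:
        y = data.expression.loc[gene].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append(
                {"gene_id": gene, "slope": 0.0, "intercept": float(y[0]),
                 "r_squared": 0.0, "p_value": 1.0, "degenerate": True}
            )
            continue
        fit = sm.OLS(y, design).fit()
        rows.append(
            {
                "gene_id": gene,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "r_squared": float(fit.rsquared),
                "p_value": float(fit.pvalues[1]),
                "degenerate": False,
            }
        )
    result = pd.DataFrame(rows).set_index("gene_id")
    reject, p_adj, _, _ = multipletests(result["p_value"], alpha=alpha, method="fdr_bh")
    result["p_adjusted"] = p_adj
    result["significant"] = reject
    return result


def mls_enrichment(
    n_sig_set: int, n_set: int, n_sig_background: int, n_background: int
) -> EnrichmentFold:
    """Fold-enrichment of significant lifespan correlations in a gene set.

    The set is contained in the background; the expected rate is the
    background-wide significant fraction.  Fisher exact p on the 2x2 of
    (significant, not) x (set, rest of background).
    """
    if not (0 <= n_sig_set <= n_set <= n_background):
        raise ValueError("require 0 <= n_sig_set <= n_set <= n_background")
    if not (0 <= n_sig_background <= n_background):
        raise ValueError("require 0 <= n_sig_background <= n_background")
    if n_sig_background == 0:
        raise ValueError("no significant genes in the background; fold undefined")
    observed = n_sig_set / n_set
    expected = n_sig_background / n_background
    table = [
        [n_sig_set, n_set - n_sig_set],
        [n_sig_background - n_sig_set, (n_background - n_set) - (n_sig_background - n_sig_set)],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentFold(
        observed_rate=observed, expected_rate=expected, fold=observed / expected,
        fisher_p=float(p),
    )
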