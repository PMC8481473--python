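"""Evolutionary conservation profiling of a gene set against a background.

Inputs are a boolean ortholog presence/absence matrix (genes x species, as
produced by an orthology resource at a fixed stringency).  A gene's overall
conservation is the percentage of species in which it has at least one
ortholog.  For a gene set, the per-species fraction of set genes with an
ortholog is compared with the background (genome-wide) fraction by a
one-degree-of-freedom chi-square goodness-of-fit test on the present/absent
counts, flagging species where the set is enriched or depleted in orthologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OrthologMatrix",
    "SpeciesConservation",
    "gene_conservation",
    "conservation_profile",
]


@dataclass
class OrthologMatrix:
    """Boolean gene x species ortholog presence grid."""

    presence: pd.DataFrame  # index: gene ids, columns: species ids, dtype bool

    def __post_init__(self) -> None:
        if self.presence.index.duplicated().any():
            raise ValueError("duplicate gene ids in ortholog matrix")
        if self.presence.columns.duplicated().any():
            raise ValueError("duplicate species ids in ortholog matrix")
        self.presence = self.presence.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMatrix":
        """Read a TSV whose first column is the gene id and remaining
        columns are species with 0/1 cells."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(presence=df.astype(bool))

    def to_tsv(self, path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t")


@dataclass(frozen=True)
class SpeciesConservation:
    """Set-vs-background ortholog presence for one species."""

    species: str
    set_fraction: float  # percent of set genes with >=1 ortholog
    background_fraction: float
    chi2_stat: float
    p_value: float


def gene_conservation(matrix: OrthologMatrix, gene: str) -> float:
    """Percent of species in which ``gene`` has at least one ortholog."""
    if gene not in matrix.presence.index:
        near = [g for g in matrix.genes if g.lower().startswith(gene[:3].lower())][:5]
        raise KeyError(f"gene {gene!r} not in matrix; nearest ids: {near}")
    row = matrix.presence.loc[gene]
    return 100.0 * float(row.sum()) / len(row)


def _gof_present_absent(observed_present: int, n: int, expected_fraction: float):
    """Two-category (present/absent) chi-square GOF, 1 df, no continuity
    correction.  Degenerate expectations (fraction 0 or 1) are resolved by
    limits: a matching observation gives chi2=0, p=1; any discrepancy gives
    p=0."""
    expected_present = n * expected_fraction
    expected_absent = n - expected_present
    if expected_present == 0 or expected_absent == 0:
        matches = (observed_present == 0) if expected_present == 0 else (observed_present == n)
        return (0.0, 1.0) if matches else (np.inf, 0.0)
    if min(expected_present, expected_absent) < 5:
        warnings.warn(
            f"expected count below 5 (present={expected_present:.2f}, "
            f"absent={expected_absent:.2f}); chi-square approximation is rough",
            stacklevel=3,
        )
    chi2, p = stats.chisquare(
        [observed_present, n - observed_present], [expected_present, expected_absent]
    )
    return float(chi2), float(p)


def conservation_profile(
    matrix: OrthologMatrix,
    gene_set: list[str] | set[str],
    background_set: list[str] | set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-species conservation of ``gene_set`` against a background.

    The background defaults to all genes in the matrix (a genome-wide
    reference).  Gene ids absent from the matrix are dropped and returned;
    an empty set after filtering is an error.  Returns a DataFrame with one
    row per species (columns ``set_fraction``, ``background_fraction``,
    ``chi2_stat``, ``p_value``), sorted by ``set_fraction`` descending
    (stable, so equal fractions keep the matrix's species order).
    """
    genes = set(matrix.presence.index)
    gene_set = list(dict.fromkeys(gene_set))
    dropped = [g for g in gene_set if g not in genes]
    kept = [g for g in gene_set if g in genes]
    if not kept:
        raise ValueError("no gene-set members found in the ortholog matrix")
    if background_set is None:
        background = matrix.presence
    else:
        bg_kept = [g for g in dict.fromkeys(background_set) if g in genes]
        if not bg_kept:
            raise ValueError("no background genes found in the ortholog matrix")
        background = matrix.presence.loc[bg_kept]

    sub = matrix.presence.loc[kept]
    n_set = len(kept)
    rows = []
    for sp in matrix.species:
        observed = int(sub[sp].sum())
        bg_fraction = float(background[sp].mean())
        chi2, p = _gof_present_absent(observed, n_set, bg_fraction)
        rows.append(
            {
                "species": sp,
                "set_fraction": 100.0 * observed / n_set,
                "background_fraction": 100.0 * bg_fraction,
                "chi2_stat": chi2,
                "p_value": p,
            }
        )
    profile = pd.DataFrame(rows).set_index("species")
    profile = profile.sort_values("set_fraction", ascending=False, kind="stable")
    return profile, dropped
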