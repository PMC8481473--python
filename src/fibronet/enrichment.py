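"""Overrepresentation of a query gene set against GMT gene-set libraries.

Per term: a one-sided Fisher exact test for overlap with the query, a
rank-deviation z-score estimated by permutation (how much better the term
ranks for the real query than for random queries of the same size), and a
combined score — the product of the natural log of the Fisher p-value and
the rank z-score, with the sign folded so that enriched terms score
positive.  A term with no overlap has p = 1, hence ln(p) = 0 and a combined
score of exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetLibrary",
    "read_gmt",
    "overrepresent",
]


@dataclass
class GeneSetLibrary:
    """Named gene-set terms with deduplicated members."""

    terms: list[tuple[str, frozenset]]

    def __post_init__(self) -> None:
        cleaned = []
        for name, members in self.terms:
            members = frozenset(members)
            if not members:
                raise ValueError(f"term {name!r} has no members")
            cleaned.append((name, members))
        self.terms = cleaned

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path) -> GeneSetLibrary:
    """Read a GMT file: term <tab> description <tab> member genes."""
    terms = []
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms.append((fields[0], frozenset(g for g in fields[2:] if g)))
    if not terms:
        raise ValueError(f"no terms parsed from GMT file {path}")
    return GeneSetLibrary(terms)


def _fisher_overrep(overlap: int, n_query: int, n_term: int, n_background: int) -> float:
    """One-sided (greater) Fisher p for query/term overlap in a background."""
    table = [
        [overlap, n_term - overlap],
        [n_query - overlap, n_background - n_term - (n_query - overlap)],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _term_pvalues(query: frozenset, terms, n_background: int) -> np.ndarray:
    n_query = len(query)
    return np.array(
        [
            _fisher_overrep(len(query & members), n_query, len(members), n_background)
            for _, members in terms
        ]
    )


def _ranks(pvalues: np.ndarray) -> np.ndarray:
    """Ascending mean ranks (1 = most significant); ties share the average."""
    return stats.rankdata(pvalues, method="average")


def overrepresent(
    query,
    library: GeneSetLibrary,
    background,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every library term for overrepresentation in ``query``.

    ``query`` must be contained in ``background``; term members outside the
    background are ignored.  The rank z-score of a term is
    ``(expected_rank - observed_rank) / sd_rank`` over ``n_perm`` random
    queries of the same size drawn from the background, so terms that rank
    much better for the real query than for random ones get positive z.
    Returns a DataFrame sorted by ``combined_score`` descending with columns
    term, overlap_count, fisher_p, rank_z, combined_score.
    """
    background = frozenset(background)
    query = frozenset(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not query:
        raise ValueError("empty query after intersecting with background")
    terms = [(name, members & background) for name, members in library.terms]
    terms = [(name, members) for name, members in terms if members]
    if not terms:
        raise ValueError("no library term overlaps the background")

    n_bg = len(background)
    observed_p = _term_pvalues(query, terms, n_bg)
    observed_rank = _ranks(observed_p)

    rng = np.random.default_rng(seed)
    bg_list = sorted(background)
    perm_ranks = np.empty((n_perm, len(terms)))
    for i in range(n_perm):
        draw = frozenset(rng.choice(bg_list, size=len(query), replace=False))
        perm_ranks[i] = _ranks(_term_pvalues(draw, terms, n_bg))
    expected_rank = perm_ranks.mean(axis=0)
    sd_rank = perm_ranks.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rank_z = np.where(sd_rank > 0, (expected_rank - observed_rank) / sd_rank, 0.0)

    log_p = np.log(observed_p)
    combined = np.abs(log_p * rank_z) * np.sign(rank_z)

    out = pd.DataFrame(
        {
            "term": [name for name, _ in terms],
            "overlap_count": [len(query & members) for _, members in terms],
            "fisher_p": observed_p,
            "rank_z": rank_z,
            "combined_score": combined,
        }
    )
    return out.sort_values("combined_score", ascending=False, kind="stable").reset_index(
        drop=True
    )
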