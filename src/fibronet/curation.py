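"""Classification of genes as pro- or anti-fibrotic from manipulation records.

The curated evidence base consists of genetic and protein-level interventions
(knockouts, overexpression, protein inhibitors/agonists, microRNA
manipulations) performed in the mouse bleomycin model of lung fibrosis, each
annotated with its effect on the fibrosis outcome.  A gene is anti-fibrotic
if raising its activity reduced fibrosis and/or lowering it promoted
fibrosis; the mirror pattern defines pro-fibrotic.  This module turns a
table of such records into per-gene calls, and scores how consistent the
evidence is across manipulations and against expression direction in human
idiopathic pulmonary fibrosis (IPF).
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Manipulation",
    "Direction",
    "Outcome",
    "FibrosisCall",
    "ManipulationRecord",
    "GeneFibrosisCall",
    "ConsistencySummary",
    "IPFDirectionRecord",
    "classify_gene",
    "classify_table",
    "manipulation_consistency",
    "ipf_consistency",
    "read_records",
    "read_ipf_directions",
]


class Manipulation(str, enum.Enum):
    KNOCKOUT = "knockout"
    KNOCKDOWN = "knockdown"
    OVEREXPRESSION = "overexpression"
    PROTEIN_INHIBITION = "protein_inhibition"
    PROTEIN_AGONIST = "protein_agonist"
    MIR_KNOCKOUT = "mir_knockout"
    MIR_OVEREXPRESSION = "mir_overexpression"


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"


class Outcome(str, enum.Enum):
    REDUCED_FIBROSIS = "reduced_fibrosis"
    PROMOTED_FIBROSIS = "promoted_fibrosis"
    NO_EFFECT = "no_effect"
    MIXED = "mixed"


class FibrosisCall(str, enum.Enum):
    ANTI_FIBROTIC = "anti_fibrotic"
    PRO_FIBROTIC = "pro_fibrotic"
    UNCLEAR = "unclear"
    NO_EFFECT = "no_effect"


#: Direction of gene/protein activity implied by each manipulation type.
#: Loss-of-function interventions (KO, knockdown, inhibitors/antibodies,
#: miR knockout) push activity down; gain-of-function (overexpression,
#: agonists/external protein, miR overexpression) push it up.
DIRECTION_OF: dict[Manipulation, Direction] = {
    Manipulation.KNOCKOUT: Direction.DOWN,
    Manipulation.KNOCKDOWN: Direction.DOWN,
    Manipulation.PROTEIN_INHIBITION: Direction.DOWN,
    Manipulation.MIR_KNOCKOUT: Direction.DOWN,
    Manipulation.OVEREXPRESSION: Direction.UP,
    Manipulation.PROTEIN_AGONIST: Direction.UP,
    Manipulation.MIR_OVEREXPRESSION: Direction.UP,
}


@dataclass(frozen=True)
class ManipulationRecord:
    """One intervention on one gene in one study, with its fibrosis outcome.

    ``direction`` is derived from ``manipulation`` and never stored
    independently, so a record cannot contradict itself.
    """

    gene_id: str
    study_id: str
    manipulation: Manipulation
    outcome: Outcome
    model: str = "bleomycin"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def direction(self) -> Direction:
        return DIRECTION_OF[self.manipulation]

    @property
    def vote(self) -> FibrosisCall | None:
        """Evidence this record casts, or None for non-informative outcomes.

        (up, reduced) or (down, promoted) -> anti-fibrotic;
        (up, promoted) or (down, reduced) -> pro-fibrotic.
        """
        if self.outcome in (Outcome.NO_EFFECT, Outcome.MIXED):
            return None
        reduced = self.outcome is Outcome.REDUCED_FIBROSIS
        up = self.direction is Direction.UP
        return FibrosisCall.ANTI_FIBROTIC if reduced == up else FibrosisCall.PRO_FIBROTIC


@dataclass(frozen=True)
class GeneFibrosisCall:
    gene_id: str
    call: FibrosisCall
    n_records: int
    n_studies: int


@dataclass(frozen=True)
class IPFDirectionRecord:
    gene_id: str
    ipf_direction: str  # up | down | unchanged | mixed


@dataclass
class ConsistencySummary:
    """Category counts with percentages recomputed as 100*count/total (1 dp)."""

    counts: dict[str, int]
    skipped: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: round(100.0 * v / total, 1) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {"count": self.counts, "percentage": {k: pct[k] for k in self.counts}}
        )


def classify_gene(records: list[ManipulationRecord]) -> GeneFibrosisCall:
    """Call a gene pro-/anti-fibrotic from all its manipulation records.

    The call is ``anti_fibrotic`` if every informative record supports it,
    ``pro_fibrotic`` likewise, ``unclear`` if both kinds of evidence exist,
    and ``no_effect`` if no record is informative.
    """
    if not records:
        raise ValueError("classify_gene requires at least one record")
    genes = {r.gene_id for r in records}
    if len(genes) > 1:
        raise ValueError(f"records mix gene_ids: {sorted(genes)}")

    votes = Counter(r.vote for r in records if r.vote is not None)
    anti = votes[FibrosisCall.ANTI_FIBROTIC]
    pro = votes[FibrosisCall.PRO_FIBROTIC]
    if anti and pro:
        call = FibrosisCall.UNCLEAR
    elif anti:
        call = FibrosisCall.ANTI_FIBROTIC
    elif pro:
        call = FibrosisCall.PRO_FIBROTIC
    else:
        call = FibrosisCall.NO_EFFECT
    return GeneFibrosisCall(
        gene_id=records[0].gene_id,
        call=call,
        n_records=len(records),
        n_studies=len({r.study_id for r in records}),
    )


def _group_by_gene(records: list[ManipulationRecord]) -> dict[str, list[ManipulationRecord]]:
    grouped: dict[str, list[ManipulationRecord]] = {}
    for r in records:
        grouped.setdefault(r.gene_id, []).append(r)
    return grouped


def classify_table(
    records: list[ManipulationRecord], bleomycin_only: bool = False
) -> list[GeneFibrosisCall]:
    """Classify every gene in a record table.

    Records from non-bleomycin fibrosis models participate by default (their
    effects track the bleomycin model in the curated evidence); pass
    ``bleomycin_only=True`` to restrict.
    """
    if bleomycin_only:
        records = [r for r in records if r.model == "bleomycin"]
    return [classify_gene(rs) for rs in _group_by_gene(records).values()]


def manipulation_consistency(
    records: list[ManipulationRecord],
    weight_by: str = "gene",
) -> tuple[dict[str, str], ConsistencySummary]:
    """Score agreement between different manipulations of the same gene.

    Only genes probed with two or more distinct manipulation types are
    scored; single-manipulation genes land in ``summary.skipped``.  Per-gene
    category: ``full`` if all manipulations cast the same vote, ``not_clear``
    if any manipulation casts no vote (no-effect/mixed outcomes), else
    ``partial`` (agreement with dissent; a tie counts as partial, see docs).
    Votes are per manipulation type: records of the same type are pooled and
    must themselves agree to yield a vote.

    ``weight_by`` selects the summary tally: ``"gene"`` counts each scored
    gene once; ``"manipulation"`` counts it once per distinct manipulation
    type, for summaries phrased in numbers of manipulations.
    """
    if weight_by not in ("gene", "manipulation"):
        raise ValueError("weight_by must be 'gene' or 'manipulation'")
    categories: dict[str, str] = {}
    weights: dict[str, int] = {}
    skipped: list[str] = []
    for gene, recs in _group_by_gene(records).items():
        by_manip: dict[Manipulation, list[ManipulationRecord]] = {}
        for r in recs:
            by_manip.setdefault(r.manipulation, []).append(r)
        if len(by_manip) < 2:
            skipped.append(gene)
            continue
        manip_votes = []
        for rs in by_manip.values():
            votes = {r.vote for r in rs if r.vote is not None}
            if len(votes) == 1 and None not in {r.vote for r in rs}:
                manip_votes.append(votes.pop())
            else:
                manip_votes.append(None)
        if None in manip_votes:
            categories[gene] = "not_clear"
        elif len(set(manip_votes)) == 1:
            categories[gene] = "full"
        else:
            categories[gene] = "partial"
        weights[gene] = len(by_manip) if weight_by == "manipulation" else 1
    counts = Counter()
    for gene, cat in categories.items():
        counts[cat] += weights[gene]
    summary = ConsistencySummary(
        counts={k: counts.get(k, 0) for k in ("full", "partial", "not_clear")},
        skipped=sorted(skipped),
    )
    return categories, summary


def ipf_consistency(
    calls: list[GeneFibrosisCall], ipf: list[IPFDirectionRecord]
) -> ConsistencySummary:
    """Compare bleomycin-model calls with expression direction in human IPF.

    ``full``: pro-fibrotic & up-in-IPF, or anti-fibrotic & down-in-IPF.
    ``inconsistent``: the crossed pairs.  ``partial``: IPF direction mixed
    (one direction matches whichever call was made).  ``not_clear``: unclear
    call, unchanged IPF expression, or gene absent from the IPF table.
    """
    ipf_by_gene = {r.gene_id: r.ipf_direction.lower() for r in ipf}
    counts = Counter()
    for call in calls:
        direction = ipf_by_gene.get(call.gene_id)
        if direction is None:
            logger.warning("gene %s missing from IPF table; counted not_clear", call.gene_id)
            counts["not_clear"] += 1
            continue
        if call.call in (FibrosisCall.UNCLEAR, FibrosisCall.NO_EFFECT) or direction == "unchanged":
            counts["not_clear"] += 1
        elif direction == "mixed":
            counts["partial"] += 1
        elif (call.call is FibrosisCall.PRO_FIBROTIC) == (direction == "up"):
            counts["full"] += 1
        else:
            counts["inconsistent"] += 1
    return ConsistencySummary(
        counts={k: counts.get(k, 0) for k in ("full", "partial", "inconsistent", "not_clear")}
    )


def read_records(path) -> list[ManipulationRecord]:
    """Read a manipulation-record TSV (gene_id, study_id, manipulation,
    outcome, model).  Enum columns are case-insensitive."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "study_id", "manipulation", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    records = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.study_id, row.gene_id, row.manipulation.lower())
        if key in seen:
            raise ValueError(f"duplicate record for (study, gene, manipulation) {key}")
        seen.add(key)
        records.append(
            ManipulationRecord(
                gene_id=row.gene_id,
                study_id=row.study_id,
                manipulation=Manipulation(row.manipulation.lower()),
                outcome=Outcome(row.outcome.lower()),
                model=getattr(row, "model", "bleomycin") or "bleomycin",
            )
        )
    return records


def read_ipf_directions(path) -> list[IPFDirectionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate genes in IPF table: {dupes}")
    return [
        IPFDirectionRecord(gene_id=g, ipf_direction=d.lower())
        for g, d in zip(df["gene_id"], df["ipf_direction"])
    ]
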