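"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one of the study-style inputs — manipulation-record
tables, ortholog presence/absence matrices, a cleaned physical interactome,
and a cross-species lung expression / maximum-lifespan dataset — with
controllable planted signal, so classification, conservation profiling,
interconnectivity statistics and lifespan modelling can all be exercised and
power-checked without any external downloads.

One top-level seed fans out to fixed per-generator sub-seeds (a documented
derivation over :class:`numpy.random.SeedSequence`), so regenerating one
input never shifts the others, and identical config+seed gives byte-identical
output on any platform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .conservation import OrthologMatrix
from .curation import (
    DIRECTION_OF,
    Direction,
    IPFDirectionRecord,
    Manipulation,
    ManipulationRecord,
    Outcome,
)
from .longevity import MLSDataset
from .network import Interactome

__all__ = [
    "TierSpec",
    "SimulationConfig",
    "SimulatedInteractome",
    "SimulatedOrthologMatrix",
    "SimulatedRecords",
    "SimulatedMLS",
    "simulate_interactome",
    "simulate_ortholog_matrix",
    "simulate_manipulation_records",
    "simulate_mls_expression",
]

# Fixed stream labels for seed fan-out; never reorder.
_STREAMS = {"interactome": 1, "orthologs": 2, "records": 3, "mls": 4}


def _rng(config: "SimulationConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STREAMS[stream])))


@dataclass(frozen=True)
class TierSpec:
    """One conservation tier: species count, background ortholog-presence
    probability, and the shift applied to planted-set genes."""

    n_species: int
    background_presence: float
    set_shift: float = 0.0


@dataclass
class SimulationConfig:
    """Study-condition knobs for all generators.

    Defaults mirror the scale of the emulated study: a dense scale-free
    interactome (3000 nodes, attachment 18, planted 100-gene module),
    a two-tier ortholog matrix over-representing the planted set in
    vertebrates, ~216 manipulated genes at 85% evidence concordance, and a
    14-species / 2-replicate lifespan-expression panel with 30% of 90 genes
    carrying a true lifespan slope.
    """

    seed: int = 17
    # interactome
    n_nodes: int = 3000
    attachment_parameter: int = 18
    planted_module_size: int = 100
    planted_module_multiplier: float = 8.0
    # ortholog matrix
    n_genes: int = 2000
    n_set_genes: int = 100
    conservation_tiers: dict = field(
        default_factory=lambda: {
            "vertebrate": TierSpec(60, 0.80, +0.15),
            "invertebrate": TierSpec(40, 0.40, -0.20),
        }
    )
    # manipulation records
    n_manip_genes: int = 216
    concordance_rate: float = 0.85
    # lifespan expression panel
    n_mls_genes: int = 90
    n_mls_species: int = 14
    samples_per_species: int = 2
    planted_slope: float = 1.0
    noise_sd: float = 0.5
    planted_fraction: float = 0.3
    mls_range_years: tuple = (2.0, 60.0)

    def __post_init__(self) -> None:
        counts = (
            self.n_nodes,
            self.attachment_parameter,
            self.planted_module_size,
            self.n_genes,
            self.n_set_genes,
            self.n_manip_genes,
            self.n_mls_genes,
            self.n_mls_species,
            self.samples_per_species,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.planted_module_multiplier < 1:
            raise ValueError("planted module multiplier must be >= 1")
        if not 0 <= self.concordance_rate <= 1:
            raise ValueError("concordance_rate must lie in [0, 1]")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.planted_module_size >= self.n_nodes:
            raise ValueError("planted module must be smaller than the interactome")
        tiers = dict(self.conservation_tiers)
        if sum(t.n_species for t in tiers.values()) < 1:
            raise ValueError("conservation tiers must contain at least one species")
        for name, tier in tiers.items():
            if not 0 <= tier.background_presence <= 1:
                raise ValueError(f"tier {name}: background presence outside [0, 1]")
            if not 0 <= tier.background_presence + tier.set_shift <= 1:
                raise ValueError(f"tier {name}: shifted presence outside [0, 1]")

    @property
    def n_species(self) -> int:
        return sum(t.n_species for t in self.conservation_tiers.values())

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "conservation_tiers" in raw:
            raw["conservation_tiers"] = {
                name: TierSpec(**spec) for name, spec in raw["conservation_tiers"].items()
            }
        if "mls_range_years" in raw:
            raw["mls_range_years"] = tuple(raw["mls_range_years"])
        return cls(**raw)


def _write_ground_truth(path, payload: dict) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, default=str)


# ---------------------------------------------------------------------------
# interactome


@dataclass
class SimulatedInteractome:
    interactome: Interactome
    module_genes: list
    config: SimulationConfig

    def ground_truth(self) -> dict:
        return {
            "module_genes": list(self.module_genes),
            "planted_module_size": self.config.planted_module_size,
            "planted_module_multiplier": self.config.planted_module_multiplier,
            "n_nodes": self.config.n_nodes,
        }

    def write_edge_list(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("symbol_a\tsymbol_b\n")
            for u, v in sorted(self.interactome.graph.edges):
                handle.write(f"{u}\t{v}\n")

    def write_biogrid_tab(self, path, organism: str = "9606") -> None:
        rows = pd.DataFrame(
            sorted(self.interactome.graph.edges),
            columns=["Official Symbol Interactor A", "Official Symbol Interactor B"],
        )
        rows["Experimental System Type"] = "physical"
        rows["Organism Interactor A"] = organism
        rows["Organism Interactor B"] = organism
        rows.to_csv(path, sep="\t", index=False)

    def write_module(self, path) -> None:
        with open(path, "w") as handle:
            handle.writelines(f"{g}\n" for g in self.module_genes)

    def write_ground_truth(self, path) -> None:
        _write_ground_truth(path, self.ground_truth())


def simulate_interactome(config: SimulationConfig) -> SimulatedInteractome:
    """Scale-free interactome with an optionally densified planted module.

    The backbone is a preferential-attachment graph (heavy-tailed degrees,
    as real interactomes).  A random node subset of the configured size is
    then rewired internally: each absent within-module edge is added with
    probability ``(multiplier - 1) * density``, so multiplier 1 plants no
    signal and the module is statistically a random set.
    """
    rng = _rng(config, "interactome")
    g = nx.barabasi_albert_graph(
        config.n_nodes, config.attachment_parameter, seed=int(rng.integers(2**31))
    )
    density = 2 * g.number_of_edges() / (config.n_nodes * (config.n_nodes - 1))
    p_extra = (config.planted_module_multiplier - 1.0) * density
    if config.planted_module_multiplier * density > 1:
        warnings.warn("planted internal edge probability exceeds 1; clipped")
    p_extra = min(1.0, p_extra)
    module = np.sort(rng.choice(config.n_nodes, config.planted_module_size, replace=False))
    if p_extra > 0:
        ii, jj = np.triu_indices(config.planted_module_size, 1)
        add = rng.random(len(ii)) < p_extra
        g.add_edges_from(zip(module[ii[add]].tolist(), module[jj[add]].tolist()))
    width = len(str(config.n_nodes - 1))
    name = {i: f"G{i:0{width}d}" for i in g.nodes}
    graph = nx.relabel_nodes(g, name)
    return SimulatedInteractome(
        interactome=Interactome(graph, provenance=f"synthetic(seed={config.seed})"),
        module_genes=[name[i] for i in module],
        config=config,
    )


# ---------------------------------------------------------------------------
# ortholog matrix


@dataclass
class SimulatedOrthologMatrix:
    matrix: OrthologMatrix
    set_genes: list
    tier_of_species: dict
    config: SimulationConfig

    def ground_truth(self) -> dict:
        return {
            "set_genes": list(self.set_genes),
            "tier_of_species": dict(self.tier_of_species),
            "tiers": {k: asdict(t) for k, t in self.config.conservation_tiers.items()},
        }

    def write_matrix(self, path) -> None:
        self.matrix.to_tsv(path)

    def write_set(self, path) -> None:
        with open(path, "w") as handle:
            handle.writelines(f"{g}\n" for g in self.set_genes)

    def write_ground_truth(self, path) -> None:
        _write_ground_truth(path, self.ground_truth())


def simulate_ortholog_matrix(config: SimulationConfig) -> SimulatedOrthologMatrix:
    """Tiered presence/absence matrix with a conservation-shifted gene set.

    Background genes have orthologs in each species with the tier's
    background probability; planted-set genes get the tier's shift added
    (positive in the vertebrate-like tier, negative in the invertebrate-like
    tier by default), emulating a gene set over-represented in vertebrates
    and under-represented in invertebrates.
    """
    rng = _rng(config, "orthologs")
    genes = [f"O{i:05d}" for i in range(config.n_genes)]
    set_idx = np.sort(rng.choice(config.n_genes, config.n_set_genes, replace=False))
    in_set = np.zeros(config.n_genes, dtype=bool)
    in_set[set_idx] = True

    columns = {}
    tier_of_species = {}
    for tier_name, tier in config.conservation_tiers.items():
        for k in range(tier.n_species):
            sp = f"{tier_name}_{k:03d}"
            tier_of_species[sp] = tier_name
            p = np.where(
                in_set,
                tier.background_presence + tier.set_shift,
                tier.background_presence,
            )
            columns[sp] = rng.random(config.n_genes) < p
    matrix = OrthologMatrix(pd.DataFrame(columns, index=genes))
    return SimulatedOrthologMatrix(
        matrix=matrix,
        set_genes=[genes[i] for i in set_idx],
        tier_of_species=tier_of_species,
        config=config,
    )


# ---------------------------------------------------------------------------
# manipulation records


@dataclass
class SimulatedRecords:
    records: list
    true_labels: dict  # gene -> "anti_fibrotic" | "pro_fibrotic"
    ipf_directions: list
    config: SimulationConfig

    def ground_truth(self) -> dict:
        return {"true_labels": dict(self.true_labels)}

    def write_records(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "study_id": r.study_id,
                    "manipulation": r.manipulation.value,
                    "outcome": r.outcome.value,
                    "model": r.model,
                }
                for r in self.records
            ]
        ).to_csv(path, sep="\t", index=False)

    def write_ipf(self, path) -> None:
        pd.DataFrame(
            [{"gene_id": r.gene_id, "ipf_direction": r.ipf_direction} for r in self.ipf_directions]
        ).to_csv(path, sep="\t", index=False)

    def write_ground_truth(self, path) -> None:
        _write_ground_truth(path, self.ground_truth())


def simulate_manipulation_records(config: SimulationConfig) -> SimulatedRecords:
    """Manipulation-record table with known pro-/anti-fibrotic labels.

    Each gene receives one to four distinct manipulation types; every
    record's outcome matches the gene's true label with probability
    ``concordance_rate`` (and is flipped otherwise).  The paired IPF
    expression-direction table matches the label (pro-fibrotic up,
    anti-fibrotic down in disease) at the same rate.
    """
    rng = _rng(config, "records")
    manipulations = list(Manipulation)
    records = []
    labels = {}
    ipf = []
    for i in range(config.n_manip_genes):
        gene = f"F{i:04d}"
        anti = bool(rng.random() < 0.5)
        labels[gene] = "anti_fibrotic" if anti else "pro_fibrotic"
        n_manip = int(rng.integers(1, 5))
        chosen = rng.choice(len(manipulations), size=n_manip, replace=False)
        for j, mi in enumerate(np.sort(chosen)):
            manip = manipulations[mi]
            up = DIRECTION_OF[manip] is Direction.UP
            concordant = bool(rng.random() < config.concordance_rate)
            # anti-fibrotic gene: raising it reduces fibrosis
            reduces = (anti == up) if concordant else (anti != up)
            records.append(
                ManipulationRecord(
                    gene_id=gene,
                    study_id=f"S{i:04d}_{j}",
                    manipulation=manip,
                    outcome=Outcome.REDUCED_FIBROSIS if reduces else Outcome.PROMOTED_FIBROSIS,
                    model="bleomycin",
                )
            )
        concordant = bool(rng.random() < config.concordance_rate)
        up_in_ipf = (not anti) if concordant else anti
        ipf.append(IPFDirectionRecord(gene_id=gene, ipf_direction="up" if up_in_ipf else "down"))
    return SimulatedRecords(records=records, true_labels=labels, ipf_directions=ipf, config=config)


# ---------------------------------------------------------------------------
# lifespan expression panel


@dataclass
class SimulatedMLS:
    sample_expression: pd.DataFrame  # genes x samples
    sample_to_species: pd.Series
    mls: pd.Series  # years per species
    planted_genes: list
    config: SimulationConfig

    @property
    def dataset(self) -> MLSDataset:
        return MLSDataset.from_samples(self.sample_expression, self.sample_to_species, self.mls)

    def ground_truth(self) -> dict:
        return {
            "planted_genes": list(self.planted_genes),
            "planted_slope": self.config.planted_slope,
            "noise_sd": self.config.noise_sd,
        }

    def write_expression(self, path) -> None:
        self.sample_expression.to_csv(path, sep="\t", index_label="gene_id")

    def write_sample_map(self, path) -> None:
        self.sample_to_species.rename("species").to_csv(path, sep="\t", index_label="sample")

    def write_mls(self, path) -> None:
        self.mls.rename("max_lifespan_years").to_csv(path, sep="\t", index_label="species")

    def write_ground_truth(self, path) -> None:
        _write_ground_truth(path, self.ground_truth())


def simulate_mls_expression(config: SimulationConfig) -> SimulatedMLS:
    """Cross-species expression panel with genes planted on lifespan.

    Maximum lifespans are log-uniform over the configured range (default
    2-60 years, a mammalian span).  For a planted gene, each replicate
    sample of a species reads ``slope * log10(MLS) + Normal(0, noise_sd)``;
    null genes are pure noise.  Replicates of a species differ by
    independent noise draws, which is what per-species aggregation then
    averages over.
    """
    if config.n_mls_species < 4:
        raise ValueError("need at least 4 species for lifespan modelling")
    rng = _rng(config, "mls")
    lo, hi = config.mls_range_years
    mls = pd.Series(
        10 ** rng.uniform(np.log10(lo), np.log10(hi), config.n_mls_species),
        index=[f"species_{i:02d}" for i in range(config.n_mls_species)],
    )
    x = np.log10(mls.to_numpy())
    genes = [f"L{i:04d}" for i in range(config.n_mls_genes)]
    n_planted = int(round(config.planted_fraction * config.n_mls_genes))
    planted_idx = np.sort(rng.choice(config.n_mls_genes, n_planted, replace=False))
    is_planted = np.zeros(config.n_mls_genes, dtype=bool)
    is_planted[planted_idx] = True

    samples, species_of = [], []
    for sp in mls.index:
        for r in range(config.samples_per_species):
            samples.append(f"{sp}_r{r}")
            species_of.append(sp)
    signal = np.where(is_planted[:, None], config.planted_slope * x[None, :], 0.0)
    data = np.empty((config.n_mls_genes, len(samples)))
    for j, sp in enumerate(species_of):
        sp_idx = mls.index.get_loc(sp)
        data[:, j] = signal[:, sp_idx] + rng.normal(0.0, config.noise_sd, config.n_mls_genes)
    return SimulatedMLS(
        sample_expression=pd.DataFrame(data, index=genes, columns=samples),
        sample_to_species=pd.Series(species_of, index=samples),
        mls=mls,
        planted_genes=[genes[i] for i in planted_idx],
        config=config,
    )
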