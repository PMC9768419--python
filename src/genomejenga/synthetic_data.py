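"""Synthetic inputs emulating the study conditions, so every stage of the
pipeline is testable without external downloads.

Two generators:

* :func:`simulate_mutations` — an evolution-experiment-like mutation time
  series.  Each gene accumulates mutations as a Poisson process whose rate
  is proportional to its length in nucleotides, with a genome-wide
  hypermutator rate increase from a configurable onset generation, and
  multiplicative selection factors on named focal gene sets (a factor < 1
  thins observed mutations, the footprint of purifying selection that the
  STIMS test detects; > 1 models positive selection; = 1 is neutral).
  Event times are discretized up to the next sampling-interval boundary,
  mimicking periodic metagenomic sampling.

* :func:`generate_toy_model` — small metabolic models with controllable
  redundancy (parallel pathways, isozyme pairs, generalist genes) whose FBA
  optima are hand-computable (all yields are 1, so the ancestral optimum
  equals the substrate uptake bound).  These are the test bed on which
  replicate Jenga games diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba_core import MetabolicModel, Reaction
from .gene_sets import GeneSet
from .io_formats import Annotation, GeneAnnotation, MutationRecord, MutationTable

__all__ = [
    "MutationSimConfig",
    "ToyModelConfig",
    "simulate_mutations",
    "generate_toy_model",
]


@dataclass
class MutationSimConfig:
    """Conditions for the mutation-series simulator.

    Defaults mirror a hypermutator lineage in a decades-long serial-transfer
    experiment: a wild-type per-nucleotide appearance rate of 1e-10 per
    generation, a 100-fold mutator arising at generation 5,000, a 50,000-
    generation series sampled every 500 generations, and ~500 genes of
    realistic bacterial lengths (0.5-2 kb).
    """

    n_genes: int = 500
    length_range: tuple[int, int] = (500, 2000)
    mu: float = 1e-10  # per nucleotide per generation
    hypermutator_onset: float = 5000.0
    fold_increase: float = 100.0
    duration: float = 50000.0
    sampling_interval: float = 500.0
    gene_set_sizes: dict[str, int] = field(default_factory=dict)
    selection_factors: dict[str, float] = field(default_factory=dict)
    explicit_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    population: str = "pop-1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.fold_increase < 1:
            raise ValueError("mu must be >= 0 and fold_increase >= 1")
        if not 0 <= self.hypermutator_onset <= self.duration:
            raise ValueError("hypermutator_onset must lie within [0, duration]")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if any(f <= 0 for f in self.selection_factors.values()):
            raise ValueError("selection factors must be positive")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with 1 <= min <= max")
        overlap = set(self.gene_set_sizes) & set(self.explicit_sets)
        if overlap:
            raise ValueError(
                f"sets {sorted(overlap)} defined both by size and explicitly"
            )


def simulate_mutations(config: MutationSimConfig):
    """Draw one mutation time series.

    Returns ``(mutations, annotation, gene_sets)`` where ``gene_sets`` holds
    the ground-truth focal sets (named random subsets of the simulated
    universe, plus any explicit sets), for power and calibration studies.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    for name in sorted(config.explicit_sets):
        for gid in config.explicit_sets[name]:
            if gid not in gene_ids:
                gene_ids.append(gid)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=len(gene_ids))
    annotation = Annotation(
        GeneAnnotation(gene_id=g, length_nt=int(n))
        for g, n in zip(gene_ids, lengths)
    )

    # assign named random sets disjointly from the background genes
    gene_sets: dict[str, GeneSet] = {}
    available = [g for g in gene_ids if not any(
        g in members for members in config.explicit_sets.values()
    )]
    pool = list(rng.permutation(available))
    for name in sorted(config.gene_set_sizes):
        size = config.gene_set_sizes[name]
        if size > len(pool):
            raise ValueError(f"set {name!r} of size {size} exhausts the gene pool")
        members, pool = pool[:size], pool[size:]
        gene_sets[name] = GeneSet(name=name, members=frozenset(members))
    for name in sorted(config.explicit_sets):
        gene_sets[name] = GeneSet(
            name=name, members=frozenset(config.explicit_sets[name])
        )

    factor_by_gene = {g: 1.0 for g in gene_ids}
    for name, factor in config.selection_factors.items():
        if name not in gene_sets:
            raise ValueError(f"selection factor names unknown set {name!r}")
        for g in gene_sets[name].members:
            factor_by_gene[g] = factor

    eras = [
        (0.0, config.hypermutator_onset, config.mu),
        (config.hypermutator_onset, config.duration, config.mu * config.fold_increase),
    ]
    records = []
    for g in gene_ids:
        length = annotation.length(g)
        factor = factor_by_gene[g]
        for start, end, rate in eras:
            span = end - start
            if span <= 0 or rate == 0:
                continue
            n_events = rng.poisson(length * rate * factor * span)
            if n_events == 0:
                continue
            times = rng.uniform(start, end, size=n_events)
            # observed at the next metagenomic sampling point
            observed = np.minimum(
                np.ceil(times / config.sampling_interval) * config.sampling_interval,
                config.duration,
            )
            records.extend(
                MutationRecord(
                    population=config.population,
                    generation=float(t),
                    gene_id=g,
                )
                for t in observed
            )
    records.sort(key=lambda r: (r.generation, r.gene_id))
    return MutationTable(records), annotation, gene_sets


@dataclass
class ToyModelConfig:
    """Shape of a redundant toy metabolic model.

    ``n_pathways`` parallel routes, each fully sufficient on its own;
    ``genes_per_pathway`` gives per-route gene counts (an int applies to
    every route; unequal counts make genome sizes diverge under Jenga).
    ``n_trunk_genes`` prepends a shared, non-redundant linear chain that
    every route depends on — its genes can never be lost, so they form the
    guaranteed core of any ensemble.  Isozyme pairs add an OR-partner gene
    to route reactions; generalist genes are OR-ed into one reaction of
    every route, so a single gene can sustain flux through multiple
    reactions.
    """

    n_pathways: int = 2
    genes_per_pathway: int | tuple[int, ...] = 2
    n_trunk_genes: int = 0
    n_isozyme_pairs: int = 0
    n_generalist_genes: int = 0
    uptake_bound: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        if isinstance(self.genes_per_pathway, int):
            self.genes_per_pathway = (self.genes_per_pathway,) * self.n_pathways
        else:
            self.genes_per_pathway = tuple(self.genes_per_pathway)
        if len(self.genes_per_pathway) != self.n_pathways:
            raise ValueError("genes_per_pathway length must equal n_pathways")
        if any(k < 1 for k in self.genes_per_pathway):
            raise ValueError("each pathway needs at least one gene")
        if min(self.n_isozyme_pairs, self.n_generalist_genes, self.n_trunk_genes) < 0:
            raise ValueError("counts must be >= 0")
        if self.uptake_bound <= 0:
            raise ValueError("uptake_bound must be positive")


def generate_toy_model(config: ToyModelConfig) -> MetabolicModel:
    """Build the toy model; its FBA optimum equals ``uptake_bound``.

    All stoichiometric coefficients are 1, so yields are 1 throughout and
    every expected optimum is hand-computable.  The model serializes to
    BiGG-JSON and round-trips through the model reader.
    """
    rng = np.random.default_rng(config.seed)
    big = 1000.0
    metabolites = ["S", "B"]
    reactions = [
        Reaction("EX_S", {"S": -1.0}, -config.uptake_bound, big),
        Reaction("BIOMASS", {"B": -1.0}, 0.0, big),
    ]
    genes: list[str] = []
    pathway_reactions: list[list[int]] = []

    # shared non-redundant trunk: S -> T_1 -> ... -> T_n, one gene each
    route_start = "S"
    for j in range(1, config.n_trunk_genes + 1):
        product = f"T_{j}"
        metabolites.append(product)
        gene = f"trunk_g{j}"
        genes.append(gene)
        reactions.append(
            Reaction(f"TRUNK{j}", {route_start: -1.0, product: 1.0}, 0.0, big,
                     gpr=gene)
        )
        route_start = product

    for p, k in enumerate(config.genes_per_pathway, start=1):
        previous = route_start
        indices = []
        for j in range(1, k + 1):
            product = "B" if j == k else f"M_p{p}_{j}"
            if product != "B":
                metabolites.append(product)
            gene = f"p{p}_g{j}"
            genes.append(gene)
            reactions.append(
                Reaction(
                    f"P{p}R{j}", {previous: -1.0, product: 1.0}, 0.0, big, gpr=gene
                )
            )
            indices.append(len(reactions) - 1)
            previous = product
        pathway_reactions.append(indices)

    # isozymes: OR-partner genes on route reactions, spread round-robin
    flat = [i for route in pathway_reactions for i in route]
    order = list(rng.permutation(len(flat)))
    for n in range(config.n_isozyme_pairs):
        idx = flat[order[n % len(flat)]]
        iso = f"iso_{n + 1}"
        genes.append(iso)
        rxn = reactions[idx]
        rxn.gpr = f"{rxn.gpr} or {iso}"

    # generalists: one gene OR-ed into a random reaction of every pathway
    for n in range(config.n_generalist_genes):
        gen = f"gen_{n + 1}"
        genes.append(gen)
        for route in pathway_reactions:
            idx = route[int(rng.integers(len(route)))]
            rxn = reactions[idx]
            rxn.gpr = f"({rxn.gpr}) or {gen}" if " " in rxn.gpr else f"{rxn.gpr} or {gen}"

    return MetabolicModel(
        id=f"toy_{config.n_pathways}x{'-'.join(map(str, config.genes_per_pathway))}",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction="BIOMASS",
        medium={},
    )
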