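"""Genome Jenga: reductive genome evolution under near-neutral purifying
selection, played on a metabolic model.

Genes are drawn in random order and removed whenever the loss is accepted
under the nearly-neutral threshold: a deletion fixes if it is beneficial or
if its relative fitness defect is below s = 1/Ne (default Ne = 3.3e7, the
effective population size of a large serial-transfer evolution experiment).
Fitness is the flux-balance biomass objective.  The game continues until no
single remaining gene can be removed; that terminal gene complement is a
*minimal genome*.  Replicates differ only by seed, and because redundancy
is lost in a random order, replicate minimal genomes diverge in content,
size, and in which genes end up essential — the phenomenon the ensemble
analyses quantify.

Acceptance compares each candidate knockout against the CURRENT genome's
fitness (sequential fixation), not the original ancestor: deleterious-but-
acceptable losses compound, so the terminal fitness obeys
final >= ancestor x (1 - s)^k after k removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba_core import (
    FbaError,
    FbaProblem,
    MetabolicModel,
    essential_genes,
    evaluate_gpr,
    gpr_genes,
    knockout,
)

__all__ = [
    "DEFAULT_NE",
    "JengaConfig",
    "MinimalGenome",
    "JengaEnsemble",
    "removal_acceptable",
    "play_jenga",
    "audit_terminality",
    "run_ensemble",
]

DEFAULT_NE = 3.3e7


@dataclass
class JengaConfig:
    """Parameters of one Jenga game.

    ``Ne`` sets the purifying-selection threshold s = 1/Ne: a relative
    fitness defect below s is effectively neutral and may fix.
    ``essentiality_fraction`` is the growth fraction below which a knockout
    counts as essential when screening the terminal genome.
    """

    Ne: float = DEFAULT_NE
    seed: int = 0
    essentiality_fraction: float = 0.01
    max_passes: int | None = None

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")

    @property
    def s_threshold(self) -> float:
        return 1.0 / self.Ne


@dataclass
class MinimalGenome:
    """One terminal Jenga endpoint."""

    replicate_id: int
    retained_genes: frozenset[str]
    removal_order: list[str]
    final_objective: float
    essential_genes: frozenset[str]
    active_reactions: frozenset[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "replicate_id": self.replicate_id,
            "retained_genes": sorted(self.retained_genes),
            "removal_order": list(self.removal_order),
            "final_objective": self.final_objective,
            "essential_genes": sorted(self.essential_genes),
            "active_reactions": sorted(self.active_reactions),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MinimalGenome":
        return cls(
            replicate_id=doc["replicate_id"],
            retained_genes=frozenset(doc["retained_genes"]),
            removal_order=list(doc["removal_order"]),
            final_objective=doc["final_objective"],
            essential_genes=frozenset(doc["essential_genes"]),
            active_reactions=frozenset(doc["active_reactions"]),
            seed=doc["seed"],
        )


@dataclass
class JengaEnsemble:
    """A replicate collection of minimal genomes from one ancestor."""

    replicates: list[MinimalGenome]
    ancestor_genes: frozenset[str]
    ancestor_objective: float
    ancestor_essential: frozenset[str]
    config: JengaConfig = field(default_factory=JengaConfig)

    def __len__(self) -> int:
        return len(self.replicates)


def removal_acceptable(f_before: float, f_after: float, config: JengaConfig) -> bool:
    """Does the nearly-neutral threshold let this gene loss fix?

    True iff the loss is beneficial (f_after >= f_before) or the relative
    defect (f_before - f_after) / f_before is strictly below s = 1/Ne.
    """
    if f_before <= 0:
        raise ValueError("ancestor must grow: f_before must be positive")
    if f_after >= f_before:
        return True
    return (f_before - f_after) / f_before < config.s_threshold


def play_jenga(
    model: MetabolicModel, config: JengaConfig, replicate_id: int = 0,
    log=None,
) -> MinimalGenome:
    """Play one full game of Genome Jenga to termination.

    Each pass shuffles the remaining genes (seeded) and tests them in order
    by single-gene knockout of the *current* genome; the first accepted
    removal is committed (the fitness baseline moves to the new genome) and
    the pass restarts with a fresh shuffle.  A full pass with no commit
    proves terminality.  Genes referenced by no GPR rule have zero fitness
    effect and are removed as soon as drawn.
    """
    problem = FbaProblem(model)
    ancestor = problem.solve()
    if ancestor.status != "optimal" or ancestor.objective_value <= 0:
        raise FbaError("ancestor model does not grow; Jenga requires a viable start")

    # reactions whose status can change when a given gene is removed
    gene_to_reactions: dict[str, list[str]] = {g: [] for g in model.genes}
    for rxn in model.reactions:
        for g in gpr_genes(model.gpr_ast(rxn.id)):
            gene_to_reactions[g].append(rxn.id)

    rng = np.random.default_rng(config.seed)
    remaining = list(model.genes)
    removed: set[str] = set()
    disabled: set[str] = set()
    removal_order: list[str] = []
    fitness = ancestor.objective_value
    passes = 0

    while True:
        if config.max_passes is not None and passes >= config.max_passes:
            break
        passes += 1
        order = [remaining[i] for i in rng.permutation(len(remaining))]
        committed = False
        for gene in order:
            candidate_removed = removed | {gene}
            newly_disabled = {
                rid
                for rid in gene_to_reactions[gene]
                if rid not in disabled
                and not evaluate_gpr(model.gpr_ast(rid), candidate_removed)
            }
            if not newly_disabled:
                f_after = fitness  # no reaction changes: exactly neutral
            else:
                f_after = problem.solve(disabled | newly_disabled).objective_value
            if removal_acceptable(fitness, f_after, config):
                removed.add(gene)
                disabled |= newly_disabled
                remaining.remove(gene)
                removal_order.append(gene)
                if log is not None:
                    log(replicate_id, gene, f_after - fitness)
                fitness = f_after
                committed = True
                break
        if not committed:
            break

    terminal_model = knockout(model, removed)
    final = FbaProblem(terminal_model).solve()
    active = frozenset(
        rxn.id
        for rxn in terminal_model.reactions
        if not (rxn.lower_bound == 0.0 and rxn.upper_bound == 0.0)
        and evaluate_gpr(terminal_model.gpr_ast(rxn.id), set())
    )
    return MinimalGenome(
        replicate_id=replicate_id,
        retained_genes=frozenset(remaining),
        removal_order=removal_order,
        final_objective=final.objective_value,
        essential_genes=frozenset(
            essential_genes(terminal_model, config.essentiality_fraction)
        ),
        active_reactions=active,
        seed=config.seed,
    )


def audit_terminality(
    model: MetabolicModel, minimal: MinimalGenome, config: JengaConfig
) -> list[str]:
    """Independent post-hoc check that a minimal genome really is terminal.

    Rebuilds the terminal model by knockout from the ancestor and re-tests
    every retained gene one at a time, without trusting any state from the
    game loop.  Returns the genes that would still be removable (empty for
    a correct endpoint).
    """
    terminal_model = knockout(model, set(model.genes) - minimal.retained_genes)
    baseline = FbaProblem(terminal_model).solve()
    violations = []
    for gene in sorted(minimal.retained_genes):
        after = FbaProblem(knockout(terminal_model, {gene})).solve()
        if removal_acceptable(baseline.objective_value, after.objective_value, config):
            violations.append(gene)
    return violations


def run_ensemble(
    model: MetabolicModel,
    config: JengaConfig,
    n_replicates: int,
    out_dir=None,
    log=None,
) -> JengaEnsemble:
    """Play ``n_replicates`` independent games; replicate r uses seed
    config.seed + r, so ensembles are reproducible under any scheduling and
    resumable from per-replicate files."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ancestor = FbaProblem(model).solve()
    if ancestor.status != "optimal" or ancestor.objective_value <= 0:
        raise FbaError("ancestor model does not grow")
    ancestor_essential = frozenset(
        essential_genes(model, config.essentiality_fraction)
    )
    replicates = []
    for r in range(n_replicates):
        rep_config = JengaConfig(
            Ne=config.Ne,
            seed=config.seed + r,
            essentiality_fraction=config.essentiality_fraction,
            max_passes=config.max_passes,
        )
        try:
            minimal = play_jenga(model, rep_config, replicate_id=r, log=log)
        except FbaError as exc:
            raise FbaError(f"replicate {r}: {exc}") from exc
        replicates.append(minimal)
        if out_dir is not None:
            from .io_formats import write_json_result

            write_json_result(
                minimal.to_dict(), f"{out_dir}/replicate_{r:04d}.json"
            )
    return JengaEnsemble(
        replicates=replicates,
        ancestor_genes=frozenset(model.genes),
        ancestor_objective=ancestor.objective_value,
        ancestor_essential=ancestor_essential,
        config=config,
    )
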