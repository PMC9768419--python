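"""Constraint-based metabolic modelling: flux balance analysis, boolean
gene-protein-reaction (GPR) rules, gene knockouts, and essentiality screens.

The model is a plain stoichiometric container (metabolites, bounded
reactions, boolean GPR rules, one biomass objective, a medium of exchange
lower bounds).  Flux balance analysis maximises the biomass flux subject to
the steady-state constraint S·v = 0 and the flux bounds; it is solved as a
linear program with scipy's HiGHS backend.  A gene knockout disables every
reaction whose GPR rule evaluates false once the gene is absent; a gene is
essential when its single knockout drops growth below a stated fraction of
the wild-type optimum.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

__all__ = [
    "GprError",
    "FbaError",
    "Reaction",
    "MetabolicModel",
    "FbaResult",
    "parse_gpr",
    "gpr_genes",
    "evaluate_gpr",
    "simplify_gpr",
    "gpr_to_string",
    "FbaProblem",
    "solve_fba",
    "reactions_disabled_by",
    "knockout",
    "essential_genes",
]

# Numerical conventions: fluxes below ZERO_FLUX are reported as exact zeros;
# LP feasibility/optimality tolerances follow the HiGHS defaults tightened
# to the values below.
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6
ZERO_FLUX = 1e-9


class GprError(ValueError):
    """Malformed gene-protein-reaction rule; message carries the position."""


class FbaError(ValueError):
    """Model misconfiguration detected during or before an LP solve."""


# ---------------------------------------------------------------------------
# GPR rules: parse / evaluate / simplify
#
# Grammar (case-insensitive keywords, standard precedence: AND binds tighter
# than OR):
#     expr   := term ( OR term )*
#     term   := factor ( AND factor )*
#     factor := IDENT | "(" expr ")"
# The AST is nested tuples: ("or", [...]), ("and", [...]), ("gene", id).
# An empty rule parses to None and is always active (orphan/spontaneous
# reaction, never disabled by knockouts).
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        text = m.group(1)
        start = m.start(1)
        low = text.lower()
        if text == "(":
            kind = "lparen"
        elif text == ")":
            kind = "rparen"
        elif low == "and":
            kind = "and"
        elif low == "or":
            kind = "or"
        else:
            kind = "ident"
        tokens.append((kind, text, start))
        pos = m.end()
    return tokens


def parse_gpr(rule: str | None):
    """Parse a GPR rule string into an AST; ``None``/blank parses to ``None``.

    Raises :class:`GprError` with the character position on malformed input.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else ("eof", "", len(rule))

    def expect(kind):
        nonlocal idx
        tok = peek()
        if tok[0] != kind:
            raise GprError(
                f"expected {kind} at position {tok[2]} in rule {rule!r}, got {tok[1]!r}"
            )
        idx += 1
        return tok

    def parse_expr():
        terms = [parse_term()]
        while peek()[0] == "or":
            expect("or")
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_term():
        factors = [parse_factor()]
        while peek()[0] == "and":
            expect("and")
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_factor():
        nonlocal idx
        tok = peek()
        if tok[0] == "lparen":
            expect("lparen")
            inner = parse_expr()
            expect("rparen")
            return inner
        if tok[0] == "ident":
            idx += 1
            return ("gene", tok[1])
        raise GprError(
            f"unexpected token {tok[1]!r} at position {tok[2]} in rule {rule!r}"
        )

    ast = parse_expr()
    tok = peek()
    if tok[0] != "eof":
        raise GprError(
            f"trailing token {tok[1]!r} at position {tok[2]} in rule {rule!r}"
        )
    return ast


def gpr_genes(ast) -> frozenset[str]:
    """All gene identifiers referenced by a parsed rule."""
    if ast is None:
        return frozenset()
    op = ast[0]
    if op == "gene":
        return frozenset([ast[1]])
    out: set[str] = set()
    for child in ast[1]:
        out |= gpr_genes(child)
    return frozenset(out)


def evaluate_gpr(rule, absent_genes) -> bool:
    """Is the reaction still catalyzable with ``absent_genes`` knocked out?

    ``rule`` may be a string or a parsed AST.  Present genes evaluate true,
    absent ones false; an empty rule is always active.
    """
    ast = parse_gpr(rule) if isinstance(rule, str) or rule is None else rule
    if ast is None:
        return True
    op = ast[0]
    if op == "gene":
        return ast[1] not in absent_genes
    if op == "and":
        return all(evaluate_gpr(c, absent_genes) for c in ast[1])
    return any(evaluate_gpr(c, absent_genes) for c in ast[1])


def simplify_gpr(ast, absent_genes):
    """Partially evaluate an AST with the given genes absent.

    Returns ``True`` (always active), ``False`` (never active), or a reduced
    AST over the remaining genes.
    """
    if ast is None:
        return True
    op = ast[0]
    if op == "gene":
        return ast if ast[1] not in absent_genes else False
    children = [simplify_gpr(c, absent_genes) for c in ast[1]]
    if op == "and":
        if any(c is False for c in children):
            return False
        children = [c for c in children if c is not True]
        if not children:
            return True
        return children[0] if len(children) == 1 else ("and", children)
    # or
    if any(c is True for c in children):
        return True
    children = [c for c in children if c is not False]
    if not children:
        return False
    return children[0] if len(children) == 1 else ("or", children)


def gpr_to_string(ast) -> str:
    """Serialize an AST back to rule syntax (inverse of :func:`parse_gpr`)."""
    if ast is None or ast is True:
        return ""
    if ast is False:
        raise GprError("cannot serialize an always-false rule")
    op = ast[0]
    if op == "gene":
        return ast[1]
    sep = f" {op} "
    parts = []
    for child in ast[1]:
        text = gpr_to_string(child)
        if child[0] != "gene" and child[0] != op:
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """One reaction: stoichiometry, flux bounds (mmol·gDW⁻¹·h⁻¹), GPR rule."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise FbaError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    def is_exchange(self) -> bool:
        """Boundary reaction: a single metabolite crossing the system edge."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    ``medium`` maps exchange-reaction ids to lower-bound overrides applied at
    solve time; it encodes nutrient availability without mutating the
    reaction list.
    """

    id: str
    metabolites: list[str]
    reactions: list[Reaction]
    genes: list[str]
    objective_reaction: str
    medium: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._reaction_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._gpr_asts = {r.id: parse_gpr(r.gpr) for r in self.reactions}
        self.validate()

    def validate(self) -> None:
        if self.objective_reaction not in self._reaction_index:
            raise FbaError(f"objective reaction {self.objective_reaction!r} not in model")
        met_set = set(self.metabolites)
        gene_set = set(self.genes)
        for rxn in self.reactions:
            missing_mets = set(rxn.stoichiometry) - met_set
            if missing_mets:
                raise FbaError(
                    f"reaction {rxn.id} references unknown metabolites {sorted(missing_mets)}"
                )
            unknown = gpr_genes(self._gpr_asts[rxn.id]) - gene_set
            if unknown:
                raise FbaError(
                    f"reaction {rxn.id} rule references unlisted gene(s) {sorted(unknown)}"
                )
        for ex in self.medium:
            if ex not in self._reaction_index:
                raise FbaError(f"medium references unknown exchange reaction {ex!r}")

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self._reaction_index[reaction_id]]

    def gpr_ast(self, reaction_id: str):
        return self._gpr_asts[reaction_id]

    def exchange_reactions(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange()]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and sorted(self.genes) == sorted(other.genes)
            and self.objective_reaction == other.objective_reaction
            and self.medium == other.medium
        )


@dataclass
class FbaResult:
    status: str  # "optimal" | "infeasible"
    objective_value: float
    fluxes: dict[str, float]


# ---------------------------------------------------------------------------
# Flux balance analysis
# ---------------------------------------------------------------------------


class FbaProblem:
    """Pre-assembled LP for one model, reusable across knockouts.

    The stoichiometric matrix and base bounds are built once; each solve may
    zero out a set of disabled reactions.  This is the workhorse behind the
    Jenga game, which performs thousands of single-knockout solves on the
    same stoichiometry.
    """

    def __init__(self, model: MetabolicModel):
        self.model = model
        n_mets = len(model.metabolites)
        n_rxns = len(model.reactions)
        met_index = {m: i for i, m in enumerate(model.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(model.reactions):
            for met, coeff in rxn.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                vals.append(float(coeff))
        self._S = csr_matrix((vals, (rows, cols)), shape=(n_mets, n_rxns))
        self._lb = np.array([r.lower_bound for r in model.reactions], float)
        self._ub = np.array([r.upper_bound for r in model.reactions], float)
        for ex, lb in model.medium.items():
            self._lb[model._reaction_index[ex]] = lb
        self._c = np.zeros(n_rxns)
        self._c[model._reaction_index[model.objective_reaction]] = -1.0  # maximize
        self._rxn_ids = [r.id for r in model.reactions]
        self._rxn_index = model._reaction_index

    def solve(self, disabled_reactions=()) -> FbaResult:
        lb = self._lb
        ub = self._ub
        if disabled_reactions:
            lb = lb.copy()
            ub = ub.copy()
            for rid in disabled_reactions:
                j = self._rxn_index[rid]
                lb[j] = 0.0
                ub[j] = 0.0
        res = linprog(
            self._c,
            A_eq=self._S,
            b_eq=np.zeros(self._S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={
                "primal_feasibility_tolerance": FEASIBILITY_TOL,
                "dual_feasibility_tolerance": OPTIMALITY_TOL,
            },
        )
        if res.status == 3:
            raise FbaError(
                "objective is unbounded: model misconfiguration "
                "(e.g. missing exchange bound)"
            )
        if res.status == 2:
            return FbaResult("infeasible", 0.0, {})
        if res.status != 0:
            raise FbaError(f"LP solver failed: {res.message}")
        fluxes = {
            rid: (0.0 if abs(v) < ZERO_FLUX else float(v))
            for rid, v in zip(self._rxn_ids, res.x)
        }
        objective = max(0.0, float(-res.fun))
        return FbaResult("optimal", objective, fluxes)


def solve_fba(model: MetabolicModel) -> FbaResult:
    """Maximize the biomass objective under S·v = 0 and the flux bounds.

    Medium overrides are applied to exchange lower bounds.  The objective
    value is deterministic; the flux vector may be degenerate.
    """
    return FbaProblem(model).solve()


def reactions_disabled_by(model: MetabolicModel, genes_removed) -> set[str]:
    """Reaction ids whose GPR rule evaluates inactive once the genes are gone."""
    removed = set(genes_removed)
    disabled = set()
    for rxn in model.reactions:
        ast = model.gpr_ast(rxn.id)
        if ast is not None and not evaluate_gpr(ast, removed):
            disabled.add(rxn.id)
    return disabled


def knockout(model: MetabolicModel, genes_removed) -> MetabolicModel:
    """A new model with the genes deleted; the input model is unmodified.

    Reactions whose rules evaluate inactive get bounds [0, 0]; the GPR rules
    of surviving reactions are partially evaluated over the remaining genes,
    and the gene list shrinks accordingly.
    """
    removed = set(genes_removed)
    unknown = removed - set(model.genes)
    if unknown:
        raise FbaError(f"cannot knock out unknown gene(s) {sorted(unknown)}")
    new_reactions = []
    for rxn in model.reactions:
        ast = model.gpr_ast(rxn.id)
        simplified = simplify_gpr(ast, removed)
        if simplified is False:
            new_reactions.append(
                replace(rxn, lower_bound=0.0, upper_bound=0.0, gpr="")
            )
        else:
            new_reactions.append(replace(rxn, gpr=gpr_to_string(simplified)))
    return MetabolicModel(
        id=model.id,
        metabolites=list(model.metabolites),
        reactions=new_reactions,
        genes=[g for g in model.genes if g not in removed],
        objective_reaction=model.objective_reaction,
        medium=dict(model.medium),
    )


def essential_genes(
    model: MetabolicModel, essentiality_fraction: float = 0.01
) -> set[str]:
    """Genes whose single knockout drops growth below
    ``essentiality_fraction`` × the wild-type optimum.

    Only genes referenced by at least one GPR rule can be essential; the
    rest are skipped without a solve.
    """
    if not 0 < essentiality_fraction < 1:
        raise ValueError("essentiality_fraction must lie in (0, 1)")
    problem = FbaProblem(model)
    wild_type = problem.solve()
    if wild_type.status != "optimal" or wild_type.objective_value <= 0:
        raise FbaError("wild-type objective is zero: essentiality undefined")
    threshold = essentiality_fraction * wild_type.objective_value
    in_rules: set[str] = set()
    for rxn in model.reactions:
        in_rules |= gpr_genes(model.gpr_ast(rxn.id))
    essential = set()
    for gene in sorted(in_rules):
        disabled = reactions_disabled_by(model, {gene})
        if not disabled:
            continue
        result = problem.solve(disabled)
        if result.objective_value < threshold:
            essential.add(gene)
    return essential
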