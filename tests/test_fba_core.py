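import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomejenga.fba_core import (
    FbaError,
    GprError,
    essential_genes,
    evaluate_gpr,
    gpr_genes,
    gpr_to_string,
    knockout,
    parse_gpr,
    simplify_gpr,
    solve_fba,
)
from genomejenga.io_formats import write_bigg_model
from genomejenga.synthetic_data import ToyModelConfig, generate_toy_model


def python_eval_gpr(rule: str, absent: set) -> bool:
    """Independent oracle: rewrite the rule as a Python boolean expression
    and eval it (gene -> True/False literal)."""
    expr = re.sub(
        r"[^\s()]+",
        lambda m: m.group(0)
        if m.group(0).lower() in ("and", "or")
        else str(m.group(0) not in absent),
        rule,
    )
    return bool(eval(expr))


class TestGpr:
    def test_isozyme_or(self):
        assert evaluate_gpr("g1 or g2", {"g1"}) is True

    def test_complex_and(self):
        assert evaluate_gpr("g1 and g2", {"g2"}) is False

    def test_nested_rule(self):
        assert evaluate_gpr("(g1 and g2) or g3", {"g1", "g3"}) is False

    def test_empty_rule_always_active(self):
        assert evaluate_gpr("", {"g1"}) is True
        assert evaluate_gpr(None, set()) is True

    @pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1 or g2", "g1 g2"])
    def test_malformed_rules_report_position(self, bad):
        with pytest.raises(GprError, match="position"):
            parse_gpr(bad)

    @pytest.mark.parametrize(
        "rule",
        [
            "g1",
            "g1 or g2",
            "g1 and g2 and g3",
            "(g1 and g2) or g3",
            "(g1 or g2) and (g3 or g4)",
            "((g1 and g2) or (g3 and g4)) and g5",
            "g1 or (g2 and (g3 or (g4 and g5))) or g6",
        ],
    )
    def test_truth_table_matches_python_eval(self, rule):
        genes = sorted(gpr_genes(parse_gpr(rule)))
        for bits in itertools.product([False, True], repeat=len(genes)):
            absent = {g for g, present in zip(genes, bits) if not present}
            assert evaluate_gpr(rule, absent) == python_eval_gpr(rule, absent)

    def test_serialization_round_trip(self):
        rule = "(g1 or g2) and (g3 or (g4 and g5))"
        ast = parse_gpr(rule)
        assert parse_gpr(gpr_to_string(ast)) == ast

    def test_simplify_partial_evaluation(self):
        ast = parse_gpr("(g1 and g2) or g3")
        assert simplify_gpr(ast, {"g3"}) == parse_gpr("g1 and g2")
        assert simplify_gpr(ast, {"g1"}) == ("gene", "g3")
        assert simplify_gpr(ast, {"g1", "g3"}) is False
        assert simplify_gpr(ast, set()) == ast


class TestSolveFba:
    def test_chain_optimum_equals_uptake(self, chain_model):
        result = solve_fba(chain_model)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_objective_clamped_to_zero(self, chain_model):
        model = chain_model.copy()
        biomass = model.reaction("BIOMASS")
        biomass.lower_bound = biomass.upper_bound = 0.0
        result = solve_fba(model)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_starvation(self, chain_model):
        model = chain_model.copy()
        model.medium["EX_A"] = 0.0
        assert solve_fba(model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_objective_is_an_error(self, chain_model):
        model = chain_model.copy()
        model.reaction("EX_A").lower_bound = -np.inf
        model.reaction("R1").upper_bound = np.inf
        model.reaction("BIOMASS").upper_bound = np.inf
        with pytest.raises(FbaError, match="unbounded"):
            solve_fba(model)

    def test_objective_reproducible(self, redundant_model):
        values = {solve_fba(redundant_model).objective_value for _ in range(3)}
        first = values.pop()
        assert all(abs(v - first) <= 1e-9 * abs(first) for v in values)


class TestKnockout:
    def test_severed_chain(self, chain_model):
        assert solve_fba(knockout(chain_model, {"g1"})).objective_value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_empty_knockout_is_identity(self, chain_model):
        assert knockout(chain_model, set()) == chain_model

    def test_original_model_unmodified(self, chain_model):
        before = chain_model.reaction("R1").upper_bound
        knockout(chain_model, {"g1"})
        assert chain_model.reaction("R1").upper_bound == before

    def test_unknown_gene_rejected(self, chain_model):
        with pytest.raises(FbaError, match="gX"):
            knockout(chain_model, {"gX"})

    def test_monotonicity_over_random_gene_pairs(self, redundant_model):
        rng = np.random.default_rng(11)
        genes = redundant_model.genes
        base = solve_fba(redundant_model).objective_value
        for _ in range(15):
            g1, g2 = rng.choice(genes, size=2, replace=False)
            single = solve_fba(knockout(redundant_model, {g1})).objective_value
            double = solve_fba(knockout(redundant_model, {g1, g2})).objective_value
            assert double <= single + 1e-9 <= base + 2e-9


class TestEssentialGenes:
    def test_chain_gene_essential(self, chain_model):
        assert essential_genes(chain_model) == {"g1"}

    def test_isozymes_not_essential_alone(self):
        model = generate_toy_model(
            ToyModelConfig(n_pathways=1, genes_per_pathway=1, n_isozyme_pairs=1)
        )
        assert essential_genes(model) == set()

    def test_sequential_knockout_creates_essentiality(self):
        # the fragility mechanism: remove one isozyme and its partner
        # becomes essential
        model = generate_toy_model(
            ToyModelConfig(n_pathways=1, genes_per_pathway=1, n_isozyme_pairs=1)
        )
        reduced = knockout(model, {"iso_1"})
        assert essential_genes(reduced) == {"p1_g1"}

    def test_zero_growth_ancestor_rejected(self, chain_model):
        dead = knockout(chain_model, {"g1"})
        with pytest.raises(FbaError, match="essentiality undefined"):
            essential_genes(dead)

    def test_essential_subset_of_rule_genes(self, redundant_model):
        in_rules = set()
        for rxn in redundant_model.reactions:
            in_rules |= gpr_genes(redundant_model.gpr_ast(rxn.id))
        assert essential_genes(redundant_model) <= in_rules


class TestCobraCrossCheck:
    """Independent oracle: the same models solved by cobrapy (GLPK)."""

    @pytest.fixture
    def as_cobra(self, tmp_path):
        cobra = pytest.importorskip("cobra")

        def _convert(model):
            path = tmp_path / f"{model.id}.json"
            write_bigg_model(model, path)
            return cobra.io.load_json_model(str(path))

        return _convert

    def test_objective_agrees(self, redundant_model, as_cobra):
        ours = solve_fba(redundant_model).objective_value
        theirs = as_cobra(redundant_model).slim_optimize()
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_single_knockouts_agree(self, redundant_model, as_cobra):
        cobra_model = as_cobra(redundant_model)
        for gene in redundant_model.genes:
            ours = solve_fba(knockout(redundant_model, {gene})).objective_value
            with cobra_model as m:
                m.genes.get_by_id(gene).knock_out()
                theirs = m.slim_optimize()
            if theirs is None or np.isnan(theirs):
                theirs = 0.0
            assert ours == pytest.approx(theirs, abs=1e-6), gene


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 2**31 - 1))
def test_random_rule_evaluation_matches_python(seed):
    """Random GPR rules over <= 6 genes evaluate identically to the
    eval-based oracle on random absence patterns."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]

    def random_rule(depth=0):
        if depth >= 2 or rng.random() < 0.4:
            return genes[rng.integers(len(genes))]
        op = " and " if rng.random() < 0.5 else " or "
        return "(" + op.join(random_rule(depth + 1) for _ in range(2)) + ")"

    rule = random_rule()
    absent = {g for g in genes if rng.random() < 0.5}
    assert evaluate_gpr(rule, absent) == python_eval_gpr(rule, absent)
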