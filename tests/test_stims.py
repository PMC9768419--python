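import numpy as np
import pytest

from genomejenga.gene_sets import GeneSet
from genomejenga.io_formats import Annotation, GeneAnnotation, MutationRecord, MutationTable
from genomejenga.stims import (
    StimsError,
    StimsResult,
    Trajectory,
    cumulative_trajectory,
    default_timepoints,
    sample_null,
    stims_test,
    tail_p_values,
)
from genomejenga.synthetic_data import MutationSimConfig, simulate_mutations


@pytest.fixture
def hand_set():
    return GeneSet("pair", frozenset({"g1", "g2"}))


class TestCumulativeTrajectory:
    def test_hand_counts(self, hand_mutations, hand_annotation, hand_set):
        trajectory = cumulative_trajectory(
            hand_mutations, "Ara-1", hand_set, hand_annotation,
            timepoints=[100, 200],
        )
        # 1 mutation / 400 nt at t=100; 3 mutations / 400 nt at t=200
        assert trajectory.values == pytest.approx([0.0025, 0.0075])

    def test_no_mutations_gives_zero_trajectory(self, hand_annotation, hand_set):
        empty = MutationTable([MutationRecord("Ara-1", 100.0, "other")])
        trajectory = cumulative_trajectory(
            empty, "Ara-1", hand_set, hand_annotation, timepoints=[100, 200]
        )
        assert np.all(trajectory.values == 0.0)

    def test_unknown_population_names_alternatives(
        self, hand_mutations, hand_annotation, hand_set
    ):
        with pytest.raises(StimsError, match="Ara-1"):
            cumulative_trajectory(
                hand_mutations, "Ara-9", hand_set, hand_annotation
            )

    def test_scale_invariance(self, hand_mutations, hand_set):
        """Doubling every gene length and keeping mutations fixed halves
        every trajectory value."""
        base = Annotation([GeneAnnotation("g1", 100), GeneAnnotation("g2", 300)])
        doubled = Annotation([GeneAnnotation("g1", 200), GeneAnnotation("g2", 600)])
        t1 = cumulative_trajectory(
            hand_mutations, "Ara-1", hand_set, base, timepoints=[100, 200]
        )
        t2 = cumulative_trajectory(
            hand_mutations, "Ara-1", hand_set, doubled, timepoints=[100, 200]
        )
        assert t2.values == pytest.approx(t1.values / 2)

    def test_default_timepoints_include_zero(self, hand_mutations):
        assert default_timepoints(hand_mutations, "Ara-1").tolist() == [0, 100, 200]

    def test_non_monotone_values_rejected(self):
        with pytest.raises(StimsError):
            Trajectory([0, 100], [0.2, 0.1])


class TestSampleNull:
    def test_whole_genome_cardinality_degenerates(self, hand_mutations, hand_annotation):
        trajectories, (lower, upper) = sample_null(
            hand_mutations, "Ara-1", hand_annotation, cardinality=2, n_null=50,
            timepoints=[100, 200], seed=1,
        )
        values = np.array([t.values for t in trajectories])
        assert np.all(values == values[0])
        assert np.all(upper - lower == 0.0)

    def test_seeded_determinism(self, hand_mutations, hand_annotation):
        universe = Annotation(
            [GeneAnnotation(f"g{i}", 100 + i) for i in range(20)]
        )
        muts = MutationTable(
            [MutationRecord("P", 100.0 * (i + 1), f"g{i % 20}") for i in range(30)]
        )
        a = sample_null(muts, "P", universe, 5, 200, seed=42)
        b = sample_null(muts, "P", universe, 5, 200, seed=42)
        assert np.array_equal(a[1][0], b[1][0]) and np.array_equal(a[1][1], b[1][1])

    def test_cardinality_exceeding_universe_rejected(self, hand_mutations, hand_annotation):
        with pytest.raises(StimsError, match="cardinality"):
            sample_null(hand_mutations, "Ara-1", hand_annotation, 5, 10)


class TestStimsTest:
    def test_ties_inclusive_p_value_hand_count(self):
        """Hand-fixed null finals {1..10}/L with observed 2/L: two nulls lie
        at or below the observed statistic, so p_lower = (1 + 2) / 11."""
        L = 1000.0
        null_final = np.arange(1, 11) / L
        p_lower, p_upper = tail_p_values(null_final, 2 / L)
        assert p_lower == pytest.approx(3 / 11)
        assert p_upper == pytest.approx(10 / 11)

    def test_p_values_recount_against_sampled_null(self):
        """The p-values inside a StimsResult match an independent recount of
        the ties-inclusive tails over its own null sample."""
        annotation = Annotation(
            [GeneAnnotation(f"g{i}", 1000) for i in range(10)]
        )
        records = []
        for i in range(10):
            records.extend(
                MutationRecord("P", 500.0, f"g{i}") for _ in range(i + 1)
            )
        muts = MutationTable(records)
        with pytest.warns(UserWarning):
            observed = stims_test(
                muts, "P", GeneSet("focal", frozenset({"g1"})), annotation,
                n_null=10, seed=0,
            )
        k_lower = int(np.sum(observed.null_final <= observed.observed.final_value))
        assert observed.p_lower == pytest.approx((1 + k_lower) / 11)
        k_upper = int(np.sum(observed.null_final >= observed.observed.final_value))
        assert observed.p_upper == pytest.approx((1 + k_upper) / 11)

    def test_extreme_deficit_hits_pseudocount_floor(self):
        config = MutationSimConfig(
            seed=3, mu=2e-10,
            gene_set_sizes={"purified": 50},
            selection_factors={"purified": 0.05},
        )
        muts, annotation, sets = simulate_mutations(config)
        result = stims_test(muts, "pop-1", sets["purified"], annotation,
                            n_null=1000, seed=9)
        assert result.p_lower == pytest.approx(1 / 1001)
        assert result.format_p(result.p_lower) == "< 0.001"

    def test_small_n_null_warns(self, hand_mutations, hand_annotation):
        with pytest.warns(UserWarning, match="resolution"):
            stims_test(hand_mutations, "Ara-1",
                       GeneSet("pair", frozenset({"g1", "g2"})),
                       hand_annotation, n_null=10, seed=0)

    def test_tails_cover_unit_probability(self):
        """p_lower + p_upper >= 1 + 1/(n_null+1), both in (0, 1]."""
        config = MutationSimConfig(seed=5, mu=2e-10, gene_set_sizes={"s": 30})
        muts, annotation, sets = simulate_mutations(config)
        result = stims_test(muts, "pop-1", sets["s"], annotation,
                            n_null=200, seed=5)
        assert 0 < result.p_lower <= 1 and 0 < result.p_upper <= 1
        assert result.p_lower + result.p_upper >= 1 + 1 / 201

    def test_deterministic_given_seed(self):
        config = MutationSimConfig(seed=8, mu=2e-10, gene_set_sizes={"s": 20})
        muts, annotation, sets = simulate_mutations(config)
        a = stims_test(muts, "pop-1", sets["s"], annotation, n_null=300, seed=4)
        b = stims_test(muts, "pop-1", sets["s"], annotation, n_null=300, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_null_envelope_calibration(self):
        """Under a shared per-nucleotide rate, a random focal set's final
        statistic falls inside the 95% envelope about 95% of the time."""
        rng = np.random.default_rng(0)
        inside = 0
        n_reps = 60
        for i in range(n_reps):
            config = MutationSimConfig(
                seed=1000 + i, mu=2e-10, n_genes=300, gene_set_sizes={"s": 40}
            )
            muts, annotation, sets = simulate_mutations(config)
            result = stims_test(muts, "pop-1", sets["s"], annotation,
                                n_null=500, seed=int(rng.integers(2**31)))
            final = result.observed.final_value
            if result.envelope_lower[-1] <= final <= result.envelope_upper[-1]:
                inside += 1
        # binomial(60, 0.95): central 99.9% range is roughly [51, 60]
        assert inside >= 51
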