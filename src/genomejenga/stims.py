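"""STIMS: a randomization test for selection on pre-defined gene sets in
evolution-experiment mutation time series.

The observed statistic is the cumulative number of mutations appearing in
the focal gene set up to each sampled generation, normalized by the set's
combined length in nucleotides (mutations per nucleotide).  The null
distribution comes from random gene sets of the same cardinality drawn
uniformly from all annotated genes, each normalized by its own combined
length.  Because both observed and null trajectories are built from the
same population's mutation stream, the test automatically controls for
temporal variation in the mutation rate (e.g. hypermutator onset) and for
rate variation along the chromosome.

One-sided p-values use the pseudocount estimator (1 + k) / (n_null + 1)
with ties counted in the tail: a deficit of mutations (lower tail) signals
purifying selection, an excess (upper tail) positive selection.  The test
statistic is the trajectory's value at the final timepoint; the exported
envelope (per-timepoint 2.5th/97.5th null percentiles) exposes the full
time course, so a panel can be read as a two-sided alpha = 0.05 band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gene_sets import GeneSet, total_length, validate_against_annotation
from .io_formats import MutationTable

__all__ = [
    "StimsError",
    "Trajectory",
    "StimsResult",
    "default_timepoints",
    "tail_p_values",
    "cumulative_trajectory",
    "sample_null",
    "stims_test",
]


class StimsError(ValueError):
    pass


@dataclass
class Trajectory:
    """A normalized cumulative mutation trajectory.

    ``values[i]`` is the number of mutations observed in the gene set at
    generations <= ``timepoints[i]``, divided by the set's total length in
    nucleotides; hence non-decreasing.
    """

    timepoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.shape != self.values.shape:
            raise StimsError("timepoints and values must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise StimsError("timepoints must be strictly increasing")
        if np.any(np.diff(self.values) < 0) or (len(self.values) and self.values[0] < 0):
            raise StimsError("trajectory values must be non-negative and non-decreasing")

    @property
    def final_value(self) -> float:
        return float(self.values[-1])


@dataclass
class StimsResult:
    """Full output of one STIMS run on one population."""

    population: str
    observed: Trajectory
    null_final: np.ndarray  # final-timepoint statistic of each null set
    envelope_lower: np.ndarray  # per-timepoint 2.5th percentile of the null
    envelope_upper: np.ndarray  # per-timepoint 97.5th percentile
    p_lower: float
    p_upper: float
    n_null: int
    seed: int
    set_name: str
    set_size: int
    set_length_nt: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "timepoints": self.observed.timepoints.tolist(),
            "observed": self.observed.values.tolist(),
            "null_final": np.asarray(self.null_final).tolist(),
            "envelope_lower": np.asarray(self.envelope_lower).tolist(),
            "envelope_upper": np.asarray(self.envelope_upper).tolist(),
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "n_null": self.n_null,
            "seed": self.seed,
            "set_name": self.set_name,
            "set_size": self.set_size,
            "set_length_nt": self.set_length_nt,
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "StimsResult":
        return cls(
            population=doc["population"],
            observed=Trajectory(
                np.asarray(doc["timepoints"]), np.asarray(doc["observed"])
            ),
            null_final=np.asarray(doc["null_final"]),
            envelope_lower=np.asarray(doc["envelope_lower"]),
            envelope_upper=np.asarray(doc["envelope_upper"]),
            p_lower=doc["p_lower"],
            p_upper=doc["p_upper"],
            n_null=doc["n_null"],
            seed=doc["seed"],
            set_name=doc["set_name"],
            set_size=doc["set_size"],
            set_length_nt=doc["set_length_nt"],
            extras=doc.get("extras", {}),
        )

    def format_p(self, p: float) -> str:
        """Report tiny p-values as a floor, e.g. '< 0.001' at n_null = 1000."""
        floor = 1.0 / (self.n_null + 1)
        if p <= floor:
            return f"< {np.ceil(floor * 1000) / 1000:g}"
        return f"{p:.4g}"


def default_timepoints(mutations: MutationTable, population: str) -> np.ndarray:
    """Sorted unique generations observed in the population, preceded by 0."""
    gens = sorted({r.generation for r in mutations.records if r.population == population})
    if not gens or gens[0] > 0:
        gens = [0.0] + gens
    return np.asarray(gens, dtype=float)


def tail_p_values(null_final, observed_final: float) -> tuple[float, float]:
    """Pseudocount one-sided p-values against a null sample, ties counted
    in the tail: p = (1 + k) / (n + 1) with k the number of null statistics
    at or beyond the observed one.  Never returns 0; the floor 1/(n+1)
    matches the '< 0.001' reporting convention at n = 1000."""
    null_final = np.asarray(null_final, dtype=float)
    n = len(null_final)
    if n == 0:
        raise StimsError("empty null sample")
    k_lower = int(np.sum(null_final <= observed_final))
    k_upper = int(np.sum(null_final >= observed_final))
    return (1 + k_lower) / (n + 1), (1 + k_upper) / (n + 1)


def _population_records(mutations: MutationTable, population: str,
                        mutation_classes=None):
    if population not in mutations.populations:
        raise StimsError(
            f"population {population!r} not in table; available: "
            f"{sorted(mutations.populations)}"
        )
    records = [r for r in mutations.records if r.population == population]
    if mutation_classes is not None:
        allowed = set(mutation_classes)
        records = [r for r in records if r.mutation_class in allowed]
    return records


class _CountsCache:
    """Per-gene cumulative mutation counts at each timepoint, as a dense
    (n_genes x n_timepoints) matrix — the shared engine behind observed and
    null trajectories."""

    def __init__(self, records, annotation, timepoints: np.ndarray):
        self.timepoints = np.asarray(timepoints, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise StimsError("timepoints must be strictly increasing")
        self.gene_ids = list(annotation.gene_ids)
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self.lengths = np.array(
            [annotation.length(g) for g in self.gene_ids], dtype=float
        )
        events = np.zeros((len(self.gene_ids), len(self.timepoints)))
        last = self.timepoints[-1]
        for r in records:
            i = self.gene_index.get(r.gene_id)
            if i is None:
                continue  # mutation in an unannotated gene: outside the universe
            if r.generation > last:
                raise StimsError(
                    f"record at generation {r.generation} exceeds the last "
                    f"timepoint {last}; timepoints must cover the data range"
                )
            j = int(np.searchsorted(self.timepoints, r.generation, side="left"))
            events[i, j] += 1.0
        self.cumulative = np.cumsum(events, axis=1)

    def trajectory_for(self, gene_indices) -> np.ndarray:
        idx = np.asarray(gene_indices, dtype=int)
        return self.cumulative[idx].sum(axis=0) / self.lengths[idx].sum()

    def null_matrix(self, index_matrix: np.ndarray) -> np.ndarray:
        """Trajectories for many gene-index draws at once: (n_null, n_t)."""
        counts = self.cumulative[index_matrix].sum(axis=1)
        lengths = self.lengths[index_matrix].sum(axis=1)
        return counts / lengths[:, None]


def cumulative_trajectory(
    mutations: MutationTable,
    population: str,
    gene_set: GeneSet,
    annotation,
    timepoints=None,
    mutation_classes=None,
) -> Trajectory:
    """Observed normalized cumulative trajectory for a focal gene set.

    Value at t = (# mutations in the set at generations <= t) divided by the
    set's total length in nucleotides.
    """
    records = _population_records(mutations, population, mutation_classes)
    if timepoints is None:
        timepoints = default_timepoints(mutations, population)
    length = total_length(gene_set, annotation)
    cache = _CountsCache(records, annotation, timepoints)
    idx = [cache.gene_index[g] for g in gene_set.members]
    counts = cache.cumulative[idx].sum(axis=0)
    return Trajectory(np.asarray(timepoints, float), counts / length)


def sample_null(
    mutations: MutationTable,
    population: str,
    annotation,
    cardinality: int,
    n_null: int,
    timepoints=None,
    seed: int = 0,
    mutation_classes=None,
):
    """Null trajectories from random equal-cardinality gene sets.

    Each null set is drawn uniformly without replacement from all annotated
    genes and normalized by its own combined length.  Returns the list of
    null :class:`Trajectory` objects and the (lower, upper) envelope, the
    per-timepoint 2.5th/97.5th percentiles — the middle 95% band left after
    the top and bottom 2.5% of null points are omitted.
    """
    records = _population_records(mutations, population, mutation_classes)
    if timepoints is None:
        timepoints = default_timepoints(mutations, population)
    if cardinality > len(annotation):
        raise StimsError(
            f"cardinality {cardinality} exceeds the {len(annotation)}-gene universe"
        )
    if cardinality < 1 or n_null < 1:
        raise StimsError("cardinality and n_null must be positive")
    cache = _CountsCache(records, annotation, timepoints)
    rng = np.random.default_rng(seed)
    n_genes = len(cache.gene_ids)
    draws = np.empty((n_null, cardinality), dtype=int)
    for b in range(n_null):
        draws[b] = rng.choice(n_genes, size=cardinality, replace=False)
    values = cache.null_matrix(draws)
    tp = np.asarray(timepoints, float)
    trajectories = [Trajectory(tp, row) for row in values]
    envelope = (
        np.percentile(values, 2.5, axis=0),
        np.percentile(values, 97.5, axis=0),
    )
    return trajectories, envelope


def stims_test(
    mutations: MutationTable,
    population: str,
    gene_set: GeneSet,
    annotation,
    n_null: int = 1000,
    seed: int = 0,
    timepoints=None,
    mutation_classes=None,
) -> StimsResult:
    """Run STIMS for one gene set in one population.

    The test statistic is the observed trajectory's value at the final
    timepoint.  p_lower = (1 + #{null_final <= observed_final}) / (n_null + 1)
    is the one-sided purifying-selection tail; p_upper is the symmetric
    positive-selection tail.  Both are always reported.
    """
    if n_null < 100:
        warnings.warn(
            f"n_null = {n_null} gives p-value resolution no finer than "
            f"{1 / (n_null + 1):.3g}; consider n_null >= 1000",
            stacklevel=2,
        )
    validated, _dropped = validate_against_annotation(gene_set, annotation)
    records = _population_records(mutations, population, mutation_classes)
    if timepoints is None:
        timepoints = default_timepoints(mutations, population)
    length = total_length(validated, annotation)

    cache = _CountsCache(records, annotation, timepoints)
    idx = [cache.gene_index[g] for g in validated.members]
    tp = np.asarray(timepoints, float)
    observed = Trajectory(tp, cache.cumulative[idx].sum(axis=0) / length)

    rng = np.random.default_rng(seed)
    n_genes = len(cache.gene_ids)
    draws = np.empty((n_null, len(validated)), dtype=int)
    for b in range(n_null):
        draws[b] = rng.choice(n_genes, size=len(validated), replace=False)
    null_values = cache.null_matrix(draws)
    null_final = null_values[:, -1]

    p_lower, p_upper = tail_p_values(null_final, observed.final_value)
    return StimsResult(
        population=population,
        observed=observed,
        null_final=null_final,
        envelope_lower=np.percentile(null_values, 2.5, axis=0),
        envelope_upper=np.percentile(null_values, 97.5, axis=0),
        p_lower=p_lower,
        p_upper=p_upper,
        n_null=n_null,
        seed=seed,
        set_name=validated.name,
        set_size=len(validated),
        set_length_nt=length,
    )
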