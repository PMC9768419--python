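"""Readers and writers for every external file format the pipelines touch.

Tabular inputs (mutation time series, gene annotations) are CSV with a
header; a *dialect* mapping renames columns so datasets with their own
schemas plug in without preprocessing.  Metabolic models use BiGG-JSON.
Gene sets are plain-text id lists.  Results serialize to JSON (scalars,
p-values, configs, with seed echoed for provenance) and CSV (matrices,
trajectories).  No science lives here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fba_core import MetabolicModel, Reaction
from .gene_sets import GeneSet

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneAnnotation",
    "Annotation",
    "MutationRecord",
    "MutationTable",
    "read_annotation",
    "read_mutations",
    "write_mutations",
    "read_bigg_model",
    "write_bigg_model",
    "read_gene_set",
    "write_gene_set",
    "read_medium",
    "write_json_result",
    "read_json_result",
    "write_matrix_csv",
    "read_matrix_csv",
]


class FormatError(ValueError):
    """File does not have the expected structure (e.g. a missing column)."""


class ValidationError(ValueError):
    """File parsed but violates an invariant; message names the row."""


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: its id and length in nucleotides.

    The length is the normalizer for cumulative mutation trajectories, so it
    must be positive; when 1-based inclusive coordinates are supplied they
    must agree with it (length == end - start + 1).
    """

    gene_id: str
    length_nt: int
    locus_tag: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.length_nt <= 0:
            raise ValidationError(
                f"gene {self.gene_id}: length_nt must be positive, got {self.length_nt}"
            )
        if self.start is not None and self.end is not None:
            if self.end - self.start + 1 != self.length_nt:
                raise ValidationError(
                    f"gene {self.gene_id}: length_nt {self.length_nt} does not "
                    f"match end - start + 1 = {self.end - self.start + 1}"
                )


class Annotation:
    """A gene annotation table: unique gene ids mapped to their records."""

    def __init__(self, genes):
        self._genes: dict[str, GeneAnnotation] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r} in annotation")
            self._genes[g.gene_id] = g

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def length(self, gene_id: str) -> int:
        return self._genes[gene_id].length_nt

    def total_length(self, gene_ids) -> int:
        return sum(self._genes[g].length_nt for g in gene_ids)


_ANNOTATION_COLUMNS = ("gene_id", "length_nt", "locus_tag", "start", "end")


def read_annotation(path, dialect: dict[str, str] | None = None) -> Annotation:
    """Read a CSV gene-annotation table.

    ``dialect`` maps canonical column names (``gene_id``, ``length_nt``,
    ``locus_tag``, ``start``, ``end``) to the file's actual headers.  A
    missing ``length_nt`` column is tolerated when ``start``/``end`` are
    present (length = end - start + 1, 1-based inclusive).
    """
    frame = pd.read_csv(path)
    cols = _apply_dialect(frame, dialect, _ANNOTATION_COLUMNS)
    if "gene_id" not in cols:
        raise FormatError(f"{path}: missing required column 'gene_id'")
    if "length_nt" not in cols and not ("start" in cols and "end" in cols):
        raise FormatError(
            f"{path}: need a 'length_nt' column or both 'start' and 'end'"
        )
    genes = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        values = dict(zip(frame.columns, row))
        try:
            start = _opt_int(values.get(cols.get("start")))
            end = _opt_int(values.get(cols.get("end")))
            if cols.get("length_nt") is not None and not pd.isna(
                values[cols["length_nt"]]
            ):
                length = int(values[cols["length_nt"]])
            else:
                length = end - start + 1
            genes.append(
                GeneAnnotation(
                    gene_id=str(values[cols["gene_id"]]).strip(),
                    length_nt=length,
                    locus_tag=_opt_str(values.get(cols.get("locus_tag"))),
                    start=start,
                    end=end,
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}, row {row_number}: {exc}") from exc
    return Annotation(genes)


def _apply_dialect(frame, dialect, canonical):
    mapping = dict(dialect or {})
    cols = {}
    for name in canonical:
        actual = mapping.get(name, name)
        if actual in frame.columns:
            cols[name] = actual
    unknown = set(mapping) - set(canonical)
    if unknown:
        raise FormatError(f"dialect maps unknown canonical column(s) {sorted(unknown)}")
    missing = {k: v for k, v in mapping.items() if v not in frame.columns}
    if missing:
        raise FormatError(
            f"dialect column(s) not found in file: {sorted(missing.values())}"
        )
    return cols


def _opt_int(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return int(value)


def _opt_str(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return str(value)


# ---------------------------------------------------------------------------
# Mutation time series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One observed mutation: which population, when (in generations), and
    in which gene it appeared."""

    population: str
    generation: float
    gene_id: str
    mutation_class: str | None = None

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValidationError(
                f"generation must be non-negative, got {self.generation}"
            )
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")


@dataclass
class MutationTable:
    """An in-memory mutation time series over one or more populations.

    Records keep file order; sorting by (population, generation) is the
    consumer's job.
    """

    records: list[MutationRecord] = field(default_factory=list)

    @property
    def populations(self) -> set[str]:
        return {r.population for r in self.records}

    def for_population(self, population: str) -> "MutationTable":
        return MutationTable([r for r in self.records if r.population == population])

    def __len__(self) -> int:
        return len(self.records)


_MUTATION_COLUMNS = ("population", "generation", "gene_id", "mutation_class")


def read_mutations(path, dialect: dict[str, str] | None = None) -> MutationTable:
    """Read a CSV mutation table (columns: population, generation, gene_id,
    optional mutation_class; renameable through ``dialect``)."""
    frame = pd.read_csv(path)
    cols = _apply_dialect(frame, dialect, _MUTATION_COLUMNS)
    for required in ("population", "generation", "gene_id"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        values = dict(zip(frame.columns, row))
        try:
            generation = float(values[cols["generation"]])
            if np.isnan(generation):
                raise ValueError("generation is missing")
            records.append(
                MutationRecord(
                    population=str(values[cols["population"]]),
                    generation=generation,
                    gene_id=str(values[cols["gene_id"]]).strip(),
                    mutation_class=_opt_str(values.get(cols.get("mutation_class"))),
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}, row {row_number}: {exc}") from exc
    return MutationTable(records)


def write_mutations(table: MutationTable, path) -> None:
    frame = pd.DataFrame(
        {
            "population": [r.population for r in table.records],
            "generation": [r.generation for r in table.records],
            "gene_id": [r.gene_id for r in table.records],
            "mutation_class": [r.mutation_class for r in table.records],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BiGG-JSON metabolic models
# ---------------------------------------------------------------------------


def read_bigg_model(path) -> MetabolicModel:
    """Read a BiGG-JSON metabolic model.

    Requires metabolites, reactions (with bounds, stoichiometry and
    ``gene_reaction_rule``), genes, and exactly one reaction carrying a
    non-zero ``objective_coefficient``.
    """
    with open(path) as handle:
        doc = json.load(handle)
    for key in ("metabolites", "reactions", "genes"):
        if key not in doc:
            raise FormatError(f"{path}: missing top-level key {key!r}")
    objective = [
        r["id"]
        for r in doc["reactions"]
        if float(r.get("objective_coefficient", 0.0)) != 0.0
    ]
    if len(objective) != 1:
        raise FormatError(
            f"{path}: expected exactly one objective reaction, found {len(objective)}"
        )
    reactions = []
    for r in doc["reactions"]:
        try:
            reactions.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={m: float(c) for m, c in r["metabolites"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    gpr=r.get("gene_reaction_rule", "") or "",
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: reaction {r.get('id')!r} missing {exc}") from exc
    try:
        return MetabolicModel(
            id=str(doc.get("id", Path(path).stem)),
            metabolites=[m["id"] for m in doc["metabolites"]],
            reactions=reactions,
            genes=[g["id"] for g in doc["genes"]],
            objective_reaction=objective[0],
            medium=dict(doc.get("medium", {})),
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_bigg_model(model: MetabolicModel, path) -> None:
    """Serialize a model to BiGG-JSON (round-trips through
    :func:`read_bigg_model` field-for-field)."""
    doc = {
        "id": model.id,
        "metabolites": [{"id": m, "compartment": ""} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": (
                    1.0 if r.id == model.objective_reaction else 0.0
                ),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
        "compartments": {},
        "version": "1",
    }
    if model.medium:
        doc["medium"] = model.medium
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True)


def read_medium(path) -> dict[str, float]:
    """JSON mapping of exchange-reaction id -> lower bound."""
    with open(path) as handle:
        doc = json.load(handle)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: medium file must be a JSON object")
    return {str(k): float(v) for k, v in doc.items()}


# ---------------------------------------------------------------------------
# Gene-set files
# ---------------------------------------------------------------------------


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene id per line; '#' comments and surrounding whitespace ignored;
    duplicates collapsed.  The set name defaults to the file stem."""
    members = set()
    with open(path) as handle:
        for line in handle:
            text = line.split("#", 1)[0].strip()
            if text:
                members.add(text)
    if not members:
        raise ValidationError(f"{path}: gene-set file contains no gene ids")
    return GeneSet(name=name or Path(path).stem, members=frozenset(members))


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as handle:
        for gene_id in sorted(gene_set.members):
            handle.write(gene_id + "\n")


# ---------------------------------------------------------------------------
# Result serialization (JSON scalars + CSV matrices)
# ---------------------------------------------------------------------------


def write_json_result(payload: dict, path) -> None:
    """Write a result dict to JSON deterministically (sorted keys)."""
    with open(path, "w") as handle:
        json.dump(_jsonable(payload), handle, indent=1, sort_keys=True)
        handle.write("\n")


def read_json_result(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_matrix_csv(frame: pd.DataFrame, path) -> None:
    """Boolean presence/absence matrix as 0/1 CSV with labelled axes."""
    frame.astype(int).to_csv(path, index=True, index_label="replicate_id")


def read_matrix_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="replicate_id")
    return frame.astype(bool)
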