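"""Gene-set algebra: validation against an annotation, total nucleotide
lengths, and exclusive (UpSet-style) intersection counts.

Intersections here are EXCLUSIVE: each gene in the union is counted in
exactly the one membership pattern matching its full profile across the
input sets, so a gene in sets A and B contributes to the (A and B, not C)
cell only — not to the marginal A∩B.  This matches UpSet plots and is the
semantics commonly confused with inclusive pairwise intersections.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GeneSetError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """A named, finite set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise GeneSetError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


@dataclass
class OverlapTable:
    """Exclusive-intersection counts over a family of sets.

    ``patterns`` maps a boolean membership tuple (one flag per input set,
    in input order) to the number of genes with exactly that profile;
    all-false patterns never appear.  Conservation invariants: counts sum
    to |union|, and each set's size equals the sum of counts over patterns
    containing it.
    """

    set_names: list[str]
    patterns: dict[tuple[bool, ...], int]
    set_sizes: dict[str, int] = field(default_factory=dict)

    def count(self, pattern) -> int:
        return self.patterns.get(tuple(bool(b) for b in pattern), 0)

    @property
    def union_size(self) -> int:
        return sum(self.patterns.values())

    def to_rows(self) -> list[dict]:
        rows = []
        for pattern in sorted(self.patterns, reverse=True):
            rows.append(
                {
                    **{
                        name: int(flag)
                        for name, flag in zip(self.set_names, pattern)
                    },
                    "count": self.patterns[pattern],
                }
            )
        return rows


def validate_against_annotation(gene_set: GeneSet, annotation):
    """Drop members missing from the annotation; report them verbatim.

    Raises :class:`GeneSetError` if nothing survives (an unannotated focal
    set cannot be length-normalized, hence cannot be tested).
    """
    if len(annotation) == 0:
        raise GeneSetError("annotation is empty")
    kept = frozenset(g for g in gene_set.members if g in annotation)
    dropped = sorted(gene_set.members - kept)
    if not kept:
        raise GeneSetError(
            f"gene set {gene_set.name!r}: no members found in the annotation"
        )
    return GeneSet(name=gene_set.name, members=kept), dropped


def total_length(gene_set: GeneSet, annotation) -> int:
    """Combined length of the set in nucleotides — the trajectory normalizer."""
    missing = [g for g in gene_set.members if g not in annotation]
    if missing:
        raise GeneSetError(
            f"gene set {gene_set.name!r}: members missing from annotation "
            f"{sorted(missing)} (validate first)"
        )
    return sum(annotation.length(g) for g in gene_set.members)


def exclusive_intersections(sets: list[GeneSet]) -> OverlapTable:
    """Classify every gene in the union by its full membership pattern."""
    if len(sets) < 2:
        raise GeneSetError("need at least two sets to intersect")
    union = set()
    for s in sets:
        union |= s.members
    patterns: dict[tuple[bool, ...], int] = {}
    for gene in union:
        pattern = tuple(gene in s.members for s in sets)
        patterns[pattern] = patterns.get(pattern, 0) + 1
    return OverlapTable(
        set_names=[s.name for s in sets],
        patterns=patterns,
        set_sizes={s.name: len(s) for s in sets},
    )
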