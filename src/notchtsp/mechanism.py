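"""Biologically constrained pair-space construction.

The classifier's feature space is not all gene pairs but the "mechanism": the
cross product of genes up-regulated by a signalling pathway (here Notch) with
genes down-regulated by it. Gene sets come in as GMT files (MSigDB-style);
genes listed in both directions are dropped from both sides before pairing,
and pairs are later restricted to genes actually measured in a cohort.

Pair orientation is fixed as (up-gene, down-gene) throughout — the vote
semantics downstream rely on it. Gene identifiers are matched by exact,
case-sensitive string equality; alias resolution is a user-side concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

UP = "up"
DOWN = "down"


class MechanismError(ValueError):
    """Raised when a mechanism cannot be built or becomes empty."""


class GMTParseError(ValueError):
    """Raised on a malformed GMT line; carries the 1-based line number."""


@dataclass(frozen=True)
class GeneSet:
    """A named, directed gene set (unique symbols, first occurrence kept)."""

    name: str
    genes: tuple[str, ...]
    direction: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise MechanismError(f"gene set {self.name!r} has duplicate symbols")
        if self.direction is not None and self.direction not in (UP, DOWN):
            raise MechanismError(
                f"direction must be {UP!r} or {DOWN!r}, got {self.direction!r}"
            )


@dataclass
class PairConstraintSet:
    """Ordered collection of (up-gene, down-gene) candidate pairs.

    ``n_up`` / ``n_down`` count the distinct genes on each side. For a
    freshly built mechanism (before measurement filtering) the number of
    pairs equals ``n_up * n_down``.
    """

    pairs: list[tuple[str, str]]
    n_up: int = field(init=False)
    n_down: int = field(init=False)

    def __post_init__(self) -> None:
        ups = {u for u, _ in self.pairs}
        downs = {d for _, d in self.pairs}
        if ups & downs:
            raise MechanismError(
                f"genes on both sides of the mechanism: {sorted(ups & downs)[:5]}"
            )
        for u, d in self.pairs:
            if u == d:
                raise MechanismError(f"pair with identical genes: {u!r}")
        if len(set(self.pairs)) != len(self.pairs):
            raise MechanismError("duplicate pairs in mechanism")
        self.n_up = len(ups)
        self.n_down = len(downs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def genes(self) -> list[str]:
        """All distinct genes in pair order (ups and downs interleaved)."""
        seen: dict[str, None] = {}
        for u, d in self.pairs:
            seen.setdefault(u)
            seen.setdefault(d)
        return list(seen)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["gene_up", "gene_down"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "PairConstraintSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["gene_up", "gene_down"]:
            raise MechanismError(
                f"pair file must have header 'gene_up\\tgene_down', got {list(df.columns)}"
            )
        return cls([(u, d) for u, d in zip(df["gene_up"], df["gene_down"])])


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Duplicate symbols within a line are dropped, keeping the first
    occurrence. Direction is not encoded in GMT; the caller assigns it
    (see :func:`merge_direction`).
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected at least name, description and one gene"
                )
            name, description, *genes = fields
            deduped = list(dict.fromkeys(g for g in genes if g))
            sets.append(
                GeneSet(name=name, genes=tuple(deduped), description=description)
            )
    return sets


def merge_direction(sets: Iterable[GeneSet], direction: str) -> list[str]:
    """Union the member genes of same-direction sets.

    Order is deterministic: first occurrence across sets in input order.
    Sets carrying an explicit direction must match the requested one.
    """
    if direction not in (UP, DOWN):
        raise MechanismError(f"direction must be {UP!r} or {DOWN!r}")
    merged: dict[str, None] = {}
    for gs in sets:
        if gs.direction is not None and gs.direction != direction:
            raise MechanismError(
                f"gene set {gs.name!r} has direction {gs.direction!r}, "
                f"expected {direction!r}"
            )
        for g in gs.genes:
            merged.setdefault(g)
    if not merged:
        raise MechanismError(f"no genes in the {direction}-regulated union")
    return list(merged)


def build_mechanism(
    up_genes: Sequence[str], down_genes: Sequence[str]
) -> PairConstraintSet:
    """Cross up-regulated with down-regulated genes into candidate pairs.

    Genes present in both lists are removed from *both* sides first, then
    every surviving up gene is paired with every surviving down gene.
    Pair order is up-gene major, down-gene minor, both in input-list order,
    so feature indices are reproducible.
    """
    if not up_genes or not down_genes:
        raise MechanismError("up and down gene lists must both be non-empty")
    up_unique = list(dict.fromkeys(up_genes))
    down_unique = list(dict.fromkeys(down_genes))
    shared = set(up_unique) & set(down_unique)
    up_kept = [g for g in up_unique if g not in shared]
    down_kept = [g for g in down_unique if g not in shared]
    if not up_kept or not down_kept:
        raise MechanismError(
            "no genes left on one side after removing "
            f"{len(shared)} symbols shared between directions"
        )
    pairs = [(u, d) for u in up_kept for d in down_kept]
    return PairConstraintSet(pairs)


def restrict_to_measured(
    mech: PairConstraintSet, measured: Iterable[str]
) -> PairConstraintSet:
    """Keep only pairs whose genes are both measured; order preserved."""
    measured_set = set(measured)
    if not measured_set:
        raise MechanismError("measured gene list is empty")
    kept = [(u, d) for u, d in mech.pairs if u in measured_set and d in measured_set]
    if not kept:
        raise MechanismError("no mechanism pair has both genes measured")
    return PairConstraintSet(kept)
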