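"""Curated disulfidptosis regulator gene sets and GMT file I/O.

Disulfidptosis is a form of cell death driven by disulfide-bond accumulation
that collapses the actin cytoskeleton.  A CRISPR loss-of-function screen
identified 21 regulator genes: 9 that promote the phenotype ("positive"
regulators, the WAVE-complex / cystine-import axis around SLC7A11) and 12
that suppress it ("negative" regulators, largely NADPH-producing and
glucose-handling enzymes such as G6PD, PGD and the GLUT transporters).
This module ships those lists as a bundled GMT file and provides reading
and writing of arbitrary gene-set collections in the MSigDB GMT dialect
(tab-separated: name, description, member genes; one set per line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Direction",
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "bundled_regulators",
    "load_gmt",
    "write_gmt",
    "BUNDLED_GMT_NAME",
]

BUNDLED_GMT_NAME = "disulfidptosis_regulators.gmt"

POSITIVE_SET_NAME = "disulfidptosis_positive"
NEGATIVE_SET_NAME = "disulfidptosis_negative"


class Direction(str, Enum):
    """Direction tag: whether a set's genes promote or suppress the phenotype."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNSIGNED = "unsigned"


class GmtParseError(ValueError):
    """Raised for malformed GMT content (line number included in message)."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered gene list with an optional direction tag.

    Parameters
    ----------
    name
        Set identifier, unique within a collection.
    genes
        Ordered gene symbols; duplicates are rejected at construction.
    direction
        ``positive`` / ``negative`` for the regulator lists, ``unsigned``
        for generic collections (hallmark sets, user GMTs).
    description
        Free-text description (second GMT column).
    """

    name: str
    genes: tuple[str, ...]
    direction: Direction = Direction.UNSIGNED
    description: str = ""

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: set[str] = set()
        for g in genes:
            key = g.casefold()
            if key in seen:
                raise ValueError(
                    f"gene set {self.name!r} contains duplicate symbol {g!r}"
                )
            seen.add(key)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "direction", Direction(self.direction))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def membership(self, gene_ids: Iterable[str], case_fold: bool = False):
        """Boolean membership over ``gene_ids`` (case-sensitive by default)."""
        if case_fold:
            members = {g.casefold() for g in self.genes}
            return [g.casefold() in members for g in gene_ids]
        members = set(self.genes)
        return [g in members for g in gene_ids]


@dataclass
class GeneSetCollection:
    """A list of gene sets with unique names, tracking where it came from."""

    sets: list[GeneSet] = field(default_factory=list)
    source: str = "memory"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names in collection: {dupes}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def by_direction(self, direction: Direction | str) -> list[GeneSet]:
        direction = Direction(direction)
        return [s for s in self.sets if s.direction is direction]

    def all_genes(self) -> list[str]:
        """Distinct genes across all sets, in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for s in self.sets:
            for g in s.genes:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out


def bundled_regulators() -> GeneSetCollection:
    """The 21 curated disulfidptosis regulators as two direction-tagged sets.

    Returns a collection with exactly two sets: ``disulfidptosis_positive``
    (9 genes) and ``disulfidptosis_negative`` (12 genes).  The lists ship as
    a GMT data file inside the package so they can be diffed or extended.
    """
    ref = resources.files("disulfiscore").joinpath("data", BUNDLED_GMT_NAME)
    with resources.as_file(ref) as path:
        collection = load_gmt(path)
    directed = []
    for s in collection.sets:
        direction = (
            Direction.POSITIVE if s.name == POSITIVE_SET_NAME else Direction.NEGATIVE
        )
        directed.append(
            GeneSet(s.name, s.genes, direction=direction, description=s.description)
        )
    return GeneSetCollection(directed, source="bundled")


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file into a collection of unsigned gene sets.

    Each line must have at least three tab-separated fields
    (name, description, gene, ...).  Duplicate genes within a line are
    dropped with a warning; duplicate set names across lines are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            deduped: list[str] = []
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                deduped.append(g)
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has duplicate genes; "
                    "duplicates dropped",
                    stacklevel=2,
                )
            if not deduped:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name, tuple(deduped), description=description))
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT (UTF-8, LF newlines, one set per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
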