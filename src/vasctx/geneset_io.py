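"""Gene-set collections: GMT parsing, term/size filtering, ortholog mapping.

Gene sets travel in the GMT format (one set per line: name, description,
then gene symbols, tab-separated), the standard carrier for MSigDB-style
collections. Ortholog maps are two-column TSV tables (source symbol,
target symbol), one pair per line; a source may map to several targets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    """A GMT line does not have the required name/description/genes fields."""


class CatalogError(ValueError):
    """Catalog-level invariant violation (e.g. duplicate set names)."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols.

    ``collection`` is a provenance tag (e.g. "Curated", "GO", "Reactome").
    """

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()
    collection: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("gene set name must be non-empty")
        if not self.genes:
            raise CatalogError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise CatalogError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def effective_size(self, universe: Iterable[str] | None = None) -> int:
        """Set size, after restriction to ``universe`` when one is given."""
        if universe is None:
            return len(self.genes)
        uni = set(universe)
        return sum(g in uni for g in self.genes)


@dataclass(frozen=True)
class GeneSetCatalog:
    """An ordered collection of gene sets with unique names."""

    sets: tuple[GeneSet, ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"duplicate set names in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)


@dataclass(frozen=True)
class OrthologMap:
    """Symbol-level ortholog mapping; a source may have several targets."""

    pairs: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, targets in self.pairs.items():
            if not src or any(not t for t in targets):
                raise CatalogError("ortholog map contains empty symbols")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        out: dict[str, list[str]] = {}
        for src, tgt in pairs:
            out.setdefault(src, [])
            if tgt not in out[src]:
                out[src].append(tgt)
        return cls({k: tuple(v) for k, v in out.items()})

    @classmethod
    def read_tsv(cls, path: str | Path, header: bool = False) -> "OrthologMap":
        """Read a 2-column TSV of (source_symbol, target_symbol) pairs."""
        pairs = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                if header and i == 0:
                    continue
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise GmtParseError(
                        f"ortholog map line {i + 1}: expected 2 tab-separated "
                        f"fields, got {len(fields)}"
                    )
                pairs.append((fields[0], fields[1]))
        return cls.from_pairs(pairs)

    @property
    def target_space(self) -> frozenset[str]:
        return frozenset(t for ts in self.pairs.values() for t in ts)


def parse_gmt(text: str, collection: str = "") -> GeneSetCatalog:
    """Parse GMT content into a catalog.

    Each non-empty line must have >= 3 tab-separated fields (name,
    description, genes...). Duplicate symbols within a line are dropped,
    keeping first occurrence; duplicate set names raise :class:`CatalogError`.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        # trailing empty cells (e.g. "A\tB\t") are tolerated, empty genes dropped
        fields = [fields[0], fields[1] if len(fields) > 1 else ""] + [
            f for f in fields[2:] if f
        ]
        if len(fields) < 3:
            raise GmtParseError(
                f"GMT line {lineno}: expected >=3 tab-separated fields "
                f"(name, description, genes...), got {len(fields)}"
            )
        name, description, *genes = fields
        if name in seen:
            raise CatalogError(f"GMT line {lineno}: duplicate set name {name!r}")
        seen.add(name)
        sets.append(
            GeneSet(
                name=name,
                description=description,
                genes=tuple(dict.fromkeys(genes)),
                collection=collection,
            )
        )
    return GeneSetCatalog(tuple(sets))


def read_gmt(path: str | Path, collection: str = "") -> GeneSetCatalog:
    return parse_gmt(Path(path).read_text(), collection=collection)


def write_gmt(catalog: GeneSetCatalog, path: str | Path | None = None) -> str:
    """Serialize a catalog to GMT; returns the text, optionally writing it."""
    lines = [
        "\t".join([s.name, s.description, *s.genes]) for s in catalog
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def _normalize_term(s: str) -> str:
    # underscores and spaces are the same separator; match case-insensitively
    return re.sub(r"[_\s]+", " ", s).lower()


def select_by_term(catalog: GeneSetCatalog, term: str) -> GeneSetCatalog:
    """Retain sets whose name or description contains ``term``.

    Matching is case-insensitive and treats underscores and spaces as the
    same separator, so "smooth muscle" matches "GO_SMOOTH_MUSCLE_CONTRACTION".
    """
    if not term:
        raise ValueError("term must be non-empty")
    needle = _normalize_term(term)
    kept = tuple(
        s
        for s in catalog
        if needle in _normalize_term(s.name) or needle in _normalize_term(s.description)
    )
    return GeneSetCatalog(kept)


def filter_by_size(
    catalog: GeneSetCatalog,
    min_size: int,
    max_size: int,
    universe: Iterable[str] | None = None,
    intersect_first: bool = True,
) -> GeneSetCatalog:
    """Retain sets whose effective size lies in [min_size, max_size].

    When a measured-gene ``universe`` is supplied and ``intersect_first`` is
    true (the default, matching enrichment-tool convention), sizes are
    computed after intersection with the universe; with ``intersect_first``
    false the raw set size is used even when a universe is supplied.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"invalid size bounds ({min_size}, {max_size})")
    eff_universe = universe if intersect_first else None
    kept = tuple(
        s for s in catalog if min_size <= s.effective_size(eff_universe) <= max_size
    )
    return GeneSetCatalog(kept)


def map_orthologs(catalog: GeneSetCatalog, omap: OrthologMap) -> GeneSetCatalog:
    """Map every symbol through the ortholog table.

    Each source symbol is replaced by all its targets (one-to-many
    expansion); symbols absent from the map are dropped and logged; mapped
    duplicates are de-duplicated; sets emptied by mapping are removed and
    logged.
    """
    out: list[GeneSet] = []
    for s in catalog:
        mapped: list[str] = []
        dropped: list[str] = []
        for g in s.genes:
            targets = omap.pairs.get(g)
            if targets is None:
                dropped.append(g)
            else:
                mapped.extend(targets)
        if dropped:
            logger.info(
                "map_orthologs: set %s: dropped %d unmapped symbol(s): %s",
                s.name, len(dropped), ",".join(dropped),
            )
        genes = tuple(dict.fromkeys(mapped))
        if not genes:
            logger.warning("map_orthologs: set %s emptied by mapping; removed", s.name)
            continue
        out.append(
            GeneSet(
                name=s.name,
                description=s.description,
                genes=genes,
                collection=s.collection,
            )
        )
    return GeneSetCatalog(tuple(out))
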