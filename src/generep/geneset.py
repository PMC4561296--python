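"""Gene-set data model, GMT/TSV I/O, identifier normalization and set algebra.

The objects here carry everything the downstream statistics need: named gene
sets (optionally signed, with linear-scale fold changes), a reference universe
against which all comparisons are restricted, and role-tagged catalogs of sets
(pathway targets, transcription-factor targets, phenotype or condition lists).

Identifiers are upper-cased HGNC-style symbols.  No remote lookup is ever
performed; alias resolution goes only through a user-supplied local mapping,
so every run is reproducible offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneSet",
    "Universe",
    "Catalog",
    "CATALOG_ROLES",
    "InvalidIdentifierError",
    "GmtParseError",
    "SchemaError",
    "DirectionError",
    "normalize_identifier",
    "read_gmt",
    "write_gmt",
    "read_signed_table",
    "restrict",
    "concordant_subset",
    "discordant_subset",
    "split_by_direction",
]

CATALOG_ROLES = ("pathway_targets", "tf_targets", "phenotype", "condition", "annotation")


class InvalidIdentifierError(ValueError):
    """Raised for empty or whitespace-only gene identifiers."""


class GmtParseError(ValueError):
    """Raised for malformed GMT lines (fewer than 3 tab-separated fields)."""


class SchemaError(ValueError):
    """Raised when a signed table lacks required columns or has invalid values."""


class DirectionError(ValueError):
    """Raised when an operation requiring per-gene direction gets an unsigned set."""


# ---------------------------------------------------------------------------
# identifier normalization
# ---------------------------------------------------------------------------

_warned_aliases: set[str] = set()


def normalize_identifier(raw: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Normalize a raw gene identifier to an upper-cased canonical symbol.

    Whitespace is stripped and the symbol upper-cased.  If ``alias_map``
    (alias -> canonical symbol) contains the upper-cased symbol, the canonical
    target is returned.  A symbol appearing in a non-empty alias map neither
    as alias nor as canonical value triggers a warning, once per symbol.

    Raises
    ------
    InvalidIdentifierError
        If ``raw`` is empty after trimming.
    """
    symbol = raw.strip().upper()
    if not symbol:
        raise InvalidIdentifierError(f"empty gene identifier: {raw!r}")
    if alias_map:
        upper_map = {k.strip().upper(): v.strip().upper() for k, v in alias_map.items()}
        if symbol in upper_map:
            return upper_map[symbol]
        if symbol not in set(upper_map.values()) and symbol not in _warned_aliases:
            _warned_aliases.add(symbol)
            warnings.warn(f"symbol {symbol!r} not found in alias map; passed through")
    return symbol


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers.

    ``direction`` (per-gene sign in {+1, -1}) and ``fold_change`` (per-gene
    linear-scale positive ratio; values < 1 mean downregulation) are optional
    and, when both present, must agree: sign(g) = +1 iff fold_change(g) > 1.
    """

    name: str
    genes: frozenset[str]
    description: str = ""
    direction: Mapping[str, int] | None = None
    fold_change: Mapping[str, float] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.direction is not None:
            missing = self.genes - set(self.direction)
            if missing:
                raise DirectionError(
                    f"set {self.name!r}: {len(missing)} genes lack a direction sign"
                )
            bad = {g for g in self.genes if self.direction[g] not in (+1, -1)}
            if bad:
                raise DirectionError(f"set {self.name!r}: directions must be +1 or -1")
        if self.fold_change is not None:
            for g in self.genes:
                fc = self.fold_change.get(g)
                if fc is None:
                    continue
                if not fc > 0:
                    raise ValueError(f"set {self.name!r}: fold_change({g}) = {fc} not > 0")
                if self.direction is not None:
                    want = +1 if fc > 1 else -1
                    if fc != 1 and self.direction[g] != want:
                        raise DirectionError(
                            f"set {self.name!r}: sign of {g} inconsistent with fold change {fc}"
                        )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    @property
    def has_direction(self) -> bool:
        return self.direction is not None

    def subset(self, genes: Iterable[str], name: str | None = None) -> "GeneSet":
        """Return the sub-set on ``genes``, carrying direction/fold-change along."""
        keep = self.genes & frozenset(genes)
        return GeneSet(
            name=name if name is not None else self.name,
            genes=keep,
            description=self.description,
            direction={g: self.direction[g] for g in keep} if self.direction else None,
            fold_change=(
                {g: self.fold_change[g] for g in keep if g in self.fold_change}
                if self.fold_change
                else None
            ),
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class Universe:
    """The reference gene list: every analysed set is first restricted to it."""

    genes: frozenset[str]
    name: str = "universe"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError("universe must be nonempty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class Catalog:
    """A role-tagged, ordered collection of named gene sets over a universe."""

    role: str
    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe: Universe | None = None

    def __post_init__(self) -> None:
        if self.role not in CATALOG_ROLES:
            raise ValueError(f"unknown catalog role {self.role!r}; expected one of {CATALOG_ROLES}")
        self.__dict__["_role_frozen"] = True

    def __setattr__(self, key: str, value) -> None:
        if key == "role" and self.__dict__.get("_role_frozen"):
            raise AttributeError("catalog role is immutable after construction")
        super().__setattr__(key, value)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate set name {gs.name!r} in catalog")
        self.sets[gs.name] = gs

    def union_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.genes
        return frozenset(out)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(
    path: str | Path,
    role: str = "annotation",
    alias_map: Mapping[str, str] | None = None,
    universe: Universe | None = None,
) -> Catalog:
    """Read a GMT file (name, description, gene, gene, ...) into a Catalog.

    Duplicate genes within a line are collapsed with a warning; a line with
    fewer than three tab-separated fields raises :class:`GmtParseError`
    naming the line number.
    """
    catalog = Catalog(role=role, universe=universe)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, description, *raw_genes = fields
            genes = [normalize_identifier(g, alias_map) for g in raw_genes if g.strip()]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has {len(genes) - len(unique)} duplicate genes; collapsed"
                )
            catalog.add(GeneSet(name=name, description=description, genes=unique))
    return catalog


def write_gmt(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog in GMT dialect (UTF-8, LF, genes sorted for determinism)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in catalog.sets:
            gs = catalog.sets[name]
            fields = [gs.name, gs.description or gs.provenance or "na", *sorted(gs.genes)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# signed differential tables
# ---------------------------------------------------------------------------


def read_signed_table(
    path: str | Path,
    fc_threshold: float = 1.4,
    name: str = "signed",
    alias_map: Mapping[str, str] | None = None,
) -> GeneSet:
    """Read a signed differential-expression TSV into a directed GeneSet.

    The table must have a ``gene`` column plus either ``fold_change`` (linear
    ratio; values < 1 mean downregulated) or ``log2fc``.  Only genes beyond
    the symmetric threshold (fold change > ``fc_threshold`` or
    < 1/``fc_threshold``) are retained; direction is the side of 1.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1 (linear scale)")
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols:
        raise SchemaError(f"{path}: missing required column 'gene'")
    if "fold_change" in cols:
        fc = df[cols["fold_change"]].astype(float)
        if (fc <= 0).any():
            raise SchemaError(f"{path}: fold_change values must be strictly positive")
    elif "log2fc" in cols:
        fc = 2.0 ** df[cols["log2fc"]].astype(float)
    else:
        raise SchemaError(f"{path}: need a 'fold_change' or 'log2fc' column")

    genes: dict[str, float] = {}
    for raw, value in zip(df[cols["gene"]], fc):
        genes[normalize_identifier(str(raw), alias_map)] = float(value)

    keep = {g: v for g, v in genes.items() if v > fc_threshold or v < 1.0 / fc_threshold}
    return GeneSet(
        name=name,
        genes=frozenset(keep),
        direction={g: (+1 if v > 1 else -1) for g, v in keep.items()},
        fold_change=keep,
        provenance=str(path),
    )


def write_signed_table(gs: GeneSet, path: str | Path) -> None:
    if gs.fold_change is None:
        raise ValueError("set has no fold changes to write")
    rows = [(g, gs.fold_change[g]) for g in sorted(gs.genes)]
    pd.DataFrame(rows, columns=["gene", "fold_change"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------


def restrict(gs: GeneSet, universe: Universe) -> GeneSet:
    """Intersect a set with the universe, preserving direction and fold change.

    Idempotent and monotone; an empty result is a valid result.
    """
    return gs.subset(universe.genes)


def concordant_subset(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes present in both signed sets with the same direction of change.

    This is the filter behind reducing a shared differential core to its
    same-direction part (e.g. 364 common genes -> 213 concordant).
    """
    if a.direction is None or b.direction is None:
        raise DirectionError("concordant_subset requires direction on both sets")
    keep = {g for g in a.genes & b.genes if a.direction[g] == b.direction[g]}
    return a.subset(keep, name=f"{a.name}&{b.name}:concordant")


def discordant_subset(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes present in both signed sets with opposite directions."""
    if a.direction is None or b.direction is None:
        raise DirectionError("discordant_subset requires direction on both sets")
    keep = {g for g in a.genes & b.genes if a.direction[g] != b.direction[g]}
    return a.subset(keep, name=f"{a.name}&{b.name}:discordant")


def split_by_direction(gs: GeneSet) -> tuple[GeneSet, GeneSet]:
    """Partition a signed set into (upregulated, downregulated) halves."""
    if gs.direction is None:
        raise DirectionError("split_by_direction requires direction")
    up = {g for g in gs.genes if gs.direction[g] == +1}
    down = gs.genes - up
    return gs.subset(up, name=f"{gs.name}:up"), gs.subset(down, name=f"{gs.name}:down")


def _clear_alias_warning_cache() -> None:
    # test hook; keeps "warn once per unknown alias" observable across tests
    _warned_aliases.clear()
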