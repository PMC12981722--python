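"""Star-allele definition tables and the dual coordinate system.

A pharmacogene star allele (e.g. CYP2D6 *2) is defined by a set of *core*
variants that a haplotype must carry; a suballele (*2.039) adds further
non-core variants on top of the same core.  Definition tables here are
desk-scale catalogues sufficient to discriminate the alleles they contain;
they are not complete PharmVar exports.

Coordinates are 1-based on the gene reference sequence (for CYP2D6,
NG_008376.4 / LRG_303 with position 1 = sequence start).  GRCh38 positions
are optional annotations and are never used for variant matching.  CYP2D6
lies on the reverse strand of chromosome 22, so for any variant annotated
in both systems the sum ``gene_pos + grch38_pos`` is a single gene-wide
constant — a cheap integrity check on the fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "VariantKey",
    "FunctionClass",
    "StructuralKind",
    "AlleleDefinition",
    "DefinitionTable",
    "DefinitionError",
    "load_definition_table",
    "write_definition_table",
    "builtin_table",
    "check_coordinate_consistency",
    "SUPPORTED_GENES",
]

SUPPORTED_GENES = ("CYP2D6", "CYP2C19")

_BASE_RE = re.compile(r"^[ACGT]+$")
_STAR_RE = re.compile(r"^\*(\d+)$")
_SUBALLELE_RE = re.compile(r"^\*(\d+)\.(\d+)$")


class DefinitionError(ValueError):
    """Raised for malformed or inconsistent allele-definition input."""


class FunctionClass(str, Enum):
    """Closed vocabulary of allele function classes."""

    NORMAL = "normal"
    DECREASED = "decreased"
    NO_FUNCTION = "no_function"
    INCREASED = "increased"
    UNCERTAIN = "uncertain"
    UNKNOWN = "unknown"

    @property
    def is_indeterminate(self) -> bool:
        """True for the classes that preclude a numeric activity value."""
        return self in (FunctionClass.UNCERTAIN, FunctionClass.UNKNOWN)


class StructuralKind(str, Enum):
    NONE = "none"
    DELETION = "deletion"
    DUPLICATION = "duplication"


@dataclass(frozen=True, order=True)
class VariantKey:
    """One small variant, identified by (gene_pos, ref_base, alt_base).

    ``rsid``, ``grch38_pos`` and ``aa_change`` are annotations; they do not
    participate in equality, so two tokens naming the same substitution at
    the same gene position compare equal regardless of annotation.
    """

    gene_pos: int
    ref_base: str
    alt_base: str
    rsid: Optional[str] = field(default=None, compare=False)
    aa_change: Optional[str] = field(default=None, compare=False)
    grch38_pos: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.gene_pos < 1:
            raise DefinitionError(f"gene_pos must be >= 1, got {self.gene_pos}")
        for base in (self.ref_base, self.alt_base):
            if not _BASE_RE.match(base):
                raise DefinitionError(f"invalid base string {base!r}")
        if self.ref_base == self.alt_base:
            raise DefinitionError(
                f"ref and alt are identical at position {self.gene_pos}"
            )

    @property
    def token(self) -> str:
        """Serialised form ``gene_pos:ref>alt[:rsid[:aa]]``."""
        parts = [f"{self.gene_pos}:{self.ref_base}>{self.alt_base}"]
        if self.rsid or self.aa_change:
            parts.append(self.rsid or ".")
        if self.aa_change:
            parts.append(self.aa_change)
        return ":".join(parts)

    @classmethod
    def from_token(cls, token: str, grch38_pos: Optional[int] = None) -> "VariantKey":
        fields = token.strip().split(":")
        if len(fields) < 2 or len(fields) > 4:
            raise DefinitionError(f"malformed variant token {token!r}")
        try:
            pos = int(fields[0])
        except ValueError as exc:
            raise DefinitionError(f"malformed variant token {token!r}") from exc
        m = re.match(r"^([ACGT]+)>([ACGT]+)$", fields[1])
        if not m:
            raise DefinitionError(f"malformed variant token {token!r}")
        rsid = fields[2] if len(fields) > 2 and fields[2] != "." else None
        aa = fields[3] if len(fields) > 3 and fields[3] != "." else None
        return cls(pos, m.group(1), m.group(2), rsid=rsid, aa_change=aa,
                   grch38_pos=grch38_pos)


def star_number(name: str) -> int:
    """Numeric part of a star-allele label: ``"*41"`` -> 41."""
    m = _STAR_RE.match(name)
    if not m:
        raise DefinitionError(f"not a star-allele label: {name!r}")
    return int(m.group(1))


def suballele_number(name: str) -> int:
    """Numeric suffix of a suballele label: ``"*2.039"`` -> 39."""
    m = _SUBALLELE_RE.match(name)
    if not m:
        raise DefinitionError(f"not a suballele label: {name!r}")
    return int(m.group(2))


@dataclass(frozen=True)
class AlleleDefinition:
    """A star allele or suballele and everything needed to call and score it."""

    gene: str
    name: str
    suballele: Optional[str]
    core_variants: frozenset[VariantKey]
    suballele_variants: frozenset[VariantKey]
    function: FunctionClass
    activity_value: Optional[float]
    structural: StructuralKind = StructuralKind.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_variants", frozenset(self.core_variants))
        object.__setattr__(
            self, "suballele_variants", frozenset(self.suballele_variants)
        )
        star_number(self.name)  # validates the label
        if self.suballele is not None:
            sub_star = _SUBALLELE_RE.match(self.suballele)
            if not sub_star or f"*{sub_star.group(1)}" != self.name:
                raise DefinitionError(
                    f"suballele {self.suballele!r} does not belong to {self.name!r}"
                )
        if self.core_variants & self.suballele_variants:
            raise DefinitionError(
                f"{self.label}: core and suballele variant sets overlap"
            )
        if self.structural is StructuralKind.DELETION and (
            self.core_variants or self.suballele_variants
        ):
            raise DefinitionError(
                f"{self.label}: a whole-gene deletion allele cannot define variants"
            )
        if self.activity_value is not None:
            if self.activity_value < 0:
                raise DefinitionError(f"{self.label}: negative activity value")
            if self.function.is_indeterminate:
                raise DefinitionError(
                    f"{self.label}: {self.function.value}-function allele "
                    "cannot carry a numeric activity value"
                )

    @property
    def label(self) -> str:
        return self.suballele if self.suballele is not None else self.name

    @property
    def all_variants(self) -> frozenset[VariantKey]:
        return self.core_variants | self.suballele_variants


@dataclass(frozen=True)
class DefinitionTable:
    """Validated collection of allele definitions for one gene."""

    gene: str
    reference_id: str
    alleles: tuple[AlleleDefinition, ...]
    default_allele: str

    def __post_init__(self) -> None:
        seen: set[tuple[str, Optional[str]]] = set()
        defaults = []
        for a in self.alleles:
            if a.gene != self.gene:
                raise DefinitionError(
                    f"allele {a.label} has gene {a.gene}, table is {self.gene}"
                )
            key = (a.name, a.suballele)
            if key in seen:
                raise DefinitionError(f"duplicate allele definition {a.label}")
            seen.add(key)
            if (
                a.suballele is None
                and a.structural is StructuralKind.NONE
                and not a.core_variants
            ):
                defaults.append(a.name)
        if defaults != [self.default_allele]:
            raise DefinitionError(
                f"expected exactly one variant-free default allele "
                f"{self.default_allele!r}, found {defaults}"
            )

    # -- lookups ---------------------------------------------------------

    def allele(self, name: str, suballele: Optional[str] = None) -> AlleleDefinition:
        for a in self.alleles:
            if a.name == name and a.suballele == suballele:
                return a
        raise KeyError(f"no allele {suballele or name} in {self.gene} table")

    def star_alleles(self) -> tuple[AlleleDefinition, ...]:
        """Top-level star alleles only (no suballele rows)."""
        return tuple(a for a in self.alleles if a.suballele is None)

    def suballeles_of(self, name: str) -> tuple[AlleleDefinition, ...]:
        return tuple(
            a for a in self.alleles if a.name == name and a.suballele is not None
        )

    def allele_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.star_alleles())

    def variant_by_rsid(self, rsid: str) -> VariantKey:
        """Convenience lookup used widely in tests and examples."""
        for a in self.alleles:
            for v in a.all_variants:
                if v.rsid == rsid:
                    return v
        raise KeyError(f"rsid {rsid} not in {self.gene} table")

    def all_variant_keys(self) -> frozenset[VariantKey]:
        keys: set[VariantKey] = set()
        for a in self.alleles:
            keys |= a.all_variants
        return frozenset(keys)


# ---------------------------------------------------------------------------
# TSV dialect
#
# Columns: gene, allele, suballele, function, activity_score, structural,
# grch38_positions, variants.  "variants" is a semicolon-separated list of
# tokens gene_pos:ref>alt[:rsid[:aa]]; "grch38_positions" is a parallel
# semicolon list of GRCh38 coordinates (or "."); "." means empty anywhere.
# A suballele row lists only the additional suballele-defining variants and
# inherits core variants, function and activity from its parent allele row,
# which must precede it.
# ---------------------------------------------------------------------------

_COLUMNS = [
    "gene",
    "allele",
    "suballele",
    "function",
    "activity_score",
    "structural",
    "grch38_positions",
    "variants",
]


def _parse_variants(cell: str, grch38_cell: str, lineno: int) -> frozenset[VariantKey]:
    if cell == ".":
        return frozenset()
    tokens = [t for t in cell.split(";") if t]
    g38: list[Optional[int]]
    if grch38_cell == ".":
        g38 = [None] * len(tokens)
    else:
        raw = grch38_cell.split(";")
        if len(raw) != len(tokens):
            raise DefinitionError(
                f"line {lineno}: grch38_positions count does not match variants"
            )
        g38 = [None if r == "." else int(r) for r in raw]
    try:
        return frozenset(
            VariantKey.from_token(t, grch38_pos=g) for t, g in zip(tokens, g38)
        )
    except DefinitionError as exc:
        raise DefinitionError(f"line {lineno}: {exc}") from exc


def load_definition_table(path: str | Path, gene: str) -> DefinitionTable:
    """Parse and validate an allele-definition TSV for ``gene``.

    Raises :class:`DefinitionError` naming the offending line for malformed
    rows, duplicate (allele, suballele) pairs, or a missing default allele.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DefinitionError(f"{path}: empty definition file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:1] == ["#reference"]:
        raise DefinitionError(f"{path}: reference pragma must follow the header")
    if header != _COLUMNS:
        raise DefinitionError(
            f"{path}: bad header, expected columns {_COLUMNS}, got {header}"
        )
    reference_id = ""
    alleles: list[AlleleDefinition] = []
    by_name: dict[str, AlleleDefinition] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip() or raw.startswith("#reference\t"):
            if raw.startswith("#reference\t"):
                reference_id = raw.split("\t", 1)[1].strip()
            continue
        cells = raw.rstrip("\n").split("\t")
        if len(cells) != len(_COLUMNS):
            raise DefinitionError(
                f"{path}: line {lineno}: expected {len(_COLUMNS)} columns, "
                f"got {len(cells)}"
            )
        row = dict(zip(_COLUMNS, cells))
        if row["gene"] != gene:
            continue
        variants = _parse_variants(row["variants"], row["grch38_positions"], lineno)
        try:
            if row["suballele"] == ".":
                activity = (
                    None if row["activity_score"] == "."
                    else float(row["activity_score"])
                )
                allele = AlleleDefinition(
                    gene=gene,
                    name=row["allele"],
                    suballele=None,
                    core_variants=variants,
                    suballele_variants=frozenset(),
                    function=FunctionClass(row["function"]),
                    activity_value=activity,
                    structural=StructuralKind(row["structural"]),
                )
                by_name[allele.name] = allele
            else:
                parent = by_name.get(row["allele"])
                if parent is None:
                    raise DefinitionError(
                        f"suballele {row['suballele']} precedes its parent "
                        f"allele {row['allele']}"
                    )
                allele = replace(
                    parent,
                    suballele=row["suballele"],
                    suballele_variants=variants,
                )
        except (ValueError, KeyError) as exc:
            raise DefinitionError(f"{path}: line {lineno}: {exc}") from exc
        alleles.append(allele)

    default = next(
        (
            a.name
            for a in alleles
            if a.suballele is None
            and a.structural is StructuralKind.NONE
            and not a.core_variants
        ),
        None,
    )
    if default is None:
        raise DefinitionError(f"{path}: no variant-free default allele for {gene}")
    return DefinitionTable(
        gene=gene, reference_id=reference_id, alleles=tuple(alleles),
        default_allele=default,
    )


def write_definition_table(table: DefinitionTable, path: str | Path) -> None:
    """Serialise ``table`` in the TSV dialect read by :func:`load_definition_table`."""

    def variant_cells(variants: Iterable[VariantKey]) -> tuple[str, str]:
        ordered = sorted(variants)
        if not ordered:
            return ".", "."
        tokens = ";".join(v.token for v in ordered)
        g38 = [v.grch38_pos for v in ordered]
        if all(g is None for g in g38):
            return tokens, "."
        return tokens, ";".join("." if g is None else str(g) for g in g38)

    out = ["\t".join(_COLUMNS)]
    if table.reference_id:
        out.append(f"#reference\t{table.reference_id}")
    for a in table.alleles:
        if a.suballele is None:
            tokens, g38 = variant_cells(a.core_variants)
            activity = "." if a.activity_value is None else f"{a.activity_value:g}"
            out.append(
                "\t".join(
                    [a.gene, a.name, ".", a.function.value, activity,
                     a.structural.value, g38, tokens]
                )
            )
        else:
            tokens, g38 = variant_cells(a.suballele_variants)
            out.append(
                "\t".join(
                    [a.gene, a.name, a.suballele, a.function.value, ".",
                     a.structural.value, g38, tokens]
                )
            )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def builtin_table(gene: str) -> DefinitionTable:
    """Packaged definition table for a supported gene.

    The CYP2D6 fixture carries the 13 catalogued star alleles plus *186 and
    the ten suballeles first described in the study cohort; CYP2C19 carries
    *1, *2, *3 and *17.
    """
    if gene not in SUPPORTED_GENES:
        raise DefinitionError(
            f"unsupported gene {gene!r}; supported genes: {', '.join(SUPPORTED_GENES)}"
        )
    data = resources.files("pgxstar.data") / f"{gene.lower()}_alleles.tsv"
    with resources.as_file(data) as p:
        return load_definition_table(p, gene)


def check_coordinate_consistency(table: DefinitionTable) -> int:
    """Verify the reverse-strand coordinate relation across the table.

    Every variant annotated with both a gene-reference and a GRCh38 position
    must satisfy ``gene_pos + grch38_pos == constant`` (the gene runs on the
    reverse strand, so one coordinate increases as the other decreases).
    Returns the constant; raises :class:`DefinitionError` if fewer than two
    variants are dual-annotated or the sum is not unique.
    """
    dual = [v for v in table.all_variant_keys() if v.grch38_pos is not None]
    if len(dual) < 2:
        raise DefinitionError(
            f"{table.gene}: need at least two dual-coordinate variants, "
            f"found {len(dual)}"
        )
    sums = {v.gene_pos + v.grch38_pos: v for v in dual}
    if len(sums) > 1:
        offender = sorted(dual, key=lambda v: v.gene_pos)[-1]
        raise DefinitionError(
            f"{table.gene}: inconsistent coordinates; gene_pos + grch38_pos "
            f"is not constant (e.g. variant at gene_pos {offender.gene_pos})"
        )
    return next(iter(sums))
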