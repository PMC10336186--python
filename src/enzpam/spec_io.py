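"""Parse and validate the user table of standard enzyme names.

The table is the entry point of the whole workflow: one row per enzyme,
giving the user-chosen standard name, its EC number(s), KEGG Orthology
identifier(s) and the pathway it belongs to.  Everything downstream (synonym
harvesting, the custom database, the presence-absence matrix rows) keys off
the ``enzyme_id`` derived here, so parsing is strict and deterministic.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ECValidationError, SpecParseError

__all__ = [
    "ECNumber",
    "EnzymeSpec",
    "validate_ec",
    "parse_enzyme_spec",
    "write_enzyme_spec",
    "slugify",
    "make_enzyme_id",
]

_KO_RE = re.compile(r"^K\d{5}$")
_EC_PREFIX_RE = re.compile(r"^\s*(?:EC\s+|ec:)", re.IGNORECASE)

REQUIRED_COLUMNS = ("standard_name", "ec_number", "ko_id", "pathway")


@dataclass(frozen=True, order=True)
class ECNumber:
    """A four-component Enzyme Commission number.

    Trailing components may be the wildcard ``-`` (an incompletely specified
    class, e.g. ``1.14.12.-``); a wildcard never precedes a numeric component
    and the first component is always numeric.
    """

    classes: tuple[str, str, str, str]

    def __post_init__(self):
        cs = self.classes
        if len(cs) != 4:
            raise ECValidationError(".".join(cs), "must have exactly four components")
        if cs[0] == "-":
            raise ECValidationError(".".join(cs), "first component may not be a wildcard")
        seen_wild = False
        for c in cs:
            if c == "-":
                seen_wild = True
            else:
                if seen_wild:
                    raise ECValidationError(
                        ".".join(cs), "numeric component after a wildcard"
                    )
                if not c.isdigit() or int(c) <= 0:
                    raise ECValidationError(".".join(cs), f"component {c!r} is not a positive integer")

    @property
    def text(self) -> str:
        return ".".join(self.classes)

    @property
    def n_specified(self) -> int:
        return sum(1 for c in self.classes if c != "-")

    def matches(self, other: "ECNumber") -> bool:
        """True when ``other`` agrees with every non-wildcard component of self."""
        return all(a == "-" or a == b for a, b in zip(self.classes, other.classes))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def validate_ec(text: str) -> ECNumber:
    """Parse ``text`` into a canonical :class:`ECNumber`.

    An optional ``EC `` or ``ec:`` prefix is stripped; trailing wildcard
    components are preserved.  Raises :class:`ECValidationError` on a wrong
    component count, a non-numeric non-wildcard component, or a wildcard
    followed by a numeric component.
    """
    stripped = _EC_PREFIX_RE.sub("", text).strip()
    parts = stripped.split(".")
    if len(parts) != 4:
        raise ECValidationError(text, f"expected four dot-separated components, got {len(parts)}")
    try:
        return ECNumber(tuple(p.strip() for p in parts))  # type: ignore[arg-type]
    except ECValidationError as exc:
        raise ECValidationError(text, exc.reason) from None


@dataclass(frozen=True)
class EnzymeSpec:
    """One user-defined enzyme: standard name, identifiers, pathway."""

    enzyme_id: str
    standard_name: str
    ec_numbers: tuple[ECNumber, ...]
    ko_ids: tuple[str, ...]
    pathway: str

    def __post_init__(self):
        if not self.standard_name.strip():
            raise SpecParseError("standard_name must be non-empty")
        if not self.pathway.strip():
            raise SpecParseError("pathway must be non-empty")
        if not self.ec_numbers and not self.ko_ids:
            raise SpecParseError(
                f"enzyme {self.standard_name!r}: at least one EC number or KO id required"
            )
        for ko in self.ko_ids:
            if not _KO_RE.match(ko):
                raise SpecParseError(f"invalid KO identifier {ko!r} (expected K#####)")


def slugify(text: str) -> str:
    """Lower-case ``text`` and replace runs of non-alphanumerics with ``-``."""
    slug = re.sub(r"[^a-z0-9]+", "-", text.casefold()).strip("-")
    return slug or "x"


def make_enzyme_id(pathway: str, standard_name: str) -> str:
    """Deterministic enzyme key: slugified pathway and standard name.

    Derived rather than user-supplied so that matrix row labels are stable
    across runs and across edits to unrelated rows.
    """
    return f"{slugify(pathway)}__{slugify(standard_name)}"


def _norm_key(name: str) -> str:
    # duplicate detection uses the same folding as synonym normalization
    from .harvest import normalize_name

    return normalize_name(name)


def parse_enzyme_spec(
    path: str | Path,
    dialect: str = "tsv",
    delimiter: str = ";",
) -> list[EnzymeSpec]:
    """Parse the spec table at ``path`` into an ordered list of enzymes.

    Parameters
    ----------
    path
        TSV (default) or CSV file with header columns ``standard_name``,
        ``ec_number``, ``ko_id``, ``pathway`` (case-insensitive, any order).
        Lines starting with ``#`` are comments.
    dialect
        ``"tsv"`` or ``"csv"``.
    delimiter
        Separator for multi-valued EC/KO cells (default ``;``).
    """
    path = Path(path)
    if dialect not in ("tsv", "csv"):
        raise SpecParseError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    sep = "\t" if dialect == "tsv" else ","
    with open(path, encoding="utf-8", newline="") as fh:
        # strip comment lines before handing to csv so quoting still works
        text = "".join(line for line in fh if not line.lstrip().startswith("#"))
    reader = csv.reader(io.StringIO(text), delimiter=sep, quotechar='"')
    rows = list(reader)
    if not rows:
        raise SpecParseError(f"{path}: file has no header row")
    header = [h.strip().casefold() for h in rows[0]]
    col = {}
    for name in REQUIRED_COLUMNS:
        if name not in header:
            raise SpecParseError(f"{path}: missing required column {name!r}")
        col[name] = header.index(name)

    specs: list[EnzymeSpec] = []
    seen: dict[tuple[str, str], int] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            standard_name = row[col["standard_name"]].strip()
            ec_cell = row[col["ec_number"]].strip()
            ko_cell = row[col["ko_id"]].strip()
            pathway = row[col["pathway"]].strip()
        except IndexError:
            raise SpecParseError(f"{path}:{lineno}: row has too few fields") from None
        ecs = tuple(
            validate_ec(v) for v in (p.strip() for p in ec_cell.split(delimiter)) if v
        )
        kos = tuple(v for v in (p.strip() for p in ko_cell.split(delimiter)) if v)
        if not ecs and not kos:
            raise SpecParseError(
                f"{path}:{lineno}: enzyme {standard_name!r} has neither an EC number nor a KO id"
            )
        key = (slugify(pathway), _norm_key(standard_name))
        if key in seen:
            raise SpecParseError(
                f"{path}: duplicate standard name {standard_name!r} in pathway "
                f"{pathway!r} (rows {seen[key]} and {lineno})"
            )
        seen[key] = lineno
        specs.append(
            EnzymeSpec(
                enzyme_id=make_enzyme_id(pathway, standard_name),
                standard_name=standard_name,
                ec_numbers=ecs,
                ko_ids=kos,
                pathway=pathway,
            )
        )
    ids = [s.enzyme_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SpecParseError(f"{path}: enzyme ids not unique after slugification: {dupes}")
    return specs


def write_enzyme_spec(
    specs: Sequence[EnzymeSpec],
    path: str | Path,
    dialect: str = "tsv",
    delimiter: str = ";",
) -> None:
    """Write ``specs`` back to disk in the input table format (round-trippable)."""
    sep = "\t" if dialect == "tsv" else ","
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, quotechar='"', lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for s in specs:
            writer.writerow(
                [
                    s.standard_name,
                    delimiter.join(e.text for e in s.ec_numbers),
                    delimiter.join(s.ko_ids),
                    s.pathway,
                ]
            )
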