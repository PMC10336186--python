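"""Cross-reference file, synonym matching, and the presence-absence matrix.

This is the standardization core: every synonym is written to a reference
table alongside the standard name and the EC/KO identifiers of its enzyme,
annotation products are matched lexically against those synonyms (exact
normalized equality, or word-bounded substring containment), an optional
curation list vetoes unwanted product names, and the surviving matches are
reduced to a binary enzymes-by-genomes matrix.  Matching is deliberately
lexical: no alignments, scores or E-values — the similarity search already
happened inside the annotator.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationRecord
from .errors import MatrixError, ReferenceError_
from .harvest import SynonymRecord, find_collisions, normalize_name
from .spec_io import EnzymeSpec

__all__ = [
    "ReferenceEntry",
    "MatchResult",
    "PresenceAbsenceMatrix",
    "MatrixComparison",
    "build_reference",
    "write_reference",
    "read_reference",
    "load_curation",
    "match_annotations",
    "build_matrix",
    "compare_matrices",
]


@dataclass(frozen=True)
class ReferenceEntry:
    """One (synonym, enzyme) pair with full cross-database identifiers."""

    norm_name: str
    raw_name: str
    enzyme_id: str
    standard_name: str
    pathway: str
    ec_numbers: str  # ";"-joined canonical EC strings
    ko_ids: str  # ";"-joined KO identifiers
    source: str


def build_reference(
    specs: Sequence[EnzymeSpec], synonyms: Sequence[SynonymRecord]
) -> tuple[list[ReferenceEntry], dict[str, list[str]]]:
    """Join synonyms with their enzymes' identifiers.

    Returns the entries (one per (synonym, enzyme), input order) and the
    collision report: norm_names claimed by more than one enzyme.  A synonym
    whose enzyme_id is not in ``specs`` is an error.
    """
    by_id = {s.enzyme_id: s for s in specs}
    entries = []
    seen: set[tuple[str, str]] = set()
    for syn in synonyms:
        spec = by_id.get(syn.enzyme_id)
        if spec is None:
            raise ReferenceError_(
                f"synonym {syn.norm_name!r} references unknown enzyme {syn.enzyme_id!r}"
            )
        key = (syn.norm_name, syn.enzyme_id)
        if key in seen:
            continue
        seen.add(key)
        entries.append(
            ReferenceEntry(
                norm_name=syn.norm_name,
                raw_name=syn.raw_name,
                enzyme_id=syn.enzyme_id,
                standard_name=spec.standard_name,
                pathway=spec.pathway,
                ec_numbers=";".join(e.text for e in spec.ec_numbers),
                ko_ids=";".join(spec.ko_ids),
                source=syn.source,
            )
        )
    return entries, find_collisions(synonyms)


_REF_COLUMNS = (
    "norm_name",
    "raw_name",
    "enzyme_id",
    "standard_name",
    "pathway",
    "ec_numbers",
    "ko_ids",
    "source",
)


def write_reference(
    entries: Sequence[ReferenceEntry],
    path: str | Path,
    collisions: Mapping[str, list[str]] | None = None,
) -> None:
    """Write the reference TSV; collisions go in a trailing comment section."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REF_COLUMNS)
        for e in entries:
            w.writerow([getattr(e, c) for c in _REF_COLUMNS])
        if collisions:
            fh.write("# collisions: norm_names claimed by more than one enzyme\n")
            for name, ids in collisions.items():
                fh.write(f"# collision\t{name}\t{';'.join(ids)}\n")


def read_reference(path: str | Path) -> list[ReferenceEntry]:
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header = tuple(rows[0])
    if header != _REF_COLUMNS:
        raise ReferenceError_(f"{path}: unexpected reference header {header}")
    return [ReferenceEntry(**dict(zip(_REF_COLUMNS, r))) for r in rows[1:]]


@dataclass(frozen=True)
class MatchResult:
    """One annotation hit on one enzyme's synonym."""

    genome_id: str
    locus_tag: str
    matched_norm_name: str
    enzyme_id: str
    match_mode: str  # exact | substring
    excluded: bool = False
    exclusion_reason: str = ""
    ambiguous: bool = False


def load_curation(path: str | Path) -> list[str]:
    """Read the curation exclusion list: one product/synonym per line,
    ``#`` comments, each line normalized like a product name."""
    lines = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            norm = normalize_name(line)
            if norm:
                lines.append(norm)
    return lines


def _word_bounded(pattern_name: str) -> re.Pattern:
    # anchor on word boundaries so "oxygenase" cannot hit inside "dioxygenase"
    return re.compile(r"(?<!\w)" + re.escape(pattern_name) + r"(?!\w)")


def match_annotations(
    records: Sequence[AnnotationRecord],
    reference: Sequence[ReferenceEntry],
    mode: str = "exact",
    curation_path: str | Path | None = None,
) -> list[MatchResult]:
    """Search annotation products for reference synonyms.

    ``exact`` mode requires the normalized product to equal a synonym's
    norm_name; ``substring`` mode requires the norm_name to occur inside the
    normalized product with word boundaries on both ends.  A curated line
    excludes any match whose matched synonym, or whose whole normalized
    product, equals that line.  Synonyms owned by several enzymes yield one
    result per owner, flagged ambiguous.  Only CDS records are searched.
    """
    if mode not in ("exact", "substring"):
        raise MatrixError(f"unknown match mode {mode!r}")
    curated: set[str] = set()
    if curation_path is not None:
        try:
            curated = set(load_curation(curation_path))
        except OSError as exc:
            raise MatrixError(f"cannot read curation file {curation_path}: {exc}") from exc

    owners: dict[str, list[str]] = {}
    for e in reference:
        owners.setdefault(e.norm_name, [])
        if e.enzyme_id not in owners[e.norm_name]:
            owners[e.norm_name].append(e.enzyme_id)
    # longest names first so substring results are deterministic
    names = sorted(owners, key=lambda n: (-len(n), n))
    patterns = {n: _word_bounded(n) for n in names} if mode == "substring" else {}

    results: list[MatchResult] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        if rec.feature_type != "CDS":
            continue
        norm_product = normalize_name(rec.product)
        if not norm_product:
            continue
        if mode == "exact":
            hit_names = [norm_product] if norm_product in owners else []
        else:
            hit_names = [n for n in names if patterns[n].search(norm_product)]
        for name in hit_names:
            ambiguous = len(owners[name]) > 1
            excluded = name in curated or norm_product in curated
            reason = ""
            if excluded:
                which = name if name in curated else norm_product
                reason = f"curated out: {which}"
            for enzyme_id in owners[name]:
                key = (rec.genome_id, rec.locus_tag, enzyme_id)
                if key in seen:
                    continue
                seen.add(key)
                results.append(
                    MatchResult(
                        genome_id=rec.genome_id,
                        locus_tag=rec.locus_tag,
                        matched_norm_name=name,
                        enzyme_id=enzyme_id,
                        match_mode=mode,
                        excluded=excluded,
                        exclusion_reason=reason,
                        ambiguous=ambiguous,
                    )
                )
    return results


@dataclass
class PresenceAbsenceMatrix:
    """Binary enzymes-by-genomes matrix with per-cell provenance.

    Rows follow spec order (grouped by pathway as the spec table lists
    them); a cell is 1 iff at least one non-excluded match supports it, and
    the supporting locus tags are kept in ``provenance``.
    """

    enzyme_ids: list[str]
    genome_ids: list[str]
    cells: dict[tuple[str, str], int]
    provenance: dict[tuple[str, str], list[str]]
    pathways: dict[str, str]  # enzyme_id -> pathway
    standard_names: dict[str, str]

    def value(self, enzyme_id: str, genome_id: str) -> int:
        return self.cells[(enzyme_id, genome_id)]

    def positives(self) -> set[tuple[str, str]]:
        return {k for k, v in self.cells.items() if v == 1}

    def to_dataframe(self):
        import pandas as pd

        data = {
            g: [self.cells[(e, g)] for e in self.enzyme_ids] for g in self.genome_ids
        }
        df = pd.DataFrame(data, index=self.enzyme_ids)
        df.insert(0, "pathway", [self.pathways[e] for e in self.enzyme_ids])
        df.insert(1, "standard_name", [self.standard_names[e] for e in self.enzyme_ids])
        df.index.name = "enzyme_id"
        return df

    def write(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["pathway", "enzyme_id", "standard_name", *self.genome_ids])
            for e in self.enzyme_ids:
                w.writerow(
                    [
                        self.pathways[e],
                        e,
                        self.standard_names[e],
                        *[self.cells[(e, g)] for g in self.genome_ids],
                    ]
                )
        if provenance_path is not None:
            with open(provenance_path, "w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["enzyme_id", "genome_id", "locus_tags"])
                for (e, g), tags in sorted(self.provenance.items()):
                    w.writerow([e, g, ";".join(tags)])

    @classmethod
    def read(cls, path: str | Path, provenance_path: str | Path | None = None):
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        header = rows[0]
        if header[:3] != ["pathway", "enzyme_id", "standard_name"]:
            raise MatrixError(f"{path}: unexpected matrix header {header[:3]}")
        genome_ids = header[3:]
        enzyme_ids, pathways, standard_names, cells = [], {}, {}, {}
        for row in rows[1:]:
            pw, e, name, *vals = row
            enzyme_ids.append(e)
            pathways[e] = pw
            standard_names[e] = name
            for g, v in zip(genome_ids, vals):
                cells[(e, g)] = int(v)
        provenance: dict[tuple[str, str], list[str]] = {}
        if provenance_path is not None and Path(provenance_path).exists():
            with open(provenance_path, encoding="utf-8", newline="") as fh:
                for row in list(csv.reader(fh, delimiter="\t"))[1:]:
                    e, g, tags = row
                    provenance[(e, g)] = tags.split(";") if tags else []
        return cls(
            enzyme_ids=enzyme_ids,
            genome_ids=genome_ids,
            cells=cells,
            provenance=provenance,
            pathways=pathways,
            standard_names=standard_names,
        )


def build_matrix(
    matches: Sequence[MatchResult],
    specs: Sequence[EnzymeSpec],
    genome_ids: Sequence[str],
) -> PresenceAbsenceMatrix:
    """Reduce matches to the binary matrix.

    Every spec enzyme appears as a row and every supplied genome as a
    column, including all-zero ones; excluded matches never contribute.  A
    match naming a genome outside ``genome_ids`` is an error.
    """
    if not genome_ids:
        raise MatrixError("genome_ids must be non-empty")
    if len(set(genome_ids)) != len(genome_ids):
        raise MatrixError("genome_ids must be unique")
    known_genomes = set(genome_ids)
    enzyme_ids = [s.enzyme_id for s in specs]
    known_enzymes = set(enzyme_ids)

    cells = {(e, g): 0 for e in enzyme_ids for g in genome_ids}
    provenance: dict[tuple[str, str], list[str]] = {}
    for m in matches:
        if m.genome_id not in known_genomes:
            raise MatrixError(f"match references unknown genome {m.genome_id!r}")
        if m.enzyme_id not in known_enzymes:
            raise MatrixError(f"match references unknown enzyme {m.enzyme_id!r}")
        if m.excluded:
            continue
        key = (m.enzyme_id, m.genome_id)
        cells[key] = 1
        tags = provenance.setdefault(key, [])
        if m.locus_tag not in tags:
            tags.append(m.locus_tag)
    return PresenceAbsenceMatrix(
        enzyme_ids=enzyme_ids,
        genome_ids=list(genome_ids),
        cells=cells,
        provenance=provenance,
        pathways={s.enzyme_id: s.pathway for s in specs},
        standard_names={s.enzyme_id: s.standard_name for s in specs},
    )


@dataclass(frozen=True)
class MatrixComparison:
    """Overlap statistics between two matrices with identical labels.

    ``frac_of_b_reproduced`` answers "what fraction of B's positives does A
    recover" (e.g. A = automatic search, B = after manual curation);
    ``frac_only_a`` is the fraction of A's positives absent from B.  Both
    are ``None`` when their denominator is zero.
    """

    n_pos_a: int
    n_pos_b: int
    n_shared: int
    n_only_a: int
    n_only_b: int
    frac_of_b_reproduced: float | None
    frac_only_a: float | None


def compare_matrices(
    a: PresenceAbsenceMatrix, b: PresenceAbsenceMatrix
) -> MatrixComparison:
    """Partition the positive cells of ``a`` and ``b`` into shared / only-a /
    only-b and report both overlap normalizations.  The matrices must carry
    identical row and column label sets."""
    if set(a.enzyme_ids) != set(b.enzyme_ids) or set(a.genome_ids) != set(b.genome_ids):
        diff = sorted(
            (set(a.enzyme_ids) ^ set(b.enzyme_ids))
            | (set(a.genome_ids) ^ set(b.genome_ids))
        )
        raise MatrixError(f"matrices have different labels; symmetric difference: {diff}")
    pos_a, pos_b = a.positives(), b.positives()
    shared = pos_a & pos_b
    only_a = pos_a - pos_b
    only_b = pos_b - pos_a
    return MatrixComparison(
        n_pos_a=len(pos_a),
        n_pos_b=len(pos_b),
        n_shared=len(shared),
        n_only_a=len(only_a),
        n_only_b=len(only_b),
        frac_of_b_reproduced=(len(shared) / len(pos_b)) if pos_b else None,
        frac_only_a=(len(only_a) / len(pos_a)) if pos_a else None,
    )
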