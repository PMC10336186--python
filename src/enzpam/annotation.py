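"""Parse per-genome annotator output into uniform records.

Prokka writes, per genome, a feature table (``.tsv``) and a GFF3 file (with
an optional ``##FASTA`` trailer).  Both dialects are supported and must
agree on the fields the matching step uses — locus tag, gene, EC and
product.  The annotator itself is external: :func:`run_external_annotator`
renders a user-supplied command template so any Prokka-compatible drop-in
works, and parsing never requires the tool to be installed.
"""

from __future__ import annotations

import shlex
import subprocess
import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import AnnotationParseError, AnnotatorError

__all__ = [
    "AnnotationRecord",
    "parse_prokka_tsv",
    "parse_prokka_gff",
    "run_external_annotator",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated feature (usually a CDS) in one genome.

    ``coords`` is ``(seq_id, start, end, strand)`` with 1-based inclusive
    start/end per GFF3, or ``None`` when the source dialect (the feature
    table) carries no coordinates.
    """

    genome_id: str
    locus_tag: str
    feature_type: str  # "CDS" | "other"
    ec_text: str
    gene: str
    product: str
    coords: tuple[str, int, int, str] | None = None

    def __post_init__(self):
        if self.coords is not None:
            _, start, end, strand = self.coords
            if start > end:
                raise AnnotationParseError(
                    f"{self.genome_id}/{self.locus_tag}: start {start} > end {end}"
                )
            if strand not in ("+", "-"):
                raise AnnotationParseError(
                    f"{self.genome_id}/{self.locus_tag}: bad strand {strand!r}"
                )
        if self.feature_type == "CDS" and not self.product:
            raise AnnotationParseError(
                f"{self.genome_id}/{self.locus_tag}: CDS with empty product"
            )


def _check_unique_locus_tags(records: Sequence[AnnotationRecord], path) -> None:
    seen: set[str] = set()
    for r in records:
        if r.locus_tag in seen:
            raise AnnotationParseError(f"{path}: duplicate locus_tag {r.locus_tag!r}")
        seen.add(r.locus_tag)


def parse_prokka_tsv(path: str | Path, genome_id: str) -> list[AnnotationRecord]:
    """Parse a Prokka-style feature table.

    Expected header: ``locus_tag  ftype  length_bp  gene  EC_number  COG
    product`` — optional columns may be missing; ``locus_tag`` and
    ``product`` are required.  Non-CDS rows are kept with
    ``feature_type="other"``.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise AnnotationParseError(f"{path}: empty file, expected a header row")
    header = [h.strip() for h in lines[0].split("\t")]
    lower = [h.casefold() for h in header]
    for req in ("locus_tag", "product"):
        if req not in lower:
            raise AnnotationParseError(f"{path}: missing required column {req!r}")

    def col(name: str) -> int | None:
        return lower.index(name) if name in lower else None

    c_locus, c_prod = lower.index("locus_tag"), lower.index("product")
    c_ftype, c_gene, c_ec = col("ftype"), col("gene"), col("ec_number")

    def cell(row: list[str], idx: int | None) -> str:
        if idx is None or idx >= len(row):
            return ""
        return row[idx].strip()

    records = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        row = ln.split("\t")
        ftype = cell(row, c_ftype) or "CDS"
        records.append(
            AnnotationRecord(
                genome_id=genome_id,
                locus_tag=cell(row, c_locus),
                feature_type="CDS" if ftype == "CDS" else "other",
                ec_text=cell(row, c_ec),
                gene=cell(row, c_gene),
                product=cell(row, c_prod),
                coords=None,
            )
        )
    _check_unique_locus_tags(records, path)
    return records


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs[key] = urllib.parse.unquote(value)
    return attrs


def parse_prokka_gff(path: str | Path, genome_id: str) -> list[AnnotationRecord]:
    """Parse a Prokka-style GFF3 file.

    Attributes are percent-decoded per the GFF3 spec (``%2C`` becomes a
    comma); the locus tag comes from ``locus_tag`` or, failing that, ``ID``;
    a trailing ``##FASTA`` section is ignored.
    """
    path = Path(path)
    records = []
    in_fasta = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if in_fasta or not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attr_text = fields
            attrs = _parse_gff_attributes(attr_text)
            locus_tag = attrs.get("locus_tag") or attrs.get("ID") or ""
            if not locus_tag:
                raise AnnotationParseError(f"{path}:{lineno}: feature without locus_tag/ID")
            try:
                coords = (seqid, int(start), int(end), strand)
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {start!r}..{end!r}"
                ) from None
            records.append(
                AnnotationRecord(
                    genome_id=genome_id,
                    locus_tag=locus_tag,
                    feature_type="CDS" if ftype == "CDS" else "other",
                    ec_text=attrs.get("eC_number", attrs.get("ec_number", "")),
                    gene=attrs.get("gene", ""),
                    product=attrs.get("product", ""),
                    coords=coords,
                )
            )
    _check_unique_locus_tags(records, path)
    return records


def run_external_annotator(
    genome_fasta: str | Path,
    custom_db: str | Path,
    workdir: str | Path,
    annotator_cmd: str,
    use_default_db: bool = False,
) -> dict[str, Path]:
    """Invoke an external annotator through a command template.

    ``annotator_cmd`` is a shell-free template with the placeholders
    ``{genome}``, ``{custom_db}``, ``{outdir}`` and ``{default_db_flag}``
    (the last expands to ``--default-db`` when ``use_default_db`` is set,
    else to nothing).  The custom database is supplied as the priority
    protein database; the template decides the exact flag.  Returns the
    paths of the produced ``.tsv`` and ``.gff`` (whichever exist).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rendered = annotator_cmd.format(
        genome=str(genome_fasta),
        custom_db=str(custom_db),
        outdir=str(workdir),
        default_db_flag="--default-db" if use_default_db else "",
    )
    argv = [a for a in shlex.split(rendered) if a]
    if not argv:
        raise AnnotatorError("annotator command template rendered to an empty command")
    try:
        proc = subprocess.run(argv, capture_output=True, text=True)
    except FileNotFoundError:
        raise AnnotatorError(f"annotator not found: {argv[0]!r}") from None
    if proc.returncode != 0:
        tail = "\n".join(proc.stderr.splitlines()[-10:])
        raise AnnotatorError(
            f"annotator exited with status {proc.returncode}; stderr tail:\n{tail}"
        )
    produced = {}
    for ext in ("tsv", "gff"):
        hits = sorted(workdir.glob(f"*.{ext}"))
        if hits:
            produced[ext] = hits[0]
    return produced
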