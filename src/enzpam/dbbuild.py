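"""Build the custom protein database consumed by the annotator.

Each harvested synonym is attached to up to ``max_seqs_per_synonym`` protein
sequences from the record source, and the whole set is written as a protein
FASTA whose headers follow the custom-database convention Prokka's
``--proteins`` option expects::

    >SDB_000001 1.13.11.1~~~catA~~~catechol 1,2-dioxygenase

i.e. ``<seq_id> <EC>~~~<gene>~~~<product>``, with empty fields allowed
between the ``~~~`` delimiters.  The annotator then copies EC, gene and
product verbatim into its output, which is what lets the matrix step map
annotations back to standard names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DbFormatError
from .harvest import RecordSource, SynonymRecord, normalize_name
from .spec_io import EnzymeSpec

__all__ = [
    "CustomDbEntry",
    "retrieve_sequences",
    "build_custom_db",
    "parse_custom_db",
    "write_pathway_dbs",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DELIM = "~~~"


@dataclass(frozen=True)
class CustomDbEntry:
    """One protein sequence destined for the custom database."""

    seq_id: str
    ec_text: str
    gene: str
    product: str
    enzyme_id: str
    sequence: str

    def __post_init__(self):
        if not self.seq_id or any(c.isspace() for c in self.seq_id):
            raise DbFormatError(f"seq_id {self.seq_id!r} must be non-empty and whitespace-free")
        if not self.product:
            raise DbFormatError(f"entry {self.seq_id}: product must be non-empty")
        for fname in ("ec_text", "gene", "product"):
            if DELIM in getattr(self, fname):
                raise DbFormatError(f"entry {self.seq_id}: {fname} contains {DELIM!r}")
        if not self.sequence:
            raise DbFormatError(f"entry {self.seq_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise DbFormatError(
                f"entry {self.seq_id}: invalid residues {sorted(bad)!r}"
            )


def retrieve_sequences(
    synonyms: Sequence[SynonymRecord],
    source: RecordSource,
    specs: Sequence[EnzymeSpec],
    max_seqs_per_synonym: int = 5,
) -> tuple[list[CustomDbEntry], list[SynonymRecord]]:
    """Attach sequences to synonyms by name lookup in ``source``.

    For each synonym, up to ``max_seqs_per_synonym`` sequences are taken in
    snapshot order.  Each entry carries the synonym's raw name as its
    product and the owning enzyme's first EC number (or empty) as
    ``ec_text``.  Returns ``(entries, misses)`` where ``misses`` lists
    synonyms with no hits — reported, never fatal.
    """
    ec_of = {
        s.enzyme_id: (s.ec_numbers[0].text if s.ec_numbers else "") for s in specs
    }
    entries: list[CustomDbEntry] = []
    misses: list[SynonymRecord] = []
    used_ids: dict[str, int] = {}
    for syn in synonyms:
        hits = source.lookup_sequences(syn.norm_name)[:max_seqs_per_synonym]
        if not hits:
            misses.append(syn)
            continue
        for acc, _name, seq in hits:
            # retrieved sequences keep their accession; suffix on reuse
            n = used_ids.get(acc, 0)
            used_ids[acc] = n + 1
            seq_id = acc if n == 0 else f"{acc}_{n}"
            entries.append(
                CustomDbEntry(
                    seq_id=seq_id,
                    ec_text=ec_of.get(syn.enzyme_id, ""),
                    gene="",
                    product=syn.raw_name,
                    enzyme_id=syn.enzyme_id,
                    sequence=seq,
                )
            )
    return entries, misses


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def build_custom_db(
    entries: Sequence[CustomDbEntry],
    out_path: str | Path,
    specs: Sequence[EnzymeSpec] | None = None,
) -> dict:
    """Write ``entries`` as a custom-database protein FASTA.

    Headers follow the ``<seq_id> <EC>~~~<gene>~~~<product>`` convention;
    sequences are wrapped at 60 columns.  Returns a manifest dict with
    per-enzyme and per-pathway sequence counts (pathway counts require
    ``specs``).  Duplicate seq_ids are an error.
    """
    ids = [e.seq_id for e in entries]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise DbFormatError(f"duplicate seq_ids: {dupes}")

    out_path = Path(out_path)
    with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
        for e in entries:
            fh.write(f">{e.seq_id} {e.ec_text}{DELIM}{e.gene}{DELIM}{e.product}\n")
            fh.write(_wrap(e.sequence) + "\n")

    per_enzyme: dict[str, int] = {}
    for e in entries:
        per_enzyme[e.enzyme_id] = per_enzyme.get(e.enzyme_id, 0) + 1
    per_pathway: dict[str, int] = {}
    if specs is not None:
        pathway_of = {s.enzyme_id: s.pathway for s in specs}
        for s in specs:
            per_pathway.setdefault(s.pathway, 0)
        for e in entries:
            pw = pathway_of.get(e.enzyme_id)
            if pw is not None:
                per_pathway[pw] += 1
    return {
        "path": str(out_path),
        "n_entries": len(entries),
        "per_enzyme": per_enzyme,
        "per_pathway": per_pathway,
    }


def write_pathway_dbs(
    entries: Sequence[CustomDbEntry],
    specs: Sequence[EnzymeSpec],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one FASTA per pathway plus the merged database the annotator uses."""
    from .spec_io import slugify

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pathway_of = {s.enzyme_id: s.pathway for s in specs}
    pathways: dict[str, list[CustomDbEntry]] = {}
    for s in specs:
        pathways.setdefault(s.pathway, [])
    for e in entries:
        pw = pathway_of.get(e.enzyme_id)
        if pw is not None:
            pathways[pw].append(e)
    paths: dict[str, Path] = {}
    for pw, ents in pathways.items():
        p = out_dir / f"custom_db.{slugify(pw)}.faa"
        build_custom_db(ents, p, specs)
        paths[pw] = p
    merged = out_dir / "custom_db.faa"
    build_custom_db(entries, merged, specs)
    paths["__merged__"] = merged
    return paths


def parse_custom_db(
    path: str | Path,
    synonyms: Sequence[SynonymRecord] | None = None,
) -> list[CustomDbEntry]:
    """Read a custom-database FASTA back into entries (inverse of build).

    ``enzyme_id`` is recovered through a product-to-synonym lookup when
    ``synonyms`` is supplied, else left empty.  A description without
    exactly two ``~~~`` delimiters is a format error.
    """
    from Bio import SeqIO

    owner: dict[str, str] = {}
    if synonyms is not None:
        for s in synonyms:
            owner.setdefault(s.norm_name, s.enzyme_id)

    entries: list[CustomDbEntry] = []
    path = Path(path)
    # track header line numbers for error reporting
    header_lines: dict[int, int] = {}
    with open(path, encoding="utf-8") as fh:
        idx = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines[idx] = lineno
                idx += 1
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        desc = rec.description
        rest = desc.split(None, 1)[1] if " " in desc else ""
        parts = rest.split(DELIM)
        if len(parts) != 3:
            raise DbFormatError(
                f"{path}:{header_lines.get(i, '?')}: header needs exactly two "
                f"{DELIM!r} delimiters, got {len(parts) - 1}"
            )
        ec_text, gene, product = parts
        entries.append(
            CustomDbEntry(
                seq_id=rec.id,
                ec_text=ec_text,
                gene=gene,
                product=product,
                enzyme_id=owner.get(normalize_name(product), ""),
                sequence=str(rec.seq),
            )
        )
    return entries


def write_db_manifest(manifest: dict, specs: Sequence[EnzymeSpec], path: str | Path) -> None:
    """Write the manifest TSV (enzyme_id, pathway, n_sequences)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["enzyme_id", "pathway", "n_sequences"])
        for s in specs:
            w.writerow([s.enzyme_id, s.pathway, manifest["per_enzyme"].get(s.enzyme_id, 0)])


def write_miss_report(misses: Sequence[SynonymRecord], path: str | Path) -> None:
    """Write the synonyms that found no sequence (one line each)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["enzyme_id", "norm_name", "source", "retrieved_via"])
        for m in misses:
            w.writerow([m.enzyme_id, m.norm_name, m.source, m.retrieved_via])
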