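"""Orchestrate the workflow as resumable, file-to-file steps.

Every step reads and writes only documented plain-text interchange files in
the work directory, so the user can inspect or hand-edit any intermediate
(the curation loop depends on exactly this) and re-run from that point.
There is no hidden state; a run manifest records the config hash and a
checksum of every file each step consumed and produced.

Step graph::

    harvest   spec table + record source      -> synonyms.tsv
    dbbuild   synonyms.tsv + record source    -> custom_db.faa (+ per-pathway,
                                                 manifest, miss report)
    annotate  genome FASTAs + custom_db.faa   -> annotations/<genome>/ (external
                                                 annotator; optional)
    reference spec table + synonyms.tsv       -> reference.tsv
    match     annotations + reference.tsv     -> matches.tsv
    matrix    matches.tsv + spec table        -> matrix.tsv + matrix_provenance.tsv
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .annotation import parse_prokka_gff, parse_prokka_tsv, run_external_annotator
from .crossref import (
    MatchResult,
    PresenceAbsenceMatrix,
    build_matrix,
    build_reference,
    match_annotations,
    read_reference,
    write_reference,
)
from .dbbuild import (
    build_custom_db,
    retrieve_sequences,
    write_db_manifest,
    write_miss_report,
    write_pathway_dbs,
)
from .errors import PipelineError
from .harvest import (
    harvest_synonyms,
    merge_manual_synonyms,
    open_source,
    read_synonyms,
    write_synonyms,
)
from .spec_io import parse_enzyme_spec

logger = logging.getLogger(__name__)

ALL_STEPS = ("harvest", "dbbuild", "annotate", "reference", "match", "matrix")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    workdir: str = "enzpam_run"
    spec_table: str = ""
    spec_dialect: str = "tsv"
    source_kind: str = "snapshot"  # snapshot | rest
    source_location: str = ""
    cache_dir: str = ""
    rate_limit: float = 3.0
    annotations_dir: str = ""  # per-genome annotator outputs (one subdir each)
    annotation_format: str = "auto"  # auto | tsv | gff
    genome_fastas: list[str] = field(default_factory=list)
    annotator_cmd: str = ""
    use_default_db: bool = False
    match_mode: str = "exact"  # exact | substring
    curation_path: str = ""
    manual_synonyms: str = ""
    max_seqs_per_synonym: int = 5
    seed: int = 0  # consumed only by the fixtures subcommand
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_MATCH_COLUMNS = (
    "genome_id",
    "locus_tag",
    "matched_norm_name",
    "enzyme_id",
    "match_mode",
    "excluded",
    "exclusion_reason",
    "ambiguous",
)


def write_matches(matches: Sequence[MatchResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MATCH_COLUMNS)
        for m in matches:
            w.writerow(
                [
                    m.genome_id,
                    m.locus_tag,
                    m.matched_norm_name,
                    m.enzyme_id,
                    m.match_mode,
                    int(m.excluded),
                    m.exclusion_reason,
                    int(m.ambiguous),
                ]
            )


def read_matches(path: str | Path) -> list[MatchResult]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                MatchResult(
                    genome_id=row["genome_id"],
                    locus_tag=row["locus_tag"],
                    matched_norm_name=row["matched_norm_name"],
                    enzyme_id=row["enzyme_id"],
                    match_mode=row["match_mode"],
                    excluded=bool(int(row["excluded"])),
                    exclusion_reason=row["exclusion_reason"],
                    ambiguous=bool(int(row["ambiguous"])),
                )
            )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, step: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"step {step!r} needs {path} which does not exist; "
            f"run the {produced_by!r} step first (or supply the file)"
        )
    return path


def load_annotations(
    annotations_dir: str | Path, annotation_format: str = "auto"
) -> tuple[list, list[str]]:
    """Read per-genome annotator outputs.

    Each subdirectory of ``annotations_dir`` is one genome; the genome id is
    the directory name.  ``auto`` prefers the feature table and falls back
    to the GFF3.
    """
    annotations_dir = Path(annotations_dir)
    if not annotations_dir.is_dir():
        raise PipelineError(f"annotations directory not found: {annotations_dir}")
    records = []
    genome_ids = []
    for gdir in sorted(p for p in annotations_dir.iterdir() if p.is_dir()):
        gid = gdir.name
        tsvs = sorted(gdir.glob("*.tsv"))
        gffs = sorted(gdir.glob("*.gff"))
        if annotation_format in ("auto", "tsv") and tsvs:
            records.extend(parse_prokka_tsv(tsvs[0], gid))
        elif annotation_format in ("auto", "gff") and gffs:
            records.extend(parse_prokka_gff(gffs[0], gid))
        else:
            raise PipelineError(f"no usable annotation file for genome {gid} in {gdir}")
        genome_ids.append(gid)
    if not genome_ids:
        raise PipelineError(f"no genome subdirectories in {annotations_dir}")
    return records, genome_ids


def run_pipeline(
    config: PipelineConfig, steps: Sequence[str] | None = None
) -> dict[str, list[str]]:
    """Run the requested steps in graph order; returns artifact paths per step.

    With ``steps=None`` every step except ``annotate`` runs (``annotate``
    requires an annotator command and genome FASTAs and is opt-in).
    """
    if steps is None:
        steps = [s for s in ALL_STEPS if s != "annotate"]
    unknown = set(steps) - set(ALL_STEPS)
    if unknown:
        raise PipelineError(f"unknown steps: {sorted(unknown)}")
    steps = [s for s in ALL_STEPS if s in steps]  # graph order

    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "synonyms": workdir / "synonyms.tsv",
        "custom_db": workdir / "custom_db.faa",
        "db_manifest": workdir / "db_manifest.tsv",
        "db_misses": workdir / "db_misses.tsv",
        "reference": workdir / "reference.tsv",
        "matches": workdir / "matches.tsv",
        "matrix": workdir / "matrix.tsv",
        "provenance": workdir / "matrix_provenance.tsv",
    }
    annotations_dir = Path(config.annotations_dir or (workdir / "annotations"))

    manifest: dict = {
        "tool": "enzpam",
        "version": __version__,
        "config_hash": config.config_hash(),
        "steps": {},
    }
    artifacts: dict[str, list[str]] = {}

    def record_step(step: str, inputs: list[Path], outputs: list[Path]):
        manifest["steps"][step] = {
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
        }
        artifacts[step] = [str(p) for p in outputs]

    def make_source():
        return open_source(
            config.source_kind,
            config.source_location,
            cache_dir=config.cache_dir or None,
            rate_limit=config.rate_limit,
        )

    for step in steps:
        logger.info("running step %s", step)
        if step == "harvest":
            spec_path = _require(Path(config.spec_table), step, "user input")
            specs = parse_enzyme_spec(spec_path, dialect=config.spec_dialect)
            source = make_source()
            records = []
            for s in specs:
                records.extend(harvest_synonyms(s, source))
            inputs = [spec_path]
            if config.manual_synonyms:
                manual = _require(Path(config.manual_synonyms), step, "user input")
                records = merge_manual_synonyms(records, manual, specs)
                inputs.append(manual)
            write_synonyms(records, specs, paths["synonyms"])
            record_step(step, inputs, [paths["synonyms"]])

        elif step == "dbbuild":
            spec_path = _require(Path(config.spec_table), step, "user input")
            syn_path = _require(paths["synonyms"], step, "harvest")
            specs = parse_enzyme_spec(spec_path, dialect=config.spec_dialect)
            synonyms = read_synonyms(syn_path)
            entries, misses = retrieve_sequences(
                synonyms, make_source(), specs, config.max_seqs_per_synonym
            )
            db_manifest = build_custom_db(entries, paths["custom_db"], specs)
            pathway_paths = write_pathway_dbs(entries, specs, workdir)
            write_db_manifest(db_manifest, specs, paths["db_manifest"])
            write_miss_report(misses, paths["db_misses"])
            record_step(
                step,
                [spec_path, syn_path],
                [paths["custom_db"], paths["db_manifest"], paths["db_misses"]]
                + [p for k, p in sorted(pathway_paths.items()) if k != "__merged__"],
            )

        elif step == "annotate":
            db_path = _require(paths["custom_db"], step, "dbbuild")
            if not config.annotator_cmd:
                raise PipelineError("step 'annotate' requires annotator_cmd in the config")
            if not config.genome_fastas:
                raise PipelineError("step 'annotate' requires genome_fastas in the config")
            outputs = []
            for fasta in config.genome_fastas:
                fasta_path = _require(Path(fasta), step, "user input")
                gid = fasta_path.stem
                produced = run_external_annotator(
                    fasta_path,
                    db_path,
                    annotations_dir / gid,
                    config.annotator_cmd,
                    use_default_db=config.use_default_db,
                )
                outputs.extend(produced.values())
            record_step(step, [db_path], outputs)

        elif step == "reference":
            spec_path = _require(Path(config.spec_table), step, "user input")
            syn_path = _require(paths["synonyms"], step, "harvest")
            specs = parse_enzyme_spec(spec_path, dialect=config.spec_dialect)
            synonyms = read_synonyms(syn_path)
            entries, collisions = build_reference(specs, synonyms)
            write_reference(entries, paths["reference"], collisions)
            record_step(step, [spec_path, syn_path], [paths["reference"]])

        elif step == "match":
            ref_path = _require(paths["reference"], step, "reference")
            records, _genomes = load_annotations(annotations_dir, config.annotation_format)
            reference = read_reference(ref_path)
            curation = config.curation_path or None
            if curation:
                _require(Path(curation), step, "user input")
            matches = match_annotations(
                records, reference, mode=config.match_mode, curation_path=curation
            )
            write_matches(matches, paths["matches"])
            inputs = [ref_path] + ([Path(curation)] if curation else [])
            record_step(step, inputs, [paths["matches"]])

        elif step == "matrix":
            spec_path = _require(Path(config.spec_table), step, "user input")
            match_path = _require(paths["matches"], step, "match")
            specs = parse_enzyme_spec(spec_path, dialect=config.spec_dialect)
            _records, genome_ids = load_annotations(annotations_dir, config.annotation_format)
            matches = read_matches(match_path)
            matrix = build_matrix(matches, specs, genome_ids)
            matrix.write(paths["matrix"], paths["provenance"])
            record_step(step, [spec_path, match_path], [paths["matrix"], paths["provenance"]])

    manifest_path = workdir / "run_manifest.json"
    existing = {}
    if manifest_path.exists():
        try:
            existing = json.loads(manifest_path.read_text(encoding="utf-8"))
        except json.JSONDecodeError:
            existing = {}
    if existing.get("config_hash") == manifest["config_hash"]:
        merged = dict(existing.get("steps", {}))
        merged.update(manifest["steps"])
        manifest["steps"] = merged
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return artifacts
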