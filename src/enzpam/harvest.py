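"""Resolve each enzyme to a set of protein-name synonyms.

Annotation repositories call the same enzyme by many names; the matrix step
can only standardize what it can recognize, so this module compiles, for
every enzyme in the user spec, every alternative product name reachable
through its KO and EC identifiers.  Lookups go through a pluggable
:class:`RecordSource`: either an offline *snapshot* directory of
KEGG-flat-file-like stanzas (the only kind tests use) or a cache-first REST
endpoint.  User-supplied synonyms are merged in afterwards.

A synonym is stored both as retrieved (``raw_name``) and in a normalized
form (``norm_name``) used for all downstream equality and substring
matching.
"""

from __future__ import annotations

import logging
import re
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import SourceError, SpecParseError
from .spec_io import ECNumber, EnzymeSpec, make_enzyme_id, validate_ec

__all__ = [
    "SynonymRecord",
    "RecordSource",
    "SnapshotSource",
    "RestSource",
    "open_source",
    "normalize_name",
    "harvest_synonyms",
    "merge_manual_synonyms",
    "find_collisions",
    "write_synonyms",
    "read_synonyms",
]

logger = logging.getLogger(__name__)

# "(EC 1.13.11.1)" / "(ec:1.14.12.-)" decorations embedded in product names
_EC_DECOR_RE = re.compile(r"\(\s*ec[:\s]*\d+(?:\.(?:\d+|-)){3}\s*\)", re.IGNORECASE)
_TRAILING_BRACKET_RE = re.compile(r"\s*[\[(][^\[\]()]*[\])]\s*$")
_WS_RE = re.compile(r"\s+")


def normalize_name(text: str) -> str:
    """Fold a protein name to its canonical matching form.

    Case-folds, collapses whitespace runs, strips ``(EC x.x.x.x)``
    decorations and trailing bracketed qualifiers; interior punctuation
    (commas, hyphens, slashes) is preserved.  Idempotent by construction:
    trailing brackets are stripped to a fixpoint.
    """
    s = _EC_DECOR_RE.sub(" ", text)
    s = s.casefold()
    s = _WS_RE.sub(" ", s).strip()
    while True:
        m = _TRAILING_BRACKET_RE.search(s)
        if m is None:
            break
        s = s[: m.start()].rstrip()
    return s


@dataclass(frozen=True)
class SynonymRecord:
    """One alternative name for one enzyme, with provenance."""

    enzyme_id: str
    raw_name: str
    norm_name: str
    source: str  # kegg_snapshot | kegg_rest | manual
    retrieved_via: str  # ec | ko | manual

    def __post_init__(self):
        if self.norm_name != normalize_name(self.raw_name):
            raise ValueError("norm_name must equal normalize_name(raw_name)")
        if not self.norm_name:
            raise ValueError(f"synonym {self.raw_name!r} normalizes to the empty string")


@dataclass
class Stanza:
    """One flat-file record: an identifier, its names, its EC numbers."""

    entry: str
    names: list[str]
    ecs: list[ECNumber]


def parse_flat_records(text: str) -> list[Stanza]:
    """Parse KEGG-flat-file-like stanzas.

    Grammar: an upper-case keyword in column 0 followed by its value;
    indented lines continue the previous keyword; ``///`` terminates a
    record.  ``NAME`` values are ``;``-separated; ``EC`` values are
    whitespace-separated.
    """
    stanzas: list[Stanza] = []
    entry = None
    fields: dict[str, list[str]] = {}
    keyword = None

    def flush():
        nonlocal entry, fields
        if entry is not None:
            names = [
                n.strip()
                for chunk in fields.get("NAME", [])
                for n in chunk.split(";")
                if n.strip()
            ]
            ecs = [
                validate_ec(tok)
                for chunk in fields.get("EC", [])
                for tok in chunk.split()
            ]
            stanzas.append(Stanza(entry=entry, names=names, ecs=ecs))
        entry, fields = None, {}

    for line in text.splitlines():
        if line.startswith("///"):
            flush()
            keyword = None
            continue
        if not line.strip():
            continue
        m = re.match(r"^([A-Z][A-Z_]*)\s+(.*)$", line)
        if m:
            keyword, value = m.group(1), m.group(2).strip()
            if keyword == "ENTRY":
                if entry is not None:
                    flush()
                entry = value.split()[0]
            else:
                fields.setdefault(keyword, []).append(value)
        elif keyword and line[:1].isspace():
            fields.setdefault(keyword, []).append(line.strip())
    flush()
    return stanzas


class RecordSource:
    """Interface for synonym/sequence lookups keyed by KO id, EC or name."""

    kind: str

    def lookup_ko(self, ko: str) -> Stanza | None:
        raise NotImplementedError

    def lookup_ec(self, ec: ECNumber) -> list[Stanza]:
        raise NotImplementedError

    def lookup_sequences(self, norm_name: str) -> list[tuple[str, str, str]]:
        """Return (accession, description, sequence) triples whose described
        protein name normalizes to ``norm_name``, in source order."""
        raise NotImplementedError


class SnapshotSource(RecordSource):
    """Offline source: a directory of flat-file stanzas plus a protein FASTA.

    Layout::

        snapshot/
          K03381.txt       one stanza per KO identifier
          1.13.11.1.txt    one stanza per EC number (optional; EC lookups
                           also match KO stanzas via their EC lines)
          proteins.fasta   ">ACC protein name" records for sequence lookup

    Every lookup resolves offline; files are read once, in sorted-filename
    order, so results are deterministic.
    """

    kind = "snapshot"

    def __init__(self, location: str | Path):
        self.location = Path(location)
        if not self.location.is_dir():
            raise SourceError(f"snapshot directory not found: {self.location}")
        self._stanzas: list[Stanza] = []
        self._by_entry: dict[str, Stanza] = {}
        for path in sorted(self.location.glob("*.txt")):
            for st in parse_flat_records(path.read_text(encoding="utf-8")):
                self._stanzas.append(st)
                self._by_entry.setdefault(st.entry, st)
        self._proteins: list[tuple[str, str, str]] = []
        fasta = self.location / "proteins.fasta"
        if fasta.exists():
            from Bio import SeqIO

            for rec in SeqIO.parse(str(fasta), "fasta"):
                desc = rec.description
                name = desc.split(None, 1)[1] if " " in desc else ""
                self._proteins.append((rec.id, name, str(rec.seq)))

    def lookup_ko(self, ko: str) -> Stanza | None:
        return self._by_entry.get(ko)

    def lookup_ec(self, ec: ECNumber) -> list[Stanza]:
        hits = []
        for st in self._stanzas:
            if any(ec.matches(other) for other in st.ecs):
                hits.append(st)
        return hits

    def lookup_sequences(self, norm_name: str) -> list[tuple[str, str, str]]:
        return [
            (acc, name, seq)
            for acc, name, seq in self._proteins
            if normalize_name(name) == norm_name
        ]


class RestSource(RecordSource):
    """Cache-first REST source modelled on the KEGG REST API.

    Every response is written to ``cache_dir`` before use, so a second run
    against the same cache is fully offline (the cache directory is itself a
    valid :class:`SnapshotSource` layout).  Requests are rate-limited and
    retried.  Tests never exercise the network path; they use snapshots.
    """

    kind = "rest"

    def __init__(
        self,
        base_url: str,
        cache_dir: str | Path,
        rate_limit: float = 3.0,
        retries: int = 3,
    ):
        self.base_url = base_url.rstrip("/")
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.rate_limit = rate_limit
        self.retries = retries
        self._last_request = 0.0

    def _fetch(self, endpoint: str, cache_name: str) -> str | None:
        cache_path = self.cache_dir / cache_name
        if cache_path.exists():
            return cache_path.read_text(encoding="utf-8")
        url = f"{self.base_url}/{endpoint}"
        last_err: Exception | None = None
        for _ in range(self.retries):
            wait = 1.0 / self.rate_limit - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(url, timeout=30) as resp:
                    body = resp.read().decode("utf-8")
                cache_path.write_text(body, encoding="utf-8")
                return body
            except Exception as exc:  # noqa: BLE001 - urllib raises many types
                last_err = exc
        raise SourceError(f"REST endpoint {url} failed after {self.retries} retries: {last_err}")

    def _snapshot(self) -> SnapshotSource:
        return SnapshotSource(self.cache_dir)

    def lookup_ko(self, ko: str) -> Stanza | None:
        self._fetch(f"get/{ko}", f"{ko}.txt")
        return self._snapshot().lookup_ko(ko)

    def lookup_ec(self, ec: ECNumber) -> list[Stanza]:
        if "-" not in ec.classes:
            self._fetch(f"get/{ec.text}", f"{ec.text}.txt")
        return self._snapshot().lookup_ec(ec)

    def lookup_sequences(self, norm_name: str) -> list[tuple[str, str, str]]:
        quoted = urllib.parse.quote(norm_name, safe="")
        body = self._fetch(f"sequences/{quoted}", "proteins.fasta")
        return self._snapshot().lookup_sequences(norm_name)


def open_source(
    kind: str,
    location: str | Path,
    cache_dir: str | Path | None = None,
    rate_limit: float = 3.0,
) -> RecordSource:
    """Factory for :class:`RecordSource` instances."""
    if kind == "snapshot":
        return SnapshotSource(location)
    if kind == "rest":
        if cache_dir is None:
            raise SourceError("rest sources require a cache_dir")
        return RestSource(str(location), cache_dir, rate_limit=rate_limit)
    raise SourceError(f"unknown source kind {kind!r}")


def _source_tag(source: RecordSource) -> str:
    return "kegg_snapshot" if source.kind == "snapshot" else "kegg_rest"


def harvest_synonyms(
    spec: EnzymeSpec, source: RecordSource
) -> list[SynonymRecord]:
    """Collect every synonym of ``spec`` reachable through ``source``.

    KO identifiers are queried first, then non-wildcard ECs, then wildcard
    ECs (which match any stanza agreeing on all non-wildcard components).
    The standard name itself is always included.  The result is
    deduplicated on ``(enzyme_id, norm_name)``, first retrieval wins, and
    ordering is deterministic for snapshot sources.
    """
    out: list[SynonymRecord] = []
    seen: set[str] = set()

    def add(raw: str, src: str, via: str):
        norm = normalize_name(raw)
        if not norm or norm in seen:
            return
        seen.add(norm)
        out.append(
            SynonymRecord(
                enzyme_id=spec.enzyme_id,
                raw_name=raw,
                norm_name=norm,
                source=src,
                retrieved_via=via,
            )
        )

    add(spec.standard_name, "manual", "manual")

    tag = _source_tag(source)
    for ko in spec.ko_ids:
        stanza = source.lookup_ko(ko)
        if stanza is None:
            logger.warning("enzyme %s: KO %s not found in source", spec.enzyme_id, ko)
            continue
        for name in stanza.names:
            add(name, tag, "ko")
    # concrete ECs before wildcard ones so the more specific retrieval wins
    for ec in sorted(spec.ec_numbers, key=lambda e: -e.n_specified):
        stanzas = source.lookup_ec(ec)
        if not stanzas:
            logger.warning("enzyme %s: EC %s not found in source", spec.enzyme_id, ec.text)
            continue
        for stanza in stanzas:
            for name in stanza.names:
                add(name, tag, "ec")
    return out


def merge_manual_synonyms(
    auto: Sequence[SynonymRecord],
    manual_path: str | Path,
    specs: Sequence[EnzymeSpec] | None = None,
) -> list[SynonymRecord]:
    """Union user-supplied synonyms into the harvested set.

    ``manual_path`` is a TSV with either an ``enzyme_id`` column or the pair
    ``standard_name`` + ``pathway`` (from which the id is derived), plus a
    ``synonym`` column.  On collision with an automatic record the manual
    record's source tag wins.  Rows naming an unknown enzyme are an error.
    """
    import csv

    known_ids = {r.enzyme_id for r in auto}
    if specs is not None:
        known_ids |= {s.enzyme_id for s in specs}

    merged: dict[tuple[str, str], SynonymRecord] = {
        (r.enzyme_id, r.norm_name): r for r in auto
    }
    order: list[tuple[str, str]] = [(r.enzyme_id, r.norm_name) for r in auto]

    with open(manual_path, encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        return list(auto)
    header = [h.strip().casefold() for h in rows[0]]
    if "synonym" not in header:
        raise SpecParseError(f"{manual_path}: missing required column 'synonym'")
    syn_col = header.index("synonym")
    id_col = header.index("enzyme_id") if "enzyme_id" in header else None
    if id_col is None and not ("standard_name" in header and "pathway" in header):
        raise SpecParseError(
            f"{manual_path}: need either an 'enzyme_id' column or 'standard_name' + 'pathway'"
        )

    for lineno, row in enumerate(rows[1:], start=2):
        if id_col is not None:
            enzyme_id = row[id_col].strip()
        else:
            enzyme_id = make_enzyme_id(
                row[header.index("pathway")].strip(),
                row[header.index("standard_name")].strip(),
            )
        if enzyme_id not in known_ids:
            raise SpecParseError(
                f"{manual_path}:{lineno}: unknown enzyme {enzyme_id!r}"
            )
        raw = row[syn_col].strip()
        norm = normalize_name(raw)
        if not norm:
            raise SpecParseError(f"{manual_path}:{lineno}: synonym normalizes to empty")
        key = (enzyme_id, norm)
        rec = SynonymRecord(
            enzyme_id=enzyme_id,
            raw_name=raw,
            norm_name=norm,
            source="manual",
            retrieved_via="manual",
        )
        if key not in merged:
            order.append(key)
        merged[key] = rec
    return [merged[k] for k in order]


def find_collisions(records: Iterable[SynonymRecord]) -> dict[str, list[str]]:
    """Map each norm_name claimed by more than one enzyme to its claimants.

    Ambiguous synonyms are kept for every claiming enzyme (curation is the
    user's resolution path); this report makes the ambiguity visible.
    """
    owners: dict[str, set[str]] = {}
    for r in records:
        owners.setdefault(r.norm_name, set()).add(r.enzyme_id)
    return {n: sorted(ids) for n, ids in sorted(owners.items()) if len(ids) > 1}


_SYN_COLUMNS = ("enzyme_id", "pathway", "standard_name", "raw_name", "norm_name", "source", "retrieved_via")


def write_synonyms(
    records: Sequence[SynonymRecord],
    specs: Sequence[EnzymeSpec],
    path: str | Path,
) -> None:
    """Write the synonyms table (the Step-1 interchange file)."""
    import csv

    by_id = {s.enzyme_id: s for s in specs}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SYN_COLUMNS)
        for r in records:
            spec = by_id[r.enzyme_id]
            w.writerow(
                [r.enzyme_id, spec.pathway, spec.standard_name, r.raw_name, r.norm_name, r.source, r.retrieved_via]
            )


def read_synonyms(path: str | Path) -> list[SynonymRecord]:
    """Inverse of :func:`write_synonyms` (pathway/standard_name are display columns)."""
    import csv

    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                SynonymRecord(
                    enzyme_id=row["enzyme_id"],
                    raw_name=row["raw_name"],
                    norm_name=row["norm_name"],
                    source=row["source"],
                    retrieved_via=row["retrieved_via"],
                )
            )
    return out
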