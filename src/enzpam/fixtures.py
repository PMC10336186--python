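"""Seeded synthetic test bundles with planted ground truth.

Real runs of the workflow depend on a live KEGG/NCBI mirror and an
installed annotator, so correctness is instead demonstrated on fully
synthetic bundles: an enzyme spec table, a snapshot synonym/sequence bank,
per-genome annotator-style outputs (TSV + GFF3) and the presence-absence
matrix that *should* come out.  The emulated situation is a handful of
draft prokaryotic genomes screened for a few degradation pathways.

Synonym strings come from a compositional grammar (an invented substrate
word crossed with a real enzyme-class vocabulary); decoy products draw on a
disjoint vocabulary, so the guarantee that no decoy contains a synonym is
structural, not probabilistic — and it is re-checked by brute force before
a bundle is emitted.  Planted products can be jittered (case, whitespace,
``(EC …)`` decoration, ``putative``-wrapping) and every transform is
recorded in a jitter log, which makes the expected behaviour of exact and
substring matching on a noisy bundle exactly computable rather than
statistical.

Only annotator *output* is simulated.  Gene calling and similarity search
happen inside the external annotator, upstream of everything this package
computes, so genome sequences are never generated.
"""

from __future__ import annotations

import random
import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .crossref import PresenceAbsenceMatrix
from .errors import FixtureError
from .harvest import normalize_name
from .spec_io import ECNumber, EnzymeSpec, make_enzyme_id

__all__ = [
    "NoiseOpts",
    "FixtureConfig",
    "FixtureBundle",
    "generate_fixture",
    "generate_random_protein",
    "NORMALIZATION_SAFE_TRANSFORMS",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# transforms normalize_name undoes, hence invisible to exact matching
NORMALIZATION_SAFE_TRANSFORMS = frozenset({"case", "whitespace", "ec_decoration"})

_SUB_PRE = ["benz", "cat", "tol", "phen", "napht", "xyl", "cres", "guai", "van", "ferul", "quin", "styr"]
_SUB_MID = ["ora", "eni", "ylo", "ade", "uco", "imo", "ara", "ozi"]
_SUB_SUF = ["ate", "ol", "ine", "one", "ene"]

_ENZYME_CLASSES = [
    "1,2-dioxygenase",
    "2,3-dioxygenase",
    "monooxygenase",
    "hydroxylase",
    "dehydrogenase",
    "reductase",
    "oxidase",
    "isomerase",
    "decarboxylase",
    "hydrolase",
    "carboxylase",
    "epimerase",
]

# decoy vocabulary shares no token with substrates or enzyme classes
_DECOY_HEADS = [
    "ribosomal protein",
    "dna polymerase subunit",
    "abc transporter permease",
    "cell division protein",
    "molecular chaperone",
    "elongation factor",
    "membrane channel protein",
    "rna helicase",
    "sigma factor",
    "peptidoglycan ligase",
    "flagellar motor protein",
    "two-component sensor",
]
_DECOY_TAILS = ["alpha", "beta", "gamma", "delta", "ii", "iv", "vi", "family member", "type a", "type b"]


@dataclass(frozen=True)
class NoiseOpts:
    """Which product-name jitters the generator may apply to planted CDS."""

    case: bool = False
    whitespace: bool = False
    ec_decoration: bool = False
    putative: bool = False

    @classmethod
    def all_on(cls) -> "NoiseOpts":
        return cls(case=True, whitespace=True, ec_decoration=True, putative=True)

    def enabled(self) -> list[str]:
        return [n for n in ("case", "whitespace", "ec_decoration", "putative") if getattr(self, n)]


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and noise level of a synthetic bundle.

    Defaults mirror the showcased application scale — a handful of
    metagenome-assembled genomes screened for a few degradation pathways —
    at 3 pathways x 5 enzymes x 4 synonyms over 6 genomes with a 0.5
    plant probability and 20 decoy CDS per genome.
    """

    n_pathways: int = 3
    enzymes_per_pathway: int = 5
    synonyms_per_enzyme: int = 4
    n_genomes: int = 6
    presence_prob: float = 0.5
    n_decoys_per_genome: int = 20
    noise_opts: NoiseOpts = field(default_factory=NoiseOpts)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pathways, self.enzymes_per_pathway, self.n_genomes) < 1:
            raise FixtureError("n_pathways, enzymes_per_pathway and n_genomes must be >= 1")
        if self.synonyms_per_enzyme < 1:
            raise FixtureError("synonyms_per_enzyme must be >= 1 (the standard name itself)")
        if self.synonyms_per_enzyme > len(_ENZYME_CLASSES):
            raise FixtureError(
                f"synonyms_per_enzyme capped at {len(_ENZYME_CLASSES)} by the class vocabulary"
            )
        if self.n_decoys_per_genome < 0:
            raise FixtureError("n_decoys_per_genome must be >= 0")
        if not (0.0 <= self.presence_prob <= 1.0):
            raise FixtureError("presence_prob must lie in [0, 1]")
        n_enzymes = self.n_pathways * self.enzymes_per_pathway
        if n_enzymes > len(_SUB_PRE) * len(_SUB_MID) * len(_SUB_SUF):
            raise FixtureError("substrate vocabulary exhausted; reduce enzyme count")


@dataclass
class PlantedCDS:
    """Jitter-log row: one planted CDS and the transforms applied to it."""

    genome_id: str
    locus_tag: str
    enzyme_id: str
    synonym_norm: str
    product: str
    transforms: tuple[str, ...]


@dataclass
class FixtureBundle:
    """Paths and in-memory ground truth of one generated bundle."""

    root: Path
    spec_table: Path
    snapshot_dir: Path
    genomes_dir: Path
    truth_path: Path
    jitter_log_path: Path
    truth: PresenceAbsenceMatrix
    specs: list[EnzymeSpec]
    genome_ids: list[str]
    jitter_log: list[PlantedCDS]

    def expected_cells(self, mode: str) -> set[tuple[str, str]]:
        """Cells a given match mode should recover, computed from the jitter log.

        Exact matching sees through normalization-invariant transforms only;
        substring matching (word-bounded) additionally sees through
        ``putative``-wrapping.
        """
        safe = set(NORMALIZATION_SAFE_TRANSFORMS)
        if mode == "substring":
            safe.add("putative")
        elif mode != "exact":
            raise ValueError(f"unknown mode {mode!r}")
        cells = set()
        for cds in self.jitter_log:
            if set(cds.transforms) <= safe:
                cells.add((cds.enzyme_id, cds.genome_id))
        return cells


def generate_random_protein(length: int, rng: random.Random) -> str:
    """Uniform random amino-acid string over the 20-letter alphabet."""
    if length < 1:
        raise FixtureError(f"protein length must be >= 1, got {length}")
    return "".join(rng.choices(AA20, k=length))


def _substrate(idx: int) -> str:
    n_mid, n_suf = len(_SUB_MID), len(_SUB_SUF)
    pre = _SUB_PRE[idx // (n_mid * n_suf)]
    mid = _SUB_MID[(idx // n_suf) % n_mid]
    suf = _SUB_SUF[idx % n_suf]
    return pre + mid + suf


def _jitter(product: str, ec_text: str, opts: NoiseOpts, rng: random.Random) -> tuple[str, tuple[str, ...]]:
    applied = []
    if opts.case and rng.random() < 0.5:
        product = "".join(c.upper() if rng.random() < 0.4 else c for c in product)
        applied.append("case")
    if opts.whitespace and rng.random() < 0.5:
        product = "  " + product.replace(" ", "  ", 1) + " "
        applied.append("whitespace")
    if opts.ec_decoration and ec_text and rng.random() < 0.5:
        product = f"{product} (EC {ec_text})"
        applied.append("ec_decoration")
    if opts.putative and rng.random() < 0.5:
        product = f"putative {product}"
        applied.append("putative")
    return product, tuple(applied)


def _decoy_safety_scan(decoy_products: Sequence[str], synonym_norms: Sequence[str]) -> None:
    # brute force: no synonym may occur word-bounded inside any decoy product
    for syn in synonym_norms:
        pat = re.compile(r"(?<!\w)" + re.escape(syn) + r"(?!\w)")
        for d in decoy_products:
            if pat.search(normalize_name(d)):
                raise FixtureError(f"decoy product {d!r} contains synonym {syn!r}")


def _gff_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" ()'[]-_.~:/|")


def generate_fixture(config: FixtureConfig, root: str | Path) -> FixtureBundle:
    """Generate a complete bundle under ``root``.

    Identical ``config`` (including seed) produces a byte-identical bundle.
    """
    rng = random.Random(config.seed)
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    snapshot_dir = root / "snapshot"
    genomes_dir = root / "genomes"
    snapshot_dir.mkdir(exist_ok=True)
    genomes_dir.mkdir(exist_ok=True)

    # --- enzymes, synonyms, spec table -------------------------------------
    specs: list[EnzymeSpec] = []
    synonyms_of: dict[str, list[str]] = {}
    ec_of: dict[str, str] = {}
    ko_of: dict[str, str] = {}
    idx = 0
    for p in range(config.n_pathways):
        pathway = f"pathway-{p + 1:02d} degradation"
        for _e in range(config.enzymes_per_pathway):
            substrate = _substrate(idx)
            syns = [f"{substrate} {cls}" for cls in _ENZYME_CLASSES[: config.synonyms_per_enzyme]]
            standard_name = syns[0]
            ko = f"K{10001 + idx:05d}"
            ec = ECNumber(("1", str(1 + idx // 100), str(1 + (idx // 10) % 10), str(1 + idx % 10)))
            enzyme_id = make_enzyme_id(pathway, standard_name)
            specs.append(
                EnzymeSpec(
                    enzyme_id=enzyme_id,
                    standard_name=standard_name,
                    ec_numbers=(ec,),
                    ko_ids=(ko,),
                    pathway=pathway,
                )
            )
            synonyms_of[enzyme_id] = syns
            ec_of[enzyme_id] = ec.text
            ko_of[enzyme_id] = ko
            idx += 1

    spec_table = root / "enzymes.tsv"
    from .spec_io import write_enzyme_spec

    write_enzyme_spec(specs, spec_table)

    # --- snapshot bank: one KO stanza per enzyme + protein FASTA -----------
    for s in specs:
        stanza = (
            f"ENTRY       {ko_of[s.enzyme_id]}            KO\n"
            f"NAME        {'; '.join(synonyms_of[s.enzyme_id])}\n"
            f"EC          {ec_of[s.enzyme_id]}\n"
            "///\n"
        )
        (snapshot_dir / f"{ko_of[s.enzyme_id]}.txt").write_text(stanza, encoding="utf-8")
    acc = 0
    with open(snapshot_dir / "proteins.fasta", "w", encoding="utf-8", newline="\n") as fh:
        for s in specs:
            for syn in synonyms_of[s.enzyme_id]:
                acc += 1
                seq = generate_random_protein(rng.randint(120, 360), rng)
                fh.write(f">ACC{acc:05d} {syn}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    # --- plant the truth ----------------------------------------------------
    genome_ids = [f"genome{g + 1:02d}" for g in range(config.n_genomes)]
    truth_cells: dict[tuple[str, str], int] = {}
    jitter_log: list[PlantedCDS] = []
    provenance: dict[tuple[str, str], list[str]] = {}

    all_synonym_norms = [normalize_name(n) for syns in synonyms_of.values() for n in syns]

    for gid in genome_ids:
        rows: list[dict] = []
        for s in specs:
            present = rng.random() < config.presence_prob
            truth_cells[(s.enzyme_id, gid)] = int(present)
            if not present:
                continue
            syn = rng.choice(synonyms_of[s.enzyme_id])
            product, transforms = _jitter(syn, ec_of[s.enzyme_id], config.noise_opts, rng)
            rows.append(
                {
                    "ftype": "CDS",
                    "gene": "",
                    "ec": ec_of[s.enzyme_id],
                    "product": product,
                    "planted": (s.enzyme_id, normalize_name(syn), transforms),
                }
            )
        decoy_products = []
        for d in range(config.n_decoys_per_genome):
            head = rng.choice(_DECOY_HEADS)
            tail = rng.choice(_DECOY_TAILS)
            prod = f"{head} {tail} {d + 1}"
            decoy_products.append(prod)
            rows.append({"ftype": "CDS", "gene": "", "ec": "", "product": prod, "planted": None})
        _decoy_safety_scan(decoy_products, all_synonym_norms)
        rows.append({"ftype": "tRNA", "gene": "", "ec": "", "product": "tRNA-Ala(agc)", "planted": None})
        rng.shuffle(rows)

        gdir = genomes_dir / gid
        gdir.mkdir(exist_ok=True)
        tsv_lines = ["locus_tag\tftype\tlength_bp\tgene\tEC_number\tCOG\tproduct"]
        gff_lines = ["##gff-version 3", f"##sequence-region contig_1 1 {1500 * len(rows) + 1000}"]
        for k, row in enumerate(rows):
            locus = f"{gid.upper()}_{k + 1:05d}"
            start = 1 + k * 1500
            end = start + 999
            strand = "+" if rng.random() < 0.5 else "-"
            tsv_lines.append(
                f"{locus}\t{row['ftype']}\t1000\t{row['gene']}\t{row['ec']}\t\t{row['product']}"
            )
            attrs = [f"ID={locus}", f"locus_tag={locus}"]
            if row["gene"]:
                attrs.append(f"gene={_gff_escape(row['gene'])}")
            if row["ec"]:
                attrs.append(f"eC_number={row['ec']}")
            attrs.append(f"product={_gff_escape(row['product'])}")
            gff_lines.append(
                "\t".join(
                    [
                        "contig_1",
                        "fixture",
                        row["ftype"],
                        str(start),
                        str(end),
                        ".",
                        strand,
                        "0" if row["ftype"] == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
            )
            if row["planted"] is not None:
                enzyme_id, syn_norm, transforms = row["planted"]
                jitter_log.append(
                    PlantedCDS(
                        genome_id=gid,
                        locus_tag=locus,
                        enzyme_id=enzyme_id,
                        synonym_norm=syn_norm,
                        product=row["product"],
                        transforms=transforms,
                    )
                )
                provenance.setdefault((enzyme_id, gid), []).append(locus)
        # GFF3 FASTA trailer with a stub contig, to exercise parser tolerance
        contig = "".join(rng.choice("ACGT") for _ in range(120))
        gff_lines += ["##FASTA", ">contig_1", contig]
        (gdir / f"{gid}.tsv").write_text("\n".join(tsv_lines) + "\n", encoding="utf-8")
        (gdir / f"{gid}.gff").write_text("\n".join(gff_lines) + "\n", encoding="utf-8")

    truth = PresenceAbsenceMatrix(
        enzyme_ids=[s.enzyme_id for s in specs],
        genome_ids=genome_ids,
        cells=truth_cells,
        provenance=provenance,
        pathways={s.enzyme_id: s.pathway for s in specs},
        standard_names={s.enzyme_id: s.standard_name for s in specs},
    )
    truth_path = root / "truth_matrix.tsv"
    truth.write(truth_path, root / "truth_provenance.tsv")

    jitter_log_path = root / "jitter_log.tsv"
    with open(jitter_log_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("genome_id\tlocus_tag\tenzyme_id\tsynonym_norm\tproduct\ttransforms\n")
        for cds in jitter_log:
            fh.write(
                f"{cds.genome_id}\t{cds.locus_tag}\t{cds.enzyme_id}\t{cds.synonym_norm}"
                f"\t{cds.product}\t{';'.join(cds.transforms)}\n"
            )

    return FixtureBundle(
        root=root,
        spec_table=spec_table,
        snapshot_dir=snapshot_dir,
        genomes_dir=genomes_dir,
        truth_path=truth_path,
        jitter_log_path=jitter_log_path,
        truth=truth,
        specs=specs,
        genome_ids=genome_ids,
        jitter_log=jitter_log,
    )
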