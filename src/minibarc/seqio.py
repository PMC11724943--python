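"""Sequence and alignment I/O.

Containers for raw sequences (with gene features), multiple alignments and
read sets, plus readers/writers for FASTA, aligned FASTA, GenBank flat
files and FASTQ.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere; report writers
  convert to 1-based inclusive.
* Sequences are stored upper-case; ``U`` is normalised to ``T`` on input.
* Gene names are matched through a built-in alias table because annotation
  labels vary between records (``COI``/``cox1``, ``16S``/``rrnL`` ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import AlignmentShapeError, FormatError, GeneLookupError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes (plus gap) accepted in stored sequences.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)

#: IUPAC code -> set of canonical bases it stands for.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
    "-": frozenset(),
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware. ``revcomp(revcomp(x)) == x``."""
    _validate_seq(seq.upper())
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str, where: str = "") -> None:
    bad = set(seq) - ALPHABET
    if bad:
        loc = f" ({where})" if where else ""
        raise FormatError(
            f"invalid sequence character(s) {sorted(bad)}{loc}; "
            f"allowed: {''.join(sorted(ALPHABET))}"
        )


def normalize_seq(seq: str) -> str:
    """Upper-case, U->T, validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    _validate_seq(s)
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a parent sequence (0-based half-open)."""

    name: str
    start: int
    end: int
    strand: int = 1  # +1 or -1
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"feature {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in (1, -1):
            raise FormatError(f"feature {self.name!r}: strand must be +1/-1")


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional gene features."""

    id: str
    seq: str
    description: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        self.seq = normalize_seq(self.seq)
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        for f in self.features:
            if f.end > len(self.seq):
                raise FormatError(
                    f"record {self.id!r}: feature {f.name!r} end {f.end} "
                    f"exceeds sequence length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_percent(self) -> float:
        """G+C content in percent of total length (S counts as G/C)."""
        gc = sum(self.seq.count(b) for b in "GCS")
        return 100.0 * gc / len(self.seq)


@dataclass
class GeneAlignment:
    """A gene's multiple alignment: equal-length rows, one per species."""

    gene: str
    species_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.species_ids):
            raise AlignmentShapeError(
                f"{self.gene}: {len(self.species_ids)} ids but "
                f"{len(self.rows)} rows"
            )
        if len(self.rows) < 2:
            raise AlignmentShapeError(f"{self.gene}: need >= 2 sequences")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise AlignmentShapeError(f"{self.gene}: duplicate species ids")
        self.rows = [normalize_seq(r) for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            offender = next(
                sid for sid, r in zip(self.species_ids, self.rows)
                if len(r) != len(self.rows[0])
            )
            raise AlignmentShapeError(
                f"{self.gene}: ragged alignment (row {offender!r} has "
                f"length {dict(zip(self.species_ids, map(len, self.rows)))[offender]}, "
                f"expected {len(self.rows[0])})"
            )
        if lengths == {0}:
            raise AlignmentShapeError(f"{self.gene}: empty alignment")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def L_aln(self) -> int:
        return len(self.rows[0])

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    def row(self, species_id: str) -> str:
        try:
            return self.rows[self.species_ids.index(species_id)]
        except ValueError:
            raise GeneLookupError(
                f"{self.gene}: species {species_id!r} not in alignment "
                f"(have {self.species_ids})"
            ) from None


@dataclass
class ReadSet:
    """Sequencing reads: (id, seq, optional quality string)."""

    reads: list[tuple[str, str, Optional[str]]]
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, seq, qual in self.reads:
            if not rid:
                raise FormatError("read with empty id")
            if qual is not None and len(qual) != len(seq):
                raise FormatError(
                    f"read {rid!r}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# gene-name aliases
# ---------------------------------------------------------------------------

def _norm_name(name: str) -> str:
    return "".join(ch for ch in name.upper() if ch.isalnum())


_ALIAS_GROUPS: dict[str, tuple[str, ...]] = {
    "COX1": ("COX1", "COI", "CO1", "COXI",
             "CYTOCHROMECOXIDASESUBUNITI", "CYTOCHROMECOXIDASESUBUNIT1",
             "CYTOCHROMEOXIDASESUBUNIT1", "CYTOCHROMEOXIDASESUBUNITI"),
    "COX2": ("COX2", "COII", "CO2", "COXII",
             "CYTOCHROMECOXIDASESUBUNITII", "CYTOCHROMECOXIDASESUBUNIT2",
             "CYTOCHROMEOXIDASESUBUNIT2"),
    "COX3": ("COX3", "COIII", "CO3", "COXIII",
             "CYTOCHROMECOXIDASESUBUNITIII", "CYTOCHROMECOXIDASESUBUNIT3",
             "CYTOCHROMEOXIDASESUBUNIT3"),
    "ATP6": ("ATP6", "ATPASE6", "ATPSYNTHASEF0SUBUNIT6", "ATP SYNTHASE6",
             "ATPSYNTHASESUBUNIT6"),
    "ATP8": ("ATP8", "ATPASE8", "ATPSYNTHASEF0SUBUNIT8",
             "ATPSYNTHASESUBUNIT8"),
    "CYTB": ("CYTB", "COB", "CYTOCHROMEB", "CYB"),
    "ND1": ("ND1", "NAD1", "NADH1", "NADHDEHYDROGENASESUBUNIT1"),
    "ND2": ("ND2", "NAD2", "NADH2", "NADHDEHYDROGENASESUBUNIT2"),
    "ND3": ("ND3", "NAD3", "NADH3", "NADHDEHYDROGENASESUBUNIT3"),
    "ND4": ("ND4", "NAD4", "NADH4", "NADHDEHYDROGENASESUBUNIT4"),
    "ND4L": ("ND4L", "NAD4L", "NADH4L", "NADHDEHYDROGENASESUBUNIT4L"),
    "ND5": ("ND5", "NAD5", "NADH5", "NADHDEHYDROGENASESUBUNIT5"),
    "ND6": ("ND6", "NAD6", "NADH6", "NADHDEHYDROGENASESUBUNIT6"),
    "16S": ("16S", "16SRRNA", "RRNL", "LRRNA", "16SRIBOSOMALRNA",
            "LARGESUBUNITRIBOSOMALRNA", "LSURRNA"),
    "12S": ("12S", "12SRRNA", "RRNS", "SRRNA", "12SRIBOSOMALRNA",
            "SMALLSUBUNITRIBOSOMALRNA", "SSURRNA"),
}

GENE_ALIASES: dict[str, str] = {
    _norm_name(alias): canon
    for canon, aliases in _ALIAS_GROUPS.items()
    for alias in aliases
}


def canonical_gene_name(name: str) -> str:
    """Map a raw annotation label to its canonical gene name.

    Unknown labels are returned in normalised (alphanumeric, upper-case)
    form so exact matches still work for e.g. tRNAs.
    """
    key = _norm_name(name)
    return GENE_ALIASES.get(key, key)


# ---------------------------------------------------------------------------
# FASTA / aligned FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file.

    Sequences are upper-cased and validated; the header up to the first
    whitespace becomes the id, the remainder the description.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    desc = ""
    chunks: list[str] = []
    header_line = 0
    seen_ids: set[str] = set()

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        try:
            rec = SequenceRecord(id=header, seq=seq, description=desc)
        except FormatError as exc:
            raise FormatError(f"{path}:{header_line}: {exc}") from None
        if rec.id in seen_ids:
            raise FormatError(f"{path}:{header_line}: duplicate record id {rec.id!r}")
        seen_ids.add(rec.id)
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header = parts[0]
                desc = parts[1] if len(parts) == 2 else ""
                chunks = []
                header_line = lineno
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
        _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    """Write records as LF-terminated FASTA wrapped at `width` columns."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def load_alignment(path: str | Path, gene: Optional[str] = None) -> GeneAlignment:
    """Load an aligned FASTA file into a :class:`GeneAlignment`.

    The gene name defaults to the file stem (minus a trailing ``.aln``).
    """
    path = Path(path)
    records = read_fasta(path)
    if gene is None:
        gene = path.stem
        if gene.endswith(".aln"):
            gene = gene[: -len(".aln")]
    return GeneAlignment(
        gene=gene,
        species_ids=[r.id for r in records],
        rows=[r.seq for r in records],
    )


def write_alignment(aln: GeneAlignment, path: str | Path) -> None:
    write_fasta(
        [SequenceRecord(id=sid, seq=row)
         for sid, row in zip(aln.species_ids, aln.rows)],
        path,
    )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("gene", "CDS", "rRNA", "tRNA")


def read_genbank(path: str | Path) -> list[SequenceRecord]:
    """Read a GenBank flat file into records with populated gene features.

    gene/CDS/rRNA/tRNA features are kept; coordinates become 0-based
    half-open. Compound (joined) locations are skipped with a warning;
    records without an ORIGIN sequence are an error.
    """
    from Bio import SeqIO as BioSeqIO  # deferred: biopython import is slow

    path = Path(path)
    out: list[SequenceRecord] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # BiopythonParserWarning on odd LOCUS lines
            biorecords = list(BioSeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed GenBank record "
                          f"(missing ORIGIN block?): {exc}") from None
    if not biorecords:
        raise FormatError(f"{path}: no GenBank records found")
    for brec in biorecords:
        try:
            seq = str(brec.seq)
        except Exception:
            seq = ""
        if not seq:
            raise FormatError(
                f"{path}: record {brec.id!r} has no ORIGIN sequence"
            )
        feats: list[GeneFeature] = []
        for f in brec.features:
            if f.type not in _FEATURE_TYPES:
                continue
            if len(getattr(f.location, "parts", [f.location])) > 1:
                logger.warning(
                    "%s: skipping compound location for %s feature %s",
                    path, f.type, f.qualifiers.get("gene", ["?"])[0],
                )
                continue
            name = None
            for key in ("gene", "product", "locus_tag"):
                if key in f.qualifiers:
                    name = f.qualifiers[key][0]
                    break
            if name is None:
                continue
            strand = -1 if f.location.strand == -1 else 1
            feats.append(GeneFeature(
                name=name,
                start=int(f.location.start),
                end=int(f.location.end),
                strand=strand,
                kind=f.type,
            ))
        out.append(SequenceRecord(
            id=brec.id or brec.name,
            seq=seq,
            description=brec.description or "",
            features=feats,
        ))
    return out


def extract_gene(rec: SequenceRecord, name: str) -> str:
    """Return the sense-strand sequence of the named gene.

    Matching is case/space-insensitive through the alias table. When a
    label maps to several distinct spans (duplicated tRNAs), the call is
    ambiguous and raises with the candidate coordinates so the caller can
    disambiguate by position.
    """
    target = canonical_gene_name(name)
    spans: dict[tuple[int, int, int], GeneFeature] = {}
    for f in rec.features:
        if canonical_gene_name(f.name) == target:
            spans.setdefault((f.start, f.end, f.strand), f)
    if not spans:
        available = sorted({canonical_gene_name(f.name) for f in rec.features})
        raise GeneLookupError(
            f"record {rec.id!r}: no feature matching {name!r}; "
            f"available: {available}"
        )
    if len(spans) > 1:
        raise GeneLookupError(
            f"record {rec.id!r}: gene {name!r} is ambiguous; spans "
            f"{sorted((s, e) for s, e, _ in spans)} — disambiguate by coordinates"
        )
    feat = next(iter(spans.values()))
    sub = rec.seq[feat.start:feat.end]
    return revcomp(sub) if feat.strand == -1 else sub


# ---------------------------------------------------------------------------
# FASTQ / generic reads
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> ReadSet:
    """Read a 4-line-per-record FASTQ file (quality kept as a raw string)."""
    path = Path(path)
    reads: list[tuple[str, str, Optional[str]]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise FormatError(f"{path}: line {i + 1}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: line {i + 3}: expected '+' separator")
        rid = head[1:].split()[0]
        reads.append((rid, normalize_seq(seq), qual))
    return ReadSet(reads=reads, source=str(path))


def write_fastq(rs: ReadSet, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rid, seq, qual in rs.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


def read_reads(path: str | Path) -> ReadSet:
    """Load reads from FASTA or FASTQ, sniffing the format."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    recs = read_fasta(path)
    return ReadSet(reads=[(r.id, r.seq, None) for r in recs], source=str(path))
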