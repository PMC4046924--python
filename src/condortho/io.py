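"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats:

* BLAST tabular hits (``-outfmt 6``): 12 standard tab-separated columns,
  with an optional 13th column interpreted as the query sequence length
  (the ``qlen`` convention).
* FASTA, read only for sequence lengths (via Biopython).
* Abundance tables: TSV with a header row of sample ids and a first
  column of feature ids (RSEM-style estimated counts or TPM). Held in
  memory as a pandas DataFrame, features x samples.
* The homology-map interchange file: 5-column TSV
  (transcript_id, gene_id, method, evalue, bit_score).

Identifiers are compared as exact strings; FASTA headers are truncated at
the first whitespace. Missing cells are not permitted in abundance tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .exceptions import ParseError, ValidationError

__all__ = [
    "BlastHit",
    "HomologyEntry",
    "HomologyMap",
    "read_blast_tab",
    "write_blast_tab",
    "read_fasta_lengths",
    "read_abundance_table",
    "write_abundance_table",
]

#: accepted provenance labels for a homology-map entry
ASSIGNMENT_METHODS = ("rbb", "conditional")


@dataclass(frozen=True, slots=True)
class BlastHit:
    """One tabular alignment record.

    Coordinates are 1-based inclusive; ``send`` may be smaller than
    ``sstart`` on reverse-orientation alignments. ``query_length`` is the
    length of the full query sequence (not the alignment) and is optional:
    it comes from the 13th column when present, or from a FASTA length
    index supplied to :func:`read_blast_tab`.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bit_score: float
    query_length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"negative e-value {self.evalue!r} for query {self.query_id!r}"
            )
        if self.alignment_length < 1:
            raise ValidationError(
                f"alignment_length must be >= 1 (query {self.query_id!r})"
            )
        if self.qstart > self.qend:
            raise ValidationError(
                f"qstart > qend for query {self.query_id!r}"
            )


def read_blast_tab(
    path: str | Path,
    length_index: Mapping[str, int] | None = None,
) -> list[BlastHit]:
    """Read a BLAST ``-outfmt 6`` tabular file, in file order.

    Each data line must have 12 or 13 tab-separated columns; a 13th
    column is taken as the query length. When absent, ``length_index``
    (id -> length) fills ``query_length``; otherwise it stays ``None``.
    Lines that are empty or start with ``#`` are skipped.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 or 13 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                    query_length=int(fields[12]) if len(fields) == 13 else (
                        length_index.get(fields[0]) if length_index else None
                    ),
                )
            except ValidationError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits as 12-column outfmt-6 lines (13 columns when
    ``query_length`` is set)."""
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_id, h.subject_id, f"{h.percent_identity:g}",
                str(h.alignment_length), str(h.mismatches), str(h.gap_opens),
                str(h.qstart), str(h.qend), str(h.sstart), str(h.send),
                repr(h.evalue), f"{h.bit_score:g}",
            ]
            if h.query_length is not None:
                fields.append(str(h.query_length))
            fh.write("\t".join(fields) + "\n")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Map each FASTA record id (header truncated at first whitespace) to
    its sequence length, counting non-whitespace characters only.

    Raises :class:`ValidationError` on duplicate ids; warns and returns an
    empty map on an empty file.
    """
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rid = header.split()[0] if header.split() else header
            if rid in lengths:
                raise ValidationError(f"{path}: duplicate FASTA id {rid!r}")
            lengths[rid] = sum(len(tok) for tok in seq.split())
    if not lengths:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return lengths


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read a features x samples abundance table (TSV, header row of
    sample ids, first column of feature ids).

    Returns a DataFrame of non-negative floats. Ragged rows or missing
    cells raise :class:`ParseError`; negative values raise
    :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return validate_abundance(df, name=str(path))


def validate_abundance(df: pd.DataFrame, name: str = "abundance table") -> pd.DataFrame:
    """Check abundance-table invariants: unique ids, numeric cells, no
    missing values, no negatives. Returns the table cast to float."""
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{name}: duplicate feature ids {dup}")
    if not df.columns.is_unique:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{name}: duplicate sample ids {dup}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{name}: non-numeric abundance value: {exc}") from exc
    if df.isna().any().any():
        raise ParseError(f"{name}: missing cells are not permitted")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{name}: negative abundance values")
    return df


def write_abundance_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


@dataclass(frozen=True, slots=True)
class HomologyEntry:
    """The reference gene assigned to one transcript, with provenance."""

    gene_id: str
    method: str  # "rbb" or "conditional"
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.method not in ASSIGNMENT_METHODS:
            raise ValidationError(
                f"unknown assignment method {self.method!r}; "
                f"expected one of {ASSIGNMENT_METHODS}"
            )


@dataclass
class HomologyMap:
    """Many-to-one transcript -> reference-gene assignment.

    Each transcript appears at most once (enforced by the dict); several
    transcripts may share a gene (assembled variants of one locus).
    """

    entries: dict[str, HomologyEntry] = field(default_factory=dict)

    HEADER = ("transcript_id", "gene_id", "method", "evalue", "bit_score")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, transcript_id: str) -> HomologyEntry:
        return self.entries[transcript_id]

    def add(self, transcript_id: str, entry: HomologyEntry) -> None:
        if transcript_id in self.entries:
            raise ValidationError(
                f"transcript {transcript_id!r} already assigned"
            )
        self.entries[transcript_id] = entry

    def gene_map(self) -> dict[str, str]:
        """Plain transcript -> gene mapping."""
        return {t: e.gene_id for t, e in self.entries.items()}

    def method_counts(self) -> dict[str, int]:
        counts = {m: 0 for m in ASSIGNMENT_METHODS}
        for e in self.entries.values():
            counts[e.method] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, e.gene_id, e.method, e.evalue, e.bit_score)
            for t, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=list(self.HEADER))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.HEADER) + "\n")
            for t, e in sorted(self.entries.items()):
                fh.write(
                    f"{t}\t{e.gene_id}\t{e.method}\t{e.evalue!r}\t{e.bit_score!r}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "HomologyMap":
        hmap = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls.HEADER:
                raise ParseError(
                    f"{path}: expected header {list(cls.HEADER)}, got {header}"
                )
            for lineno, raw in enumerate(fh, start=2):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 5 columns, got {len(fields)}"
                    )
                t, gene, method, ev, bits = fields
                if t in hmap.entries:
                    raise ValidationError(
                        f"{path}: line {lineno}: transcript {t!r} listed twice"
                    )
                try:
                    entry = HomologyEntry(gene, method, float(ev), float(bits))
                except ValueError as exc:
                    if isinstance(exc, ValidationError):
                        raise
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
                hmap.entries[t] = entry
        return hmap
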