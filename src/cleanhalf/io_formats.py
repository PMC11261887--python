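"""Readers and writers for the external formats the pipeline touches.

Covers plain multi-record FASTA, GTDB-style taxonomy strings, the per-gene
assignment TSV dialect, genome summary tables, representative metadata and
single-line 0/1 alignment column masks.  All coordinates in the codebase are
0-based, half-open.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical GTDB rank codes, domain to species.
RANK_CODES: tuple[str, ...] = ("d", "p", "c", "o", "f", "g", "s")
RANK_INDEX: dict[str, int] = {code: i for i, code in enumerate(RANK_CODES)}
RANK_NAMES: dict[str, str] = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

# IUPAC nucleotide codes accepted on read (plus N).
_IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass(frozen=True)
class ContigSeq:
    """A single contig: id plus uppercase nucleotide sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise FormatError("contig_id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyString:
    """Ordered GTDB-style classification.

    ``ranks`` is a tuple of ``(rank_code, name)`` pairs in canonical d->s
    order.  A rank may be absent entirely (truncation, or dropped by a
    majority-vote tie) or present with an empty name (``s__`` with nothing
    after the prefix).
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        prev = -1
        for code, name in self.ranks:
            if code not in RANK_INDEX:
                raise FormatError(f"unknown rank code {code!r}")
            idx = RANK_INDEX[code]
            if idx <= prev:
                raise FormatError(
                    f"rank {code!r} out of canonical order in {self.ranks!r}"
                )
            if ";" in name:
                raise FormatError(f"rank name {name!r} contains ';'")
            prev = idx

    @classmethod
    def parse(cls, text: str) -> "TaxonomyString":
        """Parse a semicolon-separated GTDB taxonomy string."""
        tokens = [t.strip() for t in text.strip().split(";")]
        ranks = []
        for tok in tokens:
            if len(tok) < 3 or tok[1:3] != "__":
                raise FormatError(f"malformed rank token {tok!r}")
            code, name = tok[0], tok[3:]
            if code not in RANK_INDEX:
                raise FormatError(f"unknown rank prefix {tok[:3]!r}")
            ranks.append((code, name))
        return cls(tuple(ranks))

    def format(self) -> str:
        return ";".join(f"{code}__{name}" for code, name in self.ranks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    def name_at(self, code: str) -> str | None:
        """Name at ``code``, or None if the rank is absent from the string."""
        for c, name in self.ranks:
            if c == code:
                return name
        return None

    def named_at(self, code: str) -> str | None:
        """Non-empty name at ``code``, else None (absent or unnamed)."""
        name = self.name_at(code)
        return name if name else None

    def truncate(self, code: str) -> "TaxonomyString":
        """Drop all ranks deeper than ``code`` (idempotent)."""
        cutoff = RANK_INDEX[code]
        return TaxonomyString(
            tuple((c, n) for c, n in self.ranks if RANK_INDEX[c] <= cutoff)
        )

    def __len__(self) -> int:
        return len(self.ranks)


def parse_taxonomy_string(text: str) -> TaxonomyString:
    return TaxonomyString.parse(text)


@dataclass(frozen=True)
class GeneAssignment:
    """One gene's closest-hit taxonomy with its position on a contig."""

    gene_id: str
    contig_id: str
    gene_index: int
    hit_taxonomy: TaxonomyString
    is_marker: bool = False

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise FormatError("gene_index must be >= 0")
        if len(self.hit_taxonomy) < 1:
            raise FormatError("hit_taxonomy needs at least one rank")


@dataclass(frozen=True)
class GenomeSummary:
    accession: str
    css_rank: str
    is_failed: bool
    genome_type: str = "MAG"

    def __post_init__(self) -> None:
        if self.css_rank not in RANK_INDEX:
            raise FormatError(f"css_rank {self.css_rank!r} not in d,p,c,o,f,g,s")
        if self.genome_type not in {"isolate", "MAG", "SAG"}:
            raise FormatError(f"unknown genome_type {self.genome_type!r}")


@dataclass(frozen=True)
class ColumnMask:
    """Per-column keep/drop flags for an MSA."""

    keep: tuple[bool, ...]

    @property
    def n_kept(self) -> int:
        return sum(self.keep)

    def __len__(self) -> int:
        return len(self.keep)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ContigSeq]:
    """Read a multi-record FASTA into ContigSeqs.

    Sequences are uppercased and line wrapping is normalised.  Raises
    FormatError on an empty file, duplicate record ids, or characters
    outside the IUPAC nucleotide alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    contigs: list[ContigSeq] = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters "
                f"{sorted(bad)!r}"
            )
        contigs.append(ContigSeq(rec.id, seq))
    return contigs


def write_fasta(path: str | Path, contigs: Iterable[ContigSeq], width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene assignment TSV dialect
#
# Columns: accession, gene_id, contig_id, gene_index, hit_taxonomy, is_marker.
# Genes lacking any hit are simply omitted from the table.

_ASSIGNMENT_COLUMNS = (
    "accession",
    "gene_id",
    "contig_id",
    "gene_index",
    "hit_taxonomy",
    "is_marker",
)


def read_gene_assignments(path: str | Path) -> dict[str, list[GeneAssignment]]:
    """Read the per-gene assignment TSV, grouped by genome accession.

    Within each genome, rows are ordered by (contig_id, gene_index) so that
    downstream consumers are independent of input row order.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = set(_ASSIGNMENT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        grouped: dict[str, list[GeneAssignment]] = {}
        seen: set[tuple[str, str, int]] = set()
        for row in reader:
            acc = row["accession"]
            idx = int(row["gene_index"])
            key = (acc, row["contig_id"], idx)
            if key in seen:
                raise FormatError(
                    f"{path}: duplicate (contig_id, gene_index) {key[1:]!r} "
                    f"for genome {acc!r}"
                )
            seen.add(key)
            grouped.setdefault(acc, []).append(
                GeneAssignment(
                    gene_id=row["gene_id"],
                    contig_id=row["contig_id"],
                    gene_index=idx,
                    hit_taxonomy=TaxonomyString.parse(row["hit_taxonomy"]),
                    is_marker=row["is_marker"].strip().lower()
                    in {"1", "true", "t", "yes"},
                )
            )
    for acc in grouped:
        grouped[acc].sort(key=lambda g: (g.contig_id, g.gene_index))
    return grouped


def write_gene_assignments(
    path: str | Path, assignments: Mapping[str, Iterable[GeneAssignment]]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ASSIGNMENT_COLUMNS)
        for acc, genes in assignments.items():
            for g in genes:
                writer.writerow(
                    [
                        acc,
                        g.gene_id,
                        g.contig_id,
                        g.gene_index,
                        g.hit_taxonomy.format(),
                        int(g.is_marker),
                    ]
                )


# ---------------------------------------------------------------------------
# Genome summaries

_SUMMARY_COLUMNS = ("accession", "css_rank", "is_failed", "genome_type")


def read_genome_summaries(path: str | Path) -> dict[str, GenomeSummary]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = set(_SUMMARY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        out: dict[str, GenomeSummary] = {}
        for row in reader:
            acc = row["accession"]
            if acc in out:
                raise FormatError(f"{path}: duplicate accession {acc!r}")
            out[acc] = GenomeSummary(
                accession=acc,
                css_rank=row["css_rank"],
                is_failed=row["is_failed"].strip().lower() in {"1", "true", "t", "yes"},
                genome_type=row["genome_type"],
            )
        return out


def write_genome_summaries(
    path: str | Path, summaries: Iterable[GenomeSummary]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SUMMARY_COLUMNS)
        for s in summaries:
            writer.writerow([s.accession, s.css_rank, int(s.is_failed), s.genome_type])


# ---------------------------------------------------------------------------
# Representative metadata (accession -> taxonomy string)


def read_rep_metadata(path: str | Path) -> dict[str, TaxonomyString]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = {"accession", "taxonomy"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        out: dict[str, TaxonomyString] = {}
        for row in reader:
            acc = row["accession"]
            if acc in out:
                raise FormatError(f"{path}: duplicate accession {acc!r}")
            out[acc] = TaxonomyString.parse(row["taxonomy"])
        return out


def write_rep_metadata(
    path: str | Path, metadata: Mapping[str, TaxonomyString]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "taxonomy"])
        for acc, tax in metadata.items():
            writer.writerow([acc, tax.format()])


# ---------------------------------------------------------------------------
# MSA column mask


def read_msa_mask(path: str | Path) -> ColumnMask:
    """Read a single-line 0/1 column mask; whitespace is ignored."""
    text = Path(path).read_text()
    symbols = "".join(text.split())
    bad = set(symbols) - {"0", "1"}
    if bad:
        raise FormatError(f"{path}: mask symbols outside 0/1: {sorted(bad)!r}")
    mask = ColumnMask(tuple(ch == "1" for ch in symbols))
    if mask.n_kept == 0:
        warnings.warn(f"{path}: mask keeps zero columns", stacklevel=2)
    return mask


def write_msa_mask(path: str | Path, mask: ColumnMask) -> None:
    Path(path).write_text("".join("1" if k else "0" for k in mask.keep) + "\n")
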