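"""Protein FASTA and BLAST-style tabular hit I/O.

Sequences are plain amino-acid strings over the 20 canonical residues plus
the ambiguity symbols X, B, Z, U and the stop/frame marker ``*``.  Reference
records carry their metagenome sample of origin in the header as
``sampleID|sequenceID``; an explicit two-column mapping file may override
that convention.

Internally all coordinates are 0-based half-open; the 12-column tabular
format (BLAST ``outfmt 6``) uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import AlphabetError, FastaParseError, HitTableFormatError

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_RESIDUES = "XBZU*"
ALLOWED_RESIDUES = frozenset(CANONICAL_RESIDUES + AMBIGUITY_RESIDUES)


@dataclass
class AminoAcidSequence:
    """A validated protein sequence with identifier and optional sample tag.

    Parameters
    ----------
    id : str
        Record identifier, unique within a file.
    residues : str
        Uppercase residue string over the allowed alphabet.
    description : str
        Free text after the identifier in the FASTA header.
    sample_id : str or None
        Metagenome sample the sequence belongs to, when known.
    """

    id: str
    residues: str
    description: str = ""
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence record has an empty identifier")
        if not self.residues:
            raise AlphabetError(f"record {self.id!r}: empty residue string")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: disallowed residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, mode: str, record_id: str) -> str:
    """Uppercase *raw* and enforce the alphabet.

    In ``strict`` mode a disallowed character raises :class:`AlphabetError`;
    in ``lenient`` mode it is mapped to ``X``.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    up = raw.upper()
    if set(up) <= ALLOWED_RESIDUES:
        return up
    if mode == "strict":
        bad = sorted(set(up) - ALLOWED_RESIDUES)
        raise AlphabetError(
            f"record {record_id!r}: disallowed residue(s) {bad!r} in strict mode"
        )
    return "".join(c if c in ALLOWED_RESIDUES else "X" for c in up)


def split_sample_id(record_id: str) -> str | None:
    """Sample tag from the ``sampleID|sequenceID`` header convention."""
    if "|" in record_id:
        return record_id.split("|", 1)[0]
    return None


def read_fasta(
    path,
    mode: str = "strict",
    sample_map: Mapping[str, str] | None = None,
) -> list[AminoAcidSequence]:
    """Read a protein FASTA file into an ordered list of sequences.

    ``sample_id`` is taken from *sample_map* when given, otherwise parsed
    from the ``sampleID|seqID`` header convention when present.
    """
    path = Path(path)
    records: list[AminoAcidSequence] = []
    try:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                residues = normalize_residues(str(rec.seq), mode, rec.id)
                if sample_map is not None and rec.id in sample_map:
                    sample = sample_map[rec.id]
                else:
                    sample = split_sample_id(rec.id)
                records.append(
                    AminoAcidSequence(
                        id=rec.id,
                        residues=residues,
                        description=rec.description[len(rec.id):].strip(),
                        sample_id=sample,
                    )
                )
    except ValueError as exc:  # Biopython's malformed-FASTA signal
        raise FastaParseError(f"{path}: {exc}") from exc
    return records


def read_sample_map(path) -> dict[str, str]:
    """Two-column TSV ``sequence_id<TAB>sample_id`` overriding the header rule."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise HitTableFormatError(
                    f"{path}: line {ln}: expected 2 tab-separated columns"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def write_fasta(sequences: Iterable[AminoAcidSequence], path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST-style 12-column tabular hits
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    """One hit (best-scoring local alignment of a query/subject pair).

    Coordinates are 1-based inclusive, as printed in BLAST ``outfmt 6``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: start > end "
                "(protein alignments have no strand)"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.query_id, self.subject_id)


def format_evalue(e: float) -> str:
    """Scientific notation with two significant digits (``1.0e-08`` style)."""
    return f"{e:.1e}"


def hit_to_row(hit: HitRecord) -> str:
    return "\t".join(
        [
            hit.query_id,
            hit.subject_id,
            f"{hit.percent_identity:.2f}",
            str(hit.alignment_length),
            str(hit.mismatches),
            str(hit.gap_opens),
            str(hit.q_start),
            str(hit.q_end),
            str(hit.s_start),
            str(hit.s_end),
            format_evalue(hit.evalue),
            f"{hit.bit_score:.1f}",
        ]
    )


def write_hits_tab(hits: Iterable[HitRecord], path) -> None:
    """Write hits as 12-column tab-separated rows (BLAST ``outfmt 6``)."""
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit_to_row(hit) + "\n")


def hits_table_text(hits: Iterable[HitRecord]) -> str:
    buf = io.StringIO()
    for hit in hits:
        buf.write(hit_to_row(hit) + "\n")
    return buf.getvalue()


def read_hits_tab(path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file; extra trailing columns are ignored."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise HitTableFormatError(
                    f"{path}: row {ln}: expected 12 columns, found {len(parts)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableFormatError(f"{path}: row {ln}: {exc}") from exc
    return hits
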