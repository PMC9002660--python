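"""Nucleotide sequence records and FASTA I/O.

TE libraries are plain multi-record FASTA.  Benchmarking truth labels use the
RepeatMasker-style header dialect ``name#Order/Superfamily``: everything after
the first ``#`` is the label.  Soft-masked (lowercase) sequence is uppercased
on input; characters outside {A,C,G,T,N} are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class FastaError(ValueError):
    """Malformed FASTA input (bad structure, alphabet, or duplicate ids)."""


@dataclass
class SequenceRecord:
    """One nucleotide TE sequence."""

    id: str
    seq: str
    description: str = ""
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FastaError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(allowed: A,C,G,T,N; case-insensitive)"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _check_structure(path: Path) -> None:
    """Reject text before the first header, reporting the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected a '>' header before "
                    f"sequence data: {stripped[:40]!r}"
                )
            return


def read_fasta(path: Union[str, Path], parse_labels: bool = False) -> list[SequenceRecord]:
    """Read a nucleotide FASTA into a list of :class:`SequenceRecord`.

    With ``parse_labels=True``, headers of the form ``name#label`` yield
    ``id=name`` and ``truth_label=label``.  Duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_structure(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header_id = rec.id
        truth = None
        if parse_labels and "#" in header_id:
            header_id, _, truth = header_id.partition("#")
        if header_id in seen:
            raise FastaError(f"{path}: duplicate sequence id {header_id!r}")
        seen.add(header_id)
        records.append(
            SequenceRecord(
                id=header_id,
                seq=str(rec.seq),
                description=rec.description,
                truth_label=truth or None,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path],
                with_labels: bool = False, width: int = 60) -> None:
    """Write records as FASTA; with_labels re-emits ``id#truth_label`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if with_labels and rec.truth_label:
                header = f"{rec.id}#{rec.truth_label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
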