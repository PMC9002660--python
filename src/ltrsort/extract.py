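"""Extract conserved domain sequences for downstream phylogenetics.

For each element classified from domain evidence, every retained hit of a
requested label yields one protein and one nucleotide sequence, oriented by
strand so the nucleotide sequence translates exactly to the protein.
Headers follow ``elementID|lineage|domain``.

Concatenated multi-domain sequences (typically RT-RH-INT) are built in the
requested label order — the order used for phylogenetic matrices — rather
than genomic order, which differs between Copia and Gypsy; only elements
carrying exactly one retained copy of every requested label are included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio.Seq import Seq

from .classification import Classification
from .records import SequenceRecord
from .translate import extract_nt


@dataclass(frozen=True)
class DomainSequence:
    """One extracted domain: aligned protein plus its coding nucleotides."""

    element_id: str
    domain_label: str
    clade: str
    aa_seq: str
    nt_seq: str
    nt_start: int
    nt_end: int
    strand: str
    lineage: str = ""

    @property
    def header(self) -> str:
        return f"{self.element_id}|{self.lineage}|{self.domain_label}"


def extract(classifications: Iterable[Classification],
            library: Sequence[SequenceRecord],
            labels: Sequence[str] = ("GAG", "AP", "INT", "RT", "RH"),
            genetic_code: int = 1) -> dict[str, list[DomainSequence]]:
    """Extract every retained hit of each requested domain label.

    Returns {domain_label: [DomainSequence, ...]} sorted by element id.
    Raises if a hit's coordinates fall outside its parent sequence (an
    upstream bug, not a data condition).
    """
    by_id = {rec.id: rec for rec in library}
    out: dict[str, list[DomainSequence]] = {label: [] for label in labels}
    for cls in sorted(classifications, key=lambda c: c.element_id):
        if not cls.evidence:
            continue
        rec = by_id.get(cls.element_id)
        if rec is None:
            raise KeyError(f"classification for unknown element {cls.element_id!r}")
        for hit in cls.evidence:
            if hit.domain_label not in out:
                continue
            if not (1 <= hit.nt_start <= hit.nt_end <= len(rec.seq)):
                raise ValueError(
                    f"{cls.element_id}: hit coordinates {hit.nt_start}.."
                    f"{hit.nt_end} outside sequence of length {len(rec.seq)}"
                )
            nt_seq = extract_nt(rec.seq, hit.nt_start, hit.nt_end, hit.strand)
            aa_seq = str(Seq(nt_seq).translate(table=genetic_code))
            out[hit.domain_label].append(DomainSequence(
                element_id=cls.element_id,
                domain_label=hit.domain_label,
                clade=hit.lineage.clade or "",
                aa_seq=aa_seq,
                nt_seq=nt_seq,
                nt_start=hit.nt_start,
                nt_end=hit.nt_end,
                strand=hit.strand,
                lineage=str(cls.lineage) if cls.lineage else "Unclassified",
            ))
    return out


def concatenate(domains: Mapping[str, Sequence[DomainSequence]],
                labels: Sequence[str] = ("RT", "RH", "INT")) -> list[DomainSequence]:
    """Concatenate domains per element in the requested label order.

    Only elements with exactly one extracted copy of every requested label
    appear; multi-copy elements are excluded (ambiguous orthology).
    """
    if not labels:
        raise ValueError("concatenate requires at least one domain label")
    per_element: dict[str, dict[str, list[DomainSequence]]] = {}
    for label in labels:
        for ds in domains.get(label, []):
            per_element.setdefault(ds.element_id, {}).setdefault(label, []).append(ds)
    out: list[DomainSequence] = []
    for element_id in sorted(per_element):
        have = per_element[element_id]
        if any(len(have.get(label, [])) != 1 for label in labels):
            continue
        parts = [have[label][0] for label in labels]
        out.append(DomainSequence(
            element_id=element_id,
            domain_label="-".join(labels),
            clade=parts[0].clade,
            aa_seq="".join(p.aa_seq for p in parts),
            nt_seq="".join(p.nt_seq for p in parts),
            nt_start=min(p.nt_start for p in parts),
            nt_end=max(p.nt_end for p in parts),
            strand=parts[0].strand,
            lineage=parts[0].lineage,
        ))
    return out


def write_domain_fasta(sequences: Iterable[DomainSequence],
                       path: Union[str, Path], kind: str = "aa",
                       width: int = 60) -> None:
    """Write extracted domains as protein (kind='aa') or nucleotide ('nt') FASTA."""
    if kind not in ("aa", "nt"):
        raise ValueError("kind must be 'aa' or 'nt'")
    with open(path, "w") as fh:
        for ds in sequences:
            seq = ds.aa_seq if kind == "aa" else ds.nt_seq
            fh.write(f">{ds.header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
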