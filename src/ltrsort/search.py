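"""Profile-HMM domain search, hit filtering, and best-hit resolution.

Translated frames are scanned against the domain database.  Raw per-domain
hits are filtered by model coverage and per-domain (independent) E-value:
hits with coverage < 20% or E-value > 1e-3 are discarded (boundary values
are kept).  Coverage is computed over the profile's match states,
``(hmm_to - hmm_from + 1) / model_length``, the usual convention for judging
how much of a domain model a hit spans.

Where several surviving hits pile up on the same locus (nucleotide overlap
greater than half the shorter interval), only the best hit — the one with
the highest bit score — is retained; non-overlapping repeat copies of the
same domain survive.

Two engine backends are supported: the embedded pyhmmer scan
(:func:`search_frames`) and an external ``hmmscan --domtblout`` table
consumed by :func:`parse_domain_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO, Union

from .lineage import Lineage
from .profiles import ProfileDatabase
from .translate import TranslatedFrame, map_aa_to_nt

_FRAME_SEP = "|aaframe="


class SearchError(RuntimeError):
    pass


def make_query_id(element_id: str, frame: int) -> str:
    """Tag an element id with its reading frame for the protein search."""
    return f"{element_id}{_FRAME_SEP}{frame:+d}"


def split_query_id(query_id: str) -> tuple[str, int]:
    element_id, sep, tag = query_id.rpartition(_FRAME_SEP)
    if not sep:
        raise ValueError(f"query id {query_id!r} carries no frame tag")
    return element_id, int(tag)


@dataclass(frozen=True)
class RawHit:
    """One unfiltered per-domain match in protein space."""

    query_id: str
    profile_name: str
    score: float
    evalue: float
    hmm_from: int
    hmm_to: int
    aa_from: int
    aa_to: int

    def __post_init__(self) -> None:
        if self.hmm_from > self.hmm_to:
            raise ValueError("hmm_from must be <= hmm_to")
        if self.aa_from > self.aa_to:
            raise ValueError("aa_from must be <= aa_to")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class DomainHit:
    """A filtered hit with lineage and forward-strand nucleotide coordinates."""

    element_id: str
    frame: int
    domain_label: str
    lineage: Lineage
    score: float
    evalue: float
    coverage: float
    nt_start: int
    nt_end: int
    strand: str
    profile_name: str


def search_frames(frames: Iterable[TranslatedFrame], db: ProfileDatabase,
                  threads: int = 1) -> list[RawHit]:
    """Scan translated frames against the database with the embedded engine.

    Results are independent of the thread count.  Hits carry the per-domain
    (independent) E-value and the alignment spans on the model and the frame.
    """
    try:
        import pyhmmer
        from pyhmmer.easel import Alphabet, TextSequence
    except ImportError as exc:  # pragma: no cover - environment guard
        raise SearchError(
            "the embedded search backend requires the 'pyhmmer' package"
        ) from exc

    frames = list(frames)
    if not frames:
        return []
    if len(db) == 0:
        raise SearchError("profile database is empty")

    abc = Alphabet.amino()
    queries = [
        TextSequence(
            name=make_query_id(f.parent_id, f.frame).encode(),
            sequence=f.protein,
        ).digitize(abc)
        for f in frames
        if f.protein
    ]
    if not queries:
        return []

    def _text(name):
        return name.decode() if isinstance(name, bytes) else str(name)

    hits: list[RawHit] = []
    for top_hits in pyhmmer.hmmer.hmmscan(queries, db.hmms, cpus=threads):
        query_id = _text(top_hits.query.name)
        for hit in top_hits:
            profile_name = _text(hit.name)
            for dom in hit.domains:
                ali = dom.alignment
                hits.append(RawHit(
                    query_id=query_id,
                    profile_name=profile_name,
                    score=float(dom.score),
                    evalue=float(dom.i_evalue),
                    hmm_from=int(ali.hmm_from),
                    hmm_to=int(ali.hmm_to),
                    aa_from=int(ali.target_from),
                    aa_to=int(ali.target_to),
                ))
    hits.sort(key=lambda h: (h.query_id, h.profile_name, h.aa_from, -h.score))
    return hits


def parse_domain_table(stream: Union[TextIO, Iterable[str]]) -> list[RawHit]:
    """Parse the per-domain tabular output (domtblout dialect) of an external
    hmmscan run into raw hits.

    Uses the independent (i-Evalue) per-domain E-value and the alignment
    coordinates; comment lines (``#``) are ignored.
    """
    hits: list[RawHit] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 23:
            raise ValueError(
                f"domain table row {lineno}: expected >= 23 columns, "
                f"got {len(fields)}"
            )
        hits.append(RawHit(
            query_id=fields[3],
            profile_name=fields[0],
            score=float(fields[13]),
            evalue=float(fields[12]),
            hmm_from=int(fields[15]),
            hmm_to=int(fields[16]),
            aa_from=int(fields[17]),
            aa_to=int(fields[18]),
        ))
    return hits


def filter_hits(hits: Iterable[RawHit], db: ProfileDatabase,
                seq_lengths: Mapping[str, int],
                min_coverage: float = 0.20,
                max_evalue: float = 1e-3) -> list[DomainHit]:
    """Keep hits with coverage >= min_coverage and E-value <= max_evalue.

    Boundary values are kept (the discard rule is strict: coverage < 20% or
    E-value > 1e-3).  Each kept hit acquires its profile's lineage and
    forward-strand nucleotide coordinates.
    """
    kept: list[DomainHit] = []
    for hit in hits:
        if hit.profile_name not in db:
            raise KeyError(
                f"hit references unknown profile {hit.profile_name!r}"
            )
        profile = db[hit.profile_name]
        coverage = (hit.hmm_to - hit.hmm_from + 1) / profile.model_length
        if coverage < min_coverage or hit.evalue > max_evalue:
            continue
        element_id, frame = split_query_id(hit.query_id)
        if element_id not in seq_lengths:
            raise KeyError(f"hit references unknown element {element_id!r}")
        nt_start, nt_end, strand = map_aa_to_nt(
            frame, hit.aa_from, hit.aa_to, seq_lengths[element_id]
        )
        kept.append(DomainHit(
            element_id=element_id,
            frame=frame,
            domain_label=profile.domain_label,
            lineage=profile.lineage,
            score=hit.score,
            evalue=hit.evalue,
            coverage=coverage,
            nt_start=nt_start,
            nt_end=nt_end,
            strand=strand,
            profile_name=hit.profile_name,
        ))
    return kept


def _overlap_gt_half_shorter(a: DomainHit, b: DomainHit) -> bool:
    ov = min(a.nt_end, b.nt_end) - max(a.nt_start, b.nt_start) + 1
    if ov <= 0:
        return False
    shorter = min(a.nt_end - a.nt_start + 1, b.nt_end - b.nt_start + 1)
    return ov > 0.5 * shorter


def resolve_best_hits(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Retain only the best hit per conflicting locus.

    Hits whose nucleotide intervals overlap by more than 50% of the shorter
    interval compete; the highest score wins, ties broken by lower E-value
    then lexicographic profile name.  Tandem (non-overlapping) domain copies
    are kept.  All hits must belong to one element.
    """
    hits = list(hits)
    if len({h.element_id for h in hits}) > 1:
        raise ValueError("resolve_best_hits expects hits of a single element")
    ranked = sorted(
        hits, key=lambda h: (-h.score, h.evalue, h.profile_name, h.nt_start)
    )
    retained: list[DomainHit] = []
    for hit in ranked:
        if not any(_overlap_gt_half_shorter(hit, kept) for kept in retained):
            retained.append(hit)
    retained.sort(key=lambda h: (h.nt_start, h.nt_end, h.profile_name))
    return retained
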