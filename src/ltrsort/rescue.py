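"""Second-pass rescue of unclassified elements by sequence similarity.

Elements without usable domain evidence (typically non-autonomous
derivatives that have lost their coding domains) are compared at the
nucleotide level against the pass-1-classified elements.  A query is rescued
when its best hit satisfies the 80-80-80 homology rule: >= 80 bp of
alignment, >= 80% identity and >= 80% query coverage (all bounds
inclusive).  Because sequence-level similarity is weaker evidence than
domain phylogeny, rescued elements are assigned the subject's lineage
truncated to the superfamily — never a clade.

Coverage is computed over the *query* from the union of all HSP query
intervals against the best subject; the alignment-length and identity tests
apply to the single best HSP.  Rescue runs exactly one round: pass-2
elements are never recycled as subjects.

Backends: an internal pairwise local aligner (blastn-like scoring, both
strands) adequate for library-scale input, or an external similarity-search
executable producing 12-column tabular output (outfmt-6 dialect) parsed by
:func:`parse_tabular`.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from Bio import Align
from Bio.Seq import Seq

from .classification import Classification
from .records import SequenceRecord, write_fasta


@dataclass(frozen=True)
class SimilarityHit:
    """Best-HSP statistics plus union query coverage for one (query, subject)."""

    query_id: str
    subject_id: str
    aln_len: int
    identity: float        # % identical over aligned columns of the best HSP
    query_coverage: float  # % of the query covered by the HSP union
    score: float

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if not (0 <= self.identity <= 100):
            raise ValueError("identity must be in [0, 100]")
        if not (0 <= self.query_coverage <= 100):
            raise ValueError("query_coverage must be in [0, 100]")


def _make_aligner() -> Align.PairwiseAligner:
    # blastn-like scoring: reward 2, penalty -3, gap open 5, gap extend 2
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _hsp_stats(alignment, qlen: int) -> tuple[int, float, float, float]:
    """(aln_len, identity%, qcov%, score) of one local alignment."""
    counts = alignment.counts()
    aln_len = counts.aligned + counts.internal_gaps
    if aln_len == 0:
        return 0, 0.0, 0.0, 0.0
    identity = 100.0 * counts.identities / aln_len
    qblocks = alignment.aligned[0]
    covered = sum(int(e - s) for s, e in qblocks)
    qcov = 100.0 * covered / qlen
    return aln_len, identity, qcov, float(alignment.score)


def similarity_search(queries: Sequence[SequenceRecord],
                      subjects: Sequence[SequenceRecord],
                      backend: str = "internal") -> list[SimilarityHit]:
    """Search unclassified queries against classified subjects on both strands.

    Returns one aggregated hit per (query, subject) pair with any local
    alignment; empty when there are no subjects.
    """
    if not subjects or not queries:
        return []
    if backend == "internal":
        return _internal_search(queries, subjects)
    if backend == "external":
        return _external_search(queries, subjects)
    raise ValueError(f"unknown rescue backend {backend!r}")


def _internal_search(queries: Sequence[SequenceRecord],
                     subjects: Sequence[SequenceRecord]) -> list[SimilarityHit]:
    aligner = _make_aligner()
    hits: list[SimilarityHit] = []
    for query in queries:
        qseqs = {"+": query.seq, "-": str(Seq(query.seq).reverse_complement())}
        for subject in subjects:
            best = None
            for qseq in qseqs.values():
                alns = aligner.align(qseq, subject.seq)
                if len(alns) == 0 or alns.score <= 0:
                    continue
                stats = _hsp_stats(alns[0], len(query.seq))
                if stats[0] >= 1 and (best is None or stats[3] > best[3]):
                    best = stats
            if best is not None:
                aln_len, identity, qcov, sc = best
                hits.append(SimilarityHit(
                    query_id=query.id, subject_id=subject.id,
                    aln_len=aln_len, identity=identity,
                    query_coverage=qcov, score=sc,
                ))
    return hits


def parse_tabular(stream: Union[TextIO, Iterable[str]],
                  query_lengths: Mapping[str, int]) -> list[SimilarityHit]:
    """Parse 12-column tabular alignment output (outfmt-6 dialect:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore) into aggregated per-(query, subject) hits.

    Per pair, the best HSP (highest bitscore) supplies identity, alignment
    length and score; query coverage is the union of all HSP query intervals.
    """
    pairs: dict[tuple[str, str], dict] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(
                f"tabular alignment row {lineno}: expected 12 columns, "
                f"got {len(fields)}"
            )
        qid, sid = fields[0], fields[1]
        pident, length = float(fields[2]), int(fields[3])
        qstart, qend = int(fields[6]), int(fields[7])
        bitscore = float(fields[11])
        if qstart > qend:
            qstart, qend = qend, qstart
        entry = pairs.setdefault((qid, sid), {
            "best": (-1.0, 0, 0.0), "intervals": []})
        if bitscore > entry["best"][0]:
            entry["best"] = (bitscore, length, pident)
        entry["intervals"].append((qstart, qend))
    hits = []
    for (qid, sid), entry in sorted(pairs.items()):
        if qid not in query_lengths:
            raise KeyError(f"unknown query id {qid!r} in alignment table")
        covered = _union_length(entry["intervals"])
        bitscore, length, pident = entry["best"]
        hits.append(SimilarityHit(
            query_id=qid, subject_id=sid, aln_len=length, identity=pident,
            query_coverage=100.0 * covered / query_lengths[qid],
            score=bitscore,
        ))
    return hits


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = 0
    for start, stop in sorted(intervals):
        if stop <= end:
            continue
        total += stop - max(start - 1, end)
        end = stop
    return total


def _external_search(queries: Sequence[SequenceRecord],
                     subjects: Sequence[SequenceRecord]) -> list[SimilarityHit]:
    exe = shutil.which("blastn")
    if exe is None:
        raise RuntimeError(
            "the external rescue backend requires a 'blastn' executable on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "queries.fa"
        spath = Path(tmp) / "subjects.fa"
        write_fasta(queries, qpath)
        write_fasta(subjects, spath)
        proc = subprocess.run(
            [exe, "-query", str(qpath), "-subject", str(spath),
             "-outfmt", "6", "-task", "blastn"],
            capture_output=True, text=True, check=True,
        )
    lengths = {q.id: len(q.seq) for q in queries}
    return parse_tabular(proc.stdout.splitlines(), lengths)


def apply_80_80_80(hits: Iterable[SimilarityHit],
                   pass1: Mapping[str, Classification],
                   min_aln_bp: int = 80,
                   min_identity: float = 80.0,
                   min_query_coverage: float = 80.0) -> list[Classification]:
    """Classify queries whose best hit passes the 80-80-80 rule.

    The best hit per query is the highest score, ties broken by higher
    identity then lexicographic subject id.  A rescued query takes the
    subject's lineage truncated to superfamily depth (pass 2, no clade, no
    completeness call).
    """
    by_query: dict[str, list[SimilarityHit]] = {}
    for hit in hits:
        if hit.subject_id not in pass1:
            raise KeyError(f"similarity hit to unknown subject {hit.subject_id!r}")
        by_query.setdefault(hit.query_id, []).append(hit)

    rescued: list[Classification] = []
    for query_id in sorted(by_query):
        best = min(by_query[query_id],
                   key=lambda h: (-h.score, -h.identity, h.subject_id))
        if (best.aln_len >= min_aln_bp
                and best.identity >= min_identity
                and best.query_coverage >= min_query_coverage):
            subject_cls = pass1[best.subject_id]
            if subject_cls.lineage is None:
                continue
            rescued.append(Classification(
                element_id=query_id,
                lineage=subject_cls.lineage.truncate("superfamily"),
                complete=None,
                strand="?",
                domain_string="",
                pass_no=2,
                evidence=[],
            ))
    return rescued
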