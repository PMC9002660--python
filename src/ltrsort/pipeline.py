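"""End-to-end pipeline: translate -> search -> filter -> resolve -> classify
-> rescue -> extract.

The pipeline proper is deterministic: identical input and configuration
produce byte-identical outputs regardless of thread count (threads only
parallelise the profile-HMM scan, whose results are thread-invariant, and
outputs are canonicalised by element id before writing).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .classification import Classification, classify_element, write_classifications
from .extract import concatenate, extract, write_domain_fasta
from .profiles import ProfileDatabase
from .records import SequenceRecord, read_fasta, write_fasta
from .rescue import apply_80_80_80, similarity_search
from .search import filter_hits, resolve_best_hits, search_frames
from .translate import translate_six_frames

logger = logging.getLogger("ltrsort")


@dataclass
class PipelineConfig:
    """Tunable thresholds and run settings; defaults are the method defaults."""

    min_coverage: float = 0.20
    max_evalue: float = 1e-3
    rule_min_aln_bp: int = 80
    rule_min_identity: float = 80.0
    rule_min_qcov: float = 80.0
    pass2_enabled: bool = True
    rescue_backend: str = "internal"
    threads: int = 1
    seed: int = 42
    genetic_code: int = 1
    extract_labels: Sequence[str] = ("GAG", "AP", "INT", "RT", "RH")
    concat_labels: Sequence[str] = ("RT", "RH", "INT")

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in [0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class PipelineResult:
    classifications: list[Classification]
    domains: dict
    concatenated: list
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(library: Union[str, Path, Sequence[SequenceRecord]],
                 db: ProfileDatabase,
                 config: Optional[PipelineConfig] = None,
                 out_dir: Optional[Union[str, Path]] = None) -> PipelineResult:
    """Run the full two-pass classification on a TE library.

    *library* is a FASTA path or a sequence of records.  When *out_dir* is
    given, the TSV/GFF3 reports and per-domain FASTA files are written there.
    """
    config = config or PipelineConfig()
    if isinstance(library, (str, Path)):
        records = read_fasta(library, parse_labels=True)
    else:
        records = list(library)
    counts: dict[str, int] = {"input": len(records)}
    t0 = time.perf_counter()

    # pass 1: domain evidence
    frames = []
    for rec in records:
        frames.extend(translate_six_frames(rec, config.genetic_code))
    counts["frames"] = len(frames)
    logger.info("translated %d elements into %d frames", len(records), len(frames))

    raw_hits = search_frames(frames, db, threads=config.threads)
    counts["raw_hits"] = len(raw_hits)
    seq_lengths = {rec.id: len(rec.seq) for rec in records}
    kept = filter_hits(raw_hits, db, seq_lengths,
                       min_coverage=config.min_coverage,
                       max_evalue=config.max_evalue)
    counts["filtered_hits"] = len(kept)
    logger.info("search: %d raw hits, %d pass the coverage/E-value filters",
                len(raw_hits), len(kept))

    by_element: dict[str, list] = {rec.id: [] for rec in records}
    for hit in kept:
        by_element[hit.element_id].append(hit)
    classifications: dict[str, Classification] = {}
    resolved_total = 0
    for element_id in sorted(by_element):
        resolved = resolve_best_hits(by_element[element_id])
        resolved_total += len(resolved)
        classifications[element_id] = classify_element(element_id, resolved)
    counts["resolved_hits"] = resolved_total
    counts["pass1_classified"] = sum(
        1 for c in classifications.values() if c.is_classified)
    logger.info("pass 1: %d/%d elements classified",
                counts["pass1_classified"], len(records))

    # pass 2: similarity rescue at superfamily level
    if config.pass2_enabled:
        subjects_cls = {
            cid: c for cid, c in classifications.items()
            if c.is_classified and c.lineage.superfamily is not None
        }
        by_id = {rec.id: rec for rec in records}
        queries = [by_id[cid] for cid in sorted(classifications)
                   if not classifications[cid].is_classified]
        subjects = [by_id[cid] for cid in sorted(subjects_cls)]
        sim_hits = similarity_search(queries, subjects,
                                     backend=config.rescue_backend)
        rescued = apply_80_80_80(
            sim_hits, subjects_cls,
            min_aln_bp=config.rule_min_aln_bp,
            min_identity=config.rule_min_identity,
            min_query_coverage=config.rule_min_qcov,
        )
        for cls in rescued:
            assert cls.lineage is not None and cls.lineage.clade is None, \
                "rescue-pass classifications must never carry a clade"
            classifications[cls.element_id] = cls
        counts["pass2_rescued"] = len(rescued)
        logger.info("pass 2: rescued %d/%d unclassified elements",
                    len(rescued), len(queries))
    else:
        counts["pass2_rescued"] = 0

    final = [classifications[cid] for cid in sorted(classifications)]
    domains = extract(final, records, labels=config.extract_labels,
                      genetic_code=config.genetic_code)
    concatenated = concatenate(domains, labels=config.concat_labels)
    counts["classified"] = sum(1 for c in final if c.is_classified)
    logger.info("done in %.1f s: %d/%d classified",
                time.perf_counter() - t0, counts["classified"], len(records))

    result = PipelineResult(classifications=final, domains=domains,
                            concatenated=concatenated, stage_counts=counts)
    if out_dir is not None:
        write_outputs(result, records, out_dir)
    return result


def write_outputs(result: PipelineResult, records: Sequence[SequenceRecord],
                  out_dir: Union[str, Path]) -> dict[str, str]:
    """Write the TSV/GFF3 reports, per-domain FASTAs, and the unclassified
    element pass-through FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out_dir / "classifications.tsv",
        "gff": out_dir / "domains.gff3",
        "unclassified": out_dir / "unclassified.fa",
    }
    write_classifications(result.classifications, paths["tsv"], paths["gff"])
    unclassified_ids = {
        c.element_id for c in result.classifications if not c.is_classified}
    write_fasta([r for r in records if r.id in unclassified_ids],
                paths["unclassified"])
    for label, seqs in result.domains.items():
        for kind in ("aa", "nt"):
            p = out_dir / f"domain_{label}.{kind}.fa"
            write_domain_fasta(seqs, p, kind=kind)
            paths[f"{label}.{kind}"] = p
    concat_path = out_dir / "domain_concatenated.aa.fa"
    write_domain_fasta(result.concatenated, concat_path, kind="aa")
    paths["concatenated"] = concat_path
    return {k: str(v) for k, v in paths.items()}
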