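"""Aggregate per-domain hits into per-element classifications.

An element's lineage is decided level by level (order -> superfamily ->
clade) by a summed-bit-score majority: at each level the value with the
greatest summed score wins, and the walk descends a level only while the
winner holds a strict majority (> 50%) of the summed score at that level.
Conflicting evidence therefore degrades gracefully to a shallower, still
supported level rather than forcing an arbitrary deep call.

For the Copia and Gypsy superfamilies an element is *complete* when all five
canonical polyprotein domains — capsid protein (GAG), aspartic proteinase
(AP), integrase (INT), reverse transcriptase (RT) and RNase H (RH) — are
present exactly once, on one strand, in the superfamily's canonical 5'->3'
order: GAG,AP,INT,RT,RH for Copia and GAG,AP,RT,RH,INT for Gypsy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .lineage import Lineage
from .search import DomainHit

#: Canonical 5'->3' polyprotein domain order per superfamily
#: (configuration data, following the standard TE classification hierarchy).
CANONICAL_DOMAIN_ORDER: dict[str, tuple[str, ...]] = {
    "Copia": ("GAG", "AP", "INT", "RT", "RH"),
    "Gypsy": ("GAG", "AP", "RT", "RH", "INT"),
}

COMPLETENESS_LABELS = ("GAG", "AP", "INT", "RT", "RH")

TSV_COLUMNS = ("element_id", "order", "superfamily", "clade", "complete",
               "strand", "domains", "pass")


@dataclass
class Classification:
    """Final per-element verdict.

    ``lineage`` is None for unclassified elements.  ``complete`` is None when
    completeness is not applicable (non-Copia/Gypsy lineages, rescue-pass
    classifications, unclassified elements).
    """

    element_id: str
    lineage: Optional[Lineage]
    complete: Optional[bool]
    strand: str
    domain_string: str
    pass_no: int
    evidence: list[DomainHit] = field(default_factory=list)

    @property
    def is_classified(self) -> bool:
        return self.lineage is not None


def _majority(hits: list[DomainHit], key) -> tuple[Optional[str], float, float]:
    """(winning value, its summed score, total summed score) at one level.

    Hits whose lineage lacks the level contribute to the total but cannot win.
    """
    total = sum(h.score for h in hits)
    sums: dict[str, float] = {}
    for h in hits:
        value = key(h)
        if value is not None:
            sums[value] = sums.get(value, 0.0) + h.score
    if not sums:
        return None, 0.0, total
    # deterministic tie-break: higher score, then lexicographic value
    winner = min(sums, key=lambda v: (-sums[v], v))
    return winner, sums[winner], total


def _domain_string(hits: list[DomainHit], strand: str) -> str:
    ordered = sorted(hits, key=lambda h: h.nt_start, reverse=(strand == "-"))
    parts = []
    for h in ordered:
        tag = h.lineage.clade or h.lineage.superfamily or h.lineage.order
        parts.append(f"{h.domain_label}|{tag}")
    return " ".join(parts)


def classify_element(element_id: str, hits: Iterable[DomainHit]) -> Classification:
    """Classify one element from its filtered, resolved domain hits.

    An empty hit list yields the unclassified sentinel (``lineage=None``).
    """
    hits = list(hits)
    if any(h.element_id != element_id for h in hits):
        raise ValueError("hits do not all belong to the given element")
    if not hits:
        return Classification(element_id=element_id, lineage=None,
                              complete=None, strand="?", domain_string="",
                              pass_no=1, evidence=[])

    # strand by summed-score majority
    plus = sum(h.score for h in hits if h.strand == "+")
    minus = sum(h.score for h in hits if h.strand == "-")
    strand = "+" if plus > minus else "-" if minus > plus else "?"

    order, order_sum, total = _majority(hits, lambda h: h.lineage.order)
    if order is None or order_sum <= 0.5 * total:
        # no order holds a strict majority: unclassifiable from these hits
        return Classification(element_id=element_id, lineage=None,
                              complete=None, strand=strand,
                              domain_string=_domain_string(hits, strand),
                              pass_no=1, evidence=hits)

    lineage = Lineage(order=order)
    order_hits = [h for h in hits if h.lineage.order == order]
    sf, sf_sum, sf_total = _majority(order_hits, lambda h: h.lineage.superfamily)
    if sf is not None and sf_sum > 0.5 * sf_total:
        lineage = Lineage(order=order, superfamily=sf)
        sf_hits = [h for h in order_hits if h.lineage.superfamily == sf]
        clade, clade_sum, clade_total = _majority(
            sf_hits, lambda h: h.lineage.clade
        )
        if clade is not None and clade_sum > 0.5 * clade_total:
            lineage = Lineage(order=order, superfamily=sf, clade=clade)

    cls = Classification(
        element_id=element_id,
        lineage=lineage,
        complete=None,
        strand=strand,
        domain_string=_domain_string(hits, strand),
        pass_no=1,
        evidence=hits,
    )
    if lineage.superfamily in CANONICAL_DOMAIN_ORDER:
        cls.complete, _ = call_completeness(cls)
    return cls


def call_completeness(cls: Classification) -> tuple[bool, str]:
    """Decide completeness from the presence and order of conserved domains.

    Complete iff all five labels occur exactly once among the retained hits,
    all on one strand, and their 5'->3' order on that strand matches the
    superfamily's canonical order.  Returns (complete, report string).
    """
    if cls.lineage is None or cls.lineage.superfamily is None:
        raise ValueError("completeness requires a superfamily-level lineage")
    canonical = CANONICAL_DOMAIN_ORDER.get(cls.lineage.superfamily)
    if canonical is None:
        return False, f"no canonical domain order for {cls.lineage.superfamily}"

    core = [h for h in cls.evidence if h.domain_label in COMPLETENESS_LABELS]
    counts = {lab: sum(1 for h in core if h.domain_label == lab)
              for lab in COMPLETENESS_LABELS}
    missing = [lab for lab, n in counts.items() if n == 0]
    if missing:
        return False, f"missing domains: {','.join(missing)}"
    duplicated = [lab for lab, n in counts.items() if n > 1]
    if duplicated:
        return False, f"multi-copy domains: {','.join(duplicated)}"
    strands = {h.strand for h in core}
    if len(strands) > 1:
        return False, "domains on both strands"
    strand = strands.pop()
    observed = tuple(
        h.domain_label
        for h in sorted(core, key=lambda h: h.nt_start, reverse=(strand == "-"))
    )
    if observed != canonical:
        return False, (f"order {'-'.join(observed)} differs from canonical "
                       f"{'-'.join(canonical)}")
    return True, "complete: " + "-".join(canonical)


def write_classifications(classifications: Iterable[Classification],
                          tsv_path: Union[str, Path],
                          gff_path: Optional[Union[str, Path]] = None) -> None:
    """Write the per-element TSV report and (optionally) a GFF3 of domain hits.

    Output order is canonicalised by element id, so identical inputs produce
    byte-identical files.
    """
    classifications = sorted(classifications, key=lambda c: c.element_id)
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for cls in classifications:
            lin = cls.lineage
            complete = ("unknown" if cls.complete is None
                        else "yes" if cls.complete else "no")
            fh.write("\t".join([
                cls.element_id,
                lin.order if lin else "Unclassified",
                (lin.superfamily or "") if lin else "",
                (lin.clade or "") if lin else "",
                complete,
                cls.strand,
                cls.domain_string,
                str(cls.pass_no) if cls.is_classified else "-",
            ]) + "\n")
    if gff_path is None:
        return
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cls in classifications:
            for hit in sorted(cls.evidence,
                              key=lambda h: (h.nt_start, h.nt_end)):
                attrs = (f"ID={hit.element_id}:{hit.domain_label}:"
                         f"{hit.nt_start}-{hit.nt_end};"
                         f"lineage={hit.lineage};domain={hit.domain_label};"
                         f"coverage={hit.coverage:.3f};evalue={hit.evalue:.3g}")
                fh.write("\t".join([
                    hit.element_id, "ltrsort", "protein_match",
                    str(hit.nt_start), str(hit.nt_end),
                    f"{hit.score:.1f}", hit.strand, ".", attrs,
                ]) + "\n")
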