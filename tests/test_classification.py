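"""Score-majority lineage aggregation and completeness calling."""

import itertools

import pytest

from ltrsort.classification import (
    CANONICAL_DOMAIN_ORDER,
    call_completeness,
    classify_element,
    write_classifications,
)
from ltrsort.lineage import Lineage
from ltrsort.search import DomainHit


def _hit(label, lineage, score, nt_start=None, strand="+", length=300,
         element_id="el1"):
    nt_start = nt_start if nt_start is not None else 100
    return DomainHit(element_id=element_id, frame=1 if strand == "+" else -1,
                     domain_label=label,
                     lineage=Lineage.from_string(lineage),
                     score=score, evalue=1e-20, coverage=0.9,
                     nt_start=nt_start, nt_end=nt_start + length - 1,
                     strand=strand,
                     profile_name=f"{lineage}:{label}")


def test_unanimous_evidence_gives_clade_and_strand():
    hits = [
        _hit(lab, "LTR/Copia/Ale", 100, nt_start=100 + 900 * i)
        for i, lab in enumerate(["GAG", "AP", "INT", "RT", "RH"])
    ]
    cls = classify_element("el1", hits)
    assert cls.lineage == Lineage.from_string("LTR/Copia/Ale")
    assert cls.strand == "+"
    assert cls.pass_no == 1
    assert cls.complete is True


def test_score_weighted_majority_descends_to_clade():
    # Ale holds 180 of 240 total at the clade level (> 50%)
    hits = [
        _hit("RT", "LTR/Copia/Ale", 100, nt_start=100),
        _hit("RH", "LTR/Copia/Ale", 80, nt_start=600),
        _hit("INT", "LTR/Copia/Tork", 60, nt_start=1100),
    ]
    cls = classify_element("el1", hits)
    assert cls.lineage == Lineage.from_string("LTR/Copia/Ale")


def test_superfamily_tie_stops_at_order():
    hits = [
        _hit("RT", "LTR/Copia/Ale", 100, nt_start=100),
        _hit("RT", "LTR/Gypsy/CRM", 100, nt_start=600),
    ]
    cls = classify_element("el1", hits)
    assert cls.lineage == Lineage(order="LTR")
    assert cls.lineage.superfamily is None
    assert cls.complete is None  # not applicable without a superfamily


def test_clade_minority_stops_at_superfamily():
    hits = [
        _hit("RT", "LTR/Copia/Ale", 100, nt_start=100),
        _hit("RH", "LTR/Copia/Tork", 100, nt_start=600),
    ]
    cls = classify_element("el1", hits)
    assert cls.lineage == Lineage(order="LTR", superfamily="Copia")


def test_empty_hits_is_unclassified_sentinel():
    cls = classify_element("el1", [])
    assert not cls.is_classified
    assert cls.lineage is None
    assert cls.strand == "?"


def test_strand_majority_by_summed_score():
    hits = [
        _hit("RT", "LTR/Copia/Ale", 100, nt_start=100, strand="-"),
        _hit("RH", "LTR/Copia/Ale", 40, nt_start=600, strand="+"),
        _hit("INT", "LTR/Copia/Ale", 30, nt_start=1100, strand="+"),
    ]
    assert classify_element("el1", hits).strand == "-"


# ---- completeness --------------------------------------------------------

def _ordered_hits(labels, strand="+", superfamily="Copia", clade="Ale",
                  element_id="el1"):
    """Place labels left-to-right in 5'->3' order on the given strand."""
    hits = []
    for i, lab in enumerate(labels):
        pos = 100 + 900 * i
        hits.append(_hit(lab, f"LTR/{superfamily}/{clade}", 100,
                         nt_start=pos, strand=strand, element_id=element_id))
    if strand == "-":
        # 5'->3' on minus means decreasing forward coordinates
        hits = [
            _hit(lab, f"LTR/{superfamily}/{clade}", 100,
                 nt_start=100 + 900 * (len(labels) - 1 - i), strand="-",
                 element_id=element_id)
            for i, lab in enumerate(labels)
        ]
    return hits


@pytest.mark.parametrize("superfamily", ["Copia", "Gypsy"])
@pytest.mark.parametrize("strand", ["+", "-"])
def test_exactly_canonical_order_is_complete(superfamily, strand):
    """Over all 5! domain orderings, only the canonical one is complete."""
    canonical = CANONICAL_DOMAIN_ORDER[superfamily]
    clade = "Ale" if superfamily == "Copia" else "CRM"
    n_complete = 0
    for perm in itertools.permutations(canonical):
        cls = classify_element(
            "el1", _ordered_hits(perm, strand=strand,
                                 superfamily=superfamily, clade=clade))
        expected = perm == canonical  # oracle: direct tuple comparison
        assert cls.complete is expected, f"{perm} on {strand}"
        n_complete += cls.complete
    assert n_complete == 1


def test_missing_domain_incomplete():
    cls = classify_element("el1", _ordered_hits(("GAG", "AP", "INT", "RT")))
    assert cls.complete is False
    ok, report = call_completeness(cls)
    assert not ok and "RH" in report


def test_duplicated_domain_incomplete():
    hits = _ordered_hits(("GAG", "AP", "INT", "RT", "RH"))
    hits.append(_hit("RT", "LTR/Copia/Ale", 90, nt_start=6000))
    assert classify_element("el1", hits).complete is False


def test_both_strands_incomplete():
    hits = _ordered_hits(("GAG", "AP", "INT", "RT", "RH"))
    hits[2] = _hit("INT", "LTR/Copia/Ale", 100, nt_start=1900, strand="-")
    assert classify_element("el1", hits).complete is False


def test_completeness_requires_superfamily():
    cls = classify_element("el1", [])
    with pytest.raises(ValueError):
        call_completeness(cls)


# ---- reports -------------------------------------------------------------

def test_write_tsv_and_gff(tmp_path):
    complete = classify_element(
        "elA", _ordered_hits(("GAG", "AP", "INT", "RT", "RH"),
                             element_id="elA"))
    unclassified = classify_element("elB", [])
    tsv, gff = tmp_path / "out.tsv", tmp_path / "out.gff3"
    write_classifications([unclassified, complete], tsv, gff)
    lines = tsv.read_text().splitlines()
    assert lines[0].split("\t") == [
        "element_id", "order", "superfamily", "clade", "complete", "strand",
        "domains", "pass"]
    assert lines[1].split("\t")[:5] == ["elA", "LTR", "Copia", "Ale", "yes"]
    assert lines[1].split("\t")[7] == "1"
    assert lines[2].split("\t")[:2] == ["elB", "Unclassified"]
    assert lines[2].split("\t")[7] == "-"
    gff_lines = gff.read_text().splitlines()
    assert gff_lines[0] == "##gff-version 3"
    assert len(gff_lines) == 6  # five domain features
    assert gff_lines[1].split("\t")[3] == "100"


def test_write_empty_input_header_only(tmp_path):
    tsv = tmp_path / "empty.tsv"
    write_classifications([], tsv)
    assert tsv.read_text().count("\n") == 1


def test_reports_are_byte_deterministic(tmp_path):
    classifications = [
        classify_element("elA", _ordered_hits(("GAG", "AP", "INT", "RT", "RH"),
                                              element_id="elA")),
        classify_element("elB", []),
    ]
    outs = []
    for i in range(2):
        tsv, gff = tmp_path / f"a{i}.tsv", tmp_path / f"a{i}.gff3"
        write_classifications(list(reversed(classifications)) if i else
                              classifications, tsv, gff)
        outs.append(tsv.read_bytes() + gff.read_bytes())
    assert outs[0] == outs[1]
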