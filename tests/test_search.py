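"""Domain search, the coverage/E-value filters, and best-hit resolution."""

import random

import pytest

from ltrsort.lineage import Lineage
from ltrsort.profiles import build_profiles_from_alignments
from ltrsort.records import SequenceRecord
from ltrsort.search import (
    DomainHit,
    RawHit,
    filter_hits,
    make_query_id,
    parse_domain_table,
    resolve_best_hits,
    search_frames,
    split_query_id,
)
from ltrsort.translate import TranslatedFrame, translate_six_frames

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def mini_db():
    rng = random.Random(11)
    base = "".join(rng.choice(AA) for _ in range(100))
    rows = []
    for _ in range(4):
        row = list(base)
        for _ in range(4):
            row[rng.randrange(100)] = rng.choice(AA)
        rows.append("".join(row))
    db = build_profiles_from_alignments({"LTR/Copia/Ale": {"RT": rows}})
    return db, base


def test_query_id_round_trip():
    qid = make_query_id("el|1", -3)
    assert split_query_id(qid) == ("el|1", -3)


def test_search_finds_planted_consensus(mini_db):
    db, consensus = mini_db
    frame = TranslatedFrame(parent_id="el1", frame=1,
                            protein="M" * 10 + consensus + "W" * 10, nt_offset=0)
    hits = search_frames([frame], db)
    assert hits, "exact consensus copy must be found"
    best = max(hits, key=lambda h: h.score)
    assert best.profile_name == "LTR/Copia/Ale:RT"
    span = best.hmm_to - best.hmm_from + 1
    assert span >= 0.95 * db["LTR/Copia/Ale:RT"].model_length


def test_search_all_x_frame_yields_nothing(mini_db):
    db, _ = mini_db
    frame = TranslatedFrame(parent_id="el1", frame=1, protein="X" * 150,
                            nt_offset=0)
    assert search_frames([frame], db) == []


def test_search_empty_frame_list(mini_db):
    db, _ = mini_db
    assert search_frames([], db) == []


# ---- domtblout parsing ---------------------------------------------------

_DOMTBL_ROW = (
    "LTR/Copia/Ale:RT -          100 el1|aaframe=+1 -          120 "
    "1.1e-40 140.0 0.1 1 1 2.2e-42 2.0e-40 139.5 0.1 "
    "10 50 12 52 11 53 0.98 -\n"
)


def test_parse_domain_table_row():
    (hit,) = parse_domain_table([_DOMTBL_ROW])
    assert hit.profile_name == "LTR/Copia/Ale:RT"
    assert hit.query_id == "el1|aaframe=+1"
    assert hit.evalue == 2.0e-40     # i-Evalue, not the full-sequence one
    assert hit.score == 139.5        # per-domain bit score
    assert (hit.hmm_from, hit.hmm_to, hit.aa_from, hit.aa_to) == (10, 50, 12, 52)


def test_parse_domain_table_coverage_downstream(mini_db):
    db, _ = mini_db
    (hit,) = parse_domain_table([_DOMTBL_ROW])
    (dom,) = filter_hits([hit], db, {"el1": 400})
    assert dom.coverage == pytest.approx((50 - 10 + 1) / 100)


def test_parse_domain_table_ignores_comments():
    assert parse_domain_table(["# comment\n", "#\n"]) == []


def test_parse_domain_table_rejects_short_rows():
    with pytest.raises(ValueError, match="row 1"):
        parse_domain_table(["a b c\n"])


# ---- filtering -----------------------------------------------------------

def _raw(evalue, hmm_from=1, hmm_to=100, aa_from=1, aa_to=100, score=50.0):
    return RawHit(query_id="el1|aaframe=+1", profile_name="LTR/Copia/Ale:RT",
                  score=score, evalue=evalue, hmm_from=hmm_from, hmm_to=hmm_to,
                  aa_from=aa_from, aa_to=aa_to)


@pytest.mark.parametrize(
    "hmm_to, evalue, kept",
    [
        (100, 1e-10, True),    # full coverage, strong E-value
        (100, 2e-3, False),    # E-value > 1e-3 discarded
        (19, 1e-10, False),    # coverage 0.19 < 0.20 discarded
        (20, 1e-3, True),      # both exactly at the boundary: kept
    ],
)
def test_filter_boundaries(mini_db, hmm_to, evalue, kept):
    db, _ = mini_db
    hits = filter_hits([_raw(evalue, hmm_from=1, hmm_to=hmm_to)], db,
                       {"el1": 400})
    assert bool(hits) is kept


def test_filter_attaches_lineage_and_nt_coordinates(mini_db):
    db, _ = mini_db
    (dom,) = filter_hits([_raw(1e-9, aa_from=5, aa_to=24)], db, {"el1": 400})
    assert dom.lineage == Lineage(order="LTR", superfamily="Copia", clade="Ale")
    assert (dom.nt_start, dom.nt_end, dom.strand) == (13, 72, "+")
    assert dom.frame == 1


def test_filter_unknown_profile_is_an_error(mini_db):
    db, _ = mini_db
    bad = RawHit(query_id="el1|aaframe=+1", profile_name="nope:RT", score=1.0,
                 evalue=0.0, hmm_from=1, hmm_to=10, aa_from=1, aa_to=10)
    with pytest.raises(KeyError, match="nope"):
        filter_hits([bad], db, {"el1": 400})


def test_filter_is_subset_idempotent_and_monotone(mini_db):
    db, _ = mini_db
    rng = random.Random(5)
    raws = [
        _raw(10 ** rng.uniform(-12, 0), hmm_from=1,
             hmm_to=rng.randint(5, 100),
             aa_from=1, aa_to=rng.randint(5, 100))
        for _ in range(100)
    ]
    kept = filter_hits(raws, db, {"el1": 1000})
    assert len(kept) <= len(raws)
    # looser thresholds keep a superset
    looser = filter_hits(raws, db, {"el1": 1000},
                         min_coverage=0.10, max_evalue=1e-1)
    kept_keys = {(h.nt_start, h.nt_end, h.evalue) for h in kept}
    looser_keys = {(h.nt_start, h.nt_end, h.evalue) for h in looser}
    assert kept_keys <= looser_keys


# ---- best-hit resolution -------------------------------------------------

def _dom(score, nt_start, nt_end, profile="LTR/Copia/Ale:RT", evalue=1e-10):
    return DomainHit(element_id="el1", frame=1, domain_label="RT",
                     lineage=Lineage(order="LTR", superfamily="Copia", clade="Ale"),
                     score=score, evalue=evalue, coverage=1.0,
                     nt_start=nt_start, nt_end=nt_end, strand="+",
                     profile_name=profile)


def oracle_resolve(hits):
    """Independent rank-order scan: a hit survives iff no higher-ranked
    surviving hit overlaps it by more than half the shorter interval."""
    def rank(h):
        return (-h.score, h.evalue, h.profile_name, h.nt_start)

    def conflict(a, b):
        ov = min(a.nt_end, b.nt_end) - max(a.nt_start, b.nt_start) + 1
        return ov > 0.5 * min(a.nt_end - a.nt_start + 1,
                              b.nt_end - b.nt_start + 1)

    survivors = []
    for h in sorted(hits, key=rank):
        if all(not conflict(h, s) for s in survivors):
            survivors.append(h)
    return sorted(survivors, key=rank)


def test_overlapping_hits_keep_highest_score():
    a, b = _dom(120, 100, 400), _dom(90, 150, 450, profile="LTR/Copia/Ale:RH")
    assert resolve_best_hits([a, b]) == [a]


def test_non_overlapping_copies_both_retained():
    a, b = _dom(120, 100, 400), _dom(90, 1000, 1300)
    assert set(resolve_best_hits([a, b])) == {a, b}


def test_single_hit_unchanged():
    a = _dom(50, 10, 100)
    assert resolve_best_hits([a]) == [a]


def test_resolution_matches_oracle_on_random_hit_sets():
    rng = random.Random(6)
    for _ in range(200):
        hits = []
        for i in range(rng.randint(1, 12)):
            start = rng.randint(1, 500)
            hits.append(_dom(
                score=rng.choice([10, 20, 50, 90, 120]) + i * 1e-3,
                nt_start=start, nt_end=start + rng.randint(30, 300),
                profile=f"LTR/Copia/Ale:{rng.choice(['RT', 'RH', 'INT'])}"))
        got = resolve_best_hits(hits)
        expected = oracle_resolve(hits)
        assert sorted(got, key=lambda h: h.nt_start) == sorted(
            expected, key=lambda h: h.nt_start)
        # invariants: subset, pairwise compatible, global best retained
        assert {id(h) for h in got} <= {id(h) for h in hits}
        for i, a in enumerate(got):
            for b in got[i + 1:]:
                ov = min(a.nt_end, b.nt_end) - max(a.nt_start, b.nt_start) + 1
                assert ov <= 0.5 * min(a.nt_end - a.nt_start + 1,
                                       b.nt_end - b.nt_start + 1)
        assert max(hits, key=lambda h: h.score) in got


def test_resolution_rejects_multi_element_input():
    a = _dom(10, 1, 100)
    b = DomainHit(element_id="other", frame=1, domain_label="RT",
                  lineage=a.lineage, score=5, evalue=1e-5, coverage=1.0,
                  nt_start=1, nt_end=100, strand="+", profile_name="p:RT")
    with pytest.raises(ValueError):
        resolve_best_hits([a, b])


def test_end_to_end_search_on_translated_element(mini_db):
    """A nucleotide element carrying the reverse-translated consensus is found
    with correct nucleotide coordinates on both strands."""
    from ltrsort.fixtures import PREFERRED_CODON, _revcomp

    db, consensus = mini_db
    coding = "".join(PREFERRED_CODON[a] for a in consensus)
    pad = "ACGT" * 30
    for strand in "+-":
        seq = pad + coding + pad
        if strand == "-":
            seq = _revcomp(seq)
        rec = SequenceRecord(id="el1", seq=seq)
        raws = search_frames(translate_six_frames(rec), db)
        doms = resolve_best_hits(
            filter_hits(raws, db, {"el1": len(seq)}))
        assert len(doms) == 1
        dom = doms[0]
        assert dom.strand == strand
        assert dom.nt_start >= len(pad) - 30
        assert dom.nt_end <= len(pad) + len(coding) + 30
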