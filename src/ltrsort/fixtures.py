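"""Synthetic planted-domain fixtures: a mini domain database plus a labelled
TE library, so the whole pipeline is testable without any external database.

The generator emulates, at small scale, a curated LTR-retrotransposon
library: each autonomous element is a polyprotein of the five canonical
domains (GAG, AP, INT, RT, RH) reverse-translated into nucleotides in the
superfamily's canonical order, flanked by random intergenic pads, on a
random strand.  Clade structure is planted in amino-acid identity space:
clades within a superfamily diverge from a shared superfamily root (>= 60%
identity), while superfamilies are unrelated (< 30% identity, i.e. random).

Mutational processes that degrade HMM-based classification are applied per
element: point substitutions, single-base indels (frameshifts), whole-domain
deletions, and fully non-autonomous derivatives — contiguous copies of a
sibling's 5' flank with all coding sequence lost — which can only be
recovered by the sequence-similarity rescue pass.

Everything is driven by a single seed; output is byte-identical across runs.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from .lineage import Lineage
from .profiles import ProfileDatabase, build_profiles_from_alignments
from .records import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

#: Most-frequent-codon reverse-translation table (fixed so sibling elements
#: share high nucleotide identity and rescue is exercised deterministically).
PREFERRED_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAC",
}

DEFAULT_CLADES = (
    ("Copia", "Ale"), ("Copia", "Ivana"), ("Copia", "SIRE"), ("Copia", "Tork"),
    ("Gypsy", "CRM"), ("Gypsy", "Reina"), ("Gypsy", "Tekay"), ("Gypsy", "Athila"),
)

DEFAULT_DOMAIN_LENGTHS = {"GAG": 150, "AP": 120, "INT": 280, "RT": 250, "RH": 150}

CANONICAL_ORDER = {
    "Copia": ("GAG", "AP", "INT", "RT", "RH"),
    "Gypsy": ("GAG", "AP", "RT", "RH", "INT"),
}

#: amino-acid divergence of a clade ancestor from its superfamily root
CLADE_DIVERGENCE = 0.15
#: per-row amino-acid noise when building the profile training alignments
ALIGNMENT_NOISE = 0.04
#: rows per training alignment
ALIGNMENT_ROWS = 6
#: in-frame linker (codons) between adjacent domains in the polyprotein
LINKER_CODONS = 5


@dataclass
class FixtureSpec:
    """Parameters of the synthetic planted-domain generator."""

    seed: int = 42
    clades: Sequence[tuple[str, str]] = DEFAULT_CLADES
    domain_length_aa: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_LENGTHS))
    n_elements_per_clade: int = 10
    substitution_rate: float = 0.0
    domain_loss_prob: float = 0.0
    frameshift_prob: float = 0.0
    nonautonomous_fraction: float = 0.0
    intergenic_pad_bp: int = 300

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "domain_loss_prob",
                     "frameshift_prob", "nonautonomous_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        self.clades = tuple((sf, cl) for sf, cl in self.clades)

    def to_json(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["clades"] = [list(c) for c in self.clades]
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FixtureSpec":
        data = json.loads(Path(path).read_text())
        data["clades"] = [tuple(c) for c in data.get("clades", DEFAULT_CLADES)]
        return cls(**data)


@dataclass(frozen=True)
class TruthRow:
    """Ground-truth record for one generated element."""

    element_id: str
    order: str
    superfamily: str
    clade: Optional[str]
    complete: bool
    strand: str
    nonautonomous: bool

    @property
    def lineage(self) -> Lineage:
        # non-autonomous truth stops at superfamily: no domains remain to
        # witness the clade
        return Lineage(order=self.order, superfamily=self.superfamily,
                       clade=None if self.nonautonomous else self.clade)


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _mutate_protein(rng: random.Random, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AMINO_ACIDS if a != out[i]])
    return "".join(out)


def generate_database(spec: FixtureSpec) -> tuple[ProfileDatabase, dict]:
    """Build the mini profile database and return it with the clade ancestors.

    Ancestors map ``(superfamily, clade, domain_label) -> protein``.  Clades
    of one superfamily descend from a shared per-domain root; different
    superfamilies use independent random roots.
    """
    if len(spec.clades) < 2:
        raise ValueError("need at least 2 clades")
    rng = random.Random(spec.seed)
    superfamilies = sorted({sf for sf, _ in spec.clades})
    labels = sorted(spec.domain_length_aa)

    roots = {
        (sf, label): _random_protein(rng, spec.domain_length_aa[label])
        for sf in superfamilies for label in labels
    }
    ancestors: dict[tuple[str, str, str], str] = {}
    alignments: dict[str, dict[str, list[str]]] = {}
    for sf, clade in sorted(spec.clades):
        lineage_path = f"LTR/{sf}/{clade}"
        alignments[lineage_path] = {}
        for label in labels:
            ancestor = _mutate_protein(rng, roots[(sf, label)], CLADE_DIVERGENCE)
            ancestors[(sf, clade, label)] = ancestor
            rows = [
                _mutate_protein(rng, ancestor, ALIGNMENT_NOISE)
                for _ in range(ALIGNMENT_ROWS)
            ]
            alignments[lineage_path][label] = rows
    db = build_profiles_from_alignments(alignments, db_name=f"fixture-{spec.seed}")
    return db, ancestors


def _reverse_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[a] for a in protein)


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def _substitute_dna(rng: random.Random, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_library(spec: FixtureSpec, ancestors: dict) -> tuple[
        list[SequenceRecord], list[TruthRow]]:
    """Generate the labelled element library from the database ancestors.

    Per clade, ``n_elements_per_clade`` elements are emitted; the last
    ``round(nonautonomous_fraction * n)`` of them are non-autonomous copies
    of the clade's first autonomous element's 5' flank.
    """
    rng = random.Random(spec.seed + 1)
    records: list[SequenceRecord] = []
    truth: list[TruthRow] = []
    n_nonaut = round(spec.nonautonomous_fraction * spec.n_elements_per_clade)
    n_aut = spec.n_elements_per_clade - n_nonaut
    if n_nonaut > 0 and n_aut == 0:
        raise ValueError("nonautonomous_fraction leaves no autonomous sibling")

    for sf, clade in sorted(spec.clades):
        order_labels = CANONICAL_ORDER[sf]
        sibling_flank: Optional[str] = None
        for i in range(spec.n_elements_per_clade):
            element_id = f"{sf}_{clade}_{i + 1:03d}"
            nonautonomous = i >= n_aut
            strand = rng.choice("+-")
            if nonautonomous:
                assert sibling_flank is not None
                seq = _substitute_dna(rng, sibling_flank,
                                      min(spec.substitution_rate, 0.10))
                complete = False
            else:
                pad5 = _random_dna(rng, spec.intergenic_pad_bp)
                pad3 = _random_dna(rng, spec.intergenic_pad_bp)
                kept = [label for label in order_labels
                        if label in spec.domain_length_aa
                        and rng.random() >= spec.domain_loss_prob]
                coding_parts = []
                for j, label in enumerate(kept):
                    if j > 0:
                        coding_parts.append(
                            _reverse_translate(
                                _random_protein(rng, LINKER_CODONS)))
                    coding_parts.append(
                        _reverse_translate(ancestors[(sf, clade, label)]))
                coding = "".join(coding_parts)
                if coding and rng.random() < spec.frameshift_prob:
                    pos = rng.randrange(len(coding))
                    if rng.random() < 0.5:
                        coding = coding[:pos] + rng.choice(BASES) + coding[pos:]
                    else:
                        coding = coding[:pos] + coding[pos + 1:]
                seq = _substitute_dna(rng, pad5 + coding + pad3,
                                      spec.substitution_rate)
                if sibling_flank is None:
                    sibling_flank = seq[:spec.intergenic_pad_bp]
                # structural completeness: all five domains retained
                # (substitutions and frameshifts do not remove a domain)
                complete = len(kept) == 5
            if strand == "-":
                seq = _revcomp(seq)
            records.append(SequenceRecord(
                id=element_id, seq=seq, truth_label=f"LTR/{sf}",
            ))
            truth.append(TruthRow(
                element_id=element_id, order="LTR", superfamily=sf,
                clade=clade, complete=complete, strand=strand,
                nonautonomous=nonautonomous,
            ))
    return records, truth


def write_truth(truth: Sequence[TruthRow], path: Union[str, Path]) -> None:
    columns = ("element_id", "order", "superfamily", "clade", "complete",
               "strand", "nonautonomous")
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in truth:
            fh.write("\t".join([
                row.element_id, row.order, row.superfamily, row.clade or "",
                "yes" if row.complete else "no", row.strand,
                "yes" if row.nonautonomous else "no",
            ]) + "\n")


def read_truth(path: Union[str, Path]) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            (element_id, order, sf, clade, complete, strand,
             nonaut) = line.rstrip("\n").split("\t")
            rows.append(TruthRow(
                element_id=element_id, order=order, superfamily=sf,
                clade=clade or None, complete=complete == "yes",
                strand=strand, nonautonomous=nonaut == "yes",
            ))
    return rows


def make_fixture_bundle(spec: FixtureSpec, out_dir: Union[str, Path]) -> dict:
    """Write library FASTA, profile DB (+ metadata TSV), truth TSV and the
    spec itself into *out_dir*; returns the path map."""
    from .records import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db, ancestors = generate_database(spec)
    records, truth = generate_library(spec, ancestors)
    paths = {
        "library": out_dir / "library.fa",
        "hmm": out_dir / "profiles.hmm",
        "metadata": out_dir / "profiles.tsv",
        "truth": out_dir / "truth.tsv",
        "spec": out_dir / "fixture_spec.json",
    }
    write_fasta(records, paths["library"], with_labels=True)
    db.write(paths["hmm"], paths["metadata"])
    write_truth(truth, paths["truth"])
    spec.to_json(paths["spec"])
    return {k: str(v) for k, v in paths.items()}
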