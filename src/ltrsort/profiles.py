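"""The profile-HMM domain database.

A database is a set of profiles, each modelling one conserved protein domain
of one lineage (e.g. the RT domain of LTR/Copia/Ale).  The authoritative
lineage source is a sidecar metadata TSV (columns: profile_name, class,
order, superfamily, clade, domain_label); when no sidecar is present the
profile name itself is parsed with the path grammar of :mod:`ltrsort.lineage`.

Profiles are stored in HMMER3 text format and built with the pyhmmer plan7
builder from per-clade domain alignments, mirroring how curated TE-domain
databases (REXdb/GyDB style) are constructed from clade-wise multiple
alignments of GAG/AP/INT/RT/RH.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pyhmmer
from pyhmmer.easel import Alphabet, TextMSA, TextSequence
from pyhmmer.plan7 import HMM, Background, Builder

from .lineage import Lineage, normalize_domain_label, parse_profile_name

METADATA_COLUMNS = ("profile_name", "class", "order", "superfamily", "clade",
                    "domain_label")

#: Builder RNG seed; fixed so databases are byte-identical across runs.
BUILDER_SEED = 42


@dataclass
class DomainProfile:
    """One profile HMM: a lineage, a domain label, and the model itself."""

    name: str
    domain_label: str
    lineage: Lineage
    model_length: int
    hmm: Optional[HMM] = None

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise ValueError(f"profile {self.name!r}: model_length must be >= 1")


@dataclass
class ProfileDatabase:
    """A named collection of domain profiles with unique names."""

    db_name: str
    profiles: dict[str, DomainProfile] = field(default_factory=dict)
    source: str = "fixture"

    def add(self, profile: DomainProfile) -> None:
        if profile.name in self.profiles:
            raise ValueError(f"duplicate profile name {profile.name!r}")
        self.profiles[profile.name] = profile

    def __len__(self) -> int:
        return len(self.profiles)

    def __contains__(self, name: str) -> bool:
        return name in self.profiles

    def __getitem__(self, name: str) -> DomainProfile:
        return self.profiles[name]

    @property
    def hmms(self) -> list[HMM]:
        out = []
        for name in sorted(self.profiles):
            hmm = self.profiles[name].hmm
            if hmm is None:
                raise ValueError(f"profile {name!r} has no loaded HMM")
            out.append(hmm)
        return out

    # ---- persistence -----------------------------------------------------

    def write(self, hmm_path: Union[str, Path],
              metadata_path: Optional[Union[str, Path]] = None) -> None:
        """Write the HMMER3 text file and (optionally) the metadata sidecar."""
        with open(hmm_path, "wb") as fh:
            for hmm in self.hmms:
                hmm.write(fh)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                fh.write("\t".join(METADATA_COLUMNS) + "\n")
                for name in sorted(self.profiles):
                    p = self.profiles[name]
                    lin = p.lineage
                    fh.write("\t".join([
                        name,
                        lin.te_class or "",
                        lin.order,
                        lin.superfamily or "",
                        lin.clade or "",
                        p.domain_label,
                    ]) + "\n")

    @classmethod
    def from_hmm_file(cls, hmm_path: Union[str, Path],
                      metadata_path: Optional[Union[str, Path]] = None,
                      db_name: Optional[str] = None,
                      source: str = "fixture") -> "ProfileDatabase":
        """Load profiles from a HMMER3 text file.

        Lineage/domain metadata comes from the sidecar TSV when given,
        otherwise from parsing each profile name.
        """
        meta: dict[str, tuple[Lineage, str]] = {}
        if metadata_path is not None:
            meta = read_metadata(metadata_path)
        db = cls(db_name=db_name or Path(hmm_path).stem, source=source)
        with pyhmmer.plan7.HMMFile(str(hmm_path)) as fh:
            for hmm in fh:
                raw = hmm.name
                name = raw.decode() if isinstance(raw, bytes) else str(raw)
                if name in meta:
                    lin, label = meta[name]
                else:
                    lin, label = parse_profile_name(name)
                db.add(DomainProfile(name=name, domain_label=label,
                                     lineage=lin, model_length=hmm.M, hmm=hmm))
        return db


def read_metadata(path: Union[str, Path]) -> dict[str, tuple[Lineage, str]]:
    """Read the sidecar TSV into {profile_name: (lineage, domain_label)}."""
    meta: dict[str, tuple[Lineage, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != METADATA_COLUMNS:
            raise ValueError(
                f"{path}: expected columns {METADATA_COLUMNS}, got {tuple(header)}"
            )
        for line in fh:
            if not line.strip():
                continue
            name, te_class, order, sf, clade, label = line.rstrip("\n").split("\t")
            lin = Lineage(order=order, superfamily=sf or None,
                          clade=clade or None, te_class=te_class or None)
            meta[name] = (lin, normalize_domain_label(label))
    return meta


def build_profiles_from_alignments(
    alignments: Mapping[str, Mapping[str, Sequence[str]]],
    db_name: str = "fixture-db",
    source: str = "fixture",
) -> ProfileDatabase:
    """Build one profile per (lineage, domain) from protein multiple alignments.

    *alignments* maps a lineage path string (e.g. ``"LTR/Copia/Ale"``) to a
    mapping of domain label -> aligned rows (equal-length protein strings,
    '-' for gaps).  The model length is the number of consensus (match)
    columns assigned by the plan7 builder; for an ungapped alignment it equals
    the alignment length.
    """
    abc = Alphabet.amino()
    builder = Builder(abc, seed=BUILDER_SEED)
    background = Background(abc)
    db = ProfileDatabase(db_name=db_name, source=source)
    for lineage_path in sorted(alignments):
        lineage = Lineage.from_string(lineage_path)
        for label in sorted(alignments[lineage_path]):
            rows = list(alignments[lineage_path][label])
            if len(rows) < 2:
                raise ValueError(
                    f"{lineage_path}:{label}: an alignment needs >= 2 rows"
                )
            if len({len(r) for r in rows}) != 1:
                raise ValueError(
                    f"{lineage_path}:{label}: ragged alignment "
                    f"(row lengths {sorted({len(r) for r in rows})})"
                )
            norm_label = normalize_domain_label(label)
            name = f"{lineage_path}:{label if norm_label == 'other' else norm_label}"
            msa = TextMSA(
                name=name.encode(),
                sequences=[
                    TextSequence(name=f"row{i}".encode(), sequence=row)
                    for i, row in enumerate(rows)
                ],
            ).digitize(abc)
            hmm, _, _ = builder.build_msa(msa, background)
            # pin the embedded timestamp so written databases are
            # byte-identical across runs
            hmm.creation_time = datetime.datetime(2020, 1, 1, 0, 0, 0)
            db.add(DomainProfile(
                name=name,
                domain_label=norm_label,
                lineage=lineage,
                model_length=hmm.M,
                hmm=hmm,
            ))
    return db
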