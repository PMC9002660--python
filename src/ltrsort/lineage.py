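"""Hierarchical TE lineages and the profile naming grammar.

A lineage is a path through the TE classification hierarchy:
``class -> order -> superfamily -> clade`` (e.g. Class_I / LTR / Copia / Ale).
Profile names encode a lineage plus a domain label in the grammar

    order[/superfamily[/clade]]:DOMAIN

e.g. ``LTR/Copia/Ale:RT`` or ``LINE:RT``.  Domain labels are normalised to
the five-label vocabulary used for completeness calling (GAG, AP, INT, RT,
RH); anything else maps to ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: Canonical domain-label vocabulary; keys are accepted aliases.
DOMAIN_ALIASES = {
    "GAG": "GAG",
    "AP": "AP",
    "PROT": "AP",  # GyDB-style name for the aspartic proteinase
    "PR": "AP",
    "INT": "INT",
    "IN": "INT",
    "RT": "RT",
    "RH": "RH",
    "RNASEH": "RH",
}

DOMAIN_LABELS = ("GAG", "AP", "INT", "RT", "RH", "other")


class ProfileNameError(ValueError):
    """Raised when a profile name does not match the naming grammar."""


@dataclass(frozen=True, order=True)
class Lineage:
    """A hierarchical classification path.

    ``order`` is always present; ``clade`` requires ``superfamily``.
    """

    order: str
    superfamily: Optional[str] = None
    clade: Optional[str] = None
    te_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("lineage order must be non-empty")
        if self.clade is not None and self.superfamily is None:
            raise ValueError("clade present requires superfamily present")

    @property
    def depth(self) -> str:
        """Deepest defined level: 'order', 'superfamily' or 'clade'."""
        if self.clade is not None:
            return "clade"
        if self.superfamily is not None:
            return "superfamily"
        return "order"

    def truncate(self, level: str) -> "Lineage":
        """Return a copy truncated to at most *level*."""
        if level == "order":
            return Lineage(order=self.order, te_class=self.te_class)
        if level == "superfamily":
            return Lineage(order=self.order, superfamily=self.superfamily,
                           te_class=self.te_class)
        if level == "clade":
            return self
        raise ValueError(f"unknown level: {level!r}")

    def at_level(self, level: str) -> Optional[str]:
        """Category string at *level* (e.g. 'LTR/Copia'), or None if shallower."""
        if level == "order":
            return self.order
        if level == "superfamily":
            if self.superfamily is None:
                return None
            return f"{self.order}/{self.superfamily}"
        if level == "clade":
            if self.clade is None:
                return None
            return f"{self.order}/{self.superfamily}/{self.clade}"
        raise ValueError(f"unknown level: {level!r}")

    def __str__(self) -> str:
        parts = [self.order]
        if self.superfamily is not None:
            parts.append(self.superfamily)
        if self.clade is not None:
            parts.append(self.clade)
        return "/".join(parts)

    @classmethod
    def from_string(cls, text: str, te_class: Optional[str] = None) -> "Lineage":
        """Parse 'LTR', 'LTR/Copia' or 'LTR/Copia/Ale'."""
        parts = [p for p in text.strip().split("/") if p]
        if not parts or len(parts) > 3:
            raise ValueError(f"cannot parse lineage from {text!r}")
        return cls(order=parts[0],
                   superfamily=parts[1] if len(parts) > 1 else None,
                   clade=parts[2] if len(parts) > 2 else None,
                   te_class=te_class)


def normalize_domain_label(label: str) -> str:
    return DOMAIN_ALIASES.get(label.strip().upper(), "other")


def parse_profile_name(name: str, dialect: str = "path") -> tuple[Lineage, str]:
    """Parse a profile name into (lineage, domain label).

    The default 'path' dialect is ``order[/superfamily[/clade]]:DOMAIN``.
    Unknown domain labels map to ``other``.
    """
    if dialect != "path":
        raise ProfileNameError(f"unknown naming dialect {dialect!r}")
    if not name or ":" not in name:
        raise ProfileNameError(
            f"profile name {name!r} does not match grammar "
            "'order[/superfamily[/clade]]:DOMAIN'"
        )
    path, _, raw_label = name.rpartition(":")
    if not path or not raw_label:
        raise ProfileNameError(
            f"profile name {name!r} does not match grammar "
            "'order[/superfamily[/clade]]:DOMAIN'"
        )
    try:
        lineage = Lineage.from_string(path)
    except ValueError as exc:
        raise ProfileNameError(str(exc)) from exc
    return lineage, normalize_domain_label(raw_label)


def render_profile_name(lineage: Lineage, domain_label: str) -> str:
    """Inverse of :func:`parse_profile_name` for the 'path' dialect."""
    return f"{lineage}:{domain_label}"
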