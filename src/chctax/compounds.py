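"""Canonical representation of acyclic cuticular hydrocarbons (CHCs).

Insect cuticular hydrocarbons fall into a small number of structural
classes: straight-chain alkanes (n-CN), monoenes with one double bond
(d-CN:1), and alkanes carrying one or two methyl branches (x-meCN,
x,y-dimeCN).  The shorthand grammar used throughout this package follows
the abbreviations conventional in the CHC literature, e.g. ``n-C_25``,
``9-C_27:1``, ``3-meC_25``, ``9,13-dimeC_29``.  An unknown branch
position is written ``X`` and kept explicit rather than guessed.

Double-bond positions are stored exactly as named, i.e. numbered from
the nearer chain terminus ("7-pentacosene" has the double bond between
carbons 7 and 8).  They are deliberately not re-canonicalised to IUPAC
lowest-locant numbering from the far end, because the dimethyl
disulfide (DMDS) localisation arithmetic in :mod:`chctax.fragments`
uses the nearer-terminus position directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "CHCClass",
    "CHCompound",
    "ComponentNameError",
    "parse_component_name",
    "format_component_name",
    "total_carbons",
]


class CHCClass:
    """String constants for the four hydrocarbon classes handled here."""

    N_ALKANE = "n_alkane"
    ALKENE = "alkene"
    MONOMETHYL = "monomethyl"
    DIMETHYL = "dimethyl"

    ALL = (N_ALKANE, ALKENE, MONOMETHYL, DIMETHYL)


#: number of methyl branches implied by each class
_METHYL_COUNT = {
    CHCClass.N_ALKANE: 0,
    CHCClass.ALKENE: 0,
    CHCClass.MONOMETHYL: 1,
    CHCClass.DIMETHYL: 2,
}


class ComponentNameError(ValueError):
    """Raised when a component label does not follow the CHC grammar."""


@dataclass(frozen=True)
class CHCompound:
    """One acyclic cuticular hydrocarbon.

    Parameters
    ----------
    label:
        Shorthand name, e.g. ``"3-meC_25"``.
    chc_class:
        One of :class:`CHCClass` constants.
    chain_length:
        Carbons in the main (longest unbranched) chain.
    methyl_positions:
        Branch carbon numbers; ``None`` marks an unknown ("X") position.
    double_bond_positions:
        Monoene double-bond position(s), numbered from the nearer
        terminus.  At most one entry (dienes are out of scope).
    """

    label: str
    chc_class: str
    chain_length: int
    methyl_positions: tuple[Optional[int], ...] = field(default=())
    double_bond_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.chc_class not in CHCClass.ALL:
            raise ComponentNameError(f"unknown CHC class {self.chc_class!r}")
        if self.chain_length < 1:
            raise ComponentNameError("chain_length must be >= 1")
        expected = _METHYL_COUNT[self.chc_class]
        if len(self.methyl_positions) != expected:
            raise ComponentNameError(
                f"{self.chc_class} requires {expected} methyl position(s), "
                f"got {len(self.methyl_positions)}"
            )
        for x in self.methyl_positions:
            if x is not None and not (2 <= x <= self.chain_length - 1):
                raise ComponentNameError(
                    f"methyl position {x} outside 2..{self.chain_length - 1}"
                )
        if self.chc_class == CHCClass.ALKENE:
            if len(self.double_bond_positions) != 1:
                raise ComponentNameError("alkenes carry exactly one double bond")
            d = self.double_bond_positions[0]
            if not (1 <= d <= self.chain_length - 1):
                raise ComponentNameError(
                    f"double-bond position {d} outside 1..{self.chain_length - 1}"
                )
        elif self.double_bond_positions:
            raise ComponentNameError(
                f"{self.chc_class} cannot carry double bonds"
            )

    @property
    def has_unknown_positions(self) -> bool:
        """True if any methyl branch position is unknown ("X")."""
        return any(x is None for x in self.methyl_positions)

    @property
    def known_methyl_positions(self) -> tuple[int, ...]:
        return tuple(x for x in self.methyl_positions if x is not None)

    @property
    def is_saturated(self) -> bool:
        return not self.double_bond_positions


# label grammar: "n-C{n}", "{d}-C{n}:1", "{x}-meC{n}", "{x},{y}-dimeC{n}";
# underscores around the chain number (subscript markers) are optional.
_RE_ALKANE = re.compile(r"^n-C_?(\d+)_?$")
_RE_ALKENE = re.compile(r"^(\d+)-C_?(\d+):1_?$")
_RE_MONOME = re.compile(r"^(\d+|X)-meC_?(\d+)_?$")
_RE_DIME = re.compile(r"^(\d+|X),(\d+|X)-dimeC_?(\d+)_?$")


def _pos(tok: str) -> Optional[int]:
    return None if tok == "X" else int(tok)


def parse_component_name(label: str) -> CHCompound:
    """Parse a shorthand CHC label into a :class:`CHCompound`.

    >>> parse_component_name("9-C_27:1").double_bond_positions
    (9,)

    Raises
    ------
    ComponentNameError
        If the label does not match the grammar, naming the offending
        token.
    """
    name = label.strip()
    if m := _RE_ALKANE.match(name):
        return CHCompound(name, CHCClass.N_ALKANE, int(m.group(1)))
    if m := _RE_ALKENE.match(name):
        return CHCompound(
            name, CHCClass.ALKENE, int(m.group(2)),
            double_bond_positions=(int(m.group(1)),),
        )
    if m := _RE_MONOME.match(name):
        return CHCompound(
            name, CHCClass.MONOMETHYL, int(m.group(2)),
            methyl_positions=(_pos(m.group(1)),),
        )
    if m := _RE_DIME.match(name):
        return CHCompound(
            name, CHCClass.DIMETHYL, int(m.group(3)),
            methyl_positions=(_pos(m.group(1)), _pos(m.group(2))),
        )
    raise ComponentNameError(f"cannot parse component label {label!r}")


def format_component_name(c: CHCompound) -> str:
    """Canonical shorthand label for a compound (underscore style)."""
    if c.chc_class == CHCClass.N_ALKANE:
        return f"n-C_{c.chain_length}"
    if c.chc_class == CHCClass.ALKENE:
        return f"{c.double_bond_positions[0]}-C_{c.chain_length}:1"
    pos = ",".join("X" if x is None else str(x) for x in c.methyl_positions)
    if c.chc_class == CHCClass.MONOMETHYL:
        return f"{pos}-meC_{c.chain_length}"
    return f"{pos}-dimeC_{c.chain_length}"


def total_carbons(c: CHCompound) -> int:
    """Total carbon count: main chain plus one per methyl branch."""
    return c.chain_length + len(c.methyl_positions)
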