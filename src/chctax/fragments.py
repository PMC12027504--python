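"""Nominal-mass EI and DMDS-adduct fragment prediction for CHCs.

Identification of cuticular hydrocarbons from GC-MS rests on three
pieces of arithmetic, all at nominal (integer) mass with CH2 = 14:

* **Molecular ions.**  A saturated compound with ``T`` total carbons has
  nominal mass ``14*T + 2``; a monoene has ``14*T``.

* **Methyl-branch diagnostic ions.**  Electron-impact cleavage is
  favoured at the bonds flanking a branch carbon (secondary carbenium
  sites).  For each such bond, both charged fragments are possible; a
  fragment containing ``m`` carbons (counting any attached branch
  methyls) appears as an even-mass ion ``14*m`` (alkene-type, after H
  transfer) and/or an odd-mass ion ``14*m + 1`` (alkyl cation).  Both
  parities are predicted here because published tables mix the two.
  Loss of the branch methyl gives M-15 for every branched alkane, and
  3-methyl compounds additionally lose an ethyl radical (M-29).

* **DMDS localisation of double bonds.**  Dimethyl disulfide adds one
  thiomethyl (SCH3, +47) to each olefinic carbon (+94 total).  EI
  cleavage between the two derivatised carbons of a ``d``-ene on an
  ``n``-carbon chain yields the pair ``14*d + 47`` (carbons 1..d plus
  one SCH3) and its complement; the pair sums to the adduct ion
  ``14*n + 94``.  Observing the pair therefore pins down ``d``, and
  :func:`locate_double_bond` inverts the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .compounds import CHCClass, CHCompound, total_carbons

__all__ = [
    "ALKENE_SERIES_IONS",
    "FragmentIon",
    "IonSet",
    "DmdsAdduct",
    "UnknownPositionError",
    "DoubleBondAmbiguityError",
    "molecular_ion",
    "methyl_diagnostic_ions",
    "dmds_fragments",
    "locate_double_bond",
    "annotate_peak",
]

#: Homologous CnH2n-1 series ions (83, 97, 111) seen for every alkene;
#: class evidence only -- they carry no information about the double-bond
#: position and are treated as a fixed alkene signature.
ALKENE_SERIES_IONS = frozenset({83, 97, 111})


class UnknownPositionError(ValueError):
    """Fragment prediction requested for an unknown ("X") branch position."""


class DoubleBondAmbiguityError(ValueError):
    """DMDS inversion found no unique double-bond position."""

    def __init__(self, message: str, candidates: Sequence[int] = ()):
        super().__init__(message)
        self.candidates = tuple(candidates)


@dataclass(frozen=True)
class FragmentIon:
    """One branch-flanking cleavage fragment (both mass parities).

    ``bond`` is the cleaved C-C bond as a pair of main-chain carbon
    numbers; ``side`` is ``"low"`` (carbons 1..a) or ``"high"``
    (carbons a+1..n); ``carbons`` counts chain carbons plus attached
    branch methyls in the charged fragment.
    """

    bond: tuple[int, int]
    side: str
    carbons: int
    branch_methyls: int
    mz_even: int
    mz_odd: int


@dataclass(frozen=True)
class IonSet:
    """Predicted nominal-mass EI ions for one compound."""

    compound: CHCompound
    molecular_ion: int
    predicted_mz: frozenset[int]
    fragments: tuple[FragmentIon, ...] = ()

    def __contains__(self, mz: int) -> bool:
        return mz in self.predicted_mz


@dataclass(frozen=True)
class DmdsAdduct:
    """Mono-DMDS adduct of a monoene and its diagnostic cleavage pair."""

    chain_length: int
    double_bond_position: int
    adduct_ion: int
    fragment_low: int
    fragment_high: int


def molecular_ion(c: CHCompound) -> int:
    """Nominal molecular mass: 14*T+2 saturated, 14*T for a monoene."""
    if c.has_unknown_positions:
        raise UnknownPositionError(
            f"{c.label}: molecular ion not predicted for unknown branch positions"
        )
    t = total_carbons(c)
    return 14 * t + 2 if c.is_saturated else 14 * t


def _fragment_carbons(c: CHCompound, bond_low_carbon: int, side: str) -> tuple[int, int]:
    """(chain carbons, attached methyls) of the charged fragment."""
    positions = c.known_methyl_positions
    if side == "low":
        chain = bond_low_carbon
        methyls = sum(1 for x in positions if x <= bond_low_carbon)
    else:
        chain = c.chain_length - bond_low_carbon
        methyls = sum(1 for x in positions if x > bond_low_carbon)
    return chain, methyls


def methyl_diagnostic_ions(c: CHCompound) -> IonSet:
    """Diagnostic EI ions of a mono- or dimethyl-branched alkane.

    For every bond flanking every branch carbon, both charged fragments
    are emitted in even (``14*m``) and odd (``14*m + 1``) variants, plus
    M-15 always and M-29 when a methyl sits at carbon 3.  Matching
    against an observed spectrum must be subset-based.
    """
    if c.chc_class not in (CHCClass.MONOMETHYL, CHCClass.DIMETHYL):
        raise ValueError(f"{c.label}: not a methyl-branched alkane")
    if c.has_unknown_positions:
        raise UnknownPositionError(
            f"{c.label}: branch position unknown ('X'); fragments not predicted"
        )
    mion = molecular_ion(c)
    mz: set[int] = {mion, mion - 15}
    if 3 in c.methyl_positions:
        mz.add(mion - 29)  # ethyl loss characteristic of 3-methyl compounds
    fragments: list[FragmentIon] = []
    for x in sorted(set(c.known_methyl_positions)):
        for a in (x - 1, x):  # bonds (x-1, x) and (x, x+1)
            if not (1 <= a <= c.chain_length - 1):
                continue
            for side in ("low", "high"):
                chain, methyls = _fragment_carbons(c, a, side)
                m = chain + methyls
                frag = FragmentIon(
                    bond=(a, a + 1), side=side, carbons=m,
                    branch_methyls=methyls, mz_even=14 * m, mz_odd=14 * m + 1,
                )
                fragments.append(frag)
                mz.update((frag.mz_even, frag.mz_odd))
    return IonSet(c, mion, frozenset(mz), tuple(fragments))


def predicted_ions(c: CHCompound) -> IonSet:
    """Predicted IonSet for any catalog compound.

    n-alkanes predict their molecular ion; alkenes predict the molecular
    ion plus the fixed 83/97/111 series; branched alkanes with known
    positions use :func:`methyl_diagnostic_ions`.  Compounds with an
    unknown branch position get an empty prediction (never imputed).
    """
    if c.chc_class == CHCClass.N_ALKANE:
        m = molecular_ion(c)
        return IonSet(c, m, frozenset({m}))
    if c.chc_class == CHCClass.ALKENE:
        m = molecular_ion(c)
        return IonSet(c, m, frozenset({m}) | ALKENE_SERIES_IONS)
    if c.has_unknown_positions:
        return IonSet(c, 0, frozenset())
    return methyl_diagnostic_ions(c)


def dmds_fragments(chain: int, d: int) -> DmdsAdduct:
    """Mono-DMDS adduct ion and cleavage pair for a ``d``-ene of ``chain`` carbons."""
    if not (2 <= d <= chain - 2):
        raise ValueError(f"double-bond position {d} outside 2..{chain - 2}")
    adduct = 14 * chain + 94
    low = 14 * d + 47
    return DmdsAdduct(chain, d, adduct, low, adduct - low)


def locate_double_bond(chain: int, observed_fragments: Iterable[int]) -> int:
    """Invert the DMDS rule: infer ``d`` from observed adduct fragments.

    Candidate positions run over the nearer-terminus range
    ``2 <= d <= chain // 2`` (positions beyond the midpoint name the
    same molecule from the far end).  A candidate is consistent if at
    least one of its predicted pair is observed; candidates whose whole
    pair is observed are preferred.  The shared adduct ion itself is
    uninformative and ignored.
    """
    observed = set(observed_fragments)
    adduct = 14 * chain + 94
    observed.discard(adduct)
    scored: list[tuple[int, int]] = []  # (matches, d)
    for d in range(2, chain // 2 + 1):
        pair = dmds_fragments(chain, d)
        matches = sum(1 for mz in (pair.fragment_low, pair.fragment_high) if mz in observed)
        if matches:
            scored.append((matches, d))
    if not scored:
        raise DoubleBondAmbiguityError(
            f"no double-bond position in 2..{chain // 2} consistent with "
            f"fragments {sorted(observed)} on a C{chain} chain"
        )
    best = max(m for m, _ in scored)
    winners = [d for m, d in scored if m == best]
    if len(winners) > 1:
        raise DoubleBondAmbiguityError(
            f"ambiguous double-bond position on C{chain}: candidates {winners}",
            candidates=winners,
        )
    return winners[0]


@dataclass(frozen=True)
class PeakCandidate:
    """One ranked identification candidate from :func:`annotate_peak`."""

    peak_no: int
    compound: CHCompound
    ion_score: float
    ki_difference: float


def annotate_peak(ki, observed_ions, catalog, ki_tolerance=15.0):
    """Rank catalog compounds against an observed peak.

    Candidates within ``ki_tolerance`` index units are ranked by the
    fraction of observed ions contained in their predicted ion set,
    ties broken by smaller KI difference, then lower peak number.  An
    empty list is a valid result.
    """
    observed = set(observed_ions)
    candidates: list[PeakCandidate] = []
    for entry in catalog:
        diff = abs(entry.ki - ki)
        if diff > ki_tolerance:
            continue
        ions = predicted_ions(entry.compound)
        score = (
            len(observed & ions.predicted_mz) / len(observed) if observed else 0.0
        )
        candidates.append(PeakCandidate(entry.peak_no, entry.compound, score, diff))
    candidates.sort(key=lambda c: (-c.ion_score, c.ki_difference, c.peak_no))
    return candidates
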