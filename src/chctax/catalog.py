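"""Bundled reference data for *Ips subelongatus* elytral CHCs.

Two small CSV fixtures ship with the package:

``elytra_chc_catalog.csv``
    The 30 GC peaks identified on *I. subelongatus* elytra, in elution
    order: retention time, retention index, shorthand label, published
    diagnostic EI ions, and male/female mean relative percentages
    (+/- SE, N = 30 males / 28 females).

``population_profiles.csv``
    Mean relative percentage (+/- SE) of each component in six
    geographic populations from northeastern China (MJHL, WDLN, GHIM,
    YCHL, EDJL, ARIM); ``nd`` marks components below detection.

Both are transcriptions of published summary tables and drive the
fixture-based tests as well as the synthetic-data generator defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Optional

import pandas as pd

from .compounds import CHCompound, parse_component_name

__all__ = [
    "CatalogEntry",
    "ComponentCatalog",
    "load_catalog",
    "load_population_profiles",
    "POPULATIONS",
    "POPULATION_N",
    "ALT_LABELS",
    "UNEXPLAINED_IONS",
]

#: population labels in table order
POPULATIONS = ("MJHL", "WDLN", "GHIM", "YCHL", "EDJL", "ARIM")

#: individuals sampled per population (ARIM limited to six by availability)
POPULATION_N = {"MJHL": 10, "WDLN": 12, "GHIM": 10, "YCHL": 8, "EDJL": 12, "ARIM": 6}

#: Conflicting published names for the same peak: the sex-resolved table
#: names peak 25 "7-C_31:1" (7-hentriacontene) while the population table
#: lists it as "9-C_31:1".  The catalog follows the sex-resolved table
#: (double bond at carbon 7); the alternative is recorded, not merged.
ALT_LABELS = {25: "9-C_31:1"}

#: Published diagnostic ions that the flanking-cleavage mass rules cannot
#: produce, recorded verbatim but excluded from prediction:
#:   peak 17 (7-C_29:1): 71 -- not part of the homologous alkene series;
#:   peak 27 (7-meC_31): 436 -- equals unbranched C31 mass (14*31+2), not a
#:     cleavage product of 7-methylhentriacontane (M=450, M-15=435);
#:   peak 30 (5,17-dimeC_31): 126, 168 -- 9- and 12-carbon fragments that no
#:     bond flanking branch 5 or 17 yields; plausibly secondary fragments.
UNEXPLAINED_IONS: dict[int, frozenset[int]] = {
    17: frozenset({71}),
    27: frozenset({436}),
    30: frozenset({126, 168}),
}


@dataclass(frozen=True)
class CatalogEntry:
    """One catalogued GC peak."""

    peak_no: int
    compound: CHCompound
    retention_time: float
    ki: int
    diagnostic_ions: tuple[int, ...]
    male_mean: float
    male_se: float
    female_mean: float
    female_se: float
    sex_difference: Optional[str] = None  # e.g. "male**", "female*"

    @property
    def label(self) -> str:
        return self.compound.label


class ComponentCatalog:
    """Ordered catalog of the 30 elytral CHC peaks."""

    def __init__(self, entries: list[CatalogEntry]):
        peaks = [e.peak_no for e in entries]
        if peaks != list(range(1, len(entries) + 1)):
            raise ValueError("peak numbers must be unique and contiguous from 1")
        rts = [e.retention_time for e in entries]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("catalog entries must be in retention order")
        self.entries = tuple(entries)
        self._by_label = {e.label: e for e in entries}

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key) -> CatalogEntry:
        if isinstance(key, str):
            return self._by_label[key]
        return self.entries[key - 1]  # by peak number

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    def compounds(self) -> tuple[CHCompound, ...]:
        return tuple(e.compound for e in self.entries)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.compound.chc_class] = counts.get(e.compound.chc_class, 0) + 1
        return counts

    def alkane_ladder_components(self) -> list[tuple[str, float]]:
        return [(e.label, e.retention_time) for e in self.entries]


def _data_path(name: str):
    return resources.files("chctax.data").joinpath(name)


def load_catalog() -> ComponentCatalog:
    """Load the bundled 30-component reference catalog."""
    with resources.as_file(_data_path("elytra_chc_catalog.csv")) as p:
        df = pd.read_csv(p, dtype={"sex_diff": "string"})
    entries = []
    for row in df.itertuples(index=False):
        compound = parse_component_name(row.label)
        ions = tuple(int(x) for x in str(row.diagnostic_ions).split(";"))
        sexdiff = None if pd.isna(row.sex_diff) else str(row.sex_diff)
        entries.append(
            CatalogEntry(
                peak_no=int(row.peak_no),
                compound=compound,
                retention_time=float(row.rt_min),
                ki=int(row.ki),
                diagnostic_ions=ions,
                male_mean=float(row.male_mean),
                male_se=float(row.male_se),
                female_mean=float(row.female_mean),
                female_se=float(row.female_se),
                sex_difference=sexdiff,
            )
        )
    return ComponentCatalog(entries)


def load_population_profiles() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load the six-population mean profile fixture.

    Returns
    -------
    means, ses, detected:
        DataFrames indexed by component label with one column per
        population.  ``nd`` cells become mean 0, SE 0, detected False.
    """
    with resources.as_file(_data_path("population_profiles.csv")) as p:
        df = pd.read_csv(p)
    df = df.set_index("label")
    means = pd.DataFrame(index=df.index, columns=list(POPULATIONS), dtype=float)
    ses = means.copy()
    detected = pd.DataFrame(True, index=df.index, columns=list(POPULATIONS))
    for pop in POPULATIONS:
        mcol, scol = df[f"{pop}_mean"], df[f"{pop}_se"]
        nd = mcol.astype(str).str.strip() == "nd"
        means[pop] = pd.to_numeric(mcol, errors="coerce").fillna(0.0)
        ses[pop] = pd.to_numeric(scol, errors="coerce").fillna(0.0)
        detected[pop] = ~nd
    return means, ses, detected
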