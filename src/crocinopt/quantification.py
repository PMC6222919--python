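"""Crocin quantification from 440 nm peak areas.

Individual crocins are quantified without authentic standards by
combining their percentage peak areas at 440 nm with the isomer-class
extinction coefficients:

    c_i (mg/g) = Mw_i * E1%1cm(440 nm) * A_i / eps

where Mw_i is the molecular weight of crocin i, A_i its percentage of
the total integrated 440 nm area, E1%1cm(440 nm) the ISO-3632 coloring
strength of the saffron sample (dry basis, dimensionless) and eps the
extinction coefficient: 89,000 M^-1 cm^-1 for trans-crocins and
63,350 M^-1 cm^-1 for cis-crocins.  The relation is applied exactly as
printed in the source method (the units do not reduce transparently;
the formula is an empirically validated convention, not a derivation).

Molecular weights follow from the crocetin core (328.40 g/mol) plus
162.14 g/mol per anhydroglucose unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CROCETIN_MW",
    "GLUCOSE_UNIT_MW",
    "EXTINCTION",
    "CrocinSpec",
    "QuantRecord",
    "BUILTIN_CROCINS",
    "crocin_molecular_weight",
    "extinction_coefficient",
    "quantify",
    "quantify_table",
]

CROCETIN_MW = 328.40  # g/mol, crocetin dicarboxylic acid core
GLUCOSE_UNIT_MW = 162.14  # g/mol per anhydroglucose unit
EXTINCTION = {"trans": 89_000.0, "cis": 63_350.0}  # M^-1 cm^-1 at 440 nm


def crocin_molecular_weight(n_glucose: int) -> float:
    """Mw of a crocetin ester with ``n_glucose`` glucose units."""
    if not 1 <= n_glucose <= 5:
        raise ValueError("crocins carry 1 to 5 glucose units")
    return CROCETIN_MW + GLUCOSE_UNIT_MW * n_glucose


def extinction_coefficient(isomer: str) -> float:
    try:
        return EXTINCTION[isomer]
    except KeyError:
        raise ValueError(
            f"unknown isomer {isomer!r}: expected 'trans' or 'cis'"
        ) from None


@dataclass(frozen=True)
class CrocinSpec:
    abbreviation: str  # e.g. "t-4GG"
    isomer: str  # "trans" | "cis"
    n_glucose: int
    Mw: float | None = None  # override; defaults to the core+sugar formula

    @property
    def molecular_weight(self) -> float:
        return self.Mw if self.Mw is not None else crocin_molecular_weight(self.n_glucose)


@dataclass(frozen=True)
class QuantRecord:
    abbreviation: str
    concentration: float  # mg/g


# Named crocins of the separation study, keyed by the field's shorthand
# (isomer prefix t/c, number of glucose units, sugar moiety letters).
BUILTIN_CROCINS: dict[str, CrocinSpec] = {
    s.abbreviation: s
    for s in (
        CrocinSpec("t-5tG", "trans", 5),
        CrocinSpec("t-5nG", "trans", 5),
        CrocinSpec("t-4GG", "trans", 4),
        CrocinSpec("t-4ng", "trans", 4),
        CrocinSpec("t-3Gg", "trans", 3),
        CrocinSpec("t-2gg", "trans", 2),
        CrocinSpec("t-2G", "trans", 2),
        CrocinSpec("t-1g", "trans", 1),
        CrocinSpec("c-4GG", "cis", 4),
        CrocinSpec("c-3Gg", "cis", 3),
        CrocinSpec("c-2gg", "cis", 2),
        CrocinSpec("c-2G", "cis", 2),
    )
}


def quantify(spec: CrocinSpec, coloring_strength: float, area_pct: float) -> QuantRecord:
    """Concentration of one crocin from its percentage area.

    ``coloring_strength`` is E1%1cm(440 nm); ``area_pct`` is the percent
    of the total integrated 440 nm area (0..100).
    """
    if coloring_strength <= 0:
        raise ValueError("coloring strength must be positive")
    if not 0 <= area_pct <= 100:
        raise ValueError("percentage area must lie in [0, 100]")
    eps = extinction_coefficient(spec.isomer)
    c = spec.molecular_weight * coloring_strength * area_pct / eps
    return QuantRecord(abbreviation=spec.abbreviation, concentration=c)


def quantify_table(
    peak_table: pd.DataFrame,
    coloring_strength: float,
    assignments: dict[str, CrocinSpec] | None = None,
) -> list[QuantRecord]:
    """Quantify every assigned analyte of a 440 nm peak table.

    ``peak_table`` needs columns ``abbreviation`` and ``area`` (raw
    areas; percentages are taken over the summed area of all integrated
    peaks, so any common scale factor cancels).  Analytes without an
    assignment are skipped with a warning.
    """
    if assignments is None:
        assignments = BUILTIN_CROCINS
    if len(peak_table) == 0:
        raise ValueError("empty peak table")
    total = float(peak_table["area"].sum())
    if total <= 0:
        raise ValueError("total peak area must be positive")
    records = []
    for row in peak_table.itertuples():
        spec = assignments.get(str(row.abbreviation))
        if spec is None:
            warnings.warn(
                f"no crocin assignment for peak {row.abbreviation!r}; skipped",
                stacklevel=2,
            )
            continue
        area_pct = 100.0 * float(row.area) / total
        records.append(quantify(spec, coloring_strength, area_pct))
    return records
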