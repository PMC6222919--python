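"""Three-level full-factorial design of experiments for gradient separations.

The separation is optimized over three factors: column temperature T
(degC), gradient duration t_g (min, time of the first linear eluent
segment) and eluent flow rate phi (mL/min).  The calibration design is
the 27-point full factorial on coded levels {-1, 0, 1}; eight external
validation points sit at the centers of the eight cubic subspaces of
the domain, i.e. at coded (+-0.5, +-0.5, +-0.5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "default_factors",
    "full_factorial",
    "external_subcube_centers",
    "campaign_design",
    "code_levels",
    "decode_levels",
    "design_to_frame",
    "design_from_frame",
]

FACTOR_NAMES = ("T", "t_g", "phi")


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three design levels (natural units)."""

    name: str
    unit: str
    low: float
    mid: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < mid < high, "
                f"got {self.low}, {self.mid}, {self.high}"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def code(self, natural: float) -> float:
        """Map a natural value to the coded scale (low -> -1, high -> +1)."""
        return (natural - self.mid) / self.half_range

    def decode(self, coded: float) -> float:
        # anchored at `low` so the design levels come out floating-point exact
        return self.low + (coded + 1.0) * self.half_range


@dataclass(frozen=True)
class DesignPoint:
    """One separation condition of the campaign."""

    id: str
    T: float
    t_g: float
    phi: float
    coded: tuple[float, float, float]
    role: str  # "calibration" | "external"
    replicate: bool = False

    @property
    def natural(self) -> tuple[float, float, float]:
        return (self.T, self.t_g, self.phi)


def default_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """The study domain: T 25-35 degC, t_g 8-12 min, phi 0.6-1.0 mL/min."""
    return (
        FactorSpec("T", "degC", 25.0, 30.0, 35.0),
        FactorSpec("t_g", "min", 8.0, 10.0, 12.0),
        FactorSpec("phi", "mL/min", 0.6, 0.8, 1.0),
    )


def _check_factors(factors) -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(f"exactly three factors required, got {len(factors)}")
    names = tuple(f.name for f in factors)
    if names != FACTOR_NAMES:
        raise ValueError(f"factors must be named {FACTOR_NAMES} in order, got {names}")
    return factors


def code_levels(natural: tuple[float, float, float], factors) -> tuple[float, ...]:
    """Natural (T, t_g, phi) -> coded triple in [-1, 1]."""
    factors = _check_factors(factors)
    return tuple(f.code(x) for f, x in zip(factors, natural))

def decode_levels(coded: tuple[float, float, float], factors) -> tuple[float, ...]:
    """Coded triple -> natural (T, t_g, phi)."""
    factors = _check_factors(factors)
    return tuple(f.decode(c) for f, c in zip(factors, coded))


def _make_point(coded, factors, role, idx, replicate=False) -> DesignPoint:
    T, t_g, phi = decode_levels(coded, factors)
    prefix = {"calibration": "C", "external": "E"}[role]
    suffix = "r" if replicate else ""
    return DesignPoint(
        id=f"{prefix}{idx:02d}{suffix}",
        T=T,
        t_g=t_g,
        phi=phi,
        coded=tuple(float(c) for c in coded),
        role=role,
        replicate=replicate,
    )


def full_factorial(factors) -> list[DesignPoint]:
    """All 27 combinations of the three coded levels {-1, 0, 1}.

    Ordering is lexicographic in coded (T, t_g, phi) with T slowest and
    phi fastest, so run ids are stable across invocations.
    """
    factors = _check_factors(factors)
    points = []
    for idx, coded in enumerate(itertools.product((-1.0, 0.0, 1.0), repeat=3), 1):
        points.append(_make_point(coded, factors, "calibration", idx))
    return points


def external_subcube_centers(factors) -> list[DesignPoint]:
    """The 8 subcube-center validation points at coded (+-0.5, +-0.5, +-0.5)."""
    factors = _check_factors(factors)
    points = []
    for idx, coded in enumerate(itertools.product((-0.5, 0.5), repeat=3), 1):
        points.append(_make_point(coded, factors, "external", idx))
    return points


def campaign_design(factors, center_replicates: int = 2) -> list[DesignPoint]:
    """Full campaign: 27 factorial runs + center replicates + 8 external runs.

    With the default 2 extra center-point runs the calibration block has
    29 chromatograms, so 21 pair resolutions per run give 609 calibration
    samples and the 8 external runs give 168.
    """
    factors = _check_factors(factors)
    points = full_factorial(factors)
    for k in range(center_replicates):
        points.append(_make_point((0.0, 0.0, 0.0), factors, "calibration",
                                  28 + k, replicate=True))
    points.extend(external_subcube_centers(factors))
    return points


def design_to_frame(points: list[DesignPoint]) -> pd.DataFrame:
    """Tabular form of a design (the CSV artifact of the pipeline)."""
    return pd.DataFrame(
        {
            "id": [p.id for p in points],
            "role": [p.role for p in points],
            "replicate": [p.replicate for p in points],
            "T_C": [p.T for p in points],
            "tg_min": [p.t_g for p in points],
            "phi_mL_min": [p.phi for p in points],
            "coded_T": [p.coded[0] for p in points],
            "coded_tg": [p.coded[1] for p in points],
            "coded_phi": [p.coded[2] for p in points],
        }
    )


def design_from_frame(df: pd.DataFrame) -> list[DesignPoint]:
    return [
        DesignPoint(
            id=str(r.id),
            T=float(r.T_C),
            t_g=float(r.tg_min),
            phi=float(r.phi_mL_min),
            coded=(float(r.coded_T), float(r.coded_tg), float(r.coded_phi)),
            role=str(r.role),
            replicate=bool(r.replicate),
        )
        for r in df.itertuples()
    ]
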