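"""Synthetic UHPLC-DAD peak tables for the 22 tracked crocin peaks.

The study's raw chromatograms were never deposited, so this module
generates peak tables with the statistical structure the downstream
analysis assumes: 22 analyte peaks eluting between roughly 5.3 and
12.3 min at the center point, whose retention times and half-height
widths respond smoothly to column temperature, gradient duration and
flow rate, with a subset of adjacent pairs kept deliberately close so
that their resolution varies materially over the factor domain.

Retention model (noise-free part), per analyte i with coded factor
levels (c_T, c_tg, c_phi) and natural flow rate phi:

    rt_i = base_rt_i * (0.8 / phi)**0.85
           + s_tg_i * c_tg + s_T_i * c_T + s_Ttg_i * c_T * c_tg
           + s_phi_i * c_phi

    w_i  = width_base_i * (rt_i / base_rt_i) * (phi / 0.8)**0.3

The multiplicative flow term reflects that halving the flow roughly
stretches the whole chromatogram, while the linear coded terms (with a
T x t_g interaction) encode analyte-specific selectivity shifts; the
interaction term makes the temperature and gradient effects
non-additive, which is what makes the neural-network model non-trivial.
Gaussian noise is added to retention times (absolute, min) and widths
(relative).  The noise-free model doubles as the ground-truth oracle
for parameter-recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from crocinopt.doe import DesignPoint, FactorSpec, decode_levels

__all__ = [
    "ANALYTE_LABELS",
    "AnalyteParams",
    "Peak",
    "Chromatogram",
    "SimulationConfig",
    "sample_analyte_params",
    "simulate_peak_table",
    "simulate_campaign",
    "true_global_resolution",
    "oracle_argmax",
    "peaks_to_frame",
]

# The 22 peaks tracked in the separation model: label, crocetin isomer,
# number of glucose units.  Labels follow the field's crocin shorthand
# (t-4GG = trans-crocetin bis(gentiobiosyl) ester, etc.); unresolved
# trans/cis crocins carry generic t#/c# labels and plausible sugar
# counts.  Fixture constants, not chemical claims.
ANALYTE_LABELS: tuple[tuple[str, str, int], ...] = (
    ("t-5tG", "trans", 5),
    ("t1", "trans", 4),
    ("t-5nG", "trans", 5),
    ("t-4GG", "trans", 4),
    ("t3", "trans", 3),
    ("t4", "trans", 3),
    ("c1", "cis", 3),
    ("t-4ng", "trans", 4),
    ("t-3Gg", "trans", 3),
    ("t7", "trans", 3),
    ("U3", "trans", 2),
    ("t8", "trans", 2),
    ("t9", "trans", 2),
    ("U4", "trans", 2),
    ("c2", "cis", 2),
    ("t-2gg", "trans", 2),
    ("t10", "trans", 2),
    ("t11", "trans", 1),
    ("c3", "cis", 2),
    ("c-4GG", "cis", 4),
    ("c5", "cis", 2),
    ("c-3Gg", "cis", 3),
)

N_ANALYTES = len(ANALYTE_LABELS)  # 22

# Fixed percentage-area vector (sums to 100): analyte 4 (the t-4GG
# analogue) dominates at ~45%, a handful of majors follow, the rest are
# minor peaks.  Fixture constants.
_AREA_WEIGHTS = np.array(
    [2.0, 1.2, 6.0, 45.0, 3.0, 2.0, 1.5, 2.5, 16.0, 1.8, 0.8,
     1.2, 1.0, 0.7, 1.5, 1.6, 1.1, 0.9, 1.3, 4.5, 1.4, 3.0]
)
AREA_PCT = 100.0 * _AREA_WEIGHTS / _AREA_WEIGHTS.sum()

# Adjacent-pair positions (i of pair (i, i+1)) kept close at the center
# point: the ten pairs the surface objective retains by default.
CLOSE_PAIR_POSITIONS: tuple[int, ...] = (4, 5, 7, 9, 11, 12, 13, 14, 15, 21)


@dataclass(frozen=True)
class AnalyteParams:
    """Ground-truth retention parameters of one simulated analyte."""

    analyte_id: int  # 1..22, elution order at the center point
    base_rt: float  # min, center-point retention time
    slope_tg: float  # min per coded t_g unit
    slope_phi: float  # min per coded phi unit (selectivity part)
    slope_T: float  # min per coded T unit
    slope_TxTg: float  # min per coded T*t_g product
    width_base: float  # min, center-point half-height width
    area_pct: float  # percent of total 440 nm area
    isomer: str  # "trans" | "cis"
    n_glucose: int  # 1..5
    label: str = ""


@dataclass(frozen=True)
class Peak:
    analyte_id: int
    rt: float  # min
    w_half: float  # min, full width at half height
    area: float  # arbitrary units

    def __post_init__(self) -> None:
        if self.rt <= 0 or self.w_half <= 0:
            raise ValueError("peak rt and w_half must be positive")


@dataclass(frozen=True)
class Chromatogram:
    condition: DesignPoint
    peaks: tuple[Peak, ...]  # exactly 22, ordered by analyte_id
    seed: int

    def __post_init__(self) -> None:
        if len(self.peaks) != N_ANALYTES:
            raise ValueError(f"expected {N_ANALYTES} peaks, got {len(self.peaks)}")


@dataclass(frozen=True)
class SimulationConfig:
    """Noise levels and sampling ranges for the synthetic campaign."""

    seed: int = 0
    rt_noise_sd: float = 0.005  # min; small vs. peak widths ~0.05 min
    width_noise_cv: float = 0.02  # relative
    # base_rt gap ranges (min) for close vs. well-separated pairs
    gap_close: tuple[float, float] = (0.05, 0.09)
    gap_wide: tuple[float, float] = (0.42, 0.68)
    close_pair_positions: tuple[int, ...] = CLOSE_PAIR_POSITIONS
    # per-gap slope increments for close pairs (min per coded unit)
    dtg_close: tuple[float, float] = (0.008, 0.020)
    dT_close: tuple[float, float] = (-0.016, -0.005)
    dTxTg_close: tuple[float, float] = (-0.006, 0.006)
    dphi_close: tuple[float, float] = (-0.005, 0.005)
    # wider, sign-free increments for the well-separated pairs
    dtg_wide: tuple[float, float] = (-0.04, 0.06)
    dT_wide: tuple[float, float] = (-0.05, 0.02)
    dTxTg_wide: tuple[float, float] = (-0.015, 0.015)
    dphi_wide: tuple[float, float] = (-0.015, 0.015)
    width_range: tuple[float, float] = (0.035, 0.055)
    total_area: float = 1000.0

    def __post_init__(self) -> None:
        if self.rt_noise_sd < 0 or self.width_noise_cv < 0:
            raise ValueError("noise parameters must be nonnegative")

    def noise_free(self) -> "SimulationConfig":
        return replace(self, rt_noise_sd=0.0, width_noise_cv=0.0)


def sample_analyte_params(config: SimulationConfig) -> list[AnalyteParams]:
    """Draw the ground-truth parameter set for the 22 analytes.

    Deterministic given ``config.seed``.  Close pairs get small center
    gaps and slope increments biased so that longer gradients and lower
    temperatures widen them (placing the separation optimum at high t_g,
    low T, low phi); well-separated pairs get larger, sign-free
    increments so their resolutions also move, just not critically.
    """
    rng = np.random.default_rng(config.seed)
    close = set(config.close_pair_positions)

    gaps = np.empty(N_ANALYTES - 1)
    dtg = np.empty(N_ANALYTES - 1)
    dT = np.empty(N_ANALYTES - 1)
    dTxTg = np.empty(N_ANALYTES - 1)
    dphi = np.empty(N_ANALYTES - 1)
    for k in range(N_ANALYTES - 1):
        pos = k + 1  # pair (pos, pos+1)
        if pos in close:
            gaps[k] = rng.uniform(*config.gap_close)
            dtg[k] = rng.uniform(*config.dtg_close)
            dT[k] = rng.uniform(*config.dT_close)
            dTxTg[k] = rng.uniform(*config.dTxTg_close)
            dphi[k] = rng.uniform(*config.dphi_close)
        else:
            gaps[k] = rng.uniform(*config.gap_wide)
            dtg[k] = rng.uniform(*config.dtg_wide)
            dT[k] = rng.uniform(*config.dT_wide)
            dTxTg[k] = rng.uniform(*config.dTxTg_wide)
            dphi[k] = rng.uniform(*config.dphi_wide)

    base_rt = 5.3 + rng.uniform(0.0, 0.08) + np.concatenate([[0.0], np.cumsum(gaps)])
    s_tg = rng.uniform(-0.02, 0.02) + np.concatenate([[0.0], np.cumsum(dtg)])
    s_T = rng.uniform(-0.02, 0.02) + np.concatenate([[0.0], np.cumsum(dT)])
    s_TxTg = rng.uniform(-0.01, 0.01) + np.concatenate([[0.0], np.cumsum(dTxTg)])
    s_phi = rng.uniform(-0.01, 0.01) + np.concatenate([[0.0], np.cumsum(dphi)])
    widths = rng.uniform(*config.width_range, size=N_ANALYTES)

    params = []
    for i in range(N_ANALYTES):
        label, isomer, n_glu = ANALYTE_LABELS[i]
        params.append(
            AnalyteParams(
                analyte_id=i + 1,
                base_rt=float(base_rt[i]),
                slope_tg=float(s_tg[i]),
                slope_phi=float(s_phi[i]),
                slope_T=float(s_T[i]),
                slope_TxTg=float(s_TxTg[i]),
                width_base=float(widths[i]),
                area_pct=float(AREA_PCT[i]),
                isomer=isomer,
                n_glucose=n_glu,
                label=label,
            )
        )
    return params


def _model_arrays(params: list[AnalyteParams]):
    get = lambda attr: np.array([getattr(p, attr) for p in params])
    return (get("base_rt"), get("slope_tg"), get("slope_phi"),
            get("slope_T"), get("slope_TxTg"), get("width_base"))


def _noise_free_rt_width(params, coded, phi):
    base_rt, s_tg, s_phi, s_T, s_TxTg, w0 = _model_arrays(params)
    c_T, c_tg, c_phi = coded
    rt = (base_rt * (0.8 / phi) ** 0.85
          + s_tg * c_tg + s_T * c_T + s_TxTg * c_T * c_tg + s_phi * c_phi)
    w = w0 * (rt / base_rt) * (phi / 0.8) ** 0.3
    return rt, w


def _check_in_domain(point: DesignPoint) -> None:
    if any(abs(c) > 1.0 + 1e-9 for c in point.coded):
        raise ValueError(
            f"design point {point.id} lies outside the factor domain: "
            f"coded {point.coded}"
        )


def simulate_peak_table(
    params: list[AnalyteParams],
    point: DesignPoint,
    config: SimulationConfig,
    replicate_seed: int = 0,
) -> Chromatogram:
    """Simulate one chromatogram (peak table) at a design point.

    Fully deterministic given (config.seed, point, replicate_seed).
    """
    _check_in_domain(point)
    c_T, c_tg, c_phi = point.coded
    phi = point.phi

    rt_det, _ = _noise_free_rt_width(params, (c_T, c_tg, c_phi), phi)
    arrays = _model_arrays(params)
    base_rt, w0 = arrays[0], arrays[5]

    rng = np.random.default_rng(
        [config.seed & 0x7FFFFFFF, replicate_seed, zlib.crc32(point.id.encode())]
    )
    eps = rng.normal(0.0, config.rt_noise_sd, size=N_ANALYTES) \
        if config.rt_noise_sd > 0 else np.zeros(N_ANALYTES)
    eta = rng.normal(0.0, config.width_noise_cv, size=N_ANALYTES) \
        if config.width_noise_cv > 0 else np.zeros(N_ANALYTES)

    rt = np.maximum(rt_det + eps, 1e-6)
    w = w0 * (rt / base_rt) * (phi / 0.8) ** 0.3 * (1.0 + eta)
    w = np.maximum(w, 1e-4)

    areas = AREA_PCT / 100.0 * config.total_area
    peaks = tuple(
        Peak(analyte_id=i + 1, rt=float(rt[i]), w_half=float(w[i]),
             area=float(areas[i]))
        for i in range(N_ANALYTES)
    )
    return Chromatogram(condition=point, peaks=peaks, seed=config.seed)


def simulate_campaign(
    params: list[AnalyteParams],
    design: list[DesignPoint],
    config: SimulationConfig,
) -> list[Chromatogram]:
    """One chromatogram per design point; replicate seeds = run index."""
    return [
        simulate_peak_table(params, point, config, replicate_seed=k)
        for k, point in enumerate(design)
    ]


def true_global_resolution(
    params: list[AnalyteParams],
    point: DesignPoint,
    retained_pairs,
) -> float:
    """Noise-free ground-truth R_G at a design point.

    Evaluates the closed-form retention model with zero noise and feeds
    the resulting peak table through the same resolution code path the
    pipeline uses, so the oracle and the pipeline can disagree only
    through the fitted surrogate, never through the resolution
    arithmetic.
    """
    from crocinopt.resolution import adjacent_resolutions

    table = simulate_peak_table(
        params, point, SimulationConfig(seed=0).noise_free(), replicate_seed=0
    )
    records = {r.pair: r.y for r in adjacent_resolutions(table)}
    return float(np.mean([records[tuple(p)] for p in retained_pairs]))


def oracle_argmax(
    params: list[AnalyteParams],
    factors: tuple[FactorSpec, FactorSpec, FactorSpec],
    retained_pairs,
    n_T: int = 41,
    n_phi: int = 41,
    tg_levels=(8.0, 10.0, 12.0),
) -> tuple[tuple[float, float, float], float]:
    """Dense-grid argmax of the noise-free R_G oracle.

    Returns ((T, t_g, phi), R_G).  This defines the "true optimum" that
    parameter-recovery tests ask the fitted pipeline to find.  Ties are
    broken toward lower phi, then lower T, then lower t_g, matching the
    pipeline's own optimizer convention.
    """
    from crocinopt.doe import code_levels

    fT, ftg, fphi = factors
    T_axis = np.linspace(fT.low, fT.high, n_T)
    phi_axis = np.linspace(fphi.low, fphi.high, n_phi)
    pairs = [tuple(p) for p in retained_pairs]

    best = None
    for t_g in tg_levels:
        for T in T_axis:
            for phi in phi_axis:
                coded = code_levels((T, t_g, phi), factors)
                rt, w = _noise_free_rt_width(params, coded, phi)
                ys = []
                for i, j in pairs:
                    gap = rt[j - 1] - rt[i - 1]
                    r = max(0.0, 2.0 * gap / (w[i - 1] + w[j - 1]))
                    ys.append(np.log10(r + 1.0))
                rg = float(np.mean(ys))
                key = (rg, -phi, -T, -t_g)
                if best is None or key > best[0]:
                    best = (key, (float(T), float(t_g), float(phi)), rg)
    return best[1], best[2]


def peaks_to_frame(chromatograms: list[Chromatogram]) -> pd.DataFrame:
    """Long-format peak-table artifact (one row per condition x analyte)."""
    rows = []
    for chrom in chromatograms:
        for p in chrom.peaks:
            rows.append((chrom.condition.id, p.analyte_id, p.rt, p.w_half, p.area))
    return pd.DataFrame(
        rows, columns=["condition_id", "analyte_id", "rt_min", "whalf_min", "area"]
    )
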