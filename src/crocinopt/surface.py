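"""Global-resolution response surface and optimum location.

The multi-response network output is collapsed into a single objective,
the global resolution R_G: the arithmetic mean of the predicted
y = log10(R_ij + 1) over a retained subset of adjacent peak pairs.
Pairs that are either well separated or hopelessly overlapped under all
conditions carry no optimization information and are excluded; the
default retained set is the ten pairs the separation study singled out.
Surfaces are evaluated on a (T, phi) grid at fixed gradient duration
t_g, and the optimum is the grid argmax over all t_g levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crocinopt.ann import EnsembleModel, predict
from crocinopt.doe import FactorSpec
from crocinopt.encoding import N_FEATURES
from crocinopt.resolution import ResolutionRecord
from crocinopt.simulate import N_ANALYTES

__all__ = [
    "DEFAULT_RETAINED_PAIRS",
    "SurfaceGrid",
    "OptimumReport",
    "global_resolution",
    "evaluate_surface",
    "locate_optimum",
    "auto_retained_pairs",
    "surfaces_to_frame",
]

DEFAULT_RETAINED_PAIRS: tuple[tuple[int, int], ...] = (
    (4, 5), (5, 6), (7, 8), (9, 10), (11, 12),
    (12, 13), (13, 14), (14, 15), (15, 16), (21, 22),
)


@dataclass(frozen=True)
class SurfaceGrid:
    t_g: float
    T_axis: np.ndarray
    phi_axis: np.ndarray
    R_G: np.ndarray  # shape (len(T_axis), len(phi_axis))


@dataclass(frozen=True)
class OptimumReport:
    argmax: tuple[float, float, float]  # (T, t_g, phi)
    rg_max: float
    per_tg_max: dict  # t_g -> (T, phi, R_G)
    on_boundary: bool
    alternatives: tuple = ()  # near-optimal (T, t_g, phi, R_G) at shorter t_g


def _check_pairs(retained) -> list[tuple[int, int]]:
    pairs = [tuple(int(v) for v in p) for p in retained]
    if not pairs:
        raise ValueError("retained pair set must be nonempty")
    for i, j in pairs:
        if not (1 <= i < j <= N_ANALYTES and j == i + 1):
            raise ValueError(f"retained pair {(i, j)} is not adjacent in 1..{N_ANALYTES}")
    return pairs


def _pair_matrix(conditions: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Stack encoded 25-vectors for every (condition row, retained pair).

    ``conditions`` has columns (T, t_g, phi); the output row order is
    condition-major, pair-minor.
    """
    n_cond, n_pairs = len(conditions), len(pairs)
    X = np.zeros((n_cond * n_pairs, N_FEATURES))
    X[:, 0] = np.repeat(conditions[:, 2], n_pairs)  # phi
    X[:, 1] = np.repeat(conditions[:, 1], n_pairs)  # t_g
    X[:, 2] = np.repeat(conditions[:, 0], n_pairs)  # T
    for k, (i, j) in enumerate(pairs):
        rows = np.arange(n_cond) * n_pairs + k
        X[rows, 2 + i] = 1.0
        X[rows, 2 + j] = 1.0
    return X


def _predict_rg(ensemble: EnsembleModel, conditions: np.ndarray, pairs) -> np.ndarray:
    X = _pair_matrix(conditions, pairs)
    y = predict(ensemble, X)
    # y = log10(R+1) is nonnegative by construction; floor stray
    # extrapolation artifacts so R_G >= 0 everywhere
    y = np.maximum(y, 0.0)
    return y.reshape(len(conditions), len(pairs)).mean(axis=1)


def global_resolution(
    ensemble: EnsembleModel,
    condition: tuple[float, float, float],
    retained=DEFAULT_RETAINED_PAIRS,
) -> float:
    """R_G at one condition (T, t_g, phi), natural units."""
    pairs = _check_pairs(retained)
    return float(_predict_rg(ensemble, np.array([condition], dtype=float), pairs)[0])


def evaluate_surface(
    ensemble: EnsembleModel,
    t_g: float,
    factors: tuple[FactorSpec, FactorSpec, FactorSpec],
    retained=DEFAULT_RETAINED_PAIRS,
    step_T: float = 0.25,
    step_phi: float = 0.01,
) -> SurfaceGrid:
    """R_G over the full (T, phi) grid at fixed t_g."""
    fT, ftg, fphi = factors
    if not ftg.low <= t_g <= ftg.high:
        raise ValueError(f"t_g={t_g} outside [{ftg.low}, {ftg.high}]")
    T_axis = np.arange(fT.low, fT.high + step_T / 2, step_T)
    phi_axis = np.arange(fphi.low, fphi.high + step_phi / 2, step_phi)
    TT, PP = np.meshgrid(T_axis, phi_axis, indexing="ij")
    conditions = np.column_stack(
        [TT.ravel(), np.full(TT.size, t_g), PP.ravel()]
    )
    pairs = _check_pairs(retained)
    rg = _predict_rg(ensemble, conditions, pairs).reshape(TT.shape)
    return SurfaceGrid(t_g=float(t_g), T_axis=T_axis, phi_axis=phi_axis, R_G=rg)


def locate_optimum(
    surfaces: list[SurfaceGrid],
    alternative_margin: float = 0.005,
) -> OptimumReport:
    """Grid argmax of R_G over all evaluated surfaces.

    Ties are broken toward lower phi, then lower T, then lower t_g
    (solvent and thermal economy).  Near-optimal conditions at shorter
    t_g (within ``alternative_margin`` of the maximum) are reported as
    alternatives, since a shorter gradient at equal resolution is the
    cheaper separation.
    """
    if not surfaces:
        raise ValueError("at least one surface required")
    best = None
    per_tg = {}
    for s in surfaces:
        flat_best = None
        for a, T in enumerate(s.T_axis):
            for b, phi in enumerate(s.phi_axis):
                key = (s.R_G[a, b], -phi, -T, -s.t_g)
                if flat_best is None or key > flat_best[0]:
                    flat_best = (key, (float(T), float(phi), float(s.R_G[a, b])))
                if best is None or key > best[0]:
                    best = (key, (float(T), s.t_g, float(phi)), float(s.R_G[a, b]))
        per_tg[s.t_g] = flat_best[1]

    (T_opt, tg_opt, phi_opt), rg_max = best[1], best[2]
    T_vals = np.concatenate([s.T_axis for s in surfaces])
    phi_vals = np.concatenate([s.phi_axis for s in surfaces])
    tg_vals = [s.t_g for s in surfaces]
    on_boundary = (
        np.isclose(T_opt, T_vals.min()) or np.isclose(T_opt, T_vals.max())
        or np.isclose(phi_opt, phi_vals.min()) or np.isclose(phi_opt, phi_vals.max())
        or np.isclose(tg_opt, min(tg_vals)) or np.isclose(tg_opt, max(tg_vals))
    )

    alternatives = []
    for s in surfaces:
        if s.t_g >= tg_opt:
            continue
        T_a, phi_a, rg_a = per_tg[s.t_g]
        if rg_max - rg_a <= alternative_margin:
            alternatives.append((T_a, s.t_g, phi_a, rg_a))

    return OptimumReport(
        argmax=(T_opt, tg_opt, phi_opt),
        rg_max=rg_max,
        per_tg_max=per_tg,
        on_boundary=bool(on_boundary),
        alternatives=tuple(alternatives),
    )


def auto_retained_pairs(
    records: list[ResolutionRecord], min_y_range: float = 0.05
) -> tuple[tuple[int, int], ...]:
    """Data-driven retained set for synthetic campaigns.

    Keeps the adjacent pairs whose transformed resolution spans at
    least ``min_y_range`` across the campaign, i.e. those actually
    responsive to the separation conditions.
    """
    by_pair: dict[tuple[int, int], list[float]] = {}
    for r in records:
        by_pair.setdefault(r.pair, []).append(r.y)
    retained = [
        pair for pair, ys in sorted(by_pair.items())
        if max(ys) - min(ys) >= min_y_range
    ]
    if not retained:
        raise ValueError("no pair exceeds the y-range threshold")
    return tuple(retained)


def surfaces_to_frame(surfaces: list[SurfaceGrid]) -> pd.DataFrame:
    """Long-format (t_g, T, phi, RG) table of one or more surfaces."""
    rows = []
    for s in surfaces:
        for a, T in enumerate(s.T_axis):
            for b, phi in enumerate(s.phi_axis):
                rows.append((s.t_g, float(T), float(phi), float(s.R_G[a, b])))
    return pd.DataFrame(rows, columns=["tg", "T", "phi", "RG"])
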