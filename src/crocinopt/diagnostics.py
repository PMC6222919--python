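"""Model diagnostics: input sensitivity and sum of ranking differences.

Sensitivity uses the partial-derivative method: the analytic derivative
of the network output with respect to each (scaled) factor input,
averaged in absolute value over the calibration samples, measures how
strongly that factor drives the predicted resolution.

Sum of ranking differences (SRD) compares model residuals across the
points of the experimental design.  For each design point, the 21
pair residuals are ranked; the SRD of a point is the sum of absolute
rank differences against the reference point (the center of the
design).  The statistic is validated by comparison of ranks by random
numbers (CRRN): the SRD distribution of uniformly random rankings is
simulated, a Gaussian is fitted by moments, and design points whose
SRD falls inside the 95% band rank residuals no differently from a
random ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from crocinopt.ann import EnsembleModel, _act_prime_from_value, _forward_scaled

__all__ = [
    "SensitivityReport",
    "SrdResult",
    "partial_derivatives",
    "factor_importance",
    "srd",
    "crrn",
    "max_srd",
]

FACTOR_COLUMNS = ("phi", "t_g", "T")  # first three encoded predictors


@dataclass(frozen=True)
class SensitivityReport:
    mean_abs_derivative: dict  # factor name -> mean |dy/dz|
    importance: dict  # factor name -> relative importance (sums to 1)


@dataclass(frozen=True)
class SrdResult:
    srd: np.ndarray  # raw SRD per column
    srd_normalized: np.ndarray  # percent of the maximum attainable
    reference: int  # reference column index
    crrn_mean: float
    crrn_sd: float
    crrn_lower: float  # Gaussian 2.5% bound
    crrn_upper: float  # Gaussian 97.5% bound
    crrn_pct_2_5: float  # empirical percentiles of the null draws
    crrn_pct_97_5: float
    inside_interval: np.ndarray  # per column, within the Gaussian 95% band


def partial_derivatives(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Per-sample derivatives of the ensemble output w.r.t. the scaled factors.

    Returns an (n_samples, 3) array for (phi, t_g, T).  Derivatives are
    computed analytically through the chain rule for each member and
    averaged; the output is on the natural response scale per unit of
    [0, 1]-scaled input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acc = np.zeros((X.shape[0], 3))
    for m in ensemble.members:
        Z = m.scale_x(X)
        _, Hv = _forward_scaled(m, Z)
        # dy_s/dz_k = sum_h w_out_h * act'(a_h) * W_h[h, k]
        weighted = _act_prime_from_value(Hv, m.activation) * m.w_out  # (n, H)
        d = weighted @ m.W_h[:, :3]  # (n, 3)
        acc += d * (m.y_max - m.y_min)
    return acc / len(ensemble.members)


def factor_importance(derivatives: np.ndarray) -> SensitivityReport:
    """Mean absolute partial derivative per factor, normalized to sum 1."""
    derivatives = np.atleast_2d(np.asarray(derivatives, dtype=float))
    if derivatives.size == 0:
        raise ValueError("empty derivative matrix")
    mad = np.mean(np.abs(derivatives), axis=0)
    total = mad.sum()
    if total == 0:
        raise ValueError("all derivatives are zero; importances undefined")
    return SensitivityReport(
        mean_abs_derivative=dict(zip(FACTOR_COLUMNS, mad.tolist())),
        importance=dict(zip(FACTOR_COLUMNS, (mad / total).tolist())),
    )


def max_srd(n: int) -> int:
    """Maximum attainable SRD for n objects: n^2/2 (even), (n^2-1)/2 (odd)."""
    return n * n // 2 if n % 2 == 0 else (n * n - 1) // 2


def _column_ranks(values: np.ndarray) -> np.ndarray:
    return rankdata(values, method="average")


def crrn(
    n_objects: int,
    n_draws: int = 100_000,
    seed: int = 0,
    reference_ranks: np.ndarray | None = None,
) -> dict:
    """Comparison of ranks by random numbers: the SRD null distribution.

    Draws ``n_draws`` uniformly random rankings of ``n_objects`` and
    computes their SRD against the reference ranking (1..n by default).
    Returns the draws plus a moment-fitted Gaussian summary and
    empirical 2.5/97.5 percentiles.
    """
    if n_objects < 2:
        raise ValueError("CRRN needs at least 2 objects")
    rng = np.random.default_rng(seed)
    if reference_ranks is None:
        reference_ranks = np.arange(1, n_objects + 1, dtype=float)
    # a uniformly random ranking = random permutation of 1..n
    perms = np.argsort(rng.random((n_draws, n_objects)), axis=1) + 1.0
    draws = np.sum(np.abs(perms - reference_ranks), axis=1)
    mean, sd = float(draws.mean()), float(draws.std(ddof=1))
    return {
        "draws": draws,
        "mean": mean,
        "sd": sd,
        "lower": mean - 1.96 * sd,
        "upper": mean + 1.96 * sd,
        "pct_2_5": float(np.percentile(draws, 2.5)),
        "pct_97_5": float(np.percentile(draws, 97.5)),
    }


def srd(
    matrix: np.ndarray,
    reference: int,
    n_draws: int = 100_000,
    seed: int = 0,
) -> SrdResult:
    """SRD of every column of ``matrix`` against the reference column.

    Rows are objects (e.g. the 21 pair residuals), columns the design
    points being compared.  Ties receive average ranks (midranks).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n_obj, n_col = matrix.shape
    if n_obj < 2:
        raise ValueError("SRD needs at least 2 objects")
    if not 0 <= reference < n_col:
        raise ValueError(f"reference column {reference} out of range")

    ranks = np.column_stack([_column_ranks(matrix[:, j]) for j in range(n_col)])
    ref_ranks = ranks[:, reference]
    srd_vals = np.sum(np.abs(ranks - ref_ranks[:, None]), axis=0)
    norm = 100.0 * srd_vals / max_srd(n_obj)

    null = crrn(n_obj, n_draws=n_draws, seed=seed, reference_ranks=ref_ranks)
    inside = (srd_vals >= null["lower"]) & (srd_vals <= null["upper"])

    return SrdResult(
        srd=srd_vals,
        srd_normalized=norm,
        reference=reference,
        crrn_mean=null["mean"],
        crrn_sd=null["sd"],
        crrn_lower=null["lower"],
        crrn_upper=null["upper"],
        crrn_pct_2_5=null["pct_2_5"],
        crrn_pct_97_5=null["pct_97_5"],
        inside_interval=inside,
    )
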