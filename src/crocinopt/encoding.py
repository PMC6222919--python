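"""Bit-string pair encoding, auto-scaling and Kennard-Stone splitting.

Each resolution record becomes one 25-variable sample: the three factor
levels (phi, t_g, T, natural units) followed by 22 peak-membership
indicator bits of which exactly the i-th and j-th are 1.  The single
network thereby models all 21 adjacent-pair resolutions at once.

The calibration samples are split into training and validation sets by
the Kennard-Stone maximin algorithm in the auto-scaled (z-scored)
25-dimensional predictor space; the response is excluded from the
distance space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crocinopt.doe import DesignPoint
from crocinopt.resolution import ResolutionRecord, adjacent_resolutions
from crocinopt.simulate import Chromatogram, N_ANALYTES

__all__ = [
    "N_FEATURES",
    "EncodedSample",
    "DatasetSplit",
    "encode",
    "encode_pair_vector",
    "assemble",
    "samples_to_arrays",
    "autoscale",
    "apply_autoscale",
    "kennard_stone",
    "split_dataset",
]

N_FEATURES = 3 + N_ANALYTES  # 25: phi, t_g, T, 22 bits


@dataclass(frozen=True)
class EncodedSample:
    x: tuple[float, ...]  # 25 predictors: (phi, t_g, T, bit1..bit22)
    y: float  # log10(R + 1)
    condition_id: str
    pair: tuple[int, int]


@dataclass(frozen=True)
class DatasetSplit:
    training: tuple[int, ...]  # indices into the calibration set
    validation: tuple[int, ...]
    scale_mean: tuple[float, ...]  # z-score params of the Kennard-Stone space
    scale_sd: tuple[float, ...]


def encode_pair_vector(point: DesignPoint, pair: tuple[int, int]) -> np.ndarray:
    """The 25-element predictor vector for (condition, adjacent pair)."""
    i, j = pair
    if not (1 <= i <= N_ANALYTES and 1 <= j <= N_ANALYTES):
        raise ValueError(f"pair indices must lie in 1..{N_ANALYTES}, got {pair}")
    if j != i + 1:
        raise ValueError(f"pair must be adjacent (j = i+1), got {pair}")
    x = np.zeros(N_FEATURES)
    x[0], x[1], x[2] = point.phi, point.t_g, point.T
    x[2 + i] = 1.0
    x[2 + j] = 1.0
    return x


def encode(record: ResolutionRecord, point: DesignPoint) -> EncodedSample:
    x = encode_pair_vector(point, record.pair)
    return EncodedSample(
        x=tuple(float(v) for v in x),
        y=record.y,
        condition_id=record.condition_id,
        pair=record.pair,
    )


def assemble(
    chromatograms: list[Chromatogram],
) -> tuple[list[EncodedSample], list[EncodedSample]]:
    """Encode a campaign into (calibration, external) sample lists.

    With the default campaign (29 calibration + 8 external runs, 21
    pairs each) this yields 609 calibration and 168 external samples.
    """
    calibration, external = [], []
    for chrom in chromatograms:
        bucket = calibration if chrom.condition.role == "calibration" else external
        for record in adjacent_resolutions(chrom):
            bucket.append(encode(record, chrom.condition))
    return calibration, external


def samples_to_arrays(samples: list[EncodedSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([s.x for s in samples])
    y = np.array([s.y for s in samples])
    return X, y


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring; returns (Xs, mean, sd).

    The three factor columns must vary (a constant factor makes the
    design degenerate).  Indicator columns with zero variance pass
    through unscaled (sd recorded as 1, mean as 0).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscale requires a 2-D array with >= 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero[: min(3, X.shape[1])]):
        raise ValueError("zero-variance factor column in calibration data")
    mean = np.where(zero, 0.0, mean)
    sd = np.where(zero, 1.0, sd)
    return (X - mean) / sd, mean, sd


def apply_autoscale(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - mean) / sd


def kennard_stone(Xs: np.ndarray, n_select: int) -> list[int]:
    """Classic Kennard-Stone maximin subset selection.

    Seeds with the two mutually most distant samples (Euclidean), then
    repeatedly adds the candidate whose minimum distance to the already
    selected set is largest.  Ties are broken toward the lowest sample
    index, which makes the selection fully deterministic.
    """
    Xs = np.asarray(Xs, dtype=float)
    n = Xs.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must lie in [2, {n}], got {n_select}")

    # pairwise squared distances via the Gram expansion
    sq = np.sum(Xs**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Xs @ Xs.T), 0.0)

    # initial pair: max distance, lexicographically smallest on ties
    iu = np.triu_indices(n, k=1)
    flat = d2[iu]
    best = np.argmax(flat)  # argmax returns the first (lowest (i,j)) maximum
    first, second = int(iu[0][best]), int(iu[1][best])
    selected = [first, second]

    in_set = np.zeros(n, dtype=bool)
    in_set[[first, second]] = True
    min_d2 = np.minimum(d2[first], d2[second])

    while len(selected) < n_select:
        min_d2[in_set] = -1.0
        nxt = int(np.argmax(min_d2))  # first max = lowest index on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_d2 = np.minimum(min_d2, d2[nxt])

    return selected


def split_dataset(
    calibration: list[EncodedSample], n_train: int = 486
) -> DatasetSplit:
    """Kennard-Stone training/validation split of the calibration set."""
    X, _ = samples_to_arrays(calibration)
    if not 2 <= n_train <= len(calibration):
        raise ValueError(
            f"training size {n_train} out of range for {len(calibration)} "
            "calibration samples"
        )
    Xs, mean, sd = autoscale(X)
    train_idx = kennard_stone(Xs, n_train)
    train_set = set(train_idx)
    val_idx = [i for i in range(len(calibration)) if i not in train_set]
    return DatasetSplit(
        training=tuple(train_idx),
        validation=tuple(val_idx),
        scale_mean=tuple(float(m) for m in mean),
        scale_sd=tuple(float(s) for s in sd),
    )
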