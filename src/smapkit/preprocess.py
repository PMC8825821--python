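"""Reporter-ion preprocessing: isotope-impurity correction, loading
normalization, log2 transform, PSM summarization and per-peptide min-max
scaling.

The fixed pipeline order is: impurity correction -> loading normalization ->
log2 (with zero flooring) -> PSM averaging -> min-max scaling. The scaled
values feed genotype inference; mean-centering is offered only as a
reporting transform since min-max scaling subsumes it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Isotope impurity row reported for the TMT126 reagent: fractions of its
#: signal observed at the 126, 127 and 128 m/z reporter masses.
TMT126_IMPURITY_ROW = (0.918, 0.079, 0.003)


@dataclass
class ImpurityMatrix:
    """Square channel x channel reagent cross-contamination matrix.

    Entry ``(i, j)`` is the fraction of channel ``i``'s reagent signal that
    appears in channel ``j``. Rows sum to at most 1 and the diagonal
    dominates (most signal lands in the intended channel).
    """

    channels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError("impurity matrix must be square over the channels")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("impurity entries must be in [0, 1]")
        if (self.values.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("impurity rows must sum to <= 1")

    @classmethod
    def identity(cls, channels) -> "ImpurityMatrix":
        channels = list(channels)
        return cls(channels, np.eye(len(channels)))

    @classmethod
    def from_csv(cls, path) -> "ImpurityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


def correct_isotope_impurity(raw: np.ndarray, impurity: ImpurityMatrix) -> np.ndarray:
    """Undo reagent isotope cross-contamination between channels.

    The observed row ``o`` relates to the true channel signals ``t`` by
    ``o = t @ impurity``; this solves for ``t`` per peptide. Negative
    solutions (numerically overshooting corrections) are clamped to 0.
    """
    raw = np.asarray(raw, dtype=float)
    if np.linalg.matrix_rank(impurity.values) < impurity.values.shape[0]:
        raise np.linalg.LinAlgError("impurity matrix is singular")
    # t @ M = o  <=>  M.T @ t.T = o.T
    corrected = np.linalg.solve(impurity.values.T, raw.T).T
    neg = corrected < 0
    if np.any(neg & ~np.isnan(corrected)):
        logger.warning(
            "clamped %d negative corrected intensities to 0", int(neg.sum())
        )
        corrected = np.where(neg, 0.0, corrected)
    return corrected


def normalize_loading(matrix: np.ndarray, trim_fraction: float = 0.1) -> np.ndarray:
    """Remove per-channel sample-loading bias.

    Each channel is multiplicatively rescaled so that its trimmed median
    intensity equals the grand (pooled) trimmed median; within-channel
    ratios are unchanged. ``trim_fraction`` is the fraction trimmed from
    each tail before taking the median.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    matrix = np.asarray(matrix, dtype=float)

    def trimmed_median(values: np.ndarray) -> float:
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise ValueError("channel with no nonmissing values")
        values = np.sort(values)
        k = int(np.floor(trim_fraction * values.size))
        if 2 * k >= values.size:
            k = 0
        return float(np.median(values[k : values.size - k]))

    channel_medians = np.array(
        [trimmed_median(matrix[:, j]) for j in range(matrix.shape[1])]
    )
    if (channel_medians <= 0).any():
        raise ValueError("loading normalization requires positive channel medians")
    grand = trimmed_median(matrix.ravel())
    return matrix * (grand / channel_medians)


def summarize_peptides(psm_matrix: np.ndarray, psm_to_peptide) -> tuple[np.ndarray, list]:
    """Average PSM rows into peptide rows, per channel, ignoring missing cells.

    ``psm_to_peptide`` maps PSM row index -> peptide key. Returns the peptide
    x channels matrix and the peptide keys in first-appearance order.
    """
    psm_matrix = np.asarray(psm_matrix, dtype=float)
    if len(psm_to_peptide) == 0:
        raise ValueError("empty PSM-to-peptide mapping")
    order: list = []
    groups: dict = {}
    for i in range(psm_matrix.shape[0]):
        key = psm_to_peptide[i]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channel slices
        out = np.vstack(
            [np.nanmean(psm_matrix[groups[key]], axis=0) for key in order]
        )
    return out, order


def log2_with_floor(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log2-transform raw intensities, flooring zeros at the batch minimum
    positive intensity.

    Zero signals are legitimate observations (absent variant peptide) but
    need a finite log2 value; they are replaced by the smallest positive
    intensity in the batch and flagged in the returned boolean mask.
    """
    matrix = np.asarray(matrix, dtype=float)
    floored = (matrix == 0) & ~np.isnan(matrix)
    positive = matrix[(matrix > 0) & ~np.isnan(matrix)]
    if positive.size == 0:
        raise ValueError("no positive intensities in batch")
    floor = positive.min()
    out = np.where(floored, floor, matrix)
    with np.errstate(invalid="ignore"):
        return np.log2(out), floored


def mean_center(matrix: np.ndarray) -> np.ndarray:
    """Subtract the per-row (per-peptide) mean across channels; reporting only."""
    matrix = np.asarray(matrix, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return matrix - np.nanmean(matrix, axis=1, keepdims=True)


def scale_minmax(raw) -> np.ndarray | None:
    """Min-max scale one peptide's log2 channel values to [0, 1].

    ``y_i = (x_i - min(x)) / (max(x) - min(x))``; the minimum maps to 0 and
    the maximum to 1. Returns None for constant vectors (max == min): such
    peptides carry no genotype signal and are excluded downstream.
    """
    x = np.asarray(raw, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 nonmissing values to scale")
    lo, hi = np.nanmin(x[finite]), np.nanmax(x[finite])
    if hi == lo:
        return None
    return (x - lo) / (hi - lo)


def scale_minmax_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise min-max scaling; returns scaled matrix and a boolean mask of
    informative (non-constant) rows. Uninformative rows are all-NaN."""
    matrix = np.asarray(matrix, dtype=float)
    out = np.full_like(matrix, np.nan)
    informative = np.zeros(matrix.shape[0], dtype=bool)
    for i in range(matrix.shape[0]):
        finite = np.isfinite(matrix[i])
        if finite.sum() < 2:
            continue
        scaled = scale_minmax(matrix[i])
        if scaled is None:
            continue
        out[i] = scaled
        informative[i] = True
    return out, informative
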