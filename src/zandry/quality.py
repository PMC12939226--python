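"""Quality indicators and the multi-criteria comprehensive score.

Dried-product quality is summarized by four indicators per treatment
(drying method x temperature): CIELAB color difference dE against the fresh
sample, pericarp dehiscence rate (%), volatile-oil content (mL/10 g) and
amide content (mg/g).  The indicators are min-max normalized per column,
weighted (either by the information-entropy method or by a published weight
vector) and combined into a comprehensive score F reported on a 0-10
display scale.

Replicate color readings are screened with Chauvenet's criterion before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

__all__ = [
    "INDICATOR_COLUMNS",
    "PUBLISHED_WEIGHTS",
    "ColorMeasurement",
    "QualityTable",
    "ScoreResult",
    "delta_e",
    "chauvenet_filter",
    "dehiscence_rate",
    "amide_content",
    "normalize_indicator",
    "entropy_weights",
    "comprehensive_score",
    "score_table",
]

#: Indicator columns of a quality table, in canonical order.
INDICATOR_COLUMNS = ("delta_e", "dehiscence_rate", "volatile_oil", "amide")

#: Optimization direction per indicator: dE is a cost (lower is better),
#: the rest are benefits.
DEFAULT_DIRECTIONS = {
    "delta_e": "cost",
    "dehiscence_rate": "benefit",
    "volatile_oil": "benefit",
    "amide": "benefit",
}

#: Published weight vector for (dE, dehiscence, volatile oil, amide).  The
#: study reports these as its entropy-derived weights; they are shipped as
#: constants for reproducing its rankings, not as an expected output of
#: :func:`entropy_weights` (the replicate-level matrix behind them was
#: never released).
PUBLISHED_WEIGHTS = {
    "delta_e": 0.21,
    "dehiscence_rate": 0.18,
    "volatile_oil": 0.22,
    "amide": 0.39,
}


class ColorMeasurement(NamedTuple):
    """A CIELAB reading: L* lightness, a* red-green, b* yellow-blue."""

    lightness: float
    a: float
    b: float


def delta_e(sample: ColorMeasurement, reference: ColorMeasurement) -> float:
    """CIE76 color difference: Euclidean distance in (L*, a*, b*)."""
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    return float(np.sqrt(np.sum((s - r) ** 2)))


def chauvenet_filter(
    values: Sequence[float], min_retained: int = 2
) -> np.ndarray:
    """Single-pass Chauvenet outlier rejection on replicate measurements.

    A value x_i is rejected when n * erfc(|x_i - mean| / (sigma sqrt(2)))
    < 0.5, i.e. when fewer than half an observation is expected that far
    from the mean under normality.  No re-iteration after rejection; at
    least ``min_retained`` values (the closest to the mean) are always
    kept.  Fewer than 3 inputs are returned unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be a 1-D sequence")
    n = len(x)
    if n < 3:
        warnings.warn("Chauvenet's criterion needs at least 3 values; returning input")
        return x.copy()
    sigma = float(np.std(x))
    if sigma == 0.0:
        return x.copy()
    dev = np.abs(x - x.mean())
    keep = n * erfc(dev / (sigma * np.sqrt(2.0))) >= 0.5
    if keep.sum() < min_retained:
        order = np.argsort(dev)
        keep = np.zeros(n, dtype=bool)
        keep[order[:min_retained]] = True
    return x[keep]


def dehiscence_rate(n_dehiscent: int, n_total: int) -> float:
    """Percentage of pericarps split open: 100 * N_0 / N_t."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= n_dehiscent <= n_total:
        raise ValueError("dehiscent count must lie in [0, n_total]")
    return 100.0 * n_dehiscent / n_total


def amide_content(
    absorbance: float,
    dilution_factor: float,
    extract_volume_ml: float,
    sample_mass_g: float,
    absorptivity: float,
) -> float:
    """Amide content in mg/g from UV absorbance: X = A K V / (m E).

    ``absorptivity`` is the mass absorptivity of the target amides in
    L g^-1 cm^-1 for a 1 cm path.
    """
    if sample_mass_g <= 0 or absorptivity <= 0:
        raise ValueError("sample mass and absorptivity must be positive")
    return absorbance * dilution_factor * extract_volume_ml / (sample_mass_g * absorptivity)


def normalize_indicator(
    values: Sequence[float], direction: str = "cost"
) -> np.ndarray:
    """Min-max normalization of one indicator column to [0, 1].

    Cost columns use d = (X_max - X_i)/(X_max - X_min) (larger raw value ->
    worse -> smaller d); benefit columns use the mirrored form.  A constant
    column is degenerate: all d = 0.5 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if direction not in ("cost", "benefit"):
        raise ValueError("direction must be 'cost' or 'benefit'")
    span = float(x.max() - x.min())
    if span == 0.0:
        warnings.warn("constant indicator column; normalization is degenerate")
        return np.full_like(x, 0.5)
    if direction == "cost":
        return (x.max() - x) / span
    return (x - x.min()) / span


def entropy_weights(normalized: "np.ndarray | pd.DataFrame") -> np.ndarray:
    """Objective column weights from information entropy of a normalized matrix.

    p_ij = d_ij / sum_i d_ij, E_j = -(ln m)^-1 sum_i p_ij ln p_ij (with
    0 ln 0 := 0), W_j = (1 - E_j) / sum_j (1 - E_j).  A column of identical
    positive entries has maximal entropy and receives zero weight; an
    all-zero column is assigned E_j = 1 (zero weight) as the degenerate
    limit.  Weights are non-negative and sum to 1.
    """
    d = np.asarray(normalized, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    if np.any(d < 0) or np.any(d > 1 + 1e-12):
        raise ValueError("normalized values must lie in [0, 1]")
    m = d.shape[0]
    col_sum = d.sum(axis=0)
    entropy = np.ones(d.shape[1])  # degenerate all-zero columns -> E = 1
    pos = col_sum > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = d[:, pos] / col_sum[pos]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy[pos] = -plogp.sum(axis=0) / np.log(m)
    one_minus = 1.0 - entropy
    total = one_minus.sum()
    if total <= 0:
        raise ValueError("all columns are maximally entropic; weights undefined")
    return one_minus / total


def comprehensive_score(
    normalized_row: Sequence[float], weights: Sequence[float]
) -> tuple[float, float]:
    """Weighted comprehensive quality score F for one treatment.

    Returns ``(f_display, f_raw)`` where f_raw = sum(d_i W_j) in [0, 1]
    and f_display = 10 * f_raw matches the study's 0-10 reporting scale.
    """
    d = np.asarray(normalized_row, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise ValueError("normalized row and weights must have equal length")
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to 1")
    raw = float(np.dot(d, w))
    return 10.0 * raw, raw


@dataclass
class QualityTable:
    """Per-treatment quality indicators (means and SDs) with directions.

    ``means`` is indexed by treatment (e.g. "MVD-60") with the columns of
    :data:`INDICATOR_COLUMNS`; ``sds`` matches; ``directions`` maps each
    column to 'cost' or 'benefit'.
    """

    means: pd.DataFrame
    sds: "pd.DataFrame | None" = None
    directions: "dict | None" = None

    def __post_init__(self) -> None:
        if self.directions is None:
            self.directions = {
                c: DEFAULT_DIRECTIONS.get(c, "benefit") for c in self.means.columns
            }
        missing = set(self.means.columns) - set(self.directions)
        if missing:
            raise ValueError(f"directions missing for columns: {sorted(missing)}")
        if len(self.means) < 2:
            raise ValueError("a quality table needs at least 2 treatments")
        if self.sds is not None and (self.sds.values < 0).any():
            raise ValueError("SDs must be non-negative")

    def normalized(self) -> pd.DataFrame:
        data = {
            col: normalize_indicator(self.means[col].to_numpy(), self.directions[col])
            for col in self.means.columns
        }
        return pd.DataFrame(data, index=self.means.index)


@dataclass
class ScoreResult:
    """Normalization, weights and comprehensive scores for a quality table."""

    normalized: pd.DataFrame
    weights: pd.Series
    entropy: "pd.Series | None"
    f_display: pd.Series
    f_raw: pd.Series

    def ranking(self) -> pd.Series:
        return self.f_display.sort_values(ascending=False)


def score_table(
    table: QualityTable, weights: "str | Sequence[float] | dict" = "published"
) -> ScoreResult:
    """Normalize a quality table, weight its columns and score every treatment.

    ``weights`` is ``"published"`` (the study's weight vector, the default
    for reproducing its rankings), ``"entropy"`` (self-computed via
    :func:`entropy_weights`), or an explicit vector/mapping.  The two named
    schemes are never mixed.
    """
    norm = table.normalized()
    entropy = None
    if isinstance(weights, str) and weights == "published":
        try:
            w = np.array([PUBLISHED_WEIGHTS[c] for c in norm.columns])
        except KeyError as exc:
            raise ValueError(
                f"no published weight for column {exc}; use explicit weights"
            ) from exc
    elif isinstance(weights, str) and weights == "entropy":
        w = entropy_weights(norm.to_numpy())
        m = len(norm)
        col_sum = norm.sum(axis=0).to_numpy()
        e = np.ones(norm.shape[1])
        for j, s in enumerate(col_sum):
            if s > 0:
                p = norm.iloc[:, j].to_numpy() / s
                pos = p > 0
                e[j] = -np.sum(p[pos] * np.log(p[pos])) / np.log(m)
        entropy = pd.Series(e, index=norm.columns)
    elif isinstance(weights, str):
        raise ValueError("weights must be 'published', 'entropy' or a vector")
    elif isinstance(weights, dict):
        w = np.array([weights[c] for c in norm.columns], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    scores = norm.to_numpy() @ w
    return ScoreResult(
        normalized=norm,
        weights=pd.Series(w, index=norm.columns),
        entropy=entropy,
        f_display=pd.Series(10.0 * scores, index=norm.index, name="F"),
        f_raw=pd.Series(scores, index=norm.index, name="F_raw"),
    )
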