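"""Fold statistics, activity calls, orthogonal-subset selection and
predicted-vs-measured comparison for sigma x promoter crosstalk screens.

Conventions: fluorescence is summarised by geometric means (flow-cytometry
events have positive, roughly lognormal distributions); fold induction is
activity with the sigma divided by reporter-only activity; a sigma counts
as active when it activates some promoter strictly more than 5-fold, an
anti-sigma when it represses strictly more than 2-fold. Off-target load of
a cognate pair sums the baseline-subtracted fold of every off-diagonal
cell in the pair's row and column (a silent cell, fold 1, contributes 0;
cells below baseline are clipped at 0 so loads stay nonnegative under
measurement noise).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, ValidationError

MATRIX_KINDS = ("fold_induction", "model_score", "fold_repression")


@dataclass
class CrosstalkMatrix:
    """sigma x promoter matrix of measured folds or model scores."""

    data: pd.DataFrame  # index: sigma ids, columns: promoter ids
    kind: str = "fold_induction"

    def __post_init__(self):
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("duplicate sigma or promoter ids in matrix")
        if self.kind.startswith("fold") and (self.data.values <= 0).any():
            raise ValidationError("fold matrices must be strictly positive")

    @property
    def sigma_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def promoter_ids(self) -> List[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind: {self.kind}\n")
            self.data.to_csv(fh, sep="\t", index_label="sigma")

    @classmethod
    def from_tsv(cls, path) -> "CrosstalkMatrix":
        kind = "fold_induction"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# kind:"):
                kind = first.split(":", 1)[1].strip()
        df = pd.read_csv(path, sep="\t", comment="#", index_col="sigma")
        return cls(data=df, kind=kind)


@dataclass
class GrowthCurve:
    """OD600 time course (1 cm pathlength normalised)."""

    times: np.ndarray  # hours
    od600: np.ndarray
    strain_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValidationError("times and od600 must have equal length")
        if not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be strictly increasing")
        if (self.od600 <= 0).any():
            raise ValidationError("od600 must be positive")


@dataclass
class OrthogonalSelection:
    """k cognate pairs ordered by ascending off-target load."""

    pairs: List[Tuple[str, str]]
    offtarget_load: List[float]

    def __post_init__(self):
        if any(b < a - 1e-9 for a, b in zip(self.offtarget_load, self.offtarget_load[1:])):
            raise ValidationError("pairs must be ordered by non-decreasing load")


# ---------------------------------------------------------------------------
# Fold statistics


def geometric_mean_fluorescence(events: Sequence[float]) -> float:
    """Geometric mean of the positive events (values <= 0 are gated out)."""
    arr = np.asarray(list(events), dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValidationError("no positive fluorescence events after gating")
    return float(np.exp(np.mean(np.log(arr))))


def fold_induction(with_sigma: float, reporter_only: float) -> float:
    if reporter_only <= 0:
        raise ValidationError("reporter-only fluorescence must be positive")
    return with_sigma / reporter_only


def fold_repression(sigma_only: float, sigma_plus_anti: float) -> float:
    if sigma_only <= 0 or sigma_plus_anti <= 0:
        raise ValidationError("fluorescence values must be positive")
    return sigma_only / sigma_plus_anti


def classify_activity(
    matrix: CrosstalkMatrix,
    sigma_threshold: float = 5.0,
    anti_threshold: float = 2.0,
) -> Set[str]:
    """Active regulators: row max strictly above the threshold.

    fold_induction matrices classify sigmas (>5-fold); fold_repression
    matrices classify anti-sigmas (>2-fold). Boundary equals inactive.
    """
    if matrix.kind == "fold_induction":
        threshold = sigma_threshold
    elif matrix.kind == "fold_repression":
        threshold = anti_threshold
    else:
        raise ValidationError("classify_activity needs a fold matrix")
    rowmax = matrix.data.max(axis=1)
    return set(rowmax.index[rowmax > threshold])


# ---------------------------------------------------------------------------
# Orthogonality


def _pair_submatrix(matrix: CrosstalkMatrix, cognate_map: Dict[str, str]) -> pd.DataFrame:
    for s, p in cognate_map.items():
        if s not in matrix.data.index:
            raise ValidationError(f"sigma {s} missing from matrix")
        if p not in matrix.data.columns:
            raise ValidationError(f"cognate promoter {p} missing from matrix")
    sigmas = sorted(cognate_map)
    promoters = [cognate_map[s] for s in sigmas]
    if len(set(promoters)) != len(promoters):
        raise ValidationError("cognate map must be one-to-one")
    return matrix.data.loc[sigmas, promoters]


def offtarget_load(matrix: CrosstalkMatrix, cognate_map: Dict[str, str]) -> Dict[Tuple[str, str], float]:
    """Off-target load of each cognate pair over the paired submatrix.

    load(s, p) = sum of max(fold - 1, 0) over the pair's row and column,
    excluding the cognate cell itself.
    """
    sub = _pair_submatrix(matrix, cognate_map)
    excess = np.clip(sub.values - 1.0, 0.0, None)
    sigmas = list(sub.index)
    loads = {}
    for i, s in enumerate(sigmas):
        row = excess[i, :].sum() - excess[i, i]
        col = excess[:, i].sum() - excess[i, i]
        loads[(s, cognate_map[s])] = float(row + col)
    return loads


def select_orthogonal(matrix: CrosstalkMatrix, cognate_map: Dict[str, str], k: int) -> OrthogonalSelection:
    """Greedy most-orthogonal subset: repeatedly drop the cognate pair with
    the largest off-target load (recomputed on the surviving submatrix)
    until k remain. Removal ties break toward the lexicographically last
    sigma id; the returned pairs are ordered by ascending load within the
    surviving submatrix, ties by sigma id.
    """
    if k > len(cognate_map):
        raise ValidationError(f"k={k} exceeds the {len(cognate_map)} cognate pairs")
    if k < 1:
        raise ValidationError("k must be >= 1")
    remaining = dict(cognate_map)
    while len(remaining) > k:
        loads = offtarget_load(matrix, remaining)
        worst = max(loads.items(), key=lambda kv: (kv[1], kv[0][0]))
        del remaining[worst[0][0]]
    loads = offtarget_load(matrix, remaining)
    ordered = sorted(loads.items(), key=lambda kv: (kv[1], kv[0][0]))
    return OrthogonalSelection(
        pairs=[pair for pair, _ in ordered],
        offtarget_load=[load for _, load in ordered],
    )


def total_selection_load(matrix: CrosstalkMatrix, cognate_map: Dict[str, str], pairs: Sequence[Tuple[str, str]]) -> float:
    """Total off-target load of a candidate pair subset (for oracle comparison)."""
    sub = {s: p for s, p in pairs}
    return sum(offtarget_load(matrix, sub).values()) / 2.0


def scores_to_folds(
    scores: CrosstalkMatrix,
    cognate_map: Dict[str, str],
    cognate_fold: float = 100.0,
) -> CrosstalkMatrix:
    """Calibrate model scores into a predicted fold-induction matrix.

    Each sigma's row is normalised to its cognate score (its full activity),
    and bit differences decay the fold geometrically:
    fold(s, p) = 1 + (cognate_fold - 1) * 2^min(S(s,p) - S(s, cognate(s)), 0).
    A cell matching the cognate score predicts full activation; each bit
    below it halves the predicted excess over baseline.
    """
    if scores.kind != "model_score":
        raise ValidationError("scores_to_folds expects a model_score matrix")
    df = scores.data.copy().astype(float)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for s in df.index:
        if s not in cognate_map or cognate_map[s] not in df.columns:
            raise ValidationError(f"no cognate column for sigma {s}")
        delta = np.minimum(df.loc[s] - df.loc[s, cognate_map[s]], 0.0)
        out.loc[s] = 1.0 + (cognate_fold - 1.0) * np.exp2(delta)
    return CrosstalkMatrix(data=out, kind="fold_induction")


def compare_predicted_measured(
    scores: CrosstalkMatrix, folds: CrosstalkMatrix
) -> Tuple[float, pd.DataFrame]:
    """Spearman rank correlation between model scores and log2 measured folds.

    Returns (rho, per-cell table with sigma, promoter, score, fold,
    log2_fold columns). Matrices must have matching ids.
    """
    if scores.kind != "model_score" or not folds.kind.startswith("fold"):
        raise ValidationError("expected a model_score and a fold matrix")
    if list(scores.data.index) != list(folds.data.index) or list(scores.data.columns) != list(
        folds.data.columns
    ):
        raise ValidationError("matrix dimensions / ids do not match")
    rows = []
    for s in scores.data.index:
        for p in scores.data.columns:
            f = folds.data.loc[s, p]
            rows.append(
                {
                    "sigma": s,
                    "promoter": p,
                    "score": scores.data.loc[s, p],
                    "fold": f,
                    "log2_fold": np.log2(f),
                }
            )
    table = pd.DataFrame(rows)
    rho = float(stats.spearmanr(table["score"], table["log2_fold"]).statistic)
    return rho, table


# ---------------------------------------------------------------------------
# Growth assays


def growth_rate(curve: GrowthCurve, window: Optional[Tuple[int, int]] = None) -> float:
    """Growth rate mu (per hour) from the slope of ln(OD600) vs time.

    ``window`` is an index range (start, stop exclusive); when omitted, the
    maximal-slope contiguous 5-point window stands in for the 'linear
    section' of the curve.
    """
    ln_od = np.log(curve.od600)
    n = len(ln_od)
    if window is None:
        if n < 3:
            raise ValidationError("growth_rate needs at least 3 points")
        width = min(5, n)
        best = None
        for i in range(0, n - width + 1):
            slope = stats.linregress(curve.times[i : i + width], ln_od[i : i + width]).slope
            if best is None or slope > best[0]:
                best = (slope, i)
        return float(best[0])
    i, j = window
    if j - i < 3:
        raise ValidationError("growth window must contain at least 3 points")
    return float(stats.linregress(curve.times[i:j], ln_od[i:j]).slope)


def percent_of_wt(value: float, wt_values: Sequence[float], toxic_below: float = 75.0) -> Tuple[float, bool]:
    """Express a growth measure as % of the wild-type mean; toxic iff strictly
    below the threshold (75% by default; the boundary itself is non-toxic)."""
    wt = np.asarray(list(wt_values), dtype=float)
    if wt.size == 0 or wt.mean() <= 0:
        raise ValidationError("WT values must be non-empty with positive mean")
    pct = 100.0 * value / wt.mean()
    return float(pct), bool(pct < toxic_below)
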