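"""Coarse-grained candidate screening by mixed context likelihood of relatedness.

Mutual information is estimated by rank transformation followed by
equal-count binning and the plug-in estimator on the joint histogram
(nats).  The mixed-CLR background correction z-scores each dynamic MI value
m_dyn(g, tf) twice: against the distribution of row g of the dynamic
(response vs TF) MI matrix, and against the distribution of column tf of the
static (TF expression vs TF expression) MI matrix — so a TF that is
promiscuously informative about everything is discounted.  Negative z are
clipped to 0 and the combined score is s = sqrt(z_row^2 + z_col^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError, warn


def _rank_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin labels of the rank transform (stable tie order)."""
    n = len(v)
    order = np.argsort(v, kind="stable")
    bins = np.empty(n, dtype=np.intp)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def default_bins(n_samples: int) -> int:
    return max(2, int(math.floor(math.sqrt(n_samples))))


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in MI (nats) of rank-binned x and y; 0 for a constant vector.

    Invariant to strictly increasing transforms of either argument because
    only ranks enter the histogram.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 4:
        raise ValidationError("mutual_information needs >= 4 samples")
    if n_bins is None:
        n_bins = default_bins(len(x))
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warn("constant vector in mutual_information; returning 0")
        return 0.0
    bx = _rank_bins(x, n_bins)
    by = _rank_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins), dtype=float)
    np.add.at(joint, (bx, by), 1.0)
    joint /= len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mi_matrix(rows: pd.DataFrame, cols: pd.DataFrame, n_bins: int | None = None) -> pd.DataFrame:
    """MI between every row of ``rows`` and every row of ``cols`` (aligned
    on identical columns); result indexed rows x cols."""
    if list(rows.columns) != list(cols.columns):
        raise ValidationError("row and column tables must share the same samples")
    out = np.zeros((rows.shape[0], cols.shape[0]))
    rvals = rows.to_numpy(dtype=float)
    cvals = cols.to_numpy(dtype=float)
    # constant rows are common in sparse designs; their MI is 0 by definition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(rows.shape[0]):
            for j in range(cols.shape[0]):
                out[i, j] = mutual_information(rvals[i], cvals[j], n_bins)
    return pd.DataFrame(out, index=rows.index, columns=cols.index)


@dataclass
class CLRScores:
    """Combined mixed-CLR scores with their component z-scores."""

    scores: pd.DataFrame
    z_row: pd.DataFrame
    z_col: pd.DataFrame


def clr_scores(m_dyn: pd.DataFrame, m_stat: pd.DataFrame) -> CLRScores:
    """Mixed-CLR background correction.

    ``m_dyn``: targets x TFs dynamic MI (response vs TF expression).
    ``m_stat``: TFs x TFs static MI (expression vs expression); its column
    sets must match m_dyn's columns.  z uses the sample (n-1) standard
    deviation; sigma = 0 yields z = 0.
    """
    if list(m_dyn.columns) != list(m_stat.columns):
        raise ValidationError("m_dyn and m_stat must have identical TF columns")
    dyn = m_dyn.to_numpy(dtype=float)
    stat = m_stat.to_numpy(dtype=float)

    mu_r = dyn.mean(axis=1, keepdims=True)
    sd_r = dyn.std(axis=1, ddof=1, keepdims=True) if dyn.shape[1] > 1 else np.zeros_like(mu_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        zr = np.where(sd_r > 0, (dyn - mu_r) / sd_r, 0.0)
    zr = np.maximum(zr, 0.0)

    # self-pairs (MI of a TF with itself) are a degenerate maximum, not a
    # draw from the background; mask them out of the column statistics
    stat_bg = stat.astype(float).copy()
    row_labels, col_labels = list(m_stat.index), list(m_stat.columns)
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_labels):
            if r == c:
                stat_bg[i, j] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu_c = np.nanmean(stat_bg, axis=0, keepdims=True)
        sd_c = np.nanstd(stat_bg, axis=0, ddof=1, keepdims=True)
    mu_c = np.where(np.isfinite(mu_c), mu_c, 0.0)
    sd_c = np.where(np.isfinite(sd_c), sd_c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zc = np.where(sd_c > 0, (dyn - mu_c) / sd_c, 0.0)
    zc = np.maximum(zc, 0.0)

    s = np.sqrt(zr**2 + zc**2)
    idx, cols = m_dyn.index, m_dyn.columns
    return CLRScores(
        pd.DataFrame(s, index=idx, columns=cols),
        pd.DataFrame(zr, index=idx, columns=cols),
        pd.DataFrame(zc, index=idx, columns=cols),
    )


def select_candidates(s: CLRScores, top_q: int = 50) -> dict[str, list[str]]:
    """Per-target candidate TF lists: score > 0, sorted by score descending
    (ties broken by TF identifier), truncated to ``top_q``; a target never
    appears among its own candidates."""
    if top_q < 1:
        raise ValidationError("top_q must be >= 1")
    out: dict[str, list[str]] = {}
    for target in s.scores.index:
        row = s.scores.loc[target]
        positive = [(tf, val) for tf, val in row.items() if val > 0 and tf != target]
        positive.sort(key=lambda p: (-p[1], p[0]))
        out[target] = [tf for tf, _ in positive[:top_q]]
    return out
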