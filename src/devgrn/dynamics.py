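"""ODE response construction: expression time series -> per-gene responses.

The inference model assumes first-order mRNA decay with rate
lambda = ln(2)/half_life.  Between consecutive samples t_k < t_{k+1} of one
continuous series, the net transcriptional drive on gene g is approximated by

    r_g(k) = (x_g(t_{k+1}) - x_g(t_k)) / (t_{k+1} - t_k) + lambda * x_g(t_k),

the finite-difference derivative plus the decay term, with the decay
evaluated at the interval start.  TF predictor columns are TF expression at
the interval start t_k (causal convention); the last timepoint of a series
contributes only through its preceding interval.  Replicates are averaged
before differencing.  Expression enters untransformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
    validate_pair,
    warn,
)


@dataclass(frozen=True)
class DecayModel:
    """First-order decay parameterized by mRNA half-life in hours."""

    half_life_h: float

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0 or math.isinf(self.half_life_h)):
            raise ValidationError("half-life must be > 0")

    @property
    def rate(self) -> float:
        """Decay rate lambda = ln(2)/half_life, per hour; 0 for infinite half-life."""
        if math.isinf(self.half_life_h):
            return 0.0
        return math.log(2.0) / self.half_life_h


@dataclass
class TimeSeriesDesign:
    """Responses (gene x interval) and TF predictors (TF x interval).

    Intervals join consecutive timepoints within one series; column ``k``
    corresponds to the interval starting at ``interval_times[k][0]``.
    """

    responses: pd.DataFrame
    predictors: pd.DataFrame
    interval_times: list[tuple[float, float]]
    series_of_interval: list[str] = field(default_factory=list)

    @property
    def n_intervals(self) -> int:
        return self.responses.shape[1]

    @property
    def targets(self) -> list[str]:
        return list(self.responses.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.predictors.index)


def average_replicates(expr: ExpressionMatrix, meta: SampleMetadata) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Arithmetic mean across replicates sharing (series_id, time_hpf).

    The collapsed metadata keeps one sample per (series, time) with
    replicate 1, named after the replicate-1 sample where present.
    """
    validate_pair(expr, meta)
    mt = meta.table.sort_values(["series_id", "time_hpf", "replicate"])
    cols, rows = [], []
    for (series, time), grp in mt.groupby(["series_id", "time_hpf"], sort=False):
        sample_ids = list(grp["sample_id"])
        mean = expr.data[sample_ids].mean(axis=1)
        name = sample_ids[0]
        cols.append(mean.rename(name))
        rows.append({"sample_id": name, "time_hpf": time, "series_id": series, "replicate": 1})
    data = pd.concat(cols, axis=1)
    return ExpressionMatrix(data, expr.unit_label), SampleMetadata(pd.DataFrame(rows))


def build_design(expr: ExpressionMatrix, meta: SampleMetadata, decay: DecayModel,
                 tf_ids) -> TimeSeriesDesign:
    """Build per-gene response vectors and the TF predictor matrix.

    Every gene in ``expr`` becomes a target row; every ``tf_ids`` entry (all
    must be measured) a predictor row.  Series with a single timepoint are
    skipped with a warning; tied timepoints within a series are an error.
    """
    validate_pair(expr, meta)
    tf_ids = list(tf_ids)
    missing = [tf for tf in tf_ids if tf not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"TF {missing[0]!r} not in expression matrix")
    lam = decay.rate

    resp_cols, pred_cols, itimes, iseries = [], [], [], []
    mt = meta.table
    for series, grp in mt.groupby("series_id", sort=False):
        grp = grp.sort_values("time_hpf")
        times = grp["time_hpf"].to_numpy(dtype=float)
        if len(times) < 2:
            warn(f"series {series!r} has a single timepoint; skipped")
            continue
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"non-monotone timepoints in series {series!r}")
        samples = list(grp["sample_id"])
        x = expr.data[samples].to_numpy(dtype=float)
        dt = np.diff(times)
        r = (x[:, 1:] - x[:, :-1]) / dt + lam * x[:, :-1]
        resp_cols.append(r)
        pred_cols.append(expr.data.loc[tf_ids, samples[:-1]].to_numpy(dtype=float))
        itimes.extend(zip(times[:-1], times[1:]))
        iseries.extend([series] * (len(times) - 1))
    if not resp_cols:
        raise ValidationError("no series with >= 2 timepoints")
    col_names = [f"iv{i}" for i in range(len(itimes))]
    responses = pd.DataFrame(np.hstack(resp_cols), index=expr.gene_ids, columns=col_names)
    predictors = pd.DataFrame(np.hstack(pred_cols), index=tf_ids, columns=col_names)
    return TimeSeriesDesign(responses, predictors, itimes, iseries)
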