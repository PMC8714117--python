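"""Fine-grained refinement: per-target Elastic Net over CLR candidates.

For each target gene, the response vector is regressed on its candidate TF
predictors under the Elastic Net objective

    (1/2n) ||r - X beta||^2 + alpha * (rho ||beta||_1 + (1-rho)/2 ||beta||_2^2),

with response and predictors standardized internally to zero mean / unit
variance, and alpha chosen on a descending grid by cross-validated MSE with
contiguous-block folds (time-series data: random shuffles would leak
temporal dependence across folds).

Each retained TF gets a signed confidence: the drop in full-fit R^2 when
that TF is removed and the model refit at the same alpha, signed by its
coefficient.  The score is bounded in [-1, 1] and comparable across
targets.  Thresholding and ranking produce the final prediction table: per
target, |confidence| above the reporting threshold ("peak value"), at most
30 ranked regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .containers import (
    MAX_PREDICTIONS_PER_TARGET,
    ExpressionMatrix,
    PredictionTable,
    SampleMetadata,
    ValidationError,
    warn,
)
from .clr import clr_scores, mi_matrix, select_candidates
from .dynamics import DecayModel, TimeSeriesDesign, average_replicates, build_design

MIN_INTERVALS = 4


@dataclass
class PenaltyConfig:
    """Elastic Net penalty and cross-validation settings.

    rho: L1 mixing weight in (0, 1].
    alpha_grid: descending penalty strengths; None derives a 30-point
        log-spaced grid from alpha_max (smallest alpha giving the all-zero
        solution) down by a factor 10^3.
    cv_folds: requested fold count; effectively min(cv_folds, n_intervals).
    repeat: >1 re-runs the fit on interval resamples and averages |c|.
    top_q: CLR candidates kept per target before the fit.
    """

    rho: float = 0.5
    alpha_grid: np.ndarray | None = None
    cv_folds: int = 5
    seed: int = 0
    repeat: int = 1
    top_q: int = 50
    n_alphas: int = 30
    alpha_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValidationError("rho must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.repeat < 1:
            raise ValidationError("repeat must be >= 1")


@dataclass
class FitResult:
    target_id: str
    coefficients: pd.Series  # standardized scale, indexed by candidate TF
    intercept: float
    alpha: float
    r2_full: float
    rho: float = 0.5
    dropped: list[str] = field(default_factory=list)


def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    return np.divide(a - mu, sd, out=np.zeros_like(a, dtype=float), where=sd > 0), sd


def _alpha_grid(Xs: np.ndarray, rs: np.ndarray, cfg: PenaltyConfig) -> np.ndarray:
    if cfg.alpha_grid is not None:
        grid = np.asarray(cfg.alpha_grid, dtype=float)
        if np.any(np.diff(grid) >= 0):
            raise ValidationError("alpha_grid must be strictly descending")
        return grid
    n = len(rs)
    alpha_max = np.max(np.abs(Xs.T @ rs)) / (n * cfg.rho)
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, alpha_max * cfg.alpha_ratio, cfg.n_alphas)


def _block_folds(n: int, k: int) -> list[np.ndarray]:
    """Contiguous blocks of interval indices, as equal as possible."""
    return [f for f in np.array_split(np.arange(n), k) if len(f)]


def _fit_at(Xs: np.ndarray, rs: np.ndarray, alpha: float, rho: float) -> ElasticNet:
    model = ElasticNet(alpha=alpha, l1_ratio=rho, fit_intercept=True, max_iter=20000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, rs)
    return model


def _r2(model: ElasticNet, Xs: np.ndarray, rs: np.ndarray) -> float:
    resid = rs - model.predict(Xs)
    ss_tot = float(np.sum((rs - rs.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def fit_elastic_net(r, X: pd.DataFrame, cfg: PenaltyConfig,
                    target_id: str = "") -> FitResult:
    """Fit the Elastic Net for one target.

    ``r``: response over intervals; ``X``: intervals x candidate-TF predictor
    frame.  Zero-variance predictors are dropped with a warning.  Returns
    standardized-scale coefficients, the CV-chosen alpha and the full-fit R^2.
    """
    r = np.asarray(r, dtype=float)
    if len(r) < MIN_INTERVALS:
        raise ValidationError(f"need >= {MIN_INTERVALS} intervals, got {len(r)}")
    if X.shape[1] < 1:
        raise ValidationError("need >= 1 candidate predictor")
    if X.shape[0] != len(r):
        raise ValidationError("response/predictor length mismatch")

    sd = X.to_numpy(dtype=float).std(axis=0)
    dropped = [c for c, s in zip(X.columns, sd) if s == 0]
    if dropped:
        warn(f"dropping zero-variance predictors: {dropped}")
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        return FitResult(target_id, pd.Series(dtype=float), 0.0, np.nan, 0.0,
                         cfg.rho, dropped)

    Xs, _ = _standardize(X.to_numpy(dtype=float))
    rs, r_sd = _standardize(r.reshape(-1, 1))
    rs = rs.ravel()
    grid = _alpha_grid(Xs, rs, cfg)

    n = len(rs)
    k = max(2, min(cfg.cv_folds, n))
    folds = _block_folds(n, k)
    cv_mse = np.zeros(len(grid))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        Xt, rt = Xs[train], rs[train]
        for a_i, alpha in enumerate(grid):
            model = _fit_at(Xt, rt, alpha, cfg.rho)
            pred = model.predict(Xs[fold])
            cv_mse[a_i] += float(np.sum((rs[fold] - pred) ** 2))
    cv_mse /= n
    best = int(np.argmin(cv_mse))  # ties -> largest alpha (grid is descending)
    alpha = float(grid[best])

    model = _fit_at(Xs, rs, alpha, cfg.rho)
    coefs = pd.Series(model.coef_, index=X.columns)
    return FitResult(target_id, coefs, float(model.intercept_), alpha,
                     _r2(model, Xs, rs), cfg.rho, dropped)


def confidence_scores(r, X: pd.DataFrame, fit: FitResult) -> pd.Series:
    """Signed leave-one-TF-out variance-explained confidence.

    c_j = sign(beta_j) * max(0, R2_full - R2 of the refit without TF j at the
    same alpha).  TFs with beta_j = 0 are excluded.  c in [-1, 1].
    """
    nonzero = [tf for tf in fit.coefficients.index if fit.coefficients[tf] != 0]
    if not nonzero:
        return pd.Series(dtype=float)
    X = X[list(fit.coefficients.index)]
    Xs, _ = _standardize(X.to_numpy(dtype=float))
    rs, _ = _standardize(np.asarray(r, dtype=float).reshape(-1, 1))
    rs = rs.ravel()
    cols = list(X.columns)
    out = {}
    for tf in nonzero:
        rest = [i for i, c in enumerate(cols) if c != tf]
        if rest:
            sub = _fit_at(Xs[:, rest], rs, fit.alpha, fit.rho)
            r2_wo = _r2(sub, Xs[:, rest], rs)
        else:
            r2_wo = 0.0  # intercept-only model explains nothing of standardized r
        drop = max(0.0, fit.r2_full - r2_wo)
        out[tf] = float(np.sign(fit.coefficients[tf]) * min(drop, 1.0))
    return pd.Series(out)


def rank_and_threshold(all_conf: dict[str, pd.Series], peak_value: float = 0.0,
                       max_per_target: int = MAX_PREDICTIONS_PER_TARGET) -> PredictionTable:
    """Threshold |c| > peak_value, rank per target by |c| descending
    (ties: TF identifier), truncate to ``max_per_target``."""
    if peak_value < 0:
        raise ValidationError("peak_value must be >= 0")
    rows = []
    for target in sorted(all_conf):
        conf = all_conf[target]
        kept = [(tf, c) for tf, c in conf.items() if abs(c) > peak_value and tf != target]
        kept.sort(key=lambda p: (-abs(p[1]), p[0]))
        for rank, (tf, c) in enumerate(kept[:max_per_target], start=1):
            rows.append({"regulator": tf, "target": target, "confidence": c, "rank": rank})
    if not rows:
        return PredictionTable(
            pd.DataFrame(columns=["regulator", "target", "confidence", "rank"]))
    return PredictionTable(pd.DataFrame(rows))


def _fit_target(target: str, design: TimeSeriesDesign, candidates: list[str],
                cfg: PenaltyConfig, interval_idx: np.ndarray | None = None) -> pd.Series:
    r = design.responses.loc[target].to_numpy(dtype=float)
    X = design.predictors.loc[candidates].T  # intervals x TFs
    if interval_idx is not None:
        r = r[interval_idx]
        X = X.iloc[interval_idx]
    fit = fit_elastic_net(r, X, cfg, target_id=target)
    return confidence_scores(r, X, fit)


def infer_network(expr: ExpressionMatrix, meta: SampleMetadata, tf_ids,
                  decay: DecayModel, cfg: PenaltyConfig,
                  peak_value: float = 0.0,
                  mi_bins: int | None = None) -> PredictionTable:
    """End-to-end inference: responses -> mixed CLR -> Elastic Net -> table.

    With ``cfg.repeat > 1`` the per-target fit is repeated on interval
    resamples (with replacement, seeds cfg.seed + i), |confidence| averaged
    across repeats and the majority sign kept.
    """
    tf_ids = sorted(set(tf_ids))
    if not tf_ids:
        return rank_and_threshold({}, peak_value)
    expr_avg, meta_avg = average_replicates(expr, meta)
    design = build_design(expr_avg, meta_avg, decay, tf_ids)
    if design.n_intervals < MIN_INTERVALS:
        raise ValidationError("too few intervals for inference")

    m_dyn = mi_matrix(design.responses, design.predictors, mi_bins)
    tf_expr = expr_avg.data.loc[tf_ids]
    m_stat = mi_matrix(tf_expr, tf_expr, mi_bins)
    candidates = select_candidates(clr_scores(m_dyn, m_stat), cfg.top_q)

    all_conf: dict[str, pd.Series] = {}
    n = design.n_intervals
    for target in design.targets:
        cand = candidates.get(target, [])
        if not cand:
            continue
        if cfg.repeat == 1:
            conf = _fit_target(target, design, cand, cfg)
        else:
            # |c| is averaged over ALL repeats (zero when a TF is not
            # selected), so the ensemble score carries selection stability
            acc: dict[str, list[float]] = {tf: [] for tf in cand}
            for i in range(cfg.repeat):
                rng = np.random.default_rng(cfg.seed + i)
                idx = np.sort(rng.integers(0, n, size=n))
                try:
                    c_i = _fit_target(target, design, cand, cfg, idx)
                except ValidationError:
                    continue
                for tf in cand:
                    acc[tf].append(float(c_i.get(tf, 0.0)))
            conf = pd.Series({
                tf: float(np.sign(np.sum(np.sign(vals)) or 1.0) * np.mean(np.abs(vals)))
                for tf, vals in acc.items()
                if vals and np.any(np.asarray(vals) != 0)
            }, dtype=float)
        conf = conf[conf != 0]
        if len(conf):
            all_conf[target] = conf
    return rank_and_threshold(all_conf, peak_value)
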