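"""Typed containers for every table the pipeline touches.

All containers wrap :class:`pandas.DataFrame` and validate their invariants
on construction, so downstream stages can assume clean inputs.  Expression is
a gene-by-sample matrix of nonnegative abundances (RPKM, normalized counts,
or transcripts per embryo); sample metadata locates each column on the
developmental time axis (hours post fertilization) within a continuous
series; edge lists and prediction tables are directed regulator -> target
relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_PREDICTIONS_PER_TARGET = 30


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate {what}: {sorted(set(dup))!r}")


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample abundance matrix.

    ``data`` has gene identifiers as the index and sample identifiers as
    columns; ``unit_label`` is free text describing the abundance unit.
    """

    data: pd.DataFrame
    unit_label: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene_ids")
        _check_unique(self.data.columns, "sample_ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.any(~np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if np.any(values < 0):
            bad = self.data.index[(values < 0).any(axis=1)][0]
            raise ValidationError(f"negative expression value for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleMetadata:
    """Per-sample time (hpf), series and replicate labels.

    ``table`` columns: sample_id, time_hpf, series_id, replicate.  Within a
    series, (time_hpf, replicate) pairs are unique; every sample_id must
    appear in the paired expression matrix (checked by :func:`validate_pair`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "time_hpf", "series_id", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        _check_unique(self.table["sample_id"], "sample_id")
        if (self.table["time_hpf"] < 0).any():
            raise ValidationError("time_hpf must be >= 0")
        if (self.table["replicate"] < 1).any():
            raise ValidationError("replicate must be >= 1")
        dup = self.table.duplicated(subset=["series_id", "time_hpf", "replicate"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ValidationError(
                "duplicate (series, time, replicate): "
                f"({row['series_id']}, {row['time_hpf']}, {row['replicate']})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


def validate_pair(expr: ExpressionMatrix, meta: SampleMetadata) -> None:
    """Check every metadata sample is a column of the expression matrix."""
    missing = set(meta.sample_ids) - set(expr.sample_ids)
    if missing:
        raise ValidationError(
            f"metadata samples missing from expression header: {sorted(missing)}"
        )


@dataclass
class GeneAnnotation:
    """Transcript -> gene map with optional length and TF / regulatory-GO flags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "transcript_id" not in self.table.columns or "gene_id" not in self.table.columns:
            raise ValidationError("annotation needs transcript_id and gene_id columns")
        _check_unique(self.table["transcript_id"], "transcript_id")
        if "transcript_length_bp" in self.table.columns:
            lengths = self.table["transcript_length_bp"].dropna()
            if (lengths <= 0).any():
                raise ValidationError("transcript_length_bp must be > 0")

    def gene_of(self) -> pd.Series:
        return self.table.set_index("transcript_id")["gene_id"]

    def tf_ids(self) -> list[str]:
        if "is_tf" not in self.table.columns:
            return []
        sub = self.table[self.table["is_tf"].astype(bool)]
        return sorted(set(sub["gene_id"]))


@dataclass
class EdgeList:
    """Directed (regulator, target) rows with optional sign and provenance.

    ``sign`` is +1 (enhancing), -1 (repressive) or 0 (unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("regulator", "target"):
            if col not in self.table.columns:
                raise ValidationError(f"edge list needs column {col!r}")
        if "sign" not in self.table.columns:
            self.table = self.table.assign(sign=0)
        if "provenance" not in self.table.columns:
            self.table = self.table.assign(provenance="")

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["regulator"], self.table["target"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GroundTruthNetwork:
    """Curated benchmark edge list: deduplicated, no self-loops, restricted
    to the measured gene universe, signaling-intermediate edges removed."""

    table: pd.DataFrame

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["regulator"], self.table["target"]))

    def signs(self) -> dict[tuple[str, str], int]:
        if "sign" not in self.table.columns:
            return {}
        return {
            (r, t): int(s)
            for r, t, s in zip(self.table["regulator"], self.table["target"], self.table["sign"])
            if s != 0
        }

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PredictionTable:
    """Directed predictions with signed confidence and per-target ranks.

    Within each target, ranks run 1..k (k <= 30) and |confidence| is
    non-increasing in rank.  The confidence sign encodes the predicted mode:
    + enhancing, - repressive.  Self-edges are structurally forbidden.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["regulator", "target", "confidence", "rank"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"prediction table missing columns: {missing}")
        if (self.table["regulator"] == self.table["target"]).any():
            bad = self.table[self.table["regulator"] == self.table["target"]].iloc[0]
            raise ValidationError(f"self-edge in predictions: {bad['target']!r}")
        dup = self.table.duplicated(subset=["regulator", "target"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ValidationError(
                f"duplicate predicted edge ({row['regulator']}, {row['target']})"
            )
        for target, grp in self.table.groupby("target", sort=False):
            grp = grp.sort_values("rank")
            k = len(grp)
            if k > MAX_PREDICTIONS_PER_TARGET:
                raise ValidationError(
                    f"target {target!r} has {k} predictions "
                    f"(max {MAX_PREDICTIONS_PER_TARGET})"
                )
            if list(grp["rank"]) != list(range(1, k + 1)):
                raise ValidationError(f"ranks for target {target!r} are not 1..{k}")
            conf = np.abs(grp["confidence"].to_numpy())
            if np.any(np.diff(conf) > 1e-12):
                raise ValidationError(
                    f"|confidence| not non-increasing in rank for target {target!r}"
                )

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["regulator"], self.table["target"]))

    def __len__(self) -> int:
        return len(self.table)

    def sorted_by_confidence(self) -> pd.DataFrame:
        """All rows ordered by |confidence| descending (ties: regulator, target)."""
        df = self.table.assign(_abs=lambda d: d["confidence"].abs())
        df = df.sort_values(
            ["_abs", "regulator", "target"], ascending=[False, True, True]
        ).drop(columns="_abs")
        return df.reset_index(drop=True)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
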