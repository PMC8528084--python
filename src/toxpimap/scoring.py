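"""Slice and overall ToxPi score computation.

The scoring chain is: cohort-relative min-max scaling of each component to
[0, 1] (inverting protective, lower-is-worse components), a weighted mean of
scaled components within each slice (the slice score ``s_i``), and the
weighted mean of slice scores (the normalized overall score):

    overall = sum_i(w_i * s_i) / sum_i(w_i)

Scaling is relative to the input cohort: the minimum observed value of a
component maps to 0 and the maximum to 1, so scores are comparative, not
absolute. Missing values contribute 0 after scaling (the most conservative
slice contribution) and constant columns map to 0 for every record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .model import Direction, ToxPiModel

logger = logging.getLogger(__name__)


@dataclass
class DataMatrix:
    """A records x components table with WGS84 point locations.

    ``values`` is indexed by record id; ``lat``/``lon`` are aligned Series.
    """

    values: pd.DataFrame
    lat: pd.Series
    lon: pd.Series

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dupes = sorted(set(ids[ids.duplicated()].astype(str)))
            raise ValidationError(f"duplicate record ids: {dupes}")
        self.lat = pd.Series(self.lat, index=ids, dtype=float)
        self.lon = pd.Series(self.lon, index=ids, dtype=float)
        if ((self.lat < -90) | (self.lat > 90)).any():
            bad = self.lat[(self.lat < -90) | (self.lat > 90)].index.tolist()
            raise ValidationError(f"latitude out of [-90, 90] for records {bad}")
        if ((self.lon < -180) | (self.lon > 180)).any():
            bad = self.lon[(self.lon < -180) | (self.lon > 180)].index.tolist()
            raise ValidationError(f"longitude out of [-180, 180] for records {bad}")

    @property
    def record_ids(self) -> list[str]:
        return list(self.values.index.astype(str))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ToxPiResults:
    """Per-record slice scores in [0, 1] and the normalized overall score.

    ``slice_scores`` is a records x slices frame; ``overall`` an aligned
    Series. ``raw`` optionally keeps the unscaled component values so map
    popups can show the underlying data.
    """

    model: ToxPiModel
    slice_scores: pd.DataFrame
    overall: pd.Series
    lat: pd.Series
    lon: pd.Series
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        ss = self.slice_scores.to_numpy(dtype=float)
        if np.any(ss < -eps) or np.any(ss > 1 + eps):
            raise ValidationError("slice scores outside [0, 1]")
        ov = self.overall.to_numpy(dtype=float)
        if np.any(ov < -eps) or np.any(ov > 1 + eps):
            raise ValidationError("overall scores outside [0, 1]")

    @property
    def record_ids(self) -> list[str]:
        return list(self.slice_scores.index.astype(str))

    def __len__(self) -> int:
        return len(self.slice_scores)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id index, lat, lon, overall, one column per slice."""
        out = pd.DataFrame(
            {"lat": self.lat, "lon": self.lon, "overall": self.overall}
        )
        return pd.concat([out, self.slice_scores], axis=1)


def scale_components(matrix: DataMatrix, model: ToxPiModel) -> DataMatrix:
    """Min-max scale every model component over the cohort to [0, 1].

    Lower-is-worse components are inverted (1 - scaled) so that 1 always
    means "worst". Missing entries become 0 after scaling; a component with
    no spread maps to 0 for all records.
    """
    missing = [c for c in model.component_names if c not in matrix.values.columns]
    if missing:
        raise ConfigurationError(
            f"data matrix lacks model component column(s): {missing}"
        )
    directions = {
        c.name: c.direction for s in model.slices for c in s.components
    }
    scaled = {}
    n_missing = 0
    for name in model.component_names:
        col = pd.to_numeric(matrix.values[name], errors="coerce").astype(float)
        lo, hi = col.min(skipna=True), col.max(skipna=True)
        if pd.isna(lo) or hi == lo:
            out = pd.Series(0.0, index=col.index)
        else:
            out = (col - lo) / (hi - lo)
            if directions[name] is Direction.LOWER_IS_WORSE:
                out = 1.0 - out
        n_missing += int(col.isna().sum())
        scaled[name] = out.fillna(0.0)
    if n_missing:
        logger.warning("imputed %d missing component value(s) as 0 after scaling", n_missing)
    return DataMatrix(values=pd.DataFrame(scaled), lat=matrix.lat, lon=matrix.lon)


def compute_slice_scores(scaled: DataMatrix, model: ToxPiModel) -> pd.DataFrame:
    """Weighted mean of scaled components within each slice.

    Returns a records x slices frame; every entry lies in [0, 1] because the
    inputs do and within-slice weights are positive.
    """
    cols = {}
    for s in model.slices:
        w = np.array([c.weight for c in s.components], dtype=float)
        vals = scaled.values[[c.name for c in s.components]].to_numpy(dtype=float)
        cols[s.name] = vals @ (w / w.sum())
    return pd.DataFrame(cols, index=scaled.values.index)


def compute_overall(slice_scores, weights) -> np.ndarray | float:
    """Normalized overall score: sum(w_i * s_i) / sum(w_i).

    ``slice_scores`` may be a vector (one record) or a records x slices
    array/frame; the weighted mean is taken over the last axis.
    """
    s = np.asarray(slice_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape[-1] != w.shape[0]:
        raise ValidationError(
            f"length mismatch: {s.shape[-1]} slice scores vs {w.shape[0]} weights"
        )
    if np.any(w <= 0):
        raise ConfigurationError("slice weights must be > 0")
    return (s @ w) / w.sum()


def score(matrix: DataMatrix, model: ToxPiModel) -> ToxPiResults:
    """Run the full scoring chain on a raw component matrix."""
    scaled = scale_components(matrix, model)
    ss = compute_slice_scores(scaled, model)
    overall = pd.Series(
        compute_overall(ss.to_numpy(), model.weights), index=ss.index, name="overall"
    )
    return ToxPiResults(
        model=model,
        slice_scores=ss,
        overall=overall,
        lat=matrix.lat,
        lon=matrix.lon,
        raw=matrix.values[model.component_names].copy(),
    )


def aggregate_group_medians(results: ToxPiResults, grouping) -> ToxPiResults:
    """Collapse records to per-group median slice scores.

    ``grouping`` maps record id -> group label (dict or Series). The group
    overall is recomputed from the median slice scores via
    :func:`compute_overall`, keeping the aggregate glyph and its score
    consistent. Group positions default to the mean member location.
    Groups are emitted ordered by label.
    """
    g = pd.Series(grouping)
    unassigned = [r for r in results.record_ids if r not in g.index]
    if unassigned:
        raise ValidationError(f"records without a group label: {unassigned}")
    g = g.reindex(results.slice_scores.index)
    empty = set(g.unique()) - set(g.dropna().unique())
    if empty:
        warnings.warn(f"skipping empty group(s): {sorted(empty)}")
    med = results.slice_scores.groupby(g).median().sort_index()
    overall = pd.Series(
        compute_overall(med.to_numpy(), results.model.weights),
        index=med.index,
        name="overall",
    )
    lat = results.lat.groupby(g).mean().reindex(med.index)
    lon = results.lon.groupby(g).mean().reindex(med.index)
    return ToxPiResults(
        model=results.model,
        slice_scores=med,
        overall=overall,
        lat=lat,
        lon=lon,
    )
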