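"""Western-blot densitometric normalization and fold change.

Band densities are assumed to be measured externally (e.g. ImageJ gel
analysis); this module implements only the arithmetic: each lane's target
band density is multiplied by the ratio of the control lane's
loading-control density to that lane's own loading-control density, and
fold change is the normalized density divided by the control lane's
normalized density.  This makes fold change exactly invariant to per-lane
loading differences and to any global rescaling of densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a lane table.
LANE_COLUMNS = [
    "lane_id",
    "condition",
    "timepoint_min",
    "target_density",
    "loading_density",
    "is_control",
]


class DensitometryError(ValueError):
    """Raised for malformed lane tables (missing control, zero loading...)."""


@dataclass
class DensitometryTable:
    """Lanes of one blot: target and loading-control band densities.

    ``lanes`` is a DataFrame with columns :data:`LANE_COLUMNS` plus an
    optional ``group`` column separating independent blots; exactly one
    lane per group must be flagged ``is_control``.
    """

    lanes: pd.DataFrame
    true_fold_change: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in LANE_COLUMNS if c not in self.lanes.columns]
        if missing:
            raise DensitometryError(f"lane table missing columns: {missing}")
        if "group" not in self.lanes.columns:
            self.lanes = self.lanes.assign(group="blot")
        lanes = self.lanes
        if not np.all(np.isfinite(lanes["target_density"])):
            raise DensitometryError("target densities must be finite")
        if np.any(lanes["target_density"] < 0):
            raise DensitometryError("target densities must be >= 0")
        if np.any(lanes["loading_density"] <= 0) or not np.all(
            np.isfinite(lanes["loading_density"])
        ):
            raise DensitometryError("loading densities must be finite and > 0")
        for grp, sub in lanes.groupby("group"):
            n_ctrl = int(sub["is_control"].sum())
            if n_ctrl != 1:
                raise DensitometryError(
                    f"group {grp!r} has {n_ctrl} control lanes; exactly one required"
                )


def normalize_expression(table: DensitometryTable) -> pd.Series:
    """Loading-corrected target density per lane.

    ``normalized_i = target_i * (loading_control / loading_i)`` where the
    loading-control density is taken from the group's control lane (time 0
    or untreated sample).  The control lane's normalized value is its own
    target density.
    """
    lanes = table.lanes
    out = pd.Series(index=lanes.index, dtype=float, name="normalized_density")
    for _, sub in lanes.groupby("group"):
        ctrl_loading = float(sub.loc[sub["is_control"], "loading_density"].iloc[0])
        out.loc[sub.index] = sub["target_density"] * (
            ctrl_loading / sub["loading_density"]
        )
    return out


def fold_change(table: DensitometryTable) -> pd.Series:
    """Normalized density of each lane divided by the control lane's.

    The control lane's fold change is exactly 1.
    """
    normalized = normalize_expression(table)
    lanes = table.lanes
    out = pd.Series(index=lanes.index, dtype=float, name="fold_change")
    for _, sub in lanes.groupby("group"):
        ctrl_idx = sub.index[sub["is_control"]][0]
        ctrl_norm = float(normalized.loc[ctrl_idx])
        if ctrl_norm <= 0:
            raise DensitometryError("control lane normalized density must be > 0")
        out.loc[sub.index] = normalized.loc[sub.index] / ctrl_norm
        out.loc[ctrl_idx] = 1.0
    return out


def read_lane_table(path) -> DensitometryTable:
    """Load a lane CSV with the :data:`LANE_COLUMNS` schema."""
    df = pd.read_csv(path)
    if df["is_control"].dtype == object:
        df["is_control"] = df["is_control"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    return DensitometryTable(lanes=df)


def write_results(table: DensitometryTable, path) -> pd.DataFrame:
    """Write lanes + normalized density + fold change as CSV; return the frame."""
    df = table.lanes.copy()
    df["normalized_density"] = normalize_expression(table)
    df["fold_change"] = fold_change(table)
    df.to_csv(path, index=False)
    return df
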