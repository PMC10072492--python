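"""Long-format measurement series: (rater, replicate, set angle, measured angle).

This is the table that feeds the reliability statistics: each simulated
CT of a set displacement level is measured ``replicates`` times by each
rater, exactly as in the validation study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["rater", "replicate", "set_angle_deg", "measured_angle_deg"]


@dataclass(frozen=True)
class MeasurementSeries:
    """Validated long-format series with a balanced rater x level x
    replicate design."""

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"series missing columns: {missing}")
        if not np.all(np.isfinite(df["measured_angle_deg"].to_numpy(float))):
            raise ValueError("measured angles must be finite")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    # -- design introspection -------------------------------------------------
    @property
    def raters(self) -> list:
        return sorted(self.data["rater"].unique().tolist())

    @property
    def levels(self) -> list:
        return sorted(self.data["set_angle_deg"].unique().tolist())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())

    def is_balanced(self) -> bool:
        counts = self.data.groupby(["rater", "set_angle_deg", "replicate"]).size()
        full = len(self.raters) * len(self.levels) * len(self.replicates)
        return len(counts) == full and bool((counts == 1).all())

    def require_balanced(self) -> None:
        if not self.is_balanced():
            raise ValueError("unbalanced series: every (rater, level, replicate) "
                             "cell must hold exactly one measurement")

    # -- reshaping -------------------------------------------------------------
    def matrix_for_replicate(self, replicate) -> pd.DataFrame:
        """Levels x raters matrix of one replicate (subjects = set-angle
        levels), the unit on which the per-investigation ICC is computed."""
        self.require_balanced()
        sub = self.data[self.data["replicate"] == replicate]
        if sub.empty:
            raise ValueError(f"no such replicate: {replicate}")
        return sub.pivot(index="set_angle_deg", columns="rater",
                         values="measured_angle_deg").sort_index()

    def pooled_matrix(self) -> pd.DataFrame:
        """(level, replicate) x raters matrix pooling all measurements."""
        self.require_balanced()
        return self.data.pivot(index=["set_angle_deg", "replicate"],
                               columns="rater",
                               values="measured_angle_deg").sort_index()

    # -- I/O -------------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSeries":
        return cls(pd.read_csv(path))
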