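"""Activity time-series container and CSV round-trip.

A recording is a sequence of nonnegative activity values at a fixed sampling
interval (30 s for study-shaped data), tagged with the species, colony and —
for isolated-ant recordings — individual it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTimeSeries",
    "write_series_csv",
    "read_series_csv",
]

#: allowed values for :attr:`ActivityTimeSeries.level`
LEVELS = ("colony", "individual")

#: allowed values for :attr:`ActivityTimeSeries.source`
SOURCES = ("pixel_change", "optical_flow", "centroid_displacement", "synthetic")


@dataclass(frozen=True)
class ActivityTimeSeries:
    """One recording's per-frame activity values.

    Parameters
    ----------
    values
        Nonnegative, finite activity values, one per frame (or per frame
        transition, depending on the extractor). At least two points.
    sample_interval_s
        Seconds between consecutive values; 30 s for study-shaped recordings.
    level
        ``"colony"`` for whole-colony recordings, ``"individual"`` for
        isolated ants.
    species, colony_id, individual_id
        Provenance tags. ``individual_id`` is ``None`` for colony recordings.
    source
        Which extractor (or generator) produced the values.
    series_id
        Unique identifier used in CSV output; derived from the tags when
        not given.
    """

    values: np.ndarray
    sample_interval_s: float
    level: str = "colony"
    species: str = "unknown"
    colony_id: str = "unknown"
    individual_id: str | None = None
    source: str = "synthetic"
    series_id: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("values must be a 1-D array with >= 2 points")
        if not np.all(np.isfinite(vals)):
            raise ValueError("activity values must be finite")
        if np.any(vals < 0):
            raise ValueError("activity values must be >= 0")
        if not self.sample_interval_s > 0:
            raise ValueError("sample_interval_s must be > 0")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.series_id is None:
            sid = f"{self.species}_{self.colony_id}"
            if self.individual_id is not None:
                sid += f"_{self.individual_id}"
            object.__setattr__(self, "series_id", sid)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Span covered by the recording, in seconds."""
        return (len(self) - 1) * self.sample_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.sample_interval_s

    def with_values(self, values: np.ndarray, **tags) -> "ActivityTimeSeries":
        """Copy of this series with new values (tags otherwise preserved)."""
        return replace(self, values=np.asarray(values, dtype=float), **tags)


_CSV_COLUMNS = [
    "series_id",
    "species",
    "colony_id",
    "individual_id",
    "level",
    "frame_index",
    "time_s",
    "activity",
]


def write_series_csv(series: Iterable[ActivityTimeSeries], path: str | Path) -> None:
    """Write a collection of recordings as one long-format CSV."""
    frames = []
    for ts in series:
        n = len(ts)
        frames.append(
            pd.DataFrame(
                {
                    "series_id": ts.series_id,
                    "species": ts.species,
                    "colony_id": ts.colony_id,
                    "individual_id": ts.individual_id if ts.individual_id is not None else "",
                    "level": ts.level,
                    "frame_index": np.arange(n),
                    "time_s": ts.times_s,
                    "activity": ts.values,
                }
            )
        )
    if not frames:
        raise ValueError("no series to write")
    pd.concat(frames, ignore_index=True)[_CSV_COLUMNS].to_csv(path, index=False)


def read_series_csv(path: str | Path, source: str = "synthetic") -> list[ActivityTimeSeries]:
    """Read a long-format series CSV back into recordings.

    Frames are ordered by ``frame_index`` within each ``series_id``; the
    sampling interval is inferred from consecutive ``time_s`` values.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "colony_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series CSV missing columns: {missing}")
    out: list[ActivityTimeSeries] = []
    for sid, g in df.groupby("series_id", sort=True):
        g = g.sort_values("frame_index")
        times = g["time_s"].to_numpy(dtype=float)
        if len(times) < 2:
            raise ValueError(f"series {sid!r} has fewer than 2 frames")
        dt = float(np.median(np.diff(times)))
        indiv = g["individual_id"].iloc[0]
        indiv = None if (pd.isna(indiv) or indiv == "") else str(indiv)
        out.append(
            ActivityTimeSeries(
                values=g["activity"].to_numpy(dtype=float),
                sample_interval_s=dt,
                level=str(g["level"].iloc[0]),
                species=str(g["species"].iloc[0]),
                colony_id=str(g["colony_id"].iloc[0]),
                individual_id=indiv,
                source=source,
                series_id=str(sid),
            )
        )
    return out
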