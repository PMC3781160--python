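"""Stride-interval series container with exact CSV/JSON round-tripping.

A :class:`StrideSeries` is the common currency of the package: the walker,
the rolling-disk limit and the benchmark generators all emit one, and the
correlation analysis accepts any of them interchangeably.  Serialization is
a two-file convention: a CSV of ``stride_index, interval_s`` next to a JSON
sidecar carrying provenance (generator parameters, seed, package version).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["StrideSeries", "sidecar_path"]


def sidecar_path(csv_path) -> Path:
    """JSON sidecar path for a series CSV (``foo.csv`` -> ``foo.json``)."""
    p = Path(csv_path)
    return p.with_suffix(".json")


@dataclass
class StrideSeries:
    """Ordered stride intervals (s) with provenance.

    One stride is two consecutive steps; generators that work in steps sum
    step pairs before constructing the series.
    """

    intervals: np.ndarray
    seed: Optional[int] = None
    params: dict = field(default_factory=dict)
    kind: str = ""
    complete: bool = True
    failed_at: Optional[int] = None

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and not (self.intervals > 0).all():
            raise ValueError("stride intervals must be strictly positive")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def n(self) -> int:
        return self.intervals.size

    @property
    def total_time(self) -> float:
        return float(self.intervals.sum())

    def to_csv(self, csv_path) -> Path:
        """Write the series CSV and its JSON sidecar; returns the CSV path."""
        csv_path = Path(csv_path)
        df = pd.DataFrame({
            "stride_index": np.arange(1, self.n + 1),
            "interval_s": self.intervals,
        })
        df.to_csv(csv_path, index=False, float_format="%.17g")
        meta = {
            "kind": self.kind,
            "seed": self.seed,
            "params": self.params,
            "complete": self.complete,
            "failed_at": self.failed_at,
            "package": "stridewalk",
            "version": _version(),
        }
        sidecar_path(csv_path).write_text(json.dumps(meta, indent=2) + "\n")
        return csv_path

    @classmethod
    def from_csv(cls, csv_path) -> "StrideSeries":
        """Read a series CSV; the JSON sidecar is optional."""
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, float_precision="round_trip")
        if "interval_s" not in df.columns:
            raise ValueError(f"{csv_path} has no 'interval_s' column")
        meta = {}
        sp = sidecar_path(csv_path)
        if sp.exists():
            meta = json.loads(sp.read_text())
        return cls(
            intervals=df["interval_s"].to_numpy(dtype=np.float64),
            seed=meta.get("seed"),
            params=meta.get("params", {}),
            kind=meta.get("kind", ""),
            complete=meta.get("complete", True),
            failed_at=meta.get("failed_at"),
        )


def _version() -> str:
    from . import __version__
    return __version__
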