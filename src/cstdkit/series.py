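"""Tabular containers for biomonitoring time-trend data.

Two record types circulate through the package:

``CSTDSeries``
    Cross-sectional trend data: lipid-normalized concentrations (ng/g lipid)
    measured in comparable individuals (e.g. ~30-year-old mothers) sampled in
    different calendar years.  This is the object every fitting routine
    consumes.

``IntakeSeries``
    A population intake time series (ng per kg body weight per day), the
    exposure reconstruction that the elimination-half-life estimator needs as
    its forcing function.  Interpolation between records is log-linear, i.e.
    intake is piecewise exponential in time.

Both round-trip through plain CSV with fixed column names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSTD_COLUMNS = ("year", "age", "conc_ng_per_g_lipid", "n")
INTAKE_COLUMNS = ("year", "intake_ng_per_kg_bw_per_day")


@dataclass
class CSTDSeries:
    """Cross-sectional trend data records (year, age, concentration[, n])."""

    year: np.ndarray
    age: np.ndarray
    concentration: np.ndarray  # ng/g lipid
    n: np.ndarray | None = None  # optional per-record sample size

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=float)
        if not (self.year.shape == self.age.shape == self.concentration.shape):
            raise ValueError("year, age and concentration must have equal length")
        if self.n is not None and self.n.shape != self.year.shape:
            raise ValueError("n must match the number of records")

    def __len__(self) -> int:
        return self.year.size

    def window(self, start: float, stop: float) -> "CSTDSeries":
        """Records with start <= year <= stop."""
        mask = (self.year >= start) & (self.year <= stop)
        return CSTDSeries(
            self.year[mask],
            self.age[mask],
            self.concentration[mask],
            None if self.n is None else self.n[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "year": self.year,
                "age": self.age,
                "conc_ng_per_g_lipid": self.concentration,
            }
        )
        df["n"] = np.nan if self.n is None else self.n
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CSTDSeries":
        missing = {"year", "age", "conc_ng_per_g_lipid"} - set(df.columns)
        if missing:
            raise ValueError(f"CSTD table missing columns: {sorted(missing)}")
        n = None
        if "n" in df.columns and df["n"].notna().any():
            n = df["n"].to_numpy(dtype=float)
        return cls(
            df["year"].to_numpy(dtype=float),
            df["age"].to_numpy(dtype=float),
            df["conc_ng_per_g_lipid"].to_numpy(dtype=float),
            n,
        )

    @classmethod
    def read_csv(cls, path) -> "CSTDSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class IntakeSeries:
    """Population intake trend: (year, intake in ng/kg body weight/day).

    Interpolation is log-linear between records; extrapolation beyond either
    end reuses the terminal log-slope and emits a warning, since the
    extrapolated exposure history is an assumption, not data.
    """

    year: np.ndarray
    intake: np.ndarray
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=float)
        self.intake = np.asarray(self.intake, dtype=float)
        if self.year.shape != self.intake.shape:
            raise ValueError("year and intake must have equal length")
        if self.year.size < 1:
            raise ValueError("intake series needs at least one record")
        if np.any(np.diff(self.year) <= 0):
            raise ValueError("intake years must be strictly ascending")
        if np.any(self.intake <= 0):
            raise ValueError("intakes must be positive (log-linear interpolation)")

    def __len__(self) -> int:
        return self.year.size

    def _terminal_slope(self, side: str) -> float:
        """Log-slope (1/year) of the first or last segment; 0 for a single record."""
        if self.year.size < 2:
            return 0.0
        if side == "left":
            y0, y1 = self.year[:2]
            i0, i1 = self.intake[:2]
        else:
            y0, y1 = self.year[-2:]
            i0, i1 = self.intake[-2:]
        return float(np.log(i1 / i0) / (y1 - y0))

    def interp(self, year) -> np.ndarray:
        """Log-linearly interpolated intake; extrapolates with terminal slopes."""
        year = np.asarray(year, dtype=float)
        out = np.exp(np.interp(year, self.year, np.log(self.intake)))
        lo = year < self.year[0]
        hi = year > self.year[-1]
        if np.any(lo):
            self._warn("left")
            out = np.where(
                lo,
                self.intake[0] * np.exp(self._terminal_slope("left") * (year - self.year[0])),
                out,
            )
        if np.any(hi):
            self._warn("right")
            out = np.where(
                hi,
                self.intake[-1] * np.exp(self._terminal_slope("right") * (year - self.year[-1])),
                out,
            )
        return out if out.ndim else float(out)

    def _warn(self, side: str) -> None:
        if side not in self._warned:
            self._warned.add(side)
            edge = self.year[0] if side == "left" else self.year[-1]
            warnings.warn(
                f"intake series extrapolated beyond its {side} edge ({edge:g}) "
                "using the terminal log-slope",
                stacklevel=3,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.year, "intake_ng_per_kg_bw_per_day": self.intake})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntakeSeries":
        missing = set(INTAKE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"intake table missing columns: {sorted(missing)}")
        return cls(
            df["year"].to_numpy(dtype=float),
            df["intake_ng_per_kg_bw_per_day"].to_numpy(dtype=float),
        )

    @classmethod
    def read_csv(cls, path) -> "IntakeSeries":
        return cls.from_frame(pd.read_csv(path))
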