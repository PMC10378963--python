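"""Accelerometer feature extraction.

Turns epoch-level wrist acceleration (ENMO-style summaries in
milligravities, mg) into the two exposures used by the survival model:

* **PA volume** — the mean acceleration over the whole wear period,
  including epochs below the 3 mg sleep threshold;
* the **intensity distribution** — relative frequencies of epochs over a
  fixed set of intensity bins, with epochs <3 mg classified as sleep and
  excluded, and everything above 500 mg pooled into one terminal
  500–2000 mg interval.

Also provides wear-validity checking (≥3 days of data and coverage of
every hour of the 24-h cycle) and time-in-range summaries in minutes per
day for walking-equivalent intensity categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SLEEP_THRESHOLD_MG = 3.0
INTENSITY_CAP_MG = 2000.0
TERMINAL_BIN_LO_MG = 500.0

__all__ = [
    "EpochSeries",
    "BinScheme",
    "IntensityHistogram",
    "default_bins",
    "validate_wear",
    "compute_volume",
    "build_histogram",
    "minutes_in_range",
    "time_budget",
    "read_epoch_csv",
    "write_histogram_csv",
    "read_histogram_csv",
]


@dataclass
class EpochSeries:
    """One participant's sequence of short-epoch accelerations.

    ``accel_mg`` values are capped at 2000 mg on construction. ``day_index``
    and ``hour_of_day`` label each epoch for wear-validity checks; when not
    supplied they are derived from the epoch position assuming a continuous
    recording starting at hour 0 of day 0.
    """

    participant_id: str | int
    accel_mg: np.ndarray
    epoch_seconds: float = 5.0
    day_index: np.ndarray | None = None
    hour_of_day: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accel_mg = np.asarray(self.accel_mg, dtype=float)
        if self.accel_mg.ndim != 1:
            raise ValueError("accel_mg must be one-dimensional")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if np.any(self.accel_mg < 0) or not np.all(np.isfinite(self.accel_mg)):
            raise ValueError("accelerations must be finite and nonnegative")
        self.accel_mg = np.minimum(self.accel_mg, INTENSITY_CAP_MG)
        n = self.accel_mg.size
        if self.day_index is None or self.hour_of_day is None:
            per_day = int(round(86400.0 / self.epoch_seconds))
            pos = np.arange(n)
            self.day_index = pos // per_day
            self.hour_of_day = (pos % per_day) * self.epoch_seconds // 3600
        self.day_index = np.asarray(self.day_index, dtype=int)
        self.hour_of_day = np.asarray(self.hour_of_day, dtype=int)
        if self.day_index.size != n or self.hour_of_day.size != n:
            raise ValueError("day/hour labels must match accel_mg length")

    def __len__(self) -> int:
        return self.accel_mg.size


@dataclass(frozen=True)
class BinScheme:
    """Intensity bins for the sleep-excluded distribution histogram.

    Edges start at the 3 mg sleep threshold and end at 2000 mg, with the
    final interval fixed at 500–2000 mg so the sparse extreme tail cannot
    dominate. ``representatives`` give one intensity value per interval at
    which weight functions are evaluated; by default the interval midpoint,
    except the terminal bin whose representative is pulled in (600 mg by
    default) because almost no person-time falls beyond it.
    """

    edges: tuple[float, ...]
    representatives: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")
        if e[0] != SLEEP_THRESHOLD_MG or e[-1] != INTENSITY_CAP_MG:
            raise ValueError("edges must run from 3 mg to 2000 mg")
        if e[-2] != TERMINAL_BIN_LO_MG:
            raise ValueError("final interval must span 500–2000 mg")
        z = np.asarray(self.representatives, dtype=float)
        if z.size != e.size - 1:
            raise ValueError("need one representative per interval")
        if np.any(z < e[:-1]) or np.any(z > e[1:]):
            raise ValueError("representatives must lie inside their interval")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def z(self) -> np.ndarray:
        return np.asarray(self.representatives, dtype=float)

    def labels(self) -> list[str]:
        e = self.edges

        def fmt(x: float) -> str:
            return f"{x:g}"

        return [f"p_{fmt(e[i])}_{fmt(e[i + 1])}" for i in range(self.n_bins)]

    def merge_adjacent(self, start: int, stop: int) -> "BinScheme":
        """Coarsen by merging bins ``start..stop-1`` into one interval.

        The terminal 500–2000 mg bin cannot be merged away.
        """
        if not (0 <= start < stop <= self.n_bins - 1):
            raise ValueError("invalid merge range (terminal bin is fixed)")
        edges = self.edges[: start + 1] + self.edges[stop:]
        merged_rep = 0.5 * (self.edges[start] + self.edges[stop])
        reps = (
            self.representatives[:start]
            + (merged_rep,)
            + self.representatives[stop:]
        )
        return BinScheme(edges, reps)


def default_bins(terminal_representative: float = 600.0) -> BinScheme:
    """Default bin scheme: 5-mg bins below 100 mg, ~10-mg bins to 250 mg,
    25-mg bins to 500 mg, one terminal 500–2000 mg interval.

    The boundaries 60, 125 and 300 mg (sedentary / slow / moderate / brisk
    walking-equivalent category cut-points) are always edges so that
    time-in-range summaries align exactly.
    """
    edges = np.unique(
        np.concatenate(
            [
                [SLEEP_THRESHOLD_MG],
                np.arange(5.0, 100.0 + 1e-9, 5.0),
                [125.0],
                np.arange(110.0, 250.0 + 1e-9, 10.0),
                np.arange(275.0, 500.0 + 1e-9, 25.0),
                [INTENSITY_CAP_MG],
            ]
        )
    )
    mids = 0.5 * (edges[:-1] + edges[1:])
    mids[-1] = terminal_representative
    return BinScheme(tuple(edges), tuple(mids))


@dataclass
class IntensityHistogram:
    """Sleep-excluded intensity distribution plus PA volume for one person.

    ``rel_freq[k]`` is the share of epochs ≥3 mg whose capped acceleration
    falls in bin k; ``sleep_fraction`` is the share of *all* epochs below
    3 mg. ``empty`` marks series with no non-sleep epochs, for which the
    relative frequencies are undefined (stored as NaN).
    """

    participant_id: str | int
    bins: BinScheme
    rel_freq: np.ndarray
    volume: float
    sleep_fraction: float
    valid_wear: bool = True
    empty: bool = False

    def __post_init__(self) -> None:
        self.rel_freq = np.asarray(self.rel_freq, dtype=float)
        if self.rel_freq.size != self.bins.n_bins:
            raise ValueError("rel_freq length must match bin count")
        if not self.empty:
            if np.any(self.rel_freq < -1e-12):
                raise ValueError("relative frequencies must be nonnegative")
            if abs(self.rel_freq.sum() - 1.0) > 1e-8:
                raise ValueError("relative frequencies must sum to 1")
        if self.volume < 0:
            raise ValueError("volume must be nonnegative")


def validate_wear(series: EpochSeries) -> bool:
    """Wear validity: ≥3 distinct days with data and all 24 hour-of-day
    slots covered (pooled across days). Empty series are invalid."""
    if len(series) == 0:
        return False
    n_days = np.unique(series.day_index).size
    hours = np.unique(series.hour_of_day)
    return n_days >= 3 and hours.size == 24


def compute_volume(series: EpochSeries) -> float:
    """PA volume: arithmetic mean of all epochs, sleep-level included."""
    if len(series) == 0:
        raise ValueError("cannot compute volume of an empty series")
    return float(series.accel_mg.mean())


def build_histogram(series: EpochSeries, bins: BinScheme) -> IntensityHistogram:
    """Bin the non-sleep epochs of a series into relative frequencies.

    Epochs <3 mg count toward ``sleep_fraction`` only. Values at exactly
    2000 mg (the cap) are kept in the terminal bin.
    """
    if len(series) == 0:
        raise ValueError("cannot build a histogram from an empty series")
    x = series.accel_mg
    sleep_fraction = float((x < SLEEP_THRESHOLD_MG).mean())
    awake = x[x >= SLEEP_THRESHOLD_MG]
    volume = compute_volume(series)
    if awake.size == 0:
        return IntensityHistogram(
            series.participant_id,
            bins,
            np.full(bins.n_bins, np.nan),
            volume,
            sleep_fraction,
            valid_wear=validate_wear(series),
            empty=True,
        )
    edges = np.asarray(bins.edges)
    counts, _ = np.histogram(np.clip(awake, edges[0], edges[-1]), bins=edges)
    return IntensityHistogram(
        series.participant_id,
        bins,
        counts / awake.size,
        volume,
        sleep_fraction,
        valid_wear=validate_wear(series),
    )


def _range_bin_mask(bins: BinScheme, lo_mg: float, hi_mg: float) -> np.ndarray:
    edges = np.asarray(bins.edges)
    if lo_mg not in edges or hi_mg not in edges:
        near_lo = edges[np.argmin(np.abs(edges - lo_mg))]
        near_hi = edges[np.argmin(np.abs(edges - hi_mg))]
        raise ValueError(
            f"range [{lo_mg}, {hi_mg}) does not align with bin edges; "
            f"nearest valid edges are {near_lo:g} and {near_hi:g}"
        )
    if lo_mg >= hi_mg:
        raise ValueError("lo_mg must be below hi_mg")
    return (edges[:-1] >= lo_mg) & (edges[1:] <= hi_mg)


def minutes_in_range(hist: IntensityHistogram, lo_mg: float, hi_mg: float) -> float:
    """Average minutes per day spent in the intensity range [lo, hi).

    The range must align with bin edges. Awake time per day is
    ``(1 - sleep_fraction) * 1440`` minutes, split across bins by the
    relative frequencies.
    """
    mask = _range_bin_mask(hist.bins, lo_mg, hi_mg)
    if hist.empty:
        return 0.0
    return float((1.0 - hist.sleep_fraction) * hist.rel_freq[mask].sum() * 1440.0)


def sleep_minutes(hist: IntensityHistogram) -> float:
    return float(hist.sleep_fraction * 1440.0)


#: Walking-equivalent time-budget categories (mg ranges).
TIME_BUDGET_CATEGORIES: dict[str, tuple[float, float]] = {
    "sedentary": (3.0, 60.0),
    "slow_walk": (60.0, 125.0),
    "moderate_walk": (125.0, 300.0),
    "brisk_walk": (300.0, 2000.0),
}


def time_budget(hist: IntensityHistogram) -> dict[str, float]:
    """Daily time budget: sleep and sedentary in hours, the three
    walking-equivalent categories in minutes per day."""
    out = {"sleep_h": sleep_minutes(hist) / 60.0}
    for name, (lo, hi) in TIME_BUDGET_CATEGORIES.items():
        mins = minutes_in_range(hist, lo, hi)
        out[name + ("_h" if name == "sedentary" else "_min")] = (
            mins / 60.0 if name == "sedentary" else mins
        )
    return out


# ---------------------------------------------------------------------------
# CSV interfaces

EPOCH_CSV_COLUMNS = ["participant_id", "epoch_index", "accel_mg"]


def read_epoch_csv(path, epoch_seconds: float = 5.0) -> list[EpochSeries]:
    """Read an epoch-level CSV (participant_id, epoch_index, accel_mg)."""
    df = pd.read_csv(path)
    missing = set(EPOCH_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("epoch_index")
        out.append(EpochSeries(pid, grp["accel_mg"].to_numpy(), epoch_seconds))
    return out


def histograms_to_frame(hists: list[IntensityHistogram]) -> pd.DataFrame:
    if not hists:
        raise ValueError("no histograms supplied")
    bins = hists[0].bins
    rows = []
    for h in hists:
        if h.bins.edges != bins.edges:
            raise ValueError("histograms use inconsistent bin schemes")
        row = {
            "participant_id": h.participant_id,
            "volume": h.volume,
            "sleep_fraction": h.sleep_fraction,
            "valid_wear": int(h.valid_wear),
        }
        row.update(dict(zip(bins.labels(), h.rel_freq)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_histogram_csv(hists: list[IntensityHistogram], path) -> None:
    histograms_to_frame(hists).to_csv(path, index=False, float_format="%.10g")


def _bins_from_labels(labels: list[str]) -> BinScheme:
    los = [float(c.split("_")[1]) for c in labels]
    his = [float(c.split("_")[2]) for c in labels]
    edges = tuple(los) + (his[-1],)
    d = default_bins()
    if edges == d.edges:
        return d
    mids = [0.5 * (a + b) for a, b in zip(los, his)]
    mids[-1] = min(600.0, his[-1])
    return BinScheme(edges, tuple(mids))


def read_histogram_csv(path) -> tuple[pd.DataFrame, BinScheme]:
    """Read a histogram CSV back into a frame plus its BinScheme."""
    df = pd.read_csv(path)
    labels = [c for c in df.columns if c.startswith("p_")]
    if not labels:
        raise ValueError("histogram CSV has no p_<lo>_<hi> columns")
    return df, _bins_from_labels(labels)
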