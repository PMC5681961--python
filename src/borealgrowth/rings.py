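"""Ring-width I/O, cross-dating QC, regional-curve standardization (RCS).

Detrending follows the residual-RCS convention: each measured width is
compared with the expected width at the same cambial age from a regional
curve (the age-aligned mean over all series, lightly smoothed), and the tree
ring index is the residual ``measured − expected`` in mm.  Residual indices
keep the absolute growth scale, so the panel model's coefficients are in mm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class RwlFormatError(ValueError):
    pass


@dataclass
class RingSeries:
    """One measured ring-width series (mm per ring, ordered by calendar year)."""

    tree_id: str
    first_year: int
    widths: np.ndarray
    site_id: str = ""
    pith_offset: int = 0  # estimated rings missed to pith

    def __post_init__(self):
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.widths) < 1:
            raise ValueError(f"series {self.tree_id}: empty widths")
        if np.any(self.widths < 0):
            raise ValueError(f"series {self.tree_id}: negative widths")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.widths))

    @property
    def cambial_ages(self) -> np.ndarray:
        """1-based cambial age of each ring (plus any pith offset)."""
        return np.arange(1, len(self.widths) + 1) + self.pith_offset


# ---------------------------------------------------------------------------
# Tucson decadal (.rwl) format
# ---------------------------------------------------------------------------

_STOP_999 = 999  # dialect: values in 0.01 mm
_STOP_9999 = -9999  # dialect: values in 0.001 mm


def read_rwl(path) -> list[RingSeries]:
    """Read a Tucson decadal .rwl file.

    The measurement dialect is auto-detected from the stop marker: ``999``
    means 0.01 mm units, ``-9999`` means 0.001 mm.  Malformed decade lines and
    duplicate series ids are reported with their line numbers.
    """
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or not rest:
                raise RwlFormatError(f"{path}:{lineno}: malformed decade line")
            try:
                decade_year = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RwlFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if len(values) == 0 or len(values) > 10:
                raise RwlFormatError(f"{path}:{lineno}: expected 1-10 values per decade line")
            if sid not in raw:
                order.append(sid)
                raw[sid] = []
            elif raw[sid] and raw[sid][-1][0] == -1:
                raise RwlFormatError(f"{path}:{lineno}: duplicate series id {sid!r}")
            raw[sid].append((decade_year, values))

    out = []
    for sid in order:
        chunks = raw[sid]
        first_year = chunks[0][0]
        flat: list[int] = []
        for decade_year, values in chunks:
            expected = first_year + len(flat)
            if decade_year != expected:
                raise RwlFormatError(f"series {sid}: decade line year {decade_year}, expected {expected}")
            flat.extend(values)
        if flat and flat[-1] == _STOP_999:
            scale = 0.01
            flat = flat[:-1]
        elif flat and flat[-1] == _STOP_9999:
            scale = 0.001
            flat = flat[:-1]
        else:
            raise RwlFormatError(f"series {sid}: missing stop marker (999 or -9999)")
        out.append(RingSeries(tree_id=sid, first_year=first_year, widths=np.array(flat) * scale))
    return out


def write_rwl(collection: list[RingSeries], path, units: float = 0.001) -> None:
    """Write Tucson decadal format; ``units`` 0.001 mm (−9999 stop) or 0.01 (999)."""
    if units not in (0.001, 0.01):
        raise RwlFormatError("units must be 0.001 or 0.01 mm")
    stop = _STOP_9999 if units == 0.001 else _STOP_999
    with open(path, "w") as fh:
        for s in collection:
            vals = [int(round(w / units)) for w in s.widths] + [stop]
            year = s.first_year
            i = 0
            while i < len(vals):
                # first line runs to the end of the decade; later lines start on it
                n = 10 - (year % 10) if i == 0 else min(10, len(vals) - i)
                n = min(n, len(vals) - i)
                chunk = vals[i : i + n]
                fh.write(f"{s.tree_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in chunk) + "\n")
                i += n
                year += n
    logger.info("wrote %d series to %s", len(collection), path)


def read_long_form(path) -> list[RingSeries]:
    """Read the long-form alternative: tree_id,site_id,year,width_mm."""
    df = pd.read_csv(path)
    return series_from_frame(df)


def series_from_frame(df: pd.DataFrame) -> list[RingSeries]:
    out = []
    for (tree, site), grp in df.groupby(["tree_id", "site_id"], sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(int)
        if not (np.diff(years) == 1).all():
            raise ValueError(f"series {tree}: years not contiguous")
        out.append(
            RingSeries(tree_id=str(tree), site_id=str(site), first_year=int(years[0]),
                       widths=grp["width_mm"].to_numpy(float))
        )
    return out


def series_to_frame(collection: list[RingSeries]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {"tree_id": s.tree_id, "site_id": s.site_id, "year": s.years, "width_mm": s.widths}
        )
        for s in collection
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Regional curve standardization
# ---------------------------------------------------------------------------


@dataclass
class RegionalCurve:
    """Expected ring width by cambial age (age-aligned mean, smoothed)."""

    cambial_age: np.ndarray  # 1..max
    expected_width: np.ndarray  # mm
    n_samples: np.ndarray
    smoothing: str = ""

    def __call__(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        idx = ages - int(self.cambial_age[0])
        if np.any(idx < 0) or np.any(idx >= len(self.cambial_age)):
            raise ValueError("cambial age outside the regional curve's support")
        return self.expected_width[idx]

    @property
    def max_age(self) -> int:
        return int(self.cambial_age[-1])


def build_regional_curve(collection: list[RingSeries], min_samples: int = 3,
                         smooth_window: int = 10) -> RegionalCurve:
    """Age-aligned mean width per cambial age, smoothed by a centered moving average.

    Ages represented by fewer than ``min_samples`` series are truncated from
    the curve's support.  Zero-width (locally absent) rings are excluded from
    the per-age means.
    """
    if not collection:
        raise ValueError("no ring series supplied")
    max_age = max(int(s.cambial_ages[-1]) for s in collection)
    sums = np.zeros(max_age)
    counts = np.zeros(max_age, dtype=int)
    for s in collection:
        idx = s.cambial_ages - 1
        w = s.widths
        keep = w > 0
        np.add.at(sums, idx[keep], w[keep])
        np.add.at(counts, idx[keep], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    support = counts >= min_samples
    if not support.any():
        raise ValueError(f"no cambial age reaches min_samples={min_samples}")
    last = int(np.max(np.nonzero(support)[0]))
    first = int(np.min(np.nonzero(support)[0]))
    ages = np.arange(first + 1, last + 2)
    mean = mean[first : last + 1]
    counts = counts[first : last + 1]
    # interior gaps (ages under-sampled between well-sampled ones) interpolated
    if np.isnan(mean).any():
        valid = ~np.isnan(mean)
        mean = np.interp(np.arange(len(mean)), np.nonzero(valid)[0], mean[valid])
    smoothed = _centered_moving_average(mean, smooth_window)
    return RegionalCurve(
        cambial_age=ages,
        expected_width=smoothed,
        n_samples=counts,
        smoothing=f"centered moving average, window={smooth_window}",
    )


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    return pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()


@dataclass
class RingIndexSeries:
    """Detrended (residual) ring indices for one tree, by calendar year."""

    tree_id: str
    site_id: str
    years: np.ndarray
    index: np.ndarray  # mm, measured − expected


def rcs_index(series: RingSeries, curve: RegionalCurve, ratio: bool = False) -> RingIndexSeries:
    """Residual RCS index: width − curve(cambial age), mapped to calendar years.

    Ages beyond the curve's support are dropped with a warning.  With
    ``ratio=True`` the index is width / curve instead (off by default).
    """
    ages = series.cambial_ages
    in_support = (ages >= curve.cambial_age[0]) & (ages <= curve.max_age)
    if not in_support.all():
        warnings.warn(
            f"series {series.tree_id}: dropping {int((~in_support).sum())} rings "
            "outside the regional curve's support",
            stacklevel=2,
        )
    expected = curve(ages[in_support])
    measured = series.widths[in_support]
    idx = measured / expected if ratio else measured - expected
    return RingIndexSeries(
        tree_id=series.tree_id,
        site_id=series.site_id,
        years=series.years[in_support],
        index=idx,
    )


def indices_to_frame(indices: list[RingIndexSeries]) -> pd.DataFrame:
    return pd.concat(
        [
            pd.DataFrame({"tree_id": s.tree_id, "site_id": s.site_id, "year": s.years, "index": s.index})
            for s in indices
        ],
        ignore_index=True,
    )


def site_chronology(indices: list[RingIndexSeries], min_depth: int = 1) -> pd.DataFrame:
    """Arithmetic mean index by year, with sample depth; shallow years flagged."""
    df = indices_to_frame(indices)
    chron = df.groupby("year")["index"].agg(["mean", "count"]).reset_index()
    chron.columns = ["year", "index", "sample_depth"]
    chron["flagged"] = chron["sample_depth"] < min_depth
    return chron


def series_master_correlation(series: RingIndexSeries, others: list[RingIndexSeries],
                              threshold: float = 0.55, min_overlap: int = 10) -> tuple[float, bool]:
    """Pearson correlation of one detrended series with its leave-one-out master.

    The master chronology is the mean index of all *other* series.  Returns
    ``(r, flagged)`` where ``flagged`` is True when r falls below ``threshold``
    (the cross-dating quality floor).
    """
    master = site_chronology([o for o in others if o.tree_id != series.tree_id])
    merged = pd.DataFrame({"year": series.years, "x": series.index}).merge(master, on="year")
    if len(merged) < min_overlap:
        raise ValueError(
            f"series {series.tree_id}: only {len(merged)} overlapping years (need {min_overlap})"
        )
    r = float(np.corrcoef(merged["x"], merged["index"])[0, 1])
    return r, r < threshold
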