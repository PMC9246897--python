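"""Fusing discordantly sampled environmental streams onto self-test timestamps.

Cabin sensors report on wildly different cadences: radiation dose and station
occupancy are daily, temperature / CO₂ / O₂ arrive sub-hourly, and acoustic
dosimetry happens only in sparse 24-hour sessions roughly every other month.
Self-tests happen twice a day every four days.  The rules for aligning the two:

* For each self-test, daily variables are joined by UTC calendar day.
* Sub-hourly variables use the average over the clock hour in which the test
  was completed, when any sample exists in that hour.  Noise (in dBA) is
  always averaged *energetically* — ``10·log10(mean(10^(dBA/10)))`` — because
  decibels are logarithmic; everything else uses the arithmetic mean.
* Temperature and noise are measured per module.  A test taken in Node 2 or
  the US Lab uses that module's sensor; anywhere else (or unknown) uses a
  75% Node 2 / 25% US Lab weighted average, reflecting where tests are
  usually taken.
* When the hourly (or daily) value is missing, temperature/CO₂/O₂/radiation
  fall back to LOESS interpolation (local linear, tricube weights,
  neighbourhood fraction α = 0.1) over the variable's observed series —
  fitted separately per temperature location.
* Noise is too sparse for LOESS.  Each dosimeter session is summarised into a
  daytime (07:00–22:59 UTC) and nighttime (23:00–06:59 UTC) energetic mean,
  and a test's noise value is linearly interpolated between the bracketing
  sessions' same-phase means (constant extrapolation beyond the first/last
  session).
* Sleep-diary fields are carried forward from the participant's last report.

Every fused covariate carries a provenance flag: ``observed``,
``interpolated``, ``carried-forward`` or ``imputed-mean``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "EnvStream",
    "energetic_mean",
    "hourly_average",
    "location_match",
    "loess_interpolate",
    "summarize_noise_sessions",
    "noise_day_night_interpolate",
    "fuse",
    "ENV_VARIABLES",
    "DAY_START_HOUR",
    "NIGHT_START_HOUR",
]

logger = logging.getLogger(__name__)

ENV_VARIABLES = ("radiation", "temperature", "co2", "o2", "noise", "occupancy")
LOCATED_VARIABLES = ("temperature", "noise")
DAILY_VARIABLES = ("radiation", "occupancy")

#: UTC daytime window for acoustic sessions: 07:00–22:59; night is 23:00–06:59.
DAY_START_HOUR = 7
NIGHT_START_HOUR = 23

NODE2 = "Node 2"
USLAB = "US Lab"
NODE2_WEIGHT = 0.75

SLEEP_FIELDS = (
    "bedtime",
    "waketime",
    "sleep_latency_min",
    "waso_min",
    "time_in_bed_after_wake_min",
)


@dataclass
class EnvStream:
    """One sensor's timestamped series.

    ``samples`` must have columns ``timestamp`` (tz-aware UTC) and ``value``,
    sorted by timestamp.  ``location`` is a module label (e.g. ``"Node 2"``)
    for located variables, ``None`` otherwise.
    """

    variable: str
    samples: pd.DataFrame
    location: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.variable not in ENV_VARIABLES:
            raise ValueError(f"unknown environmental variable: {self.variable!r}")
        s = self.samples
        if not {"timestamp", "value"}.issubset(s.columns):
            raise ValueError("samples must have 'timestamp' and 'value' columns")
        if not s["timestamp"].is_monotonic_increasing:
            self.samples = s.sort_values("timestamp").reset_index(drop=True)


def energetic_mean(dba: np.ndarray) -> float:
    """Power-domain mean of decibel values: 10·log10(mean(10^(dBA/10)))."""
    dba = np.asarray(dba, dtype=float)
    if dba.size == 0:
        raise ValueError("energetic mean of an empty sample")
    return float(10.0 * np.log10(np.mean(np.power(10.0, dba / 10.0))))


def _is_day(ts: pd.Timestamp) -> bool:
    return DAY_START_HOUR <= ts.hour < NIGHT_START_HOUR


def hourly_average(stream: EnvStream, hour_start: pd.Timestamp) -> float | None:
    """Average of a stream's samples within the clock hour starting at
    ``hour_start``; energetic for noise, arithmetic otherwise.

    Returns ``None`` ("unobserved") for an empty window — never zero.
    """
    hour_start = pd.Timestamp(hour_start).floor("h")
    ts = stream.samples["timestamp"]
    in_hour = (ts >= hour_start) & (ts < hour_start + pd.Timedelta(hours=1))
    vals = stream.samples.loc[in_hour, "value"].to_numpy(dtype=float)
    if vals.size == 0:
        return None
    if stream.variable == "noise":
        return energetic_mean(vals)
    return float(np.mean(vals))


def location_match(
    rst_location: str | None,
    node2_value: float | None,
    uslab_value: float | None,
    *,
    node2_weight: float = NODE2_WEIGHT,
) -> tuple[float | None, str]:
    """Pick or blend per-module values for one self-test.

    Exact-module value when the test was taken in Node 2 or the US Lab;
    otherwise a ``node2_weight`` / ``1−node2_weight`` weighted average.  If
    one side is missing the available side is used with provenance
    downgraded to ``"single-location"``; both missing → ``(None,
    "unobserved")``.
    """
    if rst_location == NODE2 and node2_value is not None:
        return node2_value, "exact"
    if rst_location == USLAB and uslab_value is not None:
        return uslab_value, "exact"
    if node2_value is not None and uslab_value is not None:
        return (
            node2_weight * node2_value + (1.0 - node2_weight) * uslab_value,
            "weighted",
        )
    if node2_value is not None:
        return node2_value, "single-location"
    if uslab_value is not None:
        return uslab_value, "single-location"
    return None, "unobserved"


def _hours_since(ts: pd.Series | np.ndarray, origin: pd.Timestamp) -> np.ndarray:
    ts = pd.to_datetime(ts)
    return (ts - origin).dt.total_seconds().to_numpy() / 3600.0


def loess_interpolate(
    stream: EnvStream,
    at_time: pd.Timestamp | np.ndarray,
    alpha: float = 0.1,
) -> float | np.ndarray:
    """LOESS (degree-1 local regression, tricube weights) evaluated at
    ``at_time``, using the α-fraction nearest samples.

    Vectorised: ``at_time`` may be an array of timestamps.
    """
    s = stream.samples
    n = len(s)
    window = int(np.ceil(alpha * n))
    if n < 3 or window < 3:
        raise ValueError(
            f"insufficient data for LOESS (n={n}, window={window}); "
            "use a larger alpha or denser stream"
        )
    origin = pd.Timestamp(s["timestamp"].iloc[0])
    x = _hours_since(s["timestamp"], origin)
    y = s["value"].to_numpy(dtype=float)
    scalar = np.isscalar(at_time) or isinstance(at_time, pd.Timestamp)
    at = pd.DatetimeIndex([at_time] if scalar else at_time)
    xv = (at - origin).total_seconds().to_numpy() / 3600.0
    fitted = lowess(y, x, frac=alpha, it=0, xvals=xv)
    return float(fitted[0]) if scalar else np.asarray(fitted)


def summarize_noise_sessions(streams: list[EnvStream]) -> pd.DataFrame:
    """Collapse acoustic dosimeter streams into per-session day/night means.

    A session is one UTC calendar day with noise samples (sessions run 24 h).
    Returns a frame with columns ``location``, ``day`` (UTC date as
    Timestamp), ``day_mean``, ``night_mean`` (energetic means, dBA); a phase
    with no samples in a session is NaN.
    """
    rows = []
    for st in streams:
        if st.variable != "noise":
            continue
        s = st.samples
        if s.empty:
            continue
        dates = s["timestamp"].dt.floor("D")
        for day, grp in s.groupby(dates):
            is_day = grp["timestamp"].apply(_is_day).to_numpy()
            v = grp["value"].to_numpy(dtype=float)
            rows.append(
                {
                    "location": st.location,
                    "day": day,
                    "day_mean": energetic_mean(v[is_day]) if is_day.any() else np.nan,
                    "night_mean": (
                        energetic_mean(v[~is_day]) if (~is_day).any() else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["location", "day", "day_mean", "night_mean"])


def noise_day_night_interpolate(
    sessions: pd.DataFrame,
    at_time: pd.Timestamp,
    location: str | None = None,
) -> float | None:
    """Interpolate noise at ``at_time`` from session day/night means.

    Queries in the daytime window use the daytime series and vice versa;
    linear interpolation between bracketing sessions, constant beyond the
    range.  ``location=None`` pools all sessions (energetic mean per day).
    Returns ``None`` when no usable session exists.
    """
    if sessions.empty:
        return None
    sess = sessions if location is None else sessions[sessions["location"] == location]
    if sess.empty:
        return None
    at_time = pd.Timestamp(at_time)
    col = "day_mean" if _is_day(at_time) else "night_mean"
    sub = sess.dropna(subset=[col])
    if sub.empty:
        return None
    # pool duplicate session days (e.g. several locations) energetically
    pooled = (
        sub.groupby("day")[col]
        .apply(lambda v: energetic_mean(v.to_numpy()))
        .sort_index()
    )
    days = (pooled.index - pooled.index[0]).total_seconds() / 86400.0
    q = (at_time.floor("D") - pooled.index[0]).total_seconds() / 86400.0
    return float(np.interp(q, days, pooled.to_numpy()))


def _hourly_means(stream: EnvStream) -> pd.Series:
    """Hourly averages of a stream indexed by hour start."""
    s = stream.samples
    grp = s.groupby(s["timestamp"].dt.floor("h"))["value"]
    if stream.variable == "noise":
        return grp.apply(lambda v: energetic_mean(v.to_numpy()))
    return grp.mean()


def _daily_means(stream: EnvStream) -> pd.Series:
    s = stream.samples
    return s.groupby(s["timestamp"].dt.floor("D"))["value"].mean()


class _SeriesInterpolator:
    """LOESS over a regularised (hourly- or daily-mean) series."""

    def __init__(self, series: pd.Series, alpha: float, variable: str):
        self.series = series
        self.alpha = alpha
        self.variable = variable
        self._stream = EnvStream(
            variable=variable,
            samples=pd.DataFrame(
                {"timestamp": series.index, "value": series.to_numpy()}
            ),
        )

    def at(self, times: pd.DatetimeIndex) -> np.ndarray:
        return np.asarray(loess_interpolate(self._stream, times, alpha=self.alpha))


def _pick_hour(series: pd.Series, hour: pd.Timestamp) -> float | None:
    v = series.get(hour)
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def fuse(
    rst: pd.DataFrame,
    env_streams: list[EnvStream],
    *,
    alpha: float = 0.1,
    location_col: str = "location",
) -> pd.DataFrame:
    """Build analysis-ready rows: one fully populated covariate vector per
    self-test, with per-covariate provenance flags (``<var>_src`` columns).

    ``rst`` needs ``participant`` and tz-aware ``timestamp`` columns; a
    ``location`` column and the sleep-diary fields are used when present.
    Tests falling outside every stream's time range are dropped with a log
    entry and reported in the ``fused.attrs['n_excluded']`` counter.
    """
    df = rst.sort_values(["participant", "timestamp"]).reset_index(drop=True).copy()
    hours = df["timestamp"].dt.floor("h")
    days = df["timestamp"].dt.floor("D")

    by_var: dict[str, list[EnvStream]] = {}
    for st in env_streams:
        by_var.setdefault(st.variable, []).append(st)

    # exclude tests outside the union of stream ranges
    t_lo = min(st.samples["timestamp"].iloc[0] for st in env_streams)
    t_hi = max(st.samples["timestamp"].iloc[-1] for st in env_streams)
    pad = pd.Timedelta(days=1)
    outside = (df["timestamp"] < t_lo - pad) | (df["timestamp"] > t_hi + pad)
    n_excluded = int(outside.sum())
    if n_excluded:
        logger.warning("excluding %d RST rows outside stream coverage", n_excluded)
        df = df[~outside].reset_index(drop=True)
        hours = hours[~outside.to_numpy()].reset_index(drop=True)
        days = days[~outside.to_numpy()].reset_index(drop=True)

    # ---- daily variables: join by calendar day, LOESS fallback -------------
    for var in DAILY_VARIABLES:
        if var not in by_var:
            continue
        daily = pd.concat([_daily_means(st) for st in by_var[var]]).groupby(level=0).mean()
        vals = days.map(daily)
        src = np.where(vals.notna(), "observed", "interpolated")
        if vals.isna().any():
            interp = _SeriesInterpolator(daily, max(alpha, 3.5 / len(daily)), var)
            miss = vals.isna()
            vals = vals.to_numpy(dtype=float)
            vals[miss.to_numpy()] = interp.at(
                pd.DatetimeIndex(df.loc[miss, "timestamp"])
            )
        df[var] = np.asarray(vals, dtype=float)
        df[f"{var}_src"] = src

    # ---- single-stream sub-hourly variables --------------------------------
    for var in ("co2", "o2"):
        if var not in by_var:
            continue
        hourly = pd.concat([_hourly_means(st) for st in by_var[var]]).groupby(level=0).mean()
        vals = hours.map(hourly)
        src = np.where(vals.notna(), "observed", "interpolated")
        if vals.isna().any():
            interp = _SeriesInterpolator(hourly, max(alpha, 3.5 / len(hourly)), var)
            miss = vals.isna()
            vals = vals.to_numpy(dtype=float)
            vals[miss.to_numpy()] = interp.at(
                pd.DatetimeIndex(df.loc[miss, "timestamp"])
            )
        df[var] = np.asarray(vals, dtype=float)
        df[f"{var}_src"] = src

    # ---- temperature: per-location hourly average, 3 separate LOESS --------
    if "temperature" in by_var:
        loc_streams = {st.location: st for st in by_var["temperature"]}
        hourly_by_loc = {loc: _hourly_means(st) for loc, st in loc_streams.items()}
        interp_by_loc = {
            loc: _SeriesInterpolator(h, max(alpha, 3.5 / len(h)), "temperature")
            for loc, h in hourly_by_loc.items()
        }
        locs = (
            df[location_col]
            if location_col in df.columns
            else pd.Series([None] * len(df))
        )
        values = np.empty(len(df))
        srcs: list[str] = []
        times = pd.DatetimeIndex(df["timestamp"])
        # precompute LOESS at all rows for each location (vectorised)
        loess_vals = {
            loc: it.at(times) for loc, it in interp_by_loc.items()
        }
        for idx in range(len(df)):
            hour = hours.iloc[idx]
            per_loc: dict[str, tuple[float, bool]] = {}
            for loc in loc_streams:
                obs = _pick_hour(hourly_by_loc[loc], hour)
                if obs is not None:
                    per_loc[loc] = (obs, True)
                else:
                    per_loc[loc] = (float(loess_vals[loc][idx]), False)
            n2 = per_loc.get(NODE2)
            ul = per_loc.get(USLAB)
            val, how = location_match(
                locs.iloc[idx],
                None if n2 is None else n2[0],
                None if ul is None else ul[0],
            )
            values[idx] = np.nan if val is None else val
            if how == "exact":
                used = [per_loc[locs.iloc[idx]]]
            elif how == "weighted":
                used = [n2, ul]
            else:
                used = [v for v in (n2, ul) if v is not None]
            srcs.append(
                "observed" if used and all(u[1] for u in used) else "interpolated"
            )
        df["temperature"] = values
        df["temperature_src"] = srcs

    # ---- noise: hourly energetic average else day/night interpolation ------
    if "noise" in by_var:
        noise_streams = by_var["noise"]
        hourly_by_loc = {st.location: _hourly_means(st) for st in noise_streams}
        sessions = summarize_noise_sessions(noise_streams)
        locs = (
            df[location_col]
            if location_col in df.columns
            else pd.Series([None] * len(df))
        )
        values = np.empty(len(df))
        srcs = []
        for idx in range(len(df)):
            hour = hours.iloc[idx]
            n2 = _pick_hour(hourly_by_loc.get(NODE2, pd.Series(dtype=float)), hour)
            ul = _pick_hour(hourly_by_loc.get(USLAB, pd.Series(dtype=float)), hour)
            other = [
                _pick_hour(h, hour)
                for loc, h in hourly_by_loc.items()
                if loc not in (NODE2, USLAB)
            ]
            other = [v for v in other if v is not None]
            val, how = location_match(locs.iloc[idx], n2, ul)
            if val is None and other:
                val, how = float(np.mean(other)), "single-location"
            if val is not None:
                values[idx] = val
                srcs.append("observed")
            else:
                v = noise_day_night_interpolate(sessions, df["timestamp"].iloc[idx])
                values[idx] = np.nan if v is None else v
                srcs.append("interpolated" if v is not None else "unobserved")
        df["noise"] = values
        df["noise_src"] = srcs

    # ---- sleep diary: last observation carried forward ---------------------
    present_sleep = [c for c in SLEEP_FIELDS if c in df.columns]
    if present_sleep:
        observed = df[present_sleep].notna().all(axis=1)
        df[present_sleep] = df.groupby("participant")[present_sleep].ffill()
        filled = df[present_sleep].notna().all(axis=1)
        df["sleep_src"] = np.select(
            [observed, filled], ["observed", "carried-forward"], default="missing"
        )

    df.attrs["n_excluded"] = n_excluded
    return df
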