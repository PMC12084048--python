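"""Processing of 1-Hz cardiopulmonary exercise testing (CPET) recordings.

A CPET study ramps a patient on a cycle ergometer through rest, incremental
work, peak effort and recovery while breath gases are sampled once per
second.  This module derives the headline cardiorespiratory-fitness numbers
from those traces:

* median filtering of the raw 1-Hz channels,
* shape-preserving downsampling to a fixed length (linear interpolation),
* ventilatory anaerobic-threshold (AT) detection by the V-slope method —
  a two-segment least-squares fit of V̇CO₂ against V̇O₂ whose breakpoint
  marks the onset of excess CO₂ production,
* V̇O₂ peak as the highest 30-second average oxygen uptake of the ramp,
* flattening a cohort of recordings into a fixed-width feature matrix for
  the time-series learning experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CPETSeries",
    "ATResult",
    "CRFFeatureSet",
    "median_filter",
    "downsample",
    "detect_at_vslope",
    "vo2_peak",
    "build_ts_feature_matrix",
    "extract_crf_features",
    "read_long_waveforms",
    "write_long_waveforms",
]

CHANNEL_ORDER = (
    "vo2", "vco2", "vo2_kg", "vco2_kg", "ve", "hr", "rer",
    "peto2", "petco2", "o2_pulse", "work_rate", "ve_vo2", "ve_vco2",
    "rr", "spo2",
)


@dataclass
class CPETSeries:
    """One patient's multichannel 1-Hz recording with phase annotations."""

    patient_id: str
    t: np.ndarray
    channels: dict[str, np.ndarray]
    phase_marks: dict[str, int] = field(default_factory=dict)
    body_mass_kg: float = 70.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        lengths = {len(v) for v in self.channels.values()}
        if lengths and lengths != {len(self.t)}:
            raise ValueError("all channels must share the time axis length")
        if len(self.t) > 1 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("t must advance at 1-second spacing")
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ATResult:
    """V-slope detection output: breakpoint sample and V̇O₂/kg there."""

    index: int
    vo2_at: float
    slope_below: float
    slope_above: float
    rss_two_segment: float
    rss_single_line: float

    @property
    def improvement(self) -> float:
        if self.rss_single_line == 0:
            return 0.0
        return 1.0 - self.rss_two_segment / self.rss_single_line


def median_filter(series, window: int) -> np.ndarray:
    """Running median with symmetric edge shrinking.

    At position ``i`` the half-width shrinks to ``min(h, i, n-1-i)`` so the
    window stays centred and inside the series; output length equals input
    length.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    x = np.asarray(series, dtype=float)
    n = len(x)
    if window > n:
        raise ValueError("window longer than series")
    h = window // 2
    out = np.empty(n)
    # interior computed vectorized via a strided stack; edges individually
    if n >= window:
        idx = np.arange(window) + np.arange(n - window + 1)[:, None]
        out[h:n - h] = np.median(x[idx], axis=1)
    for i in range(h):
        hi = min(h, i, n - 1 - i)
        out[i] = np.median(x[i - hi:i + hi + 1])
        j = n - 1 - i
        hj = min(h, j, n - 1 - j)
        out[j] = np.median(x[j - hj:j + hj + 1])
    return out


def downsample(series, target_len: int) -> np.ndarray:
    """Resample to ``target_len`` points by linear interpolation.

    Endpoints are preserved exactly and monotone input stays monotone;
    interpolation is exact on straight-line segments, so the curve shape the
    classifier sees is unchanged apart from resolution.
    """
    x = np.asarray(series, dtype=float)
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if target_len > len(x):
        raise ValueError("target_len exceeds series length")
    positions = np.linspace(0, len(x) - 1, target_len)
    return np.interp(positions, np.arange(len(x)), x)


def _segment_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line fit; returns (rss, slope)."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    syy = (y * y).sum()
    denom = n * sxx - sx * sx
    if denom <= 0:
        return float(syy - sy * sy / n), 0.0
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    rss = syy - intercept * sy - slope * sxy
    return float(max(rss, 0.0)), float(slope)


def detect_at_vslope(vo2, vco2, ramp_window: tuple[int, int] | None = None,
                     min_segment: int = 60, min_improvement: float = 0.05,
                     body_mass_kg: float | None = None) -> ATResult | None:
    """Locate the anaerobic threshold as the V-slope breakpoint.

    Fits two independent least-squares lines to V̇CO₂-vs-V̇O₂ over the ramp,
    splitting at every admissible breakpoint, and keeps the split with the
    smallest total residual sum of squares subject to the physiological
    constraint slope₂ > slope₁.  Returns ``None`` (indeterminate) when no
    admissible breakpoint improves on the single-line fit by at least
    ``min_improvement`` (relative RSS reduction).
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if vo2.shape != vco2.shape:
        raise ValueError("vo2 and vco2 must be aligned")
    lo, hi = ramp_window if ramp_window is not None else (0, len(vo2))
    if not (0 <= lo < hi <= len(vo2)):
        raise ValueError("ramp_window out of bounds")
    x = vo2[lo:hi]
    y = vco2[lo:hi]
    n = len(x)
    if n < 2 * min_segment:
        raise ValueError("ramp_window shorter than twice the minimum segment")

    rss_single, _ = _segment_rss(x, y)
    scale = float(((y - y.mean()) ** 2).sum())
    if rss_single <= 1e-12 * scale:
        return None  # a single line already fits perfectly
    best = None  # (rss, b, slope1, slope2)
    for b in range(min_segment, n - min_segment + 1):
        r1, s1 = _segment_rss(x[:b], y[:b])
        r2, s2 = _segment_rss(x[b:], y[b:])
        if s2 <= s1:
            continue
        total = r1 + r2
        # earliest breakpoint wins ties (to numerical precision)
        if best is None or total < best[0] * (1 - 1e-9) - 1e-12 * scale:
            best = (total, b, s1, s2)
    if best is None:
        return None
    total, b, s1, s2 = best
    if (1.0 - total / rss_single) < min_improvement:
        return None
    index = lo + b
    vo2_val = vo2[index]
    if body_mass_kg:
        vo2_val = vo2_val / body_mass_kg
    return ATResult(index=index, vo2_at=float(vo2_val),
                    slope_below=s1, slope_above=s2,
                    rss_two_segment=total, rss_single_line=rss_single)


def vo2_peak(vo2_per_kg, ramp_end: int, mode: str = "max_rolling",
             search_window: int = 60, average_window: int = 30) -> float:
    """Highest 30-second-average V̇O₂ of the ramp, in ml/kg/min.

    ``mode='last'`` takes the literal mean of the 30 samples ending at
    ``ramp_end``; the default ``'max_rolling'`` maximizes the 30-sample
    rolling mean over the final ``search_window`` seconds of the ramp, which
    dominates the literal reading and is robust to a brief terminal drop-off.
    """
    x = np.asarray(vo2_per_kg, dtype=float)
    if ramp_end < average_window or ramp_end > len(x):
        raise ValueError(f"need at least {average_window} ramp samples")
    if mode == "last":
        return float(x[ramp_end - average_window:ramp_end].mean())
    if mode != "max_rolling":
        raise ValueError(f"unknown mode {mode!r}")
    start = max(0, ramp_end - search_window)
    seg = x[start:ramp_end]
    csum = np.concatenate(([0.0], np.cumsum(seg)))
    means = (csum[average_window:] - csum[:-average_window]) / average_window
    return float(means.max())


@dataclass
class CRFFeatureSet:
    """Scalar fitness features for one patient (units as conventionally
    reported: V̇O₂/kg in ml/kg/min, HR in bpm, VE/V̇CO₂ unitless)."""

    patient_id: str
    values: dict[str, float]

    def __post_init__(self):
        at = self.values.get("vo2_kg_at")
        peak = self.values.get("vo2_kg_peak")
        if at is not None and peak is not None and at > peak + 1e-9:
            raise ValueError("V̇O₂/kg at AT cannot exceed V̇O₂/kg at peak")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")


def extract_crf_features(series: CPETSeries, filter_window: int = 5,
                         min_improvement: float = 0.05,
                         min_segment: int = 60) -> CRFFeatureSet:
    """Derive per-phase scalar features from a recording.

    Uses the phase marks for rest/ramp boundaries, detects AT on the ramp by
    V-slope, and reads HR, V̇O₂/kg, RER and VE/V̇CO₂ at rest, AT and peak.
    """
    marks = series.phase_marks
    filt = {name: median_filter(ch, filter_window)
            for name, ch in series.channels.items()}
    ramp_start = marks.get("ramp_start")
    ramp_end = marks.get("peak")
    if ramp_start is None or ramp_end is None:
        # no phase annotations: infer exercise bounds from the ergometer
        # load, falling back to the V̇O₂ maximum
        if "work_rate" in filt and (filt["work_rate"] > 0).any():
            active = np.flatnonzero(filt["work_rate"] > 0)
            ramp_start = int(active[0]) if ramp_start is None else ramp_start
            ramp_end = int(active[-1]) + 1 if ramp_end is None else ramp_end
        else:
            vo2_f = filt["vo2"]
            ramp_start = 0 if ramp_start is None else ramp_start
            ramp_end = (int(np.argmax(vo2_f)) + 1 if ramp_end is None
                        else ramp_end)
    at = detect_at_vslope(filt["vo2"], filt["vco2"],
                          ramp_window=(ramp_start, ramp_end),
                          min_segment=min(min_segment,
                                          max(2, (ramp_end - ramp_start) // 4)),
                          min_improvement=min_improvement)
    values: dict[str, float] = {}
    rest_slice = slice(0, max(ramp_start, 1))
    for name in ("hr", "vo2_kg", "rer", "ve_vco2"):
        if name in filt:
            values[f"{name}_rest"] = float(np.mean(filt[name][rest_slice]))
    if at is not None:
        for name in ("hr", "vo2_kg", "rer", "ve_vco2"):
            if name in filt:
                values[f"{name}_at"] = float(filt[name][at.index])
        if "work_rate" in filt:
            values["work_rate_at"] = float(filt["work_rate"][at.index])
    peak = vo2_peak(filt["vo2_kg"], ramp_end)
    values["vo2_kg_peak"] = peak
    for name in ("hr", "rer", "ve_vco2", "work_rate"):
        if name in filt:
            values[f"{name}_peak"] = float(filt[name][ramp_end - 1])
    # ventilatory-efficiency and oxygen-pulse slopes over the ramp
    ramp = slice(ramp_start, ramp_end)
    if "ve" in filt and "vo2" in filt:
        values["ve_vo2_slope"] = _ramp_slope(filt["vo2"][ramp], filt["ve"][ramp])
    if "ve" in filt and "vco2" in filt:
        values["ve_vco2_slope"] = _ramp_slope(filt["vco2"][ramp], filt["ve"][ramp])
    if "hr" in filt and "vo2" in filt:
        values["o2_pulse_slope"] = _ramp_slope(filt["hr"][ramp], filt["vo2"][ramp])
    return CRFFeatureSet(series.patient_id, values)


def _ramp_slope(x: np.ndarray, y: np.ndarray) -> float:
    _, slope = _segment_rss(np.asarray(x, float), np.asarray(y, float))
    return slope


def build_ts_feature_matrix(waveforms: dict[str, CPETSeries], target_len: int,
                            channels: tuple[str, ...] | None = None,
                            outcome: dict[str, int] | None = None,
                            static_columns: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten recordings into one fixed-width row per patient.

    Each row concatenates the downsampled channels in channel-major order;
    column ``{channel}__{j:04d}`` holds ``downsample(channel)[j]``.  Optional
    ``static_columns`` (indexed by patient id) are appended unchanged, and
    ``outcome`` adds a ``poms_class_d3`` column.
    """
    if not waveforms:
        raise ValueError("no waveforms supplied")
    first = next(iter(waveforms.values()))
    use = tuple(channels) if channels is not None else tuple(first.channels)
    rows = {}
    for pid, series in waveforms.items():
        missing = [c for c in use if c not in series.channels]
        if missing:
            raise ValueError(f"patient {pid} missing channels {missing}")
        parts = [downsample(series.channels[c], target_len) for c in use]
        rows[pid] = np.concatenate(parts)
    names = [f"{c}__{j:04d}" for c in use for j in range(target_len)]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    out.index.name = "patient_id"
    if static_columns is not None:
        out = out.join(static_columns)
    if outcome is not None:
        out["poms_class_d3"] = pd.Series(outcome)
    return out


# ---------------------------------------------------------------------------
# IO: long-format CSV (patient_id, t_sec, channel, value)
# ---------------------------------------------------------------------------

def write_long_waveforms(waveforms: dict[str, CPETSeries], path) -> None:
    frames = []
    for pid, series in waveforms.items():
        for name, ch in series.channels.items():
            frames.append(pd.DataFrame({
                "patient_id": pid, "t_sec": series.t.astype(int),
                "channel": name, "value": ch,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_long_waveforms(path, body_mass: dict[str, float] | None = None,
                        phase_marks: dict[str, dict[str, int]] | None = None,
                        ) -> dict[str, CPETSeries]:
    df = pd.read_csv(path)
    out = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        channels = {}
        t = None
        for name, sub in grp.groupby("channel", sort=True):
            sub = sub.sort_values("t_sec")
            channels[name] = sub["value"].to_numpy(dtype=float)
            t = sub["t_sec"].to_numpy(dtype=float)
        out[str(pid)] = CPETSeries(
            patient_id=str(pid), t=t, channels=channels,
            phase_marks=(phase_marks or {}).get(str(pid), {}),
            body_mass_kg=(body_mass or {}).get(str(pid), 70.0))
    return out
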