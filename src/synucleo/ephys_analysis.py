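"""Voltage-clamp recording quantification and group statistics.

A whole-cell recording at −60 mV holding potential is a current trace
(pA, inward negative).  Postsynaptic events are detected on a lightly
smoothed, running-median-baselined trace by a threshold-plus-slope rule;
each event carries onset/peak times, baseline-to-peak amplitude and area.
Recording-level summaries report event frequency (Hz), mean amplitude
(pA) and the charge transferred over the whole recording (nC), the latter
as the magnitude of the trapezoidal time-integral of the
baseline-subtracted current (1 pA·s = 10⁻³ nC).

Group comparison follows a test-selection ladder: Shapiro–Wilk normality
per group and Levene homogeneity across groups; two groups get an
unpaired t-test (Welch-corrected when Levene rejects) if both are normal,
otherwise a two-tailed Mann–Whitney U; more than two groups get ordinary
one-way ANOVA with Bonferroni-adjusted pairwise t-tests when variances
are homogeneous, and Welch's ANOVA with Dunnett's T3 post hoc otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "Recording",
    "Event",
    "EventList",
    "RecordingSummary",
    "DetectionParams",
    "detect_events",
    "charge_transferred",
    "summarize",
    "compare_groups",
    "ComparisonResult",
    "read_recording",
    "write_recording",
]


@dataclass
class Recording:
    """A current trace with its sampling metadata."""

    sampling_rate: float  # Hz
    current: np.ndarray  # pA, inward negative
    condition_label: str = ""
    holding_potential: float = -60.0  # mV, metadata only

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.current = np.asarray(self.current, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.current)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class Event:
    onset_time: float  # s
    peak_time: float  # s
    amplitude: float  # pA, baseline-to-peak magnitude
    area: float  # pC
    is_spike_like: bool = False

    def __post_init__(self) -> None:
        if not self.onset_time < self.peak_time:
            raise ValueError("event onset must precede its peak")
        if self.amplitude <= 0:
            raise ValueError("event amplitude must be positive")


EventList = list  # list[Event]


@dataclass
class RecordingSummary:
    frequency: float  # Hz
    mean_amplitude: float  # pA; NaN when no events
    charge_transferred: float  # nC
    n_events: int
    duration: float  # s
    condition_label: str = ""


@dataclass(frozen=True)
class DetectionParams:
    """Event-detector settings (matched to the synthetic generator defaults)."""

    amplitude_threshold: float = 20.0  # pA below baseline
    derivative_threshold: float = 5.0  # pA/ms on the rising phase
    min_interevent_ms: float = 10.0
    smoothing_ms: float = 2.5
    baseline_window_s: float = 1.0
    polarity: Literal["inward", "outward"] = "inward"
    spike_amplitude_factor: float = 5.0  # x median amplitude flags spike-like


def _smooth(x: np.ndarray, fs: float, smoothing_ms: float) -> np.ndarray:
    w = max(1, int(round(smoothing_ms * 1e-3 * fs)))
    if w <= 1:
        return x.copy()
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def running_median_baseline(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Running median over a ~1 s window (pandas rolling, edge-tolerant)."""
    w = max(3, int(round(window_s * fs)))
    return (
        pd.Series(x).rolling(w, center=True, min_periods=1).median().to_numpy()
    )


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from the median absolute successive difference."""
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2)) if len(d) else 0.0


def detect_events(rec: Recording, params: DetectionParams | None = None) -> list[Event]:
    """Threshold-plus-slope event detection on a baselined trace.

    The trace is smoothed (moving average, ``smoothing_ms``), a running
    median (``baseline_window_s``) is subtracted, and contiguous runs
    beyond ``amplitude_threshold`` in the configured polarity become
    candidate events; runs closer than ``min_interevent_ms`` are merged.
    A candidate is kept if its leading-phase slope magnitude reaches
    ``derivative_threshold``.  Amplitude is measured baseline-to-peak on
    the raw trace at the smoothed-peak sample; area is the absolute
    integral of the baselined trace over the run (pC).  Events whose
    amplitude exceeds ``spike_amplitude_factor`` x the median amplitude
    are flagged spike-like.
    """
    p = params or DetectionParams()
    if rec.n_samples == 0:
        return []
    fs = rec.sampling_rate
    sign = -1.0 if p.polarity == "inward" else 1.0
    sm = _smooth(rec.current, fs, p.smoothing_ms)
    baseline = running_median_baseline(sm, fs, p.baseline_window_s)
    d = sign * (sm - baseline)  # event deflection now positive

    noise_sd = estimate_noise_sd(sign * (rec.current - baseline))
    if p.amplitude_threshold <= noise_sd:
        warnings.warn(
            f"amplitude threshold {p.amplitude_threshold} pA is at or below the "
            f"noise floor estimate {noise_sd:.2f} pA; detections may be spurious"
        )

    above = d > p.amplitude_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(d))

    # merge runs separated by less than min_interevent
    gap = int(round(p.min_interevent_ms * 1e-3 * fs))
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    dt = 1.0 / fs
    raw_dev = sign * (rec.current - baseline)
    events: list[Event] = []
    for s, e in merged:
        seg = d[s:e]
        peak_rel = int(np.argmax(seg))
        peak_idx = s + peak_rel
        # rising-phase slope between run start and first peak, pA/ms
        rise = d[s : peak_idx + 1]
        if len(rise) >= 2:
            slope = float(np.max(np.diff(rise))) / (dt * 1e3)
        else:
            slope = float(seg[0] - (d[s - 1] if s > 0 else 0.0)) / (dt * 1e3)
        if slope < p.derivative_threshold:
            continue
        amplitude = float(raw_dev[peak_idx])
        if amplitude <= 0:
            amplitude = float(seg[peak_rel])
        onset_idx = max(s - 1, 0)
        onset_t = onset_idx * dt
        peak_t = peak_idx * dt
        if peak_t <= onset_t:
            peak_t = onset_t + 0.5 * dt
        area = float(np.trapezoid(np.abs(d[s:e]), dx=dt))  # pA*s == pC
        events.append(Event(onset_t, peak_t, amplitude, area))
    if events:
        med = float(np.median([ev.amplitude for ev in events]))
        for ev in events:
            ev.is_spike_like = med > 0 and ev.amplitude > p.spike_amplitude_factor * med
    return events


def charge_transferred(
    rec: Recording, baseline_window_s: float = 1.0
) -> float:
    """Whole-recording charge transferred, in nC.

    Magnitude of the trapezoidal integral of the baseline-subtracted
    current over the full recording; the running-median baseline makes the
    result invariant to constant offsets.  1 pA·s = 10⁻³ nC.
    """
    if rec.n_samples == 0:
        return 0.0
    baseline = running_median_baseline(rec.current, rec.sampling_rate, baseline_window_s)
    q_pa_s = float(np.trapezoid(rec.current - baseline, dx=1.0 / rec.sampling_rate))
    return abs(q_pa_s) * 1e-3


def summarize(rec: Recording, events: Sequence[Event]) -> RecordingSummary:
    """Frequency, mean amplitude and charge for one recording."""
    for ev in events:
        if not 0 <= ev.onset_time <= rec.duration:
            raise ValueError("event outside recording time range")
    n = len(events)
    return RecordingSummary(
        frequency=n / rec.duration,
        mean_amplitude=float(np.mean([ev.amplitude for ev in events])) if n else np.nan,
        charge_transferred=charge_transferred(rec),
        n_events=n,
        duration=rec.duration,
        condition_label=rec.condition_label,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    group_means: dict[str, float]
    shapiro_p: dict[str, float]
    levene_p: float
    normal: bool
    variances_homogeneous: bool
    posthoc: pd.DataFrame | None = None


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and Welch–Satterthwaite df."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def _dunnett_t3(groups: dict[str, np.ndarray], alpha: float) -> pd.DataFrame:
    """Dunnett's T3 all-pairs post hoc for unequal variances.

    Pairwise Welch t statistics with Welch–Satterthwaite df; family-wise
    adjustment via the studentized-maximum-modulus bound in its Šidák form
    p_adj = 1 − (2·F_t(|t|; df) − 1)^m over the m comparisons.
    """
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = groups[labels[i]], groups[labels[j]]
            t, df = _welch_t(a, b)
            p_raw = 2 * stats.t.sf(abs(t), df)
            p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "statistic": t,
                    "df": df,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def _bonferroni_t(groups: dict[str, np.ndarray], alpha: float) -> pd.DataFrame:
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = groups[labels[i]], groups[labels[j]]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            p_adj = min(1.0, float(p) * m)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "statistic": float(t),
                    "p_raw": float(p),
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    groups: Mapping[str, np.ndarray],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Test-selection ladder for 2 or more labeled samples.

    Shapiro–Wilk per group, Levene (mean-centred) across groups; then
    * two groups, both normal: unpaired two-tailed t-test (Student when
      Levene accepts homogeneity, Welch otherwise);
    * two groups, non-normal: two-tailed Mann–Whitney U;
    * >2 groups, homogeneous variances: one-way ANOVA + Bonferroni
      pairwise t-tests;
    * >2 groups, heterogeneous variances (Levene rejects): Welch's ANOVA
      + Dunnett's T3 post hoc.
    Every group needs n >= 3.
    """
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for k, v in data.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has n={len(v)} < 3")
    shapiro_p = {k: float(stats.shapiro(v).pvalue) for k, v in data.items()}
    normal = all(p > alpha for p in shapiro_p.values())
    levene_p = float(stats.levene(*data.values(), center="mean").pvalue)
    homo = levene_p > alpha
    means = {k: float(v.mean()) for k, v in data.items()}
    posthoc = None
    samples = list(data.values())
    if len(data) == 2:
        if normal:
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=homo)
            name = "student_t" if homo else "welch_t"
        else:
            stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            name = "mann_whitney_u"
    else:
        if homo:
            stat, p = stats.f_oneway(*samples)
            name = "one_way_anova_bonferroni"
            posthoc = _bonferroni_t(data, alpha)
        else:
            res = anova_oneway(samples, use_var="unequal", welch_correction=True)
            stat, p = float(res.statistic), float(res.pvalue)
            name = "welch_anova_dunnett_t3"
            posthoc = _dunnett_t3(data, alpha)
    return ComparisonResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        significant=float(p) < alpha,
        alpha=alpha,
        group_means=means,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        normal=normal,
        variances_homogeneous=homo,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# recording I/O: delimited text or raw float32 + JSON sidecar
# ---------------------------------------------------------------------------


def write_recording(rec: Recording, path: str | Path) -> None:
    """CSV/TSV (time_s, current_pA) or .f32 raw float32 with .json sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".csv", ".tsv", ".txt"}:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        pd.DataFrame(
            {"time_s": rec.times, "current_pA": rec.current}
        ).to_csv(path, index=False, sep=sep, float_format="%.6g")
    elif path.suffix.lower() in {".f32", ".bin"}:
        rec.current.astype(np.float32).tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "sampling_rate_hz": rec.sampling_rate,
                    "units": "pA",
                    "condition_label": rec.condition_label,
                    "holding_potential_mv": rec.holding_potential,
                }
            )
        )
    else:
        raise ValueError(f"unknown recording format for {path.name!r}")


def read_recording(path: str | Path, condition_label: str | None = None) -> Recording:
    path = Path(path)
    if path.suffix.lower() in {".csv", ".tsv", ".txt"}:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        t = df.iloc[:, 0].to_numpy(float)
        cur = df.iloc[:, 1].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return Recording(fs, cur, condition_label or "")
    if path.suffix.lower() in {".f32", ".bin"}:
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        cur = np.fromfile(path, dtype=np.float32).astype(float)
        return Recording(
            float(meta["sampling_rate_hz"]),
            cur,
            condition_label or meta.get("condition_label", ""),
            float(meta.get("holding_potential_mv", -60.0)),
        )
    raise ValueError(f"unknown recording format for {path.name!r}")
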