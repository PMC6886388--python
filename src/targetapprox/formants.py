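"""Formant-track measurement pipeline.

Turns plain tabular formant tracks (time in seconds, one column per formant
in Hz) into per-movement kinematic tables: semitone conversion, zero-phase
low-pass smoothing, spike trimming, extremum-based syllable demarcation and
movement measurement.  Velocity is always computed from the (smoothed)
semitone track and never smoothed itself, so peak-velocity magnitudes are
not attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FormantTrack",
    "SemitoneTrack",
    "Demarcation",
    "hz_to_semitone",
    "semitone_to_hz",
    "read_track_csv",
    "smooth_track",
    "trim_track",
    "demarcate",
    "measure_syllables",
    "write_textgrid",
]


def hz_to_semitone(f):
    """Frequency in Hz to semitones re 1 Hz: ``st = 12 * log2(f)``.

    Strictly increasing bijection on (0, inf); 1 Hz maps to 0 st and each
    octave adds 12 st.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f[np.isfinite(f)] <= 0):
        raise ValueError("frequencies must be > 0 Hz")
    out = 12.0 * np.log2(f)
    return float(out) if out.ndim == 0 else out


def semitone_to_hz(st):
    """Inverse of :func:`hz_to_semitone`."""
    st = np.asarray(st, dtype=float)
    out = np.exp2(st / 12.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class FormantTrack:
    """Formant frequency samples in Hz; NaN marks missing samples.

    ``f`` maps formant number (1, 2, 3, ...) to an array aligned with ``t``.
    Zero or negative frequencies are treated as gaps, never as real 0-Hz
    samples.
    """

    t: np.ndarray
    f: dict[int, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be 1-d and strictly increasing")
        clean = {}
        for j, arr in self.f.items():
            arr = np.asarray(arr, dtype=float).copy()
            if arr.shape != self.t.shape:
                raise ValueError(f"formant {j} length does not match time axis")
            arr[arr <= 0] = np.nan
            clean[int(j)] = arr
        self.f = clean

    def to_semitones(self, formant: int) -> "SemitoneTrack":
        hz = self.f[formant]
        st = np.full_like(hz, np.nan)
        ok = np.isfinite(hz)
        st[ok] = hz_to_semitone(hz[ok])
        return SemitoneTrack(t=self.t.copy(), st=st, meta=dict(self.meta, formant=formant))


@dataclass
class SemitoneTrack:
    """A single formant contour on the semitone scale (re 1 Hz)."""

    t: np.ndarray
    st: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.st = np.asarray(self.st, dtype=float)
        if self.t.shape != self.st.shape:
            raise ValueError("t and st must have the same shape")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (assumes a uniform grid)."""
        return 1.0 / float(np.mean(np.diff(self.t)))

    def velocity(self) -> np.ndarray:
        """First derivative (st/s) of the track, unsmoothed."""
        return np.gradient(self.st, self.t)


def read_track_csv(path, time_col: str = "time", sep: str | None = None) -> FormantTrack:
    """Read a plain CSV/TSV track: a time column plus f1/f2/f3... columns (Hz)."""
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if time_col not in cols:
        raise ValueError(f"no '{time_col}' column in {path}")
    f = {}
    for j in (1, 2, 3, 4, 5):
        key = f"f{j}"
        if key in cols:
            f[j] = df[cols[key]].to_numpy(dtype=float)
    if not f:
        raise ValueError(f"no formant columns (f1, f2, ...) in {path}")
    return FormantTrack(t=df[cols[time_col]].to_numpy(dtype=float), f=f, meta={"source": str(path)})


def smooth_track(track: SemitoneTrack, cutoff: float = 20.0, order: int = 4) -> SemitoneTrack:
    """Zero-phase low-pass filter of the contour (default cutoff 20 Hz).

    Uses a Butterworth filter applied forward and backward (``filtfilt``), so
    extrema are not shifted in time.  Gaps (NaN) are linearly interpolated
    before filtering and restored afterwards.
    """
    fs = track.fs
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2:.1f} Hz)")
    x = track.st.copy()
    gaps = ~np.isfinite(x)
    if gaps.any():
        if gaps.all():
            raise ValueError("track has no finite samples")
        idx = np.arange(x.size)
        x[gaps] = np.interp(idx[gaps], idx[~gaps], x[~gaps])
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    y[gaps] = np.nan
    return SemitoneTrack(t=track.t.copy(), st=y, meta=dict(track.meta, smoothed_at_hz=cutoff))


def trim_track(track: SemitoneTrack, jump_threshold: float = 1.0) -> SemitoneTrack:
    """Remove isolated single-sample spikes by local interpolation.

    A sample is a spike when it jumps by more than ``jump_threshold``
    semitones away from both neighbours in the same direction (an abrupt
    bump or sharp edge one sample wide, as produced by octave-jump style
    tracking errors).  Genuine multi-sample rises and falls are untouched;
    clean tracks come back unchanged.
    """
    x = track.st.copy()
    if x.size < 3:
        raise ValueError("need at least 3 samples to trim")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    spike = (
        np.isfinite(left)
        & np.isfinite(right)
        & (np.abs(left) > jump_threshold)
        & (np.abs(right) > jump_threshold)
        & (np.sign(left) == np.sign(right))
    )
    idx = np.where(spike)[0] + 1
    x[idx] = 0.5 * (track.st[idx - 1] + track.st[idx + 1])
    return SemitoneTrack(t=track.t.copy(), st=x, meta=dict(track.meta, trimmed=len(idx)))


@dataclass
class Demarcation:
    """Syllable boundaries at formant extrema, plus within-syllable splits.

    ``boundaries`` are the demarcation times (at the chosen extremum type);
    ``splits`` holds, per syllable, the time of the opposite extremum that
    separates the onset ramp from the offset ramp.
    """

    boundaries: np.ndarray
    splits: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.splits = np.asarray(self.splits, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.splits.size != max(self.boundaries.size - 1, 0):
            raise ValueError("need exactly one split per syllable interval")

    @property
    def n_syllables(self) -> int:
        return self.splits.size


_MODES = {
    "f1min": ("min",),
    "f2min": ("min",),
    "f2max": ("max",),
}


def demarcate(track: SemitoneTrack, mode: str = "f1min") -> Demarcation:
    """Place syllable boundaries at extrema of the (smoothed) contour.

    ``mode`` selects the boundary extremum type: minima for ``f1min`` and
    ``f2min`` (e.g. glide-to-open-vowel alternations), maxima for ``f2max``
    (high-F2 glides).  Consecutive boundaries define one syllable each; the
    intermediate opposite extremum splits it into an onset ramp and an
    offset ramp.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    kind = _MODES[mode][0]
    from .kinematics import find_turning_points

    x = track.st
    if not np.all(np.isfinite(x)):
        raise ValueError("demarcation requires a gap-free (smoothed) track")
    tps = find_turning_points(x)
    if len(tps) < 2:
        raise ValueError("fewer than 2 extrema: nothing to demarcate")
    is_min = np.array([x[i] < x[max(i - 1, 0)] or x[i] < x[min(i + 1, x.size - 1)] for i in tps])
    want = is_min if kind == "min" else ~is_min
    bidx = [i for i, w in zip(tps, want) if w]
    oidx = [i for i, w in zip(tps, want) if not w]
    if len(bidx) < 2:
        raise ValueError("fewer than 2 boundary extrema: nothing to demarcate")
    splits = []
    keep = []
    for a, b in zip(bidx[:-1], bidx[1:]):
        inner = [i for i in oidx if a < i < b]
        if len(inner) != 1:
            continue  # not a clean one-peak syllable
        keep.append((a, b))
        splits.append(track.t[inner[0]])
    if not keep:
        raise ValueError("no clean syllable intervals found")
    bounds = [track.t[keep[0][0]]] + [track.t[b] for _, b in keep]
    return Demarcation(boundaries=np.asarray(bounds), splits=np.asarray(splits), mode=mode)


def measure_syllables(track: SemitoneTrack, dem: Demarcation) -> pd.DataFrame:
    """Per-movement measurement table from a demarcated track.

    Each syllable contributes two unidirectional movements: the onset ramp
    (boundary to split) and the offset ramp (split to next boundary).  For
    each movement the table reports the contour maximum and minimum (st),
    signed displacement (st), duration (s), signed peak velocity (st/s, from
    the unsmoothed first derivative of the track) and the vp/d ratio (1/s).
    Per-syllable totals (syllable duration = onset + offset durations, mean
    absolute displacement) are attached to both rows of the syllable.
    Movements containing missing samples are flagged ``excluded``.
    """
    v = track.velocity()
    rows = []
    for s in range(dem.n_syllables):
        t0, tmid, t1 = dem.boundaries[s], dem.splits[s], dem.boundaries[s + 1]
        for label, (ta, tb) in (("onset", (t0, tmid)), ("offset", (tmid, t1))):
            i = int(np.searchsorted(track.t, ta))
            j = int(np.searchsorted(track.t, tb))
            seg = track.st[i : j + 1]
            vseg = v[i + 1 : j + 1]
            missing = not np.all(np.isfinite(seg))
            if missing or vseg.size == 0:
                peak = np.nan
                disp = np.nan
            else:
                peak = vseg[np.argmax(np.abs(vseg))]
                disp = track.st[j] - track.st[i]
            rows.append(
                {
                    "syllable": s,
                    "movement": label,
                    "t_on": track.t[i],
                    "t_off": track.t[j],
                    "max_st": np.nanmax(seg) if seg.size else np.nan,
                    "min_st": np.nanmin(seg) if seg.size else np.nan,
                    "displacement_st": disp,
                    "duration_s": track.t[j] - track.t[i],
                    "peak_velocity_st_s": peak,
                    "excluded": missing,
                }
            )
    df = pd.DataFrame(rows)
    df["vpd"] = np.where(
        np.abs(df["displacement_st"]) > 1e-9,
        np.abs(df["peak_velocity_st_s"]) / np.abs(df["displacement_st"]),
        np.nan,
    )
    per_syll = df.groupby("syllable").agg(
        syllable_duration_s=("duration_s", "sum"),
        mean_displacement_st=("displacement_st", lambda x: np.mean(np.abs(x))),
    )
    return df.join(per_syll, on="syllable")


def write_textgrid(dem: Demarcation, path, tier_name: str = "syllables") -> None:
    """Export demarcation boundaries as a Praat TextGrid interval tier."""
    b = dem.boundaries
    xmin, xmax = float(b[0]), float(b[-1])
    intervals = [(b[i], b[i + 1], f"syll{i + 1}") for i in range(len(b) - 1)]
    with open(path, "w") as fh:
        fh.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
        fh.write(f"xmin = {xmin}\nxmax = {xmax}\ntiers? <exists>\nsize = 1\nitem []:\n")
        fh.write('    item [1]:\n        class = "IntervalTier"\n')
        fh.write(f'        name = "{tier_name}"\n')
        fh.write(f"        xmin = {xmin}\n        xmax = {xmax}\n")
        fh.write(f"        intervals: size = {len(intervals)}\n")
        for k, (a, z, label) in enumerate(intervals, 1):
            fh.write(f"        intervals [{k}]:\n")
            fh.write(f"            xmin = {a}\n            xmax = {z}\n")
            fh.write(f'            text = "{label}"\n')
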