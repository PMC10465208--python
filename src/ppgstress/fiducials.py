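"""IBI-adaptive filtering and PPG fiducial (peak/onset) detection.

The chain mirrors standard wearable-PPG practice: the mean inter-beat
interval (IBI) is first read off the periodogram, then used to size a
three-stage filter (centre median + centre moving average -> zero-phase
third-order Butterworth -> slow moving-average baseline). Peaks are tiled
one per IBI on the baseline-corrected pulsatile signal, cleaned by height
and spacing criteria, and relocated onto the lightly smoothed trace; onsets
are the minima between consecutive peaks. The per-beat AC amplitude is
|peak - preceding onset|, robustly filtered for outliers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

IBI_BAND = (0.8, 3.0)  # Hz; corresponds to 48-180 beats/min

# False-peak criteria (height and spacing stand-ins for the cited
# peak-cleaning rules): a candidate is rejected if its baseline-corrected
# height is < 30% of the running median height of the last 10 accepted
# peaks, or if it falls closer than 0.5 IBI to the previous accepted peak
# (the taller of the pair is kept).
HEIGHT_FRACTION = 0.30
MIN_SPACING_IBI = 0.5
RUNNING_MEDIAN_LEN = 10
# The gap-recovery pass searches windows at least 0.5 IBI away from accepted
# peaks, which already excludes dicrotic territory, so it can afford a more
# permissive height threshold than the candidate pass.
GAPFILL_HEIGHT_FRACTION = 0.15


@dataclass
class IbiEstimate:
    ibi_seconds: float
    peak_frequency: float
    band: tuple = IBI_BAND


@dataclass
class FilteredSignals:
    w1: np.ndarray        # smoothed (median + moving average)
    w2: np.ndarray        # low-passed pulsatile signal
    baseline: np.ndarray  # slow trend


@dataclass
class FiducialSet:
    peak_indices: np.ndarray
    onset_indices: np.ndarray
    ibi: IbiEstimate

    def validate(self) -> None:
        p, o = self.peak_indices, self.onset_indices
        if np.any(np.diff(p) <= 0) or np.any(np.diff(o) <= 0):
            raise ValueError("fiducial indices not strictly increasing")
        if len(o) != len(p) - 1:
            raise ValueError("expected one onset between consecutive peaks")
        if len(o) and not np.all((o > p[:-1]) & (o < p[1:])):
            raise ValueError("onsets and peaks do not alternate")


@dataclass
class AcSeries:
    beat_times: np.ndarray   # time of each beat's peak, seconds
    ac_values: np.ndarray
    kept_mask: np.ndarray

    @property
    def kept_times(self) -> np.ndarray:
        return self.beat_times[self.kept_mask]

    @property
    def kept_values(self) -> np.ndarray:
        return self.ac_values[self.kept_mask]


def estimate_ibi(x: np.ndarray, fs: float) -> IbiEstimate:
    """Mean IBI as the reciprocal of the periodogram argmax in 0.8-3 Hz."""
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of signal to resolve the 0.8 Hz band edge")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: no spectral power in the heart-rate band")
    freqs, power = sps.periodogram(x, fs=fs, detrend="constant")
    band = (freqs >= IBI_BAND[0]) & (freqs <= IBI_BAND[1])
    if not np.any(band) or np.max(power[band]) <= 0:
        raise ValueError("no spectral power in the 0.8-3 Hz heart-rate band")
    f0 = float(freqs[band][np.argmax(power[band])])
    return IbiEstimate(ibi_seconds=1.0 / f0, peak_frequency=f0)


def _odd_window(n_samples: float) -> int:
    w = int(round(n_samples))
    if w % 2 == 0:
        w += 1
    return w


def filter_chain(x: np.ndarray, fs: float, ibi: IbiEstimate) -> FilteredSignals:
    """Three-stage IBI-adaptive filter chain (reflection at the edges)."""
    x = np.asarray(x, dtype=float)
    w_smooth = _odd_window(0.2 * ibi.ibi_seconds * fs)
    w_base = _odd_window(1.5 * ibi.ibi_seconds * fs)
    if w_smooth < 3:
        raise ValueError("smoothing window below 3 samples: IBI implausibly small")
    w1 = ndimage.median_filter(x, size=w_smooth, mode="reflect")
    w1 = ndimage.uniform_filter1d(w1, size=w_smooth, mode="reflect")
    cutoff = 1.5 * ibi.peak_frequency
    sos = sps.butter(3, cutoff, btype="low", fs=fs, output="sos")
    w2 = sps.sosfiltfilt(sos, w1)
    baseline = ndimage.uniform_filter1d(w2, size=w_base, mode="reflect")
    return FilteredSignals(w1=w1, w2=w2, baseline=baseline)


def detect_peaks(filtered: FilteredSignals, fs: float, ibi: IbiEstimate) -> np.ndarray:
    """One candidate peak per IBI tile, cleaned and relocated.

    Candidates are the per-tile argmax of the baseline-corrected low-passed
    signal. The false-peak pass applies the height and spacing criteria;
    accepted peaks are then relocated to the nearest maximum of the lightly
    smoothed signal (within a quarter IBI), which undoes the peak shift the
    heavy low-pass can introduce on asymmetric pulses.
    """
    p = filtered.w2 - filtered.baseline
    w1c = filtered.w1 - filtered.baseline
    n = len(p)
    tile = max(int(round(ibi.ibi_seconds * fs)), 2)

    candidates = []
    for start in range(0, n, tile):
        seg = p[start:start + tile]
        if len(seg):
            candidates.append(start + int(np.argmax(seg)))

    accepted: list[int] = []
    heights: list[float] = []
    min_gap = MIN_SPACING_IBI * ibi.ibi_seconds * fs
    for c in candidates:
        h = p[c]
        if h <= 0:
            continue
        if heights:
            running = float(np.median(heights[-RUNNING_MEDIAN_LEN:]))
            if h < HEIGHT_FRACTION * running:
                continue
        if accepted and (c - accepted[-1]) < min_gap:
            if h > p[accepted[-1]]:  # keep the taller of the close pair
                accepted[-1] = c
                heights[-1] = h
            continue
        accepted.append(c)
        heights.append(float(h))

    # Recover beats the fixed tiling merged away: any inter-peak gap much
    # longer than the estimated IBI is re-searched for a qualifying maximum.
    def _qualifies(idx: int) -> bool:
        if p[idx] <= 0:
            return False
        if not accepted:
            return True
        # height criterion against the nearest accepted peaks, mirroring the
        # running-median rule of the sequential pass
        order = np.argsort(np.abs(np.asarray(accepted) - idx))[:RUNNING_MEDIAN_LEN]
        local = float(np.median([p[accepted[k]] for k in order]))
        return p[idx] >= GAPFILL_HEIGHT_FRACTION * local

    changed = bool(accepted)
    passes = 0
    while changed and passes < 50:
        passes += 1
        changed = False
        known = set(accepted)
        bounds = [0] + accepted + [n - 1]
        inserts = set()
        for a, b in zip(bounds[:-1], bounds[1:]):
            lo = int(a + min_gap) if a else 0
            hi = int(b - min_gap) if b != n - 1 else n
            if (b - a) > 1.5 * tile and hi - lo > 1:
                c = lo + int(np.argmax(p[lo:hi]))
                if c not in known and _qualifies(c):
                    inserts.add(c)
        if inserts:
            accepted = sorted(known | inserts)
            changed = True

    # Final pruning: the first accepted candidate never faced the running
    # height criterion, so edge artefacts can slip in; re-check every peak
    # against its local neighbourhood.
    if accepted:
        pruned = []
        arr = np.asarray(accepted)
        for c in accepted:
            order = np.argsort(np.abs(arr - c))[:RUNNING_MEDIAN_LEN]
            local = float(np.median(p[arr[order]]))
            if p[c] >= GAPFILL_HEIGHT_FRACTION * local:
                pruned.append(c)
        accepted = pruned

    # Relocation pass on the lightly smoothed trace.
    half = max(int(round(0.25 * tile)), 1)
    relocated: list[int] = []
    for c in accepted:
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        r = lo + int(np.argmax(w1c[lo:hi]))
        if not relocated or r > relocated[-1]:
            relocated.append(r)
        elif w1c[r] > w1c[relocated[-1]]:
            relocated[-1] = r

    if not relocated:
        warnings.warn("no peak candidate survived the false-peak criteria")
    return np.asarray(relocated, dtype=int)


def detect_onsets(filtered: FilteredSignals, peaks: np.ndarray,
                  raw: np.ndarray | None = None) -> np.ndarray:
    """Onsets: the minimum of the smoothed, baseline-corrected signal
    strictly between each pair of consecutive peaks (earliest on ties).

    When the raw trace is supplied, each onset is refined to the minimum of
    the baseline-corrected raw signal in a small neighbourhood — onsets are
    defined on the PPG signal itself, and the smoothing filters can shift a
    flat diastolic valley by a few samples.
    """
    if len(peaks) < 2:
        return np.empty(0, dtype=int)
    work = filtered.w1 - filtered.baseline
    if raw is None:
        fine = None
    else:
        # 5-sample centre average: narrow enough not to displace the
        # diastolic valley, wide enough to keep sensor noise from dominating
        # the refinement. No baseline subtraction here — the window is
        # already anchored by the detrended minimum, and the baseline's
        # local slope would tilt a shallow valley by several samples.
        fine = ndimage.uniform_filter1d(np.asarray(raw, dtype=float), size=5,
                                        mode="reflect")
    half = 12
    onsets = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = work[p0 + 1:p1]
        if not len(seg):
            raise ValueError("adjacent peaks with no samples in between")
        o = p0 + 1 + int(np.argmin(seg))
        if fine is not None:
            lo = max(o - half, p0 + 1)
            hi = min(o + half + 1, p1)
            o = lo + int(np.argmin(fine[lo:hi]))
        onsets.append(o)
    return np.asarray(onsets, dtype=int)


def compute_ac(filtered: FilteredSignals, fiducials: FiducialSet, fs: float) -> AcSeries:
    """Per-beat AC amplitude |peak - preceding onset| on the low-passed
    signal, with a median +- 3 scaled-MAD outlier mask."""
    fiducials.validate()
    peaks = fiducials.peak_indices[1:]
    onsets = fiducials.onset_indices
    if len(peaks) == 0:
        return AcSeries(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    sig = filtered.w2
    ac = np.abs(sig[peaks] - sig[onsets])
    med = float(np.median(ac))
    mad = 1.4826 * float(np.median(np.abs(ac - med)))
    if mad > 0:
        kept = np.abs(ac - med) <= 3.0 * mad
    else:
        kept = np.abs(ac - med) <= np.finfo(float).eps * max(abs(med), 1.0)
    kept &= ac > 0
    return AcSeries(beat_times=peaks / fs, ac_values=ac, kept_mask=kept)


def extract_ac_series(x: np.ndarray, fs: float) -> tuple[AcSeries, FiducialSet, FilteredSignals]:
    """Full single-channel chain: IBI -> filters -> fiducials -> AC series."""
    ibi = estimate_ibi(x, fs)
    filtered = filter_chain(x, fs, ibi)
    peaks = detect_peaks(filtered, fs, ibi)
    onsets = detect_onsets(filtered, peaks, raw=x)
    fiducials = FiducialSet(peak_indices=peaks, onset_indices=onsets, ibi=ibi)
    ac = compute_ac(filtered, fiducials, fs)
    return ac, fiducials, filtered
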