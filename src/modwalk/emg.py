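"""EMG envelope extraction, gait-event detection and gait-cycle normalization.

Turns raw surface EMG of the eight paretic-leg muscles plus bilateral ground
reaction forces into the averaged, amplitude-normalized envelope matrix
(muscles x 101 points of the gait cycle) and the six-bin summaries that feed
the non-negative matrix factorization.

Processing chain (conventional for lower-limb synergy studies):
high-pass 40 Hz (zero-lag Butterworth, net 4th order), demean, full-wave
rectify, low-pass 4 Hz (zero-lag), clip at zero; segment paretic heel strike
to heel strike; linearly resample each cycle to 101 points (0-100% of the
cycle); average pointwise; normalize each muscle by the mean of its highest
gait-cycle bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    InsufficientCyclesError,
    InsufficientDataError,
    MalformedEventsError,
    NoEventsError,
    ZeroChannelError,
)

#: Canonical muscle order: tibialis anterior, soleus, medial gastrocnemius,
#: vastus medialis, rectus femoris, medial/lateral hamstrings, gluteus medius.
MUSCLES: tuple[str, ...] = ("TA", "SO", "MG", "VM", "RF", "MH", "LH", "GM")

#: Percent-of-gait-cycle grid the averaged cycles live on.
PCT_GRID = np.linspace(0.0, 100.0, 101)

BIN_LABELS: tuple[str, ...] = (
    "first_double_support",
    "first_half_single_stance",
    "second_half_single_stance",
    "second_double_support",
    "first_half_swing",
    "second_half_swing",
)


@dataclass
class EMGRecording:
    """Multichannel EMG (or envelope) time series.

    samples : (n_channels, n_samples) array, arbitrary units.
    """

    samples: np.ndarray
    fs_hz: float
    muscle_names: tuple[str, ...] = MUSCLES
    leg: str = "paretic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) for both legs, strictly increasing."""

    paretic_heel_strikes: np.ndarray
    paretic_toe_offs: np.ndarray
    nonparetic_heel_strikes: np.ndarray
    nonparetic_toe_offs: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "paretic_heel_strikes",
            "paretic_toe_offs",
            "nonparetic_heel_strikes",
            "nonparetic_toe_offs",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise MalformedEventsError(f"{name} must be strictly increasing")
        for hs, to, leg in (
            (self.paretic_heel_strikes, self.paretic_toe_offs, "paretic"),
            (self.nonparetic_heel_strikes, self.nonparetic_toe_offs, "nonparetic"),
        ):
            _check_interleaving(hs, to, leg)


def _check_interleaving(hs: np.ndarray, to: np.ndarray, leg: str) -> None:
    """Each toe-off after the first heel strike must fall between successive
    heel strikes of the same leg (one per gait cycle).  A single toe-off before
    the first heel strike is allowed (contact ongoing at record start)."""
    if hs.size < 2 or to.size == 0:
        return
    inner = to[to >= hs[0]]
    idx = np.searchsorted(hs, inner)
    # searchsorted gives the cycle index + 1 for each toe-off; duplicates mean
    # two toe-offs inside one cycle.
    if np.unique(idx).size != idx.size:
        raise MalformedEventsError(f"non-alternating contacts on {leg} leg")
    if to.size - inner.size > 1:
        raise MalformedEventsError(f"multiple toe-offs before first {leg} heel strike")


@dataclass
class CycleEnvelope:
    """Averaged gait-cycle envelope: muscles x 101 points (0..100% of cycle)."""

    matrix: np.ndarray
    n_cycles_averaged: int
    muscle_names: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 101:
            raise ValueError("CycleEnvelope matrix must be (muscles, 101)")
        if np.any(self.matrix < 0):
            raise ValueError("CycleEnvelope must be nonnegative")


@dataclass
class BinSummary:
    """Per-muscle mean envelope in the six named regions of the gait cycle."""

    bin_means: np.ndarray
    bin_edges_pct: np.ndarray
    bin_labels: tuple[str, ...] = BIN_LABELS
    muscle_names: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_edges_pct = np.asarray(self.bin_edges_pct, dtype=float)
        if self.bin_edges_pct.shape != (7,):
            raise ValueError("expected 7 bin edges")
        if not np.all(np.diff(self.bin_edges_pct) > 0):
            raise MalformedEventsError("bin edges must be strictly increasing")


def _sos(cutoff_hz: float, fs_hz: float, btype: str) -> np.ndarray:
    # Second-order sections; a forward-backward pass makes the net response
    # fourth order with zero lag.
    return signal.butter(2, cutoff_hz, btype=btype, fs=fs_hz, output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray, padlen: int) -> np.ndarray:
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def envelope(
    raw: EMGRecording, high_cut_hz: float = 40.0, low_cut_hz: float = 4.0
) -> EMGRecording:
    """Linear envelope: zero-lag high-pass, demean, rectify, zero-lag low-pass.

    Negative post-filter values (low-pass ringing) are clipped at 0.
    """
    fs = raw.fs_hz
    if fs <= 2 * high_cut_hz:
        raise ValueError("sampling rate too low for the high-pass cutoff")
    padlen = int(3 * fs / low_cut_hz)
    if raw.n_samples <= padlen:
        raise InsufficientDataError(
            f"need more than {padlen} samples at fs={fs} Hz for stable filtering"
        )
    x = _filtfilt(_sos(high_cut_hz, fs, "highpass"), raw.samples, padlen)
    x = x - x.mean(axis=-1, keepdims=True)
    x = np.abs(x)
    x = _filtfilt(_sos(low_cut_hz, fs, "lowpass"), x, padlen)
    x = np.clip(x, 0.0, None)
    return EMGRecording(x, fs, raw.muscle_names, raw.leg)


def _contact_mask(fz: np.ndarray, threshold: float, n_debounce: int) -> np.ndarray:
    """Binarize vertical force; drop contact and flight runs shorter than the
    debounce length (crossings must be sustained)."""
    mask = fz > threshold
    if n_debounce <= 1:
        return mask
    for target in (True, False):  # drop short contacts, then short flights
        out = mask.copy()
        i = 0
        n = mask.size
        while i < n:
            j = i
            while j < n and mask[j] == mask[i]:
                j += 1
            if mask[i] == target and (j - i) < n_debounce and i > 0 and j < n:
                out[i:j] = not target
            i = j
        mask = out
    return mask


def _edge_times(mask: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(mask.astype(np.int8))
    rises = (np.flatnonzero(d == 1) + 1) / fs
    falls = (np.flatnonzero(d == -1) + 1) / fs
    return rises, falls


def detect_gait_events(
    grf,
    threshold_n: float = 20.0,
    debounce_s: float = 0.010,
) -> GaitEvents:
    """Detect heel strikes / toe-offs from per-belt vertical force.

    Heel strike = upward crossing of ``threshold_n`` sustained at least the
    debounce time; toe-off = downward crossing likewise sustained.
    """
    fs = grf.fs_hz
    n_db = max(1, int(round(debounce_s * fs)))
    events = {}
    for leg in ("paretic", "nonparetic"):
        fz = np.asarray(getattr(grf, f"fz_{leg}"), dtype=float)
        mask = _contact_mask(fz, threshold_n, n_db)
        if not mask.any() or mask.all():
            raise NoEventsError(f"no contact transitions in {leg} vertical force")
        hs, to = _edge_times(mask, fs)
        if hs.size == 0:
            raise NoEventsError(f"no heel strikes detected on {leg} leg")
        events[leg] = (hs, to)
    return GaitEvents(
        paretic_heel_strikes=events["paretic"][0],
        paretic_toe_offs=events["paretic"][1],
        nonparetic_heel_strikes=events["nonparetic"][0],
        nonparetic_toe_offs=events["nonparetic"][1],
    )


def segment_and_normalize(
    env: EMGRecording, events: GaitEvents, min_cycles_warn: int = 20
) -> CycleEnvelope:
    """Resample each paretic heel-strike-to-heel-strike cycle to 101 points
    (linear interpolation) and average pointwise across cycles."""
    hs = events.paretic_heel_strikes
    if hs.size < 2:
        raise InsufficientCyclesError("need at least 2 paretic heel strikes")
    t = env.times
    t_end = t[-1]
    frac = PCT_GRID / 100.0
    cycles = []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        if t0 < 0 or t1 > t_end:
            continue
        grid = t0 + frac * (t1 - t0)
        cycles.append(
            np.stack([np.interp(grid, t, ch) for ch in env.samples], axis=0)
        )
    if not cycles:
        raise InsufficientCyclesError("no complete paretic cycles inside the record")
    if len(cycles) < min_cycles_warn:
        warnings.warn(
            f"only {len(cycles)} paretic cycles available "
            f"(fewer than {min_cycles_warn})",
            stacklevel=2,
        )
    mean_cycle = np.mean(cycles, axis=0)
    return CycleEnvelope(np.clip(mean_cycle, 0.0, None), len(cycles), env.muscle_names)


def _events_in_cycle_pct(times: np.ndarray, t0: float, t1: float) -> list[float]:
    inside = times[(times >= t0) & (times < t1)]
    return [100.0 * (x - t0) / (t1 - t0) for x in inside]


def average_event_percentages(events: GaitEvents) -> tuple[float, float, float]:
    """Average percent-of-paretic-cycle position of nonparetic toe-off,
    nonparetic heel strike and paretic toe-off across cycles."""
    hs = events.paretic_heel_strikes
    if hs.size < 2:
        raise InsufficientCyclesError("need at least 2 paretic heel strikes")
    np_to, np_hs, p_to = [], [], []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        np_to += _events_in_cycle_pct(events.nonparetic_toe_offs, t0, t1)
        np_hs += _events_in_cycle_pct(events.nonparetic_heel_strikes, t0, t1)
        p_to += _events_in_cycle_pct(events.paretic_toe_offs, t0, t1)
    if not (np_to and np_hs and p_to):
        raise MalformedEventsError("missing within-cycle events for bin boundaries")
    return float(np.mean(np_to)), float(np.mean(np_hs)), float(np.mean(p_to))


def _interval_mean(y: np.ndarray, a: float, b: float) -> float:
    """Exact mean of the piecewise-linear envelope over [a, b] percent."""
    xs = PCT_GRID
    inner = xs[(xs > a) & (xs < b)]
    fine = np.concatenate(([a], inner, [b]))
    vals = np.interp(fine, xs, y)
    return float(np.trapezoid(vals, fine) / (b - a))


def bin_edges_from_events(events: GaitEvents) -> np.ndarray:
    """Six-bin boundaries (percent of paretic cycle) from average event timing.

    Regions: first double support [0, npTO]; single stance split at its
    midpoint [npTO, npHS]; second double support [npHS, pTO]; swing split at
    its midpoint [pTO, 100].
    """
    np_to, np_hs, p_to = average_event_percentages(events)
    edges = np.array(
        [
            0.0,
            np_to,
            (np_to + np_hs) / 2.0,
            np_hs,
            p_to,
            (p_to + 100.0) / 2.0,
            100.0,
        ]
    )
    if not np.all(np.diff(edges) > 0):
        raise MalformedEventsError(f"bin boundaries out of order: {edges}")
    return edges


def bin_average(cyc: CycleEnvelope, events: GaitEvents) -> BinSummary:
    """Average each muscle's envelope within the six named gait-cycle regions."""
    edges = bin_edges_from_events(events)
    means = np.empty((cyc.matrix.shape[0], 6))
    for m, row in enumerate(cyc.matrix):
        for j in range(6):
            means[m, j] = _interval_mean(row, edges[j], edges[j + 1])
    return BinSummary(means, edges, BIN_LABELS, cyc.muscle_names)


def normalize_amplitude(
    cyc: CycleEnvelope, bins: BinSummary, on_zero: str = "raise"
) -> CycleEnvelope:
    """Divide each muscle's envelope by the mean of its highest bin, so the
    maximum bin mean per muscle becomes 1.

    on_zero: 'raise' (default) errors on a muscle with no positive bin mean;
    'drop' removes that muscle with a warning.
    """
    maxima = bins.bin_means.max(axis=1)
    keep = maxima > 0
    if not keep.all():
        bad = [n for n, k in zip(cyc.muscle_names, keep) if not k]
        if on_zero == "drop":
            warnings.warn(f"dropping all-zero channels: {bad}", stacklevel=2)
        else:
            raise ZeroChannelError(f"muscles with no positive bin mean: {bad}")
    matrix = cyc.matrix[keep] / maxima[keep, None]
    names = tuple(n for n, k in zip(cyc.muscle_names, keep) if k)
    return CycleEnvelope(matrix, cyc.n_cycles_averaged, names)
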