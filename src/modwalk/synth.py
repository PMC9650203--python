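"""Synthetic subjects and cohorts with known ground truth.

The study this pipeline implements deposits no raw data, so this module
emulates every measured input: paretic-leg EMG built as nonnegative module
mixtures amplitude-modulating a wide-band carrier, split-belt ground reaction
forces with a controllable propulsion asymmetry, per-step lengths with a
controllable step-length asymmetry, per-hemisphere CST/CRP streamline counts
with lesion-severity structure, and clinical scores coupled to the streamline
asymmetries.  Ground truth (module weights/activations, target Pp/PSR,
configured streamline means) is retained on every subject so each downstream
stage has a parameter-recovery test surface.

The "reference" cohort scenario reproduces the printed subgroup structure:
roughly 30/43 stroke survivors walk with more than two modules, 13/43 with
two, of whom about seven are severely impaired (strongly asymmetric CST and
CRP streamlines, contralesional CRP mean 16.8, ipsilesional CST 0.5,
ipsilesional CRP 3.3) and six moderately impaired (streamline asymmetries
similar to the multi-module group: contralesional CRP 11.5, ipsilesional CST
5.5, ipsilesional CRP 10.7); the multi-module group sits at contralesional
CRP 13.2, ipsilesional CST 4.1, ipsilesional CRP 8.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from . import emg as emg_mod
from .connectivity import StreamlineRecord
from .emg import MUSCLES, PCT_GRID, EMGRecording, GaitEvents
from .gaitmetrics import GRFTrace, StepLengths

# Nominal event timing (percent of paretic gait cycle).
NONPARETIC_TOE_OFF_PCT = 12.0
NONPARETIC_HEEL_STRIKE_PCT = 50.0
PARETIC_TOE_OFF_PCT = 62.0

_STANCE_SET = ("SO", "MG", "VM", "LH", "MH", "GM")
_SWING_SET = ("TA", "RF")

# Healthy four-module convention: plantarflexors (late stance), quadriceps +
# gluteus medius (early stance / weight acceptance), hamstrings (terminal
# swing into early stance), dorsiflexors + rectus femoris (swing).
_MODULE_SETS_4 = (
    ("SO", "MG"),
    ("VM", "GM"),
    ("MH", "LH"),
    ("TA", "RF"),
)
_CENTERS_4 = (42.0, 6.0, 96.0, 74.0)
_WIDTHS_4 = (11.0, 10.0, 10.0, 11.0)

# Three modules: the temporally adjacent hamstring and quadriceps modules
# merged (terminal swing through weight acceptance).
_MODULE_SETS_3 = (
    ("SO", "MG"),
    ("VM", "GM", "MH", "LH"),
    ("TA", "RF"),
)
_CENTERS_3 = (42.0, 2.0, 74.0)
_WIDTHS_3 = (11.0, 11.0, 11.0)


@dataclass
class GroundTruthModules:
    """Known module structure of a synthetic subject."""

    n_modules: int
    weights: np.ndarray  # muscles(8) x n_modules
    activations: np.ndarray  # n_modules x 101
    muscle_names: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        if np.any(self.weights < 0) or np.any(self.activations < 0):
            raise ValueError("module weights and activations must be nonnegative")
        if self.activations.shape != (self.n_modules, 101):
            raise ValueError("activations must be n_modules x 101")
        if not np.all(self.weights.max(axis=0) > 0):
            raise ValueError("each module must load at least one muscle")
        if not np.all(self.activations.max(axis=1) > 0):
            raise ValueError("each module must be active somewhere")

    @property
    def envelope(self) -> np.ndarray:
        """Noise-free envelope matrix weights @ activations (8 x 101)."""
        return self.weights @ self.activations


@dataclass
class ClinicalScores:
    fma_le: float | None = None  # 0-34
    fma_le_synergy: float | None = None  # 22-point subsection
    bbs: float | None = None  # 0-56
    dgi: float | None = None  # 0-24
    smwt_m: float | None = None
    ss_speed_m_s: float | None = None


@dataclass
class SyntheticSubjectConfig:
    true_n_modules: int = 4
    noise_sd: float = 0.05  # envelope noise, fraction of per-muscle signal RMS
    n_cycles: int = 20
    cycle_duration_s: float = 1.2
    cycle_jitter_sd: float = 0.03  # lognormal sd of multiplicative jitter
    fs_hz: float = 2000.0
    pp_true: float = 0.5
    psr_true: float = 0.5
    stride_length_m: float = 1.0
    cst_lesioned: float = 4.0
    cst_nonlesioned: float = 8.0
    crp_lesioned: float = 8.0
    crp_nonlesioned: float = 13.0
    scanner_batch: str = "A"
    seed: int = 0
    allow_degenerate_pp: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles < 20:
            raise ValueError("n_cycles must be at least 20")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not (0.0 <= self.pp_true <= 1.0 and 0.0 <= self.psr_true <= 1.0):
            raise ValueError("pp_true and psr_true must lie in [0, 1]")
        if self.pp_true in (0.0, 1.0) and not self.allow_degenerate_pp:
            raise ValueError(
                "pp_true of exactly 0 or 1 produces a zero-impulse leg; "
                "set allow_degenerate_pp=True to permit it"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # 'stroke' | 'healthy'
    config: SyntheticSubjectConfig | None
    truth: GroundTruthModules | None
    streamlines: StreamlineRecord
    clinical: ClinicalScores
    subgroup: str | None = None  # severe_two | moderate_two | multi | healthy
    emg: EMGRecording | None = None
    events: GaitEvents | None = None
    grf: GRFTrace | None = None
    step_lengths: StepLengths | None = None


def _circular_bump(center: float, width: float) -> np.ndarray:
    """Gaussian activation bump on the circular 0-100% cycle, peak 1."""
    d = np.abs(PCT_GRID - center)
    d = np.minimum(d, 100.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def make_truth_templates(n_modules: int, seed: int) -> GroundTruthModules:
    """Deterministic module templates for 2, 3 or 4 true modules.

    Two modules is the mass flexion-extension pattern: one stance module
    loading SO, MG, VM, LH, MH and GM, and one swing module loading TA and RF.
    Three and four modules split the stance module following the healthy
    four-module convention.  Member-muscle weights are drawn in [0.8, 1.0]
    and non-member weights in [0, 0.05], seeded.
    """
    if n_modules not in (2, 3, 4):
        raise ValueError("n_modules must be 2, 3 or 4")
    rng = np.random.default_rng([seed, n_modules])

    if n_modules == 2:
        sets = (_STANCE_SET, _SWING_SET)
        stance = np.sin(np.pi * np.clip(PCT_GRID, 0, 62.0) / 62.0) ** 2
        stance[PCT_GRID > 62.0] = 0.0
        swing = np.zeros_like(PCT_GRID)
        sw = PCT_GRID >= 62.0
        swing[sw] = np.sin(np.pi * (PCT_GRID[sw] - 62.0) / 38.0) ** 2
        activations = np.stack([stance, swing])
    else:
        sets, centers, widths = (
            (_MODULE_SETS_3, _CENTERS_3, _WIDTHS_3)
            if n_modules == 3
            else (_MODULE_SETS_4, _CENTERS_4, _WIDTHS_4)
        )
        activations = np.stack(
            [_circular_bump(c, w) for c, w in zip(centers, widths)]
        )
        sets = tuple(sets)

    weights = rng.uniform(0.0, 0.05, size=(len(MUSCLES), n_modules))
    for j, members in enumerate(sets):
        for m in members:
            weights[MUSCLES.index(m), j] = rng.uniform(0.8, 1.0)
    return GroundTruthModules(n_modules, weights, activations)


def _cycle_times(config: SyntheticSubjectConfig) -> np.ndarray:
    """Cumulative paretic heel-strike times (n_cycles + 1 values) with
    lognormal multiplicative jitter on the cycle duration; shared by the EMG
    and GRF generators so all signals sit on one time base."""
    rng = np.random.default_rng([config.seed, 101])
    if config.cycle_jitter_sd > 0:
        jitter = rng.lognormal(0.0, config.cycle_jitter_sd, size=config.n_cycles)
    else:
        jitter = np.ones(config.n_cycles)
    durations = config.cycle_duration_s * jitter
    return np.concatenate([[0.0], np.cumsum(durations)])


def _events_from_cycles(hs: np.ndarray) -> GaitEvents:
    durations = np.diff(hs)
    p_to = hs[:-1] + durations * PARETIC_TOE_OFF_PCT / 100.0
    np_hs = hs[:-1] + durations * NONPARETIC_HEEL_STRIKE_PCT / 100.0
    np_to = hs[:-1] + durations * NONPARETIC_TOE_OFF_PCT / 100.0
    return GaitEvents(hs, p_to, np_hs, np_to)


def _bandlimited_carrier(
    n: int, fs: float, rng: np.random.Generator, band=(20.0, 450.0)
) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(n))
    return x / max(np.std(x), 1e-12)


def _smooth_noise(
    n: int, fs: float, rng: np.random.Generator, cutoff_hz: float = 6.0
) -> np.ndarray:
    sos = _signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(n))
    return x / max(np.std(x), 1e-12)


def generate_emg(
    config: SyntheticSubjectConfig, truth: GroundTruthModules
) -> tuple[EMGRecording, GaitEvents]:
    """Raw-like EMG whose extracted envelope approximates weights @ activations.

    Each module activation is tiled across jittered cycles, mixed through the
    weights, optionally perturbed by smooth envelope noise (sd = noise_sd x
    per-muscle signal RMS), and used to amplitude-modulate a per-channel
    band-limited (20-450 Hz) Gaussian carrier.  The carrier is scaled so that
    the rectified mean of its 40 Hz high-passed version is 1, making the
    envelope pipeline approximately unit gain.
    """
    hs = _cycle_times(config)
    events = _events_from_cycles(hs)
    fs = config.fs_hz
    n = int(np.ceil(hs[-1] * fs)) + 1
    t = np.arange(n) / fs

    # Phase within the current cycle, in percent.
    cycle_idx = np.clip(np.searchsorted(hs, t, side="right") - 1, 0, len(hs) - 2)
    t0 = hs[cycle_idx]
    t1 = hs[cycle_idx + 1]
    phase_pct = 100.0 * (t - t0) / (t1 - t0)

    activ = np.stack(
        [np.interp(phase_pct, PCT_GRID, row) for row in truth.activations]
    )
    env_target = truth.weights @ activ  # 8 x n

    rng = np.random.default_rng([config.seed, 202])
    hp = _signal.butter(2, 40.0, btype="highpass", fs=fs, output="sos")
    raw = np.empty_like(env_target)
    for ch in range(env_target.shape[0]):
        env_ch = env_target[ch]
        if config.noise_sd > 0:
            rms = np.sqrt(np.mean(env_ch**2))
            env_ch = env_ch + config.noise_sd * rms * _smooth_noise(n, fs, rng)
            env_ch = np.clip(env_ch, 0.0, None)
        carrier = _bandlimited_carrier(n, fs, rng)
        gain = np.mean(np.abs(_signal.sosfiltfilt(hp, carrier)))
        raw[ch] = (carrier / max(gain, 1e-12)) * env_ch
    return EMGRecording(raw, fs, truth.muscle_names, "paretic"), events


def _stance_window(phase_pct: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Raised-sine bump over [start, stop] percent of the cycle (wraps)."""
    span = (stop - start) % 100.0 or 100.0
    rel = (phase_pct - start) % 100.0
    out = np.zeros_like(phase_pct)
    inside = rel <= span
    out[inside] = np.sin(np.pi * rel[inside] / span)
    return out


def generate_grf(
    config: SyntheticSubjectConfig,
) -> tuple[GRFTrace, StepLengths, GaitEvents]:
    """Split-belt GRF with analytic propulsion asymmetry plus step lengths.

    Propulsive lobes are half-sines of equal duration on both legs, so the
    impulse ratio equals the amplitude ratio and the paretic fraction of the
    total positive anterior impulse equals ``pp_true`` by construction.  Mean
    step lengths are rescaled so the paretic step ratio equals ``psr_true``
    exactly.
    """
    hs = _cycle_times(config)
    events = _events_from_cycles(hs)
    fs = config.fs_hz
    n = int(np.ceil(hs[-1] * fs)) + 1
    t = np.arange(n) / fs

    cycle_idx = np.clip(np.searchsorted(hs, t, side="right") - 1, 0, len(hs) - 2)
    t0 = hs[cycle_idx]
    t1 = hs[cycle_idx + 1]
    phase = 100.0 * (t - t0) / (t1 - t0)

    body_weight_n = 700.0
    fz_p = body_weight_n * _stance_window(phase, 0.0, PARETIC_TOE_OFF_PCT)
    fz_np = body_weight_n * _stance_window(
        phase, NONPARETIC_HEEL_STRIKE_PCT, NONPARETIC_TOE_OFF_PCT + 100.0
    )

    # Propulsion: identical half-sine lobes ending at each leg's toe-off,
    # snapped to the sample grid so every lobe integrates to exactly the same
    # value and the impulse ratio equals the amplitude ratio by construction.
    # Braking: negative lobes in early stance (clipped out of the positive
    # impulse; kept clear of the propulsive lobes).
    amp_np = 100.0
    pp = config.pp_true
    amp_p = amp_np * (pp / (1.0 - pp)) if pp < 1.0 else amp_np
    if pp >= 1.0:
        amp_np = 0.0
    lobe_s = 0.2 * config.cycle_duration_s

    def add_lobes(fy: np.ndarray, end_times: np.ndarray, amp: float) -> None:
        n_lobe = int(round(lobe_s * fs))
        shape = amp * np.sin(np.pi * np.arange(n_lobe + 1) / n_lobe)
        for t_end in end_times:
            i0 = int(round((t_end - lobe_s) * fs))
            if i0 >= 0 and i0 + n_lobe + 1 <= fy.size:
                fy[i0 : i0 + n_lobe + 1] += shape

    fy_p = np.zeros(n)
    fy_np = np.zeros(n)
    # skip the first cycle on both legs so both get the same lobe count
    add_lobes(fy_p, events.paretic_toe_offs[1:], amp_p)
    add_lobes(fy_np, events.nonparetic_toe_offs[1:], amp_np)
    fy_p -= 0.5 * max(amp_p, 20.0) * _stance_window(phase, 2.0, 25.0)
    fy_np -= 0.5 * max(amp_np, 20.0) * _stance_window(phase, 52.0, 75.0)

    trace = GRFTrace(fz_p, fz_np, fy_p, fy_np, fs)

    rng = np.random.default_rng([config.seed, 303])
    n_steps = config.n_cycles
    p_steps = 1.0 + 0.03 * rng.standard_normal(n_steps)
    np_steps = 1.0 + 0.03 * rng.standard_normal(n_steps)
    psr = config.psr_true
    stride = config.stride_length_m
    p_steps *= psr * stride / np.mean(p_steps)
    np_steps *= (1.0 - psr) * stride / np.mean(np_steps)
    return trace, StepLengths(p_steps, np_steps), events


# --- cohort generation -----------------------------------------------------

#: Subgroup streamline means for the reference scenario
#: (cst_lesioned, cst_nonlesioned, crp_lesioned, crp_nonlesioned).
SUBGROUP_STREAMLINE_MEANS = {
    "severe_two": (0.5, 8.0, 3.3, 16.8),
    "moderate_two": (5.5, 8.0, 10.7, 11.5),
    "multi": (4.1, 8.0, 8.6, 13.2),
    "healthy": (48.0, 50.0, 36.4, 40.0),
}

#: Gamma shape of the gamma-Poisson (negative-binomial) mixing used for the
#: ipsilesional CST counts of the non-severe stroke groups.  CST damage varies
#: widely among subjects who keep more than two modules (severe CST loss does
#: not by itself force the two-module pattern), so these counts are
#: overdispersed relative to Poisson while keeping the configured means.
CST_LESIONED_DISPERSION_SHAPE = 1.2

#: Batch effect applied to raw counts per scanner batch (scale, shift);
#: removed downstream by harmonization.
BATCH_EFFECTS = {"A": (1.0, 0.0), "B": (1.2, 1.0)}

SCENARIOS = ("reference",)


def _clip_round(x: float, lo: float, hi: float) -> float:
    return float(np.clip(np.round(x), lo, hi))


def _clinical_from_asymmetry(
    a_cst: float, a_crp: float, rng: np.random.Generator
) -> tuple[ClinicalScores, float, float]:
    """Clinical scores and gait-symmetry targets linearly coupled to the
    streamline asymmetries, signs matching the observed correlation
    directions (better integrity -> better function, smaller propulsion
    asymmetry); Gaussian noise on top."""
    fma = _clip_round(14.0 + 10.0 * a_cst + 12.0 * a_crp + rng.normal(0, 3.0), 0, 34)
    fma_syn = _clip_round(fma * 22.0 / 34.0, 0, 22)
    dgi = _clip_round(8.0 + 8.0 * a_crp + 2.0 * a_cst + rng.normal(0, 2.5), 0, 24)
    bbs = _clip_round(38.0 + 12.0 * a_crp + 3.0 * a_cst + rng.normal(0, 4.0), 0, 56)
    smwt = float(
        np.clip(120.0 + 250.0 * a_crp + 80.0 * a_cst + rng.normal(0, 60.0), 20, 700)
    )
    speed = float(
        np.clip(0.30 + 0.35 * a_crp + 0.20 * a_cst + rng.normal(0, 0.15), 0.1, 1.6)
    )
    pp_dev = float(
        np.clip(0.35 - 0.25 * a_crp - 0.12 * a_cst + rng.normal(0, 0.06), 0.0, 0.45)
    )
    pp_true = 0.5 - pp_dev
    psr_true = float(np.clip(0.5 + rng.normal(0, 0.05), 0.3, 0.7))
    scores = ClinicalScores(fma, fma_syn, bbs, dgi, smwt, speed)
    return scores, pp_true, psr_true


def _subgroup_counts(n_stroke: int) -> dict[str, int]:
    """Split a stroke cohort into the three subgroups at the study's
    proportions (7:6:30 severe-two : moderate-two : multi)."""
    n_sev = int(round(n_stroke * 7 / 43))
    n_mod = int(round(n_stroke * 6 / 43))
    n_multi = n_stroke - n_sev - n_mod
    return {"severe_two": n_sev, "moderate_two": n_mod, "multi": max(n_multi, 0)}


def generate_cohort(
    n_stroke: int,
    n_healthy: int,
    scenario: str = "reference",
    seed: int = 0,
    with_signals: bool = False,
    noise_sd: float = 0.05,
) -> list[SyntheticSubject]:
    """Seeded synthetic cohort with subgroup structure, streamline counts,
    clinical couplings and (optionally) raw EMG/GRF signals.

    Streamline counts are Poisson draws around the configured subgroup means
    with the scanner-batch effect applied on top of the raw counts.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")
    if n_stroke < 0 or n_healthy < 0:
        raise ValueError("cohort sizes must be nonnegative")
    subjects: list[SyntheticSubject] = []
    counts = _subgroup_counts(n_stroke)
    roster: list[tuple[str, str, int | None]] = []
    multi_k = [3, 4]
    i_multi = 0
    for sg in ("severe_two", "moderate_two", "multi"):
        for _ in range(counts[sg]):
            if sg == "multi":
                k = multi_k[i_multi % 2]
                i_multi += 1
            else:
                k = 2
            roster.append((sg, "stroke", k))
    roster += [("healthy", "healthy", None)] * n_healthy

    for i, (sg, group, true_k) in enumerate(roster):
        rng = np.random.default_rng([seed, 7, i])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        batch = "A" if rng.random() < 0.5 else "B"
        scale, shift = BATCH_EFFECTS[batch]
        means = SUBGROUP_STREAMLINE_MEANS[sg]
        base_counts = []
        for j, m in enumerate(means):
            if j == 0 and sg in ("moderate_two", "multi"):
                shape = CST_LESIONED_DISPERSION_SHAPE
                lam = rng.gamma(shape, m / shape)
                base_counts.append(float(rng.poisson(lam)))
            else:
                base_counts.append(float(rng.poisson(m)))
        rec = StreamlineRecord(
            f"{group[0]}{i:03d}",
            group,
            *(scale * c + shift for c in base_counts),
            batch,
        )
        # Couplings use the subject's own batch-free asymmetries (what
        # harmonization recovers downstream).
        a_cst = base_counts[0] / max(base_counts[1], 1.0)
        a_crp = base_counts[2] / max(base_counts[3], 1.0)

        if group == "stroke":
            clinical, pp_true, psr_true = _clinical_from_asymmetry(a_cst, a_crp, rng)
            config = SyntheticSubjectConfig(
                true_n_modules=true_k,
                noise_sd=noise_sd,
                pp_true=pp_true,
                psr_true=psr_true,
                scanner_batch=batch,
                seed=sub_seed,
            )
            truth = make_truth_templates(true_k, sub_seed)
            subject = SyntheticSubject(
                rec.subject_id, group, config, truth, rec, clinical, sg
            )
            if with_signals:
                subject.emg, subject.events = generate_emg(config, truth)
                subject.grf, subject.step_lengths, _ = generate_grf(config)
        else:
            subject = SyntheticSubject(
                rec.subject_id, group, None, None, rec, ClinicalScores(), sg
            )
        subjects.append(subject)
    return subjects
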