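"""Synthetic fNIRS sessions with known hemodynamic ground truth.

The generator emulates the study design this package analyses: blocks of
eight sentence-sequence events (six low-context sequences of 3-5 sentences
lasting >= 18 s and two short high-context decoys), separated by 30-s silent
baselines, one practice block plus test blocks split evenly between a
standard and a DNN hearing-aid program. Neural responses are canonical
double-gamma hemodynamic responses superposed per sentence; raw intensities
are produced by running the modified Beer-Lambert law forward and layering
cardiac, respiratory, Mayer-wave, drift and white noise plus step and spike
artifacts. Short-separation channels carry the superficial component only --
never event-locked neural signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_DPF, WAVELENGTHS_NM, extinction_matrix
from .probe_io import CONDITIONS, ProbeMontage, RawRecording, SUBREGIONS, default_montage, validate_events
from .series import HbSeries

SENTENCE_DURATION_S = 6.0
BASELINE_S = 30.0

#: left-lateral HbDiff window means per program (µM); the DNN program sits
#: ~19 µM below the standard program, and other subregions carry no effect.
DEFAULT_AMPLITUDES_UM = {
    ("standard", "left_lateral"): 4.2,
    ("dnn", "left_lateral"): -14.8,
    ("standard", "lower_medial"): 0.0,
    ("dnn", "lower_medial"): 0.0,
    ("standard", "right_lateral"): 0.0,
    ("dnn", "right_lateral"): 0.0,
}


@dataclass
class GroundTruth:
    """Programmed event-response amplitudes and artifact schedule.

    ``amplitudes_um`` maps (condition, subregion) to the HbDiff window mean the
    epoching stage should recover; HbO and HbR shares of that difference are
    set by ``hbo_fraction`` (HbO = f*HbDiff, HbR = (f-1)*HbDiff so that
    HbO - HbR = HbDiff exactly).
    """

    amplitudes_um: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES_UM))
    hbo_fraction: float = 0.75
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hbr_lag_s: float = 2.0
    superficial_gain: float = 0.4  # long-channel pickup of the scalp component
    #: the scalp/systemic component is predominantly arterial (oxygenated)
    #: pulsation, so by default it projects onto HbO only
    superficial_hbo_fraction: float = 1.0
    step_times_s: tuple = ()  # (time_s, channel, od_magnitude)
    spike_times_s: tuple = ()  # (time_s, channel, od_magnitude)

    def condition_effect_um(self, subregion: str = "left_lateral") -> float:
        return self.amplitudes_um[("standard", subregion)] - self.amplitudes_um[("dnn", subregion)]

    def hbdiff_to_hbo_hbr(self, hbdiff: float) -> tuple[float, float]:
        return self.hbo_fraction * hbdiff, (self.hbo_fraction - 1.0) * hbdiff


@dataclass
class NoiseParams:
    """Physiological and instrumental noise layered onto the true signal.

    Amplitudes are µM of equivalent hemoglobin excursion except the white
    noise, which is a relative intensity SD. ``cardiac_weights`` scales the
    cardiac oscillation per channel (length n_channels); a zero entry makes
    that channel cardiac-free, which the scalp-coupling index should flag.
    """

    cardiac_amp_um: float = 2.0
    cardiac_hz: float = 1.1
    resp_amp_um: float = 1.5
    resp_hz: float = 0.25
    mayer_amp_um: float = 2.0
    mayer_hz: float = 0.1
    drift_um_per_s: float = 0.01
    random_walk_um: float = 0.05
    white_noise_rel: float = 0.001
    cardiac_weights: np.ndarray | None = None

    @staticmethod
    def off() -> "NoiseParams":
        return NoiseParams(0.0, 1.1, 0.0, 0.25, 0.0, 0.1, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# session design


def make_session_design(
    n_blocks: int = 4,
    seed: int = 0,
    include_practice: bool = True,
    sentence_duration_s: float = SENTENCE_DURATION_S,
    baseline_s: float = BASELINE_S,
) -> pd.DataFrame:
    """Event table for one session: practice block plus ``n_blocks`` test blocks.

    Each block holds six low-context sequences (3-5 sentences, >= 18 s) and two
    decoys (1-2 high-context sentences), in seed-randomised order with 30-s
    baselines between events. Test blocks are split evenly between conditions
    and their order is randomised; the practice block always runs the standard
    program.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    conds = [CONDITIONS[i % 2] for i in range(n_blocks)]
    rng.shuffle(conds)

    rows = []
    t = baseline_s
    blocks = ([("standard", 0, True)] if include_practice else []) + [
        (conds[i], i + 1, False) for i in range(n_blocks)
    ]
    for cond, block_id, practice in blocks:
        n_low = rng.integers(3, 6, size=6)  # 3..5 sentences
        n_decoy = rng.integers(1, 3, size=2)  # 1..2 sentences
        kinds = [("low", int(n)) for n in n_low] + [("high", int(n)) for n in n_decoy]
        rng.shuffle(kinds)
        for context, n_sent in kinds:
            dur = n_sent * sentence_duration_s
            rows.append(
                {
                    "onset": t,
                    "duration": dur,
                    "condition": cond,
                    "context": context,
                    "n_sentences": n_sent,
                    "block": block_id,
                    "practice": practice,
                }
            )
            t += dur + baseline_s
    return validate_events(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hemodynamics


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response (unit scale 1 s)."""
    pos = stats.gamma.pdf(t, a=peak_s + 1.0, scale=1.0)
    neg = stats.gamma.pdf(t, a=undershoot_s + 1.0, scale=1.0)
    h = pos - ratio * neg
    return h


def _event_regressor(n_times: int, fs: float, onset: float, n_sentences: int, sentence_s: float, hrf: np.ndarray, lag_s: float = 0.0) -> np.ndarray:
    """Superposition of per-sentence boxcars convolved with the HRF."""
    box = np.zeros(n_times)
    for s in range(n_sentences):
        i0 = int(round((onset + s * sentence_s + lag_s) * fs))
        i1 = int(round((onset + (s + 1) * sentence_s + lag_s) * fs))
        box[max(i0, 0) : min(i1, n_times)] = 1.0
    r = np.convolve(box, hrf)[:n_times] / fs
    return r


def _window_mean(x: np.ndarray, fs: float, onset: float, offset: float) -> float:
    i10 = int(round((onset + 10.0) * fs))
    i_end = int(round(offset * fs))
    ib0 = int(round((onset - 5.0) * fs))
    ib1 = int(round(onset * fs))
    return float(np.mean(x[i10:i_end]) - np.mean(x[max(ib0, 0) : ib1]))


def simulate_hemodynamics(
    design: pd.DataFrame,
    truth: GroundTruth,
    montage: ProbeMontage,
    seed: int = 0,
    fs: float = 10.0,
    sentence_duration_s: float = SENTENCE_DURATION_S,
) -> HbSeries:
    """True (noise-free) HbO/HbR traces per channel for a session design.

    Each event contributes a per-sentence-boxcar x HRF response scaled so that
    the epoching window mean (10 s post-onset to offset, minus the 5-s
    pre-onset baseline) of an isolated event equals the programmed amplitude.
    Short channels carry no neural signal.
    """
    duration = float(design["onset"].iloc[-1] + design["duration"].iloc[-1] + BASELINE_S + 5.0)
    n_times = int(round(duration * fs))
    hrf = double_gamma_hrf(np.arange(0, 40.0, 1.0 / fs), truth.hrf_peak_s, truth.hrf_undershoot_s, truth.hrf_undershoot_ratio)

    hbo = np.zeros((n_times, montage.n_channels))
    hbr = np.zeros((n_times, montage.n_channels))
    for ev in design.itertuples(index=False):
        r_o = _event_regressor(n_times, fs, ev.onset, ev.n_sentences, sentence_duration_s, hrf)
        r_r = _event_regressor(n_times, fs, ev.onset, ev.n_sentences, sentence_duration_s, hrf, truth.hbr_lag_s)
        offset = ev.onset + ev.duration
        if ev.duration > 12.0:
            norm_o = _window_mean(r_o, fs, ev.onset, offset)
            norm_r = _window_mean(r_r, fs, ev.onset, offset)
        else:  # decoys: too short for the analysis window; scale by peak
            norm_o = float(r_o.max())
            norm_r = float(r_r.max())
        for ch in montage.long_channels:
            hbdiff_amp = truth.amplitudes_um[(ev.condition, ch.subregion)]
            a_o, a_r = truth.hbdiff_to_hbo_hbr(hbdiff_amp)
            if norm_o != 0.0:
                hbo[:, ch.index] += (a_o / norm_o) * r_o
            if norm_r != 0.0:
                hbr[:, ch.index] += (a_r / norm_r) * r_r
    return HbSeries(hbo=hbo, hbr=hbr, fs=fs)


# ---------------------------------------------------------------------------
# forward optics + noise


def _superficial_hb(n_times: int, fs: float, noise: NoiseParams, rng: np.random.Generator, n_channels: int):
    """Scalp/systemic hemoglobin component: shared oscillations + drift.

    Returns (shared_um (n_times,), cardiac_um (n_times,), per-channel drift
    (n_times, n_channels)). The cardiac oscillation is returned separately so
    per-channel cardiac weights can be applied.
    """
    t = np.arange(n_times) / fs
    ph = rng.uniform(0, 2 * np.pi, size=3)
    cardiac = noise.cardiac_amp_um * np.sin(2 * np.pi * noise.cardiac_hz * t + ph[0])
    shared = noise.resp_amp_um * np.sin(2 * np.pi * noise.resp_hz * t + ph[1])
    shared = shared + noise.mayer_amp_um * np.sin(2 * np.pi * noise.mayer_hz * t + ph[2])
    drift = np.zeros((n_times, n_channels))
    for c in range(n_channels):
        slope = noise.drift_um_per_s * rng.standard_normal()
        walk = np.cumsum(noise.random_walk_um * rng.standard_normal(n_times)) / np.sqrt(fs)
        drift[:, c] = slope * t + walk
    return shared, cardiac, drift


def simulate_raw_intensity(
    true_hb: HbSeries,
    noise: NoiseParams,
    montage: ProbeMontage,
    seed: int = 0,
    events: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
    meta: dict | None = None,
    baseline_intensity: float = 1.0,
    dpf: float = DEFAULT_DPF,
) -> RawRecording:
    """Run the Beer-Lambert law forward and layer noise and artifacts.

    Long channels carry neural signal plus a gain-scaled copy of the shared
    superficial component; short channels carry the superficial component
    only. Step and spike artifacts from the ground-truth schedule are applied
    multiplicatively in intensity (i.e., additively in optical density).
    """
    rng = np.random.default_rng(seed)
    truth = truth or GroundTruth()
    n_times, n_channels = true_hb.hbo.shape
    fs = true_hb.fs
    E = extinction_matrix()

    shared, cardiac, drift = _superficial_hb(n_times, fs, noise, rng, n_channels)
    cw = np.ones(n_channels) if noise.cardiac_weights is None else np.asarray(noise.cardiac_weights, float)

    intensity = np.empty((n_times, n_channels, len(WAVELENGTHS_NM)))
    for ch in montage.channels:
        gain = 1.0 if ch.is_short else truth.superficial_gain
        sup = gain * (shared + cw[ch.index] * cardiac) + drift[:, ch.index]
        f_sup = truth.superficial_hbo_fraction
        hbo_um = (0.0 if ch.is_short else true_hb.hbo[:, ch.index]) + f_sup * sup
        hbr_um = (0.0 if ch.is_short else true_hb.hbr[:, ch.index]) + (f_sup - 1.0) * sup
        d = montage.separation(ch)
        conc_mm = np.column_stack([hbo_um, hbr_um]) / 1000.0  # µM -> mM
        od = conc_mm @ E.T * (d * dpf)  # (n_times, 2)
        if np.max(np.abs(od)) > 20.0:
            raise ValueError(
                f"channel {ch.name}: programmed amplitude drives optical density to "
                f"{np.max(np.abs(od)):.1f}; intensity would underflow to zero"
            )
        for wi in range(len(WAVELENGTHS_NM)):
            w_noise = noise.white_noise_rel * rng.standard_normal(n_times)
            intensity[:, ch.index, wi] = baseline_intensity * np.exp(-od[:, wi] + w_noise)

    for t_s, ch_i, mag in truth.step_times_s:
        i = int(round(t_s * fs))
        intensity[i:, ch_i, :] *= np.exp(mag)
    for t_s, ch_i, mag in truth.spike_times_s:
        i = int(round(t_s * fs))
        intensity[i, ch_i, :] *= np.exp(mag)

    if events is None:
        events = pd.DataFrame(columns=["onset", "duration", "condition", "context", "n_sentences", "block", "practice"])
    rec = RawRecording(intensity=intensity, fs=fs, events=events, montage=montage, meta=meta or {})
    rec.validate()
    return rec


def simulate_session(
    participant: str = "P01",
    seed: int = 0,
    n_blocks: int = 4,
    truth: GroundTruth | None = None,
    noise: NoiseParams | None = None,
    montage: ProbeMontage | None = None,
    handedness: str = "right",
    fs: float = 10.0,
) -> tuple[RawRecording, HbSeries, GroundTruth]:
    """One participant's full session: design -> true hemodynamics -> raw intensity."""
    truth = truth or GroundTruth()
    noise = noise if noise is not None else NoiseParams()
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    s_design, s_hemo, s_noise = (int(rng.integers(2**31)) for _ in range(3))
    design = make_session_design(n_blocks=n_blocks, seed=s_design)
    true_hb = simulate_hemodynamics(design, truth, montage, seed=s_hemo, fs=fs)
    rec = simulate_raw_intensity(
        true_hb,
        noise,
        montage,
        seed=s_noise,
        events=design,
        truth=truth,
        meta={"participant": participant, "handedness": handedness, "session": "sim"},
    )
    return rec, true_hb, truth


# ---------------------------------------------------------------------------
# behaviour


@dataclass
class BehaviourParams:
    """Trial-level response model: rounded clipped-normal effort ratings on a
    1-7 scale and Bernoulli correctness, each per hearing-aid program."""

    effort_mean: dict = field(default_factory=lambda: {"standard": 4.02, "dnn": 3.08})
    effort_sd: float = 0.9
    p_correct: dict = field(default_factory=lambda: {"standard": 0.63, "dnn": 0.77})


def simulate_behaviour(design: pd.DataFrame, params: BehaviourParams | None = None, seed: int = 0) -> pd.DataFrame:
    """One behavioural record per non-practice event (effort rating, correctness)."""
    params = params or BehaviourParams()
    rng = np.random.default_rng(seed)
    rows = []
    for i, ev in enumerate(design.itertuples(index=False)):
        if ev.practice:
            continue
        rating = int(np.clip(np.round(rng.normal(params.effort_mean[ev.condition], params.effort_sd)), 1, 7))
        correct = bool(rng.random() < params.p_correct[ev.condition])
        rows.append(
            {
                "event": i,
                "condition": ev.condition,
                "context": ev.context,
                "block": ev.block,
                "effort": rating,
                "correct": correct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# direct trial-table simulator (for the multilevel machinery)


def simulate_trial_table(
    n_participants: int = 26,
    n_trials: int = 12,
    seed: int = 0,
    effects_um: dict | None = None,
    intercept_um: float = -7.2,
    handedness_effect_um: float = 13.46,
    p_left_handed: float = 4 / 26,
    participant_sd_um: float = 15.0,
    residual_sd_um: float = 60.0,
    behaviour: BehaviourParams | None = None,
    effort_slope_um: float = 0.0,
) -> pd.DataFrame:
    """Long-format trial x subregion table with known fixed effects.

    ``effects_um`` maps subregion -> DNN-minus-standard HbDiff effect (µM);
    default is a left-lateral-only -19 µM effect. When ``effort_slope_um`` is
    nonzero, left-lateral HbDiff on correct trials additionally tracks the
    centred effort rating with that slope, emulating a brain-behaviour
    coupling present only when the task is performed successfully.
    """
    effects = {"left_lateral": -19.0, "lower_medial": 0.0, "right_lateral": 0.0}
    if effects_um:
        effects.update(effects_um)
    behaviour = behaviour or BehaviourParams()
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        handed = "left" if rng.random() < p_left_handed else "right"
        u = participant_sd_um * rng.standard_normal()
        for cond in CONDITIONS:
            for trial in range(n_trials):
                rating = int(np.clip(np.round(rng.normal(behaviour.effort_mean[cond], behaviour.effort_sd)), 1, 7))
                correct = bool(rng.random() < behaviour.p_correct[cond])
                for sub in SUBREGIONS:
                    mu = intercept_um + u
                    if handed == "right":
                        mu += handedness_effect_um
                    if cond == "dnn":
                        mu += effects[sub]
                    if sub == "left_lateral" and correct and effort_slope_um:
                        mu += effort_slope_um * (rating - 4.0)
                    rows.append(
                        {
                            "participant": f"P{p:02d}",
                            "condition": cond,
                            "subregion": sub,
                            "event": trial,
                            "hbdiff": mu + residual_sd_um * rng.standard_normal(),
                            "effort": rating,
                            "correct": correct,
                            "handedness": handed,
                        }
                    )
    return pd.DataFrame(rows)
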