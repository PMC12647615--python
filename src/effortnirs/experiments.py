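"""Seeded simulation experiments characterising the whole analysis chain.

Each function runs the package end to end under known ground truth and
returns the measured quantity: parameter recovery through the full
preprocess -> epoch -> multilevel chain, scalp-coupling-index detection of a
cardiac-free channel, staircase estimator bias, and the power of the simple
slopes analysis to localise a left-lateral-only program effect. They are the
backing computations for the validation suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import events as ev
from .mlm import HbDiffModel, ModelSpec, simple_slopes
from .preprocessing import PipelineParams, reject_channels, run_pipeline
from .probe_io import default_montage
from .series import HbSeries
from .staircase import Listener, run_staircase, snr50_protocol
from .synthetic import (
    GroundTruth,
    NoiseParams,
    simulate_behaviour,
    simulate_raw_intensity,
    simulate_session,
    simulate_trial_table,
)

INTERACTION_NO_COVARIATE = ModelSpec(program=True, subregion=True, interaction=True)


def recover_program_effect_once(
    seed: int,
    n_participants: int = 6,
    truth: GroundTruth | None = None,
    noise: NoiseParams | None = None,
) -> float:
    """One seeded cohort through the full chain; returns the fitted DNN
    program coefficient at the left-lateral reference (µM)."""
    rng = np.random.default_rng(seed)
    truth = truth or GroundTruth()
    montage = default_montage()
    params = PipelineParams()
    tables = []
    for p in range(n_participants):
        pid = f"P{p:02d}"
        rec, _, _ = simulate_session(
            participant=pid,
            seed=int(rng.integers(2**31)),
            truth=truth,
            noise=noise,
            montage=montage,
        )
        hb, qc = run_pipeline(rec, params)
        beh = simulate_behaviour(rec.events, seed=int(rng.integers(2**31)))
        tables.append(
            ev.build_trial_table(hb, rec.events, montage, qc, beh, participant=pid)
        )
    table = pd.concat(tables, ignore_index=True)
    res = HbDiffModel(table, INTERACTION_NO_COVARIATE).fit()
    term = "C(condition, Treatment('standard'))[T.dnn]"
    return float(res.fe_params[term])


def pipeline_recovery_experiment(
    n_runs: int = 10, seed: int = 0, n_participants: int = 6
) -> dict:
    """Parameter recovery of the programmed left-lateral program effect.

    Returns the per-run estimates, the programmed truth, the mean relative
    error, and how many runs recovered the correct (negative) sign.
    """
    truth = GroundTruth()
    programmed = -truth.condition_effect_um()  # DNN-minus-standard, negative
    rng = np.random.default_rng(seed)
    estimates = [
        recover_program_effect_once(int(rng.integers(2**31)), n_participants, truth)
        for _ in range(n_runs)
    ]
    estimates = np.asarray(estimates)
    return {
        "estimates_um": estimates,
        "programmed_um": programmed,
        "mean_estimate_um": float(estimates.mean()),
        "mean_relative_error": float(abs(estimates.mean() - programmed) / abs(programmed)),
        "n_correct_sign": int((np.sign(estimates) == np.sign(programmed)).sum()),
        "n_runs": n_runs,
    }


def sci_detection_experiment(
    n_seeds: int = 100,
    seed: int = 0,
    duration_s: float = 60.0,
    threshold: float = 0.75,
    quiet_channel: int = 4,
) -> dict:
    """Reject-exactly-the-cardiac-free-channel rate over seeded simulations.

    Builds short event-free recordings in which one channel carries no
    cardiac oscillation and scores every channel's SCI.
    """
    montage = default_montage()
    fs = 10.0
    n_times = int(duration_s * fs)
    weights = np.ones(montage.n_channels)
    weights[quiet_channel] = 0.0
    noise = NoiseParams(cardiac_weights=weights)
    silent = HbSeries(np.zeros((n_times, montage.n_channels)), np.zeros((n_times, montage.n_channels)), fs)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        rec = simulate_raw_intensity(silent, noise, montage, seed=int(rng.integers(2**31)))
        qc = reject_channels(rec, threshold)
        if qc.rejected[quiet_channel] and qc.rejected.sum() == 1:
            hits += 1
    return {"hit_rate": hits / n_seeds, "n_seeds": n_seeds, "quiet_channel": quiet_channel}


def staircase_bias_experiment(
    n_runs: int = 1000, seed: int = 0, snr50_true: float = 0.0, slope: float = 1.0
) -> dict:
    """Monte-Carlo bias of the single-run SNR-50 estimator."""
    listener = Listener(snr50_true=snr50_true, slope=slope)
    rng = np.random.default_rng(seed)
    ests = np.array([run_staircase(listener, seed=int(rng.integers(2**31)))[0] for _ in range(n_runs)])
    return {
        "bias_db": float(ests.mean() - snr50_true),
        "sd_db": float(ests.std()),
        "n_runs": n_runs,
    }


def protocol_offset_experiment(
    n_listeners: int = 500, seed: int = 0, snr50_true: float = -2.6, slope: float = 1.0
) -> dict:
    """Mean three-run protocol output vs listener SNR-50 + 2 dB."""
    listener = Listener(snr50_true=snr50_true, slope=slope)
    rng = np.random.default_rng(seed)
    outs = np.array(
        [snr50_protocol(listener, seed=int(rng.integers(2**31)))[0] for _ in range(n_listeners)]
    )
    return {
        "mean_test_snr_db": float(outs.mean()),
        "expected_db": snr50_true + 2.0,
        "offset_error_db": float(outs.mean() - (snr50_true + 2.0)),
        "n_listeners": n_listeners,
    }


def slopes_localisation_experiment(
    n_seeds: int = 100,
    seed_start: int = 0,
    effect_um: float = -19.0,
    n_participants: int = 26,
    residual_sd_um: float = 60.0,
    alpha: float = 0.05,
) -> dict:
    """Power of simple slopes to localise a left-lateral-only program effect.

    A run counts as a correct localisation when the left-lateral slope is
    significant at ``alpha`` and both other subregions' slopes are not.
    """
    hits = 0
    ll_sig = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(seed_start, seed_start + n_seeds):
            tbl = simulate_trial_table(
                n_participants=n_participants,
                seed=s,
                effects_um={"left_lateral": effect_um},
                residual_sd_um=residual_sd_um,
            )
            res = HbDiffModel(tbl, INTERACTION_NO_COVARIATE).fit()
            sl = simple_slopes(res, method="contrast").set_index("subregion")
            sig = sl["p"] < alpha
            if sig["left_lateral"]:
                ll_sig += 1
                if not sig["lower_medial"] and not sig["right_lateral"]:
                    hits += 1
    return {
        "localisation_rate": hits / n_seeds,
        "left_lateral_power": ll_sig / n_seeds,
        "n_seeds": n_seeds,
    }
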