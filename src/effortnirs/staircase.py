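"""Adaptive SNR-50 staircase and a simulated logistic listener.

The search follows modified HINT adaptation rules: 20 sentences per run,
starting at 8 dB SNR against noise fixed at 70 dB(A); the SNR decreases after
a correct response and increases after an incorrect one, by 4 dB for the
adjustments applied after trials 1-5 and by 2 dB thereafter. The run's SNR-50
estimate is the mean of the SNRs presented on trials 12-20 plus the SNR that
would have been presented on trial 21. A participant completes three runs and
is tested at the mean of the last two runs' estimates plus 2 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_TRIALS = 20
START_SNR_DB = 8.0
LARGE_STEP_DB = 4.0
SMALL_STEP_DB = 2.0
N_LARGE_STEPS = 5  # adjustments after trials 1..5 use the large step
ESTIMATE_FROM_TRIAL = 12
PROTOCOL_OFFSET_DB = 2.0
NOISE_LEVEL_DBA = 70.0


@dataclass
class StaircaseState:
    """Current position in one 20-trial run."""

    trial_index: int = 1  # 1-based index of the next sentence to present
    current_snr: float = START_SNR_DB
    history: list = field(default_factory=list)  # (snr_presented, correct)
    n_large_steps: int = N_LARGE_STEPS

    @property
    def finished(self) -> bool:
        return self.trial_index > N_TRIALS


def step_size(trial_just_answered: int, n_large_steps: int = N_LARGE_STEPS) -> float:
    """Step applied after a given trial: 4 dB for trials 1-5, 2 dB after."""
    return LARGE_STEP_DB if trial_just_answered <= n_large_steps else SMALL_STEP_DB


def next_snr(state: StaircaseState, correct: bool) -> StaircaseState:
    """Record the response to the current trial and step the SNR.

    Decreases the SNR after a correct response, increases it after an
    incorrect one; errors if called once the 20-trial run is complete.
    """
    if state.finished:
        raise ValueError("staircase already completed 20 trials")
    step = step_size(state.trial_index, state.n_large_steps)
    new_snr = state.current_snr - step if correct else state.current_snr + step
    return StaircaseState(
        trial_index=state.trial_index + 1,
        current_snr=new_snr,
        history=state.history + [(state.current_snr, bool(correct))],
        n_large_steps=state.n_large_steps,
    )


@dataclass
class Listener:
    """Logistic simulated listener: P(correct | snr) = 1/(1+exp(-slope*(snr-snr50)))."""

    snr50_true: float = 0.0
    slope: float = 1.0  # dB^-1

    def p_correct(self, snr: float) -> float:
        return 1.0 / (1.0 + np.exp(-self.slope * (snr - self.snr50_true)))

    def respond(self, snr: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(snr))


def run_staircase(listener: Listener, seed: int = 0, responses=None) -> tuple[float, StaircaseState]:
    """One 20-trial run; returns (snr50 estimate, final state).

    ``responses`` may supply a deterministic correctness sequence (or callable
    of SNR) in place of the stochastic listener, for rule-level checks.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState()
    while not state.finished:
        if responses is None:
            correct = listener.respond(state.current_snr, rng)
        elif callable(responses):
            correct = bool(responses(state.current_snr))
        else:
            correct = bool(responses[state.trial_index - 1])
        state = next_snr(state, correct)
    presented = [snr for snr, _ in state.history]
    tail = presented[ESTIMATE_FROM_TRIAL - 1 : N_TRIALS] + [state.current_snr]
    return float(np.mean(tail)), state


def protocol_test_snr(runs) -> float:
    """Test SNR from three run estimates: mean of the last two plus 2 dB."""
    if len(runs) != 3:
        raise ValueError("the protocol uses exactly three runs")
    return float(np.mean(runs[1:]) + PROTOCOL_OFFSET_DB)


def snr50_protocol(listener: Listener, seed: int = 0) -> tuple[float, list]:
    """Three runs; the test SNR is mean(run 2, run 3) + 2 dB."""
    rng = np.random.default_rng(seed)
    runs = [run_staircase(listener, seed=int(rng.integers(2**31)))[0] for _ in range(3)]
    return protocol_test_snr(runs), runs
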