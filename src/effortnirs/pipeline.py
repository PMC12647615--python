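"""End-to-end orchestration: simulate -> preprocess -> epoch -> statistics.

``run_all`` drives a fully reproducible demo study from a single seed and a
config: it simulates a cohort of sessions, runs every recording through the
preprocessing pipeline, assembles the long-format trial table, and produces
the behavioural tests, the nested multilevel hierarchy, simple slopes, the
brain-behaviour model, QC JSON and figures. ``load_osf_export`` maps a
user-supplied deposited trial table onto the same long-table contract.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import mlm
from .behaviour import paired_t, rau_transform
from .preprocessing import PipelineParams, run_pipeline
from .probe_io import default_montage, write_recording
from .series import HbSeries
from .synthetic import (
    BehaviourParams,
    GroundTruth,
    NoiseParams,
    simulate_behaviour,
    simulate_session,
)


@dataclass
class RunConfig:
    """Single source of truth for a reproducible run.

    Defaults are the analysis' stated values: derivative threshold 2 SD, SCI
    threshold 0.75, wavelet IQR factor 0.1, 0.01-1.5 and 0.01-0.09 Hz bands,
    10-s response delay / 5-s baseline windows, and the 8 dB / +-4 / +-2 dB /
    +2 dB staircase constants (which live in :mod:`effortnirs.staircase`).
    """

    seed: int = 0
    outdir: str = "effortnirs_run"
    n_participants: int = 8
    n_blocks: int = 4
    left_handed_fraction: float = 4 / 26
    k_sd: float = 2.0
    sci_threshold: float = 0.75
    iqr_k: float = 0.1
    band_wide_hz: tuple = (0.01, 1.5)
    band_narrow_hz: tuple = (0.01, 0.09)
    dpf: float = 6.0
    write_snirf: bool = False
    make_figures: bool = True

    def pipeline_params(self) -> PipelineParams:
        return PipelineParams(
            k_sd=self.k_sd,
            sci_threshold=self.sci_threshold,
            iqr_k=self.iqr_k,
            band_wide_hz=tuple(self.band_wide_hz),
            band_narrow_hz=tuple(self.band_narrow_hz),
            dpf=self.dpf,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["band_wide_hz"] = list(self.band_wide_hz)
        doc["band_narrow_hz"] = list(self.band_narrow_hz)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def participant_handedness(n: int, left_fraction: float, rng: np.random.Generator) -> list[str]:
    """Deterministic left/right mix: round(n*fraction) left-handers, shuffled."""
    n_left = max(1, int(round(n * left_fraction))) if n >= 4 else 0
    handed = ["left"] * n_left + ["right"] * (n - n_left)
    rng.shuffle(handed)
    return handed


def simulate_cohort(
    config: RunConfig,
    truth: GroundTruth | None = None,
    noise: NoiseParams | None = None,
    behaviour_params: BehaviourParams | None = None,
) -> tuple[pd.DataFrame, list, GroundTruth]:
    """Simulate and preprocess every participant; return the pooled trial table.

    Returns (trial_table, per-participant QC reports, ground truth).
    """
    rng = np.random.default_rng(config.seed)
    truth = truth or GroundTruth()
    montage = default_montage()
    params = config.pipeline_params()
    handed = participant_handedness(config.n_participants, config.left_handed_fraction, rng)
    tables, qcs = [], []
    for p in range(config.n_participants):
        pid = f"P{p:02d}"
        s_sess, s_beh = int(rng.integers(2**31)), int(rng.integers(2**31))
        rec, _, _ = simulate_session(
            participant=pid,
            seed=s_sess,
            n_blocks=config.n_blocks,
            truth=truth,
            noise=noise,
            montage=montage,
            handedness=handed[p],
        )
        hb, qc = run_pipeline(rec, params)
        beh = simulate_behaviour(rec.events, behaviour_params, seed=s_beh)
        table = ev.build_trial_table(
            hb, rec.events, montage, qc, beh, participant=pid, handedness=handed[p]
        )
        tables.append(table)
        qcs.append(qc)
    return pd.concat(tables, ignore_index=True), qcs, truth


def behavioural_tables(trial_table: pd.DataFrame, n_trials_per_condition: int | None = None) -> dict:
    """Per-participant condition means -> paired tests on effort and RAU accuracy."""
    one_region = trial_table[trial_table["subregion"] == "left_lateral"]
    effort = one_region.pivot_table(index="participant", columns="condition", values="effort")
    out = {}
    out["effort"] = paired_t(effort["standard"].to_numpy(), effort["dnn"].to_numpy())
    counts = one_region.groupby(["participant", "condition"])["correct"].agg(["sum", "count"])
    n_items = n_trials_per_condition or int(counts["count"].max())
    rau = rau_transform(counts["sum"].to_numpy(), counts["count"].to_numpy())
    counts = counts.assign(rau=rau).reset_index()
    rau_wide = counts.pivot(index="participant", columns="condition", values="rau")
    out["accuracy_rau"] = paired_t(rau_wide["standard"].to_numpy(), rau_wide["dnn"].to_numpy())
    return out


def load_osf_export(path) -> pd.DataFrame:
    """Map a locally supplied deposited trial table onto the long-table contract.

    The exact deposit schema is not fixed; common column aliases are accepted
    and an error naming the expected columns is raised when a required field
    cannot be located. Nothing is ever downloaded.
    """
    df = pd.read_csv(path)
    aliases = {
        "participant": ["participant", "subject", "subject_id", "id", "pid"],
        "condition": ["condition", "program", "listening_program", "hearing_aid_program"],
        "subregion": ["subregion", "region", "roi"],
        "hbdiff": ["hbdiff", "hb_diff", "oxygenation", "hbo_minus_hbr"],
        "effort": ["effort", "effort_rating", "listening_effort"],
        "correct": ["correct", "accuracy", "is_correct"],
        "handedness": ["handedness", "handed"],
    }
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    missing = []
    for target, names in aliases.items():
        found = next((lower[n] for n in names if n in lower), None)
        if found is None:
            if target in ("effort", "correct", "handedness"):
                continue  # optional behavioural columns
            missing.append(f"{target} (one of {names})")
        else:
            rename[found] = target
    if missing:
        raise ValueError("export is missing required columns: " + "; ".join(missing))
    out = df.rename(columns=rename)
    if "event" not in out.columns:
        out["event"] = out.groupby(["participant", "condition", "subregion"]).cumcount()
    return out


def _figures(trial_table: pd.DataFrame, hb_example: HbSeries | None, outdir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    # marginal means per subregion x program
    means = (
        trial_table.dropna(subset=["hbdiff"])
        .groupby(["subregion", "condition"])["hbdiff"]
        .agg(["mean", "sem"])
        .reset_index()
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    subs = ["left_lateral", "lower_medial", "right_lateral"]
    for ci, cond in enumerate(["standard", "dnn"]):
        sel = means[means["condition"] == cond].set_index("subregion").reindex(subs)
        x = np.arange(len(subs)) + (ci - 0.5) * 0.15
        ax.errorbar(x, sel["mean"], yerr=sel["sem"], fmt="o", capsize=4, label=cond)
    ax.set_xticks(range(len(subs)), subs)
    ax.set_ylabel("HbDiff (µM)")
    ax.legend(title="program")
    ax.set_title("Estimated marginal mean HbDiff")
    fig.tight_layout()
    p = outdir / "marginal_means.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(str(p))
    return made


def run_all(
    config: RunConfig,
    truth: GroundTruth | None = None,
    noise: NoiseParams | None = None,
) -> dict:
    """Run the full seeded demo study and write the report bundle.

    Emits trial_table.csv, qc.json, behavioural_tests.csv, mlm_results.json,
    simple_slopes.csv and figures under ``config.outdir``; a stage failure
    aborts with the stage name while retaining partial artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "stages": {}}
    stage = "simulate+preprocess"
    try:
        t0 = time.perf_counter()
        trial_table, qcs, truth_used = simulate_cohort(config, truth, noise)
        trial_table.to_csv(outdir / "trial_table.csv", index=False)
        with open(outdir / "qc.json", "w") as fh:
            json.dump([q.to_dict() for q in qcs], fh, indent=2)
        report["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "behavioural_stats"
        t0 = time.perf_counter()
        beh = behavioural_tables(trial_table)
        rows = [
            beh["effort"].summary_row("standard", "dnn") | {"measure": "effort"},
            beh["accuracy_rau"].summary_row("standard", "dnn") | {"measure": "accuracy_rau"},
        ]
        pd.DataFrame(rows).to_csv(outdir / "behavioural_tests.csv", index=False)
        report["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "multilevel_models"
        t0 = time.perf_counter()
        hierarchy = mlm.nested_hierarchy(trial_table)
        slopes = mlm.simple_slopes(hierarchy["results"]["interaction"])
        slopes.to_csv(outdir / "simple_slopes.csv", index=False)
        bb = mlm.brain_behaviour_model(trial_table, correct_only=True)
        mlm_doc = {
            "models": {k: r.to_dict() for k, r in hierarchy["results"].items()},
            "comparisons": hierarchy["comparisons"],
            "brain_behaviour": {"slope": bb["slope"], "lrt": bb["lrt"]},
        }
        with open(outdir / "mlm_results.json", "w") as fh:
            json.dump(mlm_doc, fh, indent=2)
        (outdir / "mlm_summary.txt").write_text(
            "\n\n".join(r.summary() for r in hierarchy["results"].values())
        )
        report["stages"][stage] = round(time.perf_counter() - t0, 3)

        if config.make_figures:
            stage = "figures"
            t0 = time.perf_counter()
            report["figures"] = _figures(trial_table, None, outdir)
            report["stages"][stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report["n_trials"] = int(len(trial_table))
    report["programmed_effect_um"] = truth_used.condition_effect_um()
    report["recovered_left_lateral_effect_um"] = float(
        mlm.simple_slopes(hierarchy["results"]["interaction"])
        .set_index("subregion")
        .loc["left_lateral", "estimate"]
    )
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return {
        "trial_table": trial_table,
        "qc": qcs,
        "behaviour": beh,
        "hierarchy": hierarchy,
        "simple_slopes": slopes,
        "brain_behaviour": bb,
        "report": report,
    }
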