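"""End-to-end orchestration: simulate -> detect -> score -> stats.

Two canned experiments mirror the study design:

* Experiment 1 — a cohort of witness/demonstrator pairs is simulated,
  freezing is scored on the 6-bin schedule, witness and demonstrator
  split-plot ANOVAs and planned comparisons are run, and pair-level call
  counts are related to freezing (proportion of pairs emitting, Pearson
  correlations).

* Experiment 2 — playback: USV and pitch-shifted control stimuli are built
  from a simulated recording, and freezing of the four playback groups is
  analyzed on the 2-bin (before/during sound) schedule.

Reports are JSON with CSV side-tables; every report embeds the config hash
and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import stats_engine as se
from .audio_io import write_wav
from .stimulus_builder import StimulusSpec, build_stimuli, envelope_events, rms_envelope
from .synthetic_data import (
    AudioSimSpec,
    BehaviorSimSpec,
    simulate_audio,
    simulate_cohort,
)

log = logging.getLogger(__name__)

WITNESS_GROUPS = ("NcW", "EcW", "NsW", "EsW")
DEMO_GROUPS = ("D(NsW)", "D(EsW)")
PLAYBACK_GROUPS = (
    "Naive-Control", "Naive-USV", "Experienced-Control", "Experienced-USV",
)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "runs"
    n_per_group: int = 12
    usv_coupling_rho: float = 0.6
    audio: dict[str, Any] = Field(default_factory=dict)
    stimulus: dict[str, Any] = Field(default_factory=dict)
    playback_targets: dict[str, Any] | None = None

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _period_table(freezing: pd.DataFrame, groups: Sequence[str]) -> se.CohortTable:
    """Collapse 6 bins to the before/shock 2-period table for given groups."""
    sub = freezing[freezing["group"].isin(groups)]
    rows = []
    for animal, grp in sub.groupby("animal_id", sort=False):
        g = grp["group"].iloc[0]
        before = float(grp.loc[grp["bin"] == "before_shock", "value"].iloc[0])
        shock = float(grp.loc[grp["bin"] != "before_shock", "value"].mean())
        rows.append({"animal_id": animal, "group": g, "bin": "before", "value": before})
        rows.append({"animal_id": animal, "group": g, "bin": "shock", "value": shock})
    return se.CohortTable(pd.DataFrame(rows))


def _anova_dict(res: se.AnovaResult) -> dict[str, Any]:
    return {
        name: {"SS": e.ss, "df": e.df, "MS": e.ms, "F": e.f, "p": e.p}
        for name, e in {**res.effects,
                        "subjects_within_group": res.error_between,
                        "residual_within": res.error_within}.items()
    }


def _test_dict(t: se.TestResult) -> dict[str, Any]:
    return {
        "statistic": t.statistic, "df": t.df, "p_raw": t.p_raw,
        "p_adjusted": t.p_adjusted, "method": t.method, "degenerate": t.degenerate,
    }


def run_experiment1(config: RunConfig) -> dict[str, Any]:
    """Simulated witness/demonstrator experiment with full statistics."""
    log.info("experiment 1: simulating cohort (seed=%d)", config.seed)
    spec = BehaviorSimSpec(
        n_per_group=config.n_per_group, usv_coupling_rho=config.usv_coupling_rho
    )
    freezing, bouts, usv, truth = simulate_cohort(spec, config.seed)

    log.info("experiment 1: witness and demonstrator ANOVAs")
    witness_tbl = _period_table(freezing, WITNESS_GROUPS)
    witness_anova = se.mixed_anova(witness_tbl)
    demo_tbl = _period_table(freezing, DEMO_GROUPS)
    demo_anova = se.mixed_anova(demo_tbl)

    # planned comparisons: EsW vs each other witness group in the shock period
    wide = witness_tbl.data.pivot(index="animal_id", columns="bin", values="value")
    grp_of = witness_tbl.data.groupby("animal_id")["group"].first()
    shock_by_group = {
        g: wide.loc[grp_of[grp_of == g].index, "shock"].to_numpy()
        for g in WITNESS_GROUPS
    }
    planned = {}
    raw_p = []
    for other in ("NcW", "EcW", "NsW"):
        t = se.t_test(shock_by_group["EsW"], shock_by_group[other])
        planned[f"EsW_vs_{other}"] = t
        raw_p.append(t.p_raw)
    for name, p_adj in zip(planned, se.bonferroni(raw_p, m=len(raw_p))):
        planned[name].p_adjusted = float(p_adj)

    log.info("experiment 1: call-count analyses")
    usv_report: dict[str, Any] = {}
    if len(usv):
        counts_by_group = {
            g: usv.loc[usv["group"] == g, "usv_count"].to_numpy()
            for g in ("NsW", "EsW")
        }
        percents, emit_test = se.pairs_emitting_usv(counts_by_group)
        r_demo = se.pearson_r(
            usv["usv_count"], usv["demonstrator_shock_freezing"]
        )
        # witness shock-period freezing of the paired witness groups
        wit_shock = []
        for _, row in usv.iterrows():
            wit_grp, idx = row["pair_id"].removeprefix("pair_").rsplit("_", 1)
            wit_animal = f"{wit_grp}_{idx}"
            vals = freezing[(freezing["animal_id"] == wit_animal)
                            & (freezing["bin"] != "before_shock")]["value"]
            wit_shock.append(float(vals.mean()))
        r_wit = se.pearson_r(usv["usv_count"], wit_shock)
        usv_report = {
            "percent_pairs_emitting": percents,
            "emit_comparison": _test_dict(emit_test),
            "correlation_with_demonstrator_freezing": _test_dict(r_demo),
            "correlation_with_witness_freezing": _test_dict(r_wit),
        }

    group_bin = (
        freezing.groupby(["group", "bin"])["value"].mean().unstack()
    )
    report = {
        "experiment": "exp1",
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "group_bin_mean_freezing": group_bin.round(6).to_dict(),
        "witness_anova": _anova_dict(witness_anova),
        "demonstrator_anova": _anova_dict(demo_anova),
        "planned_comparisons": {k: _test_dict(v) for k, v in planned.items()},
        "usv": usv_report,
        "true_coupling_rho": truth.coupling_rho,
    }
    return report


def run_experiment2(config: RunConfig) -> dict[str, Any]:
    """Simulated playback experiment: stimuli plus the 4x2 split-plot ANOVA."""
    log.info("experiment 2: building stimuli (seed=%d)", config.seed)
    audio_spec = AudioSimSpec(**{"duration": 20.0, "n_calls": 8, **config.audio})
    recording, _ = simulate_audio(audio_spec, config.seed)
    stim_spec = StimulusSpec(**config.stimulus)
    usv_track, control_track = build_stimuli(recording, stim_spec)

    env_u = rms_envelope(usv_track)
    env_c = rms_envelope(control_track)
    report_stim = {
        "duration_usv_s": usv_track.duration,
        "duration_control_s": control_track.duration,
        "envelope_events_usv": len(envelope_events(env_u)),
        "envelope_events_control": len(envelope_events(env_c)),
    }

    log.info("experiment 2: playback cohort and ANOVA")
    targets = config.playback_targets or {
        # time effect (freezing rises during any sound), no group effect —
        # the structure the playback experiment reported
        g: {"mean": [5.0, 12.0], "sem": [2.0, 3.0]} for g in PLAYBACK_GROUPS
    }
    spec = BehaviorSimSpec(
        freezing_targets=targets, n_per_group=config.n_per_group,
        usv_coupling_rho=0.0, usv_count_params={},
    )
    from .behavior_scoring import BinSchedule, SessionSchedule, sound_test_bins

    sched = SessionSchedule(
        session_type="sound_test", baseline_duration=600.0, event_onsets=[600.0],
        total_duration=1500.0,
    )
    bins = sound_test_bins(sched)
    freezing, _, _, _ = simulate_cohort(spec, config.seed + 1, bins=bins)
    anova = se.mixed_anova(se.CohortTable(freezing))

    return {
        "experiment": "exp2",
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "groups": list(targets),
        "stimuli": report_stim,
        "playback_anova": _anova_dict(anova),
    }


def write_report(report: Mapping[str, Any], outdir: str | Path) -> Path:
    """Serialize a report to ``<outdir>/report_<experiment>.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"report_{report['experiment']}.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
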