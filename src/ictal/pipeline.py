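"""Per-session analysis and cohort-level orchestration.

``analyze_session`` runs every analysis the session's signals support
(spectral, behavior, MUA, photometry) and returns one tidy result object;
``run_pipeline`` maps it over a cohort, aggregates per-seizure and
per-event tables, runs the group statistics (period ANOVA families,
spared-vs-impaired and hit-vs-miss Mann-Whitney contrasts, phase
contrasts), and optionally writes CSVs plus a JSON summary.  The sample
unit is the seizure for period and seizure-type contrasts and the sound
event for hit/miss and phase contrasts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import mua as muamod
from . import photometry as phot
from . import spectral
from .session import EpochSet, ExcludedSeizure, Session, load_session, slice_signal
from .stats import GroupComparison, anova_with_bonferroni, comparisons_frame, mann_whitney_u

__all__ = ["SessionResult", "analyze_session", "run_pipeline", "PipelineReport"]

log = logging.getLogger(__name__)


@dataclass
class SessionResult:
    session_id: str
    epochs: EpochSet
    is_sham: bool
    seizure_class: str
    band_db: pd.DataFrame  # signal, band, period, mean_db, n_windows
    responses: pd.DataFrame  # per sound
    behavior_summary: dict
    event_delta: pd.DataFrame | None = None  # per analyzable sound: delta_db
    mua_period_pct: dict | None = None
    mua_correlation: dict | None = None
    photo_state: dict | None = None
    photo_events: pd.DataFrame | None = None
    exclusions: list[str] = field(default_factory=list)


def _spectral_block(session: Session, epochs: EpochSet) -> tuple[pd.DataFrame, dict]:
    """Baseline-normalized band summaries for every LFP channel present."""
    rows = []
    baselines: dict[str, tuple] = {}
    stim_iv = (session.annotation.stim_on_s, session.annotation.stim_off_s)
    for name in ("ofc_lfp", "hc_ipsi", "hc_contra"):
        if name not in session.signals:
            continue
        sig = session.signals[name]
        if name == "ofc_lfp":
            sig = spectral.remove_stim_artifact(sig, session.annotation.stim_off_s)
        else:
            sig = spectral.remove_dc(sig, 0.1)
        tf = spectral.compute_spectrogram(sig)
        ntf = spectral.normalize_to_baseline(tf, epochs.baseline)
        baselines[name] = (sig, ntf.baseline_mean_psd)
        summaries = spectral.band_period_summary(ntf, epochs, mask_intervals=[stim_iv])
        for band, summ in summaries.items():
            for period, db in summ.period_db.items():
                rows.append(
                    {
                        "session_id": session.session_id,
                        "signal": name,
                        "band": band,
                        "period": period,
                        "mean_db": db,
                        "n_windows": summ.period_n_windows[period],
                    }
                )
    return pd.DataFrame(rows), baselines


def _behavior_block(session: Session, epochs: EpochSet) -> tuple[pd.DataFrame, dict, str]:
    sounds = session.events["sound"].times_s
    licks = session.events["lick"].times_s
    keep = beh.select_analyzable_sounds(sounds)
    records = []
    for s, ok in zip(sounds, keep):
        records.append(
            beh.classify_response(licks, s, epoch=epochs.label_for(float(s)), analyzable=bool(ok))
        )
    responses = pd.DataFrame(
        [
            {
                "session_id": session.session_id,
                "sound_time_s": r.sound_time_s,
                "epoch": r.epoch,
                "analyzable": r.analyzable,
                "label": r.label,
                "delay_s": r.first_lick_delay_s,
                "pre_stim_rate_hz": r.pre_stim_lick_rate_hz,
            }
            for r in records
        ]
    )
    ictal = [r for r in records if r.epoch == "ictal" and r.analyzable]
    seizure_class = beh.classify_seizure(ictal)

    summary: dict = {"session_id": session.session_id, "seizure_class": seizure_class}
    for period, _ in epochs.items():
        period_records = [r for r in records if r.epoch == period and r.analyzable]
        if not period_records:
            continue
        tc = beh.lick_rate_timecourse(licks, [r.sound_time_s for r in period_records])
        max_rate, mean_delay = beh.response_metrics(tc, period_records)
        summary[f"max_lick_rate_{period}"] = max_rate
        summary[f"mean_delay_{period}"] = mean_delay
        summary[f"pre_stim_rate_{period}"] = float(
            np.mean([r.pre_stim_lick_rate_hz for r in period_records])
        )

    if "wheel_deg" in session.signals:
        circ = float(session.meta.get("wheel_circumference_cm", 50.0))
        ws = beh.wheel_speed(session.signals["wheel_deg"], circ, epochs)
        summary["running_eligible"] = ws.running_eligible
        for period, v in ws.period_speed_cm_s.items():
            summary[f"wheel_speed_{period}"] = v
    return responses, summary, seizure_class


def _mua_block(session: Session, epochs: EpochSet) -> tuple[dict, dict | None]:
    sig = muamod.mua_highpass(session.signals["mua"])
    vrms = muamod.compute_vrms(sig)
    _, _, period_pct = muamod.vrms_percent_change(vrms, epochs, session.annotation)
    corr = None
    if (
        "ofc_lfp" in session.signals
        and "hc_ipsi" in session.signals
        and epochs.ictal_duration_s >= 2.0
    ):
        res = muamod.updown_correlation(
            session.signals["mua"],
            session.signals["ofc_lfp"],
            session.signals["hc_ipsi"],
            epochs.ictal,
        )
        corr = {"r_mua_ofc": res.r_mua_ofc, "r_mua_hc": res.r_mua_hc, "n": res.n_samples}
    return period_pct, corr


def _photometry_block(
    session: Session, epochs: EpochSet, responses: pd.DataFrame
) -> tuple[dict, pd.DataFrame]:
    f470 = session.signals["photo_470"]
    f405 = session.signals["photo_405"]
    window = phot.analysis_window(epochs)
    window = (max(window[0], f470.t0_s), min(window[1], f470.end_s))
    corrected = phot.isosbestic_correct(f470, f405, window)
    z = phot.zscore_recording(corrected.dff)
    state = phot.seizure_related_change(z, corrected.times_s, epochs)
    state_dict = {
        "session_id": session.session_id,
        "flagged": state.flagged,
        "baseline_mean_z": state.baseline_mean_z,
        **{f"change_{k}": v for k, v in state.period_change.items()},
        **{f"mean_z_{k}": v for k, v in state.period_mean_z.items()},
    }

    dff_sig = corrected.as_signal()
    rows = []
    for _, r in responses[responses["analyzable"]].iterrows():
        ev = phot.event_related_change(dff_sig, float(r["sound_time_s"]))
        if ev is None:
            continue
        rows.append(
            {
                "session_id": session.session_id,
                "sound_time_s": r["sound_time_s"],
                "epoch": r["epoch"],
                "label": r["label"],
                **ev.phase_means,
            }
        )
    return state_dict, pd.DataFrame(rows)


def analyze_session(session: Session, event_spectra: bool = True) -> SessionResult:
    """Run all analyses the session's signals support."""
    epochs = session.epochs()
    result_kwargs: dict = {}
    band_db, baselines = (
        _spectral_block(session, epochs)
        if any(n in session.signals for n in ("ofc_lfp", "hc_ipsi", "hc_contra"))
        else (pd.DataFrame(), {})
    )
    responses, summary, seizure_class = _behavior_block(session, epochs)

    if event_spectra and "ofc_lfp" in baselines:
        sig, base_psd = baselines["ofc_lfp"]
        analyzable = responses[responses["analyzable"]]
        if len(analyzable):
            spectra, dropped = spectral.event_aligned_spectrum(
                sig, analyzable["sound_time_s"].to_numpy(), base_psd
            )
            by_time = {s.event_time_s: s.delta_db for s in spectra}
            ev = analyzable.copy()
            ev["delta_db"] = [by_time.get(float(t), np.nan) for t in ev["sound_time_s"]]
            result_kwargs["event_delta"] = ev.dropna(subset=["delta_db"])

    if "mua" in session.signals:
        period_pct, corr = _mua_block(session, epochs)
        result_kwargs["mua_period_pct"] = period_pct
        result_kwargs["mua_correlation"] = corr

    if "photo_470" in session.signals and "photo_405" in session.signals:
        state, events = _photometry_block(session, epochs, responses)
        result_kwargs["photo_state"] = state
        result_kwargs["photo_events"] = events

    return SessionResult(
        session_id=session.session_id,
        epochs=epochs,
        is_sham=session.annotation.is_sham,
        seizure_class=seizure_class,
        band_db=band_db,
        responses=responses,
        behavior_summary=summary,
        **result_kwargs,
    )


@dataclass
class PipelineReport:
    tables: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    summary: dict
    exclusions: list[str]


def _period_family(
    values: pd.DataFrame, value_col: str, metric: str
) -> list[GroupComparison]:
    groups = {
        period: values.loc[values["period"] == period, value_col].dropna().to_numpy()
        for period in spectral.PERIODS
    }
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if "baseline" not in groups or len(groups) < 2:
        return []
    return anova_with_bonferroni(groups, metric=metric)


def run_pipeline(
    sessions, out_dir: str | Path | None = None, event_spectra: bool = True
) -> PipelineReport:
    """Analyze a cohort of sessions (Session objects or bundle paths).

    Aggregates per-seizure period tables, seizure-type and hit/miss
    contrasts, and photometry phase contrasts; logs excluded sessions
    (e.g. seizures under 5 s) instead of failing the cohort.
    """
    results: list[SessionResult] = []
    exclusions: list[str] = []
    for item in sessions:
        session = item if isinstance(item, Session) else load_session(item)
        try:
            results.append(analyze_session(session, event_spectra=event_spectra))
        except ExcludedSeizure as exc:
            exclusions.append(f"{session.session_id}: {exc}")
            log.warning("excluded %s: %s", session.session_id, exc)
    if not results:
        raise ValueError("no valid sessions")

    tables: dict[str, pd.DataFrame] = {}
    tables["band_power"] = pd.concat([r.band_db for r in results], ignore_index=True)
    tables["responses"] = pd.concat([r.responses for r in results], ignore_index=True)
    tables["behavior_summary"] = pd.DataFrame([r.behavior_summary for r in results])
    tables["behavior_summary"]["is_sham"] = [r.is_sham for r in results]

    ev_frames = [r.event_delta for r in results if r.event_delta is not None]
    if ev_frames:
        tables["event_delta"] = pd.concat(ev_frames, ignore_index=True)
    mua_rows = [
        {"session_id": r.session_id, **{f"pct_{k}": v for k, v in r.mua_period_pct.items()},
         **(r.mua_correlation or {})}
        for r in results
        if r.mua_period_pct is not None
    ]
    if mua_rows:
        tables["mua"] = pd.DataFrame(mua_rows)
    photo_rows = [r.photo_state for r in results if r.photo_state is not None]
    if photo_rows:
        tables["photometry_state"] = pd.DataFrame(photo_rows)
    photo_ev = [r.photo_events for r in results if r.photo_events is not None]
    if photo_ev:
        tables["photometry_events"] = pd.concat(photo_ev, ignore_index=True)

    comparisons: list[GroupComparison] = []

    # period families (sample unit: seizure)
    bp = tables["band_power"]
    for (signal, band), sub in bp.groupby(["signal", "band"]):
        comparisons += _period_family(sub, "mean_db", metric=f"{signal}:{band}_db")
    if "mua" in tables:
        long = tables["mua"].melt(
            id_vars="session_id",
            value_vars=[c for c in tables["mua"] if c.startswith("pct_")],
            var_name="period", value_name="pct",
        )
        long["period"] = long["period"].str.removeprefix("pct_")
        comparisons += _period_family(long, "pct", metric="mua:vrms_pct_change")
    if "photometry_state" in tables:
        ps = tables["photometry_state"]
        ok = ps[~ps["flagged"]]
        long = ok.melt(
            id_vars="session_id",
            value_vars=[c for c in ok if c.startswith("change_")],
            var_name="period", value_name="change",
        )
        long["period"] = long["period"].str.removeprefix("change_")
        comparisons += _period_family(long, "change", metric="ach:seizure_related_change")

    # seizure-type contrasts (spared vs impaired; mixed excluded)
    classes = {r.session_id: r.seizure_class for r in results}
    summary: dict = {
        "n_sessions": len(results),
        "n_excluded": len(exclusions),
        "seizure_class_counts": pd.Series(list(classes.values()))
        .value_counts()
        .to_dict(),
    }

    def class_values(frame: pd.DataFrame, col: str, query) -> dict[str, np.ndarray]:
        sub = query(frame)
        out = {}
        for cls in ("spared", "impaired"):
            ids = [sid for sid, c in classes.items() if c == cls]
            out[cls] = sub.loc[sub["session_id"].isin(ids), col].dropna().to_numpy()
        return out

    vals = class_values(
        bp, "mean_db",
        lambda f: f[(f["signal"] == "ofc_lfp") & (f["band"] == "delta") & (f["period"] == "ictal")],
    )
    if vals["spared"].size and vals["impaired"].size:
        res = mann_whitney_u(vals["spared"], vals["impaired"])
        comparisons.append(
            GroupComparison(
                metric="ofc_lfp:delta_db_ictal", grouping="spared-vs-impaired",
                groups=("spared", "impaired"),
                n=(vals["spared"].size, vals["impaired"].size),
                mean=(float(vals["spared"].mean()), float(vals["impaired"].mean())),
                sem=(
                    float(np.std(vals["spared"], ddof=1) / np.sqrt(vals["spared"].size))
                    if vals["spared"].size > 1 else float("nan"),
                    float(np.std(vals["impaired"], ddof=1) / np.sqrt(vals["impaired"].size))
                    if vals["impaired"].size > 1 else float("nan"),
                ),
                test=f"Mann-Whitney U ({res.method})",
                statistic=res.u, p_raw=res.p, p_corrected=res.p,
            )
        )
    if "photometry_state" in tables:
        ps = tables["photometry_state"]
        vals = class_values(
            ps[~ps["flagged"]], "change_ictal", lambda f: f
        )
        if vals["spared"].size and vals["impaired"].size:
            res = mann_whitney_u(vals["spared"], vals["impaired"])
            comparisons.append(
                GroupComparison(
                    metric="ach:change_ictal", grouping="spared-vs-impaired",
                    groups=("spared", "impaired"),
                    n=(vals["spared"].size, vals["impaired"].size),
                    mean=(float(vals["spared"].mean()), float(vals["impaired"].mean())),
                    sem=(float("nan"), float("nan")),
                    test=f"Mann-Whitney U ({res.method})",
                    statistic=res.u, p_raw=res.p, p_corrected=res.p,
                )
            )

    # hit-vs-miss event contrast on ictal event-aligned delta power
    if "event_delta" in tables:
        ev = tables["event_delta"]
        ict = ev[ev["epoch"] == "ictal"]
        hits = ict.loc[ict["label"] == "hit", "delta_db"].to_numpy()
        misses = ict.loc[ict["label"] == "miss", "delta_db"].to_numpy()
        if hits.size and misses.size:
            res = mann_whitney_u(hits, misses)
            comparisons.append(
                GroupComparison(
                    metric="ofc_lfp:event_delta_db_ictal", grouping="hit-vs-miss",
                    groups=("hit", "miss"), n=(hits.size, misses.size),
                    mean=(float(hits.mean()), float(misses.mean())),
                    sem=(
                        float(np.std(hits, ddof=1) / np.sqrt(hits.size)) if hits.size > 1
                        else float("nan"),
                        float(np.std(misses, ddof=1) / np.sqrt(misses.size)) if misses.size > 1
                        else float("nan"),
                    ),
                    test=f"Mann-Whitney U ({res.method})",
                    statistic=res.u, p_raw=res.p, p_corrected=res.p,
                )
            )

    comp_frame = comparisons_frame(comparisons) if comparisons else pd.DataFrame()
    report = PipelineReport(
        tables=tables, comparisons=comp_frame, summary=summary, exclusions=exclusions
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        comp_frame.to_csv(out / "stats.csv", index=False)
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True, default=str)
            f.write("\n")
        with open(out / "run.log", "w") as f:
            f.write("\n".join(exclusions) + ("\n" if exclusions else ""))
    return report
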