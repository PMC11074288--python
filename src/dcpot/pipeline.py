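"""Cohort-level orchestration: simulate → epoch → metrics → stats → report.

``run_full_experiment`` simulates a whole cohort over the 11-session
schedule and runs every analysis stage; ``analyze_dataset`` applies the
identical stage chain to recordings and event tables on disk. Both return a
:class:`ReportBundle` of long-format tables plus the inferential layer, and
both are deterministic given the simulation seed.

Quality control mirrors the exclusion of animals with unstable potentials:
a subject is excluded when the standard deviation of its session averages
within the pre-stimulus baseline window exceeds a configurable multiple
(default 3x) of the cohort median.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dc
from .aep import detect_aep_components
from .epochs import (
    DEFAULT_P2P_THRESHOLD_UV,
    DEFAULT_WINDOW_MS,
    AverageWaveform,
    average_epochs,
    baseline_correct,
    extract_epochs,
    reject_epochs,
)
from .io import (
    EventTable,
    Recording,
    SESSION_DAYS,
    read_events,
    read_recording,
    write_events,
    write_recording,
)
from .simulate import SimConfig, simulate_session
from .stats import (
    MissingCellError,
    power_rm_anova,
    logbf_rm_anova,
    rm_anova_two_way,
    tukey_hsd,
)

__all__ = [
    "AnalysisConfig",
    "QCRule",
    "ReportBundle",
    "PipelineError",
    "run_full_experiment",
    "analyze_dataset",
    "analyze_recordings",
    "simulate_to_dir",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class QCRule:
    """Subject exclusion for unstable potentials.

    A subject is excluded when (i) the baseline-window SD of its session
    averages exceeds ``baseline_sd_factor`` times the cohort median, or
    (ii) artifact screening rejects *every* trial of some (session, tone)
    stratum — the signature of a recording too noisy to average at all.
    """

    baseline_sd_factor: float = 3.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the analysis stages (independent of simulation)."""

    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
    p2p_threshold_uv: float = DEFAULT_P2P_THRESHOLD_UV
    amp_window_ms: tuple[float, float] = (600.0, 1000.0)
    epsilon_uv: float = 1.0
    flat_threshold_uv: float = 10.0
    retain_fraction: float = 0.7
    qc: QCRule = field(default_factory=QCRule)


@dataclass
class ReportBundle:
    """Every table the analysis produces, plus provenance.

    ``metrics`` is the long-format master table (subject, session, tone,
    channel, metric_name, value, units); every statistical result is keyed
    by a short, self-describing name.
    """

    metrics: pd.DataFrame
    area_differences: pd.DataFrame
    relative_dc: pd.DataFrame
    rejection_summary: pd.DataFrame
    qc_table: pd.DataFrame
    stats: dict
    provenance: dict

    @property
    def included_subjects(self) -> list[str]:
        return sorted(self.qc_table.loc[~self.qc_table["excluded"], "subject"])

    @property
    def excluded_subjects(self) -> list[str]:
        return sorted(self.qc_table.loc[self.qc_table["excluded"], "subject"])

    def metric(
        self,
        metric_name: str,
        subjects: list[str] | None = None,
        **filters: str,
    ) -> pd.DataFrame:
        t = self.metrics[self.metrics["metric_name"] == metric_name]
        if subjects is not None:
            t = t[t["subject"].isin(subjects)]
        for col, val in filters.items():
            t = t[t[col] == val]
        return t.reset_index(drop=True)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in (
            ("metrics", self.metrics),
            ("area_differences", self.area_differences),
            ("relative_dc", self.relative_dc),
            ("rejection_summary", self.rejection_summary),
            ("qc", self.qc_table),
        ):
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / "stats.json", "w") as f:
            json.dump(_jsonable(self.stats), f, indent=2, sort_keys=True)
        with open(outdir / "provenance.json", "w") as f:
            json.dump(_jsonable(self.provenance), f, indent=2, sort_keys=True)
        return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# Per-session analysis
# ---------------------------------------------------------------------------

def _analyze_one_session(
    recording: Recording,
    events: EventTable,
    analysis: AnalysisConfig,
) -> tuple[list[dict], list[dict], dict, list[AverageWaveform], list[dict]]:
    """Metrics rows, area rows, rejection row, corrected averages and QC rows
    for one subject-session."""
    subject, session = recording.subject_id, recording.session_id
    epochs = extract_epochs(recording, events, analysis.window_ms)
    epochs, report = reject_epochs(epochs, analysis.p2p_threshold_uv)
    counts = epochs.counts()
    rejection_row = {
        "subject": subject,
        "session": session,
        "rejection_rate": report.rejection_rate,
        **counts,
    }

    tones_extracted = sorted(set(epochs.labels))
    tones_present = sorted(set(epochs.labels[epochs.accepted_mask]))
    averages: dict[str, dict[str, AverageWaveform]] = {}
    qc_rows: list[dict] = []
    for tone in sorted(set(tones_extracted) - set(tones_present)):
        qc_rows.append(
            {
                "subject": subject,
                "session": session,
                "tone": tone,
                "channel": "*",
                "baseline_sd_uv": float("nan"),
                "stratum_lost": True,
            }
        )
    for tone in tones_present:
        raw = average_epochs(epochs, tone)
        corrected = {}
        for ch, avg in raw.items():
            base = avg.window_slice(analysis.window_ms[0], 0.0)
            qc_rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "tone": tone,
                    "channel": ch,
                    "baseline_sd_uv": float(base.std()),
                    "stratum_lost": False,
                }
            )
            corrected[ch] = baseline_correct(avg)
        averages[tone] = corrected

    metric_rows: list[dict] = []
    for tone, per_channel in averages.items():
        for ch, avg in per_channel.items():
            def row(name: str, value: float, units: str) -> dict:
                return {
                    "subject": subject,
                    "session": session,
                    "tone": tone,
                    "channel": ch,
                    "metric_name": name,
                    "value": value,
                    "units": units,
                }

            metric_rows.append(
                row("mean_amp", dc.mean_dc_amplitude(avg, analysis.amp_window_ms), "uV")
            )
            a36, a610 = dc.windowed_dc_areas(avg)
            metric_rows.append(row("area_300_600", a36, "uV*ms"))
            metric_rows.append(row("area_600_1000", a610, "uV*ms"))
            r600, r1000 = dc.dc_ratios(avg, epsilon_uv=analysis.epsilon_uv)
            metric_rows.append(row("ratio_600", r600, ""))
            metric_rows.append(row("ratio_1000", r1000, ""))
            profile = dc.classify_profile(
                avg,
                flat_threshold_uv=analysis.flat_threshold_uv,
                retain_fraction=analysis.retain_fraction,
            )
            metric_rows.append(
                row("profile", {"flat": 0.0, "reduced": 1.0, "sustained": 2.0}[profile], "")
            )
            comps = detect_aep_components(avg)
            for name, value in comps.as_metric_rows().items():
                units = "s" if name.endswith("lat") else "uV"
                metric_rows.append(row(name, value, units))

    area_rows: list[dict] = []
    if {"rewarded", "unrewarded"} <= set(averages):
        for ch in epochs.channels:
            area_rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "channel": ch,
                    "integrated_area_uv_ms": dc.integrated_area_difference(
                        averages["rewarded"][ch], averages["unrewarded"][ch]
                    ),
                }
            )
    else:
        logger.warning(
            "subject %s session %s has a single tone; difference-based "
            "metrics skipped",
            subject,
            session,
        )

    flat_averages = [avg for per in averages.values() for avg in per.values()]
    return metric_rows, area_rows, rejection_row, flat_averages, qc_rows


def _qc_exclusions(qc_rows: list[dict], rule: QCRule) -> pd.DataFrame:
    qc = pd.DataFrame(qc_rows)
    per_subject = qc.groupby("subject").agg(
        baseline_sd_uv=("baseline_sd_uv", "mean"),
        strata_lost=("stratum_lost", "sum"),
    )
    cohort_median = float(per_subject["baseline_sd_uv"].median())
    threshold = rule.baseline_sd_factor * cohort_median
    out = per_subject.reset_index()
    too_noisy = out["baseline_sd_uv"] > threshold
    lost = out["strata_lost"] > 0
    out["excluded"] = too_noisy | lost
    reasons = []
    for noisy_flag, lost_flag in zip(too_noisy, lost):
        parts = []
        if noisy_flag:
            parts.append(
                f"baseline SD exceeds {rule.baseline_sd_factor:g}x cohort "
                f"median ({threshold:.2f} uV)"
            )
        if lost_flag:
            parts.append("entire (session, tone) stratum rejected as artifact")
        reasons.append("; ".join(parts))
    out["reason"] = reasons
    for subject in out.loc[out["excluded"], "subject"]:
        logger.warning("QC: subject %s excluded (unstable potentials)", subject)
    return out


def _stats_layer(
    metrics: pd.DataFrame, included: list[str], sessions: list[str]
) -> dict:
    """Inferential layer on the frontal mean-amplitude metric."""
    out: dict = {}
    amp = metrics[
        (metrics["metric_name"] == "mean_amp")
        & (metrics["channel"] == "frontal")
        & (metrics["subject"].isin(included))
    ].rename(columns={"tone": "condition"})

    cond_days = [s for s in sessions if s.startswith("conditioning")]
    if len(cond_days) >= 2 and len(included) >= 3:
        cond = amp[amp["session"].isin(cond_days)]
        try:
            aov = rm_anova_two_way(cond, "value", ("session", "condition"), "subject")
            out["conditioning_anova"] = aov
            out["conditioning_logbf"] = logbf_rm_anova(
                cond, "value", ("session", "condition"), "subject"
            )
        except MissingCellError as exc:
            out["conditioning_anova_error"] = str(exc)
        out["conditioning_tukey_by_day"] = {
            day: tukey_hsd(
                amp[amp["session"] == day], "value", "condition", "subject"
            )
            for day in cond_days
        }
    ext_days = [s for s in sessions if s.startswith("extinction")]
    if len(ext_days) >= 2 and len(included) >= 3:
        ext = amp[amp["session"].isin(ext_days)]
        try:
            out["extinction_anova"] = rm_anova_two_way(
                ext, "value", ("session", "condition"), "subject"
            )
        except MissingCellError as exc:
            out["extinction_anova_error"] = str(exc)
        out["extinction_tukey_by_day"] = {
            day: tukey_hsd(
                amp[amp["session"] == day], "value", "condition", "subject"
            )
            for day in ext_days
        }
    # A priori power at the conventional settings used for this design
    # (f = 0.3333 i.e. partial eta^2 = 0.1, alpha = .05, rho = .5, eps = 1).
    m = max(2, len(cond_days))
    out["a_priori_power"] = power_rm_anova(
        f=0.3333, alpha=0.05, rho=0.5, eps=1.0, m=m, target_power=0.8
    )
    return out


def _assemble(
    pairs: list[tuple[Recording, EventTable]],
    analysis: AnalysisConfig,
    provenance: dict,
) -> ReportBundle:
    metric_rows: list[dict] = []
    area_rows: list[dict] = []
    rejection_rows: list[dict] = []
    qc_rows: list[dict] = []
    averages: list[AverageWaveform] = []
    for recording, events in pairs:
        try:
            m, a, r, avgs, q = _analyze_one_session(recording, events, analysis)
        except Exception as exc:
            raise PipelineError(
                f"stage=epoch+metrics subject={recording.subject_id} "
                f"session={recording.session_id}: {exc}"
            ) from exc
        metric_rows += m
        area_rows += a
        rejection_rows.append(r)
        qc_rows += q
        averages += avgs

    metrics = pd.DataFrame(metric_rows).sort_values(
        ["subject", "session", "tone", "channel", "metric_name"]
    ).reset_index(drop=True)
    areas = (
        pd.DataFrame(area_rows, columns=["subject", "session", "channel", "integrated_area_uv_ms"])
        .sort_values(["subject", "session", "channel"])
        .reset_index(drop=True)
    )
    rejections = pd.DataFrame(rejection_rows)
    qc_table = _qc_exclusions(qc_rows, analysis.qc)
    included = sorted(qc_table.loc[~qc_table["excluded"], "subject"])
    sessions = sorted(
        metrics["session"].unique(), key=lambda s: SESSION_DAYS.index(s)
    )

    # Relative DC profiles per (session, channel), included subjects only.
    rel_tables = []
    channels = sorted(metrics["channel"].unique())
    for session in sessions:
        for ch in channels:
            waves = [
                w
                for w in averages
                if w.session_id == session
                and w.channel == ch
                and w.subject_id in included
            ]
            try:
                rel = dc.relative_dc_profile(waves)
            except (ValueError, KeyError):
                continue
            rel_tables.append(rel.table)
    relative = (
        pd.concat(rel_tables, ignore_index=True)
        if rel_tables
        else pd.DataFrame(
            columns=["subject", "session", "tone", "channel", "timepoint_ms", "relative_value"]
        )
    )

    try:
        stats = _stats_layer(metrics, included, sessions)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage=stats: {exc}") from exc

    return ReportBundle(
        metrics=metrics,
        area_differences=areas,
        relative_dc=relative,
        rejection_summary=rejections,
        qc_table=qc_table,
        stats=stats,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def _config_hash(config: SimConfig) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_full_experiment(
    config: SimConfig,
    sessions: list[str] | None = None,
    analysis: AnalysisConfig = AnalysisConfig(),
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Simulate the cohort over ``sessions`` (default: all 11) and analyze it."""
    sessions = list(sessions) if sessions is not None else list(SESSION_DAYS)
    unknown = [s for s in sessions if s not in SESSION_DAYS]
    if unknown:
        raise KeyError(f"unknown sessions {unknown}")
    pairs = []
    for subject in config.subject_ids():
        for session in sessions:
            try:
                recording, events, _log = simulate_session(config, session, subject)
            except Exception as exc:
                raise PipelineError(
                    f"stage=simulate subject={subject} session={session}: {exc}"
                ) from exc
            pairs.append((recording, events))
    provenance = {
        "mode": "simulated",
        "config_hash": _config_hash(config),
        "seed": config.rng_seed,
        "sessions": sessions,
        "n_subjects": config.n_subjects,
        "versions": _versions(),
    }
    bundle = _assemble(pairs, analysis, provenance)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def simulate_to_dir(
    config: SimConfig,
    outdir: str | Path,
    sessions: list[str] | None = None,
    container: str = "h5",
) -> Path:
    """Write the simulated cohort's recordings, events and artifact logs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions = list(sessions) if sessions is not None else list(SESSION_DAYS)
    for subject in config.subject_ids():
        for session in sessions:
            recording, events, log = simulate_session(config, session, subject)
            stem = f"sub-{subject}_ses-{session}"
            write_recording(recording, outdir / f"{stem}_recording.{container}")
            write_events(events, outdir / f"{stem}_events.tsv")
            log.to_csv(outdir / f"{stem}_artifacts.tsv", sep="\t", index=False)
    return outdir


def analyze_recordings(
    pairs: list[tuple[Recording, EventTable]],
    analysis: AnalysisConfig = AnalysisConfig(),
    provenance: dict | None = None,
) -> ReportBundle:
    """Run the analysis chain on in-memory recordings."""
    return _assemble(pairs, analysis, provenance or {"mode": "in-memory"})


def analyze_dataset(
    datadir: str | Path,
    analysis: AnalysisConfig = AnalysisConfig(),
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Load a directory written by :func:`simulate_to_dir` and analyze it."""
    datadir = Path(datadir)
    rec_paths = sorted(
        list(datadir.glob("*_recording.h5")) + list(datadir.glob("*_recording.edf"))
    )
    if not rec_paths:
        raise FileNotFoundError(f"no '*_recording.h5/.edf' files under {datadir}")
    pairs = []
    bad = []
    for rec_path in rec_paths:
        ev_path = rec_path.with_name(
            rec_path.name.replace("_recording", "_events").rsplit(".", 1)[0] + ".tsv"
        )
        if not ev_path.exists():
            bad.append(str(ev_path))
            continue
        pairs.append((read_recording(rec_path), read_events(ev_path)))
    if bad:
        raise PipelineError(f"stage=load: missing event files: {bad}")
    provenance = {"mode": "from-disk", "datadir": str(datadir), "versions": _versions()}
    bundle = _assemble(pairs, analysis, provenance)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _versions() -> dict[str, str]:
    import pingouin
    import scipy
    import statsmodels

    from . import __version__

    return {
        "dcpot": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "pingouin": pingouin.__version__,
    }
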