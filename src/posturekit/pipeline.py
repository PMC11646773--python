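"""Pipeline: ingest -> conditioning -> metrics -> scores -> statistics -> report.

Runs the full analysis chain in the prescribed order: mains-hum filter, then
Butterworth low-pass (force channels; markers get only the Butterworth
stage), COP computation, task metrics, the per-fit IQR outlier screen, the
H1 and H2 GLMMs with EMM-based post-hoc contrasts, and the partial Spearman
correlation — all deterministic under a fixed root seed, with every
paper-gap decision (filter order/phase, correction method, df convention)
echoed into the run report so runs are auditable.

File formats (plain text, one directory per trial):

* ``markers.tsv`` — tab-separated, header of ``<marker>_X/_Y/_Z`` columns in
  mm, one row per 200 Hz sample;
* ``plate_<k>.tsv`` — one file per plate, columns Fx Fy Fz Mx My Mz (N,
  N·m), one row per 1,000 Hz sample;
* ``meta.json`` — subject/time/task/side/trial keys and rates.

Decimal separator is a period by default; a comma dialect flag covers
European exports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pcorr as pcorr_mod
from .exceptions import IngestError, ParameterError, PipelineError
from .mixedstats import (
    COGNITIVE_VARIABLES,
    MOTOR_VARIABLES,
    SYMPTOM_VARIABLES,
    build_design,
    estimated_marginal_means,
    fit_glmm,
    posthoc_contrasts,
)
from .posturometrics import (
    balance_beam_error,
    compute_cop_single,
    detect_landing,
    one_leg_stand_error,
    precision_jump_error,
)
from .scores import iqr_outlier_filter
from .signals import FilterConfig, condition_markers, condition_plate
from .synthio import (
    CohortDesign,
    EffectSpec,
    SwayParams,
    outcomes_table,
    simulate_cohort,
    simulate_jump_trial,
    simulate_sway_trial,
)
from .types import ForcePlateRecord, TaskGeometry, TrialRecord

logger = logging.getLogger("posturekit")

__all__ = [
    "RunConfig",
    "RunReport",
    "write_trial_files",
    "read_trial_files",
    "simulate_to_dir",
    "process_raw_trials",
    "run_all",
]

_CSV_KW = dict(index=False, float_format="%.10g", lineterminator="\n")
_FORCE_COLS = ["Fx", "Fy", "Fz", "Mx", "My", "Mz"]


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    workdir: str = "."
    seed: int = 0
    simulate: bool = True
    n_raw_subjects: int = 1
    design: CohortDesign = field(default_factory=CohortDesign)
    effects: EffectSpec = field(default_factory=EffectSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    sway: SwayParams = field(default_factory=SwayParams)
    min_load: float = 10.0
    outlier_k: float = 1.5
    outlier_cap: float = 0.05
    hypotheses: tuple = ("H1", "H2")
    correction: str = "holm"
    df_convention: str = "residual"
    comma_decimal: bool = False
    figures: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.geometry).items()
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "design":
                kwargs[key] = CohortDesign(**value)
            elif key == "effects":
                kwargs[key] = EffectSpec(**value)
            elif key == "filters":
                kwargs[key] = FilterConfig(**value)
            elif key == "geometry":
                kwargs[key] = TaskGeometry(**value)
            elif key == "sway":
                kwargs[key] = SwayParams(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record counts, removed fractions, warnings and decisions."""

    seed: int
    config_hash: str
    counts: dict = field(default_factory=dict)
    removed_fractions: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    decisions: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_json(self, path):
        Path(path).write_text(
            json.dumps(asdict(self), sort_keys=True, indent=1, default=str) + "\n"
        )


# ---------------------------------------------------------------------------
# trial file I/O


def write_trial_files(trial: TrialRecord, directory, comma_decimal: bool = False):
    """Write one trial to ``directory`` in the documented TSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dec = "," if comma_decimal else "."

    def fmt(v: float) -> str:
        s = f"{v:.17g}"  # full double precision so trials round-trip exactly
        return s.replace(".", ",") if dec == "," else s

    if trial.markers:
        names = sorted(trial.markers)
        header = "\t".join(
            f"{m}_{ax}" for m in names for ax in ("X", "Y", "Z")
        )
        n = len(next(iter(trial.markers.values())))
        lines = [header]
        for i in range(n):
            lines.append(
                "\t".join(fmt(trial.markers[m][i, j]) for m in names for j in range(3))
            )
        (directory / "markers.tsv").write_text("\n".join(lines) + "\n")
    for k, plate in enumerate(trial.plates):
        lines = ["\t".join(_FORCE_COLS)]
        for i in range(plate.n_samples):
            lines.append(
                "\t".join(
                    fmt(getattr(plate, c.lower())[i]) for c in _FORCE_COLS
                )
            )
        (directory / f"plate_{k}.tsv").write_text("\n".join(lines) + "\n")
    meta = {
        "subject": trial.subject,
        "group": trial.group,
        "time": trial.time,
        "task": trial.task,
        "side": trial.side,
        "trial_index": trial.trial_index,
        "marker_rate": trial.marker_rate,
        "force_rate": trial.plates[0].rate if trial.plates else None,
        "comma_decimal": comma_decimal,
        "extra": {
            k: v for k, v in trial.meta.items() if isinstance(v, (int, float, str))
        },
    }
    (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def _read_tsv(path: Path, comma_decimal: bool) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            sep="\t",
            decimal="," if comma_decimal else ".",
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed rows reported with the file
        raise IngestError(f"{path}: cannot parse TSV ({exc})") from exc


def read_trial_files(directory, comma_decimal: bool | None = None) -> TrialRecord:
    """Read one trial directory back into a :class:`TrialRecord`."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise IngestError(f"{directory}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    if comma_decimal is None:
        comma_decimal = bool(meta.get("comma_decimal", False))
    markers = {}
    mpath = directory / "markers.tsv"
    if mpath.exists():
        df = _read_tsv(mpath, comma_decimal)
        bases = sorted({c.rsplit("_", 1)[0] for c in df.columns})
        for base in bases:
            cols = [f"{base}_{ax}" for ax in ("X", "Y", "Z")]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise IngestError(f"{mpath}: missing marker columns {missing}")
            markers[base] = df[cols].to_numpy(dtype=float)
    plates = []
    for ppath in sorted(directory.glob("plate_*.tsv")):
        df = _read_tsv(ppath, comma_decimal)
        missing = [c for c in _FORCE_COLS if c not in df.columns]
        if missing:
            raise IngestError(f"{ppath}: missing force column(s) {missing}")
        plates.append(
            ForcePlateRecord(
                fx=df["Fx"].to_numpy(float),
                fy=df["Fy"].to_numpy(float),
                fz=df["Fz"].to_numpy(float),
                mx=df["Mx"].to_numpy(float),
                my=df["My"].to_numpy(float),
                mz=df["Mz"].to_numpy(float),
                rate=float(meta.get("force_rate") or 1000.0),
                label=ppath.stem,
            )
        )
    return TrialRecord(
        subject=meta["subject"],
        group=meta.get("group", ""),
        time=meta["time"],
        task=meta["task"],
        side=meta.get("side", ""),
        trial_index=int(meta.get("trial_index", 0)),
        markers=markers,
        marker_rate=float(meta.get("marker_rate", 200.0)),
        plates=plates,
        meta=meta.get("extra", {}),
    )


# ---------------------------------------------------------------------------
# stages


def simulate_to_dir(cfg: RunConfig) -> dict:
    """Write the synthetic cohort tables and a few raw demo trials."""
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg.design, cfg.effects, seed=cfg.seed)
    cohort.subjects.to_csv(work / "subjects.csv", **_CSV_KW)
    cohort.motor.to_csv(work / "motor_trials.csv", **_CSV_KW)
    cohort.scores.to_csv(work / "scores.csv", **_CSV_KW)
    raw_root = work / "raw"
    n_raw = 0
    rng_seed = cfg.seed + 10_000
    sway = cfg.sway
    for i, subj in cohort.subjects.head(cfg.n_raw_subjects).iterrows():
        # quiet stance on one leg
        plate, _ = simulate_sway_trial(sway, center=(20.0, -10.0), seed=rng_seed + 3 * i)
        trial = TrialRecord(
            subject=subj.subject, group=subj.group, time="t1",
            task="one_leg_stand", side="left", trial_index=1,
            plates=[plate], meta={},
        )
        write_trial_files(trial, raw_root / f"{subj.subject}_t1_one_leg_stand_1",
                          cfg.comma_decimal)
        # sway around a point near the beam centreline
        mid = cfg.geometry.beam_line.mean(axis=0)
        plate2, _ = simulate_sway_trial(
            SwayParams(**{**asdict(sway), "duration": min(sway.duration, 10.0)}),
            center=(mid[0], mid[1] + 8.0), seed=rng_seed + 3 * i + 1,
        )
        trial2 = TrialRecord(
            subject=subj.subject, group=subj.group, time="t1",
            task="balance", side="", trial_index=1, plates=[plate2], meta={},
        )
        write_trial_files(trial2, raw_root / f"{subj.subject}_t1_balance_1",
                          cfg.comma_decimal)
        # precision jump with a programmed offset
        jump = simulate_jump_trial(
            cfg.geometry, offset=35.0, landing_time=1.2, seed=rng_seed + 3 * i + 2,
            subject=subj.subject,
        )
        jump.group = subj.group
        write_trial_files(jump, raw_root / f"{subj.subject}_t1_precision_jump_1",
                          cfg.comma_decimal)
        n_raw += 3
    return {"cohort": cohort, "n_raw_trials": n_raw}


def _metric_for_trial(trial: TrialRecord, cfg: RunConfig):
    """Condition one raw trial and compute its task metric."""
    plates = [condition_plate(p, cfg.filters) for p in trial.plates]
    markers = condition_markers(trial.markers, trial.marker_rate, cfg.filters)
    if trial.task == "one_leg_stand":
        cop = compute_cop_single(plates[0], cfg.min_load, label=str(trial.key))
        return one_leg_stand_error(cop, side=trial.side)
    if trial.task == "balance":
        cop = compute_cop_single(plates[0], cfg.min_load, label=str(trial.key))
        return balance_beam_error(cop, cfg.geometry, side=trial.side)
    if trial.task == "precision_jump":
        t_land = detect_landing(plates[0])
        return precision_jump_error(
            markers["toe"], trial.marker_rate, cfg.geometry, t_land, side=trial.side
        )
    raise ParameterError(f"unknown task {trial.task!r}")


def process_raw_trials(cfg: RunConfig) -> pd.DataFrame:
    """Read every trial under ``workdir/raw`` and compute its metric."""
    raw_root = Path(cfg.workdir) / "raw"
    rows = []
    for tdir in sorted(p for p in raw_root.iterdir() if p.is_dir()) if raw_root.exists() else []:
        trial = read_trial_files(tdir, cfg.comma_decimal)
        err = _metric_for_trial(trial, cfg)
        rows.append(
            {
                "subject": trial.subject,
                "group": trial.group,
                "time": trial.time,
                "task": trial.task,
                "side": trial.side,
                "trial": trial.trial_index,
                "value_mm": err.value,
                "n_valid": err.n_valid_samples,
            }
        )
        logger.info("processed raw trial %s: %.2f mm", tdir.name, err.value)
    return pd.DataFrame(rows)


def _screen_motor(outcomes: pd.DataFrame, spec_data: pd.DataFrame, variable: str,
                  cfg: RunConfig):
    """Apply the IQR screen to one motor variable's fit dataset."""
    values = spec_data.loc[spec_data["variable"] == variable, "value"]
    is_out, frac = iqr_outlier_filter(values.to_numpy(), cfg.outlier_k, cfg.outlier_cap)
    keep_idx = values.index[~is_out]
    screened = spec_data.loc[
        (spec_data["variable"] != variable) | spec_data.index.isin(keep_idx)
    ]
    return screened, frac


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the full chain; every stage error aborts with a stage label."""
    report = RunReport(seed=cfg.seed, config_hash=cfg.config_hash())
    report.decisions = {
        "filter_order": "periodic median (force) then zero-phase Butterworth",
        "butterworth": f"order {cfg.filters.butter_order} per pass, "
        f"{cfg.filters.marker_cutoff:g}/{cfg.filters.force_cutoff:g} Hz",
        "hum_freq_hz": cfg.filters.hum_freq,
        "combined_cop": "unweighted spatial average",
        "correction": cfg.correction,
        "df_convention": cfg.df_convention,
        "min_load_n": cfg.min_load,
    }
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("simulate")
    try:
        if cfg.simulate:
            sim = simulate_to_dir(cfg)
            report.counts["raw_trials_written"] = sim["n_raw_trials"]

        current = stage("process_raw")
        metrics_raw = process_raw_trials(cfg)
        metrics_raw.to_csv(work / "metrics_raw.csv", **_CSV_KW)
        report.counts["raw_trials_scored"] = len(metrics_raw)
        report.tables["metrics_raw"] = "metrics_raw.csv"

        current = stage("outcomes")
        subjects = pd.read_csv(work / "subjects.csv")
        motor = pd.read_csv(work / "motor_trials.csv")
        scores = pd.read_csv(work / "scores.csv")
        from .synthio import CohortTables

        cohort = CohortTables(subjects=subjects, motor=motor, scores=scores, truth={})
        outcomes = outcomes_table(cohort)
        outcomes.rename(columns={"time": "time"}).to_csv(
            work / "outcomes.csv", **_CSV_KW
        )
        report.counts["outcome_rows"] = len(outcomes)
        report.counts["subjects"] = outcomes["subject"].nunique()
        report.tables["outcomes"] = "outcomes.csv"

        h_results = {}
        variables_h1 = MOTOR_VARIABLES + COGNITIVE_VARIABLES
        variables_h2 = MOTOR_VARIABLES + COGNITIVE_VARIABLES + SYMPTOM_VARIABLES
        for hyp, variables in (("H1", variables_h1), ("H2", variables_h2)):
            if hyp not in cfg.hypotheses:
                continue
            current = stage(f"glmm_{hyp}")
            term_rows = []
            emm_rows = []
            posthoc_rows = []
            for var in variables:
                spec = build_design(outcomes, hyp, var)
                data = spec.data
                if var in MOTOR_VARIABLES:
                    data, frac = _screen_motor(outcomes, data, var, cfg)
                    report.removed_fractions[f"{hyp}:{var}"] = round(frac, 4)
                    if frac > cfg.outlier_cap:
                        report.warnings.append(
                            f"{hyp}:{var}: outlier screen removed {frac:.1%}"
                        )
                fit = fit_glmm(spec, data)
                tt = fit.term_tests.copy()
                tt.insert(0, "variable", var)
                tt.insert(0, "hypothesis", hyp)
                term_rows.append(tt)
                if hyp == "H2":
                    emm = estimated_marginal_means(fit, ["Time", "Skating"])
                    et = emm.table.copy()
                    et.insert(0, "variable", var)
                    emm_rows.append(et)
                    ph = posthoc_contrasts(emm, cfg.correction, factor="Time")
                    ph.insert(0, "variable", var)
                    posthoc_rows.append(ph)
            terms = pd.concat(term_rows, ignore_index=True)
            terms.to_csv(work / f"{hyp.lower()}_terms.csv", **_CSV_KW)
            report.tables[f"{hyp.lower()}_terms"] = f"{hyp.lower()}_terms.csv"
            h_results[hyp] = terms
            if hyp == "H2":
                pd.concat(emm_rows, ignore_index=True).to_csv(
                    work / "h2_emm.csv", **_CSV_KW
                )
                pd.concat(posthoc_rows, ignore_index=True).to_csv(
                    work / "h2_posthoc.csv", **_CSV_KW
                )
                report.tables["h2_emm"] = "h2_emm.csv"
                report.tables["h2_posthoc"] = "h2_posthoc.csv"

        current = stage("partial_correlation")
        averaged = pcorr_mod.subject_average(outcomes)
        result = pcorr_mod.partial_spearman(
            averaged, df_convention=cfg.df_convention
        )
        result.rho.to_csv(work / "pcorr_rho.csv", float_format="%.10g")
        result.p.to_csv(work / "pcorr_p.csv", float_format="%.10g")
        result.labels.to_csv(work / "pcorr_labels.csv")
        report.tables["pcorr_rho"] = "pcorr_rho.csv"
        report.counts["pcorr_n_obs"] = result.n_obs
        report.counts["pcorr_df"] = result.df
        if cfg.figures:
            pcorr_mod.correlation_heatmap(result, work / "pcorr_heatmap.png")

        current = stage("report")
        report.counts["motor_trial_rows"] = int((outcomes["trial"] > 0).sum())
        report.to_json(work / "report.json")
    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    return report
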