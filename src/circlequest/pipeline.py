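"""Pipeline orchestration: simulate -> observe -> fit -> optimality -> stats.

Stages map onto the analysis of the active sampling study: generate (or
load) a cohort, run the ideal observer over every trial to get per-dot
uncertainty trajectories, fit the efficiency model per participant,
compute optimal stopping points and deviations, aggregate behavioural
summaries, and produce group contrasts and affective-burden correlations
with Bonferroni control. All numeric CSV output is serialised with six
significant digits so repeated runs under a fixed seed are byte-identical.
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

from . import __version__
from .efficiency import EfficiencyFit, fit_extraction_rate
from .metrics import (
    affective_burden,
    bonferroni_threshold,
    partial_spearman,
    permutation_group_contrast,
)
from .observer import ee_opt_fast, init_prior, update_posterior
from .optimality import deviation_from_optimal
from .simulate import CohortConfig, CohortData, simulate_cohort
from .task import SampleEvent, TaskConfig

__all__ = [
    "PipelineConfig",
    "RunReport",
    "DatasetValidationError",
    "SchemaError",
    "IntegrityError",
    "TimestampOrderError",
    "StageError",
    "load_dataset",
    "write_dataset",
    "compute_trajectories",
    "fit_efficiency_all",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

TRIALS_COLUMNS = [
    "participant_id",
    "trial_id",
    "R0",
    "eta_s",
    "hidden_x",
    "hidden_y",
    "placement_x",
    "placement_y",
    "n_paid_samples",
    "error_px",
    "score",
]
SAMPLES_COLUMNS = [
    "participant_id",
    "trial_id",
    "sample_index",
    "t_s",
    "x",
    "y",
    "colour",
    "paid",
]
QUESTIONNAIRE_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "ace_iii",
    "bdi",
    "hads_dep",
    "hads_anx",
]
PASSIVE_COLUMNS = [
    "participant_id",
    "group",
    "offer_id",
    "ee_band",
    "reward",
    "ee_opt",
    "confidence",
    "subjective_uncertainty",
    "accept",
]


class DatasetValidationError(ValueError):
    """Base class for dataset validation failures."""


class SchemaError(DatasetValidationError):
    """A required column is missing or has the wrong form."""


class IntegrityError(DatasetValidationError):
    """Cross-file referential integrity is broken (orphan rows)."""


class TimestampOrderError(DatasetValidationError):
    """Sample timestamps are not non-decreasing within a trial."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs: task, cohort, stages, seed."""

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: str = "results/run"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "trajectories": True,
            "efficiency": True,
            "optimality": True,
            "metrics": True,
            "passive": True,
        }
    )
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        task = TaskConfig(**raw.get("task", {}))
        cohort_kw = raw.get("cohort", {})
        seed = int(raw.get("seed", 0))
        cohort_kw.setdefault("seed", seed)
        cohort_kw = {
            k: tuple(v) if isinstance(v, list) else v for k, v in cohort_kw.items()
        }
        cohort = CohortConfig(**cohort_kw)
        cfg = cls(
            task=task,
            cohort=cohort,
            outdir=raw.get("outdir", "results/run"),
            seed=seed,
            log_level=raw.get("log_level", "INFO"),
        )
        cfg.stages.update(raw.get("stages", {}))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {"task": asdict(self.task), "cohort": asdict(self.cohort),
             "stages": self.stages, "seed": self.seed},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Counts, statistics, and provenance of one pipeline run."""

    row_counts: dict
    contrasts: dict
    correlations: dict
    bonferroni: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# dataset I/O and validation


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def validate_dataset(data: CohortData) -> None:
    """Schema, referential-integrity and timestamp checks; raises on error."""
    _require_columns(data.trials, TRIALS_COLUMNS, "trials")
    _require_columns(data.samples, SAMPLES_COLUMNS, "samples")
    _require_columns(data.questionnaires, QUESTIONNAIRE_COLUMNS, "questionnaires")
    if data.passive is not None:
        _require_columns(data.passive, PASSIVE_COLUMNS, "passive")

    trial_keys = set(
        zip(data.trials["participant_id"], data.trials["trial_id"])
    )
    sample_keys = set(
        zip(data.samples["participant_id"], data.samples["trial_id"])
    )
    orphans = sample_keys - trial_keys
    if orphans:
        raise IntegrityError(
            f"samples reference unknown trials: {sorted(orphans)[:5]}"
        )
    known = set(data.questionnaires["participant_id"])
    unknown = set(data.trials["participant_id"]) - known
    if unknown:
        raise IntegrityError(
            f"trials reference unknown participants: {sorted(unknown)[:5]}"
        )
    for (pid, tid), sub in data.samples.groupby(["participant_id", "trial_id"]):
        t = sub.sort_values("sample_index")["t_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise TimestampOrderError(
                f"non-monotone sample timestamps in trial {tid} of {pid}"
            )


def write_dataset(data: CohortData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = {"index": False, "float_format": FLOAT_FORMAT}
    data.trials.to_csv(outdir / "trials.csv", **kw)
    data.samples.to_csv(outdir / "samples.csv", **kw)
    data.questionnaires.to_csv(outdir / "questionnaires.csv", **kw)
    if data.passive is not None:
        data.passive.to_csv(outdir / "passive.csv", **kw)


def load_dataset(indir: str | Path) -> CohortData:
    """Load and validate a dataset directory written by the pipeline."""
    indir = Path(indir)
    for name in ("trials.csv", "samples.csv", "questionnaires.csv"):
        if not (indir / name).exists():
            raise SchemaError(f"missing file: {indir / name}")
    passive_path = indir / "passive.csv"
    data = CohortData(
        trials=pd.read_csv(indir / "trials.csv"),
        samples=pd.read_csv(indir / "samples.csv"),
        questionnaires=pd.read_csv(indir / "questionnaires.csv"),
        passive=pd.read_csv(passive_path) if passive_path.exists() else None,
    )
    validate_dataset(data)
    return data


# ---------------------------------------------------------------------------
# analysis stages


def attach_condition_levels(trials: pd.DataFrame, config: TaskConfig) -> pd.DataFrame:
    """Map numeric R0 / eta_s back onto their low/high level labels."""
    r0_map = {v: k for k, v in config.initial_credit_levels.items()}
    cost_map = {v: k for k, v in config.sample_cost_levels.items()}
    out = trials.copy()
    try:
        out["R0_level"] = out["R0"].map(r0_map)
        out["cost_level"] = out["eta_s"].map(cost_map)
    except KeyError as exc:  # pragma: no cover
        raise SchemaError(f"unknown condition value: {exc}") from exc
    if out["R0_level"].isna().any() or out["cost_level"].isna().any():
        raise SchemaError("trials contain R0/eta_s values not in the task config")
    return out


def compute_trajectories(data: CohortData, config: TaskConfig) -> pd.DataFrame:
    """Ideal-observer EE after each dot of every trial.

    Returns a long table (participant_id, trial_id, dot_index, ee_px)
    with dot_index = 1 for the free initial dot.
    """
    prior = init_prior(config)
    rows = []
    samples = data.samples.sort_values(["participant_id", "trial_id", "sample_index"])
    for (pid, tid), sub in samples.groupby(["participant_id", "trial_id"], sort=True):
        grid = prior
        for k, rec in enumerate(sub.itertuples(index=False), start=1):
            obs = SampleEvent(rec.x, rec.y, rec.colour, rec.t_s, paid=bool(rec.paid))
            grid = update_posterior(grid, obs, config.circle_radius)
            rows.append(
                {
                    "participant_id": pid,
                    "trial_id": tid,
                    "dot_index": k,
                    "ee_px": ee_opt_fast(grid)[1],
                }
            )
    return pd.DataFrame(rows)


def fit_efficiency_all(
    trajectories: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, EfficiencyFit]]:
    """One efficiency fit per participant, pooling all of their trials."""
    fits: dict[str, EfficiencyFit] = {}
    rows = []
    for pid, sub in trajectories.groupby("participant_id", sort=True):
        trajs = [
            g.sort_values("dot_index")["ee_px"].tolist()
            for _, g in sub.groupby("trial_id")
        ]
        fit = fit_extraction_rate(trajs)
        fits[pid] = fit
        rows.append(
            {
                "participant_id": pid,
                "alpha": fit.alpha,
                "ee_inf": fit.ee_inf,
                "baseline": fit.baseline,
                "sse": fit.sse,
            }
        )
    return pd.DataFrame(rows), fits


def _isi_per_participant(samples: pd.DataFrame) -> pd.Series:
    """Mean inter-touch interval of paid touches, averaged over trials."""
    paid = samples[samples["paid"] == 1]
    per_trial = (
        paid.sort_values("sample_index")
        .groupby(["participant_id", "trial_id"])["t_s"]
        .apply(lambda t: np.mean(np.diff(t)) if len(t) >= 2 else np.nan)
    )
    return per_trial.groupby("participant_id").mean()


def behavioural_summary(
    data: CohortData,
    trajectories: pd.DataFrame,
    efficiency: pd.DataFrame,
    optimality: pd.DataFrame,
) -> pd.DataFrame:
    """Per-participant summary table joining all behavioural markers."""
    groups = data.questionnaires.set_index("participant_id")["group"]
    mean_isi = _isi_per_participant(data.samples)
    mean_samples = data.trials.groupby("participant_id")["n_paid_samples"].mean()
    mean_error = data.trials.groupby("participant_id")["error_px"].mean()
    final_ee = (
        trajectories.sort_values("dot_index")
        .groupby(["participant_id", "trial_id"])["ee_px"]
        .last()
        .groupby("participant_id")
        .mean()
    )
    deviation = optimality.groupby("participant_id")["deviation"].mean()
    out = pd.DataFrame(
        {
            "group": groups,
            "mean_ISI": mean_isi,
            "mean_samples": mean_samples,
            "deviation": deviation,
            "alpha": efficiency.set_index("participant_id")["alpha"],
            "mean_final_EE": final_ee,
            "mean_error": mean_error,
        }
    ).reset_index(names="participant_id")
    return out


def cohort_statistics(
    summary: pd.DataFrame,
    questionnaires: pd.DataFrame,
    seed: int = 0,
) -> tuple[dict, dict, dict]:
    """Group contrasts, affective-burden correlations, Bonferroni family.

    Contrasts (SCI minus control) use permutation tests; correlations are
    partial Spearman within the SCI group, controlling for age and
    cognitive score, over the family {burden vs ISI, burden vs
    over-sampling} with Bonferroni correction.
    """
    rng = np.random.default_rng(seed)
    contrasts = {}
    labels = summary["group"].to_numpy()
    for var in ("mean_samples", "mean_ISI", "alpha", "mean_final_EE"):
        vals = summary[var].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        diff, p = permutation_group_contrast(
            vals[ok], labels[ok], rng=rng, reference="control"
        )
        contrasts[var] = {"sci_minus_control": diff, "p": p}

    q = questionnaires.set_index("participant_id")
    burden = affective_burden(
        q["bdi"].to_numpy(float), q["hads_anx"].to_numpy(float)
    )
    q = q.assign(burden=burden.scores)
    merged = summary.set_index("participant_id").join(q[["burden", "age", "ace_iii"]])
    sci = merged[merged["group"] == "SCI"].dropna(
        subset=["burden", "mean_ISI", "deviation", "age", "ace_iii"]
    )
    correlations = {
        "pc1_variance_explained_pct": burden.variance_explained,
    }
    if len(sci) < 5:  # two covariates need at least covariates + 3 cases
        logger.warning(
            "only %d complete SCI cases; correlation stage skipped", len(sci)
        )
        return contrasts, correlations, {"n_tests": 0}
    pvals = []
    for var in ("mean_ISI", "deviation"):
        rho, p = partial_spearman(
            sci["burden"].to_numpy(),
            sci[var].to_numpy(),
            sci[["age", "ace_iii"]].to_numpy(),
            rng=rng,
        )
        correlations[f"burden_vs_{var}"] = {"rho": rho, "p": p}
        pvals.append(p)
    threshold, reject = bonferroni_threshold(np.array(pvals))
    bonf = {
        "n_tests": len(pvals),
        "threshold": threshold,
        "significant": {
            v: bool(r) for v, r in zip(("mean_ISI", "deviation"), reject)
        },
    }
    return contrasts, correlations, bonf


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    config: PipelineConfig | str | Path, data: CohortData | None = None
) -> RunReport:
    """Run the enabled stages end to end and write all artifact files.

    ``config`` may be a :class:`PipelineConfig` or a path to a YAML file.
    If ``data`` is given (or the simulate stage is disabled), the cohort
    is taken from there / loaded from ``outdir`` instead of simulated.
    Idempotent under a fixed seed.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    counts: dict[str, int] = {}
    kw = {"index": False, "float_format": FLOAT_FORMAT}

    def _stage(name: str):
        logger.info("stage %s", name)

    try:
        _stage("simulate")
        if data is None:
            if stages.get("simulate", True):
                data = simulate_cohort(
                    config.cohort,
                    config.task,
                    include_passive=stages.get("passive", True),
                )
                write_dataset(data, outdir)
            else:
                data = load_dataset(outdir)
        validate_dataset(data)
        counts["trials"] = len(data.trials)
        counts["samples"] = len(data.samples)
        counts["participants"] = len(data.questionnaires)
        if data.passive is not None:
            counts["passive"] = len(data.passive)
    except DatasetValidationError:
        raise
    except Exception as exc:
        raise StageError(f"stage simulate failed: {exc}") from exc

    trajectories = efficiency = optimality = summary = None
    fits = {}
    try:
        if stages.get("trajectories", True):
            _stage("trajectories")
            trajectories = compute_trajectories(data, config.task)
            trajectories.to_csv(outdir / "ee_trajectories.csv", **kw)
            counts["ee_trajectories"] = len(trajectories)
    except Exception as exc:
        raise StageError(f"stage trajectories failed: {exc}") from exc

    try:
        if stages.get("efficiency", True) and trajectories is not None:
            _stage("efficiency")
            efficiency, fits = fit_efficiency_all(trajectories)
            efficiency.to_csv(outdir / "efficiency.csv", **kw)
            counts["efficiency"] = len(efficiency)
    except Exception as exc:
        raise StageError(f"stage efficiency failed: {exc}") from exc

    try:
        if stages.get("optimality", True) and efficiency is not None:
            _stage("optimality")
            trials_lv = attach_condition_levels(data.trials, config.task)
            optimality = deviation_from_optimal(trials_lv, fits, config.task)
            optimality.to_csv(outdir / "optimality.csv", **kw)
            counts["optimality"] = len(optimality)
    except Exception as exc:
        raise StageError(f"stage optimality failed: {exc}") from exc

    contrasts: dict = {}
    correlations: dict = {}
    bonf: dict = {}
    try:
        if stages.get("metrics", True) and optimality is not None:
            _stage("metrics")
            summary = behavioural_summary(data, trajectories, efficiency, optimality)
            summary.to_csv(outdir / "metrics.csv", **kw)
            counts["metrics"] = len(summary)
            contrasts, correlations, bonf = cohort_statistics(
                summary, data.questionnaires, seed=config.seed
            )
    except Exception as exc:
        raise StageError(f"stage metrics failed: {exc}") from exc

    report = RunReport(
        row_counts=counts,
        contrasts=contrasts,
        correlations=correlations,
        bonferroni=bonf,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        },
    )
    (outdir / "stats_report.json").write_text(report.to_json())
    return report
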