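"""Staged pipeline: simulate -> score -> impute -> fit -> correlate.

Each stage consumes an independent sub-seed spawned from the master seed,
all outputs are plain CSV with a fixed float format (so re-runs are
byte-identical), and a provenance manifest records configuration, seeds,
package versions and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import TABLE_VARIABLES, correlation_table
from .impute import ChainedEquationsImputer, ImputedSet
from .longitudinal import fit_pooled, fit_robust_lmm, cohens_d, pooled_cohens_d
from .records import (
    COMPONENTS,
    TIMEPOINTS,
    TrialDataset,
    ValidationError,
    write_food_records,
)
from .scoring import HeiScorer, ReferenceTable
from .simulate import SimConfig, simulate_trial

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """End-to-end run options."""

    out_dir: str = "heinvs_run"
    seed: int = 0
    mode: str = "ITT"  # ITT (imputation) or PP (complete cases)
    m: int = 50
    n_boot: int = 5000
    sim_config: str | None = None  # YAML path; None = bundled defaults
    reference_table: str | None = None
    make_figure: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("ITT", "PP"):
            raise ValidationError(f"mode must be ITT or PP, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def descriptives_table(dataset: TrialDataset) -> pd.DataFrame:
    """Per arm x timepoint mean (SD) of each component score."""
    df = dataset.data
    df = df[df["variable"].isin(COMPONENTS)]
    g = df.groupby(["variable", "group", "timepoint"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["variable"] = pd.Categorical(out["variable"], categories=COMPONENTS)
    out["timepoint"] = pd.Categorical(out["timepoint"], categories=TIMEPOINTS)
    return out.sort_values(["variable", "group", "timepoint"]).reset_index(drop=True)


def complete_cases(dataset: TrialDataset) -> TrialDataset:
    """Subjects with no missing cell at any timepoint (per-protocol set)."""
    wide = dataset.to_wide()
    keep = wide.dropna().index
    if len(keep) < 4:
        raise ValidationError("fewer than 4 complete cases; PP analysis impossible")
    sub = dataset.data[dataset.data["subject_id"].isin(keep)]
    return TrialDataset(sub.reset_index(drop=True))


def trajectory_figure(dataset: TrialDataset, path: Path, outcome: str = "hei_nvs_total") -> None:
    """Group means of the outcome with 95% CIs over the four timepoints."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = dataset.data
    df = df[(df["variable"] == outcome) & df["value"].notna()]
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, marker in (("intervention", "o"), ("control", "s")):
        sub = df[df["group"] == group].groupby("timepoint")["value"]
        mean = sub.mean().reindex(TIMEPOINTS)
        se = (sub.std() / np.sqrt(sub.count())).reindex(TIMEPOINTS)
        xs = np.arange(len(TIMEPOINTS))
        ax.errorbar(xs, mean, yerr=1.96 * se, marker=marker, capsize=3, label=group)
    ax.set_xticks(range(len(TIMEPOINTS)), TIMEPOINTS)
    ax.set_ylabel(outcome)
    ax.set_xlabel("timepoint")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seed_sim, seed_imp, seed_boot = (
        int(s) for s in master.generate_state(3) % (2**31)
    )
    stage_log: list[dict] = []

    def stage(name: str):
        stage_log.append({"stage": name, "t": round(time.time() - t_start, 3)})
        logger.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    # -- simulate ----------------------------------------------------------
    stage("simulate")
    sim_config = (
        SimConfig.from_yaml(config.sim_config) if config.sim_config else SimConfig.default()
    )
    trial = simulate_trial(sim_config, seed_sim)
    write_food_records(trial.diaries, out / "diaries.csv")
    trial.dataset.to_csv(out / "trial_table.csv")
    _write(trial.allocation, out / "allocation.csv")
    _write(trial.dropout_log.fillna(""), out / "dropout_log.csv")

    # -- score -------------------------------------------------------------
    stage("score")
    refs = (
        ReferenceTable.from_yaml(config.reference_table)
        if config.reference_table
        else ReferenceTable.default()
    )
    scores = HeiScorer(reference_table=refs).fit().transform(trial.diaries)
    _write(scores, out / "scores.csv")
    # diary/panel consistency check: re-scored diaries must reproduce panel
    panel_total = trial.dataset.pivot("hei_nvs_total")
    mism = 0.0
    for row in scores.itertuples():
        mism = max(mism, abs(panel_total.loc[row.subject_id, row.timepoint] - row.hei_nvs_total))
    if mism > 1e-6:
        raise ValidationError(f"re-scored diaries deviate from panel by {mism}")

    # -- descriptives ------------------------------------------------------
    desc = descriptives_table(trial.dataset)
    _write(desc, out / "component_descriptives.csv")

    # -- impute / complete cases -------------------------------------------
    if config.mode == "ITT":
        stage("impute")
        imputer = ChainedEquationsImputer(m=config.m, random_state=seed_imp)
        imputed = imputer.fit_transform(trial.dataset)
    else:
        stage("complete-cases")
        cc = complete_cases(trial.dataset)
        imputed = ImputedSet([cc.copy(), cc.copy()], method="complete-case", seed=None)

    # -- fit ---------------------------------------------------------------
    stage("fit")
    fit = fit_pooled(imputed, outcome="hei_nvs_total")
    coef_table = fit.summary_frame().reset_index(names="predictor")
    _write(coef_table, out / "model_coefficients.csv")
    effect_rows = []
    for group in ("intervention", "control"):
        for to in ("t1", "t2", "t3"):
            e = pooled_cohens_d(imputed, group, f"t0-{to}")
            effect_rows.append(
                {
                    "group": group,
                    "interval": e.interval,
                    "d": e.d,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n": e.n,
                    "magnitude": e.magnitude,
                }
            )
    _write(pd.DataFrame(effect_rows), out / "effect_sizes.csv")

    # -- correlate ---------------------------------------------------------
    stage("correlate")
    corr = correlation_table(
        imputed, variables=TABLE_VARIABLES, B=config.n_boot, seed=seed_boot
    )
    _write(corr, out / "correlations.csv")

    # -- figure ------------------------------------------------------------
    if config.make_figure:
        stage("figure")
        trajectory_figure(trial.dataset, out / "figure_trajectory.png")

    stage("manifest")
    outputs = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "package": "heinvs",
        "version": __version__,
        "config": asdict(config),
        "seeds": {"master": config.seed, "simulate": seed_sim, "impute": seed_imp, "bootstrap": seed_boot},
        "n_subjects": len(trial.allocation),
        "n_dropouts": int(trial.dropout_log["dropout_stage"].notna().sum()),
        "clamp_rate": trial.clamp_rate,
        "stages": stage_log,
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
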