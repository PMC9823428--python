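"""Synthetic two-arm trial generator.

Emits a complete study object — permuted-block allocation, a long-format
outcome panel with monotone missing-at-random dropout, and 7-day food
diaries that re-score exactly to the panel's component scores — so the
whole analysis pipeline can be exercised without any external data.

Generative model, per subject:

* component scores: ``score = arm/timepoint mean + b_i + e_it`` with a
  subject effect carrying an ``icc`` share of the variance, clamped to
  ``[0, max]`` (the clamping rate is logged);
* the total index score is the sum of the ten simulated components;
* every other panel variable is built from its baseline draw plus a
  change score whose correlation with the standardized total-index change
  follows a configurable (PSD-validated) correlation matrix;
* dropout is monotone: a per-stage logistic hazard in arm and baseline
  BMI, with its intercept calibrated so the marginal cumulative dropout
  matches the configured rate (default 22.9%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .records import (
    COMPONENTS,
    OTHER_LABEL,
    TIMEPOINTS,
    DietaryRecord,
    FoodEntry,
    TrialDataset,
    ValidationError,
)
from .scoring import ADEQUACY, HeiScore, ReferenceTable

logger = logging.getLogger(__name__)

FOLLOW_UPS: tuple[str, ...] = TIMEPOINTS[1:]

#: Components whose mass enters the energy-density denominator.
NON_BEVERAGE_COMPONENTS: tuple[str, ...] = tuple(
    c for c in COMPONENTS if c not in ("beverages", "alcohol")
)


@dataclass(frozen=True)
class VariableSpec:
    """Mean trajectory and variance structure for one panel variable."""

    name: str
    mean_intervention: tuple[float, float, float, float]
    mean_control: tuple[float, float, float, float]
    sd: float
    icc: float
    lower: float | None = None
    upper: float | None = None
    max_points: float | None = None  # set for index components only

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"{self.name}: sd must be >= 0")
        if not 0.0 <= self.icc < 1.0:
            raise ValidationError(f"{self.name}: icc must be in [0, 1)")

    def mean(self, group: str) -> np.ndarray:
        return np.asarray(
            self.mean_intervention if group == "intervention" else self.mean_control,
            dtype=float,
        )

    @property
    def change_sd(self) -> float:
        return math.sqrt(2.0 * (1.0 - self.icc)) * self.sd


@dataclass
class SimConfig:
    """Study conditions for the synthetic trial."""

    n_total: int = 153
    block_sizes: tuple[int, ...] = (4, 6)
    dropout_cumulative: float = 0.229
    dropout_beta_control: float = 0.2
    dropout_beta_bmi: float = 0.25
    mcar: bool = False
    components: dict[str, VariableSpec] = field(default_factory=dict)
    variables: dict[str, VariableSpec] = field(default_factory=dict)
    change_correlations: dict[str, float] = field(default_factory=dict)
    correlation_matrix: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_cumulative < 1.0:
            raise ValidationError("dropout_cumulative must be in [0, 1)")
        for b in self.block_sizes:
            if b % 2 != 0:
                raise ValidationError(f"block size {b} is odd; 1:1 blocks must be even")

    @classmethod
    def default(cls) -> "SimConfig":
        text = resources.files("heinvs").joinpath("data/sim_defaults.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "SimConfig":
        design = raw.get("design", {})

        def spec(name: str, item: Mapping, is_component: bool) -> VariableSpec:
            return VariableSpec(
                name=name,
                mean_intervention=tuple(float(v) for v in item["intervention"]),
                mean_control=tuple(float(v) for v in item["control"]),
                sd=float(item["sd"]),
                icc=float(item.get("icc", 0.5)),
                lower=(0.0 if is_component else item.get("lower")),
                upper=(float(item["max_points"]) if is_component else item.get("upper")),
                max_points=(float(item["max_points"]) if is_component else None),
            )

        components = {
            n: spec(n, item, True) for n, item in raw.get("components", {}).items()
        }
        variables = {
            n: spec(n, item, False) for n, item in raw.get("variables", {}).items()
        }
        return cls(
            n_total=int(design.get("n_total", 153)),
            block_sizes=tuple(int(b) for b in design.get("block_sizes", (4, 6))),
            dropout_cumulative=float(design.get("dropout_cumulative", 0.229)),
            dropout_beta_control=float(design.get("dropout_beta_control", 0.2)),
            dropout_beta_bmi=float(design.get("dropout_beta_bmi", 0.25)),
            components=components,
            variables=variables,
            change_correlations={
                k: float(v) for k, v in raw.get("change_correlations", {}).items()
            },
        )

    def build_correlation_matrix(self) -> pd.DataFrame:
        """Change-score correlation matrix over (total index, other variables)."""
        if self.correlation_matrix is not None:
            return self.correlation_matrix
        names = ["hei_nvs_total"] + list(self.variables)
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for var, rho in self.change_correlations.items():
            if var not in self.variables:
                raise ValidationError(f"change correlation for unknown variable {var!r}")
            mat.loc["hei_nvs_total", var] = rho
            mat.loc[var, "hei_nvs_total"] = rho
        return mat


@dataclass
class SimulatedTrial:
    """Bundle of everything the generator emits."""

    dataset: TrialDataset
    diaries: list[DietaryRecord]
    allocation: pd.DataFrame
    dropout_log: pd.DataFrame
    clamp_rate: float


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def permuted_block_randomize(
    n: int, block_sizes: Sequence[int] = (4, 6), seed=None
) -> list[str]:
    """1:1 allocation in randomly chosen, internally shuffled even blocks.

    The sequence is truncated at ``n``, so the final (possibly partial)
    block is the only source of arm imbalance.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    for b in block_sizes:
        if b <= 0 or b % 2 != 0:
            raise ValidationError(f"block size {b} invalid: 1:1 blocks must be even")
    rng = _as_rng(seed)
    labels: list[str] = []
    while len(labels) < n:
        b = int(rng.choice(np.asarray(block_sizes)))
        block = ["intervention"] * (b // 2) + ["control"] * (b // 2)
        rng.shuffle(block)
        labels.extend(block)
    return labels[:n]


def _check_psd(mat: pd.DataFrame) -> None:
    arr = mat.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValidationError("change-score correlation matrix is not symmetric")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-10):
        raise ValidationError("change-score correlation matrix diagonal must be 1")
    if np.linalg.eigvalsh(arr).min() < -1e-8:
        raise ValidationError(
            "change-score correlation matrix is not positive semi-definite"
        )


def _stage_hazard_intercept(config: SimConfig) -> float:
    """Calibrate the per-stage logit intercept to the target cumulative rate."""
    n_stages = len(FOLLOW_UPS)
    p_target = 1.0 - (1.0 - config.dropout_cumulative) ** (1.0 / n_stages)
    if p_target <= 0.0:
        return -np.inf
    if config.mcar or (
        config.dropout_beta_control == 0 and config.dropout_beta_bmi == 0
    ):
        return float(special.logit(p_target))
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()

    def marginal(b0: float) -> float:
        lin = (
            b0
            + config.dropout_beta_bmi * nodes[:, None]
            + config.dropout_beta_control * np.array([0.0, 1.0])[None, :]
        )
        return float((special.expit(lin) * weights[:, None]).sum() / 2.0) - p_target

    return float(optimize.brentq(marginal, -20.0, 10.0))


def simulate_outcomes(
    config: SimConfig | None = None, seed=None
) -> tuple[TrialDataset, pd.DataFrame, pd.DataFrame, float]:
    """Draw the outcome panel.

    Returns ``(dataset, allocation, dropout_log, clamp_rate)``; diaries are
    attached separately by :func:`simulate_trial`.
    """
    config = config or SimConfig.default()
    rng = _as_rng(seed)
    n = config.n_total
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    groups = permuted_block_randomize(n, config.block_sizes, rng)
    is_control = np.array([g == "control" for g in groups])

    corr = config.build_correlation_matrix()
    _check_psd(corr)

    # --- component scores ------------------------------------------------
    comp_values: dict[str, np.ndarray] = {}  # name -> (n, 4)
    n_clamped = 0
    n_draws = 0
    for name, sp in config.components.items():
        mu = np.where(
            is_control[:, None],
            sp.mean("control")[None, :],
            sp.mean("intervention")[None, :],
        )
        b = rng.normal(0.0, math.sqrt(sp.icc) * sp.sd, size=(n, 1))
        e = rng.normal(0.0, math.sqrt(1.0 - sp.icc) * sp.sd, size=(n, 4))
        raw = mu + b + e
        clipped = np.clip(raw, 0.0, sp.max_points)
        n_clamped += int((clipped != raw).sum())
        n_draws += raw.size
        comp_values[name] = clipped
    clamp_rate = n_clamped / max(n_draws, 1)
    if clamp_rate > 0:
        logger.info("clamped %.1f%% of component draws to [0, max]", 100 * clamp_rate)

    total = np.sum([comp_values[c] for c in config.components], axis=0)  # (n, 4)

    # standardized total-index change per follow-up
    z_hei = np.empty((n, 3))
    for j in range(3):
        d = total[:, j + 1] - total[:, 0]
        sd = d.std(ddof=1)
        z_hei[:, j] = (d - d.mean()) / sd if sd > 0 else 0.0

    # --- other variables: baseline + correlated change scores ------------
    names = list(config.variables)
    rho = corr.loc["hei_nvs_total", names].to_numpy(dtype=float)
    r_vv = corr.loc[names, names].to_numpy(dtype=float)
    schur = r_vv - np.outer(rho, rho)
    chol = np.linalg.cholesky(schur + 1e-10 * np.eye(len(names)))

    var_values: dict[str, np.ndarray] = {}
    baselines = {
        name: sp.mean("intervention")[0] * ~is_control + sp.mean("control")[0] * is_control
        + rng.normal(0.0, sp.sd, size=n)
        for name, sp in config.variables.items()
    }
    deltas = {name: np.zeros((n, 3)) for name in names}
    for j in range(3):
        eta = rng.standard_normal((n, len(names)))
        c = z_hei[:, j][:, None] * rho[None, :] + eta @ chol.T  # (n, k) std changes
        for k, name in enumerate(names):
            sp = config.variables[name]
            mu = np.where(
                is_control,
                sp.mean("control")[j + 1] - sp.mean("control")[0],
                sp.mean("intervention")[j + 1] - sp.mean("intervention")[0],
            )
            deltas[name][:, j] = mu + sp.change_sd * c[:, k]
    for name, sp in config.variables.items():
        vals = np.column_stack(
            [baselines[name]] + [baselines[name] + deltas[name][:, j] for j in range(3)]
        )
        lo = -np.inf if sp.lower is None else sp.lower
        hi = np.inf if sp.upper is None else sp.upper
        var_values[name] = np.clip(vals, lo, hi)

    # --- keep diary targets attainable -----------------------------------
    # required food mass/day = energy_intake / energy_density must be at
    # least the mass implied by the scored non-beverage components
    if "energy_intake" in var_values and "energy_density" in var_values:
        refs = ReferenceTable.default()
        m_scored = np.zeros((n, 4))
        for cname in NON_BEVERAGE_COMPONENTS:
            if cname not in comp_values:
                continue
            ref = refs[cname]
            s = comp_values[cname]
            if ref.direction == ADEQUACY:
                m_scored += ref.reference_amount * s / ref.max_points
            else:
                k = ref.zero_point_multiple
                m_scored += ref.reference_amount * (k - (k - 1.0) * s / ref.max_points)
        floor = var_values["energy_density"] * m_scored
        bumped = var_values["energy_intake"] < floor
        if bumped.any():
            logger.info(
                "raised energy_intake for %d cells to keep diaries attainable",
                int(bumped.sum()),
            )
            var_values["energy_intake"] = np.maximum(var_values["energy_intake"], floor)

    # --- monotone dropout -------------------------------------------------
    dropout_stage = np.full(n, -1)  # -1 = completer; j = first missing follow-up
    if config.dropout_cumulative > 0:
        b0 = _stage_hazard_intercept(config)
        bmi_sp = config.variables.get("bmi")
        if bmi_sp is not None and not config.mcar:
            z_bmi = (var_values["bmi"][:, 0] - bmi_sp.mean("intervention")[0]) / bmi_sp.sd
        else:
            z_bmi = np.zeros(n)
        for j in range(3):
            hazard = special.expit(
                b0
                + (0.0 if config.mcar else config.dropout_beta_control) * is_control
                + (0.0 if config.mcar else config.dropout_beta_bmi) * z_bmi
            )
            at_risk = dropout_stage < 0
            drops = at_risk & (rng.random(n) < hazard)
            dropout_stage[drops] = j

    # --- assemble long panel ----------------------------------------------
    all_values = dict(comp_values)
    all_values["hei_nvs_total"] = total
    all_values.update(var_values)
    rows = []
    for i, sid in enumerate(subjects):
        last = 4 if dropout_stage[i] < 0 else dropout_stage[i] + 1
        for t, tp in enumerate(TIMEPOINTS):
            observed = t < last
            for vname, vals in all_values.items():
                rows.append(
                    (sid, groups[i], tp, vname, vals[i, t] if observed else np.nan)
                )
    dataset = TrialDataset(
        pd.DataFrame(
            rows, columns=["subject_id", "group", "timepoint", "variable", "value"]
        )
    )
    allocation = pd.DataFrame({"subject_id": subjects, "group": groups})
    dropout_log = pd.DataFrame(
        {
            "subject_id": subjects,
            "dropout_stage": [
                None if s < 0 else FOLLOW_UPS[s] for s in dropout_stage
            ],
        }
    )
    return dataset, allocation, dropout_log, clamp_rate


def diaries_from_scores(
    scores: HeiScore | Mapping[str, float],
    energy_intake: float,
    energy_density: float,
    refs: ReferenceTable | None = None,
    seed=None,
    *,
    subject_id: str = "S0001",
    timepoint: str = "t0",
    day_concentration: float = 20.0,
) -> DietaryRecord:
    """Construct a 7-day diary whose scores invert to the given targets.

    Component intakes invert the piecewise-linear scoring rules
    (adequacy: ``reference * score/max``; moderation:
    ``reference * (k - (k-1) * score/max)``).  Daily amounts are Dirichlet
    splits of the 7-day total, so means — and hence re-scored points,
    energy density and energy intake — are preserved exactly.  Energy is
    spread over non-beverage mass at the target density; beverage and
    alcohol entries carry zero energy.  The gap between the mass implied by
    the scores and the mass required by ``energy_intake / energy_density``
    is filled with unscored ``other`` food.
    """
    refs = refs or ReferenceTable.default()
    rng = _as_rng(seed)
    if isinstance(scores, HeiScore):
        score_map: Mapping[str, float] = scores.component_scores
    else:
        score_map = scores
    if energy_density <= 0 or energy_intake < 0:
        raise ValidationError("energy targets must be positive")

    intakes: dict[str, float] = {}
    for c in COMPONENTS:
        s = float(score_map[c])
        ref = refs[c]
        if not 0.0 <= s <= ref.max_points + 1e-12:
            raise ValidationError(f"target score {s} out of [0, {ref.max_points}] for {c}")
        if ref.direction == ADEQUACY:
            intakes[c] = ref.reference_amount * s / ref.max_points
        else:
            k = ref.zero_point_multiple
            intakes[c] = ref.reference_amount * (k - (k - 1.0) * s / ref.max_points)

    scored_mass = sum(intakes[c] for c in NON_BEVERAGE_COMPONENTS)
    required_mass = energy_intake / energy_density
    other = required_mass - scored_mass
    if other < -1e-9:
        raise ValidationError(
            "unattainable targets: energy_intake/energy_density implies "
            f"{required_mass:.1f} g/day of food but the component scores already "
            f"require {scored_mass:.1f} g/day"
        )
    intakes[OTHER_LABEL] = max(other, 0.0)

    entries: list[FoodEntry] = []
    for comp, mean_amount in intakes.items():
        if mean_amount <= 0:
            continue
        weights = rng.dirichlet(np.full(7, day_concentration))
        is_bev = comp in ("beverages", "alcohol")
        for day in range(7):
            amount = 7.0 * mean_amount * weights[day]
            energy = 0.0 if is_bev else energy_density * amount
            entries.append(
                FoodEntry(
                    subject_id=subject_id,
                    timepoint=timepoint,
                    day=day + 1,
                    component=comp,
                    amount=amount,
                    energy=energy,
                    is_beverage=is_bev,
                )
            )
    if not entries:  # all-zero targets: keep the 7-day structure visible
        entries = [
            FoodEntry(subject_id, timepoint, d + 1, OTHER_LABEL, 0.0, 0.0)
            for d in range(7)
        ]
    return DietaryRecord(subject_id, timepoint, entries)


def simulate_trial(config: SimConfig | None = None, seed=None) -> SimulatedTrial:
    """Full synthetic study: panel, allocation, dropout log and diaries."""
    config = config or SimConfig.default()
    rng = _as_rng(seed)
    dataset, allocation, dropout_log, clamp_rate = simulate_outcomes(config, rng)
    refs = ReferenceTable.default()
    group_of = dict(zip(allocation["subject_id"], allocation["group"]))

    wide = {
        name: dataset.pivot(name)
        for name in list(config.components) + ["energy_intake", "energy_density"]
    }
    diaries: list[DietaryRecord] = []
    for sid in allocation["subject_id"]:
        for tp in TIMEPOINTS:
            ei = wide["energy_intake"].loc[sid, tp]
            if np.isnan(ei):
                continue  # dropped-out cell: no diary
            comp_scores = {c: float(wide[c].loc[sid, tp]) for c in config.components}
            rec = diaries_from_scores(
                comp_scores,
                energy_intake=float(ei),
                energy_density=float(wide["energy_density"].loc[sid, tp]),
                refs=refs,
                seed=rng,
                subject_id=sid,
                timepoint=tp,
            )
            rec.group = group_of[sid]
            diaries.append(rec)
    return SimulatedTrial(dataset, diaries, allocation, dropout_log, clamp_rate)
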