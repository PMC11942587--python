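"""Synthetic patient-level trial cohorts.

Generates two-arm catheter-trial data with the statistical structure the
cost-effectiveness analysis assumes: exact arm sizes, binomial second-
puncture events, a multinomial complication split (none / CLABSI / unknown
fever / local), a conditional resolution pathway for patients with a
complication, right-skewed (gamma) per-category costs drawn conditional on
the pathway (no replacement-catheter cost without a removal), and per-state
QALY accrual on the 90-day horizon.

The generator makes bootstrap interval estimation, probability estimation
and cost calibration testable without any patient-level data release: its
defaults mirror the bundled PICC model, and `calibrate_costs` solves the
residual "other treatments" category so the analytic expected per-patient
total hits a stated target exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ArmConfig",
    "CohortConfig",
    "COMPLICATIONS",
    "RESOLUTIONS",
    "generate_cohort",
    "estimate_probabilities",
    "calibrate_costs",
    "expected_total_cost",
]

COMPLICATIONS = ("clabsi", "unknown_fever", "local")
RESOLUTIONS = ("resolved_no_removal", "resolved_with_removal", "worsened")
FIXED_COST_CATEGORIES = ("laboratory", "inpatient", "followup", "maintenance", "other")


@dataclass(frozen=True)
class ArmConfig:
    """Generating process for one trial arm."""

    name: str
    n: int
    p_second_puncture: float
    p_complication: dict[str, float]  # keys COMPLICATIONS; 'none' is the complement
    p_resolution: dict[str, float]  # keys RESOLUTIONS; must sum to 1
    cost_means: dict[str, float]  # per-patient means of FIXED_COST_CATEGORIES
    catheter_unit_cost: float  # per catheter placed, device + insertion
    complication_treatment_cost: dict[str, float]  # per complication type
    escalation_cost: float  # extra complication-category cost when worsened
    utilities: dict[str, float]  # complication_free + RESOLUTIONS, 90-day QALY
    cost_cv: float = 0.3

    def validate(self) -> list[str]:
        errs = []
        if self.n <= 0:
            errs.append(f"{self.name}: arm size must be positive")
        if not (0.0 <= self.p_second_puncture <= 1.0):
            errs.append(f"{self.name}: p_second_puncture outside [0, 1]")
        pc = [self.p_complication.get(c, None) for c in COMPLICATIONS]
        if any(p is None for p in pc):
            errs.append(f"{self.name}: p_complication must define {COMPLICATIONS}")
        elif any(p < 0 for p in pc) or sum(pc) > 1.0 + 1e-12:
            errs.append(f"{self.name}: complication probabilities invalid (sum {sum(pc)})")
        pr = [self.p_resolution.get(r, None) for r in RESOLUTIONS]
        if any(p is None for p in pr):
            errs.append(f"{self.name}: p_resolution must define {RESOLUTIONS}")
        elif any(p < 0 for p in pr) or abs(sum(pr) - 1.0) > 1e-9:
            errs.append(f"{self.name}: resolution probabilities must sum to 1")
        for cat in FIXED_COST_CATEGORIES:
            if self.cost_means.get(cat, -1.0) < 0:
                errs.append(f"{self.name}: cost mean for {cat!r} missing or negative")
        if self.catheter_unit_cost < 0 or self.escalation_cost < 0:
            errs.append(f"{self.name}: catheter/escalation costs must be >= 0")
        for c in COMPLICATIONS:
            if self.complication_treatment_cost.get(c, -1.0) < 0:
                errs.append(f"{self.name}: treatment cost for {c!r} missing or negative")
        for state in ("complication_free", *RESOLUTIONS):
            u = self.utilities.get(state, None)
            if u is None or not (0.0 <= u <= 1.0):
                errs.append(f"{self.name}: utility for {state!r} missing or outside [0, 1]")
        if self.cost_cv <= 0:
            errs.append(f"{self.name}: cost_cv must be positive")
        return errs


@dataclass(frozen=True)
class CohortConfig:
    arms: tuple[ArmConfig, ...]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        errs = []
        for a in self.arms:
            errs.extend(a.validate())
        if len({a.name for a in self.arms}) != len(self.arms):
            errs.append("duplicate arm names")
        return errs


def _gamma_from_mean(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Gamma draws with the given per-element mean and common CV; 0 stays 0."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / cv**2
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.gamma(shape, mean[pos] / shape)
    return out


def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw one synthetic cohort; reproducible from (config, seed).

    Row invariants guaranteed by construction: complication 'none' implies
    resolution 'n/a' and zero complication-treatment cost; the total cost
    column is the exact sum of the seven category columns; a replacement
    catheter is charged only on resolved-with-removal pathways.
    """
    errs = config.validate()
    if errs:
        raise ValueError("invalid cohort config: " + "; ".join(errs))
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for arm in config.arms:
        n = arm.n
        attempts = 1 + rng.binomial(1, arm.p_second_puncture, size=n)
        pc = np.array([arm.p_complication[c] for c in COMPLICATIONS])
        p_all = np.append(pc, 1.0 - pc.sum())
        comp_idx = rng.choice(len(p_all), size=n, p=p_all)
        complication = np.array(list(COMPLICATIONS) + ["none"], dtype=object)[comp_idx]
        pr = np.array([arm.p_resolution[r] for r in RESOLUTIONS])
        res_idx = rng.choice(len(RESOLUTIONS), size=n, p=pr)
        resolution = np.array(RESOLUTIONS, dtype=object)[res_idx]
        resolution[complication == "none"] = "n/a"

        n_catheters = attempts + (resolution == "resolved_with_removal").astype(int)
        cost_cols: dict[str, np.ndarray] = {}
        for cat in ("laboratory", "inpatient", "followup", "maintenance"):
            cost_cols[f"cost_{cat}"] = _gamma_from_mean(
                rng, np.full(n, arm.cost_means[cat]), arm.cost_cv
            )
        cost_cols["cost_catheter"] = _gamma_from_mean(
            rng, n_catheters * arm.catheter_unit_cost, arm.cost_cv
        )
        treat_mean = np.zeros(n)
        for c in COMPLICATIONS:
            treat_mean[complication == c] = arm.complication_treatment_cost[c]
        treat_mean[resolution == "worsened"] += arm.escalation_cost
        cost_cols["cost_complication"] = _gamma_from_mean(rng, treat_mean, arm.cost_cv)
        cost_cols["cost_other"] = _gamma_from_mean(
            rng, np.full(n, arm.cost_means["other"]), arm.cost_cv
        )

        state = np.where(complication == "none", "complication_free", resolution)
        qaly = np.array([arm.utilities[s] for s in state])

        df = pd.DataFrame(
            {
                "patient_id": np.arange(offset, offset + n),
                "arm": arm.name,
                "puncture_attempts": attempts,
                "complication": complication,
                "resolution": resolution,
                **cost_cols,
                "qaly": qaly,
            }
        )
        df["total_cost"] = sum(df[c] for c in df.columns if c.startswith("cost_"))
        frames.append(df)
        offset += n
    return pd.concat(frames, ignore_index=True)


def estimate_probabilities(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-arm event rates with Wilson 95% intervals.

    Events: second puncture, CLABSI, unknown fever, local complication.
    Zero-count cells get the Jeffreys point estimate (x + 1/2)/(n + 1) and
    are flagged, so downstream beta/Dirichlet uncertainty stays proper.
    """
    if cohort.empty or "arm" not in cohort.columns:
        raise ValueError("cohort table is empty or lacks an 'arm' column")
    rows = []
    for arm, sub in cohort.groupby("arm", sort=True):
        n = len(sub)
        if n == 0:
            raise ValueError(f"arm {arm!r} has no patients")
        events = {
            "second_puncture": int((sub["puncture_attempts"] == 2).sum()),
            "clabsi": int((sub["complication"] == "clabsi").sum()),
            "unknown_fever": int((sub["complication"] == "unknown_fever").sum()),
            "local": int((sub["complication"] == "local").sum()),
        }
        for event, count in events.items():
            lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
            zero_cell = count == 0
            point = (count + 0.5) / (n + 1) if zero_cell else count / n
            rows.append(
                {
                    "arm": arm,
                    "event": event,
                    "count": count,
                    "n": n,
                    "estimate": point,
                    "wilson_lo": float(lo),
                    "wilson_hi": float(hi),
                    "zero_cell": zero_cell,
                }
            )
    return pd.DataFrame(rows)


def expected_total_cost(arm: ArmConfig) -> float:
    """Analytic expectation of the per-patient total cost for one arm."""
    p_comp = sum(arm.p_complication[c] for c in COMPLICATIONS)
    e_catheters = (
        1.0
        + arm.p_second_puncture
        + p_comp * arm.p_resolution["resolved_with_removal"]
    )
    e_treat = sum(
        arm.p_complication[c] * arm.complication_treatment_cost[c] for c in COMPLICATIONS
    )
    e_escal = p_comp * arm.p_resolution["worsened"] * arm.escalation_cost
    fixed = sum(arm.cost_means[cat] for cat in FIXED_COST_CATEGORIES)
    return fixed + e_catheters * arm.catheter_unit_cost + e_treat + e_escal


def calibrate_costs(
    config: CohortConfig, targets: dict[str, float]
) -> tuple[CohortConfig, dict[str, float]]:
    """Solve each arm's residual "other treatments" mean against a target.

    The residual mean is set so the analytic expected per-patient total
    equals ``targets[arm]`` exactly; a target below the expectation of the
    non-residual categories is infeasible and raises.  Returns the adjusted
    config and the achieved analytic expectations.
    """
    new_arms = []
    achieved = {}
    for arm in config.arms:
        if arm.name not in targets:
            new_arms.append(arm)
            continue
        target = targets[arm.name]
        if target <= 0:
            raise ValueError(f"{arm.name}: target mean must be positive")
        non_residual = expected_total_cost(arm) - arm.cost_means["other"]
        residual = target - non_residual
        if residual < 0:
            raise ValueError(
                f"{arm.name}: target {target} below non-residual expectation "
                f"{non_residual:.2f} — infeasible"
            )
        means = dict(arm.cost_means)
        means["other"] = residual
        new_arm = dataclasses.replace(arm, cost_means=means)
        new_arms.append(new_arm)
        achieved[arm.name] = expected_total_cost(new_arm)
    meta = dict(config.metadata)
    meta["cost_calibration_targets"] = dict(targets)
    return CohortConfig(arms=tuple(new_arms), metadata=meta), achieved
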