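"""Synthetic neonatal cohorts with the structure the validation pipeline assumes.

The generator emulates a facility-based cohort of singleton live births in
which gestational age (GA) is only ever observed through two imperfect
dating methods -- maternal recall of the last menstrual period (LMP) and a
single prenatal ultrasound (USG) -- while two assessors independently score
each newborn on the four maturity items of the simplified gestational-age
score. True GA exists only inside the simulator; every downstream analysis
sees the same imperfect views a field study would.

Structure generated per newborn:

* true GA ~ truncated normal on [24, 43] weeks, with the location solved so
  that P(GA < 37) equals the configured preterm prevalence;
* GA by LMP = true GA + recall error (mean-zero normal);
* GA by USG = true GA + dating error whose SD grows linearly with the GA at
  which the scan was done (late scans date pregnancies less precisely);
* birthweight linear in true GA plus noise, floored at 0.3 kg;
* item scores: each newborn carries a latent maturity age (true GA plus a
  shared biological deviation); each assessor perceives it with independent
  noise per item and the perceived value is discretized against fixed,
  strictly increasing GA thresholds per item.

Eligibility filtering reproduces the study-style windows: a record is
analysable when the two dating methods agree to within 1 (or 2) weeks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .scoring import ITEM_RANGES, ItemScores

__all__ = [
    "ItemModel",
    "CohortConfig",
    "NeonateRecord",
    "ConfigError",
    "default_item_models",
    "simulate_cohort",
    "filter_eligible",
    "cohort_to_dataframe",
    "dataframe_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "config_to_dict",
    "config_from_dict",
    "write_config",
    "read_config",
]

GA_LOWER, GA_UPPER = 24.0, 43.0
PRETERM_WEEKS = 37.0
BIRTHWEIGHT_FLOOR = 0.3

#: Documented CSV header for cohort files (order is the contract).
COHORT_COLUMNS = [
    "true_ga",
    "ga_lmp",
    "ga_usg",
    "ga_at_scan",
    "birthweight",
    "posture_a1",
    "skin_a1",
    "breast_a1",
    "genitals_a1",
    "posture_a2",
    "skin_a2",
    "breast_a2",
    "genitals_a2",
    "facility",
    "sex",
    "maternal_age",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class ItemModel:
    """Monotone GA -> item-score map: score = lo + #{thresholds <= perceived GA}."""

    name: str
    lo: int
    hi: int
    thresholds: tuple[float, ...]  # strictly increasing GA cut-points, len = hi - lo

    def __post_init__(self) -> None:
        if len(self.thresholds) != self.hi - self.lo:
            raise ConfigError(
                f"item_models[{self.name}]: need {self.hi - self.lo} thresholds, "
                f"got {len(self.thresholds)}"
            )
        diffs = np.diff(self.thresholds)
        if len(diffs) and not np.all(diffs > 0):
            raise ConfigError(
                f"item_models[{self.name}]: thresholds must be strictly increasing"
            )

    def score(self, perceived_ga: np.ndarray) -> np.ndarray:
        t = np.asarray(self.thresholds)
        return self.lo + (perceived_ga[:, None] >= t[None, :]).sum(axis=1)


def default_item_models() -> tuple[ItemModel, ...]:
    """Default discretization thresholds, spread over 25-38.5 weeks.

    The cut-points are spaced so the expected total score crosses the
    screening cut-off a little below 37 weeks of perceived maturity, giving
    the low-sensitivity / high-specificity behaviour characteristic of
    postnatal maturity scores.
    """
    return (
        ItemModel("posture", *ITEM_RANGES["posture"], (26.5, 30.0, 33.5, 37.0)),
        ItemModel("skin", *ITEM_RANGES["skin"], (25.5, 28.0, 30.5, 33.0, 35.5, 38.0)),
        ItemModel("breast", *ITEM_RANGES["breast"], (26.0, 29.0, 32.0, 35.0, 38.5)),
        ItemModel("genitals", *ITEM_RANGES["genitals"], (25.0, 28.5, 31.5, 34.5, 37.5)),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the package's reference conditions.

    ``ga_mean=None`` means: solve the truncated-normal location so that
    P(true GA < 37) equals ``preterm_target``. Supplying ``ga_mean``
    explicitly overrides the solve (``preterm_target`` is then nominal only).
    """

    n_births: int = 10_000
    preterm_target: float = 0.08
    ga_mean: float | None = None
    ga_sd: float = 1.8
    lmp_error_sd: float = 1.0
    usg_error_sd_base: float = 0.2
    usg_error_slope: float = 0.015  # extra weeks of SD per week of GA at scan
    usg_scan_ga_mean: float = 32.0
    usg_scan_ga_sd: float = 6.0
    bw_intercept: float = -3.2  # kg at GA 0 (extrapolated)
    bw_slope: float = 0.155  # kg per week
    bw_sd: float = 0.35
    maturity_sd: float = 2.5  # shared biological deviation of maturity from GA
    rater_noise_sd: float = 2.0  # per-rater, per-item perception noise (GA weeks)
    item_models: tuple[ItemModel, ...] = field(default_factory=default_item_models)
    facility_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_births, int) and self.n_births > 0):
            raise ConfigError(f"n_births must be a positive integer, got {self.n_births!r}")
        if not 0.0 < self.preterm_target < 1.0:
            raise ConfigError(f"preterm_target must lie in (0, 1), got {self.preterm_target!r}")
        for name in (
            "ga_sd",
            "lmp_error_sd",
            "usg_error_sd_base",
            "usg_error_slope",
            "usg_scan_ga_sd",
            "bw_sd",
            "maturity_sd",
            "rater_noise_sd",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v!r}")
        if self.ga_sd == 0:
            raise ConfigError("ga_sd must be > 0, got 0")
        if abs(sum(self.facility_probs) - 1.0) > 1e-9 or min(self.facility_probs) < 0:
            raise ConfigError(f"facility_probs must be a probability vector, got {self.facility_probs!r}")
        seen = {m.name for m in self.item_models}
        if seen != set(ITEM_RANGES):
            raise ConfigError(f"item_models must cover {sorted(ITEM_RANGES)}, got {sorted(seen)}")

    def solved_ga_mean(self) -> float:
        """Location of the truncated normal achieving the preterm target."""
        if self.ga_mean is not None:
            return self.ga_mean
        sd = self.ga_sd

        def preterm_frac(mu: float) -> float:
            a, b = (GA_LOWER - mu) / sd, (GA_UPPER - mu) / sd
            return stats.truncnorm.cdf(PRETERM_WEEKS, a, b, loc=mu, scale=sd) - self.preterm_target

        return float(optimize.brentq(preterm_frac, GA_LOWER, GA_UPPER, xtol=1e-10))


@dataclass(frozen=True)
class NeonateRecord:
    """One newborn: imperfect GA views, weight, two assessors' item scores."""

    true_ga: float
    ga_lmp: float
    ga_usg: float
    ga_at_scan: float
    birthweight: float
    items_a1: ItemScores
    items_a2: ItemScores
    facility: str
    sex: str
    maternal_age: float


def simulate_cohort(config: CohortConfig) -> list[NeonateRecord]:
    """Draw a cohort of ``config.n_births`` newborns; identical seeds give
    bit-identical cohorts."""
    rng = np.random.default_rng(config.seed)
    n = config.n_births
    mu = config.solved_ga_mean()
    a, b = (GA_LOWER - mu) / config.ga_sd, (GA_UPPER - mu) / config.ga_sd
    true_ga = stats.truncnorm.rvs(a, b, loc=mu, scale=config.ga_sd, size=n, random_state=rng)

    ga_lmp = true_ga + rng.normal(0.0, config.lmp_error_sd, size=n)
    ga_at_scan = np.clip(
        rng.normal(config.usg_scan_ga_mean, config.usg_scan_ga_sd, size=n), 6.0, true_ga
    )
    usg_sd = config.usg_error_sd_base + config.usg_error_slope * ga_at_scan
    ga_usg = true_ga + rng.normal(0.0, 1.0, size=n) * usg_sd
    ga_lmp = np.maximum(ga_lmp, 0.1)
    ga_usg = np.maximum(ga_usg, 0.1)

    birthweight = np.maximum(
        config.bw_intercept + config.bw_slope * true_ga + rng.normal(0.0, config.bw_sd, size=n),
        BIRTHWEIGHT_FLOOR,
    )

    maturity = true_ga + rng.normal(0.0, config.maturity_sd, size=n)
    scores: dict[tuple[str, str], np.ndarray] = {}
    for rater in ("a1", "a2"):
        for m in config.item_models:
            perceived = maturity + rng.normal(0.0, config.rater_noise_sd, size=n)
            scores[(rater, m.name)] = m.score(perceived)

    facility = rng.choice(
        [f"facility_{i + 1}" for i in range(len(config.facility_probs))],
        size=n,
        p=config.facility_probs,
    )
    sex = rng.choice(["male", "female"], size=n, p=[0.51, 0.49])
    maternal_age = np.clip(rng.normal(24.0, 4.0, size=n), 18.0, 45.0)

    records = []
    for i in range(n):
        records.append(
            NeonateRecord(
                true_ga=float(true_ga[i]),
                ga_lmp=float(ga_lmp[i]),
                ga_usg=float(ga_usg[i]),
                ga_at_scan=float(ga_at_scan[i]),
                birthweight=float(birthweight[i]),
                items_a1=ItemScores(
                    *(int(scores[("a1", m.name)][i]) for m in _ordered(config.item_models))
                ),
                items_a2=ItemScores(
                    *(int(scores[("a2", m.name)][i]) for m in _ordered(config.item_models))
                ),
                facility=str(facility[i]),
                sex=str(sex[i]),
                maternal_age=float(maternal_age[i]),
            )
        )
    return records


def _ordered(models: Sequence[ItemModel]) -> list[ItemModel]:
    by_name = {m.name: m for m in models}
    return [by_name[name] for name in ITEM_RANGES]


def filter_eligible(
    records: Iterable[NeonateRecord], tolerance_weeks: float
) -> list[NeonateRecord]:
    """Records whose LMP and USG GA estimates agree to within the tolerance.

    The boundary is inclusive: |GA_LMP - GA_USG| == tolerance is eligible.
    Order is preserved.
    """
    if tolerance_weeks <= 0:
        raise ValueError(f"tolerance_weeks must be > 0, got {tolerance_weeks!r}")
    return [r for r in records if abs(r.ga_lmp - r.ga_usg) <= tolerance_weeks]


# ---------------------------------------------------------------------------
# Tabular / file interchange
# ---------------------------------------------------------------------------

def cohort_to_dataframe(records: Sequence[NeonateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "true_ga": r.true_ga,
                "ga_lmp": r.ga_lmp,
                "ga_usg": r.ga_usg,
                "ga_at_scan": r.ga_at_scan,
                "birthweight": r.birthweight,
                "posture_a1": r.items_a1.posture,
                "skin_a1": r.items_a1.skin,
                "breast_a1": r.items_a1.breast,
                "genitals_a1": r.items_a1.genitals,
                "posture_a2": r.items_a2.posture,
                "skin_a2": r.items_a2.skin,
                "breast_a2": r.items_a2.breast,
                "genitals_a2": r.items_a2.genitals,
                "facility": r.facility,
                "sex": r.sex,
                "maternal_age": r.maternal_age,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def dataframe_to_records(df: pd.DataFrame) -> list[NeonateRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "true_ga"]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    has_truth = "true_ga" in df.columns
    records = []
    for _, row in df.iterrows():
        records.append(
            NeonateRecord(
                true_ga=float(row["true_ga"]) if has_truth else float("nan"),
                ga_lmp=float(row["ga_lmp"]),
                ga_usg=float(row["ga_usg"]),
                ga_at_scan=float(row["ga_at_scan"]),
                birthweight=float(row["birthweight"]),
                items_a1=ItemScores(
                    int(row["posture_a1"]), int(row["skin_a1"]),
                    int(row["breast_a1"]), int(row["genitals_a1"]),
                ),
                items_a2=ItemScores(
                    int(row["posture_a2"]), int(row["skin_a2"]),
                    int(row["breast_a2"]), int(row["genitals_a2"]),
                ),
                facility=str(row["facility"]),
                sex=str(row["sex"]),
                maternal_age=float(row["maternal_age"]),
            )
        )
    return records


def write_cohort_csv(records: Sequence[NeonateRecord], path, *, seed: int | None = None) -> None:
    """Write the cohort as CSV; the generating seed goes into a sidecar JSON."""
    df = cohort_to_dataframe(records)
    df.to_csv(path, index=False)
    if seed is not None:
        meta = {"seed": seed, "n_records": len(records), "columns": COHORT_COLUMNS}
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def read_cohort_csv(path) -> list[NeonateRecord]:
    return dataframe_to_records(pd.read_csv(path))


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["item_models"] = [
        {"name": m.name, "lo": m.lo, "hi": m.hi, "thresholds": list(m.thresholds)}
        for m in config.item_models
    ]
    d["facility_probs"] = list(config.facility_probs)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "item_models" in d:
        d["item_models"] = tuple(
            ItemModel(m["name"], m["lo"], m["hi"], tuple(m["thresholds"]))
            for m in d["item_models"]
        )
    if "facility_probs" in d:
        d["facility_probs"] = tuple(d["facility_probs"])
    try:
        return CohortConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def write_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def read_config(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
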