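"""Config-driven end-to-end validation runs.

One invocation takes a cohort (read from CSV or simulated), applies the
eligibility filter at one or both dating-agreement tolerances, and emits the
full analysis surface: the agreement panel, the accuracy table per reference
standard and assessor (plus average-score ROC), the classification tree and
its cut-offs, the three-test latent-class fit, incremental value over
birthweight, and the decision threshold implied by the latent-class LR+.
Runs are deterministic given the seed; every report carries run metadata
(seed, package version, config echo).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import (
    REFERENCE_KINDS,
    ReferenceStandard,
    diagnostic_summary,
    reference_labels,
    roc_auc,
    two_by_two,
)
from .agreement import agreement_report
from .cart import CARTConfig, extract_cutoffs, fit_cart
from .incremental import incremental_value
from .latent_class import fit_hui_walter, patterns_from_binary_matrix
from .scoring import DEFAULT_CUTOFF, TOTAL_RANGE, ITEM_RANGES
from .synthetic import (
    COHORT_COLUMNS,
    CohortConfig,
    NeonateRecord,
    cohort_to_dataframe,
    dataframe_to_records,
    filter_eligible,
    simulate_cohort,
)
from .thresholds import testing_threshold

__all__ = ["RunConfig", "SchemaError", "load_cohort", "run_validation", "write_reports"]

log = logging.getLogger("sgaskit")


class SchemaError(ValueError):
    """The input table violates the documented cohort schema."""


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run settings. Exactly one of input_path / simulate."""

    input_path: str | None = None
    simulate: CohortConfig | None = None
    tolerances: tuple[int, ...] = (1, 2)
    cutoff: int = DEFAULT_CUTOFF
    references: tuple[str, ...] = REFERENCE_KINDS
    ga_threshold: float = 37.0
    benefit_risk: float = 5.0
    seed: int = 0
    max_bad_row_fraction: float = 0.0
    lc_n_boot: int = 200
    cart_config: CARTConfig = field(default_factory=CARTConfig)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")
        if any(t not in (1, 2) for t in self.tolerances) or not self.tolerances:
            raise ValueError(f"tolerances must be a non-empty subset of {{1, 2}}, got {self.tolerances!r}")
        lo, hi = TOTAL_RANGE
        if not lo <= self.cutoff <= hi + 1:
            raise ValueError(f"cutoff must lie in [{lo}, {hi + 1}], got {self.cutoff}")
        bad = [r for r in self.references if r not in REFERENCE_KINDS]
        if bad or not self.references:
            raise ValueError(f"references must be a non-empty subset of {REFERENCE_KINDS}, got {self.references!r}")


def load_cohort(path, *, max_bad_row_fraction: float = 0.0) -> list[NeonateRecord]:
    """Read a cohort CSV, validating every row against the schema.

    Rows with missing required fields or out-of-range item scores are
    rejected; if their fraction exceeds ``max_bad_row_fraction`` a
    SchemaError is raised naming the first offending rows and fields,
    otherwise the bad rows are dropped with a logged count.
    """
    df = pd.read_csv(path)
    required = [c for c in COHORT_COLUMNS if c != "true_ga"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if "true_ga" not in df.columns:
        df = df.assign(true_ga=float("nan"))

    records: list[NeonateRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        problem = _row_problem(row)
        if problem is not None:
            errors.append(f"row {idx}: {problem}")
            continue
        records.extend(dataframe_to_records(df.loc[[idx]]))
    if errors:
        frac = len(errors) / len(df)
        for e in errors[:20]:
            log.error("schema: %s", e)
        if frac > max_bad_row_fraction:
            raise SchemaError(
                f"{len(errors)}/{len(df)} rows invalid "
                f"(> allowed fraction {max_bad_row_fraction}); first: {errors[0]}"
            )
        log.warning("dropped %d invalid rows of %d", len(errors), len(df))
    log.info("load_cohort: %d rows in, %d records out", len(df), len(records))
    return records


def _row_problem(row) -> str | None:
    for col in ("ga_lmp", "ga_usg", "ga_at_scan", "birthweight", "maternal_age"):
        v = row[col]
        if pd.isna(v):
            return f"missing value in field '{col}'"
        if col in ("ga_lmp", "ga_usg", "birthweight") and float(v) <= 0:
            return f"field '{col}' must be > 0, got {v}"
    for item, (lo, hi) in ITEM_RANGES.items():
        for suffix in ("_a1", "_a2"):
            col = item + suffix
            v = row[col]
            if pd.isna(v):
                return f"missing value in field '{col}'"
            if not float(v).is_integer() or not lo <= int(v) <= hi:
                return f"field '{col}'={v} outside allowed range [{lo}, {hi}]"
    return None


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _estimate_dict(e) -> dict:
    d = {"value": e.value, "ci_low": e.ci_low, "ci_high": e.ci_high}
    if getattr(e, "flag", None):
        d["flag"] = e.flag
    return d


def _summary_dict(s) -> dict:
    return {
        "prevalence_pct": _estimate_dict(s.prevalence),
        "sensitivity_pct": _estimate_dict(s.sensitivity),
        "specificity_pct": _estimate_dict(s.specificity),
        "ppv_pct": _estimate_dict(s.ppv),
        "npv_pct": _estimate_dict(s.npv),
        "lr_pos": _estimate_dict(s.lr_pos),
        "lr_neg": _estimate_dict(s.lr_neg),
        "counts": {"tp": s.counts.tp, "fp": s.counts.fp, "fn": s.counts.fn, "tn": s.counts.tn},
    }


def _analyze_subset(records, config: RunConfig) -> dict:
    totals_a1 = np.array([r.items_a1.total() for r in records])
    totals_a2 = np.array([r.items_a2.total() for r in records])
    avg_score = (totals_a1 + totals_a2) / 2.0
    bw = np.array([r.birthweight for r in records])

    log.info("agreement: n=%d", len(records))
    agr = agreement_report(totals_a1, totals_a2, cutoff=config.cutoff)
    out: dict = {
        "n_eligible": len(records),
        "agreement": {
            "ccc": dict(zip(("value", "ci_low", "ci_high"), agr.ccc.as_tuple())),
            "kappa_scores": dict(zip(("value", "ci_low", "ci_high"), agr.kappa_scores.as_tuple())),
            "kappa_dichotomous": dict(
                zip(("value", "ci_low", "ci_high"), agr.kappa_dichotomous.as_tuple())
            ),
            "difference_distribution": {
                k: {"count": c, "pct": p} for k, (c, p) in agr.difference_distribution.items()
            },
        },
    }

    accuracy: dict = {}
    incremental: dict = {}
    cart_reports: dict = {}
    for kind in config.references:
        std = ReferenceStandard(kind, config.ga_threshold)
        labels = reference_labels(records, std)
        if not labels.any() or labels.all():
            log.warning("reference %s has a single class; skipping", kind)
            continue
        per_std: dict = {}
        for name, totals in (("assessor_1", totals_a1), ("assessor_2", totals_a2)):
            t = two_by_two(totals < config.cutoff, labels)
            per_std[name] = _summary_dict(diagnostic_summary(t))
        per_std["auc_average_score"] = _estimate_dict(
            roc_auc(avg_score, labels, lower_is_positive=True)
        )
        accuracy[kind] = per_std

        tree = fit_cart({"birthweight": bw, "score": totals_a1}, labels, config.cart_config)
        cart_reports[kind] = {
            "tree": tree.to_dict(),
            "cutoffs": extract_cutoffs(tree),
            "leaves": [
                {"n": leaf.n, "p_preterm": leaf.p_preterm} for leaf in tree.leaves()
            ],
        }

        inc: dict = {}
        for name, totals in (("assessor_1", totals_a1), ("assessor_2", totals_a2)):
            rep = incremental_value(bw, totals, labels)
            inc[name] = {
                "idi": dict(zip(("value", "ci_low", "ci_high"), rep.idi)),
                "nri_continuous": dict(
                    zip(("value", "ci_low", "ci_high"), rep.nri_continuous)
                ),
            }
        incremental[kind] = inc
        log.info("accuracy[%s]: n=%d, preterm=%d", kind, len(records), int(labels.sum()))

    out["accuracy"] = accuracy
    out["cart"] = cart_reports
    out["incremental_value"] = incremental

    # Latent class: score call, LMP and USG as three imperfect tests
    lmp = np.array([r.ga_lmp for r in records]) < config.ga_threshold
    usg = np.array([r.ga_usg for r in records]) < config.ga_threshold
    score_call = avg_score < config.cutoff
    tests = np.column_stack([score_call, lmp, usg]).astype(int)
    if all(0 < col.sum() < len(records) for col in tests.T):
        counts = patterns_from_binary_matrix(tests)
        fit = fit_hui_walter(
            counts, seed=config.seed + 1, ci="bootstrap", n_boot=config.lc_n_boot
        )
        test_names = ("score", "lmp", "usg")
        out["latent_class"] = {
            "tests": list(test_names),
            "pi": fit.pi,
            "pi_ci": list(fit.pi_ci),
            "se": dict(zip(test_names, fit.se)),
            "sp": dict(zip(test_names, fit.sp)),
            "se_ci": {k: list(v) for k, v in zip(test_names, fit.se_ci)},
            "sp_ci": {k: list(v) for k, v in zip(test_names, fit.sp_ci)},
            "lr_pos": dict(zip(test_names, fit.lr_pos)),
            "loglik": fit.loglik,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "boundary": fit.boundary,
        }
        thr = testing_threshold(fit.lr_pos[0], config.benefit_risk)
        out["decision_threshold"] = {
            "lr_pos": thr.lr_pos,
            "benefit_risk": thr.benefit_risk,
            "testing_threshold": thr.testing_threshold,
        }
        log.info("latent_class: loglik=%.3f iter=%d", fit.loglik, fit.n_iter)
    else:
        log.warning("latent class skipped: a test column is single-class")
    return out


def run_validation(config: RunConfig) -> dict:
    """Run the full validation surface; returns the JSON-serializable bundle."""
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        records = simulate_cohort(sim_cfg)
        log.info("simulate: n=%d seed=%d", len(records), config.seed)
    else:
        records = load_cohort(config.input_path, max_bad_row_fraction=config.max_bad_row_fraction)

    bundle: dict = {
        "metadata": {
            "package_version": __version__,
            "seed": config.seed,
            "n_input": len(records),
            "cutoff": config.cutoff,
            "ga_threshold": config.ga_threshold,
            "references": list(config.references),
            "tolerances": list(config.tolerances),
            "source": config.input_path or "simulated",
        }
    }
    for tol in sorted(config.tolerances):
        eligible = filter_eligible(records, tol)
        log.info("filter_eligible tol=%d: %d -> %d", tol, len(records), len(eligible))
        bundle[f"tolerance_{tol}"] = _analyze_subset(eligible, config)
    return _round_floats(bundle)


def _accuracy_frame(block: dict) -> pd.DataFrame:
    rows = []
    for kind, per_std in block.get("accuracy", {}).items():
        for assessor in ("assessor_1", "assessor_2"):
            s = per_std[assessor]
            for metric in (
                "prevalence_pct",
                "sensitivity_pct",
                "specificity_pct",
                "ppv_pct",
                "npv_pct",
                "lr_pos",
                "lr_neg",
            ):
                rows.append(
                    {
                        "reference": kind,
                        "assessor": assessor,
                        "metric": metric,
                        "value": s[metric]["value"],
                        "ci_low": s[metric]["ci_low"],
                        "ci_high": s[metric]["ci_high"],
                    }
                )
    return pd.DataFrame(rows)


def write_reports(bundle: dict, out_dir) -> None:
    """Write the bundle as JSON plus per-tolerance CSV tables and tree text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key, block in bundle.items():
        if not key.startswith("tolerance_"):
            continue
        _accuracy_frame(block).to_csv(out / f"accuracy_{key}.csv", index=False)
        agr = block["agreement"]["difference_distribution"]
        pd.DataFrame(
            [{"abs_difference": k, "count": v["count"], "pct": v["pct"]} for k, v in agr.items()]
        ).to_csv(out / f"agreement_{key}.csv", index=False)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(bundle["metadata"], fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_to_csv(config: CohortConfig, path) -> pd.DataFrame:
    """Simulate a cohort and write it as CSV (helper behind the CLI)."""
    records = simulate_cohort(config)
    df = cohort_to_dataframe(records)
    df.to_csv(path, index=False)
    return df
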