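"""End-to-end pipeline: generate/read -> screen -> snapshot -> correlate ->
validate, with report tables and a reproducibility manifest.

Outputs, all CSV/JSON:

* ``table1.csv`` — cohort characteristics, overall and CD4-subgroup columns
* ``table2.csv`` — indicator and outcome distributions at the index visit
* ``table3.csv`` — pairwise correlation matrix (tidy)
* ``table4.csv`` / ``table5.csv`` — weight-model / CD4-model estimates
* ``manifest.json`` — config hash, seed, versions, row counts, warnings

Percentages and means/SDs are rounded to 1 decimal in report tables,
coefficients to 3 decimals; everything upstream is carried at full
precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlations import correlation_matrix, default_measure_specs
from .indicators import TABLE2_BANDS, categorize_coverage, snapshot_table
from .models import (
    INDICATORS,
    CD4ChangeModel,
    WeightGainModel,
    build_cd4_table,
    build_weight_panel,
)
from .records import CohortData, read_cohort, screen_eligibility, write_cohort
from .simulate import CohortConfig, default_config, generate_cohort

logger = logging.getLogger("adhkit")

__all__ = ["run_pipeline", "summarize_indicators", "RunManifest"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    inputs: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _hash_config(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _pct(x: float) -> float:
    return round(100.0 * x, 1)


def _mean_sd(series: pd.Series) -> str:
    s = pd.to_numeric(series, errors="coerce").dropna()
    if s.empty:
        return ""
    return f"{s.mean():.1f} ({s.std(ddof=1):.1f})"


def _characteristics(cohort: CohortData, ids: list[str]) -> list[tuple[str, str]]:
    recs = [cohort.patients[p] for p in ids]
    n = max(1, len(recs))
    rows: list[tuple[str, str]] = [("n", str(len(recs)))]

    def frac(pred) -> str:
        return f"{_pct(sum(1 for r in recs if pred(r)) / n)}%"

    rows.append(("female", frac(lambda r: r.gender == "female")))
    for band in ("<=30", "31-40", ">40"):
        rows.append((f"age {band}", frac(lambda r, b=band: r.age_band == b)))
    for level in ("none", "primary", "secondary+"):
        rows.append((f"education {level}", frac(lambda r, l=level: r.education == l)))
    rows.append(("married", frac(lambda r: r.married)))
    for liv in ("alone", "with_child_only", "with_adult"):
        rows.append((f"living {liv}", frac(lambda r, l=liv: r.living == l)))
    for occ in ("employed", "self-employed", "unemployed"):
        rows.append((f"occupation {occ}", frac(lambda r, o=occ: r.occupation == o)))
    rows.append(("government facility", frac(lambda r: r.facility_management == "government")))
    for loc in ("capital", "other_urban", "rural"):
        rows.append((f"location {loc}", frac(lambda r, l=loc: r.location == l)))
    for stage in (1, 2, 3, 4):
        rows.append((f"WHO stage {stage}", frac(lambda r, s=stage: r.who_stage == s)))
    rows.append(("support partner", frac(lambda r: r.support_partner)))
    females = [r for r in recs if r.gender == "female"] or [None]
    n_f = sum(1 for r in females if r is not None)
    rows.append(("PMTCT history (female only)",
                 f"{_pct(sum(1 for r in females if r and r.pmtct_history) / max(1, n_f))}%"))
    rows.append(("TB at initiation", frac(lambda r: r.tb_at_initiation)))
    for label, lo, hi in (("<=100", 0, 100), ("101-200", 101, 200),
                          ("201-350", 201, 350), ("351+", 351, 10_000)):
        rows.append((f"baseline CD4 {label}",
                     frac(lambda r, a=lo, b=hi: a <= r.baseline_cd4 <= b)))
    rows.append(("baseline weight male kg",
                 _mean_sd(pd.Series([r.baseline_weight_kg for r in recs
                                     if r.gender == "male"]))))
    rows.append(("baseline weight female kg",
                 _mean_sd(pd.Series([r.baseline_weight_kg for r in recs
                                     if r.gender == "female"]))))
    return rows


def _table1(cohort: CohortData, included: list[str], cd4_ids: list[str]) -> pd.DataFrame:
    total = _characteristics(cohort, included)
    sub = dict(_characteristics(cohort, cd4_ids))
    return pd.DataFrame(
        [{"characteristic": k, "total": v, "with_cd4_test": sub.get(k, "")}
         for k, v in total]
    )


def summarize_indicators(
    snapshots: pd.DataFrame,
    cohort: CohortData | None = None,
    subgroup_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Distributions of the indicator measures at the index visit.

    One row per statistic with a ``total`` column and, when
    ``subgroup_ids`` is given, a ``with_cd4_test`` column restricted to
    that subgroup.  Band frequencies per measure sum to 100% up to
    rounding.
    """
    def one_column(df: pd.DataFrame) -> list[tuple[str, str]]:
        n = max(1, len(df))
        out: list[tuple[str, str]] = [("n", str(len(df)))]
        out.append(("days since initiation mean (min, max)",
                    f"{df['asof_day'].mean():.0f} ({df['asof_day'].min()}, {df['asof_day'].max()})"
                    if len(df) else ""))
        bands = df["pct_days_covered"].map(
            lambda p: categorize_coverage(p, "table2"))
        for band in TABLE2_BANDS:
            out.append((f"coverage {band}", f"{_pct((bands == band).sum() / n)}%"))
        out.append(("gap >30 days", f"{_pct(df['gap_gt30'].sum() / n)}%"))
        sr = df[df["selfreport_scale"] == "three_level"]
        n_sr = max(1, len(sr))
        out.append(("n self-reports mean (sd)", _mean_sd(sr["n_selfreports"])))
        out.append(("avg self-report mean (sd)", _mean_sd(sr["avg_selfreport"])))
        out.append(("all self-reports perfect",
                    f"{_pct((sr['avg_selfreport'] == 1.0).sum() / n_sr)}%"))
        out.append(("any self-report poor",
                    f"{_pct((sr['any_poor_selfreport'] == True).sum() / n_sr)}%"))  # noqa: E712
        out.append(("n visits mean (sd)", _mean_sd(df["n_visits"])))
        for label, col in (
            ("visits on/before schedule", "pct_visits_on_or_before"),
            ("visits within 3 days", "pct_visits_within_3d"),
            ("visits before exhaustion", "pct_visits_before_exhaustion"),
        ):
            v = pd.to_numeric(df[col], errors="coerce").dropna()
            nn = max(1, len(v))
            out.append((f"{label} <80%", f"{_pct((v < 80).sum() / nn)}%"))
            out.append((f"{label} 80% to <90%",
                        f"{_pct(((v >= 80) & (v < 90)).sum() / nn)}%"))
            out.append((f"{label} 90% to 100%", f"{_pct((v >= 90).sum() / nn)}%"))
        return out

    total = one_column(snapshots)
    if subgroup_ids is not None:
        sub_df = snapshots[snapshots["patient_id"].isin(subgroup_ids)]
        sub = dict(one_column(sub_df))
    else:
        sub = {}
    return pd.DataFrame(
        [{"measure": k, "total": v, "with_cd4_test": sub.get(k, "")}
         for k, v in total]
    )


def _model_tables(cohort, included, indicators=None):
    indicators = indicators or list(INDICATORS)
    panel, w_excl = build_weight_panel(cohort, included)
    cd4, c_excl = build_cd4_table(cohort, included)
    t4_rows, t5_rows = [], []
    for ind in indicators:
        try:
            res = WeightGainModel(panel, ind, exclusions=dict(w_excl)).fit()
            t4_rows.append(res.indicator_terms())
        except (ValueError, RuntimeError) as exc:
            logger.warning("weight model %s skipped: %s", ind, exc)
        try:
            res = CD4ChangeModel(cd4, ind, exclusions=dict(c_excl)).fit()
            t5_rows.append(res.indicator_terms())
        except (ValueError, RuntimeError) as exc:
            logger.warning("CD4 model %s skipped: %s", ind, exc)
    t4 = pd.concat(t4_rows, ignore_index=True) if t4_rows else pd.DataFrame()
    t5 = pd.concat(t5_rows, ignore_index=True) if t5_rows else pd.DataFrame()
    for t in (t4, t5):
        for col in ("estimate", "ci_low", "ci_high"):
            if col in t.columns:
                t[col] = t[col].round(3)
        if "p_value" in t.columns:
            t["p_value"] = t["p_value"].round(4)
    cd4_ids = list(cd4["patient_id"]) if len(cd4) else []
    return t4, t5, cd4_ids


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "report",
    seed: int | None = None,
) -> dict[str, Path]:
    """Run every stage and write the report bundle.

    ``config`` either contains a ``synthetic`` block (a
    :class:`~adhkit.simulate.CohortConfig` mapping, or ``{}`` for the
    defaults) or an ``inputs`` entry naming a directory of cohort CSVs.
    The run is fully determined by (config, seed): two runs with the same
    pair produce byte-identical bundles.
    """
    config = config or {"synthetic": {}}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(config), seed=seed,
                           version=__version__)
    paths: dict[str, Path] = {}

    # ---- stage 1: obtain the cohort --------------------------------------
    if "inputs" in config:
        cohort = read_cohort(config["inputs"])
        manifest.inputs["source"] = str(config["inputs"])
        if len(cohort.rejects):
            manifest.warnings.append(f"{len(cohort.rejects)} rejected rows")
    else:
        syn = config.get("synthetic") or {}
        cfg = CohortConfig.from_dict(syn) if syn else default_config()
        cohort, _trace = generate_cohort(cfg, seed=seed)
        manifest.inputs["source"] = "synthetic"
        manifest.inputs["generator_seed"] = seed if seed is not None else cfg.seed
        cohort_paths = write_cohort(cohort, out / "cohort")
        paths.update({f"cohort_{k}": v for k, v in cohort_paths.items()})
    manifest.row_counts["patients"] = cohort.n_patients
    manifest.row_counts["visits"] = sum(len(v) for v in cohort.visits.values())
    manifest.row_counts["dispensings"] = sum(len(v) for v in cohort.dispensings.values())
    manifest.row_counts["cd4_tests"] = sum(len(v) for v in cohort.cd4_tests.values())
    logger.info("cohort: %d patients", cohort.n_patients)

    # ---- stage 2: eligibility screen -------------------------------------
    if cohort.n_patients == 0:
        manifest.warnings.append("empty cohort; aborted at screening stage")
        manifest.write(out / "manifest.json")
        raise ValueError("empty cohort: nothing to screen")
    report = screen_eligibility(cohort)
    manifest.row_counts["eligible"] = len(report.included_ids)
    manifest.row_counts["excluded"] = len(report.excluded)
    logger.info("screen: %d included / %d excluded",
                len(report.included_ids), len(report.excluded))
    pd.DataFrame(
        [{"criterion": c, "excluded_fraction": round(f, 4)}
         for c, f in report.exclusion_fractions.items()]
    ).to_csv(out / "screening.csv", index=False)
    paths["screening"] = out / "screening.csv"
    if not report.included_ids:
        manifest.warnings.append("no eligible patients")
        manifest.write(out / "manifest.json")
        raise ValueError("no eligible patients after screening")

    # ---- stage 3: index-visit snapshots ----------------------------------
    snapshots = snapshot_table(cohort, report.included_ids)
    manifest.row_counts["snapshots"] = len(snapshots)
    snapshots.to_csv(out / "snapshots.csv", index=False)
    paths["snapshots"] = out / "snapshots.csv"

    # ---- stage 4: correlations -------------------------------------------
    table3 = correlation_matrix(snapshots, default_measure_specs())
    table3["coefficient"] = table3["coefficient"].astype(float).round(3)
    table3["p_value"] = table3["p_value"].astype(float).round(4)
    table3.to_csv(out / "table3.csv", index=False)
    paths["table3"] = out / "table3.csv"

    # ---- stage 5: validation models --------------------------------------
    table4, table5, cd4_ids = _model_tables(cohort, report.included_ids)
    table4.to_csv(out / "table4.csv", index=False)
    table5.to_csv(out / "table5.csv", index=False)
    paths["table4"] = out / "table4.csv"
    paths["table5"] = out / "table5.csv"
    manifest.row_counts["weight_model_rows"] = int(table4["n_obs"].max()) if len(table4) else 0
    manifest.row_counts["cd4_model_patients"] = int(table5["n_patients"].max()) if len(table5) else 0

    # ---- stage 6: descriptive tables -------------------------------------
    _table1(cohort, report.included_ids, cd4_ids).to_csv(out / "table1.csv", index=False)
    summarize_indicators(snapshots, cohort, cd4_ids).to_csv(out / "table2.csv", index=False)
    paths["table1"] = out / "table1.csv"
    paths["table2"] = out / "table2.csv"

    manifest.write(out / "manifest.json")
    paths["manifest"] = out / "manifest.json"
    return paths
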