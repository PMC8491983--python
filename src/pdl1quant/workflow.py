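"""Batch orchestration: run quantification over a manifest and the
cohort-level outcome analysis, with deterministic, hash-stamped outputs.

Every output table and report embeds the configuration hash and the
package version so results can be traced to the exact parameters that
produced them.  Per-sample failures are isolated and logged; they never
abort the batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .quantify import QuantConfig, SlidePair, quantify_roi
from .stats import (
    COVARIATE_FIELDS,
    PatientRecord,
    combined_class,
    concordance,
    cox_fit,
    frame_to_records,
    km_curve,
    logrank,
    pearson_r,
    positivity_rate,
    response_table,
)

__all__ = ["RunConfig", "run_quantification", "run_outcome_analysis", "package_version"]

logger = logging.getLogger("pdl1quant")


def package_version() -> str:
    try:
        return _pkg_version("pdl1quant")
    except PackageNotFoundError:  # running from a source tree
        return "0.1.0"


@dataclass
class RunConfig(QuantConfig):
    """Pipeline configuration plus run-level bookkeeping (seed, version)."""

    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("stain_matrix") is not None:
            d["stain_matrix"] = np.asarray(d["stain_matrix"]).tolist()
        d["version"] = package_version()
        return d

    def config_hash(self) -> str:
        """Stable 12-hex-digit digest of all parameters and the version."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_pair(row: pd.Series) -> SlidePair:
    return SlidePair(
        stained=pio.read_image(row["stained_path"]),
        control=pio.read_image(row["control_path"]),
        roi_stained=pio.read_roi_geojson(row["roi_stained_path"]),
        roi_control=pio.read_roi_geojson(row["roi_control_path"]),
    )


def run_quantification(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every sample in a manifest.

    Returns ``(results, failures)``: one result row per successfully
    processed sample (sorted by ``sample_id`` for byte-stable output)
    and one failure record per sample that raised, with the reason.  A
    caller treating failures as fatal should exit nonzero iff
    ``failures`` is non-empty.
    """
    config = config or RunConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pio.read_manifest(manifest)
    chash = config.config_hash()
    ver = package_version()
    rows: list[dict] = []
    failures: list[dict] = []
    for _, mrow in manifest.iterrows():
        sid = str(mrow["sample_id"])
        try:
            pair = _load_pair(mrow)
            res = quantify_roi(pair, config)
            rows.append(
                {
                    "sample_id": sid,
                    "n_total": res.n_total,
                    "n_pdl1": res.n_pdl1,
                    "n_melanin": res.n_melanin,
                    "percent_pdl1": res.percent_pdl1,
                    "call": res.call,
                    "mode": res.mode,
                    "thresholds": json.dumps(res.thresholds_used, sort_keys=True),
                    "config_hash": chash,
                    "version": ver,
                }
            )
            logger.info("sample=%s quantified: call=%s", sid, res.call)
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            logger.error("sample=%s failed: %s", sid, exc)
            failures.append({"sample_id": sid, "reason": str(exc)})
    results = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "n_total",
            "n_pdl1",
            "n_melanin",
            "percent_pdl1",
            "call",
            "mode",
            "thresholds",
            "config_hash",
            "version",
        ],
    ).sort_values("sample_id", kind="stable").reset_index(drop=True)
    if out_csv is not None:
        results.to_csv(out_csv, index=False)
    return results, failures


def _km_section(records: Sequence[PatientRecord], endpoint: str, group_of) -> dict:
    groups: dict[str, tuple[list, list]] = {}
    for r in records:
        g = group_of(r)
        groups.setdefault(g, ([], []))
        groups[g][0].append(getattr(r, f"{endpoint}_months"))
        groups[g][1].append(getattr(r, f"{endpoint}_event"))
    section: dict = {"groups": {}}
    for g in sorted(groups):
        t, e = groups[g]
        curve = km_curve(t, e)
        section["groups"][g] = {
            "n": curve.n,
            "n_events": curve.n_events,
            "median_months": curve.median if curve.median is not None else "not_reached",
        }
    try:
        stat, p = logrank([groups[g] for g in sorted(groups)])
        section["logrank_statistic"] = stat
        section["logrank_p"] = p
    except ValueError as exc:
        section["logrank_note"] = f"insufficient data: {exc}"
    return section


def run_outcome_analysis(
    cohort: pd.DataFrame | Sequence[PatientRecord] | str | Path,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run the full biomarker-outcome analysis on a cohort.

    Produces a report with five sections: the physician-vs-digital
    concordance table, the combined three-level classification counts,
    response tables with chi-square, Kaplan-Meier medians with log-rank
    tests per grouping, and multivariable Cox fits for PFS and OS.
    Sections that a tiny cohort cannot support carry an
    ``insufficient data`` note instead of numbers.

    Raises on schema violations (missing column named in the error).
    """
    config = config or RunConfig()
    if isinstance(cohort, (str, Path)):
        cohort = pio.read_cohort_csv(cohort)
    if isinstance(cohort, pd.DataFrame):
        for col in pio.COHORT_REQUIRED_COLUMNS:
            if col not in cohort.columns:
                raise ValueError(f"cohort is missing required column: {col!r}")
        records = frame_to_records(cohort)
    else:
        records = list(cohort)
    if not records:
        raise ValueError("empty cohort")

    phys = [r.physician_call for r in records]
    dig = [r.digital_call for r in records]
    table = concordance(phys, dig)
    report: dict = {
        "config_hash": config.config_hash(),
        "version": package_version(),
        "n_patients": len(records),
        "concordance": {
            "n_pos_pos": table.n_pos_pos,
            "n_neg_neg": table.n_neg_neg,
            "n_pos_digital_only": table.n_pos_digital_only,
            "n_pos_physician_only": table.n_pos_physician_only,
            "percent_agreement": table.percent_agreement,
            "percent_discordance": table.percent_discordance,
            "physician_positivity_percent": positivity_rate(phys),
            "digital_positivity_percent": positivity_rate(dig),
        },
    }

    combined = [combined_class(p_, d_) for p_, d_ in zip(phys, dig)]
    report["combined_classification"] = {
        level: int(sum(c == level for c in combined))
        for level in ("both_positive", "single_positive", "both_negative")
    }

    pcts = [
        (r.physician_pct, r.digital_pct)
        for r in records
        if r.physician_pct is not None and r.digital_pct is not None
    ]
    if len(pcts) >= 3:
        try:
            r_val, p_val = pearson_r([a for a, _ in pcts], [b for _, b in pcts])
            report["percent_correlation"] = {"pearson_r": r_val, "p_value": p_val}
        except ValueError as exc:
            report["percent_correlation"] = {"note": f"insufficient data: {exc}"}
    else:
        report["percent_correlation"] = {"note": "insufficient data: fewer than 3 paired percentages"}

    by_combined = dict(zip((r.id for r in records), combined))
    groupings = {
        "digital_call": lambda r: r.digital_call,
        "physician_call": lambda r: r.physician_call,
        "combined": lambda r: by_combined[r.id],
    }
    report["response"] = {}
    for name, group_of in groupings.items():
        try:
            rt = response_table(records, group_of)
            report["response"][name] = {
                "table": rt.table.to_dict(orient="records"),
                "chi_square": rt.chi_square,
                "p_value": rt.p_value,
                "df": rt.df,
            }
        except ValueError as exc:
            report["response"][name] = {"note": f"insufficient data: {exc}"}

    report["survival"] = {}
    for endpoint in ("pfs", "os"):
        report["survival"][endpoint] = {}
        for name, group_of in groupings.items():
            try:
                report["survival"][endpoint][name] = _km_section(records, endpoint, group_of)
            except ValueError as exc:
                report["survival"][endpoint][name] = {"note": f"insufficient data: {exc}"}

    report["cox"] = {}
    df = pd.DataFrame([vars(r) for r in records])
    df["pdl1_both_positive"] = [float(c == "both_positive") for c in combined]
    df["pdl1_digital_positive"] = [float(d_ == "positive") for d_ in dig]
    df["pdl1_physician_positive"] = [float(p_ == "positive") for p_ in phys]
    covs = [c for c in COVARIATE_FIELDS if c in df.columns]
    for indicator in ("pdl1_both_positive", "pdl1_digital_positive", "pdl1_physician_positive"):
        report["cox"][indicator] = {}
        for endpoint in ("pfs", "os"):
            try:
                fit = cox_fit(df, endpoint, [*covs, indicator])
                report["cox"][indicator][endpoint] = {
                    "summary": {
                        cov: {
                            "hazard_ratio": fit.hazard_ratio(cov),
                            "ci_95": list(fit.ci(cov)),
                            "p_value": fit.p_value(cov),
                        }
                        for cov in fit.summary.index
                    },
                    "n_used": fit.n_used,
                    "n_excluded": fit.n_excluded,
                    "n_events": fit.n_events,
                    "ties_method": fit.ties_method,
                }
            except ValueError as exc:
                report["cox"][indicator][endpoint] = {"note": f"insufficient data: {exc}"}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "outcome_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        conc = pd.DataFrame([report["concordance"]])
        conc.insert(0, "config_hash", report["config_hash"])
        conc.to_csv(out_dir / "concordance.csv", index=False)
        for name, sec in report["response"].items():
            if "table" in sec:
                t = pd.DataFrame(sec["table"])
                t.insert(0, "config_hash", report["config_hash"])
                t.to_csv(out_dir / f"response_{name}.csv", index=False)
    return report
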