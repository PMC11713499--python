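"""Per-case and cohort orchestration of the full QA workflow:
preprocess -> HU image-quality metrics -> DVH comparison -> gamma analysis
-> group statistics -> metric-vs-passing-rate correlation.

The per-case stage emits one flat row of numbers; the cohort stage collects
rows into pandas tables, compares technique groups (e.g. IMRT/VMAT vs SRS),
runs paired planning-vs-synthetic tests per DVH metric, and correlates each
image-quality metric with the gamma passing rate at each criterion.  No case
is silently dropped: structures that are absent are skipped with a logged
reason, and tests with insufficient samples are flagged "NA" rather than
fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dvh import DEFAULT_ISODOSE_FRACTIONS, StructureAbsentError, diff_metrics, dose_metrics
from .gamma import STANDARD_CRITERIA, GammaCriteria, gamma_index
from .grids import CaseBundle
from .image_quality import SSIMConstants, quality_report
from .stats import (
    ALPHA_DEFAULT,
    CorrelationResult,
    TestResult,
    bonferroni,
    independent_t_test,
    spearman,
    wilcoxon_signed_rank,
)

log = logging.getLogger("sctqa.pipeline")

QUALITY_METRICS = ("me_hu", "mae_hu", "rmse_hu", "psnr_db", "ssim")


@dataclass
class PipelineConfig:
    """Resolved configuration embedded in every report for provenance."""

    criteria: Sequence[GammaCriteria] = STANDARD_CRITERIA
    roi_mode: str = "full"              # "full" grid or "body"-restricted ROI
    ssim_mode: str = "global"
    ssim_constants: SSIMConstants = field(default_factory=SSIMConstants)
    #: fixed PSNR peak (HU) so PSNR is comparable across cases; None falls
    #: back to each case's maximum synthetic-CT value over the ROI
    psnr_peak: Optional[float] = 3000.0
    normalize_similarity: bool = False
    isodose_fractions: Sequence[float] = DEFAULT_ISODOSE_FRACTIONS
    dvh_structures: Optional[Sequence[str]] = None  # None = all but BODY
    alpha: float = ALPHA_DEFAULT
    bonferroni_family: Optional[int] = None  # None = one family per table

    def as_dict(self) -> dict:
        d = asdict(self)
        d["criteria"] = [c.label for c in self.criteria]
        return d


def _criterion_column(criteria: GammaCriteria) -> str:
    return f"gamma_pass_{criteria.dose_diff_pct:g}pct_{criteria.dta_mm:g}mm"


def run_case(bundle: CaseBundle, config: Optional[PipelineConfig] = None,
             engine=gamma_index) -> dict:
    """Run the full per-case pipeline; returns one flat result row.

    Deterministic given the bundle and config.  Structures whose masks are
    empty are skipped with a log entry rather than failing the case.
    """
    config = config or PipelineConfig()
    roi = bundle.structures.get("BODY") if config.roi_mode == "body" else None
    q = quality_report(
        bundle.planning_ct, bundle.synthetic_ct, roi=roi,
        constants=config.ssim_constants, ssim_mode=config.ssim_mode,
        psnr_peak=config.psnr_peak, normalize=config.normalize_similarity,
    )
    row: dict = {"case_id": bundle.case_id, "group": bundle.group}
    row.update(q.as_dict())

    names = (config.dvh_structures if config.dvh_structures is not None
             else [n for n in bundle.structures if n != "BODY"])
    for name in names:
        mask = bundle.structures.get(name)
        if mask is None:
            log.warning("case %s: structure %s missing, skipped",
                        bundle.case_id, name)
            continue
        try:
            ref = dose_metrics(bundle.dose_reference, mask,
                               bundle.prescription_dose,
                               config.isodose_fractions)
            ev = dose_metrics(bundle.dose_evaluated, mask,
                              bundle.prescription_dose,
                              config.isodose_fractions)
        except StructureAbsentError as exc:
            log.warning("case %s: %s", bundle.case_id, exc)
            continue
        for d in diff_metrics(ref, ev, bundle.prescription_dose):
            base = f"{name}_{d.metric}"
            row[f"{base}_ref"] = d.reference
            row[f"{base}_eval"] = d.evaluated
            row[f"{base}_diff"] = d.absolute
            row[f"{base}_normdiff_pct"] = (np.nan if d.normalized_pct is None
                                           else d.normalized_pct)
    for crit in config.criteria:
        result = engine(bundle.dose_reference, bundle.dose_evaluated, crit)
        row[_criterion_column(crit)] = result.pass_rate
    return row


@dataclass
class CohortReport:
    per_case: pd.DataFrame
    group_summary: pd.DataFrame
    group_tests: list            # between-group TestResults
    paired_tests: list           # within-group planning-vs-synthetic tests
    correlations: list           # CorrelationResults per (metric, criterion)
    config: dict
    exclusions: list = field(default_factory=list)

    def correlation_table(self) -> pd.DataFrame:
        rows = [
            {"group": getattr(c, "group", ""), "metric": c.pair[0],
             "criterion": c.pair[1], "r_s": c.coefficient, "p": c.p_value,
             "n": c.n}
            for c in self.correlations
        ]
        return pd.DataFrame(rows)


def run_cohort(bundles: Sequence[CaseBundle],
               config: Optional[PipelineConfig] = None,
               engine=gamma_index) -> CohortReport:
    """Process a cohort of cases and assemble the full report."""
    config = config or PipelineConfig()
    rows, exclusions = [], []
    for bundle in bundles:
        try:
            rows.append(run_case(bundle, config, engine=engine))
        except Exception as exc:  # no silent drops: record and continue
            log.error("case %s excluded: %s", bundle.case_id, exc)
            exclusions.append({"case_id": bundle.case_id, "reason": str(exc)})
    if not rows:
        raise ValueError("no case produced a result row")
    per_case = pd.DataFrame(rows)

    value_cols = [c for c in per_case.columns
                  if c not in ("case_id", "group")]
    group_summary = per_case.groupby("group")[value_cols].agg(["mean", "std"])

    group_tests = _between_group_tests(per_case, config)
    paired_tests = _paired_tests(per_case, config)
    correlations = _correlations(per_case, config)
    return CohortReport(per_case, group_summary, group_tests, paired_tests,
                        correlations, config.as_dict(), exclusions)


def _between_group_tests(per_case: pd.DataFrame, config: PipelineConfig):
    """Independent t-tests between the two groups, one family per metric
    table (image quality; gamma passing rates)."""
    groups = [g for g in per_case["group"].unique() if g != ""]
    if len(groups) != 2:
        return []
    a = per_case[per_case["group"] == groups[0]]
    b = per_case[per_case["group"] == groups[1]]
    gamma_cols = [c for c in per_case.columns if c.startswith("gamma_pass_")]
    out = []
    for family in (list(QUALITY_METRICS), gamma_cols):
        family = [c for c in family if c in per_case.columns]
        m = config.bonferroni_family or len(family)
        for col in family:
            xa = a[col].dropna().to_numpy()
            xb = b[col].dropna().to_numpy()
            xa = xa[np.isfinite(xa)]
            xb = xb[np.isfinite(xb)]
            if xa.size < 3 or xb.size < 3:
                out.append(TestResult(f"t[{col}]", np.nan, np.nan,
                                      n=xa.size + xb.size, not_applicable=True,
                                      note="insufficient n"))
                continue
            try:
                res = independent_t_test(xa, xb)
            except ValueError as exc:
                out.append(TestResult(f"t[{col}]", np.nan, np.nan,
                                      n=xa.size + xb.size, not_applicable=True,
                                      note=str(exc)))
                continue
            res.test_name = f"t[{col}]"
            out.append(res.adjust(m, config.alpha))
    return out


def _paired_tests(per_case: pd.DataFrame, config: PipelineConfig):
    """Wilcoxon signed-rank tests of reference vs evaluated DVH metrics,
    one family per group."""
    pairs = sorted({c[:-4] for c in per_case.columns if c.endswith("_ref")
                    and f"{c[:-4]}_eval" in per_case.columns})
    out = []
    for group, sub in per_case.groupby("group"):
        fam = []
        for base in pairs:
            ref = sub[f"{base}_ref"].dropna().to_numpy()
            ev = sub[f"{base}_eval"].dropna().to_numpy()
            if ref.size != ev.size or ref.size < 3:
                fam.append(TestResult(f"wilcoxon[{group}:{base}]", np.nan,
                                      np.nan, n=ref.size, not_applicable=True,
                                      note="insufficient n"))
                continue
            res = wilcoxon_signed_rank(ref, ev)
            res.test_name = f"wilcoxon[{group}:{base}]"
            fam.append(res)
        m = config.bonferroni_family or max(
            1, sum(not t.not_applicable for t in fam))
        out.extend(t.adjust(m, config.alpha) if not t.not_applicable else t
                   for t in fam)
    return out


def _correlations(per_case: pd.DataFrame, config: PipelineConfig):
    """Spearman correlation of each image-quality metric with the gamma
    passing rate at each criterion, per group."""
    gamma_cols = [c for c in per_case.columns if c.startswith("gamma_pass_")]
    out = []
    for group, sub in per_case.groupby("group"):
        for metric in QUALITY_METRICS:
            if metric not in sub.columns:
                continue
            for col in gamma_cols:
                x = sub[metric].to_numpy()
                y = sub[col].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    continue
                res = spearman(x[ok], y[ok], pair=(metric, col))
                res.group = group
                out.append(res)
    return out
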