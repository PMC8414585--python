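"""Orchestration of a bidirectional two-sample MR study.

An :class:`AnalysisPlan` names exposure-outcome dataset pairs (forward:
biomarker -> disease, reported as OR per SD; reverse: disease liability ->
biomarker, reported as SD change per unit log-OR). For each pair the plan
runs instrument selection, harmonization, per-SNP Wald ratios, the primary
IVW (correlation-adjusted when an LD matrix is supplied), weighted-median
and MR-Egger sensitivity estimators, Cochran's Q / I^2, leave-one-out, and
an optional binary-outcome power calculation. Family-wise significance is
Bonferroni-corrected across the plan's pairs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MRKitError
from .estimators import (
    EggerResult,
    MREstimate,
    WaldEstimate,
    egger,
    ivw,
    ivw_correlated,
    wald_estimates,
    weighted_median,
)
from .power import PowerResult, PowerSpec, detectable_or
from .sensitivity import (
    HeterogeneityResult,
    LeaveOneOutResult,
    LeaveOneOutRow,
    cochran_q,
    leave_one_out,
)
from .sumstats import (
    GENOME_WIDE_P,
    harmonize,
    read_correlation_matrix,
    read_sumstats,
    select_instruments,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairSpec:
    """One exposure-outcome analysis in the plan."""

    name: str
    exposure: str
    outcome: str
    direction: str = "forward"  # forward: OR per SD; reverse: SD per log-OR
    binary_outcome: bool = True
    correlation: str | None = None
    power: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ConfigurationError(
                f"pair {self.name}: direction must be 'forward' or 'reverse'"
            )


@dataclass(frozen=True)
class AnalysisPlan:
    """The full study: pairs plus shared thresholds and seeds."""

    pairs: tuple[PairSpec, ...]
    alpha: float = 0.05
    p_threshold: float = GENOME_WIDE_P
    inclusive_threshold: bool = False
    palindrome_eaf_limit: float = 0.42
    n_boot: int = 10_000
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConfigurationError("analysis plan contains no pairs")

    @property
    def alpha_family(self) -> float:
        """Bonferroni family-wise threshold: alpha / number of pairs."""
        return self.alpha / len(self.pairs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisPlan":
        pairs = tuple(PairSpec(**p) for p in d.get("pairs", []))
        kwargs = {k: d[k] for k in
                  ("alpha", "p_threshold", "inclusive_threshold",
                   "palindrome_eaf_limit", "n_boot", "seed") if k in d}
        return cls(pairs=pairs, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair."""

    name: str
    direction: str
    binary_outcome: bool
    n_selected: int = 0
    wald: list[WaldEstimate] = field(default_factory=list)
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    egger_result: EggerResult | None = None
    heterogeneity: HeterogeneityResult | None = None
    loo: LeaveOneOutResult | None = None
    power_result: PowerResult | None = None
    primary_method: str = "ivw"
    significant: bool = False
    error: str | None = None


@dataclass
class StudyReport:
    """Per-pair results plus the family-wise correction applied."""

    results: list[PairResult]
    alpha_family: float
    plan: AnalysisPlan

    @property
    def failed_pairs(self) -> list[str]:
        return [r.name for r in self.results if r.error is not None]


def _resolve(path: str, base_dir: Path | None) -> Path:
    p = Path(path)
    if not p.is_absolute() and base_dir is not None:
        p = base_dir / p
    return p


def _run_pair(spec: PairSpec, plan: AnalysisPlan, base_dir: Path | None) -> PairResult:
    res = PairResult(spec.name, spec.direction, spec.binary_outcome)
    exposure = read_sumstats(_resolve(spec.exposure, base_dir))
    outcome = read_sumstats(_resolve(spec.outcome, base_dir))
    instruments = select_instruments(
        exposure, plan.p_threshold, inclusive=plan.inclusive_threshold
    )
    res.n_selected = len(instruments)
    iset = harmonize(
        instruments, outcome, plan.palindrome_eaf_limit,
        exposure_name=spec.name + ":exposure", outcome_name=spec.name + ":outcome",
    )
    if spec.correlation is not None:
        corr = read_correlation_matrix(
            _resolve(spec.correlation, base_dir),
            [p.variant_id for p in iset.pairs],
        )
        iset = iset.with_correlation(corr)

    pairs = iset.pairs
    k = len(pairs)
    res.wald = wald_estimates(pairs)
    if iset.correlation is not None:
        res.primary_method = "ivw_correlated"
        res.estimates["ivw_correlated"] = ivw_correlated(pairs, iset.correlation)
    else:
        res.primary_method = "ivw"
        res.estimates["ivw"] = ivw(pairs)
    if k >= 3:
        res.estimates["weighted_median"] = weighted_median(
            pairs, n_boot=plan.n_boot, seed=plan.seed
        )
        res.egger_result = egger(pairs)
        res.estimates["egger_slope"] = res.egger_result.slope
        res.loo = leave_one_out(pairs, iset.correlation)
    if k >= 2:
        res.heterogeneity = cochran_q(pairs)
    if spec.power is not None:
        pw = dict(spec.power)
        pspec = PowerSpec.from_counts(
            n_cases=pw["n_cases"], n_controls=pw["n_controls"], r2=pw["r2"],
            alpha=pw.get("alpha", plan.alpha),
            target_power=pw.get("target_power", 0.80),
        )
        res.power_result = detectable_or(pspec)

    res.significant = res.estimates[res.primary_method].pvalue < plan.alpha_family
    return res


def run_plan(plan: AnalysisPlan, base_dir: str | Path | None = None) -> StudyReport:
    """Execute every pair in the plan; failed pairs are recorded, not fatal."""
    base = Path(base_dir) if base_dir is not None else None
    results = []
    for spec in plan.pairs:
        try:
            res = _run_pair(spec, plan, base)
            logger.info("pair %s: %d instruments, primary %s p=%.3g",
                        spec.name, res.n_selected, res.primary_method,
                        res.estimates[res.primary_method].pvalue)
        except (MRKitError, OSError) as exc:
            logger.error("pair %s failed: %s", spec.name, exc)
            res = PairResult(spec.name, spec.direction, spec.binary_outcome,
                             error=str(exc))
        results.append(res)
    return StudyReport(results, plan.alpha_family, plan)


def _estimate_row(res: PairResult, est: MREstimate, binary: bool) -> dict[str, Any]:
    row = {
        "pair": res.name,
        "direction": res.direction,
        "method": est.method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "or": float("nan"),
        "or_ci_low": float("nan"),
        "or_ci_high": float("nan"),
    }
    if binary:
        row["or"], row["or_ci_low"], row["or_ci_high"] = est.odds_ratio()
    return row


def forest_table(report: StudyReport) -> pd.DataFrame:
    """One row per (pair, pooled method): the forest-plot backing table.

    Binary outcomes carry exponentiated OR columns; continuous outcomes
    (reverse analyses) report the beta scale only.
    """
    rows = [
        _estimate_row(res, est, res.binary_outcome)
        for res in report.results if res.error is None
        for est in res.estimates.values()
    ]
    return pd.DataFrame(rows)


def wald_table(report: StudyReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        for w in res.wald:
            rows.append({
                "pair": res.name, "variant_id": w.variant_id,
                "theta": w.theta, "se": w.se_theta, "pvalue": w.pvalue,
            })
    return pd.DataFrame(rows)


def sensitivity_table(report: StudyReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        if res.error is not None:
            continue
        row: dict[str, Any] = {"pair": res.name}
        if res.heterogeneity is not None:
            h = res.heterogeneity
            row.update(q=h.q, q_df=h.df, q_pvalue=h.pvalue, i2_percent=h.i2)
        if res.egger_result is not None:
            row.update(
                egger_intercept=res.egger_result.intercept,
                egger_intercept_se=res.egger_result.intercept_se,
                egger_intercept_pvalue=res.egger_result.intercept_pvalue,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def leave_one_out_table(report: StudyReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        if res.loo is None:
            continue
        for r in res.loo.rows:
            rows.append({
                "pair": res.name, "left_out": r.variant_id,
                "beta": r.estimate.beta, "ci_low": r.estimate.ci_low,
                "ci_high": r.estimate.ci_high, "excludes_full": r.excludes_full,
            })
        rows.append({
            "pair": res.name, "left_out": "(none)",
            "beta": res.loo.full.beta, "ci_low": res.loo.full.ci_low,
            "ci_high": res.loo.full.ci_high, "excludes_full": False,
        })
    return pd.DataFrame(rows)


def power_table(report: StudyReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        if res.power_result is None:
            continue
        rows.append({
            "pair": res.name,
            "detectable_or_upper": res.power_result.detectable_or_upper,
            "detectable_or_lower": res.power_result.detectable_or_lower,
        })
    return pd.DataFrame(rows)


# -- lossless JSON round-trip ------------------------------------------------

def report_to_dict(report: StudyReport) -> dict[str, Any]:
    return {
        "alpha_family": report.alpha_family,
        "plan": dataclasses.asdict(report.plan),
        "results": [dataclasses.asdict(r) for r in report.results],
    }


def report_from_dict(d: dict[str, Any]) -> StudyReport:
    plan = AnalysisPlan.from_dict({
        **{k: v for k, v in d["plan"].items() if k != "pairs"},
        "pairs": d["plan"]["pairs"],
    })
    results = []
    for rd in d["results"]:
        res = PairResult(
            name=rd["name"], direction=rd["direction"],
            binary_outcome=rd["binary_outcome"], n_selected=rd["n_selected"],
            primary_method=rd["primary_method"], significant=rd["significant"],
            error=rd["error"],
        )
        res.wald = [WaldEstimate(**w) for w in rd["wald"]]
        res.estimates = {k: MREstimate(**v) for k, v in rd["estimates"].items()}
        if rd["egger_result"] is not None:
            er = rd["egger_result"]
            res.egger_result = EggerResult(
                MREstimate(**er["slope"]), er["intercept"],
                er["intercept_se"], er["intercept_pvalue"],
            )
        if rd["heterogeneity"] is not None:
            res.heterogeneity = HeterogeneityResult(**rd["heterogeneity"])
        if rd["loo"] is not None:
            rows = tuple(
                LeaveOneOutRow(r["variant_id"], MREstimate(**r["estimate"]),
                               r["excludes_full"])
                for r in rd["loo"]["rows"]
            )
            res.loo = LeaveOneOutResult(rows, MREstimate(**rd["loo"]["full"]))
        if rd["power_result"] is not None:
            pr = rd["power_result"]
            res.power_result = PowerResult(
                pr["detectable_or_upper"], pr["detectable_or_lower"],
                {float(k): v for k, v in pr["power_at"].items()},
            )
        results.append(res)
    return StudyReport(results, d["alpha_family"], plan)


def write_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write tidy report tables, the full JSON report, and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "estimates": forest_table(report),
        "wald_ratios": wald_table(report),
        "sensitivity": sensitivity_table(report),
        "leave_one_out": leave_one_out_table(report),
        "power": power_table(report),
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report_to_dict(report), indent=2))
    manifest = {
        "mrkit_version": __version__,
        "alpha": report.plan.alpha,
        "alpha_family": report.alpha_family,
        "p_threshold": report.plan.p_threshold,
        "palindrome_eaf_limit": report.plan.palindrome_eaf_limit,
        "n_boot": report.plan.n_boot,
        "seed": report.plan.seed,
        "n_pairs": len(report.plan.pairs),
        "failed_pairs": report.failed_pairs,
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
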