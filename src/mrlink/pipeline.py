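"""Study orchestration: run every exposure-outcome pair, apply the
sensitivity-analysis trigger, meta-analyze multi-cohort outcomes, and emit
a tidy results table.

For each pair the primary analysis is IVW (multiplicative random effects
by default).  When the primary p-value falls below the trigger (0.05 by
default) or the outcome is flagged ``always_sensitivity``, three
sensitivity analyses follow: weighted median, MR-Egger and MR-PRESSO.
Outcomes sharing a name across cohorts and listed in a meta group are
combined by fixed-effect inverse-variance meta-analysis on the log-OR
scale, with case/noncase counts summed.

All per-pair randomness (bootstrap, MR-PRESSO simulations) derives
deterministically from the plan's master seed and the pair's names, so a
rerun of the same plan is byte-identical.  No multiplicity adjustment is
applied across the panel; p-values are reported as computed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import gwas_summary as gs
from .gwas_summary import HarmonizedInstrument, InstrumentError, SummaryRecord
from .mr_core import MREstimate, egger, ivw, weighted_median
from .mr_presso import PressoNotApplicable, run_presso
from .meta_combine import fixed_meta, from_estimate

__all__ = [
    "ExposureSpec",
    "OutcomeSpec",
    "AnalysisPlan",
    "PairResult",
    "run_pair",
    "run_panel",
    "results_to_frame",
    "format_results",
]

RESULT_COLUMNS = [
    "exposure", "outcome", "cohort", "method", "n_snp",
    "beta", "se", "or", "ci_low", "ci_high", "pvalue",
    "q_stat", "i2", "q_pvalue", "cases", "noncases",
    "presso_global_p", "n_outliers", "outlier_ids",
    "presso_or", "presso_ci_low", "presso_ci_high", "presso_p",
]


@dataclass
class ExposureSpec:
    name: str
    records: list[SummaryRecord] | None = None
    path: str | None = None
    scale: str = "per_sd"
    exclusion: set[str] = field(default_factory=set)

    def load(self) -> list[SummaryRecord]:
        if self.records is not None:
            return self.records
        recs, _ = gs.read_summary_table(self.path, scale=self.scale)
        return recs


@dataclass
class OutcomeSpec:
    name: str
    cohort: str
    records: list[SummaryRecord] | None = None
    path: str | None = None
    cases: int | None = None
    noncases: int | None = None
    always_sensitivity: bool = False
    proxy_table: dict | None = None

    def load(self) -> list[SummaryRecord]:
        if self.records is not None:
            return self.records
        recs, _ = gs.read_summary_table(self.path)
        return recs


@dataclass
class AnalysisPlan:
    """Everything needed to run a panel: data, thresholds, estimator options."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    meta_groups: dict[str, list[str]] = field(default_factory=dict)
    p_instrument: float = 5e-8
    ld_max: float = 0.01
    r2_proxy: float = 0.9
    alpha_sensitivity_trigger: float = 0.05
    ivw_model: str = "mre"
    palindromic_policy: str = "infer_by_eaf"
    eaf_tolerance: float = 0.08
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    ld_table: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_sensitivity_trigger < 1:
            raise ValueError("alpha_sensitivity_trigger must be in (0, 1)")
        for name, cohorts in self.meta_groups.items():
            if len(cohorts) < 2:
                raise ValueError(f"meta group {name!r} must reference >= 2 cohorts")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        raw = yaml.safe_load(Path(path).read_text())
        exposures = []
        for e in raw.get("exposures", []):
            excl = e.get("exclusion") or []
            if isinstance(excl, str):
                excl = sorted(gs.read_exclusion_list(excl))
            exposures.append(ExposureSpec(
                name=e["name"], path=e["path"], scale=e.get("scale", "per_sd"),
                exclusion=set(excl)))
        outcomes = []
        for o in raw.get("outcomes", []):
            proxy = o.get("proxy_table")
            if isinstance(proxy, str):
                proxy = gs.read_proxy_table(proxy)
            outcomes.append(OutcomeSpec(
                name=o["name"], cohort=o.get("cohort", "cohort"),
                path=o["path"], cases=o.get("cases"), noncases=o.get("noncases"),
                always_sensitivity=bool(o.get("always_sensitivity", False)),
                proxy_table=proxy))
        thr = raw.get("thresholds", {})
        opt = raw.get("options", {})
        ld = raw.get("ld_table")
        return cls(
            exposures=exposures, outcomes=outcomes,
            meta_groups=raw.get("meta_groups", {}),
            p_instrument=float(thr.get("p_instrument", 5e-8)),
            ld_max=float(thr.get("ld_max", 0.01)),
            r2_proxy=float(thr.get("r2_proxy", 0.9)),
            alpha_sensitivity_trigger=float(thr.get("alpha_sensitivity_trigger", 0.05)),
            ivw_model=opt.get("ivw_model", "mre"),
            palindromic_policy=opt.get("palindromic_policy", "infer_by_eaf"),
            eaf_tolerance=float(opt.get("eaf_tolerance", 0.08)),
            n_boot=int(opt.get("n_boot", 1000)),
            n_sim=int(opt.get("n_sim", 1000)),
            seed=int(opt.get("seed", 0)),
            ld_table=gs.read_ld_table(ld) if ld else None,
        )


@dataclass
class PairResult:
    exposure: str
    outcome: str
    cohort: str
    rows: list[dict]
    harmonized: list[HarmonizedInstrument]
    provenance: list[gs.ProvenanceEvent]
    error: str | None = None


def pair_seed(master: int, exposure: str, outcome: str, cohort: str) -> int:
    """Deterministic per-pair seed: stable across runs and row order."""
    tag = zlib.crc32(f"{exposure}|{outcome}|{cohort}".encode())
    return int(np.random.SeedSequence([int(master), tag]).generate_state(1)[0] % (2**31))


def _row(exposure, outcome_spec, est: MREstimate, **extra) -> dict:
    lo, hi = est.or_ci
    row = dict.fromkeys(RESULT_COLUMNS)
    row.update(
        exposure=exposure, outcome=outcome_spec.name, cohort=outcome_spec.cohort,
        method=est.method, n_snp=est.n_snp, beta=est.beta, se=est.se,
        pvalue=est.pvalue, q_stat=est.q_stat, i2=est.i2, q_pvalue=est.q_pvalue,
        cases=outcome_spec.cases, noncases=outcome_spec.noncases,
        **{"or": est.odds_ratio, "ci_low": lo, "ci_high": hi},
    )
    row.update(extra)
    return row


def run_pair(exposure: ExposureSpec, outcome: OutcomeSpec, plan: AnalysisPlan) -> PairResult:
    """Run one exposure-outcome pair: selection, harmonization, primary IVW,
    and — when the trigger fires — the three sensitivity analyses."""
    seed = pair_seed(plan.seed, exposure.name, outcome.name, outcome.cohort)
    instruments = gs.select_instruments(
        exposure.load(), exposure_name=exposure.name, exposure_scale=exposure.scale,
        p_threshold=plan.p_instrument, ld_table=plan.ld_table, ld_max=plan.ld_max,
        exclusion_list=exposure.exclusion)
    outcome_records = outcome.load()
    outcome_ids = {r.variant_id for r in outcome_records}
    if outcome.proxy_table is not None or not outcome_ids.issuperset(instruments.variant_ids):
        instruments = gs.substitute_proxies(
            instruments, outcome_ids, outcome.proxy_table or {}, r2_min=plan.r2_proxy)
    hs, harm_log = gs.harmonize(
        instruments, outcome_records,
        palindromic_policy=plan.palindromic_policy, eaf_tolerance=plan.eaf_tolerance)
    provenance = instruments.provenance_log + harm_log

    primary = ivw(hs, model=plan.ivw_model)
    rows = [_row(exposure.name, outcome, primary)]

    triggered = primary.pvalue < plan.alpha_sensitivity_trigger or outcome.always_sensitivity
    if triggered:
        if len(hs) >= 3:
            rows.append(_row(exposure.name, outcome,
                             weighted_median(hs, n_boot=plan.n_boot, seed=seed)))
            slope, intercept = egger(hs, model=plan.ivw_model)
            rows.append(_row(exposure.name, outcome, slope))
            rows.append(_row(exposure.name, outcome, intercept))
        try:
            pr = run_presso(hs, n_sim=plan.n_sim, seed=seed + 1, model=plan.ivw_model)
        except PressoNotApplicable as exc:
            provenance.append(gs.ProvenanceEvent("-", "skipped", "presso_not_applicable", str(exc)))
        else:
            extra = {
                "presso_global_p": pr.global_pvalue,
                "n_outliers": len(pr.outlier_ids),
                "outlier_ids": ";".join(pr.outlier_ids),
            }
            if pr.corrected is not None:
                lo, hi = pr.corrected.or_ci
                extra.update(presso_or=pr.corrected.odds_ratio,
                             presso_ci_low=lo, presso_ci_high=hi,
                             presso_p=pr.corrected.pvalue)
                rows.append(_row(exposure.name, outcome, pr.corrected, **extra))
            else:
                rows.append(_row(exposure.name, outcome, primary,
                                 method="presso", **extra))
    return PairResult(exposure.name, outcome.name, outcome.cohort, rows, hs, provenance)


def run_panel(plan: AnalysisPlan, out_dir=None) -> pd.DataFrame:
    """Run every exposure-outcome pair and the meta groups.

    A failing pair is recorded (method ``error``) and skipped, never
    fatal.  With ``out_dir``, writes ``results.tsv`` (full precision),
    ``results_pretty.tsv`` (table-style rounding), ``provenance.log`` and
    per-pair harmonized-instrument dumps.
    """
    all_rows: list[dict] = []
    prov_lines: list[str] = []
    primary_by_pair: dict[tuple[str, str, str], tuple[MREstimate, OutcomeSpec]] = {}
    dumps: dict[str, pd.DataFrame] = {}

    for exp in plan.exposures:
        for out in plan.outcomes:
            try:
                pr = run_pair(exp, out, plan)
            except (InstrumentError, gs.InputError) as exc:
                row = dict.fromkeys(RESULT_COLUMNS)
                row.update(exposure=exp.name, outcome=out.name, cohort=out.cohort,
                           method="error", outlier_ids=str(exc))
                all_rows.append(row)
                prov_lines.append(f"[{exp.name} x {out.name}/{out.cohort}] FAILED: {exc}")
                continue
            all_rows.extend(pr.rows)
            primary = next(r for r in pr.rows if r["method"].startswith("ivw"))
            est = MREstimate(primary["method"], primary["beta"], primary["se"],
                             primary["pvalue"], primary["n_snp"])
            primary_by_pair[(exp.name, out.name, out.cohort)] = (est, out)
            counts: dict[str, int] = {}
            for ev in pr.provenance:
                counts[ev.reason] = counts.get(ev.reason, 0) + 1
            prov_lines.append(
                f"[{exp.name} x {out.name}/{out.cohort}] n_snp={len(pr.harmonized)} "
                + " ".join(f"{k}={v}" for k, v in sorted(counts.items())))
            dumps[f"{exp.name}__{out.name}__{out.cohort}"] = pd.DataFrame(
                [vars(h) for h in pr.harmonized])

    # fixed-effect meta-analysis across cohorts of each meta group
    for group_name, cohorts in plan.meta_groups.items():
        for exp in plan.exposures:
            members = [
                (primary_by_pair[k], k) for k in primary_by_pair
                if k[0] == exp.name and k[1] == group_name and k[2] in cohorts]
            if len(members) < 2:
                continue
            ests = [from_estimate(est, cohort=k[2]) for (est, _), k in members]
            meta = fixed_meta(ests)
            cases = sum(o.cases or 0 for (_, o), _ in members)
            noncases = sum(o.noncases or 0 for (_, o), _ in members)
            spec = OutcomeSpec(name=group_name, cohort="+".join(k[2] for _, k in members),
                               cases=cases, noncases=noncases)
            all_rows.append(_row(exp.name, spec, meta.estimate))

    df = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        format_results(df).to_csv(out_dir / "results_pretty.tsv", sep="\t", index=False)
        (out_dir / "provenance.log").write_text("".join(f"{l}\n" for l in prov_lines))
        dump_dir = out_dir / "harmonized"
        dump_dir.mkdir(exist_ok=True)
        for name, d in dumps.items():
            d.to_csv(dump_dir / f"{name}.tsv", sep="\t", index=False)
    return df


def results_to_frame(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=RESULT_COLUMNS)


def _sig3(p):
    return float(f"{p:.3g}") if pd.notna(p) else p


def format_results(df: pd.DataFrame) -> pd.DataFrame:
    """Human-readable rounding: OR/CI to 2 decimals, p to 3 significant
    figures.  The machine-readable table keeps full precision."""
    out = df.copy()
    for c in ("or", "ci_low", "ci_high", "presso_or", "presso_ci_low", "presso_ci_high"):
        out[c] = out[c].astype(float).round(2)
    for c in ("pvalue", "q_pvalue", "presso_global_p", "presso_p"):
        out[c] = out[c].map(_sig3)
    return out
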