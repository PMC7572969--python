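"""Statistics for comparing reference regions and quantification methods.

Covers the full comparison battery applied to a quantified cohort:

* relative test-retest (TRT) variability, |T - R| / (0.5 |T + R|) * 100,
* MAD3 outlier exclusion (median absolute deviation, normal-consistency
  constant 1.4826, multiplier 3),
* accuracy against the plasma-input gold standard DVR_PI with cerebellar
  grey reference: linear regression (method on gold, so slopes < 1 read as
  underestimation) and Bland-Altman agreement with a bias-vs-burden trend,
* longitudinal reference-region SUV stability: paired t tests with
  Bonferroni correction, follow-up standardised to 2.6 years,
* annual percent change vs baseline burden with linear-vs-quadratic model
  selection by AIC,
* discrimination of visually amyloid-positive vs -negative scans by
  Mann-Whitney U with Bonferroni correction and the Hodges-Lehmann median
  difference as effect size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tac_core import COMPOSITE_REGION, REFERENCE_REGIONS, ParameterTable

DEFAULT_TARGET_YEARS = 2.6  # average follow-up (years) changes are standardised to
MAD_CONSISTENCY = 1.4826  # scale factor making MAD consistent for normal data


class StatsInputError(ValueError):
    """Inputs violate a statistical routine's preconditions."""


# ---------------------------------------------------------------------------
# elementary quantities


def trt_variability(T: float, R: float) -> float:
    """Relative test-retest variability (%): |T - R| / (0.5 |T + R|) * 100."""
    denom = 0.5 * abs(T + R)
    if denom == 0:
        raise StatsInputError("T + R must be nonzero")
    return abs(T - R) / denom * 100.0


def annual_percent_change(BL: float, FU: float, years: float) -> float:
    """Annual percentage change: ((FU - BL) / years) * (100 / BL)."""
    if BL == 0:
        raise StatsInputError("baseline value must be nonzero")
    if years <= 0:
        raise StatsInputError("years must be positive")
    return (FU - BL) / years * 100.0 / BL


def standardize_followup(
    BL: float, FU: float, years: float, target_years: float = DEFAULT_TARGET_YEARS
) -> float:
    """Rescale the observed change linearly in time to a common follow-up interval."""
    if years <= 0:
        raise StatsInputError("years must be positive")
    return BL + (FU - BL) * (target_years / years)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p); m defaults to the number of tests supplied."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsInputError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise StatsInputError("family size must be >= 1")
    return np.minimum(1.0, m * p)


def mad_outliers(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """MAD-based outlier mask: |x - median| > k * 1.4826 * MAD.

    When MAD is 0 (over half the sample at the median), any value strictly
    different from the median is flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise StatsInputError("need at least 3 values for outlier detection")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) > k * MAD_CONSISTENCY * mad


# ---------------------------------------------------------------------------
# agreement with the gold standard


@dataclass(frozen=True)
class AgreementResult:
    r: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_intercept: float
    n: int


def agreement_regression(gold: Sequence[float], method: Sequence[float]) -> AgreementResult:
    """Pearson r and OLS of the method value on the gold standard."""
    g = np.asarray(gold, dtype=float)
    m = np.asarray(method, dtype=float)
    if g.shape != m.shape or g.size < 3:
        raise StatsInputError("need >= 3 paired values")
    if np.ptp(g) == 0:
        raise StatsInputError("gold-standard values are constant")
    slope, intercept = np.polyfit(g, m, 1)
    r = float(np.corrcoef(g, m)[0, 1])
    return AgreementResult(r=r, slope=float(slope), intercept=float(intercept), n=g.size)


def bland_altman(gold: Sequence[float], method: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, 95% limits, and bias-vs-mean trend."""
    g = np.asarray(gold, dtype=float)
    m = np.asarray(method, dtype=float)
    if g.shape != m.shape or g.size < 3:
        raise StatsInputError("need >= 3 paired values")
    d = m - g
    mean = 0.5 * (m + g)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(mean) == 0:
        trend_slope, trend_intercept = 0.0, bias
    else:
        trend_slope, trend_intercept = (float(v) for v in np.polyfit(mean, d, 1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        trend_slope=trend_slope,
        trend_intercept=trend_intercept,
        n=g.size,
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class DiscriminationResult:
    u_statistic: float
    p_value: float
    p_adjusted: float
    hodges_lehmann: float
    n_a: int
    n_b: int


def hodges_lehmann(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Median of all pairwise differences a - b (two-sample Hodges-Lehmann)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsInputError("both groups must be non-empty")
    return float(np.median(a[:, None] - b[None, :]))


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of the first group) with a two-sided p-value.

    Exact p by enumeration of the null rank distribution for m + n <= 12
    without ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def paired_t_test(baseline: Sequence[float], followup: Sequence[float]) -> tuple[float, float]:
    """Paired t test on followup - baseline; two-sided p, df = n - 1."""
    bl = np.asarray(baseline, dtype=float)
    fu = np.asarray(followup, dtype=float)
    if bl.shape != fu.shape or bl.size < 2:
        raise StatsInputError("need >= 2 paired values")
    d = fu - bl
    if d.std(ddof=1) == 0:
        raise StatsInputError("zero variance of paired differences")
    res = stats.ttest_rel(fu, bl)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# longitudinal model selection


@dataclass(frozen=True)
class ModelComparisonResult:
    aic_linear: float
    aic_quadratic: float
    delta_aic: float  # aic_linear - aic_quadratic; > 0 favours quadratic
    preferred: str
    coef_linear: tuple[float, ...]  # (intercept, slope)
    coef_quadratic: tuple[float, ...]  # (intercept, slope, curvature)
    aicc_linear: float
    aicc_quadratic: float
    n: int


def _ols_aic(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float, float]:
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    rss = float(np.sum(resid**2))
    n = x.size
    k = degree + 2  # polynomial coefficients + error variance
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    denom = n - k - 1
    aicc = aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)
    return coef[::-1], aic, aicc


def fit_linear_quadratic_aic(x: Sequence[float], y: Sequence[float]) -> ModelComparisonResult:
    """Fit y ~ x and y ~ x + x^2 by OLS; compare by AIC = n ln(RSS/n) + 2k.

    k counts the polynomial coefficients plus the error variance.  AICc is
    also reported but selection uses plain AIC; quadratic is preferred iff
    delta_aic = aic_linear - aic_quadratic > 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 4:
        raise StatsInputError("need >= 4 paired values")
    if np.ptp(xa) == 0:
        raise StatsInputError("x values are constant")
    coef_lin, aic_lin, aicc_lin = _ols_aic(xa, ya, 1)
    coef_quad, aic_quad, aicc_quad = _ols_aic(xa, ya, 2)
    delta = aic_lin - aic_quad
    return ModelComparisonResult(
        aic_linear=float(aic_lin),
        aic_quadratic=float(aic_quad),
        delta_aic=float(delta),
        preferred="quadratic" if delta > 0 else "linear",
        coef_linear=tuple(float(c) for c in coef_lin),
        coef_quadratic=tuple(float(c) for c in coef_quad),
        aicc_linear=float(aicc_lin),
        aicc_quadratic=float(aicc_quad),
        n=xa.size,
    )


# ---------------------------------------------------------------------------
# cohort-level report


@dataclass
class ReportConfig:
    gold_method: str = "DVR_PI"
    gold_reference: str = "GMCB"
    composite_region: str = COMPOSITE_REGION
    reference_regions: tuple[str, ...] = REFERENCE_REGIONS
    ratio_methods: tuple[str, ...] = ("DVR_RLOGAN", "DVR_SRTM", "SUVR_40_60", "SUVR_60_90")
    suv_methods: tuple[str, ...] = ("SUV_40_60", "SUV_60_90")
    target_years: float = DEFAULT_TARGET_YEARS
    mad_multiplier: float = 3.0
    stability_family: int = 5  # reference regions per SUV window
    discrimination_family: int = 20  # 5 reference regions x 4 methods
    agreement_on_regional: bool = True  # pool target regions; else composite only


@dataclass
class ComparisonReport:
    trt: pd.DataFrame = field(default_factory=pd.DataFrame)
    agreement: pd.DataFrame = field(default_factory=pd.DataFrame)
    bland_altman: pd.DataFrame = field(default_factory=pd.DataFrame)
    stability: pd.DataFrame = field(default_factory=pd.DataFrame)
    annual_change: pd.DataFrame = field(default_factory=pd.DataFrame)
    model_selection: pd.DataFrame = field(default_factory=pd.DataFrame)
    discrimination: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sections(self) -> dict[str, pd.DataFrame]:
        return {
            "trt": self.trt,
            "agreement": self.agreement,
            "bland_altman": self.bland_altman,
            "stability": self.stability,
            "annual_change": self.annual_change,
            "model_selection": self.model_selection,
            "discrimination": self.discrimination,
            "exclusions": self.exclusions,
        }

    def to_json(self) -> str:
        payload = {
            name: json.loads(df.to_json(orient="records", double_precision=12))
            for name, df in self.sections().items()
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        for name, df in self.sections().items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.12g")


def apply_mad_exclusion(
    table: ParameterTable, k: float = 3.0
) -> tuple[ParameterTable, pd.DataFrame]:
    """Flag MAD outliers within each (region, method, reference_region) group.

    Returns the table with excluded flags set plus a log of every exclusion
    with the group median and MAD used.
    """
    df = table.data.copy()
    log_rows = []
    for (region, method, ref), idx in df.groupby(["region", "method", "reference_region"]).groups.items():
        vals = df.loc[idx, "value"].to_numpy()
        if vals.size < 3:
            continue
        mask = mad_outliers(vals, k=k)
        if mask.any():
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            for pos, flagged in zip(idx, mask):
                if flagged:
                    df.loc[pos, "excluded"] = True
                    log_rows.append(
                        {
                            "subject_id": df.loc[pos, "subject_id"],
                            "scan_id": df.loc[pos, "scan_id"],
                            "region": region,
                            "method": method,
                            "reference_region": ref,
                            "value": df.loc[pos, "value"],
                            "group_median": med,
                            "group_mad": mad,
                        }
                    )
    log = pd.DataFrame(
        log_rows,
        columns=[
            "subject_id",
            "scan_id",
            "region",
            "method",
            "reference_region",
            "value",
            "group_median",
            "group_mad",
        ],
    )
    return ParameterTable(df), log


def build_comparison_report(
    parameter_tables: "ParameterTable | list[ParameterTable]",
    metadata: pd.DataFrame,
    config: ReportConfig | None = None,
) -> ComparisonReport:
    """Run the full comparison battery on quantified cohorts.

    ``metadata`` holds one row per scan: subject_id, scan_id, scan_role,
    and optionally visual_status and followup_years.  MAD outlier exclusion
    is applied first within each region x method x reference group; all
    downstream analyses use included rows only.
    """
    cfg = config or ReportConfig()
    if isinstance(parameter_tables, list):
        table = ParameterTable.concat(parameter_tables)
    else:
        table = parameter_tables
    table, exclusions = apply_mad_exclusion(table, k=cfg.mad_multiplier)
    df = table.included().merge(
        metadata, on=["subject_id", "scan_id"], how="left", validate="many_to_one"
    )
    report = ComparisonReport(exclusions=exclusions)

    report.trt = _trt_section(df, cfg)
    report.agreement, report.bland_altman = _agreement_section(df, cfg)
    report.stability = _stability_section(df, cfg)
    report.annual_change, report.model_selection = _longitudinal_section(df, cfg)
    report.discrimination = _discrimination_section(df, cfg)
    return report


def _trt_section(df: pd.DataFrame, cfg: ReportConfig) -> pd.DataFrame:
    comp = df[(df["region"] == cfg.composite_region) & df["scan_role"].isin(["test", "retest"])]
    rows = []
    for (method, ref), grp in comp.groupby(["method", "reference_region"]):
        wide = grp.pivot_table(index="subject_id", columns="scan_role", values="value")
        if not {"test", "retest"} <= set(wide.columns):
            continue
        wide = wide.dropna(subset=["test", "retest"])
        if wide.empty:
            continue
        var = [trt_variability(t, r) for t, r in zip(wide["test"], wide["retest"])]
        rows.append(
            {
                "method": method,
                "reference_region": ref,
                "mean_trt_pct": float(np.mean(var)),
                "sd_trt_pct": float(np.std(var, ddof=1)) if len(var) > 1 else 0.0,
                "median_trt_pct": float(np.median(var)),
                "max_trt_pct": float(np.max(var)),
                "n": len(var),
            }
        )
    return pd.DataFrame(rows)


def _agreement_section(df: pd.DataFrame, cfg: ReportConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    scans = df[df["scan_role"] == "test"]
    if scans.empty:
        scans = df[df["scan_role"] == "baseline"]
    if cfg.agreement_on_regional:
        scans = scans[
            (scans["region"] != cfg.composite_region)
            & ~scans["region"].isin(cfg.reference_regions)
        ]
    else:
        scans = scans[scans["region"] == cfg.composite_region]
    gold = scans[
        (scans["method"] == cfg.gold_method)
        & (scans["reference_region"] == cfg.gold_reference)
    ][["subject_id", "scan_id", "region", "value"]].rename(columns={"value": "gold"})
    agree_rows, ba_rows = [], []
    for (method, ref), grp in scans.groupby(["method", "reference_region"]):
        if method == cfg.gold_method and ref == cfg.gold_reference:
            continue
        if method not in cfg.ratio_methods and method != cfg.gold_method:
            continue
        merged = grp.merge(gold, on=["subject_id", "scan_id", "region"], how="inner")
        if len(merged) < 3:
            continue
        ag = agreement_regression(merged["gold"], merged["value"])
        ba = bland_altman(merged["gold"], merged["value"])
        agree_rows.append(
            {
                "method": method,
                "reference_region": ref,
                "r": ag.r,
                "slope": ag.slope,
                "intercept": ag.intercept,
                "n": ag.n,
            }
        )
        ba_rows.append(
            {
                "method": method,
                "reference_region": ref,
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "trend_slope": ba.trend_slope,
                "trend_intercept": ba.trend_intercept,
                "n": ba.n,
            }
        )
    return pd.DataFrame(agree_rows), pd.DataFrame(ba_rows)


def _stability_section(df: pd.DataFrame, cfg: ReportConfig) -> pd.DataFrame:
    suv = df[
        df["method"].isin(cfg.suv_methods)
        & df["region"].isin(cfg.reference_regions)
        & df["scan_role"].isin(["baseline", "followup"])
    ]
    rows = []
    for method in cfg.suv_methods:
        sub = suv[suv["method"] == method]
        raw = []
        for region, grp in sub.groupby("region"):
            wide = grp.pivot_table(index="subject_id", columns="scan_role", values="value")
            if not {"baseline", "followup"} <= set(wide.columns):
                continue
            wide = wide.dropna(subset=["baseline", "followup"])
            years = (
                grp[grp["scan_role"] == "followup"]
                .set_index("subject_id")["followup_years"]
                .reindex(wide.index)
            )
            ok = years.notna() & (years > 0)
            wide, years = wide[ok], years[ok]
            if len(wide) < 2:
                continue
            fu_std = [
                standardize_followup(bl, fu, yr, cfg.target_years)
                for bl, fu, yr in zip(wide["baseline"], wide["followup"], years)
            ]
            t, p = paired_t_test(wide["baseline"].to_numpy(), np.asarray(fu_std))
            raw.append(
                {
                    "method": method,
                    "region": region,
                    "mean_baseline": float(wide["baseline"].mean()),
                    "mean_followup_std": float(np.mean(fu_std)),
                    "t": t,
                    "p": p,
                    "n": len(wide),
                }
            )
        if raw:
            padj = bonferroni_adjust([r["p"] for r in raw], m=cfg.stability_family)
            for r, pa in zip(raw, padj):
                r["p_adjusted"] = float(pa)
            rows.extend(raw)
    return pd.DataFrame(rows)


def _longitudinal_section(df: pd.DataFrame, cfg: ReportConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    comp = df[
        (df["region"] == cfg.composite_region)
        & df["method"].isin(cfg.ratio_methods)
        & df["scan_role"].isin(["baseline", "followup"])
    ]
    change_rows, model_rows = [], []
    for (method, ref), grp in comp.groupby(["method", "reference_region"]):
        wide = grp.pivot_table(index="subject_id", columns="scan_role", values="value")
        if not {"baseline", "followup"} <= set(wide.columns):
            continue
        wide = wide.dropna(subset=["baseline", "followup"])
        years = (
            grp[grp["scan_role"] == "followup"]
            .set_index("subject_id")["followup_years"]
            .reindex(wide.index)
        )
        ok = years.notna() & (years > 0)
        wide, years = wide[ok], years[ok]
        if len(wide) < 4:
            continue
        apc = np.array(
            [
                annual_percent_change(bl, fu, yr)
                for bl, fu, yr in zip(wide["baseline"], wide["followup"], years)
            ]
        )
        for subj, bl, a in zip(wide.index, wide["baseline"], apc):
            change_rows.append(
                {
                    "method": method,
                    "reference_region": ref,
                    "subject_id": subj,
                    "baseline": float(bl),
                    "annual_pct_change": float(a),
                }
            )
        mc = fit_linear_quadratic_aic(wide["baseline"].to_numpy(), apc)
        model_rows.append(
            {
                "method": method,
                "reference_region": ref,
                "aic_linear": mc.aic_linear,
                "aic_quadratic": mc.aic_quadratic,
                "delta_aic": mc.delta_aic,
                "preferred": mc.preferred,
                "n": mc.n,
            }
        )
    return pd.DataFrame(change_rows), pd.DataFrame(model_rows)


def _stable_subjects(meta: pd.DataFrame) -> set[str]:
    stable = set()
    for subj, grp in meta.groupby("subject_id"):
        statuses = set(grp["visual_status"].dropna())
        if len(statuses) == 1:
            stable.add(subj)
    return stable


def _discrimination_section(df: pd.DataFrame, cfg: ReportConfig) -> pd.DataFrame:
    comp = df[(df["region"] == cfg.composite_region) & df["method"].isin(cfg.ratio_methods)]
    if comp.empty or "visual_status" not in comp.columns:
        return pd.DataFrame()
    meta = comp[["subject_id", "scan_id", "visual_status"]].drop_duplicates()
    stable = _stable_subjects(meta)
    comp = comp[comp["subject_id"].isin(stable) & comp["visual_status"].notna()]
    raw = []
    for (method, ref), grp in comp.groupby(["method", "reference_region"]):
        neg = grp[grp["visual_status"] == "negative"]["value"].to_numpy()
        pos = grp[grp["visual_status"] == "positive"]["value"].to_numpy()
        if neg.size == 0 or pos.size == 0:
            continue
        u, p = mann_whitney_u(neg, pos)
        hl = hodges_lehmann(neg, pos)  # negative first: effect sizes come out < 0
        raw.append(
            {
                "method": method,
                "reference_region": ref,
                "u_statistic": u,
                "p": p,
                "hodges_lehmann": hl,
                "n_negative": int(neg.size),
                "n_positive": int(pos.size),
            }
        )
    if not raw:
        return pd.DataFrame()
    padj = bonferroni_adjust([r["p"] for r in raw], m=cfg.discrimination_family)
    for r, pa in zip(raw, padj):
        r["p_adjusted"] = float(pa)
    return pd.DataFrame(raw)
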