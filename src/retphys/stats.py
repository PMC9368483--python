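"""Cohort statistics: group comparisons, correlations, post-hoc power.

Two-group contrasts use unpaired two-tailed Student (pooled-variance) t-tests;
associations use Pearson correlation.  Post-hoc power follows the standard
conventions of dedicated power software:

* two-sample t: effect size ``d = |m1 - m2| / s_pooled``, noncentrality
  ``delta = d * sqrt(n1*n2/(n1+n2))``, power from the noncentral t
  distribution against the two-sided critical value;
* correlation: power is the probability that the sample correlation of a
  bivariate normal with true ``rho`` exceeds the two-sided critical ``r``.
  The default "exact" method integrates the exact (Hotelling) density of the
  sample correlation coefficient; a bias-corrected Fisher-z approximation is
  available as an alternative.

Normality can be checked with Shapiro-Wilk as an advisory only — it never
gates a test.  No multiple-testing correction is applied; the report records
the number of tests performed instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "PowerResult",
    "CohortStatsReport",
    "two_sample_ttest",
    "pearson_correlation",
    "power_two_sample_t",
    "power_correlation",
    "build_report",
]

#: metrics summarized/tested in the standard report, with display units
REPORT_METRICS: dict[str, str] = {
    "d_a_um": "um",
    "d_v_um": "um",
    "v_v_mm_s": "mm/s",
    "trbf_ul_min": "uL/min",
    "o2a_ml_dl": "mLO2/dL",
    "o2v_ml_dl": "mLO2/dL",
    "o2av_ml_dl": "mLO2/dL",
    "do2_nl_min": "nLO2/min",
    "mo2_nl_min": "nLO2/min",
    "oef": "",
    "nfl_rgcl": "um",
    "ipl": "um",
    "inl": "um",
    "opl": "um",
    "onl": "um",
    "prl": "um",
    "trt_oct": "um",
    "abeta42_retina": "pg/mg",
    "abeta40_retina": "pg/mg",
    "abeta42_brain": "pg/mg",
    "abeta40_brain": "pg/mg",
}

#: metrics whose post-hoc two-sample power is reported (measured metrics only)
POWER_METRICS = ("o2a_ml_dl", "o2v_ml_dl", "d_v_um", "v_v_mm_s")


@dataclass(frozen=True)
class GroupSummary:
    metric: str
    group: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class TestResult:
    metric: str
    t: float
    df: int
    p: float
    significant: bool


@dataclass(frozen=True)
class PowerResult:
    design: str  # 'two-sample-t' or 'correlation'
    label: str
    inputs: dict
    alpha: float
    power: float


@dataclass
class CohortStatsReport:
    summaries: list[GroupSummary] = field(default_factory=list)
    tests: list[TestResult] = field(default_factory=list)
    correlations: list[dict] = field(default_factory=list)
    powers: list[PowerResult] = field(default_factory=list)
    normality: list[dict] = field(default_factory=list)
    n_tests: int = 0
    alpha: float = 0.05

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "summaries": [asdict(s) for s in self.summaries],
            "tests": [asdict(t) for t in self.tests],
            "correlations": self.correlations,
            "powers": [asdict(p) for p in self.powers],
            "normality": self.normality,
        }
        return json.dumps(payload, indent=indent)

    def to_text(self) -> str:
        lines = [
            f"Cohort statistics report (alpha = {self.alpha}, {self.n_tests} tests, "
            "no multiplicity correction)",
            "",
            f"{'metric':<16}{'group':<8}{'n':>4}{'mean':>10}{'sd':>9}",
        ]
        for s in self.summaries:
            lines.append(
                f"{s.metric:<16}{s.group:<8}{s.n:>4}{s.mean:>10.3f}{s.sd:>9.3f}"
            )
        if self.tests:
            lines += ["", f"{'metric':<16}{'t':>8}{'df':>5}{'p':>9}  sig"]
            for t in self.tests:
                flag = "*" if t.significant else ""
                lines.append(f"{t.metric:<16}{t.t:>8.3f}{t.df:>5}{t.p:>9.4f}  {flag}")
        if self.correlations:
            lines.append("")
            for c in self.correlations:
                lines.append(
                    f"corr {c['label']}: r = {c['r']:+.3f} (n = {c['n']}, "
                    f"p = {c['p']:.4f})"
                )
        if self.powers:
            lines.append("")
            for p in self.powers:
                lines.append(
                    f"power [{p.design}] {p.label}: {100 * p.power:.0f}%"
                )
        return "\n".join(lines)


def two_sample_ttest(a, b, alpha: float = 0.05, metric: str = "") -> TestResult:
    """Unpaired two-tailed Student t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return TestResult(metric=metric, t=0.0, df=df, p=1.0, significant=False)
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        metric=metric, t=float(t), df=df, p=float(p), significant=bool(p < alpha)
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-tailed p-value (t-distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def power_two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = 0.05,
) -> float:
    """Post-hoc power of the two-sided pooled t-test at the observed effect.

    ``d = |mean1 - mean2| / s_pooled``; ``delta = d * sqrt(n1*n2/(n1+n2))``;
    power = P(|T'| > t_crit) for T' noncentral t with ``n1+n2-2`` df.
    At zero effect this returns exactly ``alpha``.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    d = abs(mean1 - mean2) / sp
    delta = d * math.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta)
    return float(power)


def _sample_r_density(r: float, rho: float, n: int) -> float:
    """Exact density of the sample Pearson r for a bivariate normal (Hotelling)."""
    nu = n - 1
    const = (nu - 1) * special.gamma(nu) / (
        math.sqrt(2 * math.pi) * special.gamma(nu + 0.5)
    )
    body = (
        (1 - rho**2) ** (nu / 2)
        * (1 - r**2) ** ((nu - 3) / 2)
        * (1 - rho * r) ** (-(nu - 0.5))
    )
    return const * body * special.hyp2f1(0.5, 0.5, nu + 0.5, (1 + rho * r) / 2)


def power_correlation(
    rho: float, n: int, alpha: float = 0.05, method: str = "exact"
) -> float:
    """Power to detect a correlation of magnitude ``|rho|``, two-sided.

    The critical sample correlation is ``r_crit = t_crit / sqrt(n-2+t_crit^2)``
    with ``t_crit`` the two-sided Student quantile at ``n-2`` df.

    method='exact' (default)
        Integrates the exact sample-r density over both rejection tails.
    method='fisher-z'
        Bias-corrected Fisher-z approximation: the transformed estimate is
        treated as Normal(atanh(rho) + rho/(2(n-1)), 1/(n-3)) and only the
        dominant tail is counted (the opposite-tail mass is negligible at
        moderate effects).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rho = abs(rho)
    df = n - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    r_crit = t_crit / math.sqrt(df + t_crit**2)
    if method == "exact":
        upper, _ = integrate.quad(_sample_r_density, r_crit, 1.0, args=(rho, n))
        lower, _ = integrate.quad(_sample_r_density, -1.0, -r_crit, args=(rho, n))
        return float(upper + lower)
    if method == "fisher-z":
        if rho == 0.0:
            return float(alpha)
        mu = math.atanh(rho) + rho / (2 * (n - 1))
        z = (math.atanh(r_crit) - mu) * math.sqrt(n - 3)
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown method {method!r}")


def _shapiro_advisory(values: np.ndarray, metric: str, group: str) -> dict:
    stat, p = stats.shapiro(values)
    return {
        "metric": metric,
        "group": group,
        "W": float(stat),
        "p": float(p),
        "advisory": "normality not rejected" if p >= 0.05 else "normality questionable",
    }


def build_report(
    animals: pd.DataFrame,
    alpha: float = 0.05,
    check_normality: bool = False,
) -> CohortStatsReport:
    """Full cohort report from a per-animal metric table.

    ``animals`` needs a ``group`` column; every column of ``REPORT_METRICS``
    present in the table is summarized per group and, when two groups with
    n >= 2 each are present, tested.  The two pooled associations (O2A vs V_V
    and O2A vs NFL/RGCL) and the standard post-hoc powers are appended when
    their inputs are available.  Deterministic given the input table.
    """
    report = CohortStatsReport(alpha=alpha)
    groups = list(dict.fromkeys(animals["group"]))  # stable order
    for metric in REPORT_METRICS:
        if metric not in animals.columns:
            continue
        per_group = {}
        for g in groups:
            vals = animals.loc[animals["group"] == g, metric].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            per_group[g] = vals
            report.summaries.append(
                GroupSummary(
                    metric=metric,
                    group=str(g),
                    n=int(vals.size),
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                )
            )
        if len(per_group) == 2:
            a, b = per_group.values()
            if a.size >= 2 and b.size >= 2:
                report.tests.append(two_sample_ttest(a, b, alpha=alpha, metric=metric))
                if check_normality:
                    for g, vals in per_group.items():
                        if vals.size >= 3:
                            report.normality.append(
                                _shapiro_advisory(vals, metric, str(g))
                            )

    for xcol, ycol, label in (
        ("o2a_ml_dl", "v_v_mm_s", "O2A vs V_V"),
        ("o2a_ml_dl", "nfl_rgcl", "O2A vs NFL/RGCL"),
    ):
        if xcol in animals.columns and ycol in animals.columns:
            paired = animals[[xcol, ycol]].dropna()
            if len(paired) >= 4:
                r, p = pearson_correlation(paired[xcol], paired[ycol])
                report.correlations.append(
                    {"label": label, "r": r, "p": p, "n": int(len(paired))}
                )
                report.powers.append(
                    PowerResult(
                        design="correlation",
                        label=label,
                        inputs={"rho": r, "n": int(len(paired))},
                        alpha=alpha,
                        power=power_correlation(r, len(paired), alpha=alpha),
                    )
                )

    if len(groups) == 2:
        for metric in POWER_METRICS:
            rows = [s for s in report.summaries if s.metric == metric]
            if len(rows) == 2 and all(s.sd > 0 and s.n >= 2 for s in rows):
                s1, s2 = rows
                report.powers.append(
                    PowerResult(
                        design="two-sample-t",
                        label=metric,
                        inputs={
                            "mean1": s1.mean, "sd1": s1.sd, "n1": s1.n,
                            "mean2": s2.mean, "sd2": s2.sd, "n2": s2.n,
                        },
                        alpha=alpha,
                        power=power_two_sample_t(
                            s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, alpha=alpha
                        ),
                    )
                )

    report.n_tests = len(report.tests) + len(report.correlations)
    return report
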