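"""Paired-measurement repeatability statistics.

Implements the battery used to compare two processings of the same studies:
Spearman rank correlation, Bland–Altman agreement (mean difference and 1.96-SD
limits of agreement), the SD of pairwise percentage differences as a precision
metric, F-tests on SDs, paired t-tests, and Fisher-z tests for comparing
correlation coefficients between independent groups and between dependent
(same-subject) measurement pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "AgreementSummary",
    "RepeatabilityReport",
    "build_report",
    "spearman_r",
    "bland_altman",
    "sd_percent_diff",
    "fisher_z_independent",
    "fisher_z_dependent",
    "f_test_sd",
    "paired_t",
    "agreement_summary",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two measurements of the same quantity on the same subjects."""

    a: np.ndarray
    b: np.ndarray
    labels: tuple[str, ...] = ()
    tag: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D arrays")
        if a.size < 3:
            raise ValueError("paired series needs at least 3 observations")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series must be finite")


@dataclass
class AgreementSummary:
    """Correlation, agreement and precision of one paired comparison."""

    n: int
    r_spearman: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    sd_percent_diff: float
    normal_diff: bool | None = None  # Shapiro-Wilk screen of the differences
    tag: str = ""

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "r_spearman": self.r_spearman,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "sd_percent_diff": self.sd_percent_diff,
            "normal_diff": self.normal_diff,
            "tag": self.tag,
        }


def spearman_r(a, b) -> float:
    """Spearman rank correlation (mid-rank ties); NaN-flagged on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(sps.spearmanr(a, b).statistic)


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """Mean difference, sample SD (n-1) and 1.96-SD limits of agreement.

    Differences are ``a - b``; returns ``(mean, sd, loa_low, loa_high)``.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, sd, mean - 1.96 * sd, mean + 1.96 * sd


def sd_percent_diff(a, b) -> float:
    """Sample SD of the pairwise percentage differences.

    Each element contributes ``100 * (a_i - b_i) / ((a_i + b_i) / 2)``;
    pairs with non-positive mean are excluded (flagged degenerate for this
    ratio-scale metric).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = 0.5 * (a + b)
    ok = m > 0
    if ok.sum() < 3:
        raise ValueError("fewer than 3 pairs with positive pair-mean")
    pct = 100.0 * (a[ok] - b[ok]) / m[ok]
    return float(np.std(pct, ddof=1))


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def fisher_z_independent(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two correlations from independent samples.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided standard-normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("group sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(z), _two_sided_normal_p(float(z))


def fisher_z_dependent(
    r1: float, r2: float, r12: float, n: int
) -> tuple[float, float]:
    """Compare two dependent correlations that share no variable.

    ``r1 = corr(A1, B1)`` and ``r2 = corr(A2, B2)`` are measured on the same
    subjects; ``r12`` is the correlation between the two measurement
    occasions (assumed common to both measures, with the cross-occasion
    cross-measure correlations imputed as ``r_bar * r12``).  A Steiger-type
    test: the Pearson–Filon covariance of the two correlations is converted
    to a covariance of Fisher z's, giving

    ``z = (atanh(r1) - atanh(r2)) * sqrt((n-3) / (2 - 2*c))``.

    The implied 4x4 correlation matrix must be positive definite.  At
    ``r12 = 0`` this reduces to the independent-samples test with equal n.
    """
    for r in (r1, r2, r12):
        if not np.isfinite(r) or abs(r) >= 1.0:
            raise ValueError("correlations must be finite with |r| < 1")
    if n <= 3:
        raise ValueError("n must exceed 3")

    rbar = 0.5 * (r1 + r2)
    cross = rbar * r12  # corr(A1,B2) and corr(A2,B1)
    # variables ordered (A1, B1, A2, B2)
    m = np.array(
        [
            [1.0, r1, r12, cross],
            [r1, 1.0, cross, r12],
            [r12, cross, 1.0, r2],
            [cross, r12, r2, 1.0],
        ]
    )
    if np.linalg.eigvalsh(m)[0] <= 1e-10:
        raise ValueError("correlation triple implies a non-positive-definite matrix")

    # Pearson-Filon covariance of r1 = r_jk (j,k)=(A1,B1) and r2 = r_hm (h,m)=(A2,B2)
    p_jh = p_km = r12
    p_jm = p_kh = cross
    psi = 0.5 * (
        (p_jh - r1 * p_kh) * (p_km - p_kh * r2)
        + (p_jm - p_jh * r2) * (p_kh - r1 * p_jh)
        + (p_jh - p_jm * r2) * (p_km - r1 * p_jm)
        + (p_jm - r1 * p_km) * (p_kh - p_km * r2)
    )
    c = psi / ((1.0 - r1**2) * (1.0 - r2**2))
    c = float(np.clip(c, -0.999999, 0.999999))
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    return float(z), _two_sided_normal_p(float(z))


def f_test_sd(sd1: float, n1: int, sd2: float, n2: int) -> tuple[float, float]:
    """Two-sided F-test comparing two standard deviations.

    ``F = sd1^2 / sd2^2`` with ``(n1-1, n2-1)`` degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    f = (sd1 / sd2) ** 2
    cdf = sps.f.cdf(f, n1 - 1, n2 - 1)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return float(f), min(p, 1.0)


def paired_t(a, b) -> tuple[float, float]:
    """Paired-samples t-test on the differences ``a - b``.

    Zero-variance differences (including ``a == b``) are reported as
    ``t = 0, p = 1`` rather than the undefined 0/0 statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return 0.0, 1.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def agreement_summary(series: PairedSeries) -> AgreementSummary:
    """Full agreement panel for one paired comparison.

    Shapiro–Wilk on the differences annotates whether a Bland–Altman
    treatment (which presumes roughly normal differences) is appropriate.
    """
    mean, sd, lo, hi = bland_altman(series.a, series.b)
    d = series.a - series.b
    if np.ptp(d) == 0:
        normal = None  # constant differences: normality screen undefined
    else:
        normal = bool(sps.shapiro(d).pvalue > 0.05)
    return AgreementSummary(
        n=series.a.size,
        r_spearman=spearman_r(series.a, series.b),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        sd_percent_diff=sd_percent_diff(series.a, series.b),
        normal_diff=normal,
        tag=series.tag,
    )


# ---------------------------------------------------------------------------
# Full repeatability report
# ---------------------------------------------------------------------------

PARAMETERS = ("stress_mbf", "rest_mbf", "mfr")
REGIONS = ("LAD", "LCx", "RCA", "TOT")
COMPARISONS = ("inter", "intra")  # op1-rep1 vs op2; op1-rep1 vs op1-rep2


@dataclass
class RepeatabilityReport:
    """Agreement grid over model x parameter x region, plus cross-model tests.

    ``cells`` maps ``(model, parameter, region, comparison)`` to an
    :class:`AgreementSummary`; ``model_tests`` maps ``(parameter, region)``
    to the three inter-model comparisons of the inter-operator panel:
    correlation difference (dependent Fisher-z), mean-difference difference
    (paired t on the per-patient differences) and difference-SD ratio
    (F-test).
    """

    models: tuple[str, ...]
    cells: dict = field(default_factory=dict)
    model_tests: dict = field(default_factory=dict)
    n_patients: int = 0

    def summary(self, model: str, parameter: str, region: str,
                comparison: str = "inter") -> AgreementSummary:
        return self.cells[(model, parameter, region, comparison)]

    def r_grid(self, comparison: str = "inter") -> dict:
        return {
            (m, p, g): self.cells[(m, p, g, comparison)].r_spearman
            for m in self.models
            for p in PARAMETERS
            for g in REGIONS
        }


def build_report(measurements: dict) -> RepeatabilityReport:
    """Build the full repeatability report from a measurement grid.

    ``measurements[(model, parameter, region)]`` must hold a mapping with
    per-patient value arrays for the three processings: ``op1_rep1``,
    ``op1_rep2`` and ``op2``.  The grid must be complete over models x
    parameters x regions; a missing cell raises rather than being silently
    dropped.
    """
    models = tuple(dict.fromkeys(m for (m, _, _) in measurements))
    missing = [
        (m, p, g)
        for m in models
        for p in PARAMETERS
        for g in REGIONS
        if (m, p, g) not in measurements
    ]
    if missing:
        raise ValueError(f"measurement grid incomplete; missing cells: {missing}")

    report = RepeatabilityReport(models=models)
    for (m, p, g), runs in measurements.items():
        for key in ("op1_rep1", "op1_rep2", "op2"):
            if key not in runs:
                raise ValueError(f"cell {(m, p, g)} lacks processing '{key}'")
        tag = f"{p} {g}, {m}"
        inter = PairedSeries(a=runs["op1_rep1"], b=runs["op2"], tag=tag)
        intra = PairedSeries(a=runs["op1_rep1"], b=runs["op1_rep2"], tag=tag)
        report.cells[(m, p, g, "inter")] = agreement_summary(inter)
        report.cells[(m, p, g, "intra")] = agreement_summary(intra)
        report.n_patients = inter.a.size

    if len(models) == 2:
        m1, m2 = models
        for p in PARAMETERS:
            for g in REGIONS:
                a1, b1 = measurements[(m1, p, g)]["op1_rep1"], measurements[(m1, p, g)]["op2"]
                a2, b2 = measurements[(m2, p, g)]["op1_rep1"], measurements[(m2, p, g)]["op2"]
                s1 = report.cells[(m1, p, g, "inter")]
                s2 = report.cells[(m2, p, g, "inter")]
                n = s1.n
                # between-measure correlation of the two models, averaged over
                # the two processings; proxies the occasions' dependence
                r12_vals = [
                    r for r in (spearman_r(a1, a2), spearman_r(b1, b2))
                    if np.isfinite(r)
                ]
                r12 = (
                    float(np.clip(np.mean(r12_vals), -0.999, 0.999))
                    if r12_vals
                    else float("nan")
                )
                tests: dict[str, float] = {"r12": r12}
                try:
                    z, p_r = fisher_z_dependent(
                        s1.r_spearman, s2.r_spearman, r12, n
                    )
                    tests.update(z_r=z, p_r=p_r)
                except ValueError:
                    tests.update(z_r=float("nan"), p_r=float("nan"))
                t, p_mean = paired_t(a1 - b1, a2 - b2)
                tests.update(t_mean=t, p_mean=p_mean)
                if s1.sd_diff > 0 and s2.sd_diff > 0:
                    fstat, p_sd = f_test_sd(s1.sd_diff, n, s2.sd_diff, n)
                else:
                    fstat, p_sd = float("nan"), float("nan")
                tests.update(f_sd=fstat, p_sd=p_sd)
                report.model_tests[(p, g)] = tests
    return report
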