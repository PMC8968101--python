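"""Study statistics: normality screening, Pearson correlation with Fisher
confidence interval, categorical agreement (Cohen's kappa), and the cohort
report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import AnimalRecord, analyzable_subset, summarize
from .errors import DegenerateFitError, InsufficientDataError

__all__ = [
    "CorrelationResult",
    "AgreementResult",
    "normality_check",
    "pearson",
    "bin_for_agreement",
    "cohen_kappa",
    "build_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    ci_low: float
    ci_high: float
    ci_level: float
    n: int


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    n_items: int
    n_categories: int


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value; errors on constant or out-of-range n."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise InsufficientDataError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant sequence: normality test undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def pearson(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> CorrelationResult:
    """Product-moment correlation with t-based p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=ci_level)  # Fisher z
    return CorrelationResult(
        r=float(res.statistic),
        p_two_sided=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        ci_level=ci_level,
        n=int(x.size),
    )


def bin_for_agreement(
    values: Sequence[float], edges: Sequence[float] | None = None
) -> np.ndarray:
    """Assign each value to a half-open bin [edge_i, edge_{i+1}).

    With ``edges=None`` the cohort tertiles are used, turning continuous
    readings into the three-level categorisation that kappa requires.
    """
    x = np.asarray(values, dtype=float)
    if edges is None:
        edges = np.quantile(x, [1 / 3, 2 / 3])
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    return np.searchsorted(edges, x, side="right")


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    When both raters are constant and identical (p_e = 1) agreement is
    perfect by construction and kappa is defined as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("label sequences must have equal length")
    if a.size < 2:
        raise InsufficientDataError("need n >= 2 items for kappa")
    cats = np.union1d(a, b)
    k = cats.size
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((k, k))
    for ai, bi in zip(a, b):
        conf[idx[ai], idx[bi]] += 1
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0 if np.array_equal(a, b) else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(kappa=float(kappa), n_items=int(n), n_categories=int(k))


def build_report(
    cohort: Sequence[AnimalRecord],
    correlation: CorrelationResult | None = None,
    agreement: AgreementResult | None = None,
    figures_dir: str | Path | None = None,
) -> str:
    """Markdown cohort report; figures are written when a directory is given.

    Always contains the cohort summary (mean +/- SD for ECV, CmyB and
    covariates); appends the ECV-CmyB correlation (computed from the cohort
    when not supplied) and reader-agreement statistics when available.
    """
    lines = ["# Cohort report", "", "## Cohort summary (mean ± SD)", ""]
    analyzed = analyzable_subset(cohort)
    for var, label, fmt in [
        ("ecv", "ECV", "{:.3f}"),
        ("cmyb_mean", "CmyB (μm)", "{:.2f}"),
        ("hematocrit", "Hematocrit", "{:.3f}"),
        ("body_weight", "Body weight (kg)", "{:.1f}"),
        ("heart_rate", "Heart rate (bpm)", "{:.0f}"),
    ]:
        try:
            s = summarize(cohort, var)
        except InsufficientDataError:
            continue
        lines.append(
            f"- {label}: {fmt.format(s.mean)} ± {fmt.format(s.sd)} (n = {s.n})"
        )
    if correlation is None and len(analyzed) >= 3:
        correlation = pearson(
            [r.ecv for r in analyzed], [r.cmyb_mean for r in analyzed]
        )
    if correlation is not None:
        c = correlation
        lines += [
            "",
            "## ECV vs CmyB correlation",
            "",
            f"- r = {c.r:.3f}, p = {c.p_two_sided:.3f}, n = {c.n}",
            f"- {c.ci_level:.0%} CI [{c.ci_low:.3f}, {c.ci_high:.3f}]",
        ]
    if agreement is not None:
        lines += [
            "",
            "## Reader agreement",
            "",
            f"- Cohen's κ = {agreement.kappa:.3f} "
            f"(n = {agreement.n_items}, {agreement.n_categories} categories)",
        ]
    if figures_dir is not None and correlation is not None and len(analyzed) >= 3:
        _scatter_figure(analyzed, correlation, Path(figures_dir))
        lines += ["", f"Figure: {Path(figures_dir) / 'ecv_vs_cmyb.png'}"]
    return "\n".join(lines) + "\n"


def _scatter_figure(
    analyzed: Sequence[AnimalRecord], corr: CorrelationResult, figures_dir: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures_dir.mkdir(parents=True, exist_ok=True)
    x = np.array([r.cmyb_mean for r in analyzed])
    y = np.array([r.ecv for r in analyzed])
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 100)
    # pointwise CI band of the regression mean
    n = x.size
    resid = y - (slope * x + intercept)
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 * (1 / n + (xs - x.mean()) ** 2 / ((x - x.mean()) ** 2).sum()))
    tcrit = sps.t.ppf(0.975, n - 2)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="tab:blue")
    ax.plot(xs, slope * xs + intercept, color="tab:red")
    ax.fill_between(
        xs, slope * xs + intercept - tcrit * se, slope * xs + intercept + tcrit * se,
        alpha=0.25, color="tab:blue",
    )
    ax.set_xlabel("CmyB (μm)")
    ax.set_ylabel("ECV")
    ax.set_title(f"r = {corr.r:.3f}, p = {corr.p_two_sided:.3f}, n = {corr.n}")
    fig.tight_layout()
    fig.savefig(figures_dir / "ecv_vs_cmyb.png", dpi=120)
    plt.close(fig)
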