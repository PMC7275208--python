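"""Agreement statistics for landmark detection validation.

Per-landmark Euclidean errors are summarised as median (LQ-UQ) because
the error distributions are not normal (checked with Shapiro-Wilk);
method-vs-observer comparisons use the two-sided Wilcoxon signed-rank
test, and coronary-height agreement is quantified with the squared
Pearson correlation and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volumetric_io import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "landmark_errors",
    "summarize_distances",
    "paired_difference_test",
    "bland_altman",
    "correlation_r2",
    "agreement_report",
    "BlandAltman",
    "PairedDifference",
    "AgreementReport",
]

SIGNIFICANCE_LEVEL = 0.05  # reported alongside p-values in generated tables


def landmark_errors(pred: LandmarkSet, truth: LandmarkSet) -> dict[str, float]:
    """Per-class Euclidean distance (mm) between predicted and true landmarks."""
    return {
        name: float(np.linalg.norm(pred[name] - truth[name])) for name in LANDMARK_NAMES
    }


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation (inclusive) quartiles
    lq, med, uq = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return float(lq), float(med), float(uq)


def summarize_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Median (LQ-UQ) per landmark class plus a pooled "All" row.

    ``table`` needs columns ``landmark`` and ``error_mm`` (a ``case``
    column is carried by convention but not required). Each row also
    reports the Shapiro-Wilk normality p-value (NaN when n < 3).
    """
    if len(table) == 0:
        raise ValueError("empty distance table")
    rows = []
    groups = [(name, table.loc[table["landmark"] == name, "error_mm"].to_numpy())
              for name in LANDMARK_NAMES]
    groups = [(name, vals) for name, vals in groups if len(vals)]
    groups.append(("All", table["error_mm"].to_numpy()))
    for name, vals in groups:
        lq, med, uq = _quartiles(vals)
        if len(vals) >= 3 and np.ptp(vals) > 0:
            shapiro_p = float(stats.shapiro(vals).pvalue)
        else:
            shapiro_p = float("nan")
        rows.append(
            {"landmark": name, "n": len(vals), "median_mm": med,
             "lq_mm": lq, "uq_mm": uq, "shapiro_p": shapiro_p}
        )
    return pd.DataFrame(rows)


@dataclass
class PairedDifference:
    """Mean +/- sd of paired differences with a Wilcoxon signed-rank p."""

    mean: float
    sd: float
    p_value: float
    n: int


def _wilcoxon_p(diff: np.ndarray) -> float:
    """Two-sided signed-rank p; zero differences dropped (p=1 if none remain).

    Exact distribution for n <= 25 without ties; otherwise the normal
    approximation with continuity correction.
    """
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 1.0
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    if len(nz) <= 25 and no_ties:
        res = stats.wilcoxon(nz, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(nz, alternative="two-sided", method="approx", correction=True)
    return float(res.pvalue)


def paired_difference_test(d1, d2) -> PairedDifference:
    """Summarise d1 - d2 for matched measurement lists."""
    d1, d2 = np.asarray(d1, float), np.asarray(d2, float)
    if d1.shape != d2.shape:
        raise ValueError(f"length mismatch: {d1.shape} vs {d2.shape}")
    if len(d1) < 5:
        raise ValueError("paired comparison requires at least 5 pairs")
    diff = d1 - d2
    return PairedDifference(
        mean=float(diff.mean()),
        sd=float(diff.std(ddof=1)),
        p_value=_wilcoxon_p(diff),
        n=len(diff),
    )


@dataclass
class BlandAltman:
    """Bland-Altman bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float


def bland_altman(a, b) -> BlandAltman:
    """Bias = mean(a - b); limits of agreement = bias +/- 1.96 * sd(a - b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd)


def correlation_r2(a, b) -> float:
    """Squared Pearson correlation of two matched scalar lists."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


@dataclass
class AgreementReport:
    """Full agreement summary between two matched measurement series."""

    paired: PairedDifference
    r2: float
    bland_altman: BlandAltman


def agreement_report(a, b) -> AgreementReport:
    """Paired difference, Pearson r^2, and Bland-Altman agreement of a vs b."""
    return AgreementReport(
        paired=paired_difference_test(a, b),
        r2=correlation_r2(a, b),
        bland_altman=bland_altman(a, b),
    )


def distance_comparison_table(d1_table: pd.DataFrame, d2_table: pd.DataFrame) -> pd.DataFrame:
    """Per-class comparison of two error tables (method vs observer style).

    Both inputs need columns ``case``, ``landmark``, ``error_mm`` over the
    same cases. Output rows (per class plus pooled): median/LQ/UQ of both,
    mean +/- sd of the paired difference d1 - d2 and its Wilcoxon p.
    """
    merged = d1_table.merge(d2_table, on=["case", "landmark"], suffixes=("_1", "_2"))
    if len(merged) == 0:
        raise ValueError("no matching (case, landmark) pairs")
    rows = []
    for name in (*LANDMARK_NAMES, "All"):
        sub = merged if name == "All" else merged[merged["landmark"] == name]
        if len(sub) == 0:
            continue
        e1 = sub["error_mm_1"].to_numpy()
        e2 = sub["error_mm_2"].to_numpy()
        lq1, med1, uq1 = _quartiles(e1)
        lq2, med2, uq2 = _quartiles(e2)
        pd_ = paired_difference_test(e1, e2)
        rows.append(
            {"landmark": name, "n": len(sub),
             "d1_median_mm": med1, "d1_lq_mm": lq1, "d1_uq_mm": uq1,
             "d2_median_mm": med2, "d2_lq_mm": lq2, "d2_uq_mm": uq2,
             "paired_diff_mean_mm": pd_.mean, "paired_diff_sd_mm": pd_.sd,
             "p_value": pd_.p_value}
        )
    return pd.DataFrame(rows)


def bland_altman_plot(a, b, path, title: str = "Bland-Altman") -> None:
    """Write a Bland-Altman scatter (mean vs difference) with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = np.asarray(a, float), np.asarray(b, float)
    ba = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods (mm)")
    ax.set_ylabel("difference (mm)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
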