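"""Reproducibility statistics over repeated acquisitions.

Three estimators quantify how well a scar measure agrees between repeated
acquisitions of the same subjects:

* **WCV** — within-subject coefficient of variation by the root-mean-square
  method: ``sqrt(mean_i(s_i^2 / m_i^2))`` over subjects ``i`` with
  within-subject sample SD ``s_i`` and mean ``m_i``.  For ratio-scale
  measures under identical acquisition parameters.
* **ICC** — single-rater intraclass correlation from a two-way model in the
  McGraw-Wong convention: ICC(C,1) for consistency and ICC(A,1) for absolute
  agreement, computed from ANOVA mean squares.  Used when acquisition
  parameters differ, and for face-by-face shell comparisons.
* **Bland-Altman** — mean bias of paired differences with 95% limits of
  agreement (bias ± 1.96 · sample SD of the differences).

Within-subject SDs and Bland-Altman SDs use the sample convention
(divisor k−1); image-ROI statistics elsewhere use the population convention.
Negative ICCs are reported as computed, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonPanel",
    "ReproReport",
    "wcv",
    "icc",
    "bland_altman",
    "interpret_icc",
    "pairwise_report",
]


@dataclass
class ComparisonPanel:
    """Targets × raters measurement matrix.

    Targets are subjects (scalar metrics) or mesh faces (point-by-point shell
    comparisons); raters are acquisitions.  Rows containing NaN are removed
    (listwise deletion) with the count recorded in ``n_deleted``.
    """

    values: np.ndarray
    rater_labels: list = field(default_factory=list)
    n_deleted: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("panel must be 2-D (targets x raters)")
        keep = np.all(np.isfinite(v), axis=1)
        self.n_deleted = int((~keep).sum())
        if self.n_deleted:
            warnings.warn(
                f"listwise deletion removed {self.n_deleted} incomplete targets",
                stacklevel=2,
            )
        self.values = v[keep]
        n, k = self.values.shape
        if k < 2:
            raise ValueError("panel needs k >= 2 raters")
        if n < 2:
            raise ValueError("panel needs n >= 2 targets")
        if not self.rater_labels:
            self.rater_labels = [f"rater_{i}" for i in range(k)]


@dataclass
class ReproReport:
    """Summary of one comparison cell."""

    label: str
    n: int
    k: int
    icc_consistency: float
    icc_agreement: float
    wcv: float | None
    bias: float | None
    loa_low: float | None
    loa_high: float | None

    @property
    def interpretation(self) -> str:
        return interpret_icc(self.icc_agreement)


def interpret_icc(value: float) -> str:
    """Agreement bands: 0.41-0.60 moderate, 0.61-0.80 good, >0.81 excellent."""
    if not np.isfinite(value):
        return "n/a"
    if value > 0.81:
        return "excellent"
    if value > 0.60:
        return "good"
    if value >= 0.41:
        return "moderate"
    return "poor"


def _as_values(panel) -> np.ndarray:
    if isinstance(panel, ComparisonPanel):
        return panel.values
    return ComparisonPanel(values=np.asarray(panel, dtype=np.float64)).values


def wcv(panel) -> float:
    """Root-mean-square within-subject coefficient of variation.

    Each row is one subject's k >= 2 replicate measurements on a ratio scale.
    """
    v = _as_values(panel)
    if np.any(v < 0):
        raise ValueError("WCV requires non-negative ratio-scale measurements")
    m = v.mean(axis=1)
    if np.any(m == 0):
        raise ValueError("WCV undefined for a subject with zero mean")
    s = v.std(axis=1, ddof=1)
    return float(np.sqrt(np.mean(s**2 / m**2)))


def icc(panel, form: str = "agreement") -> float:
    """Single-rater two-way ICC from ANOVA mean squares.

    ``form='consistency'`` gives ICC(C,1) = (MSR-MSE) / (MSR+(k-1)MSE);
    ``form='agreement'`` gives ICC(A,1), which additionally charges the
    rater (column) variance: (MSR-MSE) / (MSR+(k-1)MSE + (k/n)(MSC-MSE)).
    """
    v = _as_values(panel)
    n, k = v.shape
    grand = v.mean()
    ss_total = ((v - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("degenerate panel: zero total variance")
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    if form == "agreement":
        return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))
    raise ValueError(f"unknown ICC form {form!r}")


def bland_altman(a, b) -> tuple[float, float, float]:
    """Mean bias of a-b and 95% limits of agreement (bias ± 1.96·SD)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D measurements of equal length required")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def plot_bland_altman(a, b, path, title: str = "") -> None:
    """Write a Bland-Altman plot (mean vs difference with bias/LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    bias, lo, hi = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, color="k", s=18)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="red", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pairwise_report(
    acquisitions: dict,
    scheme: list,
    ratio_scale: bool = True,
) -> pd.DataFrame:
    """Reproducibility table over a set of acquisition comparisons.

    ``acquisitions`` maps an acquisition tag to a 1-D measurement vector over
    common targets (subjects, or faces of the identical shell).  ``scheme``
    lists comparisons as tuples of tags, e.g. ``[("2", "5"), ("2", "3", "5",
    "6")]``; a tuple of k tags forms an n × k panel.  WCV and Bland-Altman
    summaries are reported for two-way comparisons on a ratio scale.
    """
    lengths = {len(np.asarray(v)) for v in acquisitions.values()}
    if len(lengths) != 1:
        raise ValueError("not a common shell: acquisitions differ in length")
    rows = []
    for tags in scheme:
        missing = [t for t in tags if t not in acquisitions]
        if missing:
            warnings.warn(f"comparison {tags}: missing acquisitions {missing}", stacklevel=2)
            continue
        mat = np.column_stack([np.asarray(acquisitions[t], dtype=np.float64) for t in tags])
        panel = ComparisonPanel(values=mat, rater_labels=list(tags))
        label = "C_" + ",".join(str(t) for t in tags)
        w = bias = lo = hi = None
        if len(tags) == 2:
            a, b = panel.values[:, 0], panel.values[:, 1]
            bias, lo, hi = bland_altman(a, b)
            if ratio_scale and np.all(panel.values >= 0) and np.all(
                panel.values.mean(axis=1) > 0
            ):
                w = wcv(panel)
        try:
            icc_c = icc(panel, "consistency")
            icc_a = icc(panel, "agreement")
        except ValueError as exc:
            warnings.warn(f"comparison {label}: {exc}", stacklevel=2)
            icc_c = icc_a = np.nan
        rows.append(
            ReproReport(
                label=label,
                n=panel.values.shape[0],
                k=panel.values.shape[1],
                icc_consistency=icc_c,
                icc_agreement=icc_a,
                wcv=w,
                bias=bias,
                loa_low=lo,
                loa_high=hi,
            )
        )
    return pd.DataFrame(
        [
            {
                "comparison": r.label,
                "n": r.n,
                "k": r.k,
                "icc_consistency": r.icc_consistency,
                "icc_agreement": r.icc_agreement,
                "interpretation": r.interpretation,
                "wcv": r.wcv,
                "bias": r.bias,
                "loa_low": r.loa_low,
                "loa_high": r.loa_high,
            }
            for r in rows
        ]
    )
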