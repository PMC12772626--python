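"""Distribution summaries and pose comparisons.

Gaussian kernel density estimates (Scott's-rule bandwidth) summarize
projected-field distributions; alignment summaries operationalize "how well
is the field aligned with the axis" as the positive-projection fraction, the
mean direction cosine and the modal mass of a 20-bin cosine histogram; and
Welch two-sample t-tests (unequal variances, Welch-Satterthwaite degrees of
freedom) compare descriptors across substrate poses. Raw p-values are
reported by default; a Holm step-down adjustment is optional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .electrostatics import ProjectionSeries
from .exceptions import ConfigurationError, DegenerateDistributionError

__all__ = [
    "KDEResult",
    "AlignmentSummary",
    "TestResult",
    "gaussian_kde",
    "alignment_summary",
    "welch_t_test",
    "pose_comparison_table",
]


@dataclass
class KDEResult:
    """Kernel density estimate on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))


@dataclass
class AlignmentSummary:
    """How well the field aligns with a probe axis over an ensemble."""

    pose_label: str
    fraction_positive: float
    mean_cosine: float
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_bin: int
    modal_mass: float
    n_frames: int


@dataclass
class TestResult:
    """Welch two-sample t-test result."""

    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def gaussian_kde(
    samples: np.ndarray,
    bandwidth: float | None = None,
    n_grid: int = 512,
) -> KDEResult:
    """Gaussian KDE with Scott's-rule bandwidth h = sigma_hat n^(-1/5).

    The density is evaluated on ``n_grid`` points spanning
    ``[min - 3h, max + 3h]``. An explicit ``bandwidth`` (same units as the
    data) overrides Scott's rule.
    """
    x = np.asarray(samples, float)
    if x.ndim != 1 or x.size < 2:
        raise ConfigurationError("KDE needs a 1-D sample with n >= 2")
    sd = x.std(ddof=1)
    if x.max() == x.min() or sd == 0:
        raise DegenerateDistributionError(
            "sample has zero variance; use a histogram (or a point mass) "
            "instead of a KDE"
        )
    if bandwidth is None:
        kde = sps.gaussian_kde(x, bw_method="scott")
        h = float(kde.factor * sd)
    else:
        if bandwidth <= 0:
            raise ConfigurationError("bandwidth must be > 0")
        h = float(bandwidth)
        kde = sps.gaussian_kde(x, bw_method=h / sd)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    return KDEResult(grid=grid, density=kde(grid), bandwidth=h)


def alignment_summary(
    series: ProjectionSeries, n_bins: int = 20
) -> AlignmentSummary:
    """Summarize field/axis alignment for one pose.

    ``fraction_positive`` is the share of frames whose projection is > 0
    (positive = field co-aligned with the axis); the cosine histogram has
    ``n_bins`` equal bins on [-1, 1] and the modal bin's probability mass is
    reported as a "degree of alignment" statistic.
    """
    proj = np.asarray(series.projections, float)
    if proj.size == 0:
        raise ConfigurationError("empty projection series")
    cos = np.asarray(series.cosines, float)
    finite = cos[np.isfinite(cos)]
    counts, edges = np.histogram(finite, bins=n_bins, range=(-1.0, 1.0))
    modal = int(np.argmax(counts))
    n = proj.size
    return AlignmentSummary(
        pose_label=series.pose_label,
        fraction_positive=float((proj > 0).mean()),
        mean_cosine=float(finite.mean()) if finite.size else float("nan"),
        bin_edges=edges,
        counts=counts,
        modal_bin=modal,
        modal_mass=float(counts[modal] / counts.sum()) if counts.sum() else 0.0,
        n_frames=n,
    )


def welch_t_test(sample_a: np.ndarray, sample_b: np.ndarray) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degenerate contracts: when both samples have zero variance, p = 1 if the
    means are equal and p = 0 (flagged) otherwise.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal = a.mean() == b.mean()
        return TestResult(
            statistic=0.0 if equal else np.inf * np.sign(a.mean() - b.mean()),
            df=float(a.size + b.size - 2),
            p_value=1.0 if equal else 0.0,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            n_a=a.size,
            n_b=b.size,
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=a.size,
        n_b=b.size,
    )


def pose_comparison_table(
    series_by_pose: dict[str, dict[str, np.ndarray]],
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise Welch tests per descriptor across poses.

    ``series_by_pose`` maps descriptor name -> pose label -> per-frame
    values. Raw p-values are reported; ``holm=True`` adds a Holm-adjusted
    column (within each descriptor).
    """
    rows = []
    for descriptor, poses in series_by_pose.items():
        if len(poses) < 2:
            raise ConfigurationError(
                f"descriptor {descriptor!r}: need >= 2 poses to compare"
            )
        for pa, pb in itertools.combinations(sorted(poses), 2):
            r = welch_t_test(poses[pa], poses[pb])
            rows.append(
                {
                    "descriptor": descriptor,
                    "pose_a": pa,
                    "pose_b": pb,
                    "mean_a": r.mean_a,
                    "mean_b": r.mean_b,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "t": r.statistic,
                    "df": r.df,
                    "p": r.p_value,
                }
            )
    df = pd.DataFrame(rows)
    if holm and not df.empty:
        from statsmodels.stats.multitest import multipletests

        adjusted = np.empty(len(df))
        for descriptor, group in df.groupby("descriptor", sort=False):
            adjusted[group.index] = multipletests(
                group["p"].to_numpy(), method="holm"
            )[1]
        df["p_holm"] = adjusted
    return df
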