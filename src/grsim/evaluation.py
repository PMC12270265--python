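"""Comparison battery for score sets and genotype matrices: bootstrap
distribution summaries, ROC/AUC, and two-component PCA projections."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .errors import ValidationError
from .sumstats import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryReport:
    """Sample statistics of a score vector with percentile-bootstrap CIs."""

    mean: float
    sd: float
    median: float
    ci_mean: tuple[float, float]
    ci_sd: tuple[float, float]
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "ci_mean": list(self.ci_mean),
            "ci_sd": list(self.ci_sd),
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def summarize_scores(scores, n_boot: int = 1000, seed: int = 0) -> SummaryReport:
    """Mean/SD (n-1 denominator)/median with 2.5-97.5 percentile bootstrap
    confidence intervals over ``n_boot`` resamples; deterministic given seed."""
    x = np.asarray(scores, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValidationError(f"need at least 2 scores, got {n}")
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    resamples = x[idx]
    boot_means = resamples.mean(axis=1)
    boot_sds = resamples.std(axis=1, ddof=1)
    ci_mean = np.percentile(boot_means, [2.5, 97.5])
    ci_sd = np.percentile(boot_sds, [2.5, 97.5])
    return SummaryReport(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        ci_mean=(float(ci_mean[0]), float(ci_mean[1])),
        ci_sd=(float(ci_sd[0]), float(ci_sd[1])),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


def roc_auc(case_scores, control_scores) -> tuple[list[tuple[float, float]], float]:
    """ROC curve over all distinct thresholds and its trapezoidal area.

    The area equals the Mann-Whitney U statistic divided by
    ``n_case * n_control`` (ties counted 1/2): the probability that a random
    case outscores a random control.
    """
    cases = np.asarray(case_scores, dtype=float).ravel()
    controls = np.asarray(control_scores, dtype=float).ravel()
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("case and control score vectors must be nonempty")
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    s = np.concatenate([cases, controls])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _fit_pca2(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center (no variance scaling) and return (mean, 2 x p components).

    Each component is oriented so its largest-magnitude loading is positive,
    making the output sign-deterministic.
    """
    mean = M.mean(axis=0)
    centered = M - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:2].copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return mean, comps


def pca_compare(
    X_a: GenotypeMatrix, X_b: GenotypeMatrix, mode: str = "separate"
) -> tuple[np.ndarray, np.ndarray]:
    """Project both matrices onto their first two principal components.

    ``separate`` fits each matrix independently; ``joint`` fits on the row
    concatenation and projects both with the shared mean and loadings.
    Columns must agree (same SNPs, same order).  Constant columns simply
    contribute zero variance.
    """
    if X_a.snp_ids != X_b.snp_ids:
        raise ValidationError("matrices must share the same SNP columns in order")
    if X_a.n_snps < 2:
        raise ValidationError("need at least 2 SNP columns for a 2-component PCA")
    if mode not in ("separate", "joint"):
        raise ValidationError(f"mode must be 'separate' or 'joint', got {mode!r}")
    A = X_a.values.astype(float)
    B = X_b.values.astype(float)
    if mode == "separate":
        mean_a, comps_a = _fit_pca2(A)
        mean_b, comps_b = _fit_pca2(B)
        return (A - mean_a) @ comps_a.T, (B - mean_b) @ comps_b.T
    mean, comps = _fit_pca2(np.vstack([A, B]))
    return (A - mean) @ comps.T, (B - mean) @ comps.T
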