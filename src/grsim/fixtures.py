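"""Ground-truth correlated genotype arrays for end-to-end testing.

A Gaussian copula over two latent haplotype draws yields dosage columns with
known frequencies and a controllable correlation structure; summary
statistics computed from such a "truth" array provide realistic, internally
consistent targets for the simulator without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import toeplitz
from scipy.stats import norm

from .errors import ValidationError
from .grs import GRSModel, InteractionTerm, LinearTerm
from .simulator import _largest_remainder_counts
from .sumstats import CorrelationTable, GenotypeMatrix, SummaryStats, compute_summary_stats

logger = logging.getLogger(__name__)

#: allele pair assigned to every fixture SNP: the "2" dosage counts 'A'
FIXTURE_ALLELES = ("A", "G")


@dataclass(frozen=True)
class FixtureSnp:
    """One fixture SNP; give frac0/1/2 to force a non-HWE genotype mix."""

    snp_id: str
    freq: float
    frac0: float | None = None
    frac1: float | None = None
    frac2: float | None = None

    @property
    def hwe_deviates(self) -> bool:
        return self.frac0 is not None


@dataclass(frozen=True)
class FixtureSpec:
    n_samples: int
    snps: tuple[FixtureSnp, ...]
    latent_corr: np.ndarray
    seed: int
    grs_model: GRSModel | None = None
    case_shift: float | None = None
    case_snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        R = np.asarray(self.latent_corr, dtype=float)
        object.__setattr__(self, "latent_corr", R)
        p = len(self.snps)
        if R.shape != (p, p):
            raise ValidationError(
                f"latent_corr shape {R.shape} does not match {p} SNPs"
            )
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValidationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValidationError("latent_corr must have unit diagonal")
        for j, snp in enumerate(self.snps):
            off = np.delete(R[j], j)
            if np.any(off != 0) and not (0.0 < snp.freq < 1.0):
                raise ValidationError(
                    f"SNP '{snp.snp_id}': freq must be in (0, 1) when latently "
                    "correlated with another SNP"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def _cholesky_with_jitter(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        pass
    try:
        return np.linalg.cholesky(R + 1e-8 * np.eye(R.shape[0]))
    except np.linalg.LinAlgError:
        raise ValidationError(
            "latent_corr is not positive semi-definite (even after 1e-8 jitter)"
        ) from None


def copula_genotypes(spec: FixtureSpec) -> GenotypeMatrix:
    """Draw a truth dosage matrix from the spec's Gaussian copula.

    Two independent latent multivariate-normal vectors per sample (one per
    chromosome copy) are thresholded at the standard-normal quantile of
    ``1 - freq``, and the dosage is the sum of the two haplotype indicators.
    Non-HWE SNPs are overridden by exact-count columns in random order, which
    intentionally breaks their latent correlation.
    """
    L = _cholesky_with_jitter(spec.latent_corr)
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, len(spec.snps)
    freqs = np.array([s.freq for s in spec.snps])
    cut = norm.ppf(1.0 - freqs)  # P(Z > cut) = freq per haplotype
    hap1 = (rng.standard_normal((n, p)) @ L.T > cut).astype(np.int64)
    hap2 = (rng.standard_normal((n, p)) @ L.T > cut).astype(np.int64)
    values = hap1 + hap2
    for j, snp in enumerate(spec.snps):
        if snp.hwe_deviates:
            counts = _largest_remainder_counts(
                (snp.frac0, snp.frac1, snp.frac2), n
            )
            col = np.repeat(np.array([0, 1, 2], dtype=np.int64), counts)
            rng.shuffle(col)
            values[:, j] = col
    sample_ids = [f"truth{i:06d}" for i in range(n)]
    return GenotypeMatrix(values, sample_ids, spec.snp_ids)


def default_fixture_spec(n_samples: int = 2000, seed: int = 7) -> FixtureSpec:
    """The standard 8-SNP test bundle: one 4-SNP correlated block (latent
    correlations 0.4-0.6), one 2-SNP block at 0.5, and two independent SNPs,
    with frequencies between 0.2 and 0.5."""
    R = np.eye(8)
    R[:4, :4] = toeplitz([1.0, 0.6, 0.5, 0.4])
    R[4:6, 4:6] = [[1.0, 0.5], [0.5, 1.0]]
    snps = (
        FixtureSnp("rs1", 0.35),
        FixtureSnp("rs2", 0.30),
        FixtureSnp("rs3", 0.40),
        FixtureSnp("rs4", 0.30),
        FixtureSnp("rs5", 0.50),
        FixtureSnp("rs6", 0.45),
        FixtureSnp("rs7", 0.20),
        FixtureSnp("rs8", 0.30),
    )
    return FixtureSpec(
        n_samples=n_samples,
        snps=snps,
        latent_corr=R,
        seed=seed,
        case_shift=0.15,
        case_snp_ids=("rs1", "rs2", "rs5", "rs7"),
    )


def default_grs_model(spec: FixtureSpec) -> GRSModel:
    """Deterministic pseudo-random model over the spec's SNPs: positive
    linear weights, alternating effect-allele orientation (to exercise the
    dosage flip), and two interaction entries on the first block."""
    rng = np.random.default_rng([spec.seed, 97])
    counted, other = FIXTURE_ALLELES
    linear = [
        LinearTerm(
            snp.snp_id,
            counted if j % 2 == 0 else other,
            float(np.round(rng.uniform(0.2, 1.0), 4)),
        )
        for j, snp in enumerate(spec.snps)
    ]
    interactions = []
    ids = spec.snp_ids
    if len(ids) >= 4:
        interactions = [
            InteractionTerm(1, ids[0], "ge1", ids[1], "ge1", 1.0),
            InteractionTerm(2, ids[2], "eq2", ids[3], "ge1", 0.5),
        ]
    return GRSModel(linear, interactions)


def with_case_shift(spec: FixtureSpec, seed_offset: int = 104729) -> FixtureSpec:
    """Derive a "case" spec by shifting the listed SNPs' frequencies upward.

    The case population gets its own RNG stream (``seed + seed_offset``) so
    case and control truth arrays are independent draws.
    """
    if spec.case_shift is None:
        raise ValidationError("spec has no case_shift")
    shifted = []
    for snp in spec.snps:
        if snp.snp_id in spec.case_snp_ids:
            if snp.hwe_deviates:
                raise ValidationError(
                    f"cannot shift non-HWE SNP '{snp.snp_id}'"
                )
            freq = float(np.clip(snp.freq + spec.case_shift, 0.01, 0.99))
            snp = replace(snp, freq=freq)
        shifted.append(snp)
    return replace(
        spec, snps=tuple(shifted), seed=spec.seed + seed_offset
    )


def build_fixture_bundle(
    spec: FixtureSpec, hwe_alpha: float = 0.05
) -> tuple[GenotypeMatrix, SummaryStats, CorrelationTable, GRSModel]:
    """Truth array plus the summary statistics computed from it.

    The returned stats/correlations are the REALIZED statistics of the truth
    array (not the latent copula parameters): the simulator's contract is to
    match given statistics, and this closes the loop for end-to-end tests.
    """
    X_truth = copula_genotypes(spec)
    alleles = {s: FIXTURE_ALLELES for s in spec.snp_ids}
    stats, corr = compute_summary_stats(X_truth, hwe_alpha=hwe_alpha, alleles=alleles)
    model = spec.grs_model if spec.grs_model is not None else default_grs_model(spec)
    return X_truth, stats, corr, model
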