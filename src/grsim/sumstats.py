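"""Summary statistics of SNP dosage matrices: types, computation, and TSV I/O.

A genotype matrix holds dosages in {0, 1, 2} (count of the allele designated
as the "2" allele for each SNP).  The summary statistics consumed by the
simulator are per-SNP allele frequencies (plus observed genotype-class
fractions for SNPs flagged as deviating from Hardy-Weinberg equilibrium) and
signed pairwise Pearson correlations of the dosage columns.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .errors import ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
VALID_PREDICATES = frozenset({"eq0", "eq1", "eq2", "ge1", "ge2"})

#: column order of the frequencies TSV
FREQ_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "freq",
    "hwe_deviates",
    "frac0",
    "frac1",
    "frac2",
)
#: column order of the correlations TSV
CORR_COLUMNS = ("snp_a", "snp_b", "rho")

_FRAC_TOL = 1e-9


def _fmt(x: float) -> str:
    """Serialize a float at 10 significant digits (round-trip stable)."""
    return format(float(x), ".10g")


@dataclass(frozen=True)
class SnpStat:
    """Marginal summary of one SNP.

    ``freq`` is the frequency of the allele counted as dosage 2, which is
    stored in ``effect_allele``; ``other_allele`` is the alternative allele.
    When ``hwe_deviates`` is set the observed genotype-class fractions
    ``frac0/frac1/frac2`` are required; otherwise they are ``None`` and the
    implied fractions are the Hardy-Weinberg values.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    freq: float
    hwe_deviates: bool = False
    frac0: float | None = None
    frac1: float | None = None
    frac2: float | None = None

    def genotype_fractions(self) -> tuple[float, float, float]:
        """Expected fractions of dosages (0, 1, 2) for this SNP."""
        if self.hwe_deviates:
            return (float(self.frac0), float(self.frac1), float(self.frac2))
        f = self.freq
        return ((1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f)

    def _validate(self) -> None:
        if not self.snp_id:
            raise ValidationError("empty snp_id")
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if allele not in VALID_ALLELES:
                raise ValidationError(
                    f"SNP '{self.snp_id}': {name} {allele!r} is not one of A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"SNP '{self.snp_id}': effect and other allele are identical"
            )
        if not (0.0 <= self.freq <= 1.0):
            raise ValidationError(
                f"SNP '{self.snp_id}': freq {self.freq} outside [0, 1]"
            )
        if self.hwe_deviates:
            fracs = (self.frac0, self.frac1, self.frac2)
            if any(v is None for v in fracs):
                raise ValidationError(
                    f"SNP '{self.snp_id}': hwe_deviates set but genotype-class "
                    "fractions are missing"
                )
            for name, v in zip(("frac0", "frac1", "frac2"), fracs):
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(
                        f"SNP '{self.snp_id}': {name} {v} outside [0, 1]"
                    )
            total = self.frac0 + self.frac1 + self.frac2
            if abs(total - 1.0) > _FRAC_TOL:
                raise ValidationError(
                    f"SNP '{self.snp_id}': genotype-class fractions sum to "
                    f"{total!r}, not 1"
                )
            implied = (self.frac1 + 2.0 * self.frac2) / 2.0
            if abs(implied - self.freq) > _FRAC_TOL:
                raise ValidationError(
                    f"SNP '{self.snp_id}': fractions imply freq {implied!r} but "
                    f"freq is {self.freq!r}"
                )
        elif any(v is not None for v in (self.frac0, self.frac1, self.frac2)):
            raise ValidationError(
                f"SNP '{self.snp_id}': genotype-class fractions given but "
                "hwe_deviates is not set"
            )


@dataclass(frozen=True)
class SummaryStats:
    """Ordered collection of per-SNP marginal summaries."""

    records: tuple[SnpStat, ...]

    def __init__(self, records: Sequence[SnpStat]):
        object.__setattr__(self, "records", tuple(records))
        seen: set[str] = set()
        for rec in self.records:
            rec._validate()
            if rec.snp_id in seen:
                raise ValidationError(f"duplicate snp_id '{rec.snp_id}'")
            seen.add(rec.snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def get(self, snp_id: str) -> SnpStat:
        for rec in self.records:
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)

    def __contains__(self, snp_id: str) -> bool:
        return any(r.snp_id == snp_id for r in self.records)


@dataclass(frozen=True)
class CorrEntry:
    snp_a: str
    snp_b: str
    rho: float


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise target correlations, one row per unordered SNP pair."""

    entries: tuple[CorrEntry, ...]

    def __init__(self, entries: Sequence[CorrEntry]):
        object.__setattr__(self, "entries", tuple(entries))
        seen: set[frozenset[str]] = set()
        for e in self.entries:
            if e.snp_a == e.snp_b:
                raise ValidationError(f"self-pair ('{e.snp_a}', '{e.snp_b}') not allowed")
            if not (-1.0 <= e.rho <= 1.0):
                raise ValidationError(
                    f"pair ('{e.snp_a}', '{e.snp_b}'): rho {e.rho} outside [-1, 1]"
                )
            key = frozenset((e.snp_a, e.snp_b))
            if key in seen:
                raise ValidationError(
                    f"pair ('{e.snp_a}', '{e.snp_b}') listed more than once"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def snp_ids(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out.add(e.snp_a)
            out.add(e.snp_b)
        return out

    def get(self, snp_a: str, snp_b: str) -> float:
        key = frozenset((snp_a, snp_b))
        for e in self.entries:
            if frozenset((e.snp_a, e.snp_b)) == key:
                return e.rho
        raise KeyError((snp_a, snp_b))


@dataclass
class GenotypeMatrix:
    """N x p dosage matrix over {0, 1, 2} with sample and SNP identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    _col_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError(f"genotype matrix must be 2-D, got ndim={values.ndim}")
        n, p = values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample_ids for {n} rows"
            )
        if len(self.snp_ids) != p:
            raise ValidationError(f"{len(self.snp_ids)} snp_ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        if len(set(self.snp_ids)) != p:
            raise ValidationError("snp_ids are not unique")
        bad = ~np.isin(values, (0, 1, 2))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"genotype value {values[i, j]!r} outside {{0, 1, 2}} at sample "
                f"'{self.sample_ids[i]}', SNP '{self.snp_ids[j]}'"
            )
        self.values = values.astype(np.int64)
        self._col_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def col_index(self, snp_id: str) -> int:
        try:
            return self._col_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP '{snp_id}' not in matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.col_index(snp_id)]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write("sample_id\t" + "\t".join(self.snp_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        path = Path(path)
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise ValidationError(f"{path}: empty file") from None
            if len(header) < 2 or header[0] != "sample_id":
                raise ValidationError(
                    f"{path}: line 1: expected header starting with 'sample_id'"
                )
            snp_ids = header[1:]
            sample_ids: list[str] = []
            rows: list[list[int]] = []
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(header):
                    raise ValidationError(
                        f"{path}: line {lineno}: expected {len(header)} fields, "
                        f"got {len(row)}"
                    )
                sample_ids.append(row[0])
                try:
                    rows.append([int(v) for v in row[1:]])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}: line {lineno}: non-integer genotype value ({exc})"
                    ) from None
        if not rows:
            raise ValidationError(f"{path}: no sample rows")
        return cls(np.array(rows, dtype=np.int64), sample_ids, snp_ids)


def compute_summary_stats(
    X: GenotypeMatrix,
    hwe_alpha: float = 0.05,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[SummaryStats, CorrelationTable]:
    """Compute per-SNP frequencies, HWE flags, and pairwise Pearson correlations.

    Parameters
    ----------
    X
        Complete dosage matrix.
    hwe_alpha
        Significance level of the chi-square goodness-of-fit test (1 df, no
        continuity correction) used to flag Hardy-Weinberg deviation.
    alleles
        Optional mapping ``snp_id -> (counted_allele, other_allele)`` naming
        which allele the matrix's "2" dosage counts.  SNPs without an entry
        get the placeholder pair ``("A", "C")``.

    Returns
    -------
    A :class:`SummaryStats` (one record per matrix column, in column order)
    and a :class:`CorrelationTable` over all unordered SNP pairs whose two
    columns are both non-constant.  Constant (monomorphic) columns are kept
    in the stats but omitted from the correlation table with a warning.
    """
    if not (0.0 < hwe_alpha < 1.0):
        raise ValidationError(f"hwe_alpha {hwe_alpha} outside (0, 1)")
    n, p = X.values.shape
    if p == 0:
        raise ValidationError("genotype matrix has no SNPs")
    if n < 2:
        raise ValidationError(
            f"need at least 2 samples to compute correlations, got {n}"
        )
    alleles = alleles or {}

    records: list[SnpStat] = []
    for j, snp in enumerate(X.snp_ids):
        col = X.values[:, j]
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        n0 = n - n1 - n2
        freq = (n1 + 2 * n2) / (2 * n)
        deviates = False
        fracs: tuple[float | None, float | None, float | None] = (None, None, None)
        if 0.0 < freq < 1.0:
            expected = n * np.array(
                [(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2]
            )
            observed = np.array([n0, n1, n2], dtype=float)
            stat = float(((observed - expected) ** 2 / expected).sum())
            pval = float(chi2.sf(stat, df=1))
            deviates = pval < hwe_alpha
            if deviates:
                fracs = (n0 / n, n1 / n, n2 / n)
        a2, other = alleles.get(snp, ("A", "C"))
        records.append(
            SnpStat(snp, a2, other, float(freq), deviates, *fracs)
        )

    stds = X.values.std(axis=0)
    keep = [j for j in range(p) if stds[j] > 0]
    dropped = [X.snp_ids[j] for j in range(p) if stds[j] == 0]
    if dropped:
        logger.warning(
            "excluding %d constant column(s) from the correlation table: %s",
            len(dropped), ", ".join(dropped),
        )
    entries: list[CorrEntry] = []
    if len(keep) >= 2:
        R = np.corrcoef(X.values[:, keep], rowvar=False)
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                rho = float(np.clip(R[a, b], -1.0, 1.0))
                entries.append(
                    CorrEntry(X.snp_ids[keep[a]], X.snp_ids[keep[b]], rho)
                )
    return SummaryStats(records), CorrelationTable(entries)


# ---------------------------------------------------------------------------
# TSV serialization


def write_summary_stats(
    stats: SummaryStats,
    corr: CorrelationTable,
    freq_path: str | Path,
    corr_path: str | Path,
) -> None:
    """Write the frequencies and correlations TSVs (10 significant digits)."""
    freq_path = Path(freq_path)
    corr_path = Path(corr_path)
    with freq_path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(FREQ_COLUMNS) + "\n")
        for rec in stats.records:
            if rec.hwe_deviates:
                fracs = [_fmt(rec.frac0), _fmt(rec.frac1), _fmt(rec.frac2)]
            else:
                fracs = ["", "", ""]
            fh.write(
                "\t".join(
                    [
                        rec.snp_id,
                        rec.effect_allele,
                        rec.other_allele,
                        _fmt(rec.freq),
                        "1" if rec.hwe_deviates else "0",
                        *fracs,
                    ]
                )
                + "\n"
            )
    with corr_path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(CORR_COLUMNS) + "\n")
        for e in corr.entries:
            fh.write("\t".join([e.snp_a, e.snp_b, _fmt(e.rho)]) + "\n")


def _parse_float(text: str, path: Path, lineno: int, colname: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"{path}: line {lineno}: cannot parse {colname} value {text!r}"
        ) from None


def load_summary_stats(
    freq_path: str | Path, corr_path: str | Path
) -> tuple[SummaryStats, CorrelationTable]:
    """Load the frequencies and correlations TSVs written by
    :func:`write_summary_stats` (inverse operation)."""
    freq_path = Path(freq_path)
    corr_path = Path(corr_path)

    records: list[SnpStat] = []
    with freq_path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{freq_path}: empty file") from None
        if tuple(header) != FREQ_COLUMNS:
            raise ValidationError(
                f"{freq_path}: line 1: expected header "
                f"{list(FREQ_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(FREQ_COLUMNS):
                raise ValidationError(
                    f"{freq_path}: line {lineno}: expected "
                    f"{len(FREQ_COLUMNS)} fields, got {len(row)}"
                )
            snp_id, eff, oth, freq_s, dev_s, f0_s, f1_s, f2_s = row
            if dev_s not in ("0", "1"):
                raise ValidationError(
                    f"{freq_path}: line {lineno}: hwe_deviates must be 0 or 1, "
                    f"got {dev_s!r}"
                )
            deviates = dev_s == "1"
            freq = _parse_float(freq_s, freq_path, lineno, "freq")
            if deviates:
                if not (f0_s and f1_s and f2_s):
                    raise ValidationError(
                        f"{freq_path}: line {lineno}: SNP '{snp_id}' has "
                        "hwe_deviates=1 but missing frac columns"
                    )
                fracs = (
                    _parse_float(f0_s, freq_path, lineno, "frac0"),
                    _parse_float(f1_s, freq_path, lineno, "frac1"),
                    _parse_float(f2_s, freq_path, lineno, "frac2"),
                )
            else:
                if f0_s or f1_s or f2_s:
                    raise ValidationError(
                        f"{freq_path}: line {lineno}: SNP '{snp_id}' has "
                        "hwe_deviates=0 but non-empty frac columns"
                    )
                fracs = (None, None, None)
            records.append(SnpStat(snp_id, eff, oth, freq, deviates, *fracs))
    stats = SummaryStats(records)

    entries: list[CorrEntry] = []
    with corr_path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{corr_path}: empty file") from None
        if tuple(header) != CORR_COLUMNS:
            raise ValidationError(
                f"{corr_path}: line 1: expected header "
                f"{list(CORR_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CORR_COLUMNS):
                raise ValidationError(
                    f"{corr_path}: line {lineno}: expected 3 fields, got {len(row)}"
                )
            snp_a, snp_b, rho_s = row
            for snp in (snp_a, snp_b):
                if snp not in stats:
                    raise ValidationError(
                        f"{corr_path}: line {lineno}: SNP '{snp}' not present "
                        f"in {freq_path}"
                    )
            entries.append(
                CorrEntry(snp_a, snp_b, _parse_float(rho_s, corr_path, lineno, "rho"))
            )
    return stats, CorrelationTable(entries)


# ---------------------------------------------------------------------------
# Optional VCF reader (convenience plumbing; the TSV matrix is canonical)


def read_vcf(
    path: str | Path, snp_ids: Sequence[str] | None = None
) -> tuple[GenotypeMatrix, dict[str, tuple[str, str]]]:
    """Read biallelic SNP records from a VCF into a dosage matrix.

    Dosage is the count of the ALT allele, so the returned allele map is
    ``snp_id -> (ALT, REF)``.  Any missing genotype among the requested SNPs
    raises, since downstream methods assume complete data.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    path = str(path)
    wanted = set(snp_ids) if snp_ids is not None else None
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    alleles: dict[str, tuple[str, str]] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_ALLELES or alt not in VALID_ALLELES:
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if wanted is not None and vid not in wanted:
            continue
        gt = np.asarray(var.gt_types)
        if (gt == 3).any():
            i = int(np.argwhere(gt == 3)[0][0])
            raise ValidationError(
                f"{path}: missing genotype for SNP '{vid}', sample '{samples[i]}'"
            )
        cols.append(gt.astype(np.int64))
        ids.append(vid)
        alleles[vid] = (alt, ref)
    if wanted is not None:
        absent = sorted(wanted - set(ids))
        if absent:
            raise ValidationError(
                f"{path}: requested SNP(s) not found as biallelic SNPs: "
                + ", ".join(absent)
            )
    if not cols:
        raise ValidationError(f"{path}: no biallelic SNP records found")
    X = GenotypeMatrix(np.column_stack(cols), samples, ids)
    return X, alleles
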