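"""Genetic risk scores: linear weighted dosage sum plus a ranked pairwise
interaction term.

The linear part is ``sum_k w_k * d_k`` where ``d_k`` is the dosage of the
model's effect allele (columns are flipped ``x -> 2 - x`` when the matrix
counts the opposite allele).  The interaction part evaluates a ranked table
of two-SNP genotype conditions; at most one entry — the satisfied entry of
minimal rank — contributes per sample.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .sumstats import VALID_ALLELES, GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)

PREDICATES = ("eq0", "eq1", "eq2", "ge1", "ge2")

LINEAR_COLUMNS = ("snp_id", "effect_allele", "weight")
INTERACTION_COLUMNS = ("rank", "snp_a", "predicate_a", "snp_b", "predicate_b", "weight")
SCORE_COLUMNS = (
    "sample_id",
    "linear_score",
    "interaction_score",
    "total",
    "interaction_rank_applied",
)


def _apply_predicate(col: np.ndarray, predicate: str) -> np.ndarray:
    if predicate == "eq0":
        return col == 0
    if predicate == "eq1":
        return col == 1
    if predicate == "eq2":
        return col == 2
    if predicate == "ge1":
        return col >= 1
    if predicate == "ge2":
        return col >= 2
    raise ValidationError(f"unknown predicate {predicate!r}")


@dataclass(frozen=True)
class LinearTerm:
    snp_id: str
    effect_allele: str
    weight: float


@dataclass(frozen=True)
class InteractionTerm:
    rank: int
    snp_a: str
    predicate_a: str
    snp_b: str
    predicate_b: str
    weight: float


@dataclass(frozen=True)
class GRSModel:
    """Per-SNP effect alleles and weights plus a ranked interaction table."""

    linear: tuple[LinearTerm, ...]
    interactions: tuple[InteractionTerm, ...] = ()

    def __init__(
        self,
        linear: Sequence[LinearTerm],
        interactions: Sequence[InteractionTerm] = (),
    ):
        object.__setattr__(self, "linear", tuple(linear))
        object.__setattr__(
            self, "interactions", tuple(sorted(interactions, key=lambda t: t.rank))
        )
        seen: set[str] = set()
        for term in self.linear:
            if term.effect_allele not in VALID_ALLELES:
                raise ValidationError(
                    f"SNP '{term.snp_id}': effect_allele {term.effect_allele!r} "
                    "is not one of A/C/G/T"
                )
            if term.snp_id in seen:
                raise ValidationError(
                    f"duplicate snp_id '{term.snp_id}' in linear terms"
                )
            seen.add(term.snp_id)
        ranks = [t.rank for t in self.interactions]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"interaction ranks must be unique and contiguous from 1, got {ranks}"
            )
        for term in self.interactions:
            if term.snp_a == term.snp_b:
                raise ValidationError(
                    f"interaction rank {term.rank}: snp_a equals snp_b "
                    f"('{term.snp_a}')"
                )
            for snp in (term.snp_a, term.snp_b):
                if snp not in seen:
                    raise ValidationError(
                        f"interaction rank {term.rank}: SNP '{snp}' has no "
                        "linear term"
                    )
            for pred in (term.predicate_a, term.predicate_b):
                if pred not in PREDICATES:
                    raise ValidationError(
                        f"interaction rank {term.rank}: unknown predicate {pred!r}"
                    )

    @property
    def snp_ids(self) -> list[str]:
        return [t.snp_id for t in self.linear]


@dataclass
class ScoreTable:
    """Per-sample score decomposition (total = linear + interaction)."""

    sample_ids: list[str]
    linear_score: np.ndarray
    interaction_score: np.ndarray
    total: np.ndarray
    interaction_rank_applied: list[int | None]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(SCORE_COLUMNS) + "\n")
            for sid, lin, inter, tot, rank in zip(
                self.sample_ids,
                self.linear_score,
                self.interaction_score,
                self.total,
                self.interaction_rank_applied,
            ):
                fh.write(
                    "\t".join(
                        [
                            sid,
                            format(lin, ".10g"),
                            format(inter, ".10g"),
                            format(tot, ".10g"),
                            "" if rank is None else str(rank),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        path = Path(path)
        sample_ids: list[str] = []
        lin: list[float] = []
        inter: list[float] = []
        tot: list[float] = []
        ranks: list[int | None] = []
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or tuple(header) != SCORE_COLUMNS:
                raise ValidationError(
                    f"{path}: line 1: expected header {list(SCORE_COLUMNS)}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(SCORE_COLUMNS):
                    raise ValidationError(
                        f"{path}: line {lineno}: expected {len(SCORE_COLUMNS)} "
                        f"fields, got {len(row)}"
                    )
                try:
                    sample_ids.append(row[0])
                    lin.append(float(row[1]))
                    inter.append(float(row[2]))
                    tot.append(float(row[3]))
                    ranks.append(int(row[4]) if row[4] else None)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}: line {lineno}: malformed value ({exc})"
                    ) from None
        return cls(sample_ids, np.array(lin), np.array(inter), np.array(tot), ranks)


def allele_map_from_stats(stats: SummaryStats) -> dict[str, tuple[str, str]]:
    """Allele map ``snp_id -> (counted_allele, other_allele)`` implied by a
    summary-statistics table (its freq refers to the counted allele)."""
    return {r.snp_id: (r.effect_allele, r.other_allele) for r in stats.records}


def _orient_columns(
    X: GenotypeMatrix,
    terms: Sequence[LinearTerm],
    allele_map: Mapping[str, tuple[str, str]],
) -> GenotypeMatrix:
    values = X.values.copy()
    for term in terms:
        j = X.col_index(term.snp_id)
        try:
            counted, other = allele_map[term.snp_id]
        except KeyError:
            raise ValidationError(
                f"allele map has no entry for SNP '{term.snp_id}'"
            ) from None
        if term.effect_allele == counted:
            continue
        if term.effect_allele == other:
            values[:, j] = 2 - values[:, j]
        else:
            raise ValidationError(
                f"SNP '{term.snp_id}': model effect allele "
                f"'{term.effect_allele}' matches neither array allele "
                f"('{counted}'/'{other}'); probable strand or ID mismatch"
            )
    return GenotypeMatrix(values, X.sample_ids, X.snp_ids)


def effect_dosage(
    X: GenotypeMatrix,
    model: GRSModel,
    allele_map: Mapping[str, tuple[str, str]],
) -> GenotypeMatrix:
    """Return X with every model SNP column oriented to count the model's
    effect allele (columns flipped ``x -> 2 - x`` where the matrix counts the
    opposite allele)."""
    for term in model.linear:
        X.col_index(term.snp_id)  # raises KeyError if absent
    return _orient_columns(X, model.linear, allele_map)


def _interaction_scores(
    Xe: GenotypeMatrix, interactions: Sequence[InteractionTerm]
) -> tuple[np.ndarray, list[int | None]]:
    n = Xe.n_samples
    scores = np.zeros(n)
    ranks: list[int | None] = [None] * n
    unassigned = np.ones(n, dtype=bool)
    for term in sorted(interactions, key=lambda t: t.rank):
        satisfied = _apply_predicate(
            Xe.column(term.snp_a), term.predicate_a
        ) & _apply_predicate(Xe.column(term.snp_b), term.predicate_b)
        hit = unassigned & satisfied
        scores[hit] = term.weight
        for i in np.nonzero(hit)[0]:
            ranks[int(i)] = term.rank
        unassigned &= ~satisfied
    return scores, ranks


def interaction_score(
    Xe: GenotypeMatrix, model: GRSModel
) -> tuple[np.ndarray, list[int | None]]:
    """Per-sample interaction contribution on an effect-oriented matrix.

    Entries are evaluated in rank order; the first entry whose two genotype
    predicates both hold contributes its weight and all later entries are
    ignored for that sample.  Samples satisfying no entry score 0 with rank
    ``None``.
    """
    return _interaction_scores(Xe, model.interactions)


def compute_grs(
    X: GenotypeMatrix,
    model: GRSModel,
    allele_map: Mapping[str, tuple[str, str]],
    snp_subset: Sequence[str] | None = None,
    allow_missing: bool = False,
) -> ScoreTable:
    """Score every sample of X under the model.

    ``snp_subset`` restricts scoring to the listed SNPs (linear terms outside
    the subset are dropped, as are interaction entries touching a dropped
    SNP), which enables sub-part decompositions such as HLA / non-HLA or
    correlated / uncorrelated splits.  Model SNPs absent from the matrix are
    an error unless ``allow_missing`` is set, in which case they contribute 0
    and are reported in a warning.
    """
    linear = list(model.linear)
    interactions = list(model.interactions)
    if snp_subset is not None:
        subset = set(snp_subset)
        unknown = subset - set(model.snp_ids)
        if unknown:
            raise ValidationError(
                "snp_subset contains SNP(s) not in the model: "
                + ", ".join(sorted(unknown))
            )
        linear = [t for t in linear if t.snp_id in subset]
        interactions = [
            t for t in interactions if t.snp_a in subset and t.snp_b in subset
        ]
    missing = [t.snp_id for t in linear if t.snp_id not in X._col_index]
    if missing:
        if not allow_missing:
            raise ValidationError(
                "model SNP(s) absent from the genotype matrix: "
                + ", ".join(missing)
            )
        logger.warning(
            "scoring without %d model SNP(s) absent from the matrix: %s",
            len(missing), ", ".join(missing),
        )
        missing_set = set(missing)
        linear = [t for t in linear if t.snp_id not in missing_set]
        interactions = [
            t
            for t in interactions
            if t.snp_a not in missing_set and t.snp_b not in missing_set
        ]

    Xe = _orient_columns(X, linear, allele_map)
    linear_score = np.zeros(X.n_samples)
    for term in linear:
        linear_score += term.weight * Xe.column(term.snp_id)
    inter_score, ranks = _interaction_scores(Xe, interactions)
    return ScoreTable(
        sample_ids=list(X.sample_ids),
        linear_score=linear_score,
        interaction_score=inter_score,
        total=linear_score + inter_score,
        interaction_rank_applied=ranks,
    )


# ---------------------------------------------------------------------------
# Model TSV I/O


def write_grs_model(
    model: GRSModel,
    linear_path: str | Path,
    interactions_path: str | Path | None = None,
) -> None:
    with Path(linear_path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(LINEAR_COLUMNS) + "\n")
        for t in model.linear:
            fh.write(
                "\t".join([t.snp_id, t.effect_allele, format(t.weight, ".10g")]) + "\n"
            )
    if interactions_path is not None:
        with Path(interactions_path).open("w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(INTERACTION_COLUMNS) + "\n")
            for t in model.interactions:
                fh.write(
                    "\t".join(
                        [
                            str(t.rank),
                            t.snp_a,
                            t.predicate_a,
                            t.snp_b,
                            t.predicate_b,
                            format(t.weight, ".10g"),
                        ]
                    )
                    + "\n"
                )


def load_grs_model(
    linear_path: str | Path, interactions_path: str | Path | None = None
) -> GRSModel:
    linear_path = Path(linear_path)
    linear: list[LinearTerm] = []
    with linear_path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != LINEAR_COLUMNS:
            raise ValidationError(
                f"{linear_path}: line 1: expected header {list(LINEAR_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValidationError(
                    f"{linear_path}: line {lineno}: expected 3 fields, got {len(row)}"
                )
            try:
                linear.append(LinearTerm(row[0], row[1], float(row[2])))
            except ValueError as exc:
                raise ValidationError(
                    f"{linear_path}: line {lineno}: malformed weight ({exc})"
                ) from None
    interactions: list[InteractionTerm] = []
    if interactions_path is not None:
        interactions_path = Path(interactions_path)
        with interactions_path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or tuple(header) != INTERACTION_COLUMNS:
                raise ValidationError(
                    f"{interactions_path}: line 1: expected header "
                    f"{list(INTERACTION_COLUMNS)}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 6:
                    raise ValidationError(
                        f"{interactions_path}: line {lineno}: expected 6 fields, "
                        f"got {len(row)}"
                    )
                try:
                    interactions.append(
                        InteractionTerm(
                            int(row[0]), row[1], row[2], row[3], row[4], float(row[5])
                        )
                    )
                except ValueError as exc:
                    raise ValidationError(
                        f"{interactions_path}: line {lineno}: malformed value ({exc})"
                    ) from None
    return GRSModel(linear, interactions)
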