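"""Expression integration and candidate screening for divergent gene pairs.

Candidates are selected by combining RNA-seq and microarray evidence: the
pair's maximum expression (the larger of the two genes' maxima) must exceed
a threshold in at least one RNA-seq source AND in at least one microarray
source, and the pair's expression correlation across RNA-seq samples must
exceed a correlation threshold.  All inequalities are strict.  Microarray
correlations are not used: sample counts below ``min_corr_samples`` are
considered unreliable and yield no coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import DivergentPair

__all__ = [
    "ExpressionMatrix",
    "GeneExprStats",
    "PairExpressionSummary",
    "SelectionCriteria",
    "CandidateRecord",
    "load_expression_matrix",
    "write_expression_matrix",
    "summarize_gene",
    "pair_correlation",
    "summarize_pair",
    "screen_pairs",
    "screen_summaries",
]

KINDS = ("rnaseq", "microarray")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table from one source.

    ``kind`` is "rnaseq" (e.g. FPKM from MSU/RAP-style projects) or
    "microarray" (hybridization intensities, CREP-style).  Values are
    nonnegative in the source's own units; missing values are NaN, never 0.
    """

    source_id: str
    kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.values.shape[1] < 1:
            raise ValueError(f"{self.source_id}: at least one sample required")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"{self.source_id}: duplicated gene_id(s) {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.source_id}: negative expression values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index


@dataclass(frozen=True)
class GeneExprStats:
    gene_id: str
    source_id: str
    min: float
    max: float
    mean: float
    n_samples: int


@dataclass(frozen=True)
class PairExpressionSummary:
    """Per-source expression summary of one divergent pair (one report row)."""

    pair_id: str
    source_id: str
    kind: str
    gene5_stats: GeneExprStats | None
    gene3_stats: GeneExprStats | None
    pearson: float | None = None
    spearman: float | None = None

    @property
    def pair_max(self) -> float | None:
        """Larger of the two genes' maxima; None if either gene is absent."""
        if self.gene5_stats is None or self.gene3_stats is None:
            return None
        return max(self.gene5_stats.max, self.gene3_stats.max)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for candidate selection; all comparisons are strict.

    Defaults: pair maximum > 10 in RNA-seq and > 5000 in microarray units,
    and Pearson correlation > 0.4 over at least ``min_corr_samples`` RNA-seq
    samples.
    """

    rnaseq_max_threshold: float = 10.0
    microarray_max_threshold: float = 5000.0
    corr_threshold: float = 0.4
    corr_method: str = "pearson"
    min_corr_samples: int = 37

    def __post_init__(self) -> None:
        if self.rnaseq_max_threshold <= 0 or self.microarray_max_threshold <= 0:
            raise ValueError("expression thresholds must be strictly positive")
        if not 0 <= self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in [0, 1]")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValueError("corr_method must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class CandidateRecord:
    pair_id: str
    summaries: tuple[PairExpressionSummary, ...]
    rnaseq_max_pass: bool
    microarray_max_pass: bool
    correlation_pass: bool

    @property
    def passed(self) -> bool:
        return self.rnaseq_max_pass and self.microarray_max_pass and self.correlation_pass


def load_expression_matrix(tsv_path, source_id: str, kind: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample names, first column gene_id).

    Empty cells become NaN (missing), never zero.  Duplicate gene rows and
    non-numeric cells raise ``ValueError`` naming the offending location.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{tsv_path}: duplicated gene_id(s) {dups}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{tsv_path}: non-numeric cell at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return ExpressionMatrix(source_id=source_id, kind=kind, values=numeric)


def write_expression_matrix(matrix: ExpressionMatrix, tsv_path) -> None:
    matrix.values.to_csv(tsv_path, sep="\t", index_label="gene_id")


def summarize_gene(matrix: ExpressionMatrix, gene_id: str) -> GeneExprStats | None:
    """Min/max/mean over non-missing samples; None signals an absent gene
    (not present, or all values missing)."""
    if gene_id not in matrix:
        return None
    row = matrix.values.loc[gene_id]
    vals = row.dropna()
    if len(vals) == 0:
        return None
    return GeneExprStats(
        gene_id=gene_id,
        source_id=matrix.source_id,
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
        n_samples=int(len(vals)),
    )


def _paired_vectors(
    matrix: ExpressionMatrix, gene5_id: str, gene3_id: str
) -> tuple[np.ndarray, np.ndarray] | None:
    if gene5_id not in matrix or gene3_id not in matrix:
        return None
    x = matrix.values.loc[gene5_id].to_numpy(dtype=float)
    y = matrix.values.loc[gene3_id].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pair_correlation(
    matrix: ExpressionMatrix,
    pair: DivergentPair,
    method: str = "pearson",
    min_samples: int = 37,
) -> float | None:
    """Correlation of the two genes' expression over jointly non-missing
    samples; None (absent) if fewer than ``min_samples`` remain or either
    vector is constant."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    vecs = _paired_vectors(matrix, pair.gene5.gene_id, pair.gene3.gene_id)
    if vecs is None:
        return None
    x, y = vecs
    if len(x) < min_samples or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        r = stats.spearmanr(x, y).statistic
    return float(r)


def summarize_pair(
    matrix: ExpressionMatrix, pair: DivergentPair, min_corr_samples: int = 37
) -> PairExpressionSummary:
    """One report row: both genes' stats plus correlations for this source.

    Correlations are computed only for RNA-seq sources with enough samples;
    microarray sources report stats only.
    """
    pearson = spearman = None
    if matrix.kind == "rnaseq":
        pearson = pair_correlation(matrix, pair, "pearson", min_corr_samples)
        spearman = pair_correlation(matrix, pair, "spearman", min_corr_samples)
    return PairExpressionSummary(
        pair_id=pair.pair_id,
        source_id=matrix.source_id,
        kind=matrix.kind,
        gene5_stats=summarize_gene(matrix, pair.gene5.gene_id),
        gene3_stats=summarize_gene(matrix, pair.gene3.gene_id),
        pearson=pearson,
        spearman=spearman,
    )


def _evaluate(
    pair_id: str,
    summaries: Sequence[PairExpressionSummary],
    criteria: SelectionCriteria,
) -> CandidateRecord:
    rnaseq_pass = any(
        s.kind == "rnaseq"
        and s.pair_max is not None
        and s.pair_max > criteria.rnaseq_max_threshold
        for s in summaries
    )
    microarray_pass = any(
        s.kind == "microarray"
        and s.pair_max is not None
        and s.pair_max > criteria.microarray_max_threshold
        for s in summaries
    )
    corr_pass = any(
        s.kind == "rnaseq"
        and getattr(s, criteria.corr_method) is not None
        and getattr(s, criteria.corr_method) > criteria.corr_threshold
        for s in summaries
    )
    return CandidateRecord(
        pair_id=pair_id,
        summaries=tuple(summaries),
        rnaseq_max_pass=rnaseq_pass,
        microarray_max_pass=microarray_pass,
        correlation_pass=corr_pass,
    )


def screen_pairs(
    pairs: Sequence[DivergentPair],
    matrices: Sequence[ExpressionMatrix],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[CandidateRecord]:
    """Apply the three selection criteria to every pair.

    A pair passes iff (a) its pair maximum exceeds ``rnaseq_max_threshold``
    in at least one RNA-seq source, (b) exceeds ``microarray_max_threshold``
    in at least one microarray source, and (c) its correlation exceeds
    ``corr_threshold`` in at least one RNA-seq source with enough samples.
    Sources combine by "any source passes" within each kind.
    """
    kinds = {m.kind for m in matrices}
    if "rnaseq" not in kinds or "microarray" not in kinds:
        raise ValueError(
            "screening requires at least one rnaseq and one microarray matrix; "
            f"got kinds {sorted(kinds)}"
        )
    records = []
    for pair in pairs:
        summaries = [
            summarize_pair(m, pair, criteria.min_corr_samples) for m in matrices
        ]
        records.append(_evaluate(pair.pair_id, summaries, criteria))
    return records


def screen_summaries(
    summaries: Iterable[PairExpressionSummary],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[CandidateRecord]:
    """Summary mode: evaluate pre-computed per-source pair summaries (e.g. a
    published report table) without the underlying expression matrices."""
    by_pair: dict[str, list[PairExpressionSummary]] = {}
    for s in summaries:
        by_pair.setdefault(s.pair_id, []).append(s)
    return [_evaluate(pid, rows, criteria) for pid, rows in by_pair.items()]


def candidates_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Flatten candidate records into a report table (one row per pair and
    source, mirroring the per-source summary layout, plus pass flags)."""
    rows = []
    for rec in records:
        for s in rec.summaries:
            rows.append(
                {
                    "pair_id": rec.pair_id,
                    "source_id": s.source_id,
                    "kind": s.kind,
                    "gene5_min": s.gene5_stats.min if s.gene5_stats else np.nan,
                    "gene5_max": s.gene5_stats.max if s.gene5_stats else np.nan,
                    "gene5_mean": s.gene5_stats.mean if s.gene5_stats else np.nan,
                    "gene3_min": s.gene3_stats.min if s.gene3_stats else np.nan,
                    "gene3_max": s.gene3_stats.max if s.gene3_stats else np.nan,
                    "gene3_mean": s.gene3_stats.mean if s.gene3_stats else np.nan,
                    "pearson": np.nan if s.pearson is None else s.pearson,
                    "spearman": np.nan if s.spearman is None else s.spearman,
                    "rnaseq_max_pass": rec.rnaseq_max_pass,
                    "microarray_max_pass": rec.microarray_max_pass,
                    "correlation_pass": rec.correlation_pass,
                    "selected": rec.passed,
                }
            )
    return pd.DataFrame(rows)
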