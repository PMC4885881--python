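"""Quantitative analysis of dual-reporter (GFP / GUS) assays.

Covers the downstream statistics of a promoter::reporter experiment:
relative expression by the 2^(-ddCt) qPCR method, GUS specific activity
(pmol 4-MU per minute per mg total protein), aggregation of transgenic
lines into biological replicates, and compact-letter significance groups
from one-way ANOVA + Tukey HSD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "ActivityRecord",
    "ReplicateSummary",
    "ddct_relative_expression",
    "gus_specific_activity",
    "summarize_replicates",
    "significance_letters",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: threshold cycle for target (e.g. GFP) or the
    endogenous control (e.g. GAPDH) in one sample."""

    sample_id: str
    tissue: str
    gene: str  # "target" | "endogenous_control"
    ct: float
    technical_rep: int = 1

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"{self.sample_id}: Ct must be positive")
        if self.gene not in ("target", "endogenous_control"):
            raise ValueError("gene must be 'target' or 'endogenous_control'")


@dataclass(frozen=True)
class ActivityRecord:
    """One fluorometric GUS measurement (already calibrated to pmol / mg)."""

    sample_id: str
    tissue: str
    mu_pmol: float  # 4-methylumbelliferone produced
    minutes: float
    protein_mg: float

    def __post_init__(self) -> None:
        if self.minutes <= 0:
            raise ValueError(f"{self.sample_id}: minutes must be positive")
        if self.protein_mg <= 0:
            raise ValueError(f"{self.sample_id}: protein_mg must be positive")
        if self.mu_pmol < 0:
            raise ValueError(f"{self.sample_id}: mu_pmol must be nonnegative")


@dataclass(frozen=True)
class ReplicateSummary:
    tissue: str
    mean: float
    se: float | None
    n: int
    letter: str = ""


def ddct_relative_expression(
    records: list[CtRecord], calibrator_sample: str
) -> dict[str, float]:
    """Fold change per sample by the 2^(-ddCt) method.

    Technical replicates are averaged on the Ct scale; dCt = Ct_target -
    Ct_control per sample; ddCt is referenced to the calibrator sample, whose
    fold change is 1 by construction.
    """
    df = pd.DataFrame(
        [(r.sample_id, r.gene, r.ct) for r in records],
        columns=["sample_id", "gene", "ct"],
    )
    mean_ct = df.groupby(["sample_id", "gene"])["ct"].mean().unstack()
    for gene in ("target", "endogenous_control"):
        if gene not in mean_ct.columns:
            raise ValueError(f"no {gene} Ct values supplied")
        missing = mean_ct.index[mean_ct[gene].isna()].tolist()
        if missing:
            raise ValueError(f"sample(s) {missing} lack {gene} Ct values")
    if calibrator_sample not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in records")
    dct = mean_ct["target"] - mean_ct["endogenous_control"]
    ddct = dct - dct.loc[calibrator_sample]
    fold = np.power(2.0, -ddct)
    return {str(s): float(f) for s, f in fold.items()}


def gus_specific_activity(rec: ActivityRecord) -> float:
    """Specific activity in pmol 4-MU / min / mg total protein."""
    return rec.mu_pmol / rec.minutes / rec.protein_mg


def summarize_replicates(
    line_values: dict[str, float],
    tissue: str = "",
    lines_per_replicate: int = 2,
    randomize: bool = False,
    seed: int = 0,
) -> ReplicateSummary:
    """Aggregate per-line measurements into biological replicates.

    Transgenic lines are grouped ``lines_per_replicate`` at a time (in input
    order, or randomly when ``randomize`` is set, seeded); each biological
    replicate is the mean of its lines.  Summary mean and SE = sd/sqrt(n)
    are computed over the replicates.
    """
    if lines_per_replicate < 1:
        raise ValueError("lines_per_replicate must be >= 1")
    names = list(line_values)
    if len(names) % lines_per_replicate != 0:
        raise ValueError(
            f"{len(names)} lines not divisible into groups of {lines_per_replicate}"
        )
    if randomize:
        rng = np.random.default_rng(seed)
        names = [names[i] for i in rng.permutation(len(names))]
    values = np.array([line_values[n] for n in names], dtype=float)
    reps = values.reshape(-1, lines_per_replicate).mean(axis=1)
    n = len(reps)
    if n < 2:
        warnings.warn(f"{tissue or 'group'}: fewer than 2 replicates, SE unavailable",
                      stacklevel=2)
        se = None
    else:
        se = float(np.std(reps, ddof=1) / np.sqrt(n))
    return ReplicateSummary(tissue=tissue, mean=float(reps.mean()), se=se, n=n)


def _tukey_nonsignificant_graph(
    groups: dict[str, np.ndarray], alpha: float
) -> nx.Graph:
    names = list(groups)
    g = nx.Graph()
    g.add_nodes_from(names)
    res = stats.tukey_hsd(*(groups[n] for n in names))
    for i, j in itertools.combinations(range(len(names)), 2):
        if res.pvalue[i, j] >= alpha:
            g.add_edge(names[i], names[j])
    return g


def significance_letters(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from one-way ANOVA followed by all-pairs Tukey
    HSD: groups sharing a letter are not significantly different at ``alpha``.

    Letters are assigned in descending group-mean order starting at "a".
    Degenerate data (all values identical everywhere) yields a shared "a".
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
    names = list(arrays)
    all_vals = np.concatenate(list(arrays.values()))
    if np.ptp(all_vals) == 0:
        return {k: "a" for k in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant within-group inputs
        anova_p = stats.f_oneway(*arrays.values()).pvalue
    if np.isnan(anova_p) or anova_p >= alpha:
        return {k: "a" for k in names}
    graph = _tukey_nonsignificant_graph(arrays, alpha)
    # every maximal clique of the "not significantly different" graph gets a
    # letter; cliques ordered by their top member mean, descending
    means = {k: float(v.mean()) for k, v in arrays.items()}
    cliques = [sorted(c, key=lambda k: -means[k]) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: (-means[c[0]], [-means[k] for k in c]))
    letters: dict[str, list[str]] = {k: [] for k in names}
    for rank, clique in enumerate(cliques):
        letter = _letter(rank)
        for member in clique:
            letters[member].append(letter)
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def _letter(rank: int) -> str:
    out = ""
    rank += 1
    while rank > 0:
        rank, rem = divmod(rank - 1, 26)
        out = chr(ord("a") + rem) + out
    return out
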