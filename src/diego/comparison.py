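"""Differential enrichment between two experiments (DiEGO scoring).

Two profiles are compared term by term with a comparative log-odds z:

    z_k = (log(delta_i) - log(delta_j)) / sqrt(SE_i^2 + SE_j^2)

which is approximately standard normal when the term is equally enriched in
both experiments.  Because z_k uses both tails, a term depleted in one
experiment and flat in the other is detected even though neither
experiment's own over-representation test fires.  Each record also carries
the Jaccard coefficient of the two contributing gene sets: similar z-scores
can come from distinct genes, and JC separates those cases.

``overlap_method`` implements the hard-thresholding baseline: each profile
is independently tested with a one-sided Fisher exact test, thresholded,
and set-differenced.  Terms sitting just either side of the threshold then
masquerade as "specific" — the false-positive mode this package's direct
comparison avoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests

from diego.enrichment import EnrichmentProfile, EnrichmentScore, P_FLOOR


@dataclass(frozen=True)
class DiegoRecord:
    """Comparative score of one term between experiments i and j."""

    term: str
    z_i: float
    z_j: float
    log_delta_i: float
    log_delta_j: float
    se_i: float
    se_j: float
    se_ij: float
    z_k: float
    p: float
    p_adj: float
    jc: float
    genes_i: frozenset[str]
    genes_j: frozenset[str]


@dataclass
class ComparisonResult:
    labels: tuple[str, str]
    records: list[DiegoRecord]
    pearson_r: float
    mean_jc: float
    alpha: float = 0.05
    adjust_method: str = "bh"
    #: terms scoreable in only one of the two profiles (not force-scored)
    only_i: set[str] = field(default_factory=set)
    only_j: set[str] = field(default_factory=set)

    def significant(self) -> list[DiegoRecord]:
        """DiEGOs at the configured threshold (adjusted p unless method=none)."""
        if self.adjust_method == "none":
            return [r for r in self.records if r.p < self.alpha]
        return [r for r in self.records if r.p_adj < self.alpha]

    @property
    def n_diegos(self) -> int:
        return len(self.significant())


def z_comparative(
    score_i: EnrichmentScore, score_j: EnrichmentScore
) -> tuple[float, float]:
    """Comparative z and combined SE for one term.

    ``se_ij = sqrt(se_i^2 + se_j^2)``; ``z_k = (log_delta_i - log_delta_j)/se_ij``.
    """
    if not (score_i.defined and score_j.defined):
        raise ValueError("comparative z needs two defined (non-skipped) scores")
    se_ij = math.hypot(score_i.se, score_j.se)
    z_k = (score_i.log_delta - score_j.log_delta) / se_ij
    return z_k, se_ij


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def adjust_pvalues(ps: Sequence[float], method: str = "bh") -> list[float]:
    """Multiplicity adjustment preserving input order.

    ``bh`` is Benjamini-Hochberg step-up (monotonicity enforced, capped at
    1), ``bonferroni`` the usual product cap, ``none`` the identity.
    """
    arr = np.asarray(ps, dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return [float(p) for p in arr]
    if method == "bh":
        adjusted = multipletests(arr, method="fdr_bh")[1]
    elif method == "bonferroni":
        adjusted = multipletests(arr, method="bonferroni")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return [float(p) for p in adjusted]


def compare_profiles(
    p_i: EnrichmentProfile,
    p_j: EnrichmentProfile,
    alpha: float = 0.05,
    adjust: str = "bh",
) -> ComparisonResult:
    """Score DiEGOs over the terms scoreable in both profiles.

    The shared universe is the intersection of the two profiles' defined
    (non-skipped, min_count-satisfying) term sets; terms scoreable in only
    one profile are reported separately, never force-scored.  Records are
    sorted by |z_k| descending, ties broken by term id.
    """
    shared = sorted(p_i.defined_terms() & p_j.defined_terms())
    if not shared:
        raise ValueError("profiles share no scoreable terms")

    raw = []
    for term in shared:
        si, sj = p_i.scores[term], p_j.scores[term]
        z_k, se_ij = z_comparative(si, sj)
        p = max(2.0 * float(norm.sf(abs(z_k))), P_FLOOR)
        raw.append((term, si, sj, z_k, se_ij, p))
    p_adj = adjust_pvalues([r[5] for r in raw], method=adjust)

    records = []
    for (term, si, sj, z_k, se_ij, p), padj in zip(raw, p_adj):
        records.append(
            DiegoRecord(
                term=term,
                z_i=si.z, z_j=sj.z,
                log_delta_i=si.log_delta, log_delta_j=sj.log_delta,
                se_i=si.se, se_j=sj.se, se_ij=se_ij, z_k=z_k,
                p=p, p_adj=padj,
                jc=jaccard(si.genes, sj.genes),
                genes_i=si.genes, genes_j=sj.genes,
            )
        )
    records.sort(key=lambda r: (-abs(r.z_k), r.term))

    zi = np.array([r.z_i for r in records])
    zj = np.array([r.z_j for r in records])
    if len(records) >= 2 and zi.std() > 0 and zj.std() > 0:
        pearson_r = float(np.corrcoef(zi, zj)[0, 1])
    else:
        pearson_r = math.nan
    jcs = [r.jc for r in records if r.genes_i or r.genes_j]
    mean_jc = float(np.mean(jcs)) if jcs else math.nan

    return ComparisonResult(
        labels=(p_i.label, p_j.label),
        records=records,
        pearson_r=pearson_r,
        mean_jc=mean_jc,
        alpha=alpha,
        adjust_method=adjust,
        only_i=p_i.defined_terms() - p_j.defined_terms(),
        only_j=p_j.defined_terms() - p_i.defined_terms(),
    )


def overlap_method(
    p_i: EnrichmentProfile,
    p_j: EnrichmentProfile,
    alpha: float = 0.05,
    adjust: str = "bh",
) -> dict[str, str]:
    """Hard-threshold overlap baseline over the shared scoreable terms.

    Each profile is independently scored with a one-sided Fisher exact test
    for over-representation on its own contingency table, the p-values are
    multiplicity-adjusted within each profile, each term is thresholded at
    ``alpha``, and the two significant sets are set-differenced.  Returns
    term -> membership in {"both", "i-only", "j-only", "neither"}.
    """
    shared = sorted(p_i.defined_terms() & p_j.defined_terms())
    if not shared:
        raise ValueError("profiles share no scoreable terms")

    def fisher_ps(profile: EnrichmentProfile) -> list[float]:
        ps = []
        for term in shared:
            t = profile.scores[term].table
            contingency = [[t.n1, t.n2], [t.n3, t.n4]]
            ps.append(
                max(float(fisher_exact(contingency, alternative="greater")[1]),
                    P_FLOOR)
            )
        return ps

    sig_i = [p < alpha for p in adjust_pvalues(fisher_ps(p_i), method=adjust)]
    sig_j = [p < alpha for p in adjust_pvalues(fisher_ps(p_j), method=adjust)]

    membership = {}
    for term, si, sj in zip(shared, sig_i, sig_j):
        if si and sj:
            membership[term] = "both"
        elif si:
            membership[term] = "i-only"
        elif sj:
            membership[term] = "j-only"
        else:
            membership[term] = "neither"
    return membership


COMPARISON_COLUMNS = (
    "term", "name", "z_i", "z_j", "z_k", "se_ij", "p", "p_adj", "jc",
    "genes_i", "genes_j",
)


def write_comparison(
    result: ComparisonResult,
    handle: IO[str],
    names: dict[str, str] | None = None,
) -> None:
    """TSV dump of a comparison, one DiegoRecord per row, |z_k| descending."""
    names = names or {}
    handle.write(f"# labels: {result.labels[0]}\t{result.labels[1]}\n")
    handle.write(f"# pearson_r: {result.pearson_r:.6g}\n")
    handle.write(f"# mean_jc: {result.mean_jc:.6g}\n")
    handle.write(f"# n_diegos: {result.n_diegos}\n")
    handle.write(
        f"# alpha: {result.alpha:g}\tadjust: {result.adjust_method}\n"
    )
    handle.write("\t".join(COMPARISON_COLUMNS) + "\n")
    for r in result.records:
        handle.write(
            "\t".join([
                r.term, names.get(r.term, ""),
                f"{r.z_i:.10g}", f"{r.z_j:.10g}", f"{r.z_k:.10g}",
                f"{r.se_ij:.10g}", f"{r.p:.10g}", f"{r.p_adj:.10g}",
                f"{r.jc:.10g}",
                ",".join(sorted(r.genes_i)), ",".join(sorted(r.genes_j)),
            ]) + "\n"
        )
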