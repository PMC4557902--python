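"""Per-term enrichment scoring by log-odds-ratio z.

For each ontology term a 2x2 contingency table is built from four disjoint
cells:

    n1 = query genes annotated to the term
    n2 = query genes not annotated
    n3 = background-minus-query genes annotated
    n4 = background-minus-query genes not annotated

The odds ratio delta = (n1*n4)/(n2*n3) measures over- (delta > 1) or
under-representation (delta < 1) of the term in the query.  Its log has the
Woolf standard error SE = sqrt(1/n1 + 1/n2 + 1/n3 + 1/n4), giving the
enrichment z-score

    z = log(delta) / SE

which is approximately standard normal under no enrichment; the two-sided
p-value is 2 * (1 - Phi(|z|)).  Zero cells are handled by the
Haldane-Anscombe correction (+0.5 to all four cells) by default, or the
term can be skipped entirely (``zero_correction="skip"``).

The background universe always contains the query; cells are computed on
background-minus-query so the two rows of the table are disjoint, which the
odds ratio requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from scipy.stats import norm

from diego.ontology import AnnotationSet, OntologyGraph

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: smallest reported p-value; normal tail probabilities underflow near |z|~38
P_FLOOR = 5e-324


@dataclass(frozen=True)
class ContingencyTable:
    n1: float
    n2: float
    n3: float
    n4: float

    def __post_init__(self):
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise ValueError("negative contingency cell")

    @property
    def query_size(self) -> float:
        return self.n1 + self.n2

    @property
    def background_rest(self) -> float:
        return self.n3 + self.n4

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.n1, self.n2, self.n3, self.n4)


@dataclass(frozen=True)
class EnrichmentScore:
    """Log-odds enrichment of one term in one experiment.

    ``ci_low``/``ci_high`` bound log(delta) at 95% (log(delta) +/- 1.96*SE);
    ``zband_low``/``zband_high`` additionally report the literal z +/- 1.96*SE
    band.  ``defined`` is False when a zero cell was skipped instead of
    corrected, in which case the numeric fields are NaN.
    """

    term: str
    table: ContingencyTable
    delta: float
    log_delta: float
    se: float
    z: float
    ci_low: float
    ci_high: float
    zband_low: float
    zband_high: float
    p: float
    genes: frozenset[str] = frozenset()
    defined: bool = True
    corrected: bool = False


@dataclass
class EnrichmentProfile:
    """One experiment's per-term enrichment scores plus its inputs."""

    label: str
    query: list[str]
    background: set[str]
    scores: dict[str, EnrichmentScore]
    min_count: int = 2
    names: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        return set(self.scores)

    def defined_terms(self) -> set[str]:
        return {t for t, s in self.scores.items() if s.defined}


def build_table(
    term: str,
    query: Iterable[str],
    annot: AnnotationSet,
    background: Iterable[str] | None = None,
) -> ContingencyTable:
    """Count the four disjoint cells for one term.

    ``query`` must be a subset of ``background`` (default: the annotation
    universe); the background row is background-minus-query.
    """
    qset = set(query)
    bg = set(background) if background is not None else set(annot.universe)
    if not qset:
        raise ValueError("empty query gene set")
    if not qset <= bg:
        raise ValueError("query is not a subset of the background universe")
    rest = bg - qset
    if not rest:
        raise ValueError(
            "background equals the query: no genes left in the comparison row"
        )
    term_genes = annot.genes_for(term)
    n1 = len(qset & term_genes)
    n3 = len(rest & term_genes)
    return ContingencyTable(n1, len(qset) - n1, n3, len(rest) - n3)


def log_odds(
    table: ContingencyTable, zero_correction: str = "haldane"
) -> tuple[float, float, bool]:
    """Log odds ratio and its Woolf standard error.

    Returns ``(log_delta, se, corrected)``.  With a zero cell and
    ``zero_correction="haldane"``, 0.5 is added to all four cells before
    computing; with ``"skip"`` both values come back NaN and the term is
    meant to be excluded downstream.
    """
    if zero_correction not in ("haldane", "skip"):
        raise ValueError(f"unknown zero_correction {zero_correction!r}")
    n1, n2, n3, n4 = table.as_tuple()
    corrected = False
    if min(n1, n2, n3, n4) == 0:
        if zero_correction == "skip":
            return math.nan, math.nan, False
        n1, n2, n3, n4 = n1 + 0.5, n2 + 0.5, n3 + 0.5, n4 + 0.5
        corrected = True
    log_delta = math.log(n1) + math.log(n4) - math.log(n2) - math.log(n3)
    se = math.sqrt(1.0 / n1 + 1.0 / n2 + 1.0 / n3 + 1.0 / n4)
    return log_delta, se, corrected


def z_single(
    table: ContingencyTable,
    term: str = "",
    genes: Iterable[str] = (),
    zero_correction: str = "haldane",
) -> EnrichmentScore:
    """Score one table: z = log(delta)/SE with two-sided normal p-value."""
    log_delta, se, corrected = log_odds(table, zero_correction)
    if math.isnan(log_delta):
        nan = math.nan
        return EnrichmentScore(
            term=term, table=table, delta=nan, log_delta=nan, se=nan, z=nan,
            ci_low=nan, ci_high=nan, zband_low=nan, zband_high=nan, p=nan,
            genes=frozenset(genes), defined=False,
        )
    z = log_delta / se
    p = max(2.0 * float(norm.sf(abs(z))), P_FLOOR)
    return EnrichmentScore(
        term=term,
        table=table,
        delta=math.exp(log_delta),
        log_delta=log_delta,
        se=se,
        z=z,
        ci_low=log_delta - Z_95 * se,
        ci_high=log_delta + Z_95 * se,
        zband_low=z - Z_95 * se,
        zband_high=z + Z_95 * se,
        p=p,
        genes=frozenset(genes),
        corrected=corrected,
    )


def enrich(
    query: Sequence[str],
    annot: AnnotationSet,
    graph: OntologyGraph | None = None,
    background: Iterable[str] | None = None,
    min_count: int = 2,
    zero_correction: str = "haldane",
    label: str = "query",
) -> EnrichmentProfile:
    """Score every term with at least ``min_count`` query hits.

    Parameters
    ----------
    query
        Ordered gene list of the experiment.
    annot
        Propagated annotations; its ``universe`` is the default background.
    graph
        Optional ontology, used only to attach term names to the profile.
    background
        Optional explicit universe; must contain the query.
    min_count
        Minimum number of query genes hitting a term for it to be scored
        (0 scores everything, including empty terms).
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    qset = set(query)
    bg = set(background) if background is not None else set(annot.universe)
    # validate once so per-term build_table cannot fail midway
    if not qset:
        raise ValueError("empty query gene set")
    missing = qset - bg
    if missing:
        raise ValueError(
            f"{len(missing)} query genes absent from the background universe "
            f"(e.g. {sorted(missing)[:3]})"
        )
    if bg == qset:
        raise ValueError(
            "background equals the query: no genes left in the comparison row"
        )
    scores: dict[str, EnrichmentScore] = {}
    for term in sorted(annot.propagated):
        hits = qset & annot.genes_for(term)
        if len(hits) < min_count:
            continue
        table = build_table(term, qset, annot, bg)
        scores[term] = z_single(table, term=term, genes=hits,
                                zero_correction=zero_correction)
    names = {}
    if graph is not None:
        names = {t: graph.name(t) for t in scores if t in graph}
    return EnrichmentProfile(
        label=label,
        query=list(query),
        background=bg,
        scores=scores,
        min_count=min_count,
        names=names,
    )


PROFILE_COLUMNS = (
    "term", "name", "n1", "n2", "n3", "n4", "delta", "log_delta", "se", "z",
    "ci_low", "ci_high", "zband_low", "zband_high", "p", "genes",
)


def write_profile(profile: EnrichmentProfile, handle: IO[str]) -> None:
    """Serialize a profile as TSV (header comments carry label/query/universe)."""
    handle.write(f"# label: {profile.label}\n")
    handle.write(f"# min_count: {profile.min_count}\n")
    handle.write(f"# query: {','.join(profile.query)}\n")
    handle.write(f"# background: {','.join(sorted(profile.background))}\n")
    handle.write("\t".join(PROFILE_COLUMNS) + "\n")
    for term in sorted(profile.scores):
        s = profile.scores[term]
        t = s.table
        row = [
            term, profile.names.get(term, ""),
            f"{t.n1:g}", f"{t.n2:g}", f"{t.n3:g}", f"{t.n4:g}",
            f"{s.delta:.10g}", f"{s.log_delta:.10g}", f"{s.se:.10g}",
            f"{s.z:.10g}", f"{s.ci_low:.10g}", f"{s.ci_high:.10g}",
            f"{s.zband_low:.10g}", f"{s.zband_high:.10g}", f"{s.p:.10g}",
            ",".join(sorted(s.genes)),
        ]
        handle.write("\t".join(row) + "\n")


def read_profile(source: str | IO[str]) -> EnrichmentProfile:
    """Read a profile written by :func:`write_profile`."""
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    label, min_count, query, background = "query", 2, [], set()
    scores: dict[str, EnrichmentScore] = {}
    names: dict[str, str] = {}
    try:
        header_seen = False
        for line in source:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                key, _, value = line[2:].partition(": ")
                if key == "label":
                    label = value
                elif key == "min_count":
                    min_count = int(value)
                elif key == "query":
                    query = [g for g in value.split(",") if g]
                elif key == "background":
                    background = {g for g in value.split(",") if g}
                continue
            if not header_seen:
                if line.split("\t") != list(PROFILE_COLUMNS):
                    raise ValueError("unrecognized profile header")
                header_seen = True
                continue
            cols = line.split("\t")
            table = ContingencyTable(*(float(c) for c in cols[2:6]))
            genes = frozenset(g for g in cols[15].split(",") if g)
            vals = [float(c) for c in cols[6:15]]
            score = EnrichmentScore(
                term=cols[0], table=table, delta=vals[0], log_delta=vals[1],
                se=vals[2], z=vals[3], ci_low=vals[4], ci_high=vals[5],
                zband_low=vals[6], zband_high=vals[7], p=vals[8],
                genes=genes, defined=not math.isnan(vals[1]),
            )
            scores[cols[0]] = score
            if cols[1]:
                names[cols[0]] = cols[1]
    finally:
        if close:
            source.close()
    return EnrichmentProfile(
        label=label, query=query, background=background,
        scores=scores, min_count=min_count, names=names,
    )
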