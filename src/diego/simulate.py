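"""Synthetic ontologies, genomes, annotations and experiments.

The generator produces a complete, internally consistent toy study: a random
acyclic ontology, a toy genome whose genes carry Poisson-distributed direct
annotations, and per-experiment gene lists (optionally BED peak sets at the
genes' promoters) drawn with planted per-term odds-ratio enrichment.  Every
output is plain text, parseable by the package's own readers, and
byte-identical for a fixed :class:`SimConfig`.

Planted enrichment is sampled from the exponentially tilted subset
distribution P(S) proportional to the product of per-gene weights
w(g) = prod_t OR_t^[g in propagated(t)].  For a single planted term this is
exactly Fisher's noncentral hypergeometric distribution, whose realized
sample odds ratio concentrates at the planted OR; sequential
probability-proportional-to-weight draws (the Wallenius scheme) would
systematically overshoot the planted odds ratio and are not used.  With
several overlapping planted terms the tilted distribution is sampled by a
Metropolis swap chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import nchypergeom_fisher

from diego.genome import GenomicInterval, PeakSet, TranscriptRecord
from diego.ontology import AnnotationSet, OntologyGraph, parse_obo, propagate


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale study: 500 genes on 5 chromosomes, a
    100-term DAG, about 3 direct annotations per gene, and experiments of
    150 genes each.
    """

    seed: int
    n_genes: int = 500
    n_terms: int = 100
    extra_parent_prob: float = 0.2
    annotation_rate: float = 3.0
    query_size: int = 150
    #: term id -> {experiment label -> odds ratio}; absent means OR = 1
    planted: dict[str, dict[str, float]] = field(default_factory=dict)
    peak_mode: bool = False
    n_chromosomes: int = 5

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("need at least 2 terms")
        if self.query_size > self.n_genes:
            raise ValueError("query_size exceeds n_genes")
        for term, per_exp in self.planted.items():
            for odds in per_exp.values():
                if odds <= 0:
                    raise ValueError(f"odds ratio for {term} must be > 0")


@dataclass
class SimOutput:
    config: SimConfig
    graph: OntologyGraph
    obo_text: str
    transcripts: list[TranscriptRecord]
    transcript_tsv: str
    direct: dict[str, set[str]]
    association_tsv: str
    annotations: AnnotationSet
    labels: list[str]
    gene_lists: dict[str, list[str]]
    peak_sets: dict[str, PeakSet]
    truth: dict

    def write(self, out_dir: str | Path) -> Path:
        """Write all fixture files (OBO, TSVs, gene lists, BEDs, truth.json)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "ontology.obo").write_text(self.obo_text)
        (out / "transcripts.tsv").write_text(self.transcript_tsv)
        (out / "associations.tsv").write_text(self.association_tsv)
        (out / "genes_all.txt").write_text(
            "".join(f"{t.gene}\n" for t in self.transcripts)
        )
        for label in self.labels:
            (out / f"{label}.genes.txt").write_text(
                "".join(f"{g}\n" for g in self.gene_lists[label])
            )
            peaks = self.peak_sets.get(label)
            if peaks is not None:
                with open(out / f"{label}.bed", "w") as fh:
                    from diego.genome import write_bed

                    write_bed(peaks, fh)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")
        return out


def _term_id(index: int) -> str:
    return f"T:{index + 1:07d}"


def _gene_id(index: int) -> str:
    return f"g{index + 1:04d}"


def simulate_ontology(cfg: SimConfig) -> tuple[OntologyGraph, str]:
    """Random DAG: term k takes one uniform parent among earlier terms, plus
    a second (``part_of``) parent with probability ``extra_parent_prob``.
    Acyclic by construction (edges only point to earlier terms)."""
    rng = np.random.default_rng([cfg.seed, 1])
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    parents: list[list[tuple[str, str]]] = [[]]
    for k in range(1, cfg.n_terms):
        p1 = int(rng.integers(0, k))
        plist = [(_term_id(p1), "is_a")]
        if k >= 2 and rng.random() < cfg.extra_parent_prob:
            p2 = int(rng.integers(0, k - 1))
            if p2 >= p1:
                p2 += 1  # distinct second parent
            plist.append((_term_id(p2), "part_of"))
        parents.append(plist)
    for k in range(cfg.n_terms):
        lines.append("[Term]")
        lines.append(f"id: {_term_id(k)}")
        lines.append(f"name: synthetic term {k + 1}")
        lines.append("namespace: synthetic")
        for pid, rel in parents[k]:
            if rel == "is_a":
                lines.append(f"is_a: {pid}")
            else:
                lines.append(f"relationship: part_of {pid}")
        lines.append("")
    obo_text = "\n".join(lines)
    import io

    return parse_obo(io.StringIO(obo_text)), obo_text


def simulate_genome_and_annotations(
    cfg: SimConfig, graph: OntologyGraph
) -> tuple[list[TranscriptRecord], str, dict[str, set[str]], str]:
    """Toy genome plus Poisson direct annotations.

    Genes sit on ``n_chromosomes`` synthetic chromosomes as non-overlapping
    2 kb transcripts whose starts are 12 kb apart (10 kb gaps), strand
    alternating.  Each gene draws Poisson(``annotation_rate``) direct terms
    uniformly without replacement.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    term_ids = [_term_id(k) for k in range(cfg.n_terms)]
    transcripts = []
    per_chrom_index: dict[str, int] = {}
    tsv_lines = ["gene\tchrom\ttxStart\ttxEnd\tstrand"]
    for i in range(cfg.n_genes):
        chrom = f"chr{i % cfg.n_chromosomes + 1}"
        j = per_chrom_index.get(chrom, 0)
        per_chrom_index[chrom] = j + 1
        start = 10000 + j * 12000
        end = start + 2000
        strand = "+" if i % 2 == 0 else "-"
        gene = _gene_id(i)
        transcripts.append(
            TranscriptRecord(gene, GenomicInterval(chrom, start, end, strand=strand))
        )
        tsv_lines.append(f"{gene}\t{chrom}\t{start}\t{end}\t{strand}")

    direct: dict[str, set[str]] = {}
    assoc_lines = []
    for i in range(cfg.n_genes):
        gene = _gene_id(i)
        k = min(int(rng.poisson(cfg.annotation_rate)), cfg.n_terms)
        if k == 0:
            continue
        chosen = rng.choice(cfg.n_terms, size=k, replace=False)
        terms = {term_ids[c] for c in chosen}
        direct[gene] = terms
        for t in sorted(terms):
            assoc_lines.append(f"{gene}\t{t}")
    return (
        transcripts,
        "\n".join(tsv_lines) + "\n",
        direct,
        "\n".join(assoc_lines) + "\n",
    )


def _tilted_subset(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Sample k indices without replacement from P(S) ~ prod(weights[S]).

    Uniform weights reduce to a plain uniform subset; two weight classes are
    sampled exactly via Fisher's noncentral hypergeometric; more classes use
    a seeded Metropolis swap chain (stationary distribution is the tilted
    subset law).
    """
    n = len(weights)
    distinct = np.unique(weights)
    if len(distinct) == 1:
        return rng.choice(n, size=k, replace=False)
    if len(distinct) == 2:
        lo, hi = distinct
        hi_idx = np.flatnonzero(weights == hi)
        lo_idx = np.flatnonzero(weights == lo)
        odds = hi / lo
        kmin = max(0, k - len(lo_idx))
        kmax = min(k, len(hi_idx))
        k_hi = int(
            nchypergeom_fisher.rvs(n, len(hi_idx), k, odds, random_state=rng)
        )
        k_hi = min(max(k_hi, kmin), kmax)
        chosen_hi = rng.choice(hi_idx, size=k_hi, replace=False)
        chosen_lo = rng.choice(lo_idx, size=k - k_hi, replace=False)
        return np.concatenate([chosen_hi, chosen_lo])
    # Metropolis swap chain over subsets
    logw = np.log(weights)
    current = rng.choice(n, size=k, replace=False)
    in_set = np.zeros(n, dtype=bool)
    in_set[current] = True
    members = list(current)
    n_iter = 40 * n
    for _ in range(n_iter):
        i_pos = int(rng.integers(0, k))
        a = members[i_pos]
        b = int(rng.integers(0, n))
        if in_set[b]:
            continue
        if math.log(rng.random()) < logw[b] - logw[a]:
            in_set[a] = False
            in_set[b] = True
            members[i_pos] = b
    return np.array(members)


def _realized_odds(
    query: set[str], term_genes: set[str], universe: list[str]
) -> float:
    rest = set(universe) - query
    n1 = len(query & term_genes)
    n2 = len(query) - n1
    n3 = len(rest & term_genes)
    n4 = len(rest) - n3
    if min(n1, n2, n3, n4) == 0:
        n1, n2, n3, n4 = n1 + 0.5, n2 + 0.5, n3 + 0.5, n4 + 0.5
    return (n1 * n4) / (n2 * n3)


def simulate_experiment(
    cfg: SimConfig,
    annot: AnnotationSet,
    experiment_index: int,
    transcripts: list[TranscriptRecord] | None = None,
) -> tuple[list[str], PeakSet | None, dict]:
    """Draw one experiment's gene list (and peaks in ``peak_mode``).

    Genes are sampled without replacement from the tilted subset law with
    per-gene weights w(g) = prod over planted terms t of OR_t^[g in
    propagated(t)], using this experiment's planted odds ratios (absent
    means 1, i.e. a null draw).  The realized odds ratio of every planted
    term is recorded in the returned truth record.
    """
    label = f"expt{experiment_index + 1}"
    rng = np.random.default_rng([cfg.seed, 3, experiment_index])
    universe = [_gene_id(i) for i in range(cfg.n_genes)]
    weights = np.ones(cfg.n_genes)
    for term, per_exp in sorted(cfg.planted.items()):
        odds = per_exp.get(label, 1.0)
        if odds == 1.0:
            continue
        term_genes = annot.genes_for(term)
        mask = np.array([g in term_genes for g in universe])
        weights[mask] *= odds
    idx = np.sort(_tilted_subset(rng, weights, cfg.query_size))
    genes = [universe[i] for i in idx]

    qset = set(genes)
    truth = {"label": label, "planted": {}}
    for term, per_exp in sorted(cfg.planted.items()):
        truth["planted"][term] = {
            "target_or": per_exp.get(label, 1.0),
            "realized_or": _realized_odds(qset, annot.genes_for(term), universe),
        }

    peaks = None
    if cfg.peak_mode:
        if transcripts is None:
            raise ValueError("peak_mode needs the transcript table")
        by_gene = {t.gene: t for t in transcripts}
        intervals = []
        for g in genes:
            iv = by_gene[g].interval
            if iv.strand == "+":
                lo, hi = max(0, iv.start - 400), iv.start
            else:
                lo, hi = iv.end, iv.end + 400
            intervals.append(GenomicInterval(iv.chrom, lo, hi, strand=iv.strand,
                                             name=g))
        peaks = PeakSet(label=label, intervals=intervals)
    return genes, peaks, truth


def simulate(
    cfg: SimConfig,
    n_experiments: int = 2,
    out_dir: str | Path | None = None,
) -> SimOutput:
    """Run all generator stages and optionally write the fixture directory.

    Each stage draws from its own seed substream, so changing a later
    stage's parameters leaves earlier stages' outputs untouched.
    """
    graph, obo_text = simulate_ontology(cfg)
    transcripts, tx_tsv, direct, assoc_tsv = simulate_genome_and_annotations(
        cfg, graph
    )
    all_genes = [t.gene for t in transcripts]
    annot = propagate(graph, direct, extra_universe=all_genes)

    labels, gene_lists, peak_sets, truths = [], {}, {}, []
    for i in range(n_experiments):
        genes, peaks, truth = simulate_experiment(cfg, annot, i, transcripts)
        labels.append(truth["label"])
        gene_lists[truth["label"]] = genes
        if peaks is not None:
            peak_sets[truth["label"]] = peaks
        truths.append(truth)

    out = SimOutput(
        config=cfg,
        graph=graph,
        obo_text=obo_text,
        transcripts=transcripts,
        transcript_tsv=tx_tsv,
        direct=direct,
        association_tsv=assoc_tsv,
        annotations=annot,
        labels=labels,
        gene_lists=gene_lists,
        peak_sets=peak_sets,
        truth={
            "seed": cfg.seed,
            "n_genes": cfg.n_genes,
            "n_terms": cfg.n_terms,
            "experiments": truths,
        },
    )
    if out_dir is not None:
        out.write(out_dir)
    return out


def plant_shared_enrichment(
    annot: AnnotationSet,
    labels: list[str],
    odds_ratios: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 3.0),
    size_range: tuple[int, int] = (30, 120),
) -> dict[str, dict[str, float]]:
    """Planted-effect map for replicate experiments sharing true enrichment.

    Spreads ``odds_ratios`` over evenly spaced mid-size terms and plants each
    identically in every experiment: the pair is null for *differential*
    enrichment while both experiments carry genuine enrichment.  This is the
    realistic replicate situation in which per-experiment significance
    thresholds straddle and hard-threshold overlap comparisons over-report.
    """
    sizes = sorted((len(g), t) for t, g in annot.propagated.items())
    mids = [t for n, t in sizes if size_range[0] <= n <= size_range[1]]
    if not mids:
        raise ValueError("no terms in the requested size range")
    step = max(1, len(mids) // len(odds_ratios))
    hosts = mids[::step][: len(odds_ratios)]
    return {
        t: {lab: o for lab in labels}
        for t, o in zip(hosts, odds_ratios)
    }


def pick_planted_term(
    annot: AnnotationSet,
    graph: OntologyGraph | None = None,
    fraction: float = 0.2,
    separation: float = 1.6,
) -> str:
    """Deterministically pick a term suited to hosting planted enrichment.

    The term's propagated size should be closest to ``fraction`` of the
    universe — big enough to carry signal, small enough to stay specific.
    When ``graph`` is given, candidates separated from their relatives are
    preferred: every ancestor at least ``separation`` times larger and every
    descendant at least ``separation`` times smaller.  A term with a
    near-duplicate ancestor or descendant is a poor planting host because
    the relative inherits (or supplies) essentially the whole effect and
    the planted signal stops being attributable to one term.  Falls back to
    the pure size rule if no candidate separates.
    """
    target = fraction * len(annot.universe)

    def size_key(t: str):
        return (abs(len(annot.propagated[t]) - target), t)

    candidates = sorted(annot.propagated)
    if graph is not None:
        descendants: dict[str, set[str]] = {t: set() for t in candidates}
        for t in candidates:
            for a in graph.ancestors(t):
                descendants[a].add(t)
        separated = [
            t for t in candidates
            if len(annot.propagated[t]) > 0
            and all(
                len(annot.propagated[a]) >= separation * len(annot.propagated[t])
                for a in graph.ancestors(t)
            )
            and all(
                len(annot.propagated[d]) * separation <= len(annot.propagated[t])
                for d in descendants[t]
            )
        ]
        if separated:
            return min(separated, key=size_key)
    return min(candidates, key=size_key)
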