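import io
import re

import pytest

from diego.ontology import (
    OntologyError,
    OntologyGraph,
    OntologyTerm,
    parse_associations,
    parse_obo,
    propagate,
)
from diego.simulate import SimConfig, simulate_ontology


def brute_force_ancestors(graph: OntologyGraph, term: str) -> set:
    """Independent reachability oracle walking OntologyTerm.parents."""
    seen = set()
    stack = [p for p, _ in graph.terms[term].parents]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(p for p, _ in graph.terms[t].parents)
    return seen


class TestParseObo:
    def test_edges_transcribed(self):
        obo = (
            "format-version: 1.2\nontology: x\n\n"
            "[Term]\nid: T:0000001\nname: a\n\n"
            "[Term]\nid: T:0000002\nname: b\nis_a: T:0000001\n\n"
            "[Term]\nid: T:0000003\nname: c\n"
            "relationship: part_of T:0000001\n"
        )
        g = parse_obo(io.StringIO(obo))
        assert set(g.edges()) == {
            ("T:0000002", "T:0000001", "is_a"),
            ("T:0000003", "T:0000001", "part_of"),
        }

    def test_obsolete_terms_dropped(self):
        obo = (
            "format-version: 1.2\nontology: x\n\n"
            "[Term]\nid: T:0000001\nname: a\n\n"
            "[Term]\nid: T:0000002\nname: dead\nis_obsolete: true\n"
        )
        g = parse_obo(io.StringIO(obo))
        assert "T:0000002" not in g
        assert len(g) == 1

    def test_non_propagating_relations_ignored(self):
        obo = (
            "format-version: 1.2\nontology: x\n\n"
            "[Term]\nid: T:0000001\nname: a\n\n"
            "[Term]\nid: T:0000002\nname: b\nis_a: T:0000001\n"
            "relationship: regulates T:0000001\n"
        )
        g = parse_obo(io.StringIO(obo))
        assert g.edges() == [("T:0000002", "T:0000001", "is_a")]

    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            OntologyGraph([
                OntologyTerm("A", parents=(("B", "is_a"),)),
                OntologyTerm("B", parents=(("A", "is_a"),)),
            ])

    def test_self_parent_rejected(self):
        with pytest.raises(OntologyError, match="own parent"):
            OntologyGraph([OntologyTerm("A", parents=(("A", "is_a"),))])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_simulated_obo_roundtrip(self, seed):
        """Re-parsing simulator OBO text recovers exactly its edge list."""
        cfg = SimConfig(seed=seed, n_terms=50)
        graph, obo_text = simulate_ontology(cfg)
        # independent extraction straight from the OBO text
        expected = set()
        current = None
        for line in obo_text.splitlines():
            if m := re.match(r"^id: (T:\d{7})$", line):
                current = m.group(1)
            elif m := re.match(r"^is_a: (T:\d{7})$", line):
                expected.add((current, m.group(1), "is_a"))
            elif m := re.match(r"^relationship: part_of (T:\d{7})$", line):
                expected.add((current, m.group(1), "part_of"))
        reparsed = parse_obo(io.StringIO(obo_text))
        assert set(reparsed.edges()) == expected == set(graph.edges())


GAF_HEADER = "!gaf-version: 2.2\n"


def gaf_row(gene, term, qualifier="involved_in"):
    cols = ["DB", f"id_{gene}", gene, qualifier, term, "PMID:1", "IEA",
            "", "P", "", "", "protein", "taxon:1", "20200101", "DB", "", ""]
    return "\t".join(cols) + "\n"


class TestParseAssociations:
    def test_tsv(self):
        assert parse_associations(io.StringIO("g1\tT:0000001\n")) == {
            "g1": {"T:0000001"}
        }

    def test_gaf_not_qualifier_skipped(self):
        text = GAF_HEADER + gaf_row("g1", "T:0000001", "NOT|involved_in")
        assert parse_associations(io.StringIO(text), dialect="gaf") == {}

    def test_gaf_fixture_counts(self, diamond_graph):
        """20 rows, 3 NOT, 1 dangling term -> 16 rows survive propagation."""
        rows = []
        genes = [f"g{i}" for i in range(20)]
        terms = ["T:0000001", "T:0000002", "T:0000003", "T:0000004"]
        for i, g in enumerate(genes):
            qual = "NOT|involved_in" if i < 3 else "involved_in"
            term = "T:9999999" if i == 3 else terms[i % 4]
            rows.append(gaf_row(g, term, qual))
        direct = parse_associations(io.StringIO(GAF_HEADER + "".join(rows)),
                                    dialect="gaf")
        assert sum(len(v) for v in direct.values()) == 17  # 20 - 3 NOT
        annot = propagate(diamond_graph, direct)
        assert sum(len(v) for v in annot.direct.values()) == 16  # dangling gone

    def test_gene_column_switch(self):
        text = GAF_HEADER + gaf_row("sym1", "T:0000001")
        by_id = parse_associations(io.StringIO(text), dialect="gaf",
                                   gene_column="id")
        assert by_id == {"id_sym1": {"T:0000001"}}


class TestPropagate:
    def test_single_edge(self):
        g = OntologyGraph([
            OntologyTerm("A"), OntologyTerm("B", parents=(("A", "is_a"),)),
        ])
        annot = propagate(g, {"g1": {"B"}})
        assert annot.propagated["A"] == annot.propagated["B"] == {"g1"}

    def test_diamond_no_double_count(self, diamond_graph):
        annot = propagate(diamond_graph, {"g1": {"T:0000004"}})
        assert annot.propagated["T:0000001"] == {"g1"}

    def test_universe_includes_extra_background(self, diamond_graph):
        annot = propagate(diamond_graph, {"g1": {"T:0000002"}},
                          extra_universe=["bg1"])
        assert annot.universe == {"g1", "bg1"}

    def test_idempotent(self, diamond_graph, diamond_annot):
        again = propagate(diamond_graph, diamond_annot.direct)
        assert again.propagated == diamond_annot.propagated

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_bruteforce_closure(self, seed):
        """Propagation equals per-gene transitive-closure enumeration."""
        import numpy as np

        cfg = SimConfig(seed=seed, n_terms=50, n_genes=200)
        graph, _ = simulate_ontology(cfg)
        rng = np.random.default_rng(seed + 1000)
        term_ids = sorted(graph.terms)
        direct = {}
        for i in range(cfg.n_genes):
            k = int(rng.integers(0, 4))
            if k:
                direct[f"g{i}"] = {
                    term_ids[j] for j in rng.choice(50, size=k, replace=False)
                }
        annot = propagate(graph, direct)
        expected = {t: set() for t in term_ids}
        for gene, terms in direct.items():
            for t in terms:
                expected[t].add(gene)
                for anc in brute_force_ancestors(graph, t):
                    expected[anc].add(gene)
        assert annot.propagated == expected
        # monotone counts along every edge
        for child, parent, _ in graph.edges():
            assert len(annot.propagated[parent]) >= len(annot.propagated[child])


class TestAncestors:
    def test_root_has_none(self, diamond_graph):
        assert diamond_graph.ancestors("T:0000001") == frozenset()

    def test_chain(self, diamond_graph):
        assert diamond_graph.ancestors("T:0000004") == {
            "T:0000001", "T:0000002", "T:0000003"
        }

    def test_unknown_term_errors(self, diamond_graph):
        with pytest.raises(OntologyError):
            diamond_graph.ancestors("T:9999999")

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_bruteforce(self, seed):
        graph, _ = simulate_ontology(SimConfig(seed=seed, n_terms=40))
        for t in graph.terms:
            assert graph.ancestors(t) == brute_force_ancestors(graph, t)
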