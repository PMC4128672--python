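"""Protein-to-reference-gene mapping: composition, collapse, provenance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tfcrosstalk.idmap import (
    MappingChain,
    ProteomeList,
    ReferenceGeneSet,
    map_proteins_to_reference,
    merge_reference_sets,
    read_mapping_table,
    read_protein_list,
    write_mapping_table,
)


def chain_of(p2g, g2h, h2r):
    return MappingChain(protein_to_gene=p2g, gene_to_group=g2h, group_to_reference=h2r)


class TestMapProteins:
    def test_many_to_one_collapse_with_provenance(self):
        chain = chain_of({"p1": "gA", "p2": "gA"}, {"gA": "h1"}, {"h1": "mG"})
        res = map_proteins_to_reference(ProteomeList("rat", {"p1", "p2"}), chain)
        assert res.genes == {"mG"}
        assert res.provenance == {"mG": {"p1", "p2"}}
        assert res.unmapped == set()

    def test_missing_first_link_goes_to_unmapped(self):
        chain = chain_of({}, {}, {})
        res = map_proteins_to_reference(ProteomeList("rat", {"p3"}), chain)
        assert res.genes == set() and res.unmapped == {"p3"}

    @pytest.mark.parametrize("broken_step", ["gene", "group", "reference"])
    def test_break_at_any_step_is_unmapped(self, broken_step):
        p2g = {"p": "g"} if broken_step != "gene" else {}
        g2h = {"g": "h"} if broken_step != "group" else {}
        h2r = {"h": "m"} if broken_step != "reference" else {}
        res = map_proteins_to_reference(ProteomeList("rat", {"p"}), chain_of(p2g, g2h, h2r))
        assert res.unmapped == {"p"}

    def test_empty_proteome_warns_not_errors(self, caplog):
        with caplog.at_level("WARNING"):
            res = map_proteins_to_reference(ProteomeList("rat", set()), chain_of({}, {}, {}))
        assert res.genes == set()
        assert any("empty" in r.message for r in caplog.records)

    def test_fifty_protein_fixture_matches_exhaustive_walk(self):
        # 30 complete chains over 18 distinct genes (12 redundant pairs), 8 broken links
        rng = np.random.default_rng(42)
        p2g, g2h, h2r = {}, {}, {}
        proteins = [f"P{i:02d}" for i in range(50)]
        # proteins 0..29 map onto genes 0..17: first 12 genes get 2 proteins each
        for i in range(30):
            gene = f"g{i // 2}" if i < 24 else f"g{i - 12}"
            p2g[proteins[i]] = gene
        for j in range(18):
            g2h[f"g{j}"] = f"h{j}"
            h2r[f"h{j}"] = f"m{j}"
        # proteins 30..41 have chains broken at varying depths; 42..49 absent entirely
        for i in range(30, 34):
            p2g[proteins[i]] = f"gX{i}"  # no group link
        for i in range(34, 38):
            p2g[proteins[i]] = f"gY{i}"
            g2h[f"gY{i}"] = f"hY{i}"  # no reference link
        chain = chain_of(p2g, g2h, h2r)
        res = map_proteins_to_reference(ProteomeList("ram", set(proteins)), chain)

        # independent oracle: exhaustive walk of the three tables
        expected_genes, expected_unmapped = set(), set()
        for p in proteins:
            try:
                expected_genes.add(h2r[g2h[p2g[p]]])
            except KeyError:
                expected_unmapped.add(p)
        assert res.genes == expected_genes
        assert res.unmapped == expected_unmapped
        assert len(res.genes) == 18
        assert len(res.genes) <= len(proteins)

    @given(
        ids=st.sets(st.text(st.characters(min_codepoint=33, max_codepoint=126), min_size=1, max_size=6), max_size=25),
        fate=st.integers(0, 2),
    )
    def test_conservation_every_input_lands_exactly_once(self, ids, fate):
        """Every protein id ends in exactly one of provenance or unmapped."""
        p2g = {p: f"g{hash(p) % 7}" for i, p in enumerate(sorted(ids)) if i % 3 != fate}
        g2h = {g: g.replace("g", "h") for g in p2g.values()}
        h2r = {h: h.replace("h", "m") for h in g2h.values()}
        res = map_proteins_to_reference(
            ProteomeList("sp", frozenset(ids)) if ids else ProteomeList("sp", frozenset({"x"})),
            chain_of(p2g, g2h, h2r),
        )
        in_prov = set().union(*res.provenance.values()) if res.provenance else set()
        assert in_prov | res.unmapped == (set(ids) or {"x"})
        assert in_prov & res.unmapped == set()

    def test_determinism(self):
        chain = chain_of({"p": "g"}, {"g": "h"}, {"h": "m"})
        prot = ProteomeList("rat", {"p", "q"})
        a = map_proteins_to_reference(prot, chain)
        b = map_proteins_to_reference(prot, chain)
        assert a.genes == b.genes and a.unmapped == b.unmapped


def _rgs(genes, reference="mouse"):
    return ReferenceGeneSet(
        reference=reference, genes=set(genes), provenance={g: {f"p_{g}"} for g in genes}
    )


class TestMerge:
    def test_union_and_identity(self):
        assert merge_reference_sets(_rgs({"g1", "g2"}), _rgs({"g2", "g3"})).genes == {"g1", "g2", "g3"}
        x = _rgs({"a", "b"})
        assert merge_reference_sets(x, _rgs(set())).genes == x.genes

    def test_known_overlap_counting(self):
        rng = np.random.default_rng(3)
        universe = [f"m{i:04d}" for i in range(400)]
        a = set(rng.choice(universe, 100, replace=False))
        shared = set(list(a)[:37])
        rest = [g for g in universe if g not in a]
        b = shared | set(rng.choice(rest, 63, replace=False))
        merged = merge_reference_sets(_rgs(a), _rgs(b))
        assert len(merged.genes) == len(a) + len(b) - len(a & b) == 163

    def test_mismatched_reference_space_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            merge_reference_sets(_rgs({"a"}, "mouse"), _rgs({"b"}, "human"))

    @given(
        a=st.sets(st.integers(0, 30), max_size=15),
        b=st.sets(st.integers(0, 30), max_size=15),
        c=st.sets(st.integers(0, 30), max_size=15),
    )
    def test_merge_commutative_and_associative(self, a, b, c):
        A, B, C = (_rgs({str(x) for x in s}) for s in (a, b, c))
        assert merge_reference_sets(A, B).genes == merge_reference_sets(B, A).genes
        left = merge_reference_sets(merge_reference_sets(A, B), C).genes
        right = merge_reference_sets(A, merge_reference_sets(B, C)).genes
        assert left == right

    def test_provenance_unioned_per_gene(self):
        a = ReferenceGeneSet("mouse", {"g"}, set(), {"g": {"p1"}})
        b = ReferenceGeneSet("mouse", {"g"}, set(), {"g": {"p2"}})
        assert merge_reference_sets(a, b).provenance["g"] == {"p1", "p2"}


class TestIO:
    def test_protein_list_skips_comments(self, tmp_path):
        f = tmp_path / "prot.txt"
        f.write_text("# header comment\nP1\n\nP2\n")
        pl = read_protein_list(f, "rat")
        assert pl.protein_ids == {"P1", "P2"}

    def test_mapping_table_round_trip_and_function_invariant(self, tmp_path):
        f = tmp_path / "map.tsv"
        write_mapping_table({"a": "1", "b": "2"}, f)
        assert read_mapping_table(f) == {"a": "1", "b": "2"}
        f.write_text("source\ttarget\na\t1\na\t2\n")
        with pytest.raises(ValueError, match="conflicting"):
            read_mapping_table(f)
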