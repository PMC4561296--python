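"""Gene-set model, GMT/TSV I/O, normalization and direction-aware set algebra."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from generep.geneset import (
    Catalog,
    DirectionError,
    GeneSet,
    GmtParseError,
    InvalidIdentifierError,
    SchemaError,
    Universe,
    concordant_subset,
    discordant_subset,
    normalize_identifier,
    read_gmt,
    read_signed_table,
    restrict,
    split_by_direction,
    write_gmt,
)
from conftest import make_set

genes_strategy = st.sets(st.sampled_from([f"G{i:03d}" for i in range(60)]), max_size=40)


class TestNormalizeIdentifier:
    @pytest.mark.parametrize(
        "raw, alias_map, expected",
        [
            ("hnf4a ", None, "HNF4A"),
            ("CHREBP", {"CHREBP": "MLXIPL"}, "MLXIPL"),
            ("FOXO1A", {}, "FOXO1A"),  # legacy symbols pass through untouched
            ("  mlxipl\t", None, "MLXIPL"),
        ],
    )
    def test_examples(self, raw, alias_map, expected):
        assert normalize_identifier(raw, alias_map) == expected

    @pytest.mark.parametrize("raw", ["", "   ", "\t\n"])
    def test_empty_identifier_rejected(self, raw):
        with pytest.raises(InvalidIdentifierError):
            normalize_identifier(raw)

    def test_unknown_symbol_warns_once(self):
        amap = {"CHREBP": "MLXIPL"}
        with pytest.warns(UserWarning, match="NOTAGENE"):
            normalize_identifier("NOTAGENE", amap)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert normalize_identifier("NOTAGENE", amap) == "NOTAGENE"

    def test_deterministic(self):
        amap = {"CHREBP": "MLXIPL"}
        assert [normalize_identifier("chrebp", amap) for _ in range(3)] == ["MLXIPL"] * 3


class TestGeneSetInvariants:
    def test_direction_must_cover_all_genes(self):
        with pytest.raises(DirectionError):
            GeneSet(name="x", genes=frozenset({"A", "B"}), direction={"A": 1})

    def test_sign_consistent_with_fold_change(self):
        with pytest.raises(DirectionError):
            GeneSet(
                name="x",
                genes=frozenset({"A"}),
                direction={"A": -1},
                fold_change={"A": 2.0},
            )

    def test_fold_change_positive(self):
        with pytest.raises(ValueError):
            GeneSet(name="x", genes=frozenset({"A"}), fold_change={"A": -1.0})

    def test_catalog_role_immutable(self):
        cat = Catalog(role="phenotype")
        with pytest.raises(AttributeError):
            cat.role = "condition"

    def test_catalog_rejects_duplicate_set_names(self):
        cat = Catalog(role="phenotype")
        cat.add(make_set("LIVER", {"ALB"}))
        with pytest.raises(ValueError):
            cat.add(make_set("LIVER", {"AFP"}))


class TestGmtIO:
    def test_duplicates_collapsed_with_warning(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("LIVER\tsrc\tALB\tAFP\tALB\n")
        with pytest.warns(UserWarning, match="duplicate"):
            cat = read_gmt(p)
        assert cat.sets["LIVER"].genes == {"ALB", "AFP"}

    def test_empty_file_gives_empty_catalog(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0

    def test_large_membership_line(self, tmp_path):
        genes = "\t".join(f"g{i}" for i in range(129))
        p = tmp_path / "glc.gmt"
        p.write_text(f"GLUCOSE_HEPG2\thigh glucose response\t{genes}\n")
        assert len(read_gmt(p).sets["GLUCOSE_HEPG2"]) == 129

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("OK\tsrc\tA\nBADLINE\n")
        with pytest.raises(GmtParseError, match=":2"):
            read_gmt(p)

    def test_round_trip_preserves_membership(self, tmp_path):
        cat = Catalog(role="pathway_targets")
        cat.add(make_set("A", {"G1", "G2", "G3"}, description="first"))
        cat.add(make_set("B", {"G2", "G9"}, description="second"))
        out = tmp_path / "rt.gmt"
        write_gmt(cat, out)
        back = read_gmt(out, role="pathway_targets")
        assert set(back.sets) == set(cat.sets)
        for name in cat.sets:
            assert back.sets[name].genes == cat.sets[name].genes


class TestSignedTable:
    def _write(self, tmp_path, rows, header="gene\tfold_change"):
        p = tmp_path / "t.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_symmetric_threshold(self, tmp_path):
        p = self._write(tmp_path, ["A\t2.0", "B\t1.2", "C\t0.5"])
        gs = read_signed_table(p, fc_threshold=1.4)
        assert gs.genes == {"A", "C"}
        assert gs.direction == {"A": +1, "C": -1}

    def test_no_gene_passes_at_unit_fold_change(self, tmp_path):
        p = self._write(tmp_path, ["A\t1.0", "B\t1.0"])
        assert len(read_signed_table(p)) == 0

    def test_count_matches_independent_scan(self, tmp_path, rng):
        fcs = rng.lognormal(mean=0.0, sigma=0.6, size=500)
        rows = [f"g{i}\t{fc:.6f}" for i, fc in enumerate(fcs)]
        p = self._write(tmp_path, rows)
        expected = sum(1 for fc in fcs if fc > 1.4 or fc < 1 / 1.4)
        assert len(read_signed_table(p, fc_threshold=1.4)) == expected

    def test_log2fc_dialect(self, tmp_path):
        p = self._write(tmp_path, ["A\t1.0", "B\t-1.0", "C\t0.1"], header="gene\tlog2fc")
        gs = read_signed_table(p, fc_threshold=1.4)
        assert gs.direction == {"A": +1, "B": -1}

    def test_nonpositive_fold_change_rejected(self, tmp_path):
        p = self._write(tmp_path, ["A\t-2.0"])
        with pytest.raises(SchemaError):
            read_signed_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = self._write(tmp_path, ["A\t2.0"], header="gene\tscore")
        with pytest.raises(SchemaError):
            read_signed_table(p)


class TestRestrict:
    def test_subset_unchanged(self, small_universe):
        s = make_set("s", {"G0001", "G0002"})
        assert restrict(s, small_universe).genes == s.genes

    def test_disjoint_empty(self, small_universe):
        s = make_set("s", {"X1", "X2"})
        assert len(restrict(s, small_universe)) == 0

    def test_detected_background_shrinks_set(self):
        # a 447-gene list of which only 129 are detected in the cell line
        inside = {f"IN{i}" for i in range(129)}
        outside = {f"OUT{i}" for i in range(318)}
        universe = Universe(genes=frozenset(inside | {f"U{i}" for i in range(20000)}))
        s = make_set("high_glucose", inside | outside)
        assert len(restrict(s, universe)) == 129

    @given(genes=genes_strategy, universe_genes=genes_strategy)
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_monotone(self, genes, universe_genes):
        if not universe_genes:
            universe_genes = {"G000"}
        u = Universe(genes=frozenset(universe_genes))
        s = make_set("s", genes)
        once = restrict(s, u)
        assert restrict(once, u).genes == once.genes
        sub = make_set("sub", set(sorted(genes)[: len(genes) // 2]))
        assert restrict(sub, u).genes <= once.genes

    def test_direction_preserved(self, small_universe):
        s = make_set("s", ["G0001", "X9"], signs=[+1, -1])
        r = restrict(s, small_universe)
        assert r.direction == {"G0001": +1}


class TestConcordance:
    def test_forced_example(self):
        a = make_set("a", ["X", "Y", "Z"], signs=[+1, -1, +1])
        b = make_set("b", ["X", "Y", "Z"], signs=[+1, +1, -1])
        assert concordant_subset(a, b).genes == {"X"}

    def test_self_concordance_is_identity(self):
        a = make_set("a", ["X", "Y"], signs=[+1, -1])
        assert concordant_subset(a, a).genes == a.genes

    def test_requires_direction(self):
        a = make_set("a", ["X"], signs=[+1])
        b = make_set("b", {"X"})
        with pytest.raises(DirectionError):
            concordant_subset(a, b)

    @given(
        signs_a=st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=30),
        signs_b=st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_concordant_discordant_partition_intersection(self, signs_a, signs_b):
        n = min(len(signs_a), len(signs_b))
        genes = [f"G{i}" for i in range(n)]
        a = make_set("a", genes, signs=signs_a[:n])
        b = make_set("b", genes, signs=signs_b[:n])
        conc, disc = concordant_subset(a, b), discordant_subset(a, b)
        assert conc.genes | disc.genes == a.genes & b.genes
        assert not conc.genes & disc.genes
        assert conc.genes == concordant_subset(b, a).genes  # symmetric membership


class TestSplitByDirection:
    def test_known_split(self):
        genes = [f"G{i}" for i in range(213)]
        signs = [+1] * 34 + [-1] * 179
        up, down = split_by_direction(make_set("deg", genes, signs=signs))
        assert (len(up), len(down)) == (34, 179)

    def test_all_positive(self):
        up, down = split_by_direction(make_set("s", ["A", "B"], signs=[+1, +1]))
        assert len(up) == 2 and len(down) == 0

    @given(signs=st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_partition_sizes_match_sign_tally(self, signs):
        genes = [f"G{i}" for i in range(len(signs))]
        up, down = split_by_direction(make_set("s", genes, signs=signs))
        assert len(up) == sum(1 for s in signs if s > 0)
        assert len(up) + len(down) == len(signs)

    def test_requires_direction(self):
        with pytest.raises(DirectionError):
            split_by_direction(make_set("s", {"A"}))
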