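"""Diagnostic position discovery, matrix analysis, minimal set search."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladebarcode import (
    Alignment,
    OPUAssignment,
    build_matrix,
    find_diagnostic_positions,
    minimal_diagnostic_set,
    read_opu_table,
    redundant_diagnostic_set,
    published_matrix_fixture,
)
from cladebarcode.diagnostics import (
    DiagnosticMatrix,
    DiagnosticPosition,
    OPUError,
    opu_state,
    read_matrix_tsv,
    write_matrix_tsv,
)


def matrix_from_profiles(profiles: dict[str, str]) -> DiagnosticMatrix:
    """Build a matrix directly from OPU -> state-string profiles."""
    opus = list(profiles)
    n = len(next(iter(profiles.values())))
    positions = tuple(
        DiagnosticPosition(
            region="m",
            pos_1based=j + 1,
            state_by_opu={o: profiles[o][j] for o in opus},
        )
        for j in range(n)
    )
    return DiagnosticMatrix(positions=positions, opu_labels=tuple(opus))


def brute_force_minimum(matrix: DiagnosticMatrix) -> tuple[int, tuple[int, ...]]:
    """Oracle: smallest subset (lexicographically first) reaching the full
    matrix's unique-OPU count, by direct enumeration of all subsets."""
    profs = matrix.profiles
    n = len(matrix.positions)

    def n_unique(idx):
        rp = {o: tuple(p[i] for i in idx) for o, p in profs.items()}
        return sum(1 for v in rp.values() if list(rp.values()).count(v) == 1)

    target = n_unique(tuple(range(n)))
    for k in range(n + 1):
        for combo in combinations(range(n), k):
            if n_unique(combo) == target:
                return k, combo
    raise AssertionError


class TestReadOPUTable:
    def test_basic_table_with_header(self, tmp_path):
        p = tmp_path / "opus.tsv"
        p.write_text("sample\topu\na\tg1\nb\tg1\nc\tg2\n")
        opus = read_opu_table(p)
        assert opus.opu_labels == ("g1", "g2")
        assert opus.members("g1") == ["a", "b"]

    def test_headerless_table(self, tmp_path):
        p = tmp_path / "opus.tsv"
        p.write_text("a\tg1\nb\tg2\n")
        assert read_opu_table(p).opu_labels == ("g1", "g2")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "opus.tsv"
        p.write_text("")
        with pytest.raises(OPUError, match="empty"):
            read_opu_table(p)

    def test_conflicting_duplicate_rejected(self, tmp_path):
        p = tmp_path / "opus.tsv"
        p.write_text("a\tg1\na\tg2\n")
        with pytest.raises(OPUError, match="assigned to both"):
            read_opu_table(p)

    def test_samples_missing_from_table_are_reported(self):
        aln = Alignment(sample_ids=("a", "b", "c"), rows=("A", "C", "G"))
        opus = OPUAssignment.from_mapping({"a": "g1", "b": "g2", "zz": "g3"})
        restricted, unassigned = opus.restricted_to(aln)
        assert restricted.opu_labels == ("g1", "g2")
        assert unassigned == ["c"]


class TestOPUState:
    @pytest.mark.parametrize(
        "symbols,expected",
        [
            (["A", "A", "A"], "A"),
            (["A", "C"], "polymorphic"),
            (["A", "N", "-"], "N"),       # missing fraction 2/3 > 0.5
            (["N", "N"], "N"),
            (["A", "N"], "A"),            # 0.5 missing allowed
        ],
    )
    def test_state_summaries(self, symbols, expected):
        assert opu_state(symbols) == expected

    def test_missing_tolerance_flag(self):
        assert opu_state(["A", "N", "N", "N"], max_missing_in_group=0.8) == "A"
        assert opu_state(["A", "N", "N", "N"], max_missing_in_group=0.5) == "N"


class TestFindDiagnosticPositions:
    def two_group_alignment(self):
        # column 0: g1 fixed A, g2 fixed C (diagnostic for both)
        # column 1: g1 polymorphic (A/C), g2 fixed G
        # column 2: constant
        rows = ("AAT", "AAT", "ACT", "CGT", "CGT")
        ids = ("a1", "a2", "a3", "b1", "b2")
        opus = OPUAssignment.from_mapping(
            {"a1": "g1", "a2": "g1", "a3": "g1", "b1": "g2", "b2": "g2"}
        )
        return Alignment(sample_ids=ids, rows=rows), opus

    def test_two_fixed_states_diagnostic_for_both(self):
        aln, opus = self.two_group_alignment()
        positions = find_diagnostic_positions(aln, opus)
        by_col = {p.column: p for p in positions}
        assert by_col[0].diagnostic_for == {"g1", "g2"}
        assert by_col[0].state_by_opu == {"g1": "A", "g2": "C"}

    def test_polymorphic_group_not_diagnostic(self):
        aln, opus = self.two_group_alignment()
        by_col = {p.column: p for p in find_diagnostic_positions(aln, opus)}
        p1 = by_col[1]
        assert p1.state_by_opu["g1"] == "polymorphic"
        # g2 is fixed G, and G does not occur in g1 -> diagnostic for g2 only
        assert p1.diagnostic_for == {"g2"}

    def test_three_group_fixed_absent_enumeration(self):
        # g1 fixed A; g2 polymorphic containing A; g3 fixed C:
        # A occurs outside g1, so only g3 (C absent elsewhere) is diagnostic
        rows = ("A", "A", "A", "G", "C", "C")
        ids = tuple(f"s{i}" for i in range(6))
        opus = OPUAssignment.from_mapping(
            {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2", "s4": "g3", "s5": "g3"}
        )
        (p,) = find_diagnostic_positions(Alignment(sample_ids=ids, rows=rows), opus)
        assert p.state_by_opu == {"g1": "A", "g2": "polymorphic", "g3": "C"}
        assert p.diagnostic_for == {"g3"}

    def test_all_missing_group_gets_n_and_never_diagnostic(self):
        rows = ("A", "A", "N", "N", "C", "C")
        ids = tuple(f"s{i}" for i in range(6))
        opus = OPUAssignment.from_mapping(
            {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2", "s4": "g3", "s5": "g3"}
        )
        (p,) = find_diagnostic_positions(Alignment(sample_ids=ids, rows=rows), opus)
        assert p.state_by_opu["g2"] == "N"
        assert p.diagnostic_for == {"g1", "g3"}

    def test_single_opu_rejected(self):
        aln = Alignment(sample_ids=("a", "b"), rows=("AC", "AC"))
        opus = OPUAssignment.from_mapping({"a": "g1", "b": "g1"})
        with pytest.raises(OPUError, match="at least two"):
            find_diagnostic_positions(aln, opus)

    def test_adding_consensus_sample_never_shrinks_diagnostics(self):
        aln, opus = self.two_group_alignment()
        before = {
            p.column: p.diagnostic_for
            for p in find_diagnostic_positions(aln, opus)
        }
        # append a sample matching g1's consensus at every fixed column
        aln2 = Alignment(
            sample_ids=aln.sample_ids + ("a4",), rows=aln.rows + ("AAT",)
        )
        opus2 = OPUAssignment.from_mapping({**opus.mapping, "a4": "g1"})
        after = {
            p.column: p.diagnostic_for
            for p in find_diagnostic_positions(aln2, opus2)
        }
        for col, diag in before.items():
            assert diag <= after.get(col, frozenset())


class TestBuildMatrix:
    def test_published_matrix_uniqueness_and_collision(self):
        matrix, _ = published_matrix_fixture()
        assert len(matrix.positions) == 9
        assert len(matrix.opu_labels) == 9
        assert matrix.unique_opus == {
            "clade_1", "clade_2", "aristata_clade_4", "asiatica_clade_5",
            "clade_6", "clade_7", "Mahonia_clade_9",
        }
        assert matrix.profile_collisions == [frozenset({"clade_3", "SA_clade_8"})]

    def test_soundness_diagnostic_opus_are_profile_unique(self):
        matrix, _ = published_matrix_fixture()
        for p in matrix.positions:
            assert p.diagnostic_for <= matrix.unique_opus

    def test_single_opu_trivially_unique(self):
        m = matrix_from_profiles({"only": "ACGT"})
        assert m.unique_opus == {"only"}
        assert m.profile_collisions == []

    def test_all_identical_profiles_one_collision(self):
        m = matrix_from_profiles({"a": "AC", "b": "AC", "c": "AC"})
        assert m.unique_opus == set()
        assert m.profile_collisions == [frozenset({"a", "b", "c"})]

    def test_n_in_profile_compares_equal_only_to_n(self):
        m = matrix_from_profiles({"a": "AN", "b": "AA"})
        assert m.unique_opus == {"a", "b"}


class TestMinimalSet:
    def test_published_matrix_minimum_is_seven(self):
        matrix, _ = published_matrix_fixture()
        result = minimal_diagnostic_set(matrix)
        k, combo = brute_force_minimum(matrix)
        assert k == 7
        assert result.indices == combo
        assert len(result.achieved_unique) == 7
        assert result.unresolvable == (frozenset({"clade_3", "SA_clade_8"}),)
        assert result.method == "exhaustive"

    def test_three_profiles_two_columns_suffice_lexicographic(self):
        m = matrix_from_profiles({"o1": "AAC", "o2": "ACA", "o3": "CAA"})
        result = minimal_diagnostic_set(m)
        assert result.indices == (0, 1)
        assert len(result.achieved_unique) == 3

    def test_identical_pair_reported_unresolvable(self):
        m = matrix_from_profiles({"a": "AC", "b": "AC", "c": "GT"})
        result = minimal_diagnostic_set(m)
        assert frozenset({"a", "b"}) in result.unresolvable
        assert result.achieved_unique == {"c"}

    def test_no_discriminating_positions(self):
        m = matrix_from_profiles({"a": "A", "b": "A"})
        result = minimal_diagnostic_set(m)
        assert result.indices == ()
        assert result.achieved_unique == frozenset()
        assert result.unresolvable == (frozenset({"a", "b"}),)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_opus=st.integers(2, 5),
        n_pos=st.integers(1, 8),
    )
    def test_exhaustive_matches_brute_force_oracle(self, seed, n_opus, n_pos):
        rng = np.random.default_rng(seed)
        profiles = {
            f"o{i}": "".join(rng.choice(list("ACGT"), size=n_pos))
            for i in range(n_opus)
        }
        m = matrix_from_profiles(profiles)
        result = minimal_diagnostic_set(m)
        k, combo = brute_force_minimum(m)
        assert len(result.indices) == k
        assert result.indices == combo

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_greedy_reaches_full_uniqueness_with_bounded_size(self, seed):
        rng = np.random.default_rng(seed)
        profiles = {
            f"o{i}": "".join(rng.choice(list("ACGT"), size=10))
            for i in range(4)
        }
        m = matrix_from_profiles(profiles)
        exact = minimal_diagnostic_set(m, exhaustive_limit=20)
        greedy = minimal_diagnostic_set(m, exhaustive_limit=0)
        assert greedy.method == "greedy"
        # greedy must reach the same number of unique OPUs, possibly with
        # more positions than the optimum (never fewer)
        assert len(greedy.achieved_unique) == len(exact.achieved_unique)
        assert len(greedy.indices) >= len(exact.indices)

    def test_redundant_set_restores_paired_diagnostics(self):
        # with redundancy 2 the paired diagnostic sites for the same OPU
        # (e.g. two sites both private to the target clade) come back,
        # expanding the 7-position minimum to the full 9-position table
        matrix, _ = published_matrix_fixture()
        redundant = redundant_diagnostic_set(matrix, redundancy=2)
        assert redundant == tuple(range(9))
        minimal = set(minimal_diagnostic_set(matrix).indices)
        assert minimal <= set(redundant)


class TestPlantedRecovery:
    def test_planted_diagnostics_recovered_exactly(self):
        from cladebarcode import SimSpec, simulate_alignment

        spec = SimSpec(
            length=400,
            opu_sizes={"g1": 4, "g2": 3, "g3": 5},
            planted_diagnostics={
                "g1": [(10, "A"), (50, "T")],
                "g2": [(120, "C")],
                "g3": [(300, "G")],
            },
            n_extra_variable=12,
            n_pis=5,
            seed=42,
        )
        aln, opus, truth = simulate_alignment(spec)
        positions = find_diagnostic_positions(aln, opus)
        found = {
            p.column: p.diagnostic_for for p in positions if p.diagnostic_for
        }
        planted = {
            col: {opu}
            for opu, cols in truth["planted_diagnostics"].items()
            for col, _ in cols
        }
        assert found == planted  # 100% precision and recall


def test_matrix_tsv_roundtrip(tmp_path):
    matrix, _ = published_matrix_fixture()
    p = tmp_path / "matrix.tsv"
    write_matrix_tsv(matrix, p, genotype_style=True)
    text = p.read_text()
    assert "AA" in text and "matK:755" in text
    back = read_matrix_tsv(p)
    assert back.profiles == matrix.profiles
    assert back.unique_opus == matrix.unique_opus
    assert [p.label for p in back.positions] == [p.label for p in matrix.positions]
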