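import io

import numpy as np
import pytest

from phylogo.errors import InputError, StructureError
from phylogo.familyqc import (
    MultipleAlignment,
    core_columns,
    criterion_E1,
    criterion_E2,
    criterion_P1,
    criterion_P2,
    flag_family,
    forward_track_ids,
    parse_fasta_alignment,
    write_fasta_alignment,
    write_qc_tsv,
)
from phylogo.fixtures import make_split_msa


def msa_from(rows):
    return MultipleAlignment.from_rows(rows)


def dense(n_rows, width, prefix="m"):
    return msa_from([(f"{prefix}{i}", "A" * width) for i in range(n_rows)])


# -- core columns -----------------------------------------------------------------


def test_all_gap_column_never_core():
    m = msa_from([("a", "A-A"), ("b", "A-A")])
    assert core_columns(m) == [0, 2]


def test_occupancy_boundary_is_inclusive():
    # 2 of 4 rows occupied = exactly 0.5 -> core
    m = msa_from([("a", "A"), ("b", "A"), ("c", "-"), ("d", "-")])
    assert core_columns(m, occupancy=0.5) == [0]


@pytest.mark.parametrize("seed", range(5))
def test_core_columns_match_per_column_count(seed):
    rng = np.random.default_rng(seed)
    rows = [
        (f"m{i}", "".join(rng.choice(["A", "-"], size=40)))
        for i in range(8)
    ]
    m = msa_from(rows)
    expected = [
        j for j in range(40)
        if sum(r[1][j] != "-" for r in rows) / 8 >= 0.5
    ]
    assert core_columns(m) == expected


# -- E1: members not aligning to the core -------------------------------------------


def test_e1_dense_alignment_not_flagged():
    flag, frac = criterion_E1(dense(10, 50))
    assert not flag and frac == 0.0


def test_e1_flags_when_over_half_miss_the_core():
    # 4 dense rows + 6 sparse rows in disjoint 10-column blocks over columns
    # 40-99, so columns 40-99 stay core (5/10 occupancy) while each sparse
    # row holds only 10 core residues (< 30)
    rows = [(f"d{i}", "A" * 100) for i in range(4)]
    for i in range(6):
        start = 40 + 10 * i
        rows.append((f"s{i}", "-" * start + "A" * 10 + "-" * (90 - start)))
    m = msa_from(rows)
    assert core_columns(m) == list(range(40, 100))
    flag, frac = criterion_E1(m)
    assert flag and frac == 0.6


def test_e1_exactly_half_is_not_flagged():
    rows = [(f"d{i}", "A" * 100) for i in range(5)]
    rows += [(f"s{i}", "A" * 10 + "-" * 90) for i in range(5)]
    flag, frac = criterion_E1(msa_from(rows))
    assert frac == 0.5 and not flag


# -- E2: short core, long alignment --------------------------------------------------


def _core_then_junk(n_core, width, n_rows=10):
    # n_core fully occupied columns, the rest occupied by a single row each
    rows = []
    for i in range(n_rows):
        junk = ["-"] * (width - n_core)
        for j in range(i, len(junk), n_rows):
            junk[j] = "A"
        rows.append((f"m{i}", "A" * n_core + "".join(junk)))
    return msa_from(rows)


def test_e2_core99_width396_flagged():
    m = _core_then_junk(99, 396)
    assert len(core_columns(m)) == 99
    assert criterion_E2(m)


def test_e2_core100_not_short():
    m = _core_then_junk(100, 1000)
    assert not criterion_E2(m)


def test_e2_width_just_under_4x_not_flagged():
    m = _core_then_junk(50, 199)
    assert not criterion_E2(m)


def test_e2_width_exactly_4x_flagged():
    m = _core_then_junk(50, 200)
    assert criterion_E2(m)


# -- P1: sparse members ----------------------------------------------------------------


def test_p1_all_members_wide_enough():
    flag, frac = criterion_P1(dense(10, 40))
    assert not flag and frac == 0.0


def test_p1_at_least_ten_percent_boundary():
    rows = [(f"d{i}", "A" * 100) for i in range(9)]
    rows += [("s0", "A" * 29 + "-" * 71)]
    flag, frac = criterion_P1(msa_from(rows))
    assert frac == 0.10 and flag  # "at least 10%" is inclusive


def test_p1_29_vs_30_column_floor():
    rows = [(f"d{i}", "A" * 100) for i in range(9)]
    ok = rows + [("s0", "A" * 30 + "-" * 70)]
    assert not criterion_P1(msa_from(ok))[0]


@pytest.mark.parametrize("seed", range(5))
def test_p1_matches_row_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    rows = [
        (f"m{i}", "".join(rng.choice(["A", "-"], size=80, p=[0.6, 0.4])))
        for i in range(12)
    ]
    m = msa_from(rows)
    core = set(core_columns(m))
    n_sparse = sum(
        1 for _, seq in rows
        if sum(1 for j, c in enumerate(seq) if c != "-" and j in core) < 30
    )
    flag, frac = criterion_P1(m)
    assert frac == n_sparse / 12
    assert flag == (frac >= 0.10)


# -- P2: disjoint subtrees ---------------------------------------------------------------


def test_p2_disjoint_blocks_share_zero():
    msa, tree = make_split_msa(5, 5, 50, 50, overlap=0, seed=1)
    flag, worst = criterion_P2(msa, tree)
    assert flag and worst == 0


def test_p2_overlap_equals_shared_sites():
    msa, tree = make_split_msa(5, 5, 100, 100, overlap=40, seed=2)
    flag, worst = criterion_P2(msa, tree)
    assert worst == 40 and not flag


def test_p2_overlap_29_flagged():
    msa, tree = make_split_msa(5, 5, 100, 100, overlap=29, seed=3)
    flag, worst = criterion_P2(msa, tree)
    assert worst == 29 and flag


def test_p2_full_length_ungapped_no_flag():
    msa, tree = make_split_msa(5, 5, 60, 60, overlap=60, seed=4)
    flag, worst = criterion_P2(msa, tree)
    assert worst == 60 and not flag


def test_p2_leaf_mismatch_is_error():
    msa, tree = make_split_msa(5, 5, 50, 50, overlap=10, seed=5)
    other = msa_from([("x", "AA"), ("y", "AA")])
    with pytest.raises(StructureError, match="differ"):
        criterion_P2(other, tree)


def test_p2_invariant_to_column_permutation():
    msa, tree = make_split_msa(4, 4, 80, 80, overlap=25, seed=6)
    rng = np.random.default_rng(0)
    perm = rng.permutation(msa.width)
    permuted = msa_from(
        [(m, "".join(seq[j] for j in perm)) for m, seq in msa.rows()]
    )
    assert criterion_P2(permuted, tree) == criterion_P2(msa, tree)


# -- union report --------------------------------------------------------------------------


def test_flag_union_and_measurements():
    msa, tree = make_split_msa(5, 5, 60, 60, overlap=0, seed=7)
    report = flag_family(msa, tree)
    # disjoint halves: every member misses half the core -> E1/P2 style flags
    assert "P2_disjoint_subtrees" in report.flags
    assert report.flagged
    assert 0 <= report.noncore_member_fraction <= 1
    assert 0 <= report.sparse_member_fraction <= 1
    assert report.worst_split_shared_sites <= msa.width


def test_clean_family_has_no_flags():
    msa, tree = make_split_msa(5, 5, 120, 120, overlap=120, seed=8)
    report = flag_family(msa, tree)
    assert report.flags == set()


def test_criteria_invariant_to_row_order():
    msa, tree = make_split_msa(5, 5, 70, 70, overlap=20, seed=9)
    reversed_msa = msa_from(list(reversed(msa.rows())))
    a, b = flag_family(msa, tree), flag_family(reversed_msa, tree)
    assert a.flags == b.flags
    assert a.core_column_count == b.core_column_count
    assert a.worst_split_shared_sites == b.worst_split_shared_sites


def test_qc_tsv_has_flag_columns():
    msa, tree = make_split_msa(5, 5, 60, 60, overlap=0, seed=10)
    buf = io.StringIO()
    write_qc_tsv([flag_family(msa, tree)], buf)
    header = buf.getvalue().splitlines()[0]
    assert "P2_disjoint_subtrees" in header and "family_id" in header


def test_fasta_roundtrip():
    msa, _ = make_split_msa(3, 3, 40, 40, overlap=10, seed=11)
    buf = io.StringIO()
    write_fasta_alignment(msa.rows(), buf)
    again = parse_fasta_alignment(buf.getvalue())
    assert again.rows() == msa.rows()


# -- forward tracking ------------------------------------------------------------------------


def test_forward_track_largest_overlap():
    result = forward_track_ids(
        {"F1": {"a", "b", "c", "d", "e"}},
        {"C1": {"a", "b", "c"}, "C2": {"d", "e"}},
    )
    assert result.mapping == {"F1": "C1"}
    assert result.fresh == {"C2": "NEWFAM00001"}


def test_forward_track_tie_breaks_lexicographically():
    result = forward_track_ids({"F1": {"a", "b"}}, {"C2": {"b"}, "C1": {"a"}})
    assert result.mapping == {"F1": "C1"}


def test_forward_track_retires_vanished_family():
    result = forward_track_ids(
        {"F1": {"a"}, "F2": {"z"}}, {"C1": {"a"}},
    )
    assert result.mapping == {"F1": "C1"}
    assert result.retired == ["F2"]


def test_alignment_validation():
    with pytest.raises(InputError):
        msa_from([("a", "AA")])  # fewer than 2 rows
    with pytest.raises(InputError):
        msa_from([("a", "AA"), ("a", "AA")])  # duplicate ids
    with pytest.raises(InputError):
        msa_from([("a", "AA"), ("b", "AAA")])  # ragged
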