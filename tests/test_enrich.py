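import numpy as np
import pytest
from scipy import stats

from oracles import mwu_pairwise_enumeration
from phylogo.annotation import AnnotationSet
from phylogo.enrich import (
    UNCLASSIFIED,
    bh_fdr,
    binomial_overrep,
    bonferroni,
    fisher_overrep,
    mann_whitney_enrich,
    read_gene_list,
    read_gene_values,
    results_to_frame,
    results_to_json,
    results_to_xml,
    run_enrichment,
    run_overrepresentation,
)
from phylogo.errors import InputError
from phylogo.fixtures import make_annotations, make_dag, make_enriched_lists


# -- Fisher ----------------------------------------------------------------------


def test_fisher_all_list_genes_annotated():
    # N=10, K=5, n=5, k=5 -> 1/C(10,5) = 1/252
    assert fisher_overrep(5, 5, 5, 10, "greater") == pytest.approx(1 / 252, abs=1e-15)


def test_fisher_symmetric_table_two_sided_is_one():
    assert fisher_overrep(1, 2, 2, 4, "two_sided") == 1.0


def test_fisher_degenerate_list_equals_reference():
    for alt in ("greater", "less", "two_sided"):
        assert fisher_overrep(7, 10, 7, 10, alt) == 1.0


def test_fisher_invalid_counts_rejected():
    with pytest.raises(InputError):
        fisher_overrep(6, 5, 5, 10)
    with pytest.raises(InputError):
        fisher_overrep(0, 5, 8, 10)  # k below the support floor
    with pytest.raises(InputError):
        fisher_overrep(1, 5, 11, 10)


@pytest.mark.parametrize("seed", range(5))
def test_fisher_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        N = int(rng.integers(2, 60))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        for alt, scipy_alt in [("greater", "greater"), ("less", "less"),
                               ("two_sided", "two-sided")]:
            ours = fisher_overrep(k, n, K, N, alt)
            theirs = stats.fisher_exact(table, alternative=scipy_alt)[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)


# -- binomial --------------------------------------------------------------------


def test_binomial_closed_form():
    assert binomial_overrep(2, 2, 0.5, "greater") == pytest.approx(0.25)


def test_binomial_degenerate_p0_zero():
    assert binomial_overrep(0, 17, 0.0, "greater") == 1.0


def test_binomial_bad_inputs():
    with pytest.raises(InputError):
        binomial_overrep(3, 2, 0.5)
    with pytest.raises(InputError):
        binomial_overrep(1, 2, 1.5)


@pytest.mark.parametrize("seed", range(3))
def test_binomial_approaches_fisher_for_large_reference(seed):
    # hypergeometric -> binomial limit: N >= 100 * n
    rng = np.random.default_rng(seed + 40)
    for _ in range(10):
        n = int(rng.integers(3, 10))
        N = 100 * n * int(rng.integers(1, 4))
        K = int(rng.integers(N // 10, N // 2))
        k = int(rng.hypergeometric(K, N - K, n))  # a table the null produces
        pf = fisher_overrep(k, n, K, N, "greater")
        pb = binomial_overrep(k, n, K / N, "greater")
        assert pb == pytest.approx(pf, rel=0.1)


# -- Mann-Whitney ----------------------------------------------------------------


def test_mwu_small_example():
    u, p = mann_whitney_enrich([3, 4], [1, 2])
    assert u == 4.0
    assert p == pytest.approx(1 / 3)


def test_mwu_identical_lists_p_one():
    u, p = mann_whitney_enrich([5.0] * 4, [5.0] * 6)
    assert p == 1.0


def test_mwu_empty_rejected():
    with pytest.raises(InputError):
        mann_whitney_enrich([], [1.0])


@pytest.mark.parametrize("seed", range(8))
def test_mwu_exact_matches_pairwise_enumeration(seed):
    rng = np.random.default_rng(seed)
    nx = int(rng.integers(2, 5))
    ny = int(rng.integers(2, 8 - nx + 5))
    x = rng.integers(0, 6, size=nx).astype(float)  # ties likely
    y = rng.integers(0, 6, size=ny).astype(float)
    u_ours, p_ours = mann_whitney_enrich(x, y)
    u_oracle, p_oracle = mwu_pairwise_enumeration(x, y)
    assert u_ours == pytest.approx(u_oracle)
    assert p_ours == pytest.approx(p_oracle, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_mwu_normal_approx_close_to_exact_at_20(seed):
    rng = np.random.default_rng(seed + 7)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    _, p_exact = mann_whitney_enrich(x, y, exact_limit=20)
    _, p_approx = mann_whitney_enrich(x, y, exact_limit=0)
    assert abs(p_exact - p_approx) < 0.01


# -- corrections ------------------------------------------------------------------


def test_bh_step_up_worked_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert bh_fdr([0.3]) == [0.3]


def test_bh_between_raw_and_bonferroni():
    rng = np.random.default_rng(11)
    p = rng.random(50).tolist()
    adjusted = bh_fdr(p)
    capped = bonferroni(p)
    for raw, adj, bon in zip(p, adjusted, capped):
        assert raw <= adj <= bon + 1e-15


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    p = rng.random(200)
    ours = bh_fdr(p.tolist())
    theirs = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)


def test_bh_order_invariance():
    rng = np.random.default_rng(5)
    p = rng.random(30).tolist()
    shuffled = list(reversed(p))
    assert sorted(bh_fdr(p)) == pytest.approx(sorted(bh_fdr(shuffled)))


def test_bonferroni_formula_and_caps():
    assert bonferroni([0.01, 0.5]) == [0.02, 1.0]
    assert bonferroni([0.0, 0.0]) == [0.0, 0.0]
    assert bonferroni([1.0]) == [1.0]


def test_out_of_range_p_rejected():
    with pytest.raises(InputError):
        bh_fdr([0.5, 1.2])
    with pytest.raises(InputError):
        bonferroni([-0.1])


# -- overrepresentation driver -----------------------------------------------------


@pytest.fixture(scope="module")
def overrep_world():
    graph = make_dag(40, seed=2)
    annotations = make_annotations(300, graph, seed=3)
    return graph, annotations


def test_list_equals_reference_is_null(overrep_world):
    graph, annotations = overrep_world
    ref = annotations.genes()
    results = run_overrepresentation(ref, ref, annotations, graph)
    assert all(r.p_adjusted == 1.0 for r in results)
    assert all(r.fold_enrichment == pytest.approx(1.0) for r in results)


def test_planted_enrichment_ranks_first(overrep_world):
    graph, annotations = overrep_world
    from phylogo.annotation import close_over_ontology

    closed = close_over_ontology(annotations, graph)
    by_term = closed.by_term()
    roots = set(graph.roots.values())
    # a mid-sized class (~10% of the reference) carries the planted signal
    target = min(
        (t for t in by_term if t not in roots and len(by_term[t]) >= 10),
        key=lambda t: abs(len(by_term[t]) - len(closed.genes()) // 10),
    )
    gene_list, reference = make_enriched_lists(closed, target, effect=8.0, seed=4)
    results = run_overrepresentation(gene_list, reference, annotations, graph)
    over = [r for r in results if r.direction == "over" and r.term_id != UNCLASSIFIED]
    top_terms = {r.term_id for r in over[:3]}
    assert target in top_terms


def test_direction_matches_expected_sign(overrep_world):
    graph, annotations = overrep_world
    rng = np.random.default_rng(6)
    ref = sorted(annotations.genes())
    gene_list = {g for g in ref if rng.random() < 0.2}
    results = run_overrepresentation(gene_list, set(ref), annotations, graph)
    for r in results:
        if r.direction == "over":
            assert r.k >= r.expected
        else:
            assert r.k < r.expected


def test_unannotated_genes_form_unclassified_class(overrep_world):
    graph, annotations = overrep_world
    ref = annotations.genes() | {"ORPHAN1", "ORPHAN2"}
    results = run_overrepresentation({"ORPHAN1"}, ref, annotations, graph)
    unclassified = [r for r in results if r.term_id == UNCLASSIFIED]
    assert len(unclassified) == 1
    assert unclassified[0].K == 2 and unclassified[0].k == 1


def test_list_gene_missing_from_reference(overrep_world):
    graph, annotations = overrep_world
    ref = annotations.genes()
    some = sorted(ref)[:5]
    with pytest.raises(InputError, match="absent from the reference"):
        run_overrepresentation(set(some) | {"GHOST"}, ref, annotations, graph)
    results = run_overrepresentation(
        set(some) | {"GHOST"}, ref, annotations, graph, coerce_missing=True
    )
    assert results[0].N == len(ref) + 1


def test_count_consistency(overrep_world):
    graph, annotations = overrep_world
    from phylogo.annotation import close_over_ontology

    closed = close_over_ontology(annotations, graph)
    ref = annotations.genes()
    results = run_overrepresentation(ref, ref, annotations, graph)
    total_k = sum(r.K for r in results if r.term_id != UNCLASSIFIED)
    assert total_k == len(closed.records)


def test_results_sorted_by_adjusted_p(overrep_world):
    graph, annotations = overrep_world
    rng = np.random.default_rng(8)
    ref = sorted(annotations.genes())
    gene_list = {g for g in ref if rng.random() < 0.15}
    results = run_overrepresentation(gene_list, set(ref), annotations, graph)
    adj = [r.p_adjusted for r in results]
    assert adj == sorted(adj)


# -- value-based enrichment ---------------------------------------------------------


def test_constant_values_all_p_one(overrep_world):
    graph, annotations = overrep_world
    values = {g: 1.0 for g in sorted(annotations.genes())[:50]}
    results = run_enrichment(values, annotations, graph)
    assert results and all(r.p_raw == 1.0 for r in results)


def test_shifted_class_detected(overrep_world):
    graph, annotations = overrep_world
    by_term = annotations.by_term()
    target = max(by_term, key=lambda t: len(by_term[t]))
    target_genes = by_term[target]
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        values = {
            g: rng.normal(3.0 if g in target_genes else 0.0)
            for g in annotations.genes()
        }
        results = run_enrichment(values, annotations, graph)
        if results[0].term_id == target or target in {
            r.term_id for r in results[:3]
        }:
            hits += 1
    assert hits >= 19


def test_enrichment_invariant_to_gene_order(overrep_world):
    graph, annotations = overrep_world
    rng = np.random.default_rng(9)
    genes = sorted(annotations.genes())[:80]
    values = {g: float(rng.normal()) for g in genes}
    a = run_enrichment(values, annotations, graph)
    b = run_enrichment(dict(reversed(list(values.items()))), annotations, graph)
    assert [(r.term_id, r.p_raw) for r in a] == [(r.term_id, r.p_raw) for r in b]


def test_enrichment_needs_two_genes():
    with pytest.raises(InputError):
        run_enrichment({"g": 1.0}, AnnotationSet())


# -- I/O ------------------------------------------------------------------------------


def test_read_gene_list_and_values():
    assert read_gene_list(["g1", "", "# c", "g2"]) == {"g1", "g2"}
    assert read_gene_values(["g1\t1.5", "g2\t-2"]) == {"g1": 1.5, "g2": -2.0}
    with pytest.raises(InputError, match="line 1"):
        read_gene_values(["g1\tnotanumber"])


def test_serializations_roundtrip_fields(overrep_world):
    graph, annotations = overrep_world
    ref = annotations.genes()
    results = run_overrepresentation(ref, ref, annotations, graph)[:5]
    frame = results_to_frame(results)
    assert list(frame["term_id"]) == [r.term_id for r in results]
    assert "p_adjusted" in results_to_json(results)
    xml = results_to_xml(results)
    assert xml.count("<result>") == 5
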