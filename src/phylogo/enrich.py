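"""Gene-list overrepresentation and value-based enrichment statistics.

Two tests, mirroring the classic gene-list analysis workflow:

* the **overrepresentation test** compares the annotation counts of an input
  gene list against a reference list, per functional class, under a
  hypergeometric null (Fisher's exact test, the default) or a binomial
  approximation (the legacy option);
* the **enrichment test** takes a numeric value per gene (e.g. a fold
  change) and asks, per class, whether the values of annotated genes differ
  from the distribution for all genes (Mann-Whitney U).

P-values are adjusted with the Benjamini-Hochberg FDR step-up procedure by
default; Bonferroni remains available.  Corrections are applied per ontology
aspect across all tested terms.

Fisher tail probabilities are computed with exact integer arithmetic over
the hypergeometric support (a binomial-coefficient recurrence), so they
agree with full enumeration to floating-point rounding; the two-sided test
uses the point-probability rule (sum of all outcomes no more probable than
the observed table).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, TextIO
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, close_over_ontology
from .errors import InputError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

EXACT_MWU_LIMIT = 20  # combined sample size up to which the exact MWU is used

_ALTERNATIVES = ("greater", "less", "two_sided")


# -- Fisher's exact test ------------------------------------------------------


def _hypergeom_weights(n: int, K: int, N: int) -> tuple[int, list[int]]:
    """Integer weights w(k) = C(K,k)*C(N-K,n-k) over the support, plus kmin."""
    kmin = max(0, n + K - N)
    kmax = min(n, K)
    w = math.comb(K, kmin) * math.comb(N - K, n - kmin)
    weights = [w]
    for k in range(kmin, kmax):
        # w(k+1) = w(k) * (K-k)(n-k) / ((k+1)(N-K-n+k+1)); division is exact
        w = w * (K - k) * (n - k) // ((k + 1) * (N - K - n + k + 1))
        weights.append(w)
    return kmin, weights


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise InputError(f"invalid margins: n={n}, K={K}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise InputError(
            f"count k={k} outside hypergeometric support for n={n}, K={K}, N={N}"
        )


def fisher_overrep(
    k: int, n: int, K: int, N: int, alternative: str = "two_sided"
) -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    k of the n list genes carry the class; K of the N reference genes do.
    ``greater``/``less`` are the upper/lower tails; ``two_sided`` sums every
    outcome whose point probability does not exceed the observed one.
    """
    _check_table(k, n, K, N)
    if alternative not in _ALTERNATIVES:
        raise InputError(f"unknown alternative {alternative!r}")
    kmin, weights = _hypergeom_weights(n, K, N)
    total = sum(weights)
    idx = k - kmin
    if alternative == "greater":
        num = sum(weights[idx:])
    elif alternative == "less":
        num = sum(weights[: idx + 1])
    else:
        observed = weights[idx]
        num = sum(w for w in weights if w <= observed)
    return float(Fraction(num, total))


def binomial_overrep(
    k: int, n: int, p0: float, alternative: str = "two_sided"
) -> float:
    """Exact binomial tail probability (legacy overrepresentation test)."""
    if not (0 <= k <= n):
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise InputError(f"p0 must be in [0, 1], got {p0}")
    if alternative not in _ALTERNATIVES:
        raise InputError(f"unknown alternative {alternative!r}")
    scipy_alt = "two-sided" if alternative == "two_sided" else alternative
    return float(stats.binomtest(k, n, p0, alternative=scipy_alt).pvalue)


# -- Mann-Whitney U -----------------------------------------------------------


def _u_statistic(class_ranks: np.ndarray, n_class: int) -> float:
    return float(class_ranks.sum() - n_class * (n_class + 1) / 2.0)


def mann_whitney_enrich(
    class_values: Sequence[float],
    other_values: Sequence[float],
    exact_limit: int = EXACT_MWU_LIMIT,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact by enumeration of all label assignments when the combined sample
    size is at most ``exact_limit``; otherwise the normal approximation with
    tie and continuity corrections.  Returns (U, p).
    """
    x = np.asarray(class_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:nx], nx)
    mu = nx * ny / 2.0

    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    if nx + ny <= exact_limit:
        eps = 1e-9
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        for positions in itertools.combinations(range(nx + ny), nx):
            u = _u_statistic(ranks[list(positions)], nx)
            if abs(u - mu) >= dev - eps:
                hits += 1
            total += 1
        return u_obs, hits / total

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_obs, float(min(1.0, res.pvalue))


# -- multiple-testing corrections --------------------------------------------


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise InputError("p-values must lie in [0, 1]")
    return p


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = _check_pvalues(p_values)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        # multiply by the factor (>= 1) rather than p*m/rank: keeps
        # adjusted >= raw exact in floating point at the top rank
        running = min(running, p[i] * (m / rank_from_top))
        adjusted[i] = running
    return adjusted.tolist()


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """min(1, m*p) elementwise."""
    p = _check_pvalues(p_values)
    return np.minimum(1.0, p * p.size).tolist()


def adjust(p_values: Sequence[float], correction: str) -> list[float]:
    if correction == "fdr":
        return bh_fdr(p_values)
    if correction == "bonferroni":
        return bonferroni(p_values)
    if correction == "none":
        return list(_check_pvalues(p_values))
    raise InputError(f"unknown correction {correction!r}")


# -- result container ---------------------------------------------------------


@dataclass
class EnrichmentResult:
    """One tested functional class with counts, effect size and p-values."""

    term_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    expected: float
    fold_enrichment: float
    direction: str  # "over" | "under"
    p_raw: float
    p_adjusted: float
    method: str  # "fisher" | "binomial" | "mann_whitney"
    correction: str  # "fdr" | "bonferroni" | "none"


RESULT_COLUMNS = [
    "term_id", "name", "K", "k", "n", "N", "expected", "fold_enrichment",
    "direction", "p_raw", "p_adjusted", "method", "correction",
]


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [asdict(r) for r in results]
    return pd.DataFrame(rows, columns=list(
        EnrichmentResult.__dataclass_fields__
    ))[RESULT_COLUMNS] if rows else pd.DataFrame(columns=RESULT_COLUMNS)


def write_results_tsv(results: Iterable[EnrichmentResult], stream: TextIO) -> None:
    results_to_frame(results).to_csv(stream, sep="\t", index=False)


def results_to_json(results: Iterable[EnrichmentResult]) -> str:
    return json.dumps([asdict(r) for r in results], indent=2)


def results_to_xml(results: Iterable[EnrichmentResult]) -> str:
    root = ET.Element("enrichment_results")
    for r in results:
        el = ET.SubElement(root, "result")
        for key, value in asdict(r).items():
            child = ET.SubElement(el, key)
            child.text = str(value)
    return ET.tostring(root, encoding="unicode")


# -- list / value I/O ---------------------------------------------------------


def read_gene_list(stream: TextIO | Iterable[str]) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in stream:
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_gene_values(stream: TextIO | Iterable[str]) -> dict[str, float]:
    """Two-column TSV: gene id, numeric value."""
    out: dict[str, float] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise InputError(f"values TSV line {lineno}: expected 2 columns")
        try:
            out[cols[0]] = float(cols[1])
        except ValueError as exc:
            raise InputError(f"values TSV line {lineno}: {exc}") from exc
    return out


# -- drivers ------------------------------------------------------------------


def _term_name(graph: OntologyGraph | None, term_id: str) -> str:
    if graph is not None and term_id in graph:
        return graph.terms[term_id].name
    return ""


def _aspect_group(graph: OntologyGraph | None, term_id: str) -> str:
    if term_id == UNCLASSIFIED:
        return "unclassified"
    if graph is not None and term_id in graph:
        return graph.aspect_of(term_id) or "unspecified"
    return "unspecified"


def run_overrepresentation(
    gene_list: set[str],
    reference: set[str],
    annotations: AnnotationSet,
    graph: OntologyGraph | None = None,
    test: str = "fisher",
    correction: str = "fdr",
    alternative: str = "two_sided",
    coerce_missing: bool = False,
) -> list[EnrichmentResult]:
    """Per-class over/underrepresentation of a gene list against a reference.

    Annotations are closure-expanded over the ontology before counting (when
    a graph is given).  Every term annotating at least one reference gene is
    tested; genes with no annotation at all form an ``UNCLASSIFIED``
    pseudo-class.  The correction is applied per aspect across all tested
    terms; rows come back sorted by adjusted p ascending.
    """
    gene_list, reference = set(gene_list), set(reference)
    if not gene_list or not reference:
        raise InputError("gene list and reference must be non-empty")
    missing = gene_list - reference
    if missing:
        if not coerce_missing:
            raise InputError(
                f"{len(missing)} list gene(s) absent from the reference "
                f"(e.g. {sorted(missing)[:3]}); pass coerce_missing=True to add them"
            )
        logger.warning("adding %d list genes to the reference", len(missing))
        reference |= missing
    if test not in ("fisher", "binomial"):
        raise InputError(f"unknown test {test!r}")

    if graph is not None:
        annotations = close_over_ontology(annotations, graph)
    by_term = annotations.by_term()
    annotated_genes = annotations.genes()

    N, n = len(reference), len(gene_list)
    term_genes: dict[str, set[str]] = {}
    for term, genes in by_term.items():
        in_ref = genes & reference
        if in_ref:
            term_genes[term] = in_ref
    unclassified = reference - annotated_genes
    if unclassified:
        term_genes[UNCLASSIFIED] = unclassified

    results: list[EnrichmentResult] = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        K = len(genes)
        k = len(genes & gene_list)
        expected = n * K / N
        if test == "fisher":
            p = fisher_overrep(k, n, K, N, alternative)
        else:
            p = binomial_overrep(k, n, K / N, alternative)
        fold = (k / expected) if expected > 0 else math.nan
        results.append(
            EnrichmentResult(
                term_id=term,
                name=_term_name(graph, term),
                k=k, n=n, K=K, N=N,
                expected=expected,
                fold_enrichment=fold,
                direction="over" if k >= expected else "under",
                p_raw=p,
                p_adjusted=p,
                method=test,
                correction=correction,
            )
        )
    _apply_correction(results, graph, correction)
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return results


def _apply_correction(
    results: list[EnrichmentResult],
    graph: OntologyGraph | None,
    correction: str,
) -> None:
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        groups.setdefault(_aspect_group(graph, r.term_id), []).append(i)
    for indices in groups.values():
        adjusted = adjust([results[i].p_raw for i in indices], correction)
        for i, q in zip(indices, adjusted):
            results[i].p_adjusted = q


def run_enrichment(
    values: Mapping[str, float],
    annotations: AnnotationSet,
    graph: OntologyGraph | None = None,
    correction: str = "fdr",
    min_class_size: int = 2,
) -> list[EnrichmentResult]:
    """Value-based enrichment: per class, Mann-Whitney U of the values of
    annotated genes against the distribution for ALL genes.

    Classes with fewer than ``min_class_size`` annotated genes that carry a
    value are skipped (logged).  ``fold_enrichment`` reports the ratio of
    class mean to overall mean value (NaN when the overall mean is 0).
    """
    if len(values) < 2:
        raise InputError("need values for at least 2 genes")
    if graph is not None:
        annotations = close_over_ontology(annotations, graph)
    all_values = np.array([values[g] for g in sorted(values)], dtype=float)
    overall_mean = float(all_values.mean())

    results: list[EnrichmentResult] = []
    by_term = annotations.by_term()
    valued = set(values)
    for term in sorted(by_term):
        genes = sorted(by_term[term] & valued)
        if len(genes) < min_class_size:
            logger.info("skipping %s: %d gene(s) with values", term, len(genes))
            continue
        class_values = np.array([values[g] for g in genes], dtype=float)
        u, p = mann_whitney_enrich(class_values, all_values)
        class_mean = float(class_values.mean())
        results.append(
            EnrichmentResult(
                term_id=term,
                name=_term_name(graph, term),
                k=len(genes), n=len(values), K=len(genes), N=len(values),
                expected=overall_mean,
                fold_enrichment=(class_mean / overall_mean)
                if overall_mean != 0 else math.nan,
                direction="over" if class_mean >= overall_mean else "under",
                p_raw=p,
                p_adjusted=p,
                method="mann_whitney",
                correction=correction,
            )
        )
    _apply_correction(results, graph, correction)
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return results
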