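"""Category-percentage arithmetic and a hypergeometric over-representation test.

The percentage convention follows annotation-clustering tools: the
denominator N is the number of *input* genes carrying at least one category
annotation (the "recognized" genes), not the raw list length, and a gene may
contribute to several categories (no normalization across categories).
Results are ranked by descending percentage with lexicographic ties.

The significance measure is the one-sided hypergeometric upper tail
P(X >= k) for drawing k category members in a list of n recognized genes
from a universe of N genes of which K are category members; a
Benjamini-Hochberg adjusted value is reported alongside but never used for
filtering (ranking is by percentage only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionError, GeneAnnotation
from .normalize import round_half_up


@dataclass(frozen=True)
class CategoryResult:
    category: str
    members: tuple          # input genes carrying the category
    k: int                  # member count
    n_annotated: int        # recognized-gene denominator N
    percent: float          # 100*k/N rounded half-up to 1 decimal
    p_value: float          # one-sided over-representation tail (nan if no universe)
    q_value: float          # Benjamini-Hochberg adjusted (nan if no universe)


def overrepresentation_test(k: int, n_list: int, K_universe: int,
                            N_universe: int) -> float:
    """One-sided hypergeometric upper-tail probability P(X >= k)."""
    if not 0 <= k <= min(n_list, K_universe):
        raise ExpressionError("inconsistent counts: require 0 <= k <= min(n, K)")
    if not (0 <= K_universe <= N_universe and n_list <= N_universe):
        raise ExpressionError("inconsistent counts: require K <= N and n <= N")
    return float(hypergeom.sf(k - 1, N_universe, K_universe, n_list))


def category_percentages(genes, annotation: GeneAnnotation,
                         universe=None) -> list[CategoryResult]:
    """Percentage (and optional enrichment p-value) of each category in a list.

    ``genes`` is the input gene list (order-irrelevant, case-insensitive,
    duplicates ignored); ``universe`` — when given — is the background gene
    list used for the hypergeometric test.
    """
    seen, ordered = set(), []
    for gene in genes:
        key = str(gene).casefold()
        if key not in seen:
            seen.add(key)
            ordered.append(gene)
    if not ordered:
        return []

    annotated = [g for g in ordered if annotation.categories_of(g)]
    n_annotated = len(annotated)
    if n_annotated == 0:
        return []

    by_category: dict[str, list] = {}
    for gene in annotated:
        for cat in annotation.categories_of(gene):
            by_category.setdefault(cat, []).append(gene)

    if universe is not None:
        universe = list(dict.fromkeys(str(g) for g in universe))
        n_universe = len(universe)
        in_category = {
            cat: sum(1 for g in universe if cat in annotation.categories_of(g))
            for cat in by_category}

    results = []
    for cat in sorted(by_category):
        members = tuple(sorted(by_category[cat], key=str))
        k = len(members)
        percent = round_half_up(100.0 * k / n_annotated, 1)
        if universe is not None:
            p = overrepresentation_test(k, n_annotated, in_category[cat],
                                        n_universe)
        else:
            p = math.nan
        results.append(CategoryResult(cat, members, k, n_annotated, percent,
                                      p, math.nan))

    if universe is not None:
        _, q_values, _, _ = multipletests([r.p_value for r in results],
                                          method="fdr_bh")
        results = [CategoryResult(r.category, r.members, r.k, r.n_annotated,
                                  r.percent, r.p_value, float(q))
                   for r, q in zip(results, q_values)]

    results.sort(key=lambda r: (-r.percent, r.category))
    return results


def write_category_report(results: list[CategoryResult], path) -> None:
    """TSV + JSON twin of the ranked category table."""
    import json

    import pandas as pd

    rows = [{
        "category": r.category,
        "percent": f"{r.percent:.1f}",
        "k": r.k,
        "n_annotated": r.n_annotated,
        "p_value": "" if math.isnan(r.p_value) else f"{r.p_value:.3g}",
        "q_value": "" if math.isnan(r.q_value) else f"{r.q_value:.3g}",
        "genes": ", ".join(map(str, r.members)),
    } for r in results]
    pd.DataFrame(rows, columns=["category", "percent", "k", "n_annotated",
                                "p_value", "q_value", "genes"]).to_csv(
        path, sep="\t", index=False)
    twin = str(path)
    twin = twin[:-4] + ".json" if twin.endswith(".tsv") else twin + ".json"
    with open(twin, "w", encoding="utf-8") as handle:
        json.dump([r.__dict__ | {"members": list(r.members)} for r in results],
                  handle, indent=1, default=float)
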