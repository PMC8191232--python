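"""Hypergeometric term enrichment of target sets against GO/KEGG-style maps.

For a term with K annotated genes in a universe of N, and k hits in a target
set of n, the upper-tail p-value is

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n).

BH q-values are computed within each category (BP, MF, CC, KEGG) separately.
Significance is reported at both raw P < 0.05 and BH q, since either rule may
be wanted downstream.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_enrich(
    targets: set[str] | Iterable[str],
    annotation_map: pd.DataFrame,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term.

    ``annotation_map`` needs columns gene_id, term_id, term_name, category.
    The default universe is every gene with ≥1 annotation.  Target genes
    outside the universe are an error.
    """
    required = {"gene_id", "term_id", "term_name", "category"}
    missing = required - set(annotation_map.columns)
    if missing:
        raise ValueError(f"annotation map missing columns {sorted(missing)}")
    targets = set(targets)
    if universe is None:
        universe = set(annotation_map["gene_id"])
    else:
        universe = set(universe)
    outside = targets - universe
    if outside:
        raise ValueError(f"target genes outside the universe: {sorted(outside)[:10]}")
    amap = annotation_map[annotation_map["gene_id"].isin(universe)]
    N = len(universe)
    n = len(targets)
    rows = []
    grouped = amap.groupby(["term_id", "term_name", "category"])["gene_id"]
    for (term_id, term_name, category), genes in grouped:
        gene_set = set(genes)
        K = len(gene_set)
        k = len(gene_set & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term_name, category, k, K, n, N, min(1.0, p)))
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p_value"],
    )
    result["q_value"] = 1.0
    for cat, idx in result.groupby("category").groups.items():
        result.loc[idx, "q_value"] = multipletests(
            result.loc[idx, "p_value"], method="fdr_bh"
        )[1]
    result["significant_p"] = result["p_value"] < 0.05
    result["significant_q"] = result["q_value"] < 0.05
    return result.sort_values(["p_value", "term_id"]).reset_index(drop=True)
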