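"""Gene-set overrepresentation and log-fold-change shift statistics.

Overrepresentation uses the one-sided hypergeometric upper tail (the
Fisher exact test's enrichment direction) with BH correction across
terms; a two-sided option is exposed. Distribution-shift comparisons use
the two-sided Wilcoxon rank-sum test with midranks for ties, exact
enumeration for small tie-free samples and a tie-corrected,
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu

from .de import bh_adjust
from .errors import DomainError, InputError
from .io import GeneSetCollection

ENRICHMENT_COLUMNS = ["term_id", "description", "k", "K", "n", "N",
                      "p_value", "fdr"]


def fisher_enrichment(de_genes, background, annotation: GeneSetCollection,
                      alternative: str = "greater") -> pd.DataFrame:
    """Per-term overrepresentation of ``de_genes`` within ``background``.

    Terms are intersected with the background before testing and skipped
    when the intersection is empty. For each term with K background genes,
    k of them DE, n DE genes overall and N background genes,
    p = P(X >= k) under Hypergeometric(N, K, n) (or the two-sided Fisher
    probability when ``alternative='two-sided'``); BH across tested terms.
    """
    de = set(de_genes)
    bg = set(background)
    if not de <= bg:
        raise InputError("DE genes must be a subset of the background")
    N = len(bg)
    n = len(de)
    rows = []
    for term in annotation:
        term_genes = annotation.genes(term) & bg
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & de)
        if alternative == "greater":
            p = float(hypergeom.sf(k - 1, N, K, n))
        elif alternative == "two-sided":
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
        else:
            raise DomainError("alternative must be 'greater' or 'two-sided'")
        rows.append((term, annotation.description(term), k, K, n, N, p))
    result = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    result["fdr"] = bh_adjust(result["p_value"].to_numpy()) if len(result) else []
    return result


def wilcoxon_shift_test(x, y, mode: str = "auto") -> float:
    """Two-sided rank-sum p-value for a location shift between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if mode == "auto":
        mode = "exact" if (max(x.size, y.size) <= 12 and not has_ties) \
            else "normal-approx"
    if mode == "exact":
        method = "exact"
    elif mode == "normal-approx":
        method = "asymptotic"
    else:
        raise DomainError("mode must be 'exact', 'normal-approx' or 'auto'")
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(min(res.pvalue, 1.0))


def compare_lfc_distributions(de_results: pd.DataFrame, gene_labels,
                              use_abs: bool = False) -> tuple[int, float]:
    """Compare LFCs of labeled genes against the remaining genes.

    Partitions the table's log_fc by membership in ``gene_labels`` and
    applies the rank-sum test on raw LFC (``use_abs=False``) or |LFC|.
    Returns (shift_direction, p_value) with direction the sign of the
    labeled-minus-unlabeled median difference.
    """
    labels = set(gene_labels)
    in_set = de_results["gene_id"].isin(labels).to_numpy()
    lfc = de_results["log_fc"].to_numpy(dtype=float)
    if use_abs:
        lfc = np.abs(lfc)
    x = lfc[in_set]
    y = lfc[~in_set]
    if x.size < 2 or y.size < 2:
        raise DomainError("need >= 2 genes in both the labeled set and its "
                          "complement")
    p = wilcoxon_shift_test(x, y)
    direction = int(np.sign(np.median(x) - np.median(y)))
    return direction, p
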