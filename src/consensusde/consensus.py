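"""The three DE strategies and the consensus call combining them.

The '4vs4' strategy keeps one replicate pool per site (removing the site
factor by construction) and repeats a two-group exact test over every
possible replicate selection (2^S combinations, 256 for the 8-site
design); each combination is a complete standalone analysis (its own
low-count filter, RLE factors, dispersions and BH correction). The '8vs8'
strategy uses all libraries with site absorbed as a nested fixed factor in
an NB GLM. The random-effects analogue shares a single within-site
correlation across genes. The consensus call requires significance in the
8vs8 analysis AND in at least ceil(85% of the combinations) of the 4vs4
runs.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd

from .de import (bh_adjust, estimate_common_dispersion, estimate_duplicate_correlation,
                 estimate_tagwise_dispersions, fit_nb_glm, gls_moderated_test, lr_test,
                 nb_exact_test_batch)
from .errors import DesignError
from .io import CountMatrix, StudyDesign
from .normalization import filter_low_counts, log_cpm, pseudo_counts, rle_factors

logger = logging.getLogger(__name__)

DE_RESULT_COLUMNS = ["gene_id", "log_fc", "log_cpm", "p_value", "fdr"]


def enumerate_combinations(design: StudyDesign) -> list[tuple[str, ...]]:
    """All ways of choosing one replicate library per site.

    Returned in deterministic lexicographic order over (site order,
    pool index); 2^S selections for S sites with two pools each.
    """
    t = design.table
    per_site: list[list[str]] = []
    for site in design.sites:
        rows = t[t["site"] == site].sort_values("pool_index")
        if len(rows) != 2:
            raise DesignError(f"site {site!r} has {len(rows)} replicate pools, "
                              "expected exactly 2")
        per_site.append(rows["library_id"].tolist())
    return [tuple(sel) for sel in itertools.product(*per_site)]


def _category_labels(design: StudyDesign, library_ids: list[str]) -> np.ndarray:
    cat = design.category_of_library()
    return np.array([cat[l] for l in library_ids])


def run_4vs4_all(counts: CountMatrix, design: StudyDesign, alpha: float = 0.05,
                 min_total: int = 10, prior_df: float = 10.0,
                 dispersion_policy: str = "per-combination",
                 grid_size: int = 129) -> pd.DataFrame:
    """Tally, per gene, the replicate selections in which it is significant.

    Every selection is refiltered, renormalized and (by default)
    re-dispersed independently, then exact-tested and BH-adjusted within
    the combination. A gene filtered out of a combination counts as not
    significant there. Returns a table with columns gene_id, n_combos_de,
    n_combos_present, n_combos_total.
    """
    selections = enumerate_combinations(design)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    tally = np.zeros(counts.n_genes, dtype=int)
    present = np.zeros(counts.n_genes, dtype=int)

    inherited = None
    if dispersion_policy == "inherit":
        filt16 = filter_low_counts(counts, min_total)
        fac16 = rle_factors(filt16)
        pseudo16 = pseudo_counts(filt16, fac16)
        sites16 = [design.table.set_index("library_id")["site"][l]
                   for l in filt16.library_ids]
        common16 = estimate_common_dispersion(pseudo16, sites16)
        est16 = estimate_tagwise_dispersions(pseudo16, sites16, common16,
                                             prior_df, grid_size=grid_size)
        inherited = dict(zip(filt16.gene_ids, est16.shrunk))
    elif dispersion_policy != "per-combination":
        raise ValueError("dispersion_policy must be 'per-combination' or 'inherit'")

    for sel in selections:
        sub = counts.subset_libraries(list(sel))
        filt = filter_low_counts(sub, min_total)
        if filt.n_genes == 0:
            continue
        factors = rle_factors(filt)
        pseudo = pseudo_counts(filt, factors)
        labels = _category_labels(design, filt.library_ids)
        idx_a = np.flatnonzero(labels == "ancient")
        idx_b = np.flatnonzero(labels == "recent")
        if inherited is not None:
            disp = np.array([inherited.get(g, np.median(list(inherited.values())))
                             for g in filt.gene_ids])
        else:
            common = estimate_common_dispersion(pseudo, labels)
            est = estimate_tagwise_dispersions(pseudo, labels, common,
                                               prior_df, grid_size=grid_size)
            disp = est.shrunk
        _, pvals = nb_exact_test_batch(pseudo, idx_a, idx_b, disp)
        fdr = bh_adjust(pvals)
        rows = np.array([gene_pos[g] for g in filt.gene_ids])
        present[rows] += 1
        tally[rows[fdr < alpha]] += 1

    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "n_combos_de": tally,
        "n_combos_present": present,
        "n_combos_total": len(selections),
    })


def nested_design_matrices(design: StudyDesign, library_ids: list[str],
                           include_site_terms: bool = True,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Full and reduced design matrices for the all-libraries GLM.

    Full: intercept + invasion indicator (1 = recent) + sum-to-zero site
    contrasts within each category; reduced: the same without the invasion
    column. With sites nested in category this is the full-rank encoding
    that keeps the invasion effect estimable.
    """
    t = design.table.set_index("library_id").loc[library_ids]
    cats = t["invasion_category"].to_numpy()
    sites = t["site"].to_numpy()
    n = len(library_ids)
    cols = [np.ones(n), (cats == "recent").astype(float)]
    if include_site_terms:
        for cat in ("ancient", "recent"):
            cat_sites = list(dict.fromkeys(sites[cats == cat]))
            for s in cat_sites[:-1]:
                col = np.where(sites == s, 1.0,
                               np.where(sites == cat_sites[-1], -1.0, 0.0))
                col = np.where(cats == cat, col, 0.0)
                cols.append(col)
    full = np.column_stack(cols)
    reduced = np.delete(full, 1, axis=1)
    return full, reduced


def run_8vs8(counts: CountMatrix, design: StudyDesign, alpha: float = 0.05,
             min_total: int = 10, prior_df: float = 10.0,
             include_site_terms: bool = True, grid_size: int = 257,
             prior_count: float = 0.125) -> pd.DataFrame:
    """All-libraries NB GLM with site as a nested fixed factor; LRT on invasion.

    The test is the unpenalized likelihood-ratio test; the reported
    log-fold-change comes from a fit with ``prior_count`` reads (scaled by
    relative library size) added to every observation, which keeps fold
    changes finite for genes observed in only one category.
    """
    filt = filter_low_counts(counts, min_total)
    factors = rle_factors(filt)
    pseudo = pseudo_counts(filt, factors)
    site_of = design.table.set_index("library_id")["site"]
    sites = [site_of[l] for l in filt.library_ids]
    common = estimate_common_dispersion(pseudo, sites)
    est = estimate_tagwise_dispersions(pseudo, sites, common, prior_df,
                                       grid_size=grid_size)
    offsets = np.log(factors.effective_lib_sizes)
    full_X, reduced_X = nested_design_matrices(design, filt.library_ids,
                                               include_site_terms)
    full = fit_nb_glm(filt.counts, full_X, offsets, est.shrunk)
    reduced = fit_nb_glm(filt.counts, reduced_X, offsets, est.shrunk)
    pvals = lr_test(full, reduced, df=1)
    lcpm = log_cpm(filt, factors).mean(axis=1)
    rel_size = factors.effective_lib_sizes / factors.effective_lib_sizes.mean()
    augmented = filt.counts + prior_count * rel_size[None, :]
    shrunk_fit = fit_nb_glm(augmented, full_X, offsets, est.shrunk)
    result = pd.DataFrame({
        "gene_id": filt.gene_ids,
        "log_fc": shrunk_fit.coefficients[:, 1] / np.log(2.0),
        "log_cpm": lcpm,
        "p_value": pvals,
        "fdr": bh_adjust(pvals),
    })
    result.attrs["common_dispersion"] = common
    return result


def run_ranef(counts: CountMatrix, design: StudyDesign, alpha: float = 0.05,
              min_total: int = 10) -> pd.DataFrame:
    """Shared within-site correlation GLS with moderated t statistics."""
    filt = filter_low_counts(counts, min_total)
    factors = rle_factors(filt)
    E = log_cpm(filt, factors)
    sub_design = design.subset(filt.library_ids)
    rho = estimate_duplicate_correlation(E, sub_design)
    logger.info("consensus within-site correlation estimate: %.4f", rho)
    fit = gls_moderated_test(E, sub_design, rho)
    result = pd.DataFrame({
        "gene_id": filt.gene_ids,
        "log_fc": fit.gls_coefficients[:, 1],
        "log_cpm": E.mean(axis=1),
        "p_value": fit.p_value,
        "fdr": bh_adjust(fit.p_value),
    })
    result.attrs["consensus_correlation"] = rho
    result.attrs["prior_df_eb"] = fit.prior_df_eb
    return result


def combine_calls(tally: pd.DataFrame, de_8vs8: pd.DataFrame,
                  de_ranef: pd.DataFrame | None = None,
                  threshold_frac: float = 0.85, alpha: float = 0.05,
                  ) -> pd.DataFrame:
    """Final consensus: significant in 8vs8 AND in >= ceil(85% of combos) 4vs4 runs.

    Tables are joined on the union of gene universes; a gene absent from an
    analysis (filtered out) carries an explicit absent flag and counts as
    not significant there. ``systematic_4vs4`` marks genes significant in
    every combination, reported separately from the consensus call.
    """
    n_total = int(tally["n_combos_total"].iloc[0]) if len(tally) else 0
    threshold = math.ceil(threshold_frac * n_total)
    t = tally.set_index("gene_id")
    e = de_8vs8.set_index("gene_id")
    genes = t.index.union(e.index)
    if de_ranef is not None:
        r = de_ranef.set_index("gene_id")
        genes = genes.union(r.index)

    out = pd.DataFrame(index=genes)
    out["n_combos_de"] = t["n_combos_de"].reindex(genes).fillna(0).astype(int)
    out["n_combos_total"] = n_total
    out["present_4vs4"] = genes.isin(t.index)
    out["present_8vs8"] = genes.isin(e.index)
    out["in_8vs8"] = e["fdr"].reindex(genes).lt(alpha)
    if de_ranef is not None:
        out["present_ranef"] = genes.isin(r.index)
        out["in_ranef"] = r["fdr"].reindex(genes).lt(alpha)
    else:
        out["present_ranef"] = False
        out["in_ranef"] = False
    out["systematic_4vs4"] = out["n_combos_de"] == n_total
    out["final_de"] = out["in_8vs8"] & (out["n_combos_de"] >= threshold)
    out.attrs["consensus_threshold"] = threshold
    return out.reset_index().rename(columns={"index": "gene_id"})


def tally_histogram(consensus: pd.DataFrame) -> pd.DataFrame:
    """Bar-plot data: distribution of 4vs4 tallies among 8vs8-significant genes.

    This is the diagnostic from which the consensus threshold is chosen.
    """
    sig = consensus[consensus["in_8vs8"]]
    n_total = int(consensus["n_combos_total"].iloc[0]) if len(consensus) else 0
    values = np.bincount(sig["n_combos_de"], minlength=n_total + 1)
    return pd.DataFrame({"n_combos_de": np.arange(n_total + 1),
                         "n_genes": values})
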