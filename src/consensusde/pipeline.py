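"""End-to-end orchestration: filter -> normalize -> strategies -> consensus -> enrichment.

A pipeline run is configured by a single flat YAML mapping (echoed
verbatim into the machine-readable run manifest, so every threshold that
shaped a result is auditable), executes the requested strategies, writes
every intermediate table, and is byte-deterministic for a fixed config.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import (combine_calls, run_4vs4_all, run_8vs8, run_ranef,
                        tally_histogram)
from .enrichment import fisher_enrichment
from .errors import ParameterError
from .io import (read_counts, read_design, read_gmt, write_results)
from .normalization import filter_low_counts, rle_factors

logger = logging.getLogger(__name__)

STRATEGIES = ("fourvfour", "eightveight", "ranef")


@dataclass
class PipelineConfig:
    counts: str = ""
    design: str = ""
    gmt: str = ""
    out_dir: str = "results"
    alpha: float = 0.05
    consensus_threshold: float = 0.85
    prior_df: float = 10.0
    min_total_count: int = 10
    seed: int = 0
    strategy_set: tuple[str, ...] = STRATEGIES

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if not 0.0 < self.consensus_threshold <= 1.0:
            raise ParameterError("consensus_threshold must lie in (0, 1]")
        bad = [s for s in self.strategy_set if s not in STRATEGIES]
        if bad:
            raise ParameterError(f"unknown strategies: {bad}")
        self.strategy_set = tuple(self.strategy_set)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analyses; returns the manifest (also written).

    Output files land in ``config.out_dir``: factors.tsv, one DE table per
    strategy, consensus.tsv + tally_histogram.tsv when both consensus
    inputs ran, enrichment.tsv when an annotation and a final DE set
    exist, and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_counts(config.counts)
    design = read_design(config.design)
    annotation = read_gmt(config.gmt) if config.gmt else None

    manifest: dict = {
        "tool": "consensusde",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": [],
    }
    manifest["stages"]["input"] = {"n_genes": counts.n_genes,
                                   "n_libraries": counts.n_libraries}

    filt = filter_low_counts(counts, config.min_total_count)
    manifest["stages"]["filter"] = {"n_genes": filt.n_genes}
    factors = rle_factors(filt)
    write_results(pd.DataFrame({
        "library_id": factors.library_ids,
        "size_factor": factors.size_factors,
        "effective_lib_size": factors.effective_lib_sizes,
    }), out / "factors.tsv")
    manifest["outputs"].append("factors.tsv")

    tally = de8 = der = None
    if "fourvfour" in config.strategy_set:
        tally = run_4vs4_all(counts, design, alpha=config.alpha,
                             min_total=config.min_total_count,
                             prior_df=config.prior_df)
        write_results(tally, out / "tally_4vs4.tsv")
        manifest["outputs"].append("tally_4vs4.tsv")
        manifest["stages"]["fourvfour"] = {
            "n_combinations": int(tally["n_combos_total"].iloc[0]),
            "n_systematic": int((tally["n_combos_de"]
                                 == tally["n_combos_total"]).sum()),
        }
    if "eightveight" in config.strategy_set:
        de8 = run_8vs8(counts, design, alpha=config.alpha,
                       min_total=config.min_total_count,
                       prior_df=config.prior_df)
        write_results(de8, out / "de_8vs8.tsv")
        manifest["outputs"].append("de_8vs8.tsv")
        manifest["stages"]["eightveight"] = {
            "n_genes": len(de8),
            "n_de": int((de8["fdr"] < config.alpha).sum()),
        }
    if "ranef" in config.strategy_set:
        der = run_ranef(counts, design, alpha=config.alpha,
                        min_total=config.min_total_count)
        write_results(der, out / "de_ranef.tsv")
        manifest["outputs"].append("de_ranef.tsv")
        manifest["stages"]["ranef"] = {
            "n_genes": len(der),
            "n_de": int((der["fdr"] < config.alpha).sum()),
            "consensus_correlation": der.attrs["consensus_correlation"],
        }

    consensus = None
    if tally is not None and de8 is not None:
        consensus = combine_calls(tally, de8, der,
                                  threshold_frac=config.consensus_threshold,
                                  alpha=config.alpha)
        write_results(consensus, out / "consensus.tsv")
        write_results(tally_histogram(consensus), out / "tally_histogram.tsv")
        manifest["outputs"] += ["consensus.tsv", "tally_histogram.tsv"]
        manifest["stages"]["consensus"] = {
            "threshold": math.ceil(config.consensus_threshold
                                   * int(tally["n_combos_total"].iloc[0])),
            "n_final_de": int(consensus["final_de"].sum()),
        }
    else:
        warnings.warn("final consensus requires both the 4vs4 and 8vs8 "
                      "strategies; consensus.tsv not written")

    if annotation is not None and consensus is not None:
        de_set = set(consensus.loc[consensus["final_de"], "gene_id"])
        background = set(filt.gene_ids)
        enr = fisher_enrichment(de_set & background, background, annotation)
        write_results(enr, out / "enrichment.tsv")
        manifest["outputs"].append("enrichment.tsv")
        manifest["stages"]["enrichment"] = {
            "n_terms_tested": len(enr),
            "n_significant": int((enr["fdr"] < config.alpha).sum())
            if len(enr) else 0,
        }

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    return manifest
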