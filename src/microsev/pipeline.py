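"""End-to-end orchestration: load or simulate a cohort, filter, transform,
then run diversity, PERMANOVA/PCA, differential/TSD and interaction screens,
writing TSV outputs plus a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import summarize_level, tsd
from .diversity import diversity_table
from .interactions import screen_interactions
from .io import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    align,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_count_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from .multivariate import pca, permanova
from .synthetic import SyntheticCohortSpec, default_paper_like_spec, generate
from .transforms import (
    aggregate_to_level,
    aitchison_distance,
    build_tree_from_taxonomy,
    clr,
    drop_zero_taxa,
    filter_mean_relabund,
    ilr_balances,
)

logger = logging.getLogger("microsev")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run; serialized beside outputs."""

    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    simulate: bool = False
    simulation_spec: dict | None = None
    level: str = "genus"
    pseudocount: float = 0.5
    filter_threshold: float = 1e-4
    alpha: float = 0.05
    n_perm: int = 19999
    seed: int = 0
    ilr_weighting: str = "uniform"
    out_dir: str = "microsev_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        spec_kwargs = cfg.simulation_spec or {}
        if spec_kwargs:
            spec = SyntheticCohortSpec(**spec_kwargs)
            spec.seed = cfg.seed
        else:
            spec = default_paper_like_spec(seed=cfg.seed)
        ct, tax, md, tree, _truth = generate(spec)
        return ct, tax, md, tree
    ct = read_count_table(cfg.counts_path)
    tax = read_taxonomy(cfg.taxonomy_path)
    md = read_metadata(cfg.metadata_path)
    tree = read_tree(cfg.tree_path, tax) if cfg.tree_path else None
    return ct, tax, md, tree


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory result bundle and writes TSVs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, tax, md, tree = _load_inputs(cfg)
    ct, tax, md = align(ct, tax, md)
    n0 = len(ct.taxon_ids)
    ct = drop_zero_taxa(ct)
    ct = filter_mean_relabund(ct, cfg.filter_threshold)
    logger.info("filtering: %d -> %d taxa", n0, len(ct.taxon_ids))
    tax = TaxonomyTable(tax.data.loc[ct.taxon_ids])
    if tree is None:
        tree = build_tree_from_taxonomy(tax, seed=cfg.seed)
    else:
        tree = tree.shear(ct.taxon_ids)

    results: dict = {}

    div = diversity_table(ct, tax, md)
    div.to_csv(out / "diversity.tsv", sep="\t")
    results["diversity"] = div

    balances = ilr_balances(ct, tree, cfg.pseudocount, cfg.ilr_weighting)
    balances.to_csv(out / "ilr_balances.tsv", sep="\t", index_label="sample_id")
    pc = pca(balances)
    pc.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    results["pca"] = pc

    dist = aitchison_distance(balances)
    perm = permanova(dist, md.group.reindex(ct.data.index),
                     n_perm=cfg.n_perm, seed=cfg.seed)
    pd.DataFrame(
        [{"pseudo_F": perm.pseudo_F, "p_value": perm.p_value,
          "n_permutations": perm.n_permutations}]
    ).to_csv(out / "permanova.tsv", sep="\t", index=False)
    results["permanova"] = perm

    summary_all = summarize_level(ct, tax, md, cfg.level, alpha=1.0,
                                  pseudocount=cfg.pseudocount)
    summary_all.to_csv(out / f"differential_{cfg.level}_all.tsv", sep="\t")
    summary_sig = summary_all[summary_all["p_fdr_ordinal3"] < cfg.alpha]
    summary_sig.to_csv(out / f"differential_{cfg.level}_significant.tsv", sep="\t")
    results["differential"] = summary_all

    tsd_res = tsd(ct, tax, md, alpha=cfg.alpha, pseudocount=cfg.pseudocount)
    tsd_res.to_csv(out / "tsd.tsv", sep="\t")
    results["tsd"] = tsd_res

    candidates = list(summary_sig.index)
    if candidates:
        level_ct = aggregate_to_level(ct, tax, cfg.level)
        hla_tab, titer_tab = screen_interactions(
            level_ct, md, candidates, pseudocount=cfg.pseudocount
        )
        hla_tab.to_csv(out / "interactions_hla.tsv", sep="\t", index=False)
        titer_tab.to_csv(out / "interactions_titer.tsv", sep="\t", index=False)
        results["hla_interactions"] = hla_tab
        results["titer_interactions"] = titer_tab
    else:
        logger.info("no FDR-significant taxa; interaction screen skipped")

    write_count_table(ct, out / "counts_filtered.tsv")
    write_taxonomy(tax, out / "taxonomy_filtered.tsv")
    write_metadata(md, out / "metadata.tsv")
    write_tree(tree, out / "tree.nwk")

    (out / "config.json").write_text(cfg.to_json())
    manifest = {
        "microsev_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "n_samples": len(ct.sample_ids),
        "n_taxa": len(ct.taxon_ids),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
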