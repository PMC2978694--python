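"""End-to-end orchestration: synthetic inputs (or files) through footprint,
refinement, mutual information, degeneracy classification and the code table.

Every stage parameter lives in :class:`PipelineConfig`; a run is fully
deterministic given the config seed.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codetable, degeneracy, mi, pwmrefine, seqio, synthetic
from .domains import partition_classes
from .footprint import GibbsConfig, gibbs_search
from .synthetic import PlantedCode, Region

logger = logging.getLogger(__name__)

# default planted code: six recognition classes, one palindrome each,
# echoing the kind of (AA-15, AA-16) -> (NT-5, NT-4) map the family shows
DEFAULT_CODE_MAP = {
    "KA": "TA",
    "KS": "GT",
    "NA": "AA",
    "RQ": "GG",
    "RS": "CA",
    "YQ": "TG",
}


@dataclass
class PipelineConfig:
    seed: int
    # synthetic inputs
    n_classes: int = 6
    tfs_per_class: int = 8
    site_rate: float = 0.8
    region_len: int = 150
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    identity: float = 0.9
    code_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CODE_MAP))
    # class restriction
    restrict: str | None = "TVSR"
    # footprint stage
    gibbs_chains: int = 4
    gibbs_iters: int = 1600
    gibbs_burn_in: int = 400
    confidence_cutoff: float = 0.40
    # refinement stage
    pseudocount: float = 1.0
    n_null: int = 100_000
    alpha: float = 1e-3
    max_iter: int = 50
    z_min: float = 4.0
    # degeneracy / code table
    alpha_fdr: float = 0.05


@dataclass
class PipelineResult:
    class_map: dict[str, str]
    regions: list[Region]
    truth: pd.DataFrame
    gibbs_sites: pd.DataFrame
    refined_sites: pd.DataFrame
    relations: dict[str, list[degeneracy.DegeneracyRelation]]
    mi_matrix: mi.MIMatrix | None
    code_table: pd.DataFrame
    summary: dict


def run_synthetic(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Generate a synthetic family and run the full analysis over it."""
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    code = PlantedCode.simple(dict(sorted(config.code_map.items())))
    records, class_map = synthetic.generate_family(
        config.n_classes, config.tfs_per_class, code,
        seed=int(rng.integers(2**31 - 1)),
    )
    regions, truth = synthetic.generate_regions(
        class_map, code, config.site_rate, config.region_len,
        config.background, seed=int(rng.integers(2**31 - 1)),
        identity=config.identity,
    )
    classes = partition_classes(records, restrict=config.restrict)
    result = run_analysis(
        records={r.id: r.aligned_seq for r in records},
        classes={c.aa_pair: c.members for c in classes},
        regions=regions,
        config=config,
        seed_stream=rng,
    )
    result.class_map = class_map
    result.truth = truth
    result.regions = regions
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    if outdir is not None:
        write_outputs(result, records, outdir, config)
    return result


def run_analysis(
    records: dict[str, str],
    classes: dict[str, list[str]],
    regions: list[Region],
    config: PipelineConfig,
    seed_stream: np.random.Generator | None = None,
) -> PipelineResult:
    """Footprint -> refine -> degeneracy -> MI -> code table over prepared
    inputs. ``records`` maps tf_id -> aligned domain sequence; ``classes``
    maps aa_pair -> member tf_ids; regions carry strict/extended sequences."""
    if seed_stream is None:
        seed_stream = np.random.default_rng(config.seed)
    by_tf = {r.tf_id: r for r in regions}
    tf_map = {r.region_id: r.tf_id for r in regions}

    gibbs_parts: list[pd.DataFrame] = []
    refined_parts: list[pd.DataFrame] = []
    relations: dict[str, list[degeneracy.DegeneracyRelation]] = {}
    site_tables: dict[str, pd.DataFrame] = {}

    for aa_pair in sorted(classes):
        members = [m for m in classes[aa_pair] if m in by_tf]
        strict = [(by_tf[m].region_id, by_tf[m].strict_seq) for m in members]
        extended = [(by_tf[m].region_id, by_tf[m].extended_seq) for m in members]
        if len(strict) < 2:
            logger.warning("class %s has < 2 regions; skipped", aa_pair)
            continue
        gcfg = GibbsConfig(
            seed=int(seed_stream.integers(2**31 - 1)),
            background=config.background,
            confidence_cutoff=config.confidence_cutoff,
            n_chains=config.gibbs_chains,
            iters=config.gibbs_iters,
            burn_in=config.gibbs_burn_in,
        )
        seeds = gibbs_search(strict, gcfg, tf_map)
        logger.info("class %s: footprint kept %d seed sites", aa_pair, len(seeds))
        if len(seeds) == 0:
            site_tables[aa_pair] = seqio.make_site_table()
            relations[aa_pair] = []
            continue
        gibbs_parts.append(seeds.assign(aa_pair=aa_pair))
        res = pwmrefine.refine(
            seeds, extended,
            pseudocount=config.pseudocount, n_null=config.n_null,
            alpha=config.alpha, max_iter=config.max_iter,
            seed=int(seed_stream.integers(2**31 - 1)),
            background=config.background, palindromic=True, tf_map=tf_map,
        )
        final = pwmrefine.zscore_filter(res.sites, config.z_min)
        logger.info(
            "class %s: refine converged in %d iterations, %d sites (%d after Z filter)",
            aa_pair, res.n_iterations, len(res.sites), len(final),
        )
        site_tables[aa_pair] = final
        if len(final):
            refined_parts.append(final.assign(aa_pair=aa_pair))
            _, _, rels = degeneracy.classify_sites(
                list(final["sequence"]), alpha_fdr=config.alpha_fdr
            )
            relations[aa_pair] = rels
        else:
            relations[aa_pair] = []

    gibbs_sites = pd.concat(gibbs_parts, ignore_index=True) if gibbs_parts \
        else seqio.make_site_table().assign(aa_pair="")
    refined_sites = pd.concat(refined_parts, ignore_index=True) if refined_parts \
        else seqio.make_site_table().assign(aa_pair="")

    mi_result = None
    if len(refined_sites) >= 2:
        bs_rows = {
            f"site_{i}": row.sequence
            for i, row in enumerate(refined_sites.itertuples())
        }
        pairing = {
            f"site_{i}": row.tf_id
            for i, row in enumerate(refined_sites.itertuples())
        }
        mi_result = mi.mi_matrix(records, bs_rows, pairing)

    code = codetable.assemble(
        classes, site_tables, relations, alpha_fdr=config.alpha_fdr
    )
    summary = codetable.summarize(code, relations)
    return PipelineResult(
        class_map={}, regions=regions, truth=pd.DataFrame(),
        gibbs_sites=gibbs_sites, refined_sites=refined_sites,
        relations=relations, mi_matrix=mi_result, code_table=code,
        summary=summary,
    )


def write_outputs(result: PipelineResult, records, outdir: str | Path,
                  config: PipelineConfig) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta([(r.id, r.aligned_seq) for r in records], out / "domains.fasta")
    seqio.write_fasta(
        [(r.region_id, r.strict_seq) for r in result.regions],
        out / "regions_strict.fasta",
    )
    seqio.write_fasta(
        [(r.region_id, r.extended_seq) for r in result.regions],
        out / "regions_extended.fasta",
    )
    if len(result.truth):
        seqio.write_truth(result.truth, out / "truth.tsv")
    seqio.write_sites(
        result.gibbs_sites.drop(columns=["aa_pair"], errors="ignore"),
        out / "gibbs_sites.tsv",
    )
    seqio.write_sites(
        result.refined_sites.drop(columns=["aa_pair"], errors="ignore"),
        out / "refined_sites.tsv",
    )
    result.code_table.to_csv(out / "code_table.tsv", sep="\t", index=False)
    rel_rows = [
        {"aa_pair": aa, "kind": r.kind, "semiseq_a": r.semiseq_a,
         "semiseq_b": r.semiseq_b, "rendered": r.render(), "pvalue": r.pvalue}
        for aa, rels in sorted(result.relations.items()) for r in rels
    ]
    pd.DataFrame(
        rel_rows,
        columns=["aa_pair", "kind", "semiseq_a", "semiseq_b", "rendered", "pvalue"],
    ).to_csv(out / "relations.tsv", sep="\t", index=False)
    if result.mi_matrix is not None:
        pd.DataFrame(result.mi_matrix.values).to_csv(
            out / "mi_matrix.tsv", sep="\t", index=False
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True, default=str)
    return out
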