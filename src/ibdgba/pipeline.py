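"""End-to-end orchestration shared by the CLI and the analysis drivers.

Each stage reads its inputs, runs the corresponding library operations, and
writes deterministic result tables; ``run_all`` chains the stages and writes
a run manifest alongside the results.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from . import curate as cur
from . import expression as expr
from . import harmonize as harm
from . import io as cio
from . import overlap as ov
from . import snp_classify as sc

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters for a pipeline run; defaults follow the
    standard thresholds (p < 5e-8, >= 3 studies, wordcloud p < 0.01,
    N = 20,000, alpha = 0.05)."""

    uc_catalog: Optional[str] = None
    cd_catalog: Optional[str] = None
    hgnc_table: Optional[str] = None
    gct: Optional[str] = None
    tissue_groups: Optional[str] = None
    out_dir: str = "results"
    min_studies: int = 3
    wordcloud_p_threshold: float = 0.01
    genomewide_p_threshold: float = 5e-8
    background_n: int = ov.DEFAULT_BACKGROUND_N
    alpha: float = 0.05
    seed: int = 0

    def curation_config(self) -> cur.CurationConfig:
        return cur.CurationConfig(
            min_studies=self.min_studies,
            wordcloud_p_threshold=self.wordcloud_p_threshold,
            genomewide_p_threshold=self.genomewide_p_threshold,
        )

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if not path:
                raise ValueError(f"config field {name!r} is required for this stage")
            if not os.path.exists(path):
                raise FileNotFoundError(f"config field {name!r}: no such file {path!r}")


def _load_trait(path: str, hgnc: Optional[cio.HgncMap]) -> list[harm.GeneAssignment]:
    records = cio.read_gwas_catalog(path)
    return harm.assign_genes(records, hgnc)


def run_curation(config: RunConfig) -> dict[str, object]:
    """Curate both trait catalogs: per-gene evidence, recurrent sets, panel."""
    config.require("uc_catalog", "cd_catalog", "hgnc_table")
    hgnc = cio.read_hgnc_table(config.hgnc_table)
    ccfg = config.curation_config()
    out: dict[str, object] = {"hgnc": hgnc}
    recurrent: dict[str, set[str]] = {}
    for trait, path in (("UC", config.uc_catalog), ("CD", config.cd_catalog)):
        assignments = _load_trait(path, hgnc)
        evidence = cur.unify_study_gene(assignments, ccfg)
        recurrent[trait] = cur.recurrent_genes(evidence, ccfg)
        out[f"{trait}_assignments"] = assignments
        out[f"{trait}_evidence"] = evidence
        cio.write_table(
            cur.evidence_table(evidence),
            os.path.join(config.out_dir, f"gene_evidence_{trait.lower()}.tsv"),
        )
        weights = cur.wordcloud_weights(assignments, ccfg)
        cio.write_table(
            pd.DataFrame(sorted(weights.items(), key=lambda kv: (-kv[1], kv[0])),
                         columns=["symbol", "weight"]),
            os.path.join(config.out_dir, f"wordcloud_{trait.lower()}.tsv"),
        )
        cio.write_table(
            harm.unresolved_report(assignments),
            os.path.join(config.out_dir, f"unresolved_symbols_{trait.lower()}.tsv"),
        )
    panel = recurrent["UC"] & recurrent["CD"]
    out["recurrent"] = recurrent
    out["panel"] = panel
    cio.write_gene_set(recurrent["UC"], os.path.join(config.out_dir, "recurrent_uc.txt"))
    cio.write_gene_set(recurrent["CD"], os.path.join(config.out_dir, "recurrent_cd.txt"))
    cio.write_gene_set(panel, os.path.join(config.out_dir, "shared_panel.txt"))
    log.info("recurrent genes: UC %d, CD %d, shared panel %d",
             len(recurrent["UC"]), len(recurrent["CD"]), len(panel))
    return out


def run_classification(config: RunConfig, curation: Optional[dict] = None) -> dict[str, object]:
    """Filter significant pairs per trait and classify SNPs over the panel."""
    curation = curation or run_curation(config)
    ccfg = config.curation_config()
    uc_pairs = sc.filter_genomewide_pairs(curation["UC_assignments"], ccfg)
    cd_pairs = sc.filter_genomewide_pairs(curation["CD_assignments"], ccfg)
    calls = sc.classify_snp_pairs(uc_pairs, cd_pairs, curation["panel"])
    summary = sc.burden_summary(calls)
    cio.write_table(sc.calls_table(calls), os.path.join(config.out_dir, "snp_calls.tsv"))
    mat = sc.oncoprint_matrix(calls)
    cio._atomic_write(os.path.join(config.out_dir, "oncoprint.tsv"), mat.to_csv(sep="\t"))
    circos = sc.circos_records(calls)
    cio.write_table(circos, os.path.join(config.out_dir, "circos_tracks.bed"))
    burden = pd.DataFrame(
        [
            {"symbol": g, "snp_count": summary.per_gene_snp_count[g],
             "percent": summary.per_gene_percent[g]}
            for g in summary.gene_order()
        ]
    )
    cio.write_table(burden, os.path.join(config.out_dir, "gene_burden.tsv"))
    classes = pd.DataFrame(
        [
            {"disease_class": c, "count": summary.class_counts.get(c, 0),
             "percent": summary.class_percents.get(c, 0.0)}
            for c in sc.CLASSES
        ]
    )
    cio.write_table(classes, os.path.join(config.out_dir, "class_summary.tsv"))
    log.info("classified %d SNP calls over %d panel genes",
             summary.total_snps, len(summary.per_gene_snp_count))
    return {"uc_pairs": uc_pairs, "cd_pairs": cd_pairs, "calls": calls, "summary": summary}


def run_overlap(
    config: RunConfig, sets: Mapping[str, set[str]]
) -> list[ov.OverlapResult]:
    """Pairwise overlap enrichment plus UpSet regions for named gene sets."""
    results = ov.pairwise_overlap(sets, n_background=config.background_n, alpha=config.alpha)
    df = pd.DataFrame([r.to_dict() for r in results])
    cio.write_table(df, os.path.join(config.out_dir, "overlap_matrix.tsv"))
    cio._atomic_write(
        os.path.join(config.out_dir, "overlap_matrix.json"),
        json.dumps([r.to_dict() for r in results], indent=2),
    )
    regions = ov.exclusive_intersections(sets)
    region_df = pd.DataFrame(
        [{"sets": "&".join(k), "degree": len(k), "count": v} for k, v in regions.items()]
    ).sort_values(["degree", "sets"], ignore_index=True)
    cio.write_table(region_df, os.path.join(config.out_dir, "upset_regions.tsv"))
    return results


def run_expression(config: RunConfig, genes: set[str]) -> dict[str, object]:
    """Tissue profiles and group comparisons for a gene set."""
    config.require("gct")
    group_map = dict(expr.DEFAULT_TISSUE_GROUPS)
    if config.tissue_groups:
        group_map = cio.read_tissue_groups(config.tissue_groups)
    matrix = cio.read_gct(config.gct, group_map)
    profiles = expr.mean_tpm_profile(matrix, genes)
    cio.write_table(expr.profile_table(profiles),
                    os.path.join(config.out_dir, "tissue_profiles.tsv"))
    cio.write_table(expr.color_rank_table(profiles),
                    os.path.join(config.out_dir, "tissue_rank_colors.tsv"))
    tests = {
        "git_vs_brain": expr.compare_git_vs_brain(matrix, genes),
        "set_vs_background_git": expr.compare_gene_set_vs_background(matrix, genes, cio.GIT),
        "set_vs_background_brain": expr.compare_gene_set_vs_background(matrix, genes, cio.BRAIN),
        "heterogeneity_git": expr.region_heterogeneity(matrix, genes, cio.GIT),
        "heterogeneity_brain": expr.region_heterogeneity(matrix, genes, cio.BRAIN),
    }
    rows = [
        {"comparison": name, "test": t.test, "statistic": t.statistic,
         "p_value": t.p_value, "n_per_group": "/".join(map(str, t.n_per_group))}
        for name, t in tests.items()
    ]
    cio.write_table(pd.DataFrame(rows), os.path.join(config.out_dir, "expression_tests.tsv"))
    return {"matrix": matrix, "profiles": profiles, "tests": tests}


def write_manifest(config: RunConfig, path: str, extra: Optional[dict] = None) -> None:
    manifest = {"version": __version__, "config": asdict(config)}
    if extra:
        manifest.update(extra)
    cio._atomic_write(path, json.dumps(manifest, indent=2, sort_keys=True))


def run_all(config: RunConfig, expression_genes: Optional[set[str]] = None) -> dict[str, object]:
    """Full pipeline: curation, classification, overlap of the trait gene
    sets, and (when a GCT is configured) expression profiling.

    ``expression_genes`` defaults to the union of the recurrent UC and CD
    sets; with a synthetic bundle, callers usually pass the planted set.
    """
    curation = run_curation(config)
    classification = run_classification(config, curation)
    sets = {
        "UC_recurrent": curation["recurrent"]["UC"],
        "CD_recurrent": curation["recurrent"]["CD"],
    }
    overlap_results = run_overlap(config, sets)
    out: dict[str, object] = {
        "curation": curation,
        "classification": classification,
        "overlap": overlap_results,
    }
    if config.gct:
        genes = expression_genes
        if genes is None:
            genes = curation["recurrent"]["UC"] | curation["recurrent"]["CD"]
        out["expression"] = run_expression(config, genes)
    write_manifest(config, os.path.join(config.out_dir, "run_manifest.json"))
    return out
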