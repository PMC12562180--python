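"""Seeded synthetic GWAS Catalog files and TPM matrices with planted truth.

Every pipeline stage can be exercised against known ground truth without any
external download: catalog files are written in the GWAS Catalog TSV dialect
with planted per-gene publication recurrence and planted SNP
disease-specificity classes, and expression matrices are written in GCT 1.2
with planted tissue-group means and region effects.  Each output file draws
from its own pseudo-random stream derived from ``(seed, file role)``, so
adding a file never perturbs the others, and a fixed seed reproduces every
file byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import BRAIN, GIT, OTHER, TpmMatrix, _atomic_write, write_gct
from .expression import DEFAULT_TISSUE_GROUPS
from .snp_classify import BOTH, CD_ONLY, UC_ONLY

# stream roles: deterministic sub-seeds per generated file
_ROLE_PLAN, _ROLE_UC, _ROLE_CD, _ROLE_TPM = 101, 102, 103, 104

UC_TRAIT = "EFO_0000729"
CD_TRAIT = "EFO_0005624"

CATALOG_COLUMNS = [
    "PUBMEDID",
    "FIRST AUTHOR",
    "DISEASE/TRAIT",
    "MAPPED_TRAIT_URI",
    "SNPS",
    "CHR_ID",
    "CHR_POS",
    "MAPPED_GENE",
    "SNP_GENE_IDS",
    "P-VALUE",
]


class SimConfigError(ValueError):
    """Raised when a planted simulation plan is internally inconsistent."""


def _rng(seed: int, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), role]))


# ---------------------------------------------------------------------------
# catalog simulation
# ---------------------------------------------------------------------------

@dataclass
class CatalogSimConfig:
    """Plan for a pair of synthetic UC/CD catalog files.

    ``study_counts`` plants, per gene, the number of distinct publications in
    the UC and CD files; ``snp_classes`` plants genome-wide-significant SNPs
    with their disease-specificity class (UC_only / CD_only / Both), which
    fixes the file(s) each SNP is written to.  P-values for planted
    significant SNPs are drawn strictly below 5e-8 and fillers strictly
    above; both are rendered in the catalog's mixed scientific-notation
    dialects to exercise the tolerant parser.
    """

    genes: list[str]
    study_counts: dict[str, tuple[int, int]]
    snp_classes: dict[tuple[str, str], str]
    chromosome_assignment: dict[str, tuple[str, int]]
    snp_positions: dict[tuple[str, str], int]
    aliases: dict[str, str]
    ensembl_ids: dict[str, str]
    seed: int = 0
    sig_exponent_range: tuple[int, int] = (9, 25)
    background_exponent_range: tuple[int, int] = (1, 6)
    min_studies: int = 3

    def __post_init__(self) -> None:
        for (snp, gene), cls in self.snp_classes.items():
            if cls not in (UC_ONLY, CD_ONLY, BOTH):
                raise SimConfigError(f"unknown class {cls!r} for {snp}@{gene}")
            uc, cd = self.study_counts.get(gene, (0, 0))
            if cls in (UC_ONLY, BOTH) and uc < 1:
                raise SimConfigError(f"{snp}@{gene} planted in UC but gene has no UC studies")
            if cls in (CD_ONLY, BOTH) and cd < 1:
                raise SimConfigError(f"{snp}@{gene} planted in CD but gene has no CD studies")
            if (snp, gene) not in self.snp_positions:
                raise SimConfigError(f"no planted position for {snp}@{gene}")

    def panel(self) -> set[str]:
        """Genes planted as recurrent (>= min_studies publications) in both traits."""
        return {
            g for g, (uc, cd) in self.study_counts.items()
            if uc >= self.min_studies and cd >= self.min_studies
        }

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_genes: int = 80,
        n_panel: int = 26,
        n_uc_recurrent_only: int = 8,
        n_cd_recurrent_only: int = 10,
        n_extra_uc: int = 250,
        n_extra_cd: int = 310,
    ) -> "CatalogSimConfig":
        """Standard study-condition bundle: ~80 genes, ~60 studies, ~700
        genome-wide-significant SNP-gene pairs, 26-gene shared panel, class
        mix proportional to 10:25:34 (UC_only : CD_only : Both)."""
        rng = _rng(seed, _ROLE_PLAN)
        genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]

        study_counts: dict[str, tuple[int, int]] = {}
        for i, g in enumerate(genes):
            if i < n_panel:
                study_counts[g] = (int(rng.integers(3, 7)), int(rng.integers(3, 7)))
            elif i < n_panel + n_uc_recurrent_only:
                study_counts[g] = (int(rng.integers(3, 6)), int(rng.integers(1, 3)))
            elif i < n_panel + n_uc_recurrent_only + n_cd_recurrent_only:
                study_counts[g] = (int(rng.integers(1, 3)), int(rng.integers(3, 6)))
            else:
                study_counts[g] = (int(rng.integers(0, 3)), int(rng.integers(0, 3)))

        chrom_labels = [str(c) for c in range(1, 23)] + ["X", "Y"]
        chromosome_assignment = {
            g: (chrom_labels[i % len(chrom_labels)], int(1_000_000 + 2_000_000 * i))
            for i, g in enumerate(genes)
        }
        ensembl_ids = {g: f"ENSG{(100000 + i):011d}" for i, g in enumerate(genes)}
        aliases = {g: f"{g}OLD" for i, g in enumerate(genes) if i % 3 == 0}

        snp_classes: dict[tuple[str, str], str] = {}
        snp_positions: dict[tuple[str, str], int] = {}
        counter = 0

        def add_snp(gene: str, klass: str) -> None:
            nonlocal counter
            counter += 1
            snp = f"rs{1000000 + counter}"
            snp_classes[(snp, gene)] = klass
            _, base = chromosome_assignment[gene]
            snp_positions[(snp, gene)] = int(base + rng.integers(1, 1_000_000))

        class_probs = np.array([10, 25, 34], dtype=float) / 69.0
        for g in genes[:n_panel]:
            for _ in range(int(rng.integers(2, 5))):
                add_snp(g, [UC_ONLY, CD_ONLY, BOTH][int(rng.choice(3, p=class_probs))])
        uc_eligible = [g for g in genes[n_panel:] if study_counts[g][0] >= 1]
        cd_eligible = [g for g in genes[n_panel:] if study_counts[g][1] >= 1]
        for _ in range(n_extra_uc):
            add_snp(str(rng.choice(uc_eligible)), UC_ONLY)
        for _ in range(n_extra_cd):
            add_snp(str(rng.choice(cd_eligible)), CD_ONLY)

        return cls(
            genes=genes,
            study_counts=study_counts,
            snp_classes=snp_classes,
            chromosome_assignment=chromosome_assignment,
            snp_positions=snp_positions,
            aliases=aliases,
            ensembl_ids=ensembl_ids,
            seed=seed,
        )

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "CatalogSimConfig":
        """Bundle sized to the reported trait magnitudes (~500 UC and ~627 CD
        significant pairs over a 26-gene shared panel)."""
        return cls.default(seed=seed, n_extra_uc=450, n_extra_cd=560)


def _render_p(rng: np.random.Generator, exponent_range: tuple[int, int]) -> tuple[str, float]:
    """Draw a p-value and render it in one of the catalog's dialects.

    Returns (string as written, exact float value a tolerant parser yields).
    """
    e = int(rng.integers(exponent_range[0], exponent_range[1] + 1))
    m = round(float(rng.uniform(1.0, 9.99)), 2)
    value = float(f"{m}e-{e}")
    style = rng.integers(0, 3)
    if style == 0:
        text = f"{m}E-{e}"
    elif style == 1:
        text = f"{m} x 10-{e}"
    else:
        text = f"{m} × 10-{e}"
    return text, value


@dataclass
class CatalogBundle:
    uc_path: str
    cd_path: str
    hgnc_path: str
    truth: dict[str, pd.DataFrame]


def generate_catalog(config: CatalogSimConfig, out_dir: str | os.PathLike) -> CatalogBundle:
    """Write synthetic UC and CD catalog TSVs plus an HGNC table and truth tables.

    Each gene appears in exactly its planted number of distinct PUBMEDIDs per
    trait; every planted significant SNP is written with a sub-threshold
    p-value into the file(s) its class dictates; MAPPED_GENE fields exercise
    the single, " - ", and ", " dialects and occasionally the planted alias
    spelling; some rows carry only SNP_GENE_IDS.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    by_trait_gene: dict[str, dict[str, list[tuple[str, str]]]] = {"UC": {}, "CD": {}}
    for (snp, gene), cls in config.snp_classes.items():
        if cls in (UC_ONLY, BOTH):
            by_trait_gene["UC"].setdefault(gene, []).append((snp, cls))
        if cls in (CD_ONLY, BOTH):
            by_trait_gene["CD"].setdefault(gene, []).append((snp, cls))

    wordcloud_truth: list[dict] = []

    def write_trait(trait: str, role: int, trait_uri: str, path: str) -> None:
        rng = _rng(config.seed, role)
        idx = 0 if trait == "UC" else 1
        study_pool = [str(30000000 + (idx * 500) + i) for i in range(40)]
        authors = [f"Author{j:02d}" for j in range(40)]
        rows: list[dict] = []
        filler_counter = 0
        p01_counts: dict[str, int] = {}

        def mapped_gene_text(gene: str) -> str:
            u = rng.uniform()
            if u < 0.10:
                return f"{gene}, {gene}"
            if u < 0.20:
                return f"{gene} - {gene}"
            if u < 0.28 and gene in config.aliases:
                return config.aliases[gene]
            if u < 0.33:
                return ""  # resolved through SNP_GENE_IDS
            return gene

        def emit(gene: str, study: str, snp: str, text_p: str, value_p: float, pos: int) -> None:
            chrom, _ = config.chromosome_assignment[gene]
            rows.append(
                {
                    "PUBMEDID": study,
                    "FIRST AUTHOR": authors[study_pool.index(study)],
                    "DISEASE/TRAIT": "Ulcerative colitis" if trait == "UC" else "Crohn's disease",
                    "MAPPED_TRAIT_URI": f"http://www.ebi.ac.uk/efo/{trait_uri}",
                    "SNPS": snp,
                    "CHR_ID": chrom,
                    "CHR_POS": str(pos),
                    "MAPPED_GENE": mapped_gene_text(gene),
                    "SNP_GENE_IDS": config.ensembl_ids[gene],
                    "P-VALUE": text_p,
                }
            )
            if value_p < 0.01:
                p01_counts[gene] = p01_counts.get(gene, 0) + 1

        for gene in config.genes:
            k = config.study_counts[gene][idx]
            if k < 1:
                continue
            studies = [study_pool[j] for j in rng.choice(len(study_pool), size=k, replace=False)]
            _, base = config.chromosome_assignment[gene]
            # one filler (non-significant) row anchors each (gene, study) pair
            for study in studies:
                filler_counter += 1
                text_p, value_p = _render_p(rng, config.background_exponent_range)
                emit(gene, study, f"rs9{idx}{filler_counter:06d}", text_p,
                     value_p, int(base + rng.integers(1, 1_000_000)))
            # planted significant SNPs cycle through the gene's studies
            for j, (snp, _cls) in enumerate(sorted(by_trait_gene[trait].get(gene, []))):
                text_p, value_p = _render_p(rng, config.sig_exponent_range)
                emit(gene, studies[j % k], snp, text_p, value_p,
                     config.snp_positions[(snp, gene)])

        df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
        _atomic_write(path, df.to_csv(sep="\t", index=False))
        for gene, n in sorted(p01_counts.items()):
            wordcloud_truth.append({"trait": trait, "gene": gene, "entries_below_0.01": n})

    uc_path = os.path.join(out_dir, "catalog_uc.tsv")
    cd_path = os.path.join(out_dir, "catalog_cd.tsv")
    write_trait("UC", _ROLE_UC, UC_TRAIT, uc_path)
    write_trait("CD", _ROLE_CD, CD_TRAIT, cd_path)

    hgnc_rows = [
        {
            "symbol": g,
            "alias_symbol": config.aliases.get(g, ""),
            "prev_symbol": "",
            "ensembl_gene_id": config.ensembl_ids[g],
        }
        for g in config.genes
    ]
    hgnc_path = os.path.join(out_dir, "hgnc.tsv")
    _atomic_write(hgnc_path, pd.DataFrame(hgnc_rows).to_csv(sep="\t", index=False))

    panel = config.panel()
    gene_truth = pd.DataFrame(
        [
            {
                "gene": g,
                "uc_studies": config.study_counts[g][0],
                "cd_studies": config.study_counts[g][1],
                "in_panel": g in panel,
            }
            for g in config.genes
        ]
    )
    snp_truth = pd.DataFrame(
        [
            {
                "snp_id": snp,
                "gene": gene,
                "disease_class": cls,
                "chrom": config.chromosome_assignment[gene][0],
                "pos": config.snp_positions[(snp, gene)],
                "in_panel": gene in panel,
            }
            for (snp, gene), cls in sorted(config.snp_classes.items())
        ]
    )
    truth = {
        "genes": gene_truth,
        "snps": snp_truth,
        "wordcloud": pd.DataFrame(wordcloud_truth, columns=["trait", "gene", "entries_below_0.01"]),
    }
    for name, df in truth.items():
        _atomic_write(os.path.join(out_dir, f"truth_{name}.tsv"), df.to_csv(sep="\t", index=False))
    return CatalogBundle(uc_path=uc_path, cd_path=cd_path, hgnc_path=hgnc_path, truth=truth)


# ---------------------------------------------------------------------------
# TPM matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class TpmSimConfig:
    """Plan for a synthetic gene x tissue TPM matrix.

    Gene-set genes are drawn multiplicatively log-normal around the planted
    group mean of each tissue's group; background genes around a lower
    baseline.  Noise decomposes into a gene-level factor shared across
    tissues (``gene_sd_log``, the dominant variance component in real
    expression data) and an independent per-cell factor (``noise_sd_log``);
    both are mean-one on the natural scale.  Region effects are mean-one
    multipliers within each group so planted group means are preserved
    exactly.

    ``set_genes`` optionally names the leading gene-set rows as
    ``(ensembl_id, symbol)`` pairs — used to tie the matrix to a simulated
    catalog bundle's genes; identities never affect the sampled values.
    """

    n_genes_set: int = 413
    n_genes_background: int = 1987
    git_mean: float = 22.54
    brain_mean: float = 12.76
    other_mean: float = 15.0
    background_mean: float = 8.0
    region_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: {GIT: 0.0, BRAIN: 0.3, OTHER: 0.0}
    )
    noise_sd_log: float = 0.3
    gene_sd_log: float = 0.12
    tissue_layout: Sequence[tuple[str, str]] = field(
        default_factory=lambda: tuple(DEFAULT_TISSUE_GROUPS.items())
    )
    set_genes: Optional[Sequence[tuple[str, str]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("git_mean", "brain_mean", "other_mean", "background_mean"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.noise_sd_log < 0 or self.gene_sd_log < 0:
            raise SimConfigError("noise SDs must be >= 0")
        if any(sd < 0 for sd in self.region_effect_sd.values()):
            raise SimConfigError("region effect SDs must be >= 0")
        names = [t for t, _ in self.tissue_layout]
        if len(set(names)) != len(names):
            raise SimConfigError("tissue names must be unique")
        if self.set_genes is not None and len(self.set_genes) > self.n_genes_set:
            raise SimConfigError("more planted set-gene identities than set rows")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "TpmSimConfig":
        """Zero-effect control: identical planted means in every tissue group
        and no region effects."""
        kwargs.setdefault("git_mean", 15.0)
        kwargs.setdefault("brain_mean", 15.0)
        kwargs.setdefault("other_mean", 15.0)
        kwargs.setdefault("region_effect_sd", {GIT: 0.0, BRAIN: 0.0, OTHER: 0.0})
        return cls(seed=seed, **kwargs)

    def group_mean(self, group: str) -> float:
        return {GIT: self.git_mean, BRAIN: self.brain_mean, OTHER: self.other_mean}[group]


def generate_tpm_matrix(
    config: TpmSimConfig, out_dir: Optional[str | os.PathLike] = None
) -> tuple[TpmMatrix, dict]:
    """Simulate the planted TPM matrix; optionally write GCT + truth JSON.

    Returns the in-memory matrix and a truth dict holding the planted group
    means, per-tissue region multipliers, and the gene-set identifiers.
    With all SDs zero, every gene-set gene's value equals its tissue group's
    planted mean exactly.
    """
    rng = _rng(config.seed, _ROLE_TPM)
    tissues = [t for t, _ in config.tissue_layout]
    groups = {t: g for t, g in config.tissue_layout}

    n_set, n_bg = config.n_genes_set, config.n_genes_background
    set_ids = [f"ENSG{(200000 + i):011d}.2" for i in range(n_set)]
    bg_ids = [f"ENSG{(500000 + i):011d}.2" for i in range(n_bg)]
    symbols = {g: f"SET{i + 1:04d}" for i, g in enumerate(set_ids)}
    symbols.update({g: f"BG{i + 1:04d}" for i, g in enumerate(bg_ids)})
    if config.set_genes:
        for i, (ensembl_id, symbol) in enumerate(config.set_genes):
            del symbols[set_ids[i]]
            set_ids[i] = ensembl_id
            symbols[ensembl_id] = symbol

    # mean-one region multipliers within each group
    region_mult: dict[str, float] = {}
    for group in sorted({g for g in groups.values()}):
        members = [t for t in tissues if groups[t] == group]
        sd = float(config.region_effect_sd.get(group, 0.0))
        effects = np.exp(rng.normal(0.0, sd, size=len(members))) if sd > 0 else np.ones(len(members))
        effects = effects / effects.mean()
        for t, m in zip(members, effects):
            region_mult[t] = float(m)

    n_total = n_set + n_bg
    base = np.empty((n_total, len(tissues)))
    for j, t in enumerate(tissues):
        gm = config.group_mean(groups[t])
        base[:n_set, j] = gm * region_mult[t]
        base[n_set:, j] = config.background_mean * region_mult[t]

    sg, sc = config.gene_sd_log, config.noise_sd_log
    gene_factor = (
        np.exp(rng.normal(0.0, sg, size=n_total) - sg ** 2 / 2) if sg > 0 else np.ones(n_total)
    )
    cell_factor = (
        np.exp(rng.normal(0.0, sc, size=(n_total, len(tissues))) - sc ** 2 / 2)
        if sc > 0
        else np.ones((n_total, len(tissues)))
    )
    values = base * gene_factor[:, None] * cell_factor

    df = pd.DataFrame(values, index=set_ids + bg_ids, columns=tissues)
    df.index.name = "Name"
    matrix = TpmMatrix(values=df, gene_symbols=symbols, tissue_groups=dict(groups))
    truth = {
        "planted_means": {
            GIT: config.git_mean,
            BRAIN: config.brain_mean,
            OTHER: config.other_mean,
            "background": config.background_mean,
        },
        "region_multipliers": region_mult,
        "set_gene_ids": set_ids,
        "set_gene_symbols": [symbols[g] for g in set_ids],
        "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_gct(matrix, os.path.join(out_dir, "expression.gct"))
        _atomic_write(os.path.join(out_dir, "truth_tpm.json"), json.dumps(truth, indent=2))
        groups_df = pd.DataFrame({"tissue": tissues, "group": [groups[t] for t in tissues]})
        _atomic_write(os.path.join(out_dir, "tissue_groups.tsv"),
                      groups_df.to_csv(sep="\t", index=False))
    return matrix, truth
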