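"""Genome-wide-significant SNP filtering and disease-specificity classification.

SNP-gene pairs passing the genome-wide threshold with valid chromosomal
coordinates are classified over a shared-gene panel as UC_only, CD_only, or
Both, by presence in the per-subtype filtered datasets.  Downstream data
products: per-gene burden percentages, an oncoprint-style class matrix, and
BED-like circos track records.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .curate import CurationConfig
from .harmonize import GeneAssignment

log = logging.getLogger(__name__)

UC_ONLY = "UC_only"
CD_ONLY = "CD_only"
BOTH = "Both"
CLASSES = (UC_ONLY, CD_ONLY, BOTH)


def round_percent(count: int, total: int) -> float:
    """Percentage of total, rounded half-up to one decimal."""
    if total == 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def map_chromosome(chr_id: str) -> Optional[int]:
    """Map a printed CHR_ID to an integer 1-24 (X=23, Y=24) or None if invalid."""
    s = str(chr_id).strip().upper()
    if s == "X":
        return 23
    if s == "Y":
        return 24
    if s.isdigit():
        v = int(s)
        if 1 <= v <= 24:
            return v
    return None


def chromosome_label(chrom: int) -> str:
    """UCSC-style label for an integer chromosome (23 -> chrX, 24 -> chrY)."""
    if chrom == 23:
        return "chrX"
    if chrom == 24:
        return "chrY"
    return f"chr{chrom}"


@dataclass(frozen=True)
class SnpGenePair:
    """One genome-wide-significant SNP-gene association with valid coordinates."""

    snp_id: str
    symbol: str
    chrom: int
    pos: int
    p_value: float


@dataclass(frozen=True)
class SnpCall:
    """One classified SNP-gene pair over the shared-gene panel."""

    snp_id: str
    symbol: str
    chrom: int
    pos: int
    disease_class: str
    p_uc: Optional[float]
    p_cd: Optional[float]


@dataclass
class BurdenSummary:
    """Per-gene and per-class SNP counts with printed-style percentages."""

    total_snps: int
    per_gene_snp_count: dict[str, int]
    per_gene_percent: dict[str, float]
    class_counts: dict[str, int]
    class_percents: dict[str, float]

    def gene_order(self) -> list[str]:
        """Genes by descending SNP count, ties alphabetical (oncoprint rows)."""
        return sorted(self.per_gene_snp_count, key=lambda g: (-self.per_gene_snp_count[g], g))


def filter_genomewide_pairs(
    assignments: Iterable[GeneAssignment],
    config: CurationConfig = CurationConfig(),
) -> list[SnpGenePair]:
    """Keep SNP-gene pairs with p strictly below the genome-wide threshold and
    valid coordinates (integer chromosome 1-24, position > 0).

    Duplicate (snp_id, symbol) pairs collapse to the best (smallest) p-value.
    Exclusion reasons are counted and logged.
    """
    reasons: Counter[str] = Counter()
    best: dict[tuple[str, str], SnpGenePair] = {}
    for a in assignments:
        rec = a.source_record
        p = rec.p_value
        if p is None or not (p < config.genomewide_p_threshold):
            reasons["not_genomewide_significant"] += 1
            continue
        chrom = map_chromosome(rec.chr_id)
        if chrom is None:
            reasons["invalid_chromosome"] += 1
            continue
        if rec.chr_pos is None or rec.chr_pos <= 0:
            reasons["invalid_position"] += 1
            continue
        key = (rec.snp_id, a.symbol)
        prev = best.get(key)
        if prev is None or p < prev.p_value:
            best[key] = SnpGenePair(rec.snp_id, a.symbol, chrom, rec.chr_pos, p)
    if reasons:
        log.info("filtered assignments: %s", dict(reasons))
    return list(best.values())


def classify_snp_pairs(
    uc_pairs: Iterable[SnpGenePair],
    cd_pairs: Iterable[SnpGenePair],
    panel: set[str],
) -> list[SnpCall]:
    """Classify each SNP-gene pair on the panel by presence in the filtered sets.

    Present only among UC pairs -> UC_only; only among CD pairs -> CD_only;
    in both -> Both.  Pairs on genes outside the panel are excluded.  The
    returned calls are sorted by (chrom, pos, symbol, snp_id) for stable
    downstream output.
    """
    uc = {(p.snp_id, p.symbol): p for p in uc_pairs if p.symbol in panel}
    cd = {(p.snp_id, p.symbol): p for p in cd_pairs if p.symbol in panel}
    calls: list[SnpCall] = []
    for key in set(uc) | set(cd):
        u, c = uc.get(key), cd.get(key)
        if u and c:
            cls = BOTH
        elif u:
            cls = UC_ONLY
        else:
            cls = CD_ONLY
        anchor = u if u is not None else c
        calls.append(
            SnpCall(
                snp_id=key[0],
                symbol=key[1],
                chrom=anchor.chrom,
                pos=anchor.pos,
                disease_class=cls,
                p_uc=u.p_value if u else None,
                p_cd=c.p_value if c else None,
            )
        )
    calls.sort(key=lambda s: (s.chrom, s.pos, s.symbol, s.snp_id))
    return calls


def burden_summary(calls: Iterable[SnpCall]) -> BurdenSummary:
    """Per-gene and per-class SNP burden with percentages of the total."""
    calls = list(calls)
    total = len(calls)
    gene_counts: Counter[str] = Counter(c.symbol for c in calls)
    class_counts = {cls: 0 for cls in CLASSES}
    for c in calls:
        class_counts[c.disease_class] += 1
    if total == 0:
        return BurdenSummary(0, {}, {}, {}, {})
    return BurdenSummary(
        total_snps=total,
        per_gene_snp_count=dict(gene_counts),
        per_gene_percent={g: round_percent(n, total) for g, n in gene_counts.items()},
        class_counts=class_counts,
        class_percents={cls: round_percent(n, total) for cls, n in class_counts.items()},
    )


def oncoprint_matrix(calls: Iterable[SnpCall]) -> pd.DataFrame:
    """Gene x SNP class matrix (oncoprint layout).

    Rows are genes in burden order (descending SNP count, ties alphabetical);
    columns are SNPs ordered by chromosome then position; cells hold the
    class label or an empty string.  A SNP mapped to several panel genes
    fills one cell per gene in its column.
    """
    calls = list(calls)
    if not calls:
        return pd.DataFrame()
    summary = burden_summary(calls)
    genes = summary.gene_order()
    snp_pos: dict[str, tuple[int, int]] = {}
    for c in calls:
        snp_pos.setdefault(c.snp_id, (c.chrom, c.pos))
    snps = sorted(snp_pos, key=lambda s: (*snp_pos[s], s))
    mat = pd.DataFrame("", index=genes, columns=snps)
    for c in calls:
        mat.loc[c.symbol, c.snp_id] = c.disease_class
    mat.index.name = "gene"
    return mat


def circos_records(calls: Iterable[SnpCall]) -> pd.DataFrame:
    """BED-like track records for circos-style genome plots.

    One record per call: 0-based half-open interval [pos-1, pos), name
    "snp|gene", class label as the extra column; sorted by (chromosome,
    start) with a stable secondary sort by symbol.
    """
    rows = [
        {
            "chrom": chromosome_label(c.chrom),
            "start": c.pos - 1,
            "end": c.pos,
            "name": f"{c.snp_id}|{c.symbol}",
            "disease_class": c.disease_class,
            "_chrom_num": c.chrom,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "disease_class", "_chrom_num"])
    if df.empty:
        return df.drop(columns=["_chrom_num"], errors="ignore")
    df = df.sort_values(
        ["_chrom_num", "start", "name"], kind="mergesort", ignore_index=True
    )
    return df.drop(columns=["_chrom_num"])


def calls_table(calls: Iterable[SnpCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": c.snp_id,
                "symbol": c.symbol,
                "chrom": c.chrom,
                "pos": c.pos,
                "disease_class": c.disease_class,
                "p_uc": c.p_uc,
                "p_cd": c.p_cd,
            }
            for c in calls
        ],
        columns=["snp_id", "symbol", "chrom", "pos", "disease_class", "p_uc", "p_cd"],
    )
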