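"""Publication-based gene curation.

Catalog associations are unified so that a gene contributes once per
publication (keeping the most significant p-value per study), genes are
called "strongly associated" when they recur in at least ``min_studies``
independent publications, and word-cloud weights count raw catalog entries
below a nominal p threshold.  The two counters are deliberately separate:
recurrence counts publications, word-cloud weight counts entries.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .harmonize import GeneAssignment

log = logging.getLogger(__name__)

GENOMEWIDE_P = 5e-8


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds for publication-based curation.

    min_studies
        Minimum number of distinct publications for a gene to count as
        strongly associated (default 3, inclusive).
    wordcloud_p_threshold
        Strict upper bound on entry p-values counted toward word-cloud
        weights (default 0.01).
    genomewide_p_threshold
        Strict genome-wide significance bound for SNP filtering
        (default 5e-8).
    """

    min_studies: int = 3
    wordcloud_p_threshold: float = 0.01
    genomewide_p_threshold: float = GENOMEWIDE_P

    def __post_init__(self) -> None:
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")
        for name in ("wordcloud_p_threshold", "genomewide_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class GeneEvidence:
    """Per-gene publication support."""

    symbol: str
    per_study_best_p: dict[str, float] = field(default_factory=dict)
    studies: set = field(default_factory=set)
    wordcloud_weight: int = 0

    @property
    def study_count(self) -> int:
        return len(self.studies)

    @property
    def min_p(self) -> Optional[float]:
        return min(self.per_study_best_p.values()) if self.per_study_best_p else None


def unify_study_gene(
    assignments: Iterable[GeneAssignment],
    config: CurationConfig = CurationConfig(),
) -> list[GeneEvidence]:
    """Collapse assignments to one evidence entry per gene.

    Within a publication a gene is counted once, retaining the smallest
    p-value; assignments with a missing p-value still register the
    (gene, study) pair but do not enter best-p selection.  Word-cloud weight
    counts raw qualifying entries (no per-publication deduplication).
    """
    by_gene: dict[str, GeneEvidence] = {}
    n_missing_p = 0
    for a in assignments:
        ev = by_gene.get(a.symbol)
        if ev is None:
            ev = by_gene[a.symbol] = GeneEvidence(symbol=a.symbol)
        ev.studies.add(a.study_id)
        p = a.p_value
        if p is None:
            n_missing_p += 1
        else:
            best = ev.per_study_best_p.get(a.study_id)
            if best is None or p < best:
                ev.per_study_best_p[a.study_id] = p
            if p < config.wordcloud_p_threshold:
                ev.wordcloud_weight += 1
    if n_missing_p:
        log.info("%d assignments had missing p-values (counted for recurrence only)", n_missing_p)
    return [by_gene[s] for s in by_gene]


def recurrent_genes(
    evidence: Iterable[GeneEvidence],
    config: CurationConfig = CurationConfig(),
) -> set[str]:
    """Genes supported by at least ``min_studies`` distinct publications."""
    return {ev.symbol for ev in evidence if ev.study_count >= config.min_studies}


def wordcloud_weights(
    assignments: Iterable[GeneAssignment],
    config: CurationConfig = CurationConfig(),
) -> dict[str, int]:
    """Word-cloud weight per gene: count of catalog entries with p below threshold.

    Entries are counted as reported (no per-publication collapse); genes with
    weight zero are excluded from the mapping.
    """
    weights: dict[str, int] = defaultdict(int)
    for a in assignments:
        if a.p_value is not None and a.p_value < config.wordcloud_p_threshold:
            weights[a.symbol] += 1
    return dict(weights)


def evidence_table(evidence: Iterable[GeneEvidence]) -> pd.DataFrame:
    """Gene-evidence result table: symbol, study_count, wordcloud_weight, min p."""
    rows = [
        {
            "symbol": ev.symbol,
            "study_count": ev.study_count,
            "wordcloud_weight": ev.wordcloud_weight,
            "min_p": ev.min_p,
        }
        for ev in evidence
    ]
    df = pd.DataFrame(rows, columns=["symbol", "study_count", "wordcloud_weight", "min_p"])
    return df.sort_values(["study_count", "symbol"], ascending=[False, True], ignore_index=True)
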