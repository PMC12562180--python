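"""Tissue-level expression aggregation along the gut-brain axis.

A gene set's TPM values are averaged per tissue (genes unweighted), tissues
are ranked within their anatomical group, and three group comparisons are
run with the gene as the sampling unit: gene set vs background within a
tissue group (Mann-Whitney U), gut vs brain for the gene set (Mann-Whitney
U), and across-region heterogeneity within a group (one-way ANOVA).  TPM
values are used untransformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import BRAIN, GIT, OTHER, TpmMatrix

log = logging.getLogger(__name__)

# GTEx v8 gastrointestinal and brain tissue groupings (7 GIT, 13 brain regions)
DEFAULT_TISSUE_GROUPS: dict[str, str] = {
    "Colon - Sigmoid": GIT,
    "Colon - Transverse": GIT,
    "Esophagus - Gastroesophageal Junction": GIT,
    "Esophagus - Mucosa": GIT,
    "Esophagus - Muscularis": GIT,
    "Small Intestine - Terminal Ileum": GIT,
    "Stomach": GIT,
    "Brain - Amygdala": BRAIN,
    "Brain - Anterior cingulate cortex (BA24)": BRAIN,
    "Brain - Caudate (basal ganglia)": BRAIN,
    "Brain - Cerebellar Hemisphere": BRAIN,
    "Brain - Cerebellum": BRAIN,
    "Brain - Cortex": BRAIN,
    "Brain - Frontal Cortex (BA9)": BRAIN,
    "Brain - Hippocampus": BRAIN,
    "Brain - Hypothalamus": BRAIN,
    "Brain - Nucleus accumbens (basal ganglia)": BRAIN,
    "Brain - Putamen (basal ganglia)": BRAIN,
    "Brain - Spinal cord (cervical c-1)": BRAIN,
    "Brain - Substantia nigra": BRAIN,
}

# rank color buckets, highest mean expression first
RANK_COLORS = ["red", "orange", "yellow", "green", "blue", "indigo", "violet"]


class ExpressionError(ValueError):
    """Raised when an expression comparison is not well-posed."""


@dataclass(frozen=True)
class TissueProfile:
    tissue: str
    group: str
    mean_tpm: float
    rank_in_group: int


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]


def _subset(matrix: TpmMatrix, genes: Iterable[str]) -> pd.DataFrame:
    matched, unmatched = matrix.match_genes(genes)
    if unmatched:
        log.info(
            "%d requested genes not in the matrix (e.g. %s)",
            len(unmatched),
            ", ".join(unmatched[:5]),
        )
    if not matched:
        raise ExpressionError("no requested genes are present in the matrix")
    return matrix.values.loc[matched]


def mean_tpm_profile(matrix: TpmMatrix, genes: Iterable[str]) -> list[TissueProfile]:
    """Per-tissue unweighted mean TPM over the gene set, ranked within groups.

    Rank 1 is the highest mean in its group; ties break by tissue name so the
    ranking is deterministic.  Unmatched requested genes are logged, not an
    error, unless none match.
    """
    sub = _subset(matrix, genes)
    means = sub.mean(axis=0)
    profiles: list[TissueProfile] = []
    for group in (GIT, BRAIN, OTHER):
        tissues = matrix.tissues_in_group(group)
        ranked = sorted(tissues, key=lambda t: (-means[t], t))
        for rank, t in enumerate(ranked, start=1):
            profiles.append(TissueProfile(t, group, float(means[t]), rank))
    order = {t: i for i, t in enumerate(matrix.tissue_names)}
    profiles.sort(key=lambda p: order[p.tissue])
    return profiles


def group_mean_tpm(matrix: TpmMatrix, genes: Iterable[str], group: str) -> float:
    """Mean TPM of the gene set over all tissues of one group."""
    sub = _subset(matrix, genes)
    tissues = matrix.tissues_in_group(group)
    if not tissues:
        raise ExpressionError(f"no tissues in group {group}")
    return float(sub[tissues].values.mean())


def compare_gene_set_vs_background(
    matrix: TpmMatrix, genes: Iterable[str], group: str
) -> GroupTestResult:
    """Mann-Whitney U: gene set vs all other genes, within one tissue group.

    The observation for each gene is its mean TPM over the group's tissues;
    two-sided, normal approximation with tie and continuity correction.
    """
    tissues = matrix.tissues_in_group(group)
    if not tissues:
        raise ExpressionError(f"no tissues in group {group}")
    matched, _ = matrix.match_genes(genes)
    in_set = matrix.values.index.isin(matched)
    per_gene = matrix.values[tissues].mean(axis=1)
    x = per_gene[in_set].to_numpy()
    y = per_gene[~in_set].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ExpressionError("both gene classes need at least two genes")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupTestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), (len(x), len(y)))


def compare_git_vs_brain(matrix: TpmMatrix, genes: Iterable[str]) -> GroupTestResult:
    """Mann-Whitney U on the gene set's per-gene GIT means vs brain means."""
    sub = _subset(matrix, genes)
    git = matrix.tissues_in_group(GIT)
    brain = matrix.tissues_in_group(BRAIN)
    if not git or not brain:
        raise ExpressionError("both GIT and BRAIN groups need at least one tissue")
    x = sub[git].mean(axis=1).to_numpy()
    y = sub[brain].mean(axis=1).to_numpy()
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupTestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), (len(x), len(y)))


def region_heterogeneity(matrix: TpmMatrix, genes: Iterable[str], group: str) -> GroupTestResult:
    """One-way ANOVA across the group's tissues, per-gene TPM as observations."""
    sub = _subset(matrix, genes)
    tissues = matrix.tissues_in_group(group)
    if len(tissues) < 2:
        raise ExpressionError(f"group {group} needs at least two tissues for ANOVA")
    samples = [sub[t].to_numpy() for t in tissues]
    if any(len(s) < 2 for s in samples):
        raise ExpressionError("every tissue needs at least two observations")
    if all(np.array_equal(s, samples[0]) for s in samples[1:]):
        # identical value vectors in every tissue: zero between-group variance
        return GroupTestResult("one_way_anova", 0.0, 1.0, tuple(len(s) for s in samples))
    f, p = stats.f_oneway(*samples)
    return GroupTestResult("one_way_anova", float(f), float(p), tuple(len(s) for s in samples))


def profile_table(profiles: Iterable[TissueProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tissue": p.tissue, "group": p.group, "mean_tpm": p.mean_tpm, "rank_in_group": p.rank_in_group}
            for p in profiles
        ],
        columns=["tissue", "group", "mean_tpm", "rank_in_group"],
    )


def color_rank_table(profiles: Iterable[TissueProfile]) -> pd.DataFrame:
    """Map each tissue's within-group rank onto a red-to-violet color bucket."""
    profiles = list(profiles)
    rows = []
    for group in (GIT, BRAIN, OTHER):
        members = [p for p in profiles if p.group == group]
        n = len(members)
        for p in members:
            if n == 1:
                idx = 0
            else:
                idx = round((p.rank_in_group - 1) * (len(RANK_COLORS) - 1) / (n - 1))
            rows.append(
                {"tissue": p.tissue, "group": group, "rank_in_group": p.rank_in_group,
                 "color": RANK_COLORS[idx]}
            )
    return pd.DataFrame(rows, columns=["tissue", "group", "rank_in_group", "color"])
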