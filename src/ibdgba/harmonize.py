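"""Gene-symbol harmonization against HGNC nomenclature.

MAPPED_GENE fields from the catalog carry three dialects: a single symbol,
an intergenic flank pair joined by " - " (space-hyphen-space), and a
comma-separated list of co-mapped genes.  Hyphenated symbols themselves
(IRF1-AS1, IFNG-AS1, ...) are legitimate HGNC names and must never be split,
so only the padded separator splits a field.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .io import AssociationRecord, HgncMap, strip_ensembl_version

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAssignment:
    """One (association record, gene symbol) pair after harmonization."""

    symbol: str
    source_record: AssociationRecord
    standardized: bool

    @property
    def study_id(self) -> str:
        return self.source_record.study_id

    @property
    def p_value(self):
        return self.source_record.p_value


def parse_mapped_gene_field(raw: Optional[str]) -> list[str]:
    """Split a MAPPED_GENE field into symbols.

    Splits on ", " (multiple mapped genes) and on the padded " - " intergenic
    separator only; trims whitespace; deduplicates preserving first
    occurrence.  Empty and "NR" fields give [].
    """
    if raw is None:
        return []
    s = str(raw).strip()
    if not s or s.upper() == "NR" or s.lower() == "nan":
        return []
    tokens: list[str] = []
    for part in s.split(", "):
        for tok in part.split(" - "):
            tok = tok.strip()
            if tok and tok.upper() != "NR":
                tokens.append(tok)
    out: list[str] = []
    for t in tokens:
        if t not in out:
            out.append(t)
    return out


def standardize_symbol(symbol: str, hgnc: Optional[HgncMap]) -> tuple[str, bool]:
    """Resolve a symbol to its HGNC-approved form.

    Approved symbols return themselves, known aliases/previous symbols return
    their approved target (flag True); unknown symbols pass through uppercased
    (flag False).  Without a map everything passes through.
    """
    s = symbol.strip().upper()
    if hgnc is None:
        return s, False
    return hgnc.resolve(s)


def assign_genes(
    records: Iterable[AssociationRecord],
    hgnc: Optional[HgncMap] = None,
) -> list[GeneAssignment]:
    """Expand records into per-gene assignments with standardized symbols.

    When MAPPED_GENE is empty but SNP_GENE_IDS holds ENSG accessions, each is
    resolved to a symbol through the HGNC map (version suffixes stripped);
    unresolvable ENSGs are kept under their accession string.  One assignment
    per (record, distinct symbol).
    """
    assignments: list[GeneAssignment] = []
    unknown: Counter[str] = Counter()
    for rec in records:
        symbols = parse_mapped_gene_field(rec.mapped_gene_raw)
        if not symbols and rec.ensembl_ids:
            for ensg in rec.ensembl_ids:
                sym = hgnc.resolve_ensembl(ensg) if hgnc else None
                symbols.append(sym if sym else strip_ensembl_version(ensg))
        seen: set[str] = set()
        for raw_sym in symbols:
            sym, ok = standardize_symbol(raw_sym, hgnc)
            if sym in seen:
                continue
            seen.add(sym)
            if not ok and hgnc is not None and not sym.startswith("ENSG"):
                unknown[sym] += 1
            assignments.append(GeneAssignment(symbol=sym, source_record=rec, standardized=ok))
    for sym in sorted(unknown):
        log.debug("symbol %s not in HGNC map (%d occurrences), passed through", sym, unknown[sym])
    if unknown:
        log.info("%d distinct symbols not resolvable against HGNC, passed through", len(unknown))
    return assignments


def unresolved_report(assignments: Iterable[GeneAssignment]) -> pd.DataFrame:
    """Tabulate symbols that did not resolve against HGNC (symbol, count)."""
    counts = Counter(a.symbol for a in assignments if not a.standardized)
    return pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["symbol", "occurrences"],
    )
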