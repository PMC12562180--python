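"""Readers and writers for the three external file formats.

The pipeline consumes NHGRI-EBI GWAS Catalog association exports (tab-separated,
v1.0 column dialect), the HGNC complete-set table, and GTEx-style GCT 1.2
expression matrices.  Raw fields are preserved byte-for-byte on the parsed
records so every downstream decision can be audited against the source row.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GIT = "GIT"
BRAIN = "BRAIN"
OTHER = "OTHER"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRecord:
    """One parsed GWAS Catalog association row.

    ``chr_pos`` and ``p_value`` are ``None`` when the source field is blank or
    unparseable; such rows are flagged, never dropped, so row counts are
    conserved.
    """

    study_id: str
    first_author: str
    trait_id: str
    snp_id: str
    chr_id: str
    chr_pos: Optional[int]
    mapped_gene_raw: str
    ensembl_ids: tuple[str, ...]
    p_value: Optional[float]


@dataclass(frozen=True)
class HgncMap:
    """HGNC nomenclature lookup: approved symbols, alias resolution, Ensembl links.

    All symbols are stored uppercased; resolution is deterministic (one target
    per alias) and an alias colliding with an approved symbol is dropped in
    favour of the approved identity.
    """

    approved: frozenset[str]
    alias_to_approved: Mapping[str, str]
    symbol_to_ensembl: Mapping[str, str]
    ensembl_to_symbol: Mapping[str, str]

    def resolve(self, symbol: str) -> tuple[str, bool]:
        """Return ``(approved_symbol, True)`` or ``(symbol, False)`` for unknowns."""
        s = symbol.strip().upper()
        if s in self.approved:
            return s, True
        if s in self.alias_to_approved:
            return self.alias_to_approved[s], True
        return s, False

    def resolve_ensembl(self, ensg: str) -> Optional[str]:
        """Map an ENSG accession (versioned or not) to its approved symbol."""
        return self.ensembl_to_symbol.get(strip_ensembl_version(ensg))


@dataclass
class TpmMatrix:
    """Gene x tissue TPM expression with tissue-group labels.

    ``values`` is a DataFrame indexed by gene id (as read, possibly versioned
    ENSG) with one column per tissue.  ``tissue_groups`` maps every tissue to
    exactly one of ``GIT``, ``BRAIN``, ``OTHER``.
    """

    values: pd.DataFrame
    gene_symbols: dict[str, str]
    tissue_groups: dict[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.values.columns)

    def tissues_in_group(self, group: str) -> list[str]:
        return [t for t in self.values.columns if self.tissue_groups[t] == group]

    def match_genes(self, genes: Iterable[str]) -> tuple[list[str], list[str]]:
        """Match requested symbols/ENSG ids against the matrix.

        Returns ``(matched_row_ids, unmatched_requests)``.  ENSG ids are
        compared with version suffixes stripped; symbols are compared
        case-insensitively against the Description column.
        """
        by_unversioned = {strip_ensembl_version(g): g for g in self.values.index}
        by_symbol: dict[str, str] = {}
        for gid, sym in self.gene_symbols.items():
            by_symbol.setdefault(sym.upper(), gid)
        matched: list[str] = []
        unmatched: list[str] = []
        seen: set[str] = set()
        for g in genes:
            key = str(g).strip()
            row = by_unversioned.get(strip_ensembl_version(key)) or by_symbol.get(key.upper())
            if row is None:
                unmatched.append(key)
            elif row not in seen:
                seen.add(row)
                matched.append(row)
        return matched, unmatched


# ---------------------------------------------------------------------------
# field-level parsers
# ---------------------------------------------------------------------------

_ENSG_VERSION = re.compile(r"^(ENSG\d+)\.\d+$")
# catalog exports print p-values either as plain floats / E-notation or in the
# human dialect "6 x 10-12" (with ASCII x or U+00D7, hyphen or U+2212 minus)
_P_DIALECT = re.compile(
    r"^\s*([0-9]*\.?[0-9]+)\s*[x×]\s*10\s*\^?\s*[-−]?\s*([0-9]+)\s*$"
)


def strip_ensembl_version(ensg: str) -> str:
    m = _ENSG_VERSION.match(ensg.strip())
    return m.group(1) if m else ensg.strip()


def parse_catalog_p(raw: object) -> Optional[float]:
    """Parse a GWAS Catalog p-value in either E-notation or 'm x 10-e' dialect.

    Returns None for blank/unparseable values; values outside (0, 1] are
    treated as unparseable.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if not s or s.upper() in {"NR", "NA"}:
        return None
    try:
        v = float(s)
    except ValueError:
        m = _P_DIALECT.match(s)
        if not m:
            return None
        v = float(f"{m.group(1)}e-{m.group(2)}")
    if not (0.0 < v <= 1.0):
        return None
    return v


def parse_position(raw: object) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if not s:
        return None
    try:
        return int(float(s))
    except ValueError:
        return None


def parse_ensembl_field(raw: object) -> tuple[str, ...]:
    """Split a SNP_GENE_IDS field (comma- or semicolon-separated ENSG list)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ()
    toks = re.split(r"[;,]\s*", str(raw).strip())
    out: list[str] = []
    for t in toks:
        t = t.strip()
        if t and t not in out:
            out.append(t)
    return tuple(out)


# ---------------------------------------------------------------------------
# GWAS Catalog association export
# ---------------------------------------------------------------------------

CATALOG_REQUIRED = ["PUBMEDID", "SNPS", "CHR_ID", "CHR_POS", "MAPPED_GENE", "P-VALUE"]


def read_gwas_catalog(path: str | os.PathLike, trait_id: Optional[str] = None) -> list[AssociationRecord]:
    """Read a GWAS Catalog association TSV into AssociationRecords.

    One record per body row, in file order; nothing is dropped (bad p-values
    or positions are flagged missing).  When ``trait_id`` is given and the
    export carries a ``MAPPED_TRAIT_URI`` column, rows are restricted to that
    EFO accession.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    for col in CATALOG_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"GWAS Catalog file is missing mandatory column {col!r}")
    if trait_id and "MAPPED_TRAIT_URI" in df.columns:
        df = df[df["MAPPED_TRAIT_URI"].str.contains(trait_id, regex=False)]
    records: list[AssociationRecord] = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        records.append(
            AssociationRecord(
                study_id=d["PUBMEDID"].strip(),
                first_author=d.get("FIRST AUTHOR", "").strip(),
                trait_id=trait_id or d.get("MAPPED_TRAIT_URI", "").strip(),
                snp_id=d["SNPS"].strip(),
                chr_id=d["CHR_ID"],
                chr_pos=parse_position(d["CHR_POS"]),
                mapped_gene_raw=d["MAPPED_GENE"],
                ensembl_ids=parse_ensembl_field(d.get("SNP_GENE_IDS", "")),
                p_value=parse_catalog_p(d["P-VALUE"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# HGNC complete set
# ---------------------------------------------------------------------------

_HGNC_COLS = {
    "symbol": ("symbol", "approved symbol", "approved_symbol"),
    "alias": ("alias_symbol", "alias symbols", "alias_symbols"),
    "prev": ("prev_symbol", "previous symbols", "prev_symbols"),
    "ensembl": ("ensembl_gene_id", "ensembl id(supplied by ensembl)", "ensembl_id"),
}


def _find_col(df: pd.DataFrame, names: Sequence[str]) -> Optional[str]:
    lower = {c.lower(): c for c in df.columns}
    for n in names:
        if n in lower:
            return lower[n]
    return None


def _split_multi(raw: str) -> list[str]:
    return [t.strip().upper() for t in re.split(r"[|,]", raw) if t.strip()]


def read_hgnc_table(path: str | os.PathLike) -> HgncMap:
    """Read an HGNC complete-set TSV into an HgncMap.

    Aliases and previous symbols fold into one alias map; an alias that
    collides with an approved symbol is dropped (approved wins).  Duplicate
    approved symbols are a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    sym_col = _find_col(df, _HGNC_COLS["symbol"])
    if sym_col is None:
        raise FormatError("HGNC table is missing an approved-symbol column")
    alias_col = _find_col(df, _HGNC_COLS["alias"])
    prev_col = _find_col(df, _HGNC_COLS["prev"])
    ens_col = _find_col(df, _HGNC_COLS["ensembl"])

    approved: set[str] = set()
    alias_map: dict[str, str] = {}
    sym_to_ens: dict[str, str] = {}
    ens_to_sym: dict[str, str] = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        sym = d[sym_col].strip().upper()
        if not sym:
            continue
        if sym in approved:
            raise FormatError(f"duplicate approved symbol {sym!r} in HGNC table")
        approved.add(sym)
        aliases: list[str] = []
        if alias_col:
            aliases += _split_multi(d[alias_col])
        if prev_col:
            aliases += _split_multi(d[prev_col])
        for a in aliases:
            if a and a != sym:
                # first mapping wins; later conflicting aliases are ignored
                alias_map.setdefault(a, sym)
        if ens_col and d[ens_col].strip():
            ensg = strip_ensembl_version(d[ens_col].strip())
            sym_to_ens[sym] = ensg
            ens_to_sym.setdefault(ensg, sym)
    # approved symbols win over any alias of the same spelling
    for a in list(alias_map):
        if a in approved:
            del alias_map[a]
    return HgncMap(
        approved=frozenset(approved),
        alias_to_approved=alias_map,
        symbol_to_ensembl=sym_to_ens,
        ensembl_to_symbol=ens_to_sym,
    )


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def read_gct(path: str | os.PathLike, group_map: Optional[Mapping[str, str]] = None) -> TpmMatrix:
    """Read a GCT 1.2 gene x tissue matrix.

    The declared dimensions must match the body; negative expression values
    are a format error.  Tissues absent from ``group_map`` default to OTHER.
    """
    with open(path, "r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError("GCT dimensions line must hold two integers")
        n_genes, n_tissues = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns[:2]) != ["Name", "Description"]:
        raise FormatError("GCT body must start with Name and Description columns")
    tissues = list(df.columns[2:])
    if len(df) != n_genes or len(tissues) != n_tissues:
        raise FormatError(
            f"GCT dimensions line declares {n_genes}x{n_tissues} but body is "
            f"{len(df)}x{len(tissues)}"
        )
    if len(set(tissues)) != len(tissues):
        raise FormatError("GCT tissue names are not unique")
    values = df.set_index("Name")[tissues].astype(float)
    if (values.values < 0).any():
        raise FormatError("GCT contains negative expression values")
    group_map = dict(group_map or {})
    groups = {t: group_map.get(t, OTHER) for t in tissues}
    bad = {g for g in groups.values()} - {GIT, BRAIN, OTHER}
    if bad:
        raise FormatError(f"unknown tissue group label(s): {sorted(bad)}")
    symbols = dict(zip(df["Name"], df["Description"].astype(str)))
    return TpmMatrix(values=values, gene_symbols=symbols, tissue_groups=groups)


def write_gct(matrix: TpmMatrix, path: str | os.PathLike, float_fmt: str = "%.6g") -> None:
    df = matrix.values.copy()
    df.insert(0, "Description", [matrix.gene_symbols.get(g, g) for g in df.index])
    df.insert(0, "Name", df.index)
    body = df.to_csv(sep="\t", index=False, float_format=float_fmt)
    _atomic_write(path, f"#1.2\n{len(matrix.values)}\t{len(matrix.values.columns)}\n" + body)


# ---------------------------------------------------------------------------
# tissue-group table and result tables
# ---------------------------------------------------------------------------

def read_tissue_groups(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (tissue, group) TSV into a group map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if "tissue" not in cols or "group" not in cols:
        raise FormatError("tissue-group table needs 'tissue' and 'group' columns")
    t_col = df.columns[cols.index("tissue")]
    g_col = df.columns[cols.index("group")]
    return {r[t_col].strip(): r[g_col].strip().upper() for _, r in df.iterrows()}


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    """Write-then-rename so partial failures never leave truncated files."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | os.PathLike, float_fmt: str = "%.6g") -> None:
    """Write a result table as TSV with a header row (atomic)."""
    _atomic_write(path, df.to_csv(sep="\t", index=False, float_format=float_fmt))


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_set(symbols: Iterable[str], path: str | os.PathLike) -> None:
    _atomic_write(path, "\n".join(sorted(symbols)) + "\n")


def read_gene_set(path: str | os.PathLike) -> set[str]:
    """Read a one-symbol-per-line gene set file."""
    with open(path, "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}
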