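"""Readers and writers for the text formats the pipeline exchanges.

All formats are tab-delimited UTF-8 with one header row.  Missing values are
encoded as ``NA`` (case-insensitive) or an empty cell.  The canonical
association-table header is::

    rsid  effect_allele  other_allele  eaf  beta  se  pval  n  n_cases  n_controls

plus an optional ``locus`` column.  Consortium dumps that name their columns
differently are accommodated by passing a ``dialect`` mapping from canonical
names to the file's column names.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .exceptions import DuplicateRecordError, FormatError
from .records import AssociationSet, InstrumentAnnotation, LdMatrix, ProxyCandidate, SnpAssociation

PathLike = Union[str, Path]

CANONICAL_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
    "n_controls",
    "locus",
)

_REQUIRED = ("rsid", "effect_allele", "other_allele", "beta", "se")

_NA_STRINGS = {"", "na", "nan", "none", "nil"}


def _is_missing(cell) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return True
    return str(cell).strip().lower() in _NA_STRINGS


def _parse_float(cell, row: int, col: str) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(str(cell))
    except ValueError as exc:
        raise FormatError(f"row {row}: column {col!r} is not numeric: {cell!r}") from exc


def _parse_int(cell, row: int, col: str) -> Optional[int]:
    v = _parse_float(cell, row, col)
    if v is None:
        return None
    if v != int(v):
        raise FormatError(f"row {row}: column {col!r} is not an integer: {cell!r}")
    return int(v)


def read_association_table(
    path: PathLike,
    trait_name: str = "",
    trait_type: str = "continuous",
    dialect: Optional[Mapping[str, str]] = None,
    provenance: str = "",
) -> AssociationSet:
    """Read a GWAS summary-association TSV into an :class:`AssociationSet`.

    ``dialect`` maps canonical column names to the file's header names;
    unmapped canonical names default to themselves.  Rows violating the
    record invariants are rejected with a row-numbered diagnostic.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    for canon in _REQUIRED:
        if colmap[canon] not in df.columns:
            raise FormatError(
                f"{path.name}: required column {colmap[canon]!r} (for {canon!r}) missing "
                f"from header {list(df.columns)}"
            )

    def cell(row_s, canon):
        name = colmap[canon]
        return row_s[name] if name in df.columns else None

    aset = AssociationSet(trait_name or path.stem, trait_type, provenance=provenance)
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based incl. header
        rsid = str(row[colmap["rsid"]]).strip()
        if not rsid or _is_missing(rsid):
            raise FormatError(f"row {i}: empty rsid")
        try:
            rec = SnpAssociation(
                rsid=rsid,
                effect_allele=str(cell(row, "effect_allele")).strip().upper(),
                other_allele=str(cell(row, "other_allele")).strip().upper(),
                eaf=_parse_float(cell(row, "eaf"), i, "eaf"),
                beta=_parse_float(cell(row, "beta"), i, "beta"),
                se=_parse_float(cell(row, "se"), i, "se"),
                p=_parse_float(cell(row, "pval"), i, "pval"),
                n=_parse_int(cell(row, "n"), i, "n"),
                n_cases=_parse_int(cell(row, "n_cases"), i, "n_cases"),
                n_controls=_parse_int(cell(row, "n_controls"), i, "n_controls"),
                locus_label="" if _is_missing(cell(row, "locus")) else str(cell(row, "locus")).strip(),
            )
        except FormatError as exc:
            raise FormatError(f"{path.name} row {i}: {exc}") from exc
        try:
            aset.add(rec)
        except DuplicateRecordError as exc:
            raise DuplicateRecordError(f"{path.name} row {i}: {exc}") from exc
    return aset


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return format(v, ".17g")
    return str(v)


def write_association_table(aset: AssociationSet, path: PathLike) -> None:
    """Write an :class:`AssociationSet` in the canonical dialect (lossless)."""
    rows = []
    for rec in aset:
        rows.append(
            {
                "rsid": rec.rsid,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "eaf": _fmt(rec.eaf),
                "beta": _fmt(rec.beta),
                "se": _fmt(rec.se),
                "pval": _fmt(rec.p),
                "n": _fmt(rec.n),
                "n_cases": _fmt(rec.n_cases),
                "n_controls": _fmt(rec.n_controls),
                "locus": rec.locus_label or "NA",
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: PathLike) -> LdMatrix:
    """Read a signed correlation matrix from a labelled square TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path.name}: LD matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path.name}: row and column rsid labels differ")
    try:
        return LdMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
    except FormatError as exc:
        raise type(exc)(f"{path.name}: {exc}") from exc


def write_ld_matrix(ld: LdMatrix, path: PathLike) -> None:
    pd.DataFrame(ld.r, index=ld.rsids, columns=ld.rsids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_annotation_table(path: PathLike) -> dict[str, InstrumentAnnotation]:
    """Read instrument annotations.

    Columns: ``rsid``, ``pleiotropy`` (semicolon-joined trait names or NA),
    ``functional`` (0/1), ``proxies`` (comma-joined ``rsid:r2:kb:X>Y`` items
    or NA, where X is the index SNP's effect allele and Y the proxy's).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("rsid", "pleiotropy", "functional", "proxies"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    out: dict[str, InstrumentAnnotation] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        rsid = row["rsid"].strip()
        if rsid in out:
            raise DuplicateRecordError(f"{path.name} row {i}: duplicate rsid {rsid}")
        terms: tuple[str, ...] = ()
        if not _is_missing(row["pleiotropy"]):
            terms = tuple(t.strip() for t in row["pleiotropy"].split(";") if t.strip())
        proxies = []
        if not _is_missing(row["proxies"]):
            for item in row["proxies"].split(","):
                try:
                    prsid, r2, kb, amap = item.strip().split(":")
                    a_from, a_to = amap.split(">")
                except ValueError as exc:
                    raise FormatError(f"{path.name} row {i}: bad proxy item {item!r}") from exc
                proxies.append(
                    ProxyCandidate(prsid, float(r2), float(kb), (a_from.upper(), a_to.upper()))
                )
        out[rsid] = InstrumentAnnotation(
            rsid=rsid,
            pleiotropy_terms=terms,
            functional=row["functional"].strip() in ("1", "true", "True"),
            proxy_candidates=tuple(proxies),
        )
    return out


def write_results_table(results, path: PathLike) -> None:
    """Write a results table as TSV, one row per outcome x instrument subset.

    Odds ratios, mean differences and CI bounds are rounded to two decimals;
    inestimable combinations render as ``NA``.
    """
    rows = list(results.rows)
    if not rows:
        raise FormatError("results table is empty")
    out = []
    for row in rows:
        out.append(
            {
                "outcome": row.outcome,
                "consortium": row.consortium,
                "subset": row.subset,
                "n_snps": row.n_snps if row.n_snps is not None else "NA",
                "estimate": row.estimate_str(),
                "ci_95": row.ci_str(),
                "p": format(row.p, ".3g") if row.p is not None else "NA",
                "nominal_significant": _flag(row.nominal_significant),
                "bonferroni_significant": _flag(row.bonferroni_significant),
                "note": row.note,
            }
        )
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def _flag(v) -> str:
    return "NA" if v is None else ("yes" if v else "no")
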