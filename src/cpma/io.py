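"""Readers and writers for summary-statistic tables, plus the bundled fixture.

The summary-table dialect follows the common GWAS cross-phenotype layout:
identifier columns (SNP, CHR, POS, major_al, minor_al, optional Genes and
Disease), then one ``{NAME}.Z`` / ``{NAME}.P`` column pair per phenotype, in
panel order.  Missing cells are an NA token in both columns of the pair.
Numeric fields may use either the ASCII hyphen-minus or the typographic
minus sign U+2212 (frequent in tables copied from publications).

The bundled fixture is a transcription of the 47-SNP x 7-disease association
table (RA, psoriasis, MS, SLE, Crohn's, coeliac, T1D) used throughout the
test suite, including its single missing cell (rs2082412 in MS), the printed
cross-phenotype meta-analysis p-value per SNP, and a discovery-disease
annotation where the table's study reference resolves to one of the seven
contributing scans.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .core import AssociationCell, AssociationMatrix, ScreenResult, SnpRecord

__all__ = [
    "SummaryTableDialect",
    "read_summary_table",
    "write_summary_table",
    "load_fixture_table2",
    "fixture_table2_frame",
    "write_screen_result",
    "atomic_write_text",
]

_MINUS = "−"


@dataclass(frozen=True)
class SummaryTableDialect:
    """Parsing conventions for a summary table."""

    missing_token: str = "NA"
    normalize_minus: bool = True
    snp_column: str = "SNP"
    chrom_column: str = "CHR"
    pos_column: str = "POS"
    major_column: str = "major_al"
    minor_column: str = "minor_al"
    genes_column: str = "Genes"
    discovery_column: str = "Disease"
    z_suffix: str = ".Z"
    p_suffix: str = ".P"


DEFAULT_DIALECT = SummaryTableDialect()


class SummaryTableError(ValueError):
    """Malformed summary table (missing columns, bad values, ...)."""


def _phenotype_pairs(columns, dialect: SummaryTableDialect) -> list[str]:
    """Phenotype names with both Z and P columns, in column order."""
    z_names = [c[: -len(dialect.z_suffix)] for c in columns
               if c.endswith(dialect.z_suffix)]
    p_names = {c[: -len(dialect.p_suffix)] for c in columns
               if c.endswith(dialect.p_suffix)}
    unpaired = (set(z_names) ^ p_names)
    if unpaired:
        raise SummaryTableError(
            f"phenotypes with unpaired Z/P columns: {sorted(unpaired)}"
        )
    if not z_names:
        raise SummaryTableError("no phenotype Z/P column pairs found")
    return z_names


def _parse_number(token: str, dialect: SummaryTableDialect) -> float:
    if dialect.normalize_minus:
        token = token.replace(_MINUS, "-")
    return float(token)


def read_summary_table(
    path: Union[str, Path],
    dialect: SummaryTableDialect = DEFAULT_DIALECT,
) -> AssociationMatrix:
    """Parse a per-SNP, per-phenotype summary-statistic TSV.

    Enforces the association-cell invariants: p in (0, 1], finite Z, and Z/P
    of a cell either both present or both missing.  Violations raise
    :class:`SummaryTableError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [dialect.snp_column, dialect.chrom_column, dialect.pos_column,
                dialect.major_column, dialect.minor_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SummaryTableError(f"missing required columns: {missing}")
    phenotypes = _phenotype_pairs(df.columns, dialect)

    records: list[SnpRecord] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        snp_id = row[dialect.snp_column]
        cells: dict[str, AssociationCell] = {}
        for ph in phenotypes:
            z_tok = row[ph + dialect.z_suffix].strip()
            p_tok = row[ph + dialect.p_suffix].strip()
            z_missing = z_tok == dialect.missing_token or z_tok == ""
            p_missing = p_tok == dialect.missing_token or p_tok == ""
            if z_missing != p_missing:
                raise SummaryTableError(
                    f"line {rowno} ({snp_id}): {ph} has Z/P half-missing"
                )
            if z_missing:
                cells[ph] = AssociationCell()
                continue
            try:
                z = _parse_number(z_tok, dialect)
                p = _parse_number(p_tok, dialect)
            except ValueError as e:
                raise SummaryTableError(
                    f"line {rowno} ({snp_id}): unparseable number in {ph}: {e}"
                ) from None
            try:
                cells[ph] = AssociationCell(z=z, p=p)
            except ValueError as e:
                raise SummaryTableError(
                    f"line {rowno} ({snp_id}): {ph}: {e}"
                ) from None
        discovery = None
        if dialect.discovery_column in df.columns:
            tok = row[dialect.discovery_column].strip()
            if tok and tok != dialect.missing_token:
                discovery = tok
        records.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=str(row[dialect.chrom_column]),
                pos=int(row[dialect.pos_column]),
                major_allele=row[dialect.major_column],
                minor_allele=row[dialect.minor_column],
                gene_label=row.get(dialect.genes_column, ""),
                discovery_phenotype=discovery,
                cells=cells,
            )
        )
    return AssociationMatrix(phenotypes=phenotypes, records=records)


def write_summary_table(
    matrix: AssociationMatrix,
    path: Union[str, Path],
    dialect: SummaryTableDialect = DEFAULT_DIALECT,
) -> None:
    """Write a matrix back to the summary-TSV dialect (17-digit round trip)."""
    cols = [dialect.snp_column, dialect.chrom_column, dialect.pos_column,
            dialect.major_column, dialect.minor_column,
            dialect.genes_column, dialect.discovery_column]
    for ph in matrix.phenotypes:
        cols += [ph + dialect.z_suffix, ph + dialect.p_suffix]
    lines = ["\t".join(cols)]
    for rec in matrix.records:
        vals = [rec.snp_id, rec.chrom, str(rec.pos),
                rec.major_allele, rec.minor_allele,
                rec.gene_label or dialect.missing_token,
                rec.discovery_phenotype or dialect.missing_token]
        for ph in matrix.phenotypes:
            c = rec.cells[ph]
            if c.missing:
                vals += [dialect.missing_token, dialect.missing_token]
            else:
                vals += [f"{c.z:.17g}", f"{c.p:.17g}"]
        lines.append("\t".join(vals))
    atomic_write_text(path, "\n".join(lines) + "\n")


def _fixture_path() -> Path:
    return Path(importlib.resources.files("cpma") / "data" / "table2.tsv")


def fixture_table2_frame() -> pd.DataFrame:
    """The raw bundled fixture table, including the printed per-SNP
    cross-phenotype p-value (column ``cpma.p``) and panel annotation."""
    return pd.read_csv(_fixture_path(), sep="\t", dtype=str,
                       keep_default_na=False)


def load_fixture_table2() -> AssociationMatrix:
    """The bundled 47-SNP x 7-disease association matrix."""
    return read_summary_table(_fixture_path())


def write_screen_result(
    result: ScreenResult,
    path: Union[str, Path],
    fmt: str = "tsv",
) -> None:
    """Persist a panel screen as TSV (per-SNP table) or JSON (table + summary)."""
    if fmt == "tsv":
        atomic_write_text(path, result.table.to_csv(sep="\t", index=False))
    elif fmt == "json":
        payload = {
            "n_snps": result.n_snps,
            "n_significant": result.n_significant,
            "cpma_alpha": result.cpma_alpha,
            "enrichment_p": None if math.isnan(result.enrichment_p)
            else result.enrichment_p,
            "errors": result.errors,
            "results": result.table.to_dict(orient="records"),
        }
        atomic_write_text(path, json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def atomic_write_text(path: Union[str, Path], text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
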