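"""Reading, validating and writing the tabular formats the pipeline consumes.

Three external formats are supported, all tab-delimited UTF-8 text:

* GWAS summary statistics with header
  ``variant_id chromosome position effect_allele other_allele eaf beta se pvalue n``
  (remappable via a column map); coordinates are 1-based.
* Gene regions with header ``gene chromosome start end`` (1-based inclusive).
* Square LD (r-squared) matrices whose first column and header row are variant ids.

Missing ``eaf``/``n`` are encoded as the literal ``NA``; any other non-numeric
token is an error, so dialect drift fails loudly rather than silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

ALLELES = frozenset("ACGT")

GWAS_COLUMNS: Tuple[str, ...] = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

RESULT_COLUMNS: Tuple[str, ...] = (
    "exposure",
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "or_",
    "ci_low",
    "ci_high",
    "pvalue",
    "fdr_pvalue",
    "q_stat",
    "q_pvalue",
    "egger_intercept",
    "egger_intercept_pvalue",
    "reliable",
)


class GwasIoError(Exception):
    """Base class for I/O layer failures."""


class ConfigError(GwasIoError):
    """A required column or configuration key is missing."""


class FormatError(GwasIoError):
    """The file shape does not match the declared format."""


class ValidationError(GwasIoError):
    """Values violate a domain invariant; the message itemizes offending rows."""


@dataclass
class GwasRecord:
    """One variant's association summary for one trait.

    ``beta`` is per effect allele, in trait SD units for quantitative traits and
    log-odds for binary traits; ``se`` is its standard error.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: Optional[int] = None

    def problems(self) -> List[str]:
        """Return a list of invariant violations (empty when valid)."""
        out: List[str] = []
        if self.effect_allele not in ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in ALLELES:
            out.append(f"other_allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not self.position >= 1:
            out.append(f"position {self.position} < 1")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append(f"eaf {self.eaf} outside [0, 1]")
        if not (math.isfinite(self.se) and self.se > 0):
            out.append(f"se {self.se} is not > 0")
        if not (0.0 < self.pvalue <= 1.0):
            out.append(f"pvalue {self.pvalue} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            out.append(f"n {self.n} is not positive")
        return out


@dataclass(frozen=True)
class GeneRegion:
    """A gene body in 1-based inclusive coordinates; the cis anchor for IV selection."""

    gene: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region {self.gene}: start {self.start} > end {self.end}")


@dataclass
class LdMatrix:
    """Pairwise squared-correlation matrix over an ordered set of variants."""

    variant_ids: Tuple[str, ...]
    r2: np.ndarray
    _index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = tuple(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise ValidationError(f"variant {variant_id!r} absent from LD matrix") from None

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index(a), self.index(b)])

    def subset(self, variant_ids: Sequence[str]) -> "LdMatrix":
        idx = [self.index(v) for v in variant_ids]
        return LdMatrix(tuple(variant_ids), self.r2[np.ix_(idx, idx)])


def _parse_float(token: str, *, column: str, row: int, allow_na: bool = False) -> Optional[float]:
    if token == "NA":
        if allow_na:
            return None
        raise ValidationError(f"row {row}: column {column} may not be NA")
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"row {row}: column {column} has non-numeric value {token!r}") from None


def _parse_int(token: str, *, column: str, row: int, allow_na: bool = False) -> Optional[int]:
    value = _parse_float(token, column=column, row=row, allow_na=allow_na)
    if value is None:
        return None
    if value != int(value):
        raise ValidationError(f"row {row}: column {column} value {token!r} is not an integer")
    return int(value)


def read_gwas(path, column_map: Optional[Mapping[str, str]] = None) -> List[GwasRecord]:
    """Read a summary-statistics table into validated :class:`GwasRecord` objects.

    ``column_map`` maps canonical column names (``GWAS_COLUMNS``) to the names used
    in the file. Row order is preserved; every failing row is itemized (with its
    1-based data row number) in a single :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping = {name: name for name in GWAS_COLUMNS}
    if column_map:
        mapping.update(column_map)
    for canonical, actual in mapping.items():
        if actual not in df.columns:
            raise ConfigError(f"missing mandatory column {actual!r} (for {canonical})")

    records: List[GwasRecord] = []
    errors: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        values = {canonical: getattr(row, actual) for canonical, actual in mapping.items()}
        try:
            rec = GwasRecord(
                variant_id=values["variant_id"],
                chromosome=str(values["chromosome"]),
                position=_parse_int(values["position"], column="position", row=i),
                effect_allele=values["effect_allele"],
                other_allele=values["other_allele"],
                eaf=_parse_float(values["eaf"], column="eaf", row=i, allow_na=True),
                beta=_parse_float(values["beta"], column="beta", row=i),
                se=_parse_float(values["se"], column="se", row=i),
                pvalue=_parse_float(values["pvalue"], column="pvalue", row=i),
                n=_parse_int(values["n"], column="n", row=i, allow_na=True),
            )
        except ValidationError as exc:
            errors.append(str(exc))
            continue
        bad = rec.problems()
        if bad:
            errors.extend(f"row {i}: {msg}" for msg in bad)
        else:
            records.append(rec)
    if errors:
        raise ValidationError("invalid GWAS rows:\n" + "\n".join(errors))
    return records


def _fmt(value, *, na: str = "NA", digits: int = 10) -> str:
    if value is None:
        return na
    if isinstance(value, str):
        return value
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float) and math.isnan(value):
        return na
    return f"{value:.{digits}g}"


def write_gwas(records: Iterable[GwasRecord], path) -> None:
    """Write records in the canonical column order (floats to 10 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(GWAS_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.chromosome,
                        str(r.position),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pvalue),
                        _fmt(r.n),
                    ]
                )
                + "\n"
            )


def read_regions(path) -> List[GeneRegion]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "chromosome", "start", "end"):
        if col not in df.columns:
            raise ConfigError(f"missing mandatory column {col!r} in regions file")
    regions = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        regions.append(
            GeneRegion(
                gene=row.gene,
                chromosome=str(row.chromosome),
                start=_parse_int(row.start, column="start", row=i),
                end=_parse_int(row.end, column="end", row=i),
            )
        )
    return regions


def write_regions(regions: Iterable[GeneRegion], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tchromosome\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.gene}\t{r.chromosome}\t{r.start}\t{r.end}\n")


def read_ld_matrix(path, *, tolerance: float = 1e-8) -> LdMatrix:
    """Read and validate a square r-squared matrix.

    The header row and first column must carry identical variant ids in identical
    order; asymmetries or diagonal departures beyond ``tolerance`` are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix is not square: shape {df.shape}")
    cols = [str(c) for c in df.columns]
    rows = [str(r) for r in df.index]
    if cols != rows:
        raise FormatError("LD matrix header and row ids differ")
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"LD matrix contains non-numeric entries: {exc}") from None
    if np.abs(mat - mat.T).max(initial=0.0) > tolerance:
        raise ValidationError("LD matrix asymmetric beyond tolerance 1e-8")
    if np.abs(np.diag(mat) - 1.0).max(initial=0.0) > tolerance:
        raise ValidationError("LD matrix diagonal differs from 1 beyond tolerance 1e-8")
    if mat.min(initial=1.0) < -tolerance or mat.max(initial=0.0) > 1.0 + tolerance:
        raise ValidationError("LD matrix entries outside [0, 1]")
    mat = np.clip((mat + mat.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return LdMatrix(tuple(rows), mat)


def write_ld_matrix(ld: LdMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant_id\t" + "\t".join(ld.variant_ids) + "\n")
        for vid, row in zip(ld.variant_ids, ld.r2):
            fh.write(vid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def write_results_table(results: Iterable, path) -> None:
    """Write MR results one row per (exposure, outcome, method).

    Columns are fixed (:data:`RESULT_COLUMNS`), floats are serialized with 6
    significant digits, missing diagnostics are ``NA`` and rows are sorted
    lexicographically by (exposure, outcome, method) for determinism.
    """
    rows = sorted(results, key=lambda r: (r.exposure, r.outcome, r.method))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(_fmt(getattr(r, col, None), digits=6) for col in RESULT_COLUMNS) + "\n"
            )


def read_results_table(path) -> pd.DataFrame:
    """Read a results table back (``NA`` becomes NaN); used for round-trip checks."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
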