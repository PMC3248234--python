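"""Expression matrices, result tables, and their tab-delimited serialization.

Expression files are genes-as-rows TSV: a mandatory header line
``gene_id<TAB><sample_1><TAB>...<TAB><sample_n>`` followed by one line per
gene, the gene identifier and then ``n`` log-scale expression values.
Floats are written with 17 significant digits so a write/read round trip is
the identity at full double precision, and identical results serialize to
byte-identical files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

#: Fixed float format used by every writer (17 significant digits round-trips
#: IEEE doubles exactly, making determinism checks byte-exact).
FLOAT_FMT = "{:.17g}"


class GdaaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GdaaError):
    """Malformed input file; the message names the offending line."""


class ConfigError(GdaaError):
    """Invalid analysis configuration (shapes, identifiers, subgroup counts)."""


class DegenerateDataError(GdaaError):
    """Zero-variance gene encountered while strict variance checking is on."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ConfigError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log-scale expression values.

    Rows are genes, columns are samples (subjects/slides). Values must be
    finite; gene and sample identifiers must be unique.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigError("expression values must be a 2-D genes × samples array")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ConfigError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ConfigError(f"{len(self.sample_ids)} sample ids for {n} columns")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.isfinite(self.values).all():
            raise ConfigError("expression values contain NaN or Inf")

    @property
    def m(self) -> int:
        """Number of genes."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.shape[1]


@dataclass
class GdaaResult:
    """Per-gene output of a differential-association run.

    ``n_star`` is the observed N-statistic, ``p_value`` the permutation
    p-value on the grid {0, 1/K, ..., 1}, and ``p_adjusted`` the extended
    Bonferroni (per-family error rate) adjustment ``p × m`` — deliberately
    NOT capped at 1, since a PFER is an expected count of false positives.
    """

    gene_ids: list[str]
    n_star: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray
    K: int
    G: int
    seed: int

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.n_star = np.asarray(self.n_star, dtype=np.float64)
        self.p_value = np.asarray(self.p_value, dtype=np.float64)
        self.p_adjusted = np.asarray(self.p_adjusted, dtype=np.float64)
        m = len(self.gene_ids)
        for name, arr in (("n_star", self.n_star), ("p_value", self.p_value),
                          ("p_adjusted", self.p_adjusted)):
            if arr.shape != (m,):
                raise ConfigError(f"{name} has shape {arr.shape}, expected ({m},)")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if np.any(self.p_value < 0) or np.any(self.p_value > 1):
            raise ConfigError("p-values outside [0, 1]")
        counts = self.p_value * self.K
        if not np.allclose(counts, np.round(counts), atol=1e-9, rtol=0):
            raise ConfigError("p-values are not multiples of 1/K")
        if not np.array_equal(self.p_adjusted, self.p_value * m):
            raise ConfigError("p_adjusted must equal p_value * m exactly")
        if np.any(self.n_star < -1e-9):
            raise ConfigError("negative N-statistic beyond roundoff tolerance")

    @property
    def m(self) -> int:
        return len(self.gene_ids)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes × samples expression TSV.

    Raises :class:`ParseError` naming the offending (1-based) file line for a
    malformed header, ragged row, non-numeric cell, or duplicate identifier.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: line 1: empty file") from None
        if not header or header[0] != "gene_id":
            raise ParseError(f"{path}: line 1: header must start with 'gene_id'")
        sample_ids = header[1:]
        if not sample_ids:
            raise ParseError(f"{path}: line 1: header lists no samples")
        seen_samples: set[str] = set()
        for s in sample_ids:
            if s in seen_samples:
                raise ParseError(f"{path}: line 1: duplicate sample id {s!r}")
            seen_samples.add(s)
        n = len(sample_ids)

        gene_ids: list[str] = []
        seen_genes: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:  # tolerate a trailing blank line
                continue
            if len(row) != n + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n + 1} fields, got {len(row)}"
                )
            gid = row[0]
            if gid in seen_genes:
                raise ParseError(f"{path}: line {lineno}: duplicate gene id {gid!r}")
            seen_genes.add(gid)
            try:
                vals = [float(v) for v in row[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            if not all(np.isfinite(vals)):
                raise ParseError(f"{path}: line {lineno}: non-finite value")
            gene_ids.append(gid)
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: file contains no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=np.float64))


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write ``matrix`` as a TSV parseable by :func:`read_expression_tsv`."""
    if not np.isfinite(matrix.values).all():
        raise ConfigError("refusing to write non-finite expression values")
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(FLOAT_FMT.format(v) for v in row) + "\n")


def write_results_tsv(result: GdaaResult, path) -> None:
    """Write a result table: gene_id, n_statistic, p_value, p_adjusted.

    Gene order is input order (no sorting); fixed float formatting makes the
    output byte-stable, so identically-configured runs produce byte-identical
    files regardless of parallel execution layout.
    """
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\tn_statistic\tp_value\tp_adjusted\n")
        for gid, ns, p, pa in zip(result.gene_ids, result.n_star,
                                  result.p_value, result.p_adjusted):
            fh.write(
                f"{gid}\t{FLOAT_FMT.format(ns)}\t{FLOAT_FMT.format(p)}"
                f"\t{FLOAT_FMT.format(pa)}\n"
            )
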