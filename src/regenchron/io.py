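"""Readers and writers for the pipeline's tabular formats.

The in-memory currency is plain pandas objects with a documented schema:

* expression matrix — ``DataFrame`` of log2 signal intensities, probes in
  rows (index named ``probe_id``), samples in columns;
* sample table — ``DataFrame`` with columns ``sample_id``, ``day``,
  ``replicate`` and optional ``stage``, sorted by ``(day, replicate)``;
* probe annotation — ``DataFrame`` with ``probe_id`` and optional
  ``gene_symbol`` / ``annotation_id`` columns;
* gene sets — :class:`GeneSetCollection` parsed from GMT.

All readers validate invariants up front (unique identifiers, finite
values, required columns) and raise :class:`FormatError` with the
offending location so malformed inputs fail loudly rather than
propagating NaNs into the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STAGES = ("PB", "EB", "MB", "LB", "P", "DO")


class FormatError(ValueError):
    """An input file violates the expected tabular format."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a log2 expression matrix (TSV, probes x samples).

    The first column must be ``probe_id``; the header row carries the
    sample identifiers.  Row and column order are preserved.

    Raises
    ------
    FormatError
        On duplicate probe or sample identifiers, or any non-numeric or
        non-finite cell (the location is named in the message).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected probe_id column plus >=1 sample column")
    dup_samples = _duplicates(header[1:])
    if dup_samples:
        raise FormatError(f"{path}: duplicate sample column(s): {', '.join(dup_samples)}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    sample_ids = header[1:]
    raw.columns = header
    probe_ids = raw.iloc[:, 0].tolist()
    dup_probes = _duplicates(probe_ids)
    if dup_probes:
        raise FormatError(f"{path}: duplicate probe id(s): {', '.join(dup_probes[:5])}")
    values = np.empty((len(probe_ids), len(sample_ids)), dtype=float)
    for j, col in enumerate(sample_ids):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(converted.to_numpy(dtype=float)))
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"{path}: non-numeric or non-finite value {raw[col].iloc[i]!r} "
                f"at probe {probe_ids[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix as TSV (header ``probe_id\\t<sample...>``)."""
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def validate_expression_matrix(matrix: pd.DataFrame, samples: pd.DataFrame | None = None) -> None:
    """Check matrix invariants; optionally that all samples resolve in *samples*."""
    if not matrix.index.is_unique:
        raise FormatError("expression matrix has duplicate probe ids")
    if not matrix.columns.is_unique:
        raise FormatError("expression matrix has duplicate sample ids")
    if not np.isfinite(matrix.to_numpy()).all():
        raise FormatError("expression matrix contains non-finite values")
    if samples is not None:
        missing = set(matrix.columns) - set(samples["sample_id"])
        if missing:
            raise FormatError(f"samples absent from sample table: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (TSV: sample_id, day, replicate[, stage]).

    Returns the table sorted by ``(day, replicate)`` with ``day`` parsed
    as float (fractional days like 0.5 are meaningful) and ``replicate``
    as int.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    for col in ("sample_id", "day", "replicate"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    table["day"] = pd.to_numeric(table["day"], errors="raise").astype(float)
    table["replicate"] = pd.to_numeric(table["replicate"], errors="raise").astype(int)
    if "stage" not in table.columns:
        table["stage"] = pd.NA
    return _validate_sample_table(table, source=str(path))


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "day", "replicate"] + (["stage"] if "stage" in samples.columns else [])
    samples[cols].to_csv(path, sep="\t", index=False)


def _validate_sample_table(table: pd.DataFrame, source: str = "sample table") -> pd.DataFrame:
    if (table["day"] < 0).any():
        raise FormatError(f"{source}: negative day")
    if (table["replicate"] < 1).any():
        raise FormatError(f"{source}: replicate must be a positive integer")
    dup = table.duplicated(subset=["day", "replicate"])
    if dup.any():
        row = table[dup].iloc[0]
        raise FormatError(
            f"{source}: duplicate (day, replicate) pair ({row['day']}, {row['replicate']})"
        )
    if not table["sample_id"].is_unique:
        raise FormatError(f"{source}: duplicate sample_id")
    known = table["stage"].dropna()
    bad = set(known) - set(STAGES)
    if bad:
        raise FormatError(f"{source}: unknown stage label(s) {sorted(bad)}")
    return table.sort_values(["day", "replicate"], kind="mergesort").reset_index(drop=True)


def schedule_of(samples: pd.DataFrame) -> list[float]:
    """The ordered distinct days of a sample table."""
    return sorted(set(samples["day"].tolist()))


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read probe -> gene annotation (TSV: probe_id[, gene_symbol, annotation_id]).

    Unannotated probes are permitted; their annotation fields stay empty.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "probe_id" not in table.columns:
        raise FormatError(f"{path}: missing required column 'probe_id'")
    if not table["probe_id"].is_unique:
        raise FormatError(f"{path}: duplicate probe_id")
    for col in ("gene_symbol", "annotation_id"):
        if col not in table.columns:
            table[col] = pd.NA
    return table[["probe_id", "gene_symbol", "annotation_id"]]


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets with unique term ids."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term_id TAB description TAB member...).

    Duplicate members within a set are collapsed; a line with fewer than
    three fields is a format error reported with its line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, term_name = fields[0], fields[1]
            if term_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {term_id!r} has no members")
            sets.append(GeneSet(term_id, term_name, members))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV, byte-stable for identical input.

    Floats are serialised with 6 significant digits so that reruns diff
    cleanly; identifiers and integer columns are written exactly.
    """
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups
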