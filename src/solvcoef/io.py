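"""Readers/writers for coefficient, solute and SMILES tables, plus packaged fixtures.

File dialects
-------------
* Coefficient table: CSV with header ``name,c,e,s,a,b,v,convention``; ``c`` may
  be blank for ``zero_intercept`` rows.
* Paired table: CSV with header ``name,c,e,s,a,b,v,e0,s0,a0,b0,v0`` carrying an
  original row and its zero-intercept recalibration side by side.
* Solute table: CSV with header ``name,E,S,A,B,V``.
* SMILES: ``.smi`` lines of ``SMILES<whitespace>name``.

Lines starting with ``#`` are comments in every dialect.  Duplicate solvent or
solute names (case-insensitive) are rejected.
"""
from __future__ import annotations

import csv
import io as _stdio
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import ORIGINAL, ZERO_INTERCEPT, COEFF_KEYS, SoluteDescriptors, SolventCoefficients
from .errors import InvalidInputError, SchemaError

__all__ = [
    "read_coefficient_table",
    "write_coefficient_table",
    "read_paired_table",
    "write_paired_table",
    "read_solute_table",
    "read_smiles",
    "load_table1",
    "table1_original",
    "table1_zero_intercept",
    "load_table3",
    "load_solvent_smiles",
    "paired_to_original",
    "paired_to_zero_intercept",
]

PAIRED_COLUMNS = ["name", "c", "e", "s", "a", "b", "v", "e0", "s0", "a0", "b0", "v0"]


def _open_rows(path):
    """Yield (line_number, row) from a CSV file, skipping blanks and comments."""
    with open(path, "r", newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            yield lineno, [cell.strip() for cell in row]


def _parse_float(value: str, what: str, lineno: int, path) -> float:
    try:
        out = float(value)
    except ValueError:
        raise InvalidInputError(f"{path}:{lineno}: cannot parse {what} value {value!r}") from None
    if not math.isfinite(out):
        raise InvalidInputError(f"{path}:{lineno}: {what} must be finite, got {value!r}")
    return out


def _check_duplicates(names: Iterable[str], path) -> None:
    seen: set[str] = set()
    for name in names:
        key = name.strip().lower()
        if key in seen:
            raise InvalidInputError(f"{path}: duplicate solvent/solute name {name!r}")
        seen.add(key)


def read_coefficient_table(path) -> list[SolventCoefficients]:
    """Read a ``name,c,e,s,a,b,v,convention`` CSV into typed rows."""
    rows_iter = _open_rows(path)
    try:
        _, header = next(rows_iter)
    except StopIteration:
        raise InvalidInputError(f"{path}: empty coefficient table") from None
    expected = ["name", "c", "e", "s", "a", "b", "v", "convention"]
    if [h.lower() for h in header] != expected:
        raise SchemaError(f"{path}: expected header {','.join(expected)!r}, got {','.join(header)!r}")
    out: list[SolventCoefficients] = []
    for lineno, row in rows_iter:
        if len(row) != len(expected):
            raise InvalidInputError(f"{path}:{lineno}: expected {len(expected)} fields, got {len(row)}")
        name, c_raw, *weights, convention = row
        convention = convention.lower()
        if convention not in (ORIGINAL, ZERO_INTERCEPT):
            raise InvalidInputError(f"{path}:{lineno}: unknown convention {convention!r}")
        if c_raw == "":
            if convention == ORIGINAL:
                raise InvalidInputError(f"{path}:{lineno}: original-convention row {name!r} requires c")
            c = None
        else:
            c = _parse_float(c_raw, "c", lineno, path)
        e, s, a, b, v = (_parse_float(w, k, lineno, path) for w, k in zip(weights, COEFF_KEYS))
        try:
            out.append(SolventCoefficients(name, e, s, a, b, v, c=c, convention=convention))
        except InvalidInputError as exc:
            raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
    if not out:
        raise InvalidInputError(f"{path}: coefficient table has a header but no rows")
    _check_duplicates((r.name for r in out), path)
    return out


def write_coefficient_table(path, rows: Sequence[SolventCoefficients], header_comment: str | None = None) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["name", "c", "e", "s", "a", "b", "v", "convention"])
        for r in rows:
            writer.writerow([r.name, "" if r.c is None else repr(float(r.c)),
                             *(repr(float(getattr(r, k))) for k in COEFF_KEYS), r.convention])


def read_paired_table(path) -> pd.DataFrame:
    """Read a paired original/zero-intercept CSV into a DataFrame."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in PAIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: paired table missing columns {missing}")
    _check_duplicates(frame["name"].astype(str), path)
    return frame[PAIRED_COLUMNS]


def write_paired_table(path, paired: pd.DataFrame, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(paired[PAIRED_COLUMNS].to_csv(index=False))


def read_solute_table(path) -> list[SoluteDescriptors]:
    """Read a ``name,E,S,A,B,V`` CSV into typed solute rows."""
    rows_iter = _open_rows(path)
    try:
        _, header = next(rows_iter)
    except StopIteration:
        raise InvalidInputError(f"{path}: empty solute table") from None
    expected = ["name", "e", "s", "a", "b", "v"]
    if [h.lower() for h in header] != expected:
        raise SchemaError(f"{path}: expected header name,E,S,A,B,V, got {','.join(header)!r}")
    out: list[SoluteDescriptors] = []
    for lineno, row in rows_iter:
        if len(row) != 6:
            raise InvalidInputError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
        name = row[0]
        E, S, A, B, V = (_parse_float(x, k, lineno, path) for x, k in zip(row[1:], "ESABV"))
        try:
            out.append(SoluteDescriptors(E, S, A, B, V, name=name))
        except InvalidInputError as exc:
            raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
    if not out:
        raise InvalidInputError(f"{path}: solute table has a header but no rows")
    _check_duplicates((r.name for r in out), path)
    return out


def write_solute_table(path, rows: Sequence[SoluteDescriptors]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "E", "S", "A", "B", "V"])
        for r in rows:
            writer.writerow([r.name, *(repr(float(getattr(r, k))) for k in "ESABV")])


def read_smiles(path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file into (name, smiles) pairs; names kept verbatim."""
    out: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise InvalidInputError(f"{path}:{lineno}: expected 'SMILES name', got {line!r}")
            smiles, name = parts
            out.append((name.strip(), smiles))
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("solvcoef.data").joinpath(filename)


def load_table1() -> pd.DataFrame:
    """The packaged measured-coefficient table as a paired DataFrame.

    91 rows: 80 structural solvents, water, peanut oil, and 9 ethanol/water
    mixtures; original coefficients (c..v) alongside the published
    zero-intercept recalibration (e0..v0).
    """
    with resources.as_file(_data_path("table1_measured.csv")) as path:
        return read_paired_table(path)


def paired_to_original(paired: pd.DataFrame, provenance: str = "measured") -> list[SolventCoefficients]:
    """The original-convention side of a paired table as typed rows."""
    return [
        SolventCoefficients(r["name"], r["e"], r["s"], r["a"], r["b"], r["v"],
                            c=float(r["c"]), convention=ORIGINAL, provenance=provenance)
        for _, r in paired.iterrows()
    ]


def paired_to_zero_intercept(paired: pd.DataFrame, provenance: str = "measured") -> list[SolventCoefficients]:
    """The zero-intercept side of a paired table as typed rows."""
    return [
        SolventCoefficients(r["name"], r["e0"], r["s0"], r["a0"], r["b0"], r["v0"],
                            convention=ZERO_INTERCEPT, provenance=provenance)
        for _, r in paired.iterrows()
    ]


def table1_original() -> list[SolventCoefficients]:
    """Measured original-convention rows from the packaged table."""
    return paired_to_original(load_table1())


def table1_zero_intercept() -> list[SolventCoefficients]:
    """Published zero-intercept rows from the packaged table."""
    return paired_to_zero_intercept(load_table1())


def load_table3() -> list[SolventCoefficients]:
    """Packaged model-predicted zero-intercept rows for sustainable solvents (118 rows)."""
    with resources.as_file(_data_path("table3_predicted.csv")) as path:
        frame = pd.read_csv(path, comment="#")
    _check_duplicates(frame["name"].astype(str), path)
    return [
        SolventCoefficients(r["name"], r["e0"], r["s0"], r["a0"], r["b0"], r["v0"],
                            convention=ZERO_INTERCEPT, provenance="predicted")
        for _, r in frame.iterrows()
    ]


def load_solvent_smiles() -> list[tuple[str, str]]:
    """Curated (name, SMILES) pairs for the structural solvents of the measured table."""
    with resources.as_file(_data_path("solvent_smiles.smi")) as path:
        return read_smiles(path)


def find_solvent(rows: Sequence[SolventCoefficients], name: str) -> SolventCoefficients:
    """Case-insensitive lookup of a solvent by name."""
    key = name.strip().lower()
    for row in rows:
        if row.key == key:
            return row
    raise KeyError(f"solvent {name!r} not found")
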