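"""Synthetic cohort tables: generation, splitting and CSV round-trip.

A cohort is a plain :class:`pandas.DataFrame` with the 19 input columns in a
fixed order, optionally followed by the 4 blood-gas output columns once the
physiology simulator has labelled it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import (
    INPUT_PARAMETERS,
    ParameterDistribution,
    default_distributions,
)

__all__ = [
    "INPUT_COLUMNS", "OUTPUT_COLUMNS", "generate_cohort", "split_cohort",
    "write_cohort", "read_cohort", "is_labelled", "SchemaError",
]

INPUT_COLUMNS: tuple[str, ...] = INPUT_PARAMETERS
OUTPUT_COLUMNS: tuple[str, ...] = ("PaO2", "PaCO2", "HCO3", "pH")


class SchemaError(ValueError):
    """Cohort table does not match the fixed column contract."""


def generate_cohort(n: int, seed: int,
                    spec: Sequence[ParameterDistribution] | None = None
                    ) -> pd.DataFrame:
    """Generate ``n`` virtual-patient states.

    Each of the 19 input parameters is sampled independently from its marginal
    distribution (no inter-parameter correlation is imposed).  Bit-identical
    output for identical ``(n, seed, spec)``.

    Parameters
    ----------
    n
        Number of patient states (rows).
    seed
        Seed for the random stream; one child stream per parameter, so a
        parameter's draw does not depend on the others' sample counts.
    spec
        One :class:`ParameterDistribution` per input parameter; defaults to
        the shipped specification.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if spec is None:
        spec = default_distributions()
    by_name = {s.name: s for s in spec}
    missing = [c for c in INPUT_COLUMNS if c not in by_name]
    if missing:
        raise SchemaError(f"distribution spec missing parameter(s): {missing}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(INPUT_COLUMNS))
    data = {}
    for col, child in zip(INPUT_COLUMNS, children):
        rng = np.random.Generator(np.random.PCG64(child))
        data[col] = by_name[col].sample(n, rng)
    return pd.DataFrame(data, columns=list(INPUT_COLUMNS))


def split_cohort(table: pd.DataFrame,
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Shuffle and partition a cohort into train/validation/test tables.

    Partition sizes are ``floor(n * f)`` for validation and test with the
    remainder assigned to the training split (the largest partition).  The
    three outputs are disjoint and their union is the input.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(n)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    parts = tuple(table.iloc[idx].reset_index(drop=True)
                  for idx in (idx_train, idx_val, idx_test))
    return parts


def is_labelled(table: pd.DataFrame) -> bool:
    """True if the table carries the 4 simulator output columns."""
    return all(c in table.columns for c in OUTPUT_COLUMNS)


def _check_schema(columns: Sequence[str]) -> bool:
    """Validate column names/order; returns labelled flag."""
    cols = list(columns)
    if cols == list(INPUT_COLUMNS):
        return False
    if cols == list(INPUT_COLUMNS) + list(OUTPUT_COLUMNS):
        return True
    expected = set(INPUT_COLUMNS)
    missing = [c for c in INPUT_COLUMNS if c not in cols]
    extra = [c for c in cols if c not in expected and c not in OUTPUT_COLUMNS]
    raise SchemaError(
        f"bad cohort header: missing {missing or 'none'}, "
        f"unexpected {extra or 'none'}, order must be {list(INPUT_COLUMNS)}"
        f" optionally followed by {list(OUTPUT_COLUMNS)}")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, fixed header, full float precision)."""
    _check_schema(table.columns)
    if table.isna().any().any():
        raise SchemaError("cohort contains missing values")
    table.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the exact header contract.

    Returns the table; inspect :func:`is_labelled` for whether the output
    columns are present.
    """
    head = pd.read_csv(path, nrows=0)
    _check_schema(head.columns)
    table = pd.read_csv(path)
    bad = table.columns[[not np.issubdtype(dt, np.number)
                         for dt in table.dtypes]]
    if len(bad):
        col = bad[0]
        numeric = pd.to_numeric(table[col], errors="coerce")
        row = int(numeric.isna().idxmax())
        raise SchemaError(f"non-numeric cell in column {col!r} at row {row}")
    if table.isna().any().any():
        col = table.columns[table.isna().any()][0]
        row = int(table[col].isna().idxmax())
        raise SchemaError(f"missing value in column {col!r} at row {row}")
    return table
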