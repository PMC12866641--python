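"""Validated long-format input tables and variable-role declarations.

A dice plot consumes *long-format* (tidy) records: one record per observed
(row-category, column-category, dot-category) combination, optionally
annotated with a background group and — for domino plots — a contrast, a
binary split level and two continuous values (a signed effect size and a
nonnegative significance score).

The central contract is :func:`validate_table`: it binds columns to roles,
registers the ordered levels of every categorical role, enforces the
six-level ceiling on pip-bearing variables, deduplicates records and coerces
continuous columns.  Every downstream layout consumes only the resulting
:class:`LongTable`, never the raw file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DiceGlyphError,
    EmptyInput,
    MissingColumn,
    NonBinarySplit,
    NonNumericValue,
    TooManyLevels,
)

#: Hard ceiling on the number of levels a pip-bearing variable may take.
#: Six keeps the die-face metaphor intact and the patterns recognizable.
MAX_PIP_LEVELS = 6

#: Role keys used throughout the package (registry keys, JSON export).
CATEGORICAL_ROLES = ("row", "col", "dot", "bg", "contrast", "split")


@dataclass(frozen=True)
class VariableRoles:
    """Maps plot roles to column names of the input table.

    ``row_var``, ``col_var`` and ``dot_var`` are always required.  Domino
    mode additionally requires ``contrast_var`` (the pip-bearing variable),
    ``color_var`` (signed effect size, e.g. log2 fold change) and
    ``size_var`` (nonnegative significance score, e.g. -log10 adjusted p).
    ``split_var``, when given, must have exactly two observed levels.  In
    domino mode ``dot_var`` may be omitted, in which case it aliases
    ``contrast_var``.
    """

    row_var: str
    col_var: str
    dot_var: str | None = None
    bg_var: str | None = None
    contrast_var: str | None = None
    split_var: str | None = None
    color_var: str | None = None
    size_var: str | None = None

    def resolved(self, mode: str) -> "VariableRoles":
        """Return roles with mode-dependent defaults filled in."""
        if mode == "domino" and self.dot_var is None and self.contrast_var:
            return replace(self, dot_var=self.contrast_var)
        return self

    def pip_var(self, mode: str) -> str:
        """The column whose levels occupy pip slots in the given mode."""
        if mode == "domino":
            assert self.contrast_var is not None
            return self.contrast_var
        assert self.dot_var is not None
        return self.dot_var

    def categorical_columns(self) -> dict[str, str]:
        """Role-key -> column-name for every bound categorical role."""
        pairs = {
            "row": self.row_var,
            "col": self.col_var,
            "dot": self.dot_var,
            "bg": self.bg_var,
            "contrast": self.contrast_var,
            "split": self.split_var,
        }
        return {k: v for k, v in pairs.items() if v is not None}


@dataclass
class LongTable:
    """A validated record collection plus per-role level registries.

    ``records`` is a deduplicated DataFrame whose categorical role columns
    are strings; continuous columns (if any) are float64 with NaN marking
    "tested but no value".  ``level_registry`` maps each role key ("row",
    "col", "dot", ...) to its ordered level list: declared factor order
    first, then remaining observed levels in first-appearance order.
    """

    records: pd.DataFrame
    roles: VariableRoles
    mode: str
    level_registry: dict[str, list[str]]
    n_duplicates_dropped: int = 0

    def levels(self, role: str) -> list[str]:
        return self.level_registry[role]

    @property
    def dot_levels(self) -> list[str]:
        """Levels of the pip-bearing variable (contrasts in domino mode)."""
        return self.level_registry["contrast" if self.mode == "domino" else "dot"]


@dataclass
class PresenceMatrix:
    """Binary presence profiles for one axis, marginal over the other.

    ``profile[i, k]`` is 1 iff at least one record pairs ``labels[i]`` with
    the k-th pip-variable level.  Labels declared in a factor order but
    never observed on this axis keep all-zero profiles.
    """

    axis: str
    labels: list[str]
    dot_levels: list[str]
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.int8)
        assert self.profile.shape == (len(self.labels), len(self.dot_levels))
        assert set(np.unique(self.profile)) <= {0, 1}


def _as_dataframe(raw_records) -> pd.DataFrame:
    if isinstance(raw_records, pd.DataFrame):
        return raw_records.copy()
    return pd.DataFrame(list(raw_records))


def _registry_order(observed: Sequence[str], declared: Sequence[str] | None) -> list[str]:
    # Declared factor order wins; observed-but-undeclared levels append in
    # first-appearance order; declared-but-unobserved levels are kept (they
    # surface as all-zero presence profiles / empty axis positions).
    seen: list[str] = list(declared) if declared else []
    known = set(seen)
    for lev in observed:
        if lev not in known:
            seen.append(lev)
            known.add(lev)
    return seen


def validate_table(
    raw_records,
    roles: VariableRoles,
    mode: str = "dice",
    factor_orders: Mapping[str, Sequence[str]] | None = None,
) -> LongTable:
    """Validate raw records against declared roles and return a LongTable.

    Parameters
    ----------
    raw_records
        A DataFrame or an iterable of mappings (e.g. parsed CSV rows).
    roles
        Column bindings for each plot role.
    mode
        ``"dice"`` or ``"domino"``.
    factor_orders
        Optional mapping from role key ("row", "col", "dot", ...) to a
        declared level order for that role.

    Raises
    ------
    MissingColumn, EmptyInput, TooManyLevels, NonBinarySplit,
    NonNumericValue
        On the corresponding contract violation; duplicated keys are *not*
        an error — they collapse to the first occurrence with a warning.
    """
    if mode not in ("dice", "domino"):
        raise DiceGlyphError(f"unknown mode {mode!r}; expected 'dice' or 'domino'")
    roles = roles.resolved(mode)
    if mode == "domino":
        missing_roles = [
            name
            for name, val in (
                ("contrast_var", roles.contrast_var),
                ("color_var", roles.color_var),
                ("size_var", roles.size_var),
            )
            if val is None
        ]
        if missing_roles:
            raise MissingColumn(
                f"domino mode requires {', '.join(missing_roles)} to be declared"
            )
    if roles.dot_var is None:
        raise MissingColumn("dot_var must be declared")
    core = {roles.row_var, roles.col_var, roles.dot_var}
    if len(core) < 3 and not (mode == "domino" and roles.dot_var == roles.contrast_var):
        raise DiceGlyphError(
            "row_var, col_var and dot_var must name distinct columns"
        )

    df = _as_dataframe(raw_records)
    if df.empty:
        raise EmptyInput("input table holds zero records")

    cat_cols = roles.categorical_columns()
    value_cols = [c for c in (roles.color_var, roles.size_var) if c is not None]
    for col in list(dict.fromkeys(list(cat_cols.values()) + value_cols)):
        if col not in df.columns:
            raise MissingColumn(f"role column {col!r} absent from input table")

    # Normalize categorical columns to plain strings.
    for col in set(cat_cols.values()) - set(value_cols):
        bad = df[col].isna() | (df[col].astype(str).str.len() == 0)
        if bad.any():
            raise DiceGlyphError(
                f"{int(bad.sum())} record(s) have a missing value in required "
                f"role column {col!r}"
            )
        df[col] = df[col].astype(str)

    # Coerce continuous columns; values that were present but unparseable
    # are an error, genuinely-missing entries stay NaN ("tested, no value").
    for col in value_cols:
        orig_missing = df[col].isna() | (df[col].astype(str).str.strip() == "")
        coerced = pd.to_numeric(df[col], errors="coerce")
        broken = coerced.isna() & ~orig_missing
        if broken.any():
            sample = df.loc[broken, col].iloc[0]
            raise NonNumericValue(
                f"column {col!r} contains non-numeric value {sample!r} "
                f"({int(broken.sum())} offending record(s))"
            )
        df[col] = coerced.astype(float)

    if roles.size_var is not None:
        neg = df[roles.size_var] < 0
        if neg.any():
            raise NonNumericValue(
                f"size column {roles.size_var!r} contains negative value(s); "
                "significance scores must be nonnegative"
            )

    # Deduplicate on the full categorical key; first occurrence wins.
    key_cols = list(dict.fromkeys(cat_cols.values()))
    n_before = len(df)
    df = df.drop_duplicates(subset=key_cols, keep="first").reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(
            f"collapsed {n_dropped} duplicate record(s) on key {key_cols}",
            stacklevel=2,
        )

    factor_orders = dict(factor_orders or {})
    registry: dict[str, list[str]] = {}
    for role_key, col in cat_cols.items():
        observed = list(dict.fromkeys(df[col].tolist()))
        declared = factor_orders.get(role_key)
        registry[role_key] = _registry_order(
            observed, [str(x) for x in declared] if declared else None
        )

    pip_role = "contrast" if mode == "domino" else "dot"
    pip_levels = registry[pip_role]
    if len(pip_levels) > MAX_PIP_LEVELS:
        raise TooManyLevels(
            f"{pip_role} variable {cat_cols[pip_role]!r} has "
            f"{len(pip_levels)} levels (maximum {MAX_PIP_LEVELS}): "
            f"{pip_levels}"
        )
    if mode == "dice" and "contrast" in registry and len(registry["contrast"]) > MAX_PIP_LEVELS:
        raise TooManyLevels(
            f"contrast variable has {len(registry['contrast'])} levels "
            f"(maximum {MAX_PIP_LEVELS}): {registry['contrast']}"
        )
    if mode == "domino" and len(registry["dot"]) > MAX_PIP_LEVELS and roles.dot_var != roles.contrast_var:
        raise TooManyLevels(
            f"dot variable {cat_cols['dot']!r} has {len(registry['dot'])} "
            f"levels (maximum {MAX_PIP_LEVELS}): {registry['dot']}"
        )

    if roles.split_var is not None and mode == "domino":
        n_split = len(registry["split"])
        if n_split != 2:
            raise NonBinarySplit(
                f"split variable {roles.split_var!r} has {n_split} observed "
                f"level(s), expected exactly 2: {registry['split']}"
            )

    return LongTable(
        records=df,
        roles=roles,
        mode=mode,
        level_registry=registry,
        n_duplicates_dropped=n_dropped,
    )


def presence_matrix(table: LongTable, axis: str) -> PresenceMatrix:
    """Binary presence profiles for ``axis`` ("row" or "col").

    Marginalizes over the other axis: a label's profile bit k is set iff
    any record pairs the label with pip-variable level k.
    """
    if axis not in ("row", "col"):
        raise DiceGlyphError(f"axis must be 'row' or 'col', got {axis!r}")
    roles = table.roles
    axis_col = roles.row_var if axis == "row" else roles.col_var
    pip_col = roles.pip_var(table.mode)
    labels = table.levels(axis)
    dot_levels = table.dot_levels
    label_idx = {lab: i for i, lab in enumerate(labels)}
    dot_idx = {lev: k for k, lev in enumerate(dot_levels)}
    profile = np.zeros((len(labels), len(dot_levels)), dtype=np.int8)
    for lab, lev in zip(table.records[axis_col], table.records[pip_col]):
        profile[label_idx[lab], dot_idx[lev]] = 1
    return PresenceMatrix(axis=axis, labels=labels, dot_levels=dot_levels, profile=profile)


def read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format CSV/TSV file (RFC 4180, header row required).

    The delimiter is inferred from the extension (``.tsv``/``.tab`` ->
    tab, otherwise comma) unless ``sep`` is given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)


def melt_wide(
    df: pd.DataFrame,
    id_vars: Sequence[str],
    var_name: str = "variable",
    value_name: str = "value",
) -> pd.DataFrame:
    """Thin convenience wrapper turning a wide table into long format."""
    return df.melt(id_vars=list(id_vars), var_name=var_name, value_name=value_name)
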