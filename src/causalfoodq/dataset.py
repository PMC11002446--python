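"""Typed tabular datasets.

Food-quality tables mix measurement scales: continuous physicochemical
variables, binary sensory judgements (taste ok / off, odour present /
absent) and ordinal quality grades.  :class:`Dataset` couples a pandas
DataFrame with a per-column kind declaration so downstream stages can
decide how to treat each column, and round-trips through CSV plus a
sidecar JSON schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"
ORDINAL = "ordinal"


@dataclass(frozen=True)
class ColumnKind:
    """Measurement scale of one column.

    ``levels`` is required for ordinal columns and lists the ordered
    category labels (low to high).
    """

    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, BINARY, ORDINAL):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == ORDINAL:
            if not self.levels or len(self.levels) < 2:
                raise ValueError("ordinal kind requires >= 2 ordered levels")
        elif self.levels is not None:
            raise ValueError("levels only apply to ordinal columns")


def continuous() -> ColumnKind:
    return ColumnKind(CONTINUOUS)


def binary() -> ColumnKind:
    return ColumnKind(BINARY)


def ordinal(levels: Sequence[Any]) -> ColumnKind:
    return ColumnKind(ORDINAL, tuple(str(l) for l in levels))


@dataclass
class Dataset:
    """A rectangular table with declared column kinds.

    Invariants: every column has a kind, ordinal values come from the
    declared levels, and there are no missing values.
    """

    df: pd.DataFrame
    kinds: dict[str, ColumnKind]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.df.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"columns without a declared kind: {sorted(missing)}")
        extra = set(self.kinds) - set(self.df.columns)
        if extra:
            raise ValueError(f"kinds declared for absent columns: {sorted(extra)}")
        if self.df.isna().any().any():
            bad = list(self.df.columns[self.df.isna().any()])
            raise ValueError(f"missing values in columns {bad}")
        for col, kind in self.kinds.items():
            if kind.kind == ORDINAL:
                observed = set(self.df[col].astype(str))
                declared = set(kind.levels)
                if not observed <= declared:
                    raise ValueError(
                        f"ordinal column {col!r} has values outside declared "
                        f"levels: {sorted(observed - declared)}"
                    )
            elif kind.kind == BINARY:
                observed = set(pd.unique(self.df[col]))
                if not observed <= {0, 1, True, False}:
                    raise ValueError(f"binary column {col!r} has non-0/1 values")

    # -- basic queries ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.df.columns)

    def kind_of(self, column: str) -> ColumnKind:
        return self.kinds[column]

    def continuous_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.columns if self.kinds[c].kind == CONTINUOUS)

    # -- numeric view ----------------------------------------------------

    def to_numeric(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        """Float view: binary as 0/1, ordinal as level codes 0..K-1.

        The numeric coding of ordinal grades follows the convention of
        treating quality scores as equally spaced numbers, which is how
        effects in "grade per unit" are reported.
        """
        cols = list(columns) if columns is not None else list(self.columns)
        out = {}
        for c in cols:
            kind = self.kinds[c]
            if kind.kind == ORDINAL:
                codes = pd.Categorical(
                    self.df[c].astype(str), categories=kind.levels, ordered=True
                ).codes
                out[c] = np.asarray(codes, dtype=float)
            else:
                out[c] = self.df[c].to_numpy(dtype=float)
        return pd.DataFrame(out, index=self.df.index)

    def subset(self, columns: Sequence[str]) -> "Dataset":
        return Dataset(
            self.df[list(columns)].copy(),
            {c: self.kinds[c] for c in columns},
            dict(self.provenance),
        )

    # -- I/O -------------------------------------------------------------

    def schema(self) -> dict[str, Any]:
        cols = {}
        for c, kind in self.kinds.items():
            entry: dict[str, Any] = {"kind": kind.kind}
            if kind.levels is not None:
                entry["levels"] = list(kind.levels)
            cols[c] = entry
        return {"columns": cols, "provenance": self.provenance}

    def write_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        if schema_path is None:
            schema_path = path.with_suffix(path.suffix + ".schema.json")
        Path(schema_path).write_text(json.dumps(self.schema(), indent=2) + "\n")

    @classmethod
    def read_csv(
        cls, path: str | Path, schema_path: str | Path | None = None
    ) -> "Dataset":
        path = Path(path)
        if schema_path is None:
            candidate = path.with_suffix(path.suffix + ".schema.json")
            schema_path = candidate if candidate.exists() else None
        df = pd.read_csv(path)
        if schema_path is not None:
            schema = json.loads(Path(schema_path).read_text())
            kinds = {}
            for c, entry in schema["columns"].items():
                kinds[c] = ColumnKind(
                    entry["kind"],
                    tuple(str(l) for l in entry["levels"]) if "levels" in entry else None,
                )
            for c, kind in kinds.items():
                if kind.kind == ORDINAL:
                    df[c] = df[c].astype(str)
            return cls(df, kinds, schema.get("provenance", {}))
        # no schema: infer numeric columns as continuous, strings as ordinal
        kinds = {}
        for c in df.columns:
            if pd.api.types.is_numeric_dtype(df[c]):
                vals = set(pd.unique(df[c].dropna()))
                kinds[c] = binary() if vals <= {0, 1} else continuous()
            else:
                df[c] = df[c].astype(str)
                kinds[c] = ordinal(sorted(df[c].unique()))
        return cls(df, kinds)
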