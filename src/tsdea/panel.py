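"""DMU panel container, delimited-text I/O, and descriptive summaries.

A *decision-making unit* (DMU) is one evaluated entity — here a
county-level administrative division — carrying a vector of inputs
(e.g. fiscal expenditure per capita, instructors per 1000 residents),
a vector of outputs (e.g. regular-exercise participation rate), and
optionally a vector of environmental covariates outside managerial
control (GDP per capita, urbanization rate, ...).

The on-disk schema is a UTF-8 CSV with a header row.  Column roles are
detected from prefixes — ``i_`` inputs, ``o_`` outputs, ``z_``
environment — or given explicitly through a :class:`PanelSchema`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DMUPanel",
    "PanelSchema",
    "PanelValidationError",
    "SchemaError",
    "read_panel",
    "write_panel",
    "summarize_descriptives",
]


class PanelValidationError(ValueError):
    """Raised when panel data violate the DMU-panel invariants."""


class SchemaError(ValueError):
    """Raised when a file does not carry the columns the schema names."""


@dataclass(frozen=True)
class PanelSchema:
    """Explicit column mapping for :func:`read_panel`.

    Parameters
    ----------
    id, group : str
        Column names holding the DMU identifier and the group label.
    inputs, outputs, env : sequence of str
        Column names holding the K inputs, M outputs and P environmental
        covariates, in the order they should appear in the matrices.
    """

    id: str = "dmu_id"
    group: str = "group"
    inputs: Sequence[str] = ()
    outputs: Sequence[str] = ()
    env: Sequence[str] = ()


@dataclass
class DMUPanel:
    """Rectangular DMU dataset: ids, group labels, X (inputs), Y (outputs), Z (environment).

    Invariants (enforced by :meth:`validate`): unique ids; X and Y finite
    and nonnegative with every DMU having at least one strictly positive
    input and output; matching row counts throughout.
    """

    dmu_id: np.ndarray
    group: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray | None = None
    input_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)
    env_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dmu_id = np.asarray(self.dmu_id, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not self.input_names:
            self.input_names = [f"x{k + 1}" for k in range(self.X.shape[1])]
        if not self.output_names:
            self.output_names = [f"y{m + 1}" for m in range(self.Y.shape[1])]
        if self.Z is not None and not self.env_names:
            self.env_names = [f"z{p + 1}" for p in range(self.Z.shape[1])]
        self.validate()

    # -- dimensions ---------------------------------------------------
    @property
    def n_dmu(self) -> int:
        return len(self.dmu_id)

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[1]

    @property
    def n_env(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    def validate(self) -> None:
        n = self.n_dmu
        if n < 1:
            raise PanelValidationError("panel needs at least one DMU")
        if len(self.group) != n or self.X.shape[0] != n or self.Y.shape[0] != n:
            raise PanelValidationError("row counts of id/group/X/Y differ")
        if self.Z is not None and self.Z.shape[0] != n:
            raise PanelValidationError("Z row count differs from dmu_id")
        ids, counts = np.unique(self.dmu_id.astype(str), return_counts=True)
        if (counts > 1).any():
            dupes = ids[counts > 1].tolist()
            raise PanelValidationError(f"duplicate dmu_id values: {dupes}")
        for name, M in (("input", self.X), ("output", self.Y)):
            if not np.isfinite(M).all():
                bad = self.dmu_id[~np.isfinite(M).all(axis=1)].tolist()
                raise PanelValidationError(
                    f"non-finite {name} values for DMUs {bad}"
                )
            if (M < 0).any():
                bad = self.dmu_id[(M < 0).any(axis=1)].tolist()
                raise PanelValidationError(
                    f"negative {name} values for DMUs {bad}"
                )
            if (M.max(axis=1) <= 0).any():
                bad = self.dmu_id[M.max(axis=1) <= 0].tolist()
                raise PanelValidationError(
                    f"DMUs with no strictly positive {name}: {bad}"
                )
        if self.Z is not None and not np.isfinite(self.Z).all():
            raise PanelValidationError("non-finite environmental values")

    # -- conversion ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical prefixed CSV layout."""
        data: dict[str, np.ndarray] = {
            "dmu_id": self.dmu_id,
            "group": self.group,
        }
        for j, name in enumerate(self.input_names):
            data[f"i_{name}"] = self.X[:, j]
        for j, name in enumerate(self.output_names):
            data[f"o_{name}"] = self.Y[:, j]
        for j, name in enumerate(self.env_names):
            data[f"z_{name}"] = self.Z[:, j]
        return pd.DataFrame(data)

    def with_inputs(self, X_new: np.ndarray) -> "DMUPanel":
        """Copy of the panel with a replaced input matrix (same outputs/Z)."""
        return DMUPanel(
            dmu_id=self.dmu_id.copy(),
            group=self.group.copy(),
            X=np.asarray(X_new, dtype=float).copy(),
            Y=self.Y.copy(),
            Z=None if self.Z is None else self.Z.copy(),
            input_names=list(self.input_names),
            output_names=list(self.output_names),
            env_names=list(self.env_names),
        )


def _schema_from_prefixes(columns: Sequence[str]) -> PanelSchema:
    return PanelSchema(
        inputs=[c for c in columns if c.startswith("i_")],
        outputs=[c for c in columns if c.startswith("o_")],
        env=[c for c in columns if c.startswith("z_")],
    )


def _strip_prefix(name: str, prefix: str) -> str:
    return name[len(prefix):] if name.startswith(prefix) else name


def read_panel(path: str | Path, schema: PanelSchema | None = None) -> DMUPanel:
    """Read a DMU panel from a delimited text file.

    With ``schema=None`` the column roles come from the ``i_``/``o_``/``z_``
    prefixes.  Rows with missing cells in any required column are rejected.
    """
    df = pd.read_csv(path)
    if schema is None:
        schema = _schema_from_prefixes(df.columns)
    required = [schema.id, schema.group, *schema.inputs, *schema.outputs, *schema.env]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    if not schema.inputs or not schema.outputs:
        raise SchemaError(
            "schema must name at least one input and one output column"
        )
    incomplete = df[required].isna().any(axis=1)
    if incomplete.any():
        bad = df.loc[incomplete, schema.id].tolist()
        raise PanelValidationError(f"missing required cells for rows {bad}")
    Z = df[list(schema.env)].to_numpy(float) if schema.env else None
    return DMUPanel(
        dmu_id=df[schema.id].to_numpy(object),
        group=df[schema.group].to_numpy(object),
        X=df[list(schema.inputs)].to_numpy(float),
        Y=df[list(schema.outputs)].to_numpy(float),
        Z=Z,
        input_names=[_strip_prefix(c, "i_") for c in schema.inputs],
        output_names=[_strip_prefix(c, "o_") for c in schema.outputs],
        env_names=[_strip_prefix(c, "z_") for c in schema.env],
    )


def write_panel(panel: DMUPanel, path: str | Path) -> None:
    """Write the panel as a prefixed CSV re-readable by :func:`read_panel`."""
    panel.to_frame().to_csv(path, index=False)


def summarize_descriptives(table: pd.DataFrame | DMUPanel) -> pd.DataFrame:
    """Per-variable mean, sample SD, min, max and coefficient of variation.

    CV = SD/mean is dimensionless; a zero-mean column has no defined CV and
    raises.  SD uses the n−1 denominator.
    """
    if isinstance(table, DMUPanel):
        table = table.to_frame()
    num = table.select_dtypes("number")
    if num.shape[1] == 0:
        raise ValueError("no numeric columns to summarize")
    means = num.mean()
    if (means == 0).any():
        bad = means.index[means == 0].tolist()
        raise ValueError(f"CV undefined for zero-mean columns: {bad}")
    sds = num.std(ddof=1)
    out = pd.DataFrame(
        {
            "mean": means,
            "sd": sds,
            "min": num.min(),
            "max": num.max(),
            "cv": sds / means,
        }
    )
    out.index.name = "variable"
    return out
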