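"""Panel data model and file I/O.

A :class:`PanelDataset` holds a long-format panel of decision-making units
(DMUs, e.g. provinces) observed over years on named variables, each tagged
with a *role* (``input`` / ``output``) and a *resource_class* (``human`` /
``non_human`` / ``other``).  A :class:`SpatialWeights` holds a contiguity
matrix aligned to the same unit ordering.  Both round-trip losslessly
through plain-text formats (tidy CSV for panels; GAL or dense CSV for
weights).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROLES = ("input", "output")
RESOURCE_CLASSES = ("human", "non_human", "other")


class PanelValidationError(ValueError):
    """A panel record violates a dataset invariant."""


class SchemaError(ValueError):
    """A variable is missing from, or inconsistent with, the schema."""


class AlignmentError(ValueError):
    """Two containers that must share unit ordering do not."""


@dataclass(frozen=True)
class VariableInfo:
    """Role and resource-class tags for one panel variable."""

    role: str
    resource_class: str = "other"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.resource_class not in RESOURCE_CLASSES:
            raise SchemaError(
                f"resource_class must be one of {RESOURCE_CLASSES}, "
                f"got {self.resource_class!r}"
            )


@dataclass
class PanelDataset:
    """Long-format unit x year x variable panel with tagged variables.

    Parameters
    ----------
    data
        Tidy frame with columns ``unit``, ``year``, ``variable``, ``value``.
    schema
        Mapping from variable name to :class:`VariableInfo`.
    """

    data: pd.DataFrame
    schema: dict[str, VariableInfo]
    unit_ids: list[str] = field(init=False)
    years: list[int] = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"unit", "year", "variable", "value"}
        missing = required - set(df.columns)
        if missing:
            raise PanelValidationError(f"panel frame missing columns {sorted(missing)}")
        df = df.copy()
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)

        unmapped = set(df["variable"]) - set(self.schema)
        if unmapped:
            raise SchemaError(f"variables absent from schema: {sorted(unmapped)}")

        bad = df[~np.isfinite(df["value"]) | (df["value"] < 0)]
        if not bad.empty:
            r = bad.iloc[0]
            raise PanelValidationError(
                f"non-finite or negative value {r['value']} at "
                f"(unit={r['unit']!r}, year={r['year']}, variable={r['variable']!r})"
            )

        dup = df.duplicated(subset=["unit", "year", "variable"])
        if dup.any():
            r = df[dup].iloc[0]
            raise PanelValidationError(
                f"duplicate record for (unit={r['unit']!r}, year={r['year']}, "
                f"variable={r['variable']!r})"
            )

        df = df.sort_values(["unit", "year", "variable"], kind="stable").reset_index(drop=True)
        self.data = df
        self.unit_ids = sorted(df["unit"].unique().tolist())
        self.years = sorted(int(y) for y in df["year"].unique())

        n_expected = len(self.unit_ids) * len(self.years) * df["variable"].nunique()
        if len(df) < n_expected:
            cells = df.groupby(["unit", "year"])["variable"].nunique()
            short = cells[cells < df["variable"].nunique()]
            log.warning(
                "panel has %d missing (unit, year, variable) cells; incomplete pairs: %s",
                n_expected - len(df), list(short.index[:5]),
            )

    @property
    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique().tolist())

    def variables_by(self, role: str, resource_class: str | None = None) -> list[str]:
        """Variable names with the given role (and optionally resource class)."""
        out = []
        for name in self.variables:
            info = self.schema[name]
            if info.role != role:
                continue
            if resource_class is not None and info.resource_class != resource_class:
                continue
            out.append(name)
        return out

    def matrix(self, variables: list[str], year: int) -> np.ndarray:
        """Return a (len(variables), n_units) matrix for one year.

        Raises on missing cells: DEA linear programs need complete rows.
        """
        wide = self.data[self.data["year"] == year].pivot(
            index="variable", columns="unit", values="value"
        )
        try:
            mat = wide.loc[variables, self.unit_ids]
        except KeyError as exc:
            raise PanelValidationError(f"year {year}: missing variable or unit: {exc}") from exc
        if mat.isna().any().any():
            missing = [
                (v, u) for v in variables for u in self.unit_ids if pd.isna(wide.loc[v, u])
            ]
            raise PanelValidationError(f"year {year}: missing cells {missing[:5]}")
        return mat.to_numpy(dtype=float)

    def dea_matrices(
        self, year: int, input_class: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(inputs, outputs) matrices for one year, optionally restricting the
        input set to one resource class (outputs are always all outputs)."""
        x_vars = self.variables_by("input", input_class)
        y_vars = self.variables_by("output")
        if not x_vars or not y_vars:
            raise PanelValidationError(
                f"need at least one input and one output variable "
                f"(input_class={input_class!r}); "
                f"have inputs={x_vars}, outputs={y_vars}"
            )
        return self.matrix(x_vars, year), self.matrix(y_vars, year)

    def score_frame(self, scores: dict[int, np.ndarray]) -> pd.DataFrame:
        """Assemble per-year unit score vectors into a units x years frame."""
        return pd.DataFrame(scores, index=self.unit_ids)


@dataclass
class SpatialWeights:
    """Spatial contiguity weights aligned with a panel's unit ordering."""

    unit_ids: list[str]
    matrix: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        n = len(self.unit_ids)
        if w.shape != (n, n):
            raise AlignmentError(f"weights matrix shape {w.shape} != ({n}, {n})")
        if (w < 0).any():
            raise PanelValidationError("weights must be non-negative")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise PanelValidationError("weights diagonal must be zero")
        if self.standardized:
            sums = w.sum(axis=1)
            nz = sums > 0
            if nz.any() and np.abs(sums[nz] - 1.0).max() > 1e-12:
                raise PanelValidationError("standardized weights rows must sum to 1")
        self.matrix = w

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def row_standardize(self) -> "SpatialWeights":
        """Return a row-standardized copy; zero-neighbor rows stay zero."""
        w = self.matrix.copy()
        sums = w.sum(axis=1)
        islands = np.where(sums == 0)[0]
        if islands.size:
            warnings.warn(
                f"units with no neighbors left as zero rows: "
                f"{[self.unit_ids[i] for i in islands]}",
                stacklevel=2,
            )
        nz = sums > 0
        w[nz] = w[nz] / sums[nz, None]
        return SpatialWeights(list(self.unit_ids), w, standardized=True)

    def align_to(self, unit_ids: list[str]) -> "SpatialWeights":
        """Reorder to match a panel's unit ordering; error on mismatch."""
        if set(unit_ids) != set(self.unit_ids):
            raise AlignmentError(
                "weights and panel unit labels differ: "
                f"{sorted(set(unit_ids) ^ set(self.unit_ids))[:5]}"
            )
        idx = [self.unit_ids.index(u) for u in unit_ids]
        return SpatialWeights(
            list(unit_ids), self.matrix[np.ix_(idx, idx)], self.standardized
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_schema(path) -> dict[str, VariableInfo]:
    """Read a ``variable,role,resource_class`` CSV into a schema mapping."""
    df = pd.read_csv(path)
    return {
        str(r["variable"]): VariableInfo(str(r["role"]), str(r["resource_class"]))
        for _, r in df.iterrows()
    }


def read_panel(path, schema: dict[str, VariableInfo]) -> PanelDataset:
    """Read a tidy ``unit,year,variable,value`` CSV into a validated panel."""
    df = pd.read_csv(path)
    return PanelDataset(df, schema)


def write_panel(panel: PanelDataset, path) -> None:
    panel.data.to_csv(path, index=False)


def write_schema(schema: dict[str, VariableInfo], path) -> None:
    rows = [
        {"variable": k, "role": v.role, "resource_class": v.resource_class}
        for k, v in sorted(schema.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weights(path, format: str = "gal", standardize: bool = False) -> SpatialWeights:
    """Read spatial weights from a GAL file or a dense labelled CSV.

    GAL dialect: a header line whose last token is the unit count, then per
    unit a ``label n_neighbors`` line followed by a whitespace-separated
    neighbor-label line.  Contiguity must be symmetric.
    """
    if format == "gal":
        w = _read_gal(path)
    elif format == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise AlignmentError("dense weights CSV must have matching row/column labels")
        w = SpatialWeights([str(u) for u in df.index], df.to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown weights format {format!r}")
    return w.row_standardize() if standardize else w


def _read_gal(path) -> SpatialWeights:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    n = int(lines[0].split()[-1])
    units: list[str] = []
    neigh: dict[str, list[str]] = {}
    i = 1
    while i < len(lines):
        label, k_str = lines[i].rsplit(None, 1)
        k = int(k_str)
        units.append(label)
        if k == 0:
            neigh[label] = []
            i += 1
            continue
        nbr_line = lines[i + 1]
        # tab-separated neighbor lists support labels containing spaces
        nbrs = nbr_line.split("\t") if "\t" in nbr_line else nbr_line.split()
        if len(nbrs) != k:
            raise PanelValidationError(
                f"GAL unit {label!r}: declared {k} neighbors, parsed {len(nbrs)}"
            )
        neigh[label] = nbrs
        i += 2
    if len(units) != n:
        raise PanelValidationError(f"GAL header declares {n} units, found {len(units)}")
    index = {u: i for i, u in enumerate(units)}
    w = np.zeros((n, n))
    for u, nbrs in neigh.items():
        for v in nbrs:
            if v not in index:
                raise PanelValidationError(f"GAL neighbor {v!r} of {u!r} is not a unit")
            w[index[u], index[v]] = 1.0
    if not np.array_equal(w, w.T):
        a, b = np.argwhere(w != w.T)[0]
        raise PanelValidationError(
            f"asymmetric contiguity: {units[a]!r} lists {units[b]!r} but not conversely"
        )
    return SpatialWeights(units, w)


def write_weights(w: SpatialWeights, path, format: str = "gal") -> None:
    if format == "dense_csv":
        pd.DataFrame(w.matrix, index=w.unit_ids, columns=w.unit_ids).to_csv(path)
        return
    if w.standardized:
        raise ValueError("GAL stores binary contiguity; write the unstandardized matrix")
    with open(path, "w") as fh:
        fh.write(f"0 {w.n}\n")
        for i, u in enumerate(w.unit_ids):
            nbrs = [w.unit_ids[j] for j in np.nonzero(w.matrix[i])[0]]
            fh.write(f"{u} {len(nbrs)}\n")
            fh.write("\t".join(nbrs) + "\n")
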