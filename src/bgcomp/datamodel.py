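"""Core data structures for partially observed tables of source and explanatory variables.

A study table holds three kinds of columns:

* **source** variables — the measured quantities that combine deterministically
  into the outcome (e.g. height and weight for logBMI; sex, gestational age and
  head circumference for microcephaly);
* **explanatory** variables — covariates that define populations of interest but
  are not consumed by the derivation (e.g. a group indicator, age);
* **derived** — at most one column holding the outcome ``Y = f(sources)``.

Missing entries are stored as NaN; the boolean missingness mask is derived from
the values, so ``mask True ⇔ value absent`` holds by construction.
"""

from __future__ import annotations

import io
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "MissingTable",
    "DerivedOutcomeSpec",
    "PopulationSpec",
    "EstimandSpec",
    "PosteriorDraws",
    "EstimandDraws",
    "TableValidationError",
    "DerivedConsistencyError",
    "load_table",
    "write_table",
    "complete_derived",
    "complete_cases",
]

Role = Literal["source", "explanatory", "derived"]

#: relative tolerance for checking observed derived values against f(sources);
#: f may involve logs of measured values, so exact equality is too strict.
DERIVED_RTOL = 1e-8


class TableValidationError(ValueError):
    """A table violates a structural invariant (roles, all-missing row, ...)."""


class DerivedConsistencyError(TableValidationError):
    """An observed derived value contradicts f applied to its observed sources."""


@dataclass(frozen=True)
class DerivedOutcomeSpec:
    """The deterministic derivation ``Y = f(W_source)``.

    ``func`` must be a pure function accepting one positional array (or scalar)
    per source variable, in ``source_names`` order, vectorized over rows.
    """

    func: Callable[..., np.ndarray]
    source_names: tuple[str, ...]
    outcome_kind: Literal["binary", "continuous"] = "continuous"
    name: str = "Y"

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_names", tuple(self.source_names))
        if len(self.source_names) == 0:
            raise ValueError("DerivedOutcomeSpec needs at least one source variable")

    @property
    def p(self) -> int:
        return len(self.source_names)

    def apply(self, sources) -> np.ndarray:
        """Evaluate f row-wise on a DataFrame / mapping / 2-d array of sources."""
        if isinstance(sources, pd.DataFrame):
            cols = [sources[n].to_numpy(dtype=float) for n in self.source_names]
        elif isinstance(sources, Mapping):
            cols = [np.asarray(sources[n], dtype=float) for n in self.source_names]
        else:
            arr = np.asarray(sources, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            cols = [arr[:, j] for j in range(len(self.source_names))]
        out = np.asarray(self.func(*cols), dtype=float)
        if self.outcome_kind == "binary":
            bad = ~np.isin(out[np.isfinite(out)], (0.0, 1.0))
            if bad.any():
                raise ValueError("binary derivation returned values outside {0, 1}")
        return out


@dataclass
class MissingTable:
    """An n × (p+q[+1]) table with NaN-coded missingness and variable roles."""

    data: pd.DataFrame
    roles: dict[str, Role]
    binary: frozenset[str] = frozenset()
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.binary = frozenset(self.binary)
        unknown = set(self.roles) - set(self.data.columns)
        if unknown:
            raise TableValidationError(f"roles refer to unknown columns: {sorted(unknown)}")
        uncovered = set(self.data.columns) - set(self.roles)
        if uncovered:
            raise TableValidationError(f"columns without a role: {sorted(uncovered)}")
        derived = [c for c, r in self.roles.items() if r == "derived"]
        if len(derived) > 1:
            raise TableValidationError(f"at most one derived column allowed, got {derived}")
        # the paper's framework permits source/explanatory overlap but we require
        # the partition to be disjoint (roles are per-column so this is automatic;
        # guard against aliased names in future role containers is not needed).
        self.data = self.data.astype(float)
        if self.n > 0:
            all_missing = self.mask.all(axis=1)
            if all_missing.any():
                rows = list(self.data.index[all_missing])
                raise TableValidationError(f"rows with every entry missing: {rows}")
        for c in self.binary:
            obs = self.data[c].dropna()
            if not obs.isin((0.0, 1.0)).all():
                raise TableValidationError(f"binary column {c!r} has values outside {{0,1}}")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator; True where the value is absent."""
        return self.data.isna()

    def names(self, role: Role) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == role]

    @property
    def source_names(self) -> list[str]:
        return self.names("source")

    @property
    def explanatory_names(self) -> list[str]:
        return self.names("explanatory")

    @property
    def derived_name(self) -> str | None:
        d = self.names("derived")
        return d[0] if d else None

    def copy(self) -> "MissingTable":
        return replace(self, data=self.data.copy(), warnings=list(self.warnings))

    # -- invariant checks ------------------------------------------------
    def check_derived(self, spec: DerivedOutcomeSpec, rtol: float = DERIVED_RTOL) -> None:
        """Verify observed derived entries equal f(sources) wherever all sources are observed."""
        y = self.derived_name
        if y is None:
            return
        src = self.data[list(spec.source_names)]
        complete_src = ~src.isna().any(axis=1)
        have_y = ~self.data[y].isna()
        idx = complete_src & have_y
        if not idx.any():
            return
        expect = spec.apply(src.loc[idx])
        got = self.data.loc[idx, y].to_numpy(dtype=float)
        scale = np.maximum(np.abs(expect), 1.0)
        bad = np.abs(got - expect) > rtol * scale + 1e-12
        if bad.any():
            rows = list(self.data.index[idx][bad])
            raise DerivedConsistencyError(
                f"derived column {y!r} inconsistent with f(sources) at rows {rows[:5]}"
            )


# ---------------------------------------------------------------------------
# populations, estimands, posterior containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One of the D target populations over which E(Y | W_expl) is standardized.

    ``conditioning`` pins explanatory variables to fixed values (e.g. ``{"X": 1}``);
    unconditioned explanatory covariates are drawn from ``covariate_law`` —
    ``"empirical"`` resamples the observed covariate rows uniformly, or a callable
    ``law(rng, size) -> DataFrame/dict`` provides a parametric law.  ``gamma_spec``
    optionally declares unknown population parameters γ_d, each computed from a
    posterior parameter record (and imputation record) per draw.
    """

    index: int = 1
    conditioning: Mapping[str, float] = field(default_factory=dict)
    covariate_law: object = "empirical"
    gamma_spec: Mapping[str, Callable] | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("population index d must be >= 1")
        object.__setattr__(self, "conditioning", dict(self.conditioning))


@dataclass(frozen=True)
class EstimandSpec:
    """θ = g(E*_1, …, E*_D): a deterministic combination of population expectations."""

    combine: Callable[[np.ndarray], float]
    name: str = "theta"

    @staticmethod
    def identity() -> "EstimandSpec":
        """D = 1 mean outcome, θ = E*(Y)."""
        return EstimandSpec(lambda e: float(e[0]), name="mean")

    @staticmethod
    def difference() -> "EstimandSpec":
        """D = 2 contrast θ = E*_2 − E*_1 (population 2 minus population 1)."""
        return EstimandSpec(lambda e: float(e[1] - e[0]), name="difference")


@dataclass
class PosteriorDraws:
    """M joint posterior draws of the source-model parameters plus imputations.

    ``params`` is an M-row frame of named parameters (φ_source).  ``imputed_expl``
    and ``imputed_source`` are M-row frames with one column per missing cell,
    named ``"<var>[<row>]"``; they are empty when the data have no missingness in
    the corresponding roles.
    """

    params: pd.DataFrame
    model: str
    imputed_expl: pd.DataFrame = field(default_factory=pd.DataFrame)
    imputed_source: pd.DataFrame = field(default_factory=pd.DataFrame)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.params) == 0:
            raise ValueError("PosteriorDraws requires M > 0")
        for f in (self.imputed_expl, self.imputed_source):
            if len(f) not in (0, len(self.params)):
                raise ValueError("imputation records must have M rows")

    @property
    def M(self) -> int:
        return len(self.params)

    def record(self, m: int) -> dict[str, float]:
        """The m-th joint record of parameters (a plain name → value mapping)."""
        return {k: float(v) for k, v in self.params.iloc[m].items()}

    def summary(self) -> pd.DataFrame:
        q = self.params.quantile([0.025, 0.5, 0.975]).T
        q.columns = ["q2.5", "median", "q97.5"]
        for col in ("rhat", "ess"):
            vals = self.diagnostics.get(col, {})
            q[col] = [vals.get(name, np.nan) for name in q.index]
        return q


@dataclass
class EstimandDraws:
    """M posterior samples of the estimand θ with inner Monte Carlo diagnostics."""

    theta: np.ndarray
    S: int
    mc_se: float = np.nan

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.S < 1:
            raise ValueError("inner Monte Carlo size S must be >= 1")

    @property
    def M(self) -> int:
        return len(self.theta)

    def summary(self) -> dict[str, float]:
        lo, med, hi = np.percentile(self.theta, [2.5, 50.0, 97.5])
        return {
            "median": float(med),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "mean": float(np.mean(self.theta)),
            "M": self.M,
            "S": self.S,
            "mc_se": float(self.mc_se),
        }


# ---------------------------------------------------------------------------
# IO and table operations
# ---------------------------------------------------------------------------


def load_table(
    path,
    roles: Mapping[str, Role],
    missing_token: str = "NA",
    binary: Sequence[str] = (),
) -> MissingTable:
    """Read a delimited text file (comma-separated, header row) into a MissingTable.

    ``missing_token`` marks absent entries.  Every column must appear in
    ``roles``; an all-missing row is a validation error naming the row.
    """
    if isinstance(path, (str, Path)):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    df = pd.read_csv(
        path, na_values=[missing_token], keep_default_na=False, skipinitialspace=True
    )
    return MissingTable(data=df, roles=dict(roles), binary=frozenset(binary))


def write_table(table: MissingTable, path, missing_token: str = "NA") -> None:
    """Write a MissingTable as comma-separated text, ``missing_token`` for NaN.

    Floats are written with ``repr`` precision so that load_table round-trips
    values and mask bit-exactly.
    """
    buf = io.StringIO()
    df = table.data
    buf.write(",".join(df.columns) + "\n")
    for _, row in df.iterrows():
        cells = [missing_token if pd.isna(v) else repr(float(v)) for v in row]
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


def complete_derived(
    table: MissingTable, spec: DerivedOutcomeSpec, rtol: float = DERIVED_RTOL
) -> MissingTable:
    """Fill the derived column by f wherever all sources are observed.

    Observed derived entries are validated against f (source-variable-level
    semantics: the derivation is deterministic, so an observed value that
    contradicts it is an error, not data).  A missing derived column is created.
    Observed source entries are never changed.
    """
    out = table.copy()
    y = out.derived_name
    if y is None:
        y = spec.name
        out.data[y] = np.nan
        out.roles[y] = "derived"
        if spec.outcome_kind == "binary":
            out.binary = out.binary | {y}
    out.check_derived(spec, rtol=rtol)
    src = out.data[list(spec.source_names)]
    fillable = ~src.isna().any(axis=1)
    if fillable.any():
        out.data.loc[fillable, y] = spec.apply(src.loc[fillable])
    return out


def complete_cases(table: MissingTable) -> MissingTable:
    """The subtable of rows with no missing entry in any role.

    complete_cases is idempotent.  An empty result is returned (with a warning
    recorded on the table), never raised.
    """
    keep = ~table.mask.any(axis=1)
    out = replace(table, data=table.data.loc[keep].copy(), warnings=list(table.warnings))
    if out.n == 0:
        msg = "complete-case analysis removed every row"
        out.warnings.append(msg)
        _warnings.warn(msg, UserWarning, stacklevel=2)
    return out
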