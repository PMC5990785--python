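"""Call table data model, CSV input/output, variable transforms and collinearity screening.

A call table has one row per measured hoo call: identity and recording
covariates (caller, sex, age, behavioural context, observer, recording
device, bout membership) plus twelve acoustic variables describing the
fundamental-frequency (F0) contour and spectral peak of the call.

The screening step mirrors standard practice for discriminant analyses of
acoustic data: candidate predictors that are pairwise correlated beyond a
threshold (|r| > 0.7 by default) are thinned, and the retained set must have
variance inflation factors below 2.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "SEXES",
    "OBSERVERS",
    "DEVICES",
    "AGE_CLASSES",
    "ACOUSTIC_VARIABLES",
    "CANDIDATE_VARIABLES",
    "CallRecord",
    "CallTableError",
    "CallTableFormatError",
    "CallTableValidationError",
    "TransformDomainError",
    "CollinearityError",
    "TransformSpec",
    "FeatureMatrix",
    "AnalysisView",
    "ScreeningResult",
    "read_call_table",
    "write_call_table",
    "apply_transforms",
    "screen_correlations",
    "variance_inflation_factors",
]

CONTEXTS = ("rest", "travel", "alert")
SEXES = ("female", "male")
OBSERVERS = ("CC", "TG")
#: s = directional microphone + solid-state recorder, cs = video camera with
#: external directional microphone, c = video camera internal microphone.
DEVICES = ("s", "cs", "c")
AGE_CLASSES = ("adult", "subadult")

ID_COLUMNS = (
    "call_id",
    "subject_id",
    "sex",
    "age_years",
    "age_class",
    "context",
    "observer",
    "device",
    "bout_id",
    "position_in_bout",
)

#: The twelve acoustic measurements attached to each call.
ACOUSTIC_VARIABLES = (
    "duration_s",
    "f0_start_hz",
    "f0_end_hz",
    "f0_max_hz",
    "f0_drop_hz",
    "slope_steepness_hz_per_s",
    "peak_freq_hz",
    "t_f0max_s",
    "t_peakfreq_s",
    "pos_f0max",
    "pos_peakfreq",
    "inter_call_interval_s",
)

#: Candidate predictor set entering collinearity screening.  The two event
#: times are represented by their proportional positions, and raw peak
#: frequency enters only through its position, so that discarding the three
#: F0-redundant variables leaves the six predictors used in the analyses.
CANDIDATE_VARIABLES = (
    "duration_s",
    "f0_start_hz",
    "f0_end_hz",
    "f0_max_hz",
    "f0_drop_hz",
    "slope_steepness_hz_per_s",
    "pos_f0max",
    "pos_peakfreq",
    "inter_call_interval_s",
)

ALL_COLUMNS = ID_COLUMNS + ACOUSTIC_VARIABLES

#: Consistency tolerance for derived fields on file input, in the variable's units.
DERIVED_FIELD_TOL = 1e-6


class CallTableError(Exception):
    """Base class for call-table problems."""


class CallTableFormatError(CallTableError):
    """The file is structurally unusable (e.g. a required column is missing)."""


class CallTableValidationError(CallTableError):
    """A row violates the call data model; the message names the row."""


class TransformDomainError(CallTableError):
    """A transform was applied outside its domain (log of a non-positive value)."""


class CollinearityError(CallTableError):
    """The predictor matrix is singular; offending variables are listed."""

    def __init__(self, message: str, variables: Sequence[str] = ()):
        super().__init__(message)
        self.variables = list(variables)


@dataclass(frozen=True)
class CallRecord:
    """One measured call with identity covariates and acoustic variables."""

    call_id: str
    subject_id: str
    sex: str
    age_years: float
    age_class: str
    context: str
    observer: str
    device: str
    bout_id: str
    position_in_bout: int
    duration_s: float
    f0_start_hz: float
    f0_end_hz: float
    f0_max_hz: float
    f0_drop_hz: float
    slope_steepness_hz_per_s: float
    peak_freq_hz: float
    t_f0max_s: float
    t_peakfreq_s: float
    pos_f0max: float
    pos_peakfreq: float
    inter_call_interval_s: float | None = None

    def validate(self) -> None:
        _validate_row(dataclasses.asdict(self), label=self.call_id)


def _validate_row(row: Mapping[str, object], label: object) -> None:
    def err(msg: str) -> None:
        raise CallTableValidationError(f"row {label!r}: {msg}")

    if row["sex"] not in SEXES:
        err(f"sex {row['sex']!r} not in {SEXES}")
    if row["context"] not in CONTEXTS:
        err(f"context {row['context']!r} not in {CONTEXTS}")
    if row["observer"] not in OBSERVERS:
        err(f"observer {row['observer']!r} not in {OBSERVERS}")
    if row["device"] not in DEVICES:
        err(f"device {row['device']!r} not in {DEVICES}")
    if row["age_class"] not in AGE_CLASSES:
        err(f"age_class {row['age_class']!r} not in {AGE_CLASSES}")
    age = float(row["age_years"])
    if not age >= 0:
        err(f"age_years {age} must be >= 0")
    pos = int(row["position_in_bout"])
    if pos < 1:
        err(f"position_in_bout {pos} must be >= 1")

    dur = float(row["duration_s"])
    if not dur > 0:
        err(f"duration_s {dur} must be > 0")
    for name in ("f0_start_hz", "f0_end_hz", "f0_max_hz", "peak_freq_hz"):
        v = float(row[name])
        if not v > 0:
            err(f"{name} {v} must be > 0")
    if float(row["f0_drop_hz"]) < -DERIVED_FIELD_TOL:
        err(f"f0_drop_hz {row['f0_drop_hz']} must be >= 0")

    f0_max = float(row["f0_max_hz"])
    if f0_max < float(row["f0_start_hz"]) - DERIVED_FIELD_TOL:
        err("f0_max_hz < f0_start_hz")
    if f0_max < float(row["f0_end_hz"]) - DERIVED_FIELD_TOL:
        err("f0_max_hz < f0_end_hz")

    # absolute tolerance plus a term covering 9-significant-digit storage
    drop_expected = f0_max - float(row["f0_end_hz"])
    if abs(float(row["f0_drop_hz"]) - drop_expected) > DERIVED_FIELD_TOL + 1e-8 * f0_max:
        err(
            f"f0_drop_hz {row['f0_drop_hz']} inconsistent with "
            f"f0_max_hz - f0_end_hz = {drop_expected}"
        )

    for t_name, p_name in (("t_f0max_s", "pos_f0max"), ("t_peakfreq_s", "pos_peakfreq")):
        t = float(row[t_name])
        p = float(row[p_name])
        if t < -DERIVED_FIELD_TOL or t > dur + DERIVED_FIELD_TOL:
            err(f"{t_name} {t} outside [0, duration]")
        if abs(p - t / dur) > DERIVED_FIELD_TOL:
            err(f"{p_name} {p} inconsistent with {t_name}/duration_s = {t / dur}")
        if p < -DERIVED_FIELD_TOL or p > 1 + DERIVED_FIELD_TOL:
            err(f"{p_name} {p} outside [0, 1]")

    ici = row.get("inter_call_interval_s")
    if ici is not None and not (isinstance(ici, float) and math.isnan(ici)):
        if not float(ici) > 0:
            err(f"inter_call_interval_s {ici} must be > 0 when present")


@dataclass(frozen=True)
class TransformSpec:
    """Mapping from variable name to one of {log, sqrt, none}.

    Two presets are provided.  ``table_defaults`` follows the annotations of
    the published discriminant-loadings table (positions of maximum F0 and
    peak frequency log- and sqrt-transformed respectively);
    ``positions_untransformed`` follows the literal methods text, which
    leaves the two position variables untransformed.  Natural logarithms are
    used throughout: the base only rescales loadings affinely and changes
    neither classifications nor likelihood-ratio tests.
    """

    mapping: Mapping[str, str]

    VALID = ("log", "sqrt", "none")

    def __post_init__(self) -> None:
        for var, tag in self.mapping.items():
            if tag not in self.VALID:
                raise ValueError(f"unknown transform {tag!r} for {var!r}")

    def get(self, var: str) -> str:
        return self.mapping.get(var, "none")

    @classmethod
    def table_defaults(cls) -> "TransformSpec":
        return cls(
            {
                "duration_s": "log",
                "f0_max_hz": "log",
                "f0_drop_hz": "sqrt",
                "pos_f0max": "log",
                "pos_peakfreq": "sqrt",
                "inter_call_interval_s": "sqrt",
            }
        )

    @classmethod
    def positions_untransformed(cls) -> "TransformSpec":
        m = dict(cls.table_defaults().mapping)
        m["pos_f0max"] = "none"
        m["pos_peakfreq"] = "none"
        return cls(m)


@dataclass(frozen=True)
class AnalysisView:
    """Dense, finite slice of a feature matrix ready for numeric analysis."""

    X: np.ndarray
    variables: tuple[str, ...]
    labels: np.ndarray
    subjects: np.ndarray
    index: np.ndarray  # positional indices into the parent records


class FeatureMatrix:
    """A call table plus a declared set of (possibly transformed) predictors.

    ``records`` keeps the original, untransformed rows; ``data`` holds the
    predictor values actually entering analyses, aligned row-for-row with
    ``records``.  Calls without an inter-call interval (single calls, last
    calls of bouts) carry NaN there and are excluded from any view in which
    that variable is active.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        variables: Sequence[str] | None = None,
        data: pd.DataFrame | None = None,
        transforms: Mapping[str, str] | None = None,
    ):
        records = records.reset_index(drop=True)
        missing = [c for c in ALL_COLUMNS if c not in records.columns]
        if missing:
            raise CallTableFormatError(f"missing required columns: {missing}")
        self.records = records
        self.variables = tuple(variables) if variables is not None else CANDIDATE_VARIABLES
        if data is None:
            data = records.loc[:, list(self.variables)].astype(float).copy()
        self.data = data.reset_index(drop=True)
        self.transforms = dict(transforms) if transforms else {v: "none" for v in self.variables}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def active_variables(self) -> list[tuple[str, str]]:
        """Predictor names with their transformation tags."""
        return [(v, self.transforms.get(v, "none")) for v in self.variables]

    def with_variables(self, variables: Sequence[str]) -> "FeatureMatrix":
        unknown = [v for v in variables if v not in self.data.columns]
        if unknown:
            raise CallTableFormatError(f"unknown variables: {unknown}")
        return FeatureMatrix(
            self.records,
            variables=variables,
            data=self.data.loc[:, list(variables)].copy(),
            transforms={v: self.transforms.get(v, "none") for v in variables},
        )

    def analysis_view(
        self,
        variables: Sequence[str] | None = None,
        contexts: Sequence[str] | None = None,
    ) -> AnalysisView:
        """Finite rows for the given predictors, optionally restricted by context."""
        variables = tuple(variables) if variables is not None else self.variables
        unknown = [v for v in variables if v not in self.data.columns]
        if unknown:
            raise CallTableFormatError(f"unknown variables: {unknown}")
        mask = np.isfinite(self.data.loc[:, list(variables)].to_numpy(float)).all(axis=1)
        if contexts is not None:
            mask &= self.records["context"].isin(list(contexts)).to_numpy()
        idx = np.flatnonzero(mask)
        return AnalysisView(
            X=np.ascontiguousarray(self.data.iloc[idx][list(variables)].to_numpy(float)),
            variables=variables,
            labels=self.records["context"].to_numpy(object)[idx],
            subjects=self.records["subject_id"].to_numpy(object)[idx],
            index=idx,
        )


# ---------------------------------------------------------------------------
# I/O


def read_call_table(path, dialect: Mapping[str, str] | None = None) -> FeatureMatrix:
    """Read a call-table CSV, validating every row.

    Parameters
    ----------
    path:
        CSV file with snake_case headers matching the call data model.
    dialect:
        Optional mapping of file column name -> canonical column name, for
        tables exported under different headers.
    """
    df = pd.read_csv(path, dtype={"call_id": str, "subject_id": str, "bout_id": str})
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise CallTableFormatError(f"{path}: missing required columns {missing}")
    df = df.loc[:, list(ALL_COLUMNS)]
    for i, row in df.iterrows():
        d = row.to_dict()
        _validate_row(d, label=d.get("call_id", i))
    return FeatureMatrix(df)


def write_call_table(fm: FeatureMatrix, path) -> None:
    """Write the (untransformed) records as CSV; absent intervals become empty fields."""
    fm.records.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Transforms


def apply_transforms(fm: FeatureMatrix, spec: TransformSpec) -> FeatureMatrix:
    """Return a new FeatureMatrix whose predictor values are transformed per ``spec``.

    The original records are untouched; transformation tags are recorded on
    the active variables.  Log and sqrt domains are enforced: a log of a
    non-positive or sqrt of a negative value raises, naming variable and row.
    """
    data = fm.data.copy()
    transforms = dict(fm.transforms)
    for var in fm.variables:
        tag = spec.get(var)
        col = data[var].to_numpy(float)
        finite = np.isfinite(col)
        if tag == "log":
            bad = finite & (col <= 0)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise TransformDomainError(
                    f"log transform of {var!r} undefined at row "
                    f"{fm.records['call_id'].iloc[row]!r} (value {col[row]})"
                )
            out = np.where(finite, np.log(np.where(finite, col, 1.0)), np.nan)
        elif tag == "sqrt":
            bad = finite & (col < 0)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise TransformDomainError(
                    f"sqrt transform of {var!r} undefined at row "
                    f"{fm.records['call_id'].iloc[row]!r} (value {col[row]})"
                )
            out = np.where(finite, np.sqrt(np.where(finite, col, 0.0)), np.nan)
        else:
            out = col
        data[var] = out
        transforms[var] = tag
    return FeatureMatrix(fm.records, variables=fm.variables, data=data, transforms=transforms)


def invert_transforms(fm: FeatureMatrix) -> FeatureMatrix:
    """Back-transform predictor values to the original scale (round-trip check)."""
    data = fm.data.copy()
    transforms = {}
    for var in fm.variables:
        tag = fm.transforms.get(var, "none")
        if tag == "log":
            data[var] = np.exp(data[var])
        elif tag == "sqrt":
            data[var] = np.square(data[var])
        transforms[var] = "none"
    return FeatureMatrix(fm.records, variables=fm.variables, data=data, transforms=transforms)


# ---------------------------------------------------------------------------
# Collinearity screening

#: Variables dropped preferentially when they sit in a high-correlation pair:
#: slope steepness (derived from F0 drop) and the start/end F0 measures
#: (near-copies of maximum F0).
PREFERRED_DISCARDS = ("slope_steepness_hz_per_s", "f0_start_hz", "f0_end_hz")


@dataclass
class ScreeningResult:
    pairwise_r: pd.DataFrame
    discarded: list[str]
    vif: dict[str, float]
    retained: list[str]
    r_threshold: float
    vif_threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var in list(self.pairwise_r.columns):
            rows.append(
                {
                    "variable": var,
                    "vif": self.vif.get(var, np.nan),
                    "retained": var in self.retained,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "r_threshold": self.r_threshold,
                "vif_threshold": self.vif_threshold,
                "discarded": self.discarded,
                "retained": self.retained,
                "vif": {k: round(float(v), 9) for k, v in self.vif.items()},
            },
            indent=2,
            sort_keys=True,
        )


def variance_inflation_factors(data: pd.DataFrame) -> dict[str, float]:
    """VIF of each column: 1/(1-R^2) from an OLS regression on all other columns."""
    cols = list(data.columns)
    X = data.to_numpy(float)
    X = X[np.isfinite(X).all(axis=1)]
    n = X.shape[0]
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum(resid**2))
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def screen_correlations(
    fm: FeatureMatrix,
    r_threshold: float = 0.7,
    vif_threshold: float = 2.0,
    drop_policy: Sequence[str] = PREFERRED_DISCARDS,
    variables: Sequence[str] | None = None,
) -> ScreeningResult:
    """Thin a candidate predictor set by pairwise correlation, then check VIFs.

    While any pair exceeds ``|r| > r_threshold``, one member is discarded:
    a variable on the ``drop_policy`` preference list if one is involved,
    otherwise the variable with the largest mean absolute correlation to all
    remaining candidates.  VIFs are then computed on the survivors; if any
    reaches ``vif_threshold`` the worst is discarded and VIFs recomputed,
    so the retained set always satisfies ``vif < vif_threshold``.
    The procedure is deterministic and invariant to row order.
    """
    variables = list(variables) if variables is not None else list(fm.variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 candidate variables")
    data = fm.data.loc[:, variables].astype(float)
    if len(data.dropna()) < 3:
        raise ValueError("need at least 3 complete rows")

    # pairwise-complete Pearson correlations over the full candidate set
    full_r = data.corr(method="pearson")
    if full_r.isna().any().any():
        degenerate = [c for c in variables if data[c].nunique(dropna=True) <= 1]
        raise CollinearityError(
            f"constant or empty candidate variables: {degenerate}", degenerate
        )

    discarded: list[str] = []
    current = list(variables)
    while True:
        r = data.loc[:, current].corr(method="pearson")
        offending = []
        for i, a in enumerate(current):
            for b in current[i + 1 :]:
                if abs(r.loc[a, b]) > r_threshold:
                    offending.append((a, b))
        if not offending:
            break
        involved = {v for pair in offending for v in pair}
        victim = None
        for pref in drop_policy:
            if pref in involved:
                victim = pref
                break
        if victim is None:
            mean_abs = {
                v: float(np.nanmean(np.abs(r.loc[v, [c for c in current if c != v]])))
                for v in involved
            }
            victim = max(sorted(mean_abs), key=lambda v: mean_abs[v])
        current.remove(victim)
        discarded.append(victim)
        if len(current) < 2:
            break

    vif = variance_inflation_factors(data.loc[:, current]) if len(current) >= 2 else {
        v: 1.0 for v in current
    }
    while len(current) >= 2 and max(vif.values()) >= vif_threshold:
        over = [v for v in current if vif[v] >= vif_threshold]
        worst = next((p for p in drop_policy if p in over), None)
        if worst is None:
            worst = max(sorted(over), key=lambda v: vif[v])
            if not math.isfinite(vif[worst]):
                # exact linear dependence among survivors
                raise CollinearityError(
                    f"singular predictor matrix among {sorted(current)}", current
                )
        current.remove(worst)
        discarded.append(worst)
        vif = variance_inflation_factors(data.loc[:, current])

    return ScreeningResult(
        pairwise_r=full_r,
        discarded=discarded,
        vif=vif,
        retained=list(current),
        r_threshold=r_threshold,
        vif_threshold=vif_threshold,
    )
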