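"""Data model and tabular I/O for crossover urine-profiling studies.

The single interchange object between all analysis stages is the
:class:`MetaboliteProfileTable`: a wide sample x metabolite concentration
matrix carried inside a :class:`pandas.DataFrame`, with a fixed block of
reserved design-metadata columns (subject, intervention arm, sampling
hour, sample role, batch, injection order, urinary creatinine) followed
by one column per metabolite.

Concentrations start raw in umol/L; creatinine normalization converts
them to umol/mmol Cr to correct for urine dilution.  The table tracks a
forward-only transform state (``raw -> imputed -> log -> scaled``) so
stages cannot be applied out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved metadata columns, in file order.  Everything after them in a
#: wide CSV/TSV is interpreted as a metabolite column.
RESERVED_COLUMNS = [
    "sample_id",
    "subject_id",
    "intervention",
    "time_h",
    "role",
    "batch_id",
    "injection_order",
    "creatinine_mmol_per_L",
]

INTERVENTIONS = ("vehicle", "alcohol")
ROLES = ("experimental", "qc", "repeat")
DEFAULT_TIMES = (0, 1, 2, 3, 4)

_STATE_ORDER = {"raw": 0, "imputed": 1, "log": 2, "scaled": 3}


class UrometError(Exception):
    """Base class for all structured errors raised by this package."""


class FormatError(UrometError):
    """A file or frame does not have the expected wide-table layout."""


class ValidationError(UrometError):
    """A table violates a data invariant (names the offending row/column)."""


class DesignError(UrometError):
    """The sample layout contradicts the crossover design."""


class NormalizationError(UrometError):
    """Creatinine normalization cannot be applied to a sample."""


@dataclass(frozen=True)
class StudyDesign:
    """Two-period crossover design: every subject receives both
    interventions, half starting with each, with one urine sample per
    hour 0..4 per intervention."""

    subjects: tuple[str, ...] = tuple(f"S{i:02d}" for i in range(1, 13))
    times: tuple[int, ...] = DEFAULT_TIMES
    interventions: tuple[str, ...] = INTERVENTIONS
    crossover_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.crossover_assignment:
            half = len(self.subjects) // 2
            assign = {s: ("vehicle" if i < half else "alcohol")
                      for i, s in enumerate(self.subjects)}
            object.__setattr__(self, "crossover_assignment", assign)
        first = set(self.crossover_assignment.values())
        if set(self.crossover_assignment) != set(self.subjects):
            raise DesignError("crossover assignment must cover every subject")
        if len(self.subjects) > 1 and first != set(self.interventions):
            raise DesignError(
                "crossover assignment must split subjects into two groups "
                "whose period-1 interventions differ"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


class MetaboliteProfileTable:
    """Wide sample x metabolite table with design metadata.

    Parameters
    ----------
    data :
        DataFrame whose first columns are :data:`RESERVED_COLUMNS` and
        remaining columns are metabolite concentrations.
    normalized :
        Whether values are creatinine-normalized (umol/mmol Cr) rather
        than raw (umol/L).
    transform_state :
        One of ``raw``, ``imputed``, ``log``, ``scaled``.
    scaler :
        Retained :class:`~uromet.preprocess.ScalerParams` once the table
        has been transformed/scaled, for projecting held-out rows.
    """

    def __init__(self, data: pd.DataFrame, *, normalized: bool = False,
                 transform_state: str = "raw", scaler=None, validate: bool = True):
        missing = [c for c in RESERVED_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"missing metadata column(s): {', '.join(missing)}")
        if transform_state not in _STATE_ORDER:
            raise ValidationError(f"unknown transform_state {transform_state!r}")
        metab = [c for c in data.columns if c not in RESERVED_COLUMNS]
        if not metab:
            raise FormatError("table has no metabolite columns")
        # canonical column order: reserved block first
        self.data = data[RESERVED_COLUMNS + metab].reset_index(drop=True)
        self.normalized = bool(normalized)
        self.transform_state = transform_state
        self.scaler = scaler
        self.dropped_metabolites: list[str] = []
        if validate:
            self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[RESERVED_COLUMNS]

    @property
    def values(self) -> pd.DataFrame:
        return self.data[self.metabolites]

    @property
    def experimental(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "experimental"]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def copy(self) -> "MetaboliteProfileTable":
        t = MetaboliteProfileTable(
            self.data.copy(), normalized=self.normalized,
            transform_state=self.transform_state, scaler=self.scaler,
            validate=False)
        t.dropped_metabolites = list(self.dropped_metabolites)
        return t

    def subset(self, mask) -> "MetaboliteProfileTable":
        """Row subset (no design-completeness re-validation)."""
        t = MetaboliteProfileTable(
            self.data.loc[mask].reset_index(drop=True),
            normalized=self.normalized, transform_state=self.transform_state,
            scaler=self.scaler, validate=False)
        t.dropped_metabolites = list(self.dropped_metabolites)
        return t

    def replace_values(self, values: pd.DataFrame, *, normalized=None,
                       transform_state=None, scaler=None) -> "MetaboliteProfileTable":
        """New table with the same metadata and a new value block.

        ``transform_state`` may only advance forward along
        raw -> imputed -> log -> scaled.
        """
        state = self.transform_state if transform_state is None else transform_state
        if _STATE_ORDER[state] < _STATE_ORDER[self.transform_state]:
            raise ValidationError(
                f"transform_state may not move backwards "
                f"({self.transform_state} -> {state})")
        df = pd.concat([self.meta.reset_index(drop=True),
                        values.reset_index(drop=True)], axis=1)
        t = MetaboliteProfileTable(
            df, normalized=self.normalized if normalized is None else normalized,
            transform_state=state,
            scaler=self.scaler if scaler is None else scaler, validate=False)
        t.dropped_metabolites = list(self.dropped_metabolites)
        return t

    # -- validation --------------------------------------------------------

    def validate(self, design: StudyDesign | None = None) -> None:
        """Check structural invariants; raise a structured error naming the
        offending row and column on the first violation found."""
        df = self.data
        bad = ~df["intervention"].isin(INTERVENTIONS)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"row {i} (sample {df['sample_id'].iat[i]!r}): invalid "
                f"intervention {df['intervention'].iat[i]!r}")
        bad = ~df["role"].isin(ROLES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"row {i}: invalid role {df['role'].iat[i]!r}")
        times = pd.to_numeric(df["time_h"], errors="coerce")
        if times.isna().any() or (times % 1 != 0).any() or (times < 0).any():
            i = int(np.flatnonzero(times.isna() | (times % 1 != 0) | (times < 0))[0])
            raise ValidationError(f"row {i}: time_h must be a non-negative integer hour")
        if self.transform_state in ("raw", "imputed"):
            vals = self.values.to_numpy(dtype=float)
            neg = np.argwhere(vals < 0)
            if neg.size:
                r, c = neg[0]
                raise ValidationError(
                    f"negative concentration at row {r}, metabolite "
                    f"{self.metabolites[c]!r} in state {self.transform_state!r}")
        # duplicate experimental design cells
        exp = df[df["role"] == "experimental"]
        dup = exp.duplicated(["subject_id", "intervention", "time_h"], keep=False)
        if dup.any():
            row = exp[dup].iloc[0]
            raise DesignError(
                f"duplicate experimental sample for subject "
                f"{row['subject_id']!r}, {row['intervention']}, t={row['time_h']} h")
        if design is not None:
            want = set(design.times)
            got = exp.groupby(["subject_id", "intervention"])["time_h"].agg(set)
            for (subj, arm), t in got.items():
                if set(int(x) for x in t) != want:
                    raise DesignError(
                        f"subject {subj!r} / {arm}: expected one sample per "
                        f"hour {sorted(want)}, got {sorted(int(x) for x in t)}")

    # -- I/O ---------------------------------------------------------------

    def write(self, path, dialect: str = "wide_csv") -> None:
        write_profile_table(self, path, dialect)

    def __repr__(self):  # pragma: no cover
        return (f"<MetaboliteProfileTable {self.n_samples} samples x "
                f"{len(self.metabolites)} metabolites, "
                f"normalized={self.normalized}, state={self.transform_state}>")


_SEPS = {"wide_csv": ",", "wide_tsv": "\t"}


def read_profile_table(path, dialect: str = "wide_csv", *,
                       normalized: bool = False,
                       design: StudyDesign | None = None) -> MetaboliteProfileTable:
    """Read a wide CSV/TSV profile table and validate it.

    The header must contain the reserved metadata columns
    (:data:`RESERVED_COLUMNS`) followed by metabolite columns.
    """
    if dialect not in _SEPS:
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=_SEPS[dialect])
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing metadata column(s): {', '.join(missing)}")
    metab = [c for c in df.columns if c not in RESERVED_COLUMNS]
    df[metab] = df[metab].astype(float)
    df["time_h"] = df["time_h"].astype(int)
    df["injection_order"] = df["injection_order"].astype(int)
    table = MetaboliteProfileTable(df, normalized=normalized)
    if design is not None:
        table.validate(design)
    return table


def write_profile_table(table: MetaboliteProfileTable, path,
                        dialect: str = "wide_csv") -> None:
    """Write the wide-table dialect read by :func:`read_profile_table`."""
    if dialect not in _SEPS:
        raise FormatError(f"unknown dialect {dialect!r}")
    table.data.to_csv(path, sep=_SEPS[dialect], index=False)
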