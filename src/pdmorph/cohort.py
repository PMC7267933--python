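"""Data model and file I/O for longitudinal morphometry cohorts.

The pipeline's universal currency is the :class:`LongTable`: a tidy,
long-format table with one row per (subject, visit), subject-level
metadata repeated on every row, and one column per brain region.  Region
columns are declared explicitly in a region dictionary that tags each
region as a volume (cm^3), a planar area (mm^2) or a cortical thickness
(mm), so measurements with different units are never mixed in one
normalization pass.

Times are decimal years from baseline; ``visit_index`` is ordinal, not
calendar.  Cognitive status is stored per visit (it is re-evaluated at
every follow-up), whereas the diagnostic group (CTRL / PDN / PDCI) is
frozen at baseline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SEXES",
    "COGNITIVE_STATUSES",
    "CONVERTER_LABELS",
    "META_COLUMNS",
    "Region",
    "SubjectRecord",
    "VisitMeasurement",
    "LongTable",
    "PdmorphError",
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "read_long_table",
    "write_long_table",
    "label_converters",
]

GROUPS = ("CTRL", "PDN", "PDCI")
SEXES = ("M", "F")
COGNITIVE_STATUSES = ("NORMAL", "MCI", "DEMENTIA", "NA")
CONVERTER_LABELS = ("nPDN", "cPDN", "NA")
REGION_KINDS = ("volume", "area", "thickness")

#: Fixed metadata column order for on-disk tables (region columns follow,
#: sorted lexicographically; unknown extra columns sit in between, sorted).
META_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "education",
    "baseline_age",
    "icv",
    "converter_label",
    "visit_index",
    "time_from_baseline",
    "age_at_visit",
    "cognitive_status",
    "mean_thickness",
]

#: Columns that must be constant across all visits of one subject.
SUBJECT_LEVEL_COLUMNS = [
    "group",
    "sex",
    "education",
    "baseline_age",
    "icv",
    "converter_label",
]


class PdmorphError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PdmorphError):
    """A required column or region declaration is missing or malformed."""


class IntegrityError(PdmorphError):
    """The table violates a structural invariant."""


class ParseError(PdmorphError):
    """A cell could not be parsed; the message names the row."""


@dataclass(frozen=True)
class Region:
    """A declared region: measurement kind and physical units."""

    kind: str
    units: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise SchemaError(f"unknown region kind {self.kind!r}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: str
    education: float
    baseline_age: float
    icv: float
    converter_label: str = "NA"

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise IntegrityError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise IntegrityError(f"{self.subject_id}: unknown sex {self.sex!r}")
        if not self.icv > 0:
            raise IntegrityError(f"{self.subject_id}: icv must be positive")
        if not (18.0 <= self.baseline_age <= 110.0):
            raise IntegrityError(
                f"{self.subject_id}: baseline_age {self.baseline_age} outside [18, 110]"
            )
        if self.education < 0:
            raise IntegrityError(f"{self.subject_id}: negative education")
        if self.converter_label not in CONVERTER_LABELS:
            raise IntegrityError(
                f"{self.subject_id}: unknown converter label {self.converter_label!r}"
            )
        if self.converter_label != "NA" and self.group != "PDN":
            raise IntegrityError(
                f"{self.subject_id}: converter label on non-PDN subject"
            )


@dataclass
class VisitMeasurement:
    subject_id: str
    visit_index: int
    time_from_baseline: float
    age_at_visit: float
    cognitive_status: str = "NA"
    values: dict = field(default_factory=dict)
    mean_thickness: float = float("nan")


class LongTable:
    """Tidy per-visit morphometry records plus their region dictionary.

    Parameters
    ----------
    df
        One row per (subject, visit).  Must contain :data:`META_COLUMNS`
        (``converter_label``, ``cognitive_status`` and ``mean_thickness``
        are filled with defaults when absent) and one column per declared
        region.  Additional columns (e.g. cognitive scores) are carried
        through untouched.
    regions
        Mapping region name -> :class:`Region`.
    """

    def __init__(self, df: pd.DataFrame, regions: Mapping[str, Region]):
        df = df.copy()
        if "converter_label" not in df.columns:
            df["converter_label"] = "NA"
        if "cognitive_status" not in df.columns:
            df["cognitive_status"] = "NA"
        if "mean_thickness" not in df.columns:
            df["mean_thickness"] = np.nan
        self.regions = dict(regions)
        self.df = df
        # provenance flags, set by the normalization stage
        self.normalized = False
        self.corrected = False
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        subjects: Iterable[SubjectRecord],
        visits: Iterable[VisitMeasurement],
        regions: Mapping[str, Region],
    ) -> "LongTable":
        subj = {}
        for s in subjects:
            s.validate()
            if s.subject_id in subj:
                raise IntegrityError(f"duplicate subject {s.subject_id}")
            subj[s.subject_id] = s
        rows = []
        for v in visits:
            if v.subject_id not in subj:
                raise IntegrityError(f"visit references unknown subject {v.subject_id}")
            s = subj[v.subject_id]
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "education": s.education,
                "baseline_age": s.baseline_age,
                "icv": s.icv,
                "converter_label": s.converter_label,
                "visit_index": v.visit_index,
                "time_from_baseline": v.time_from_baseline,
                "age_at_visit": v.age_at_visit,
                "cognitive_status": v.cognitive_status,
                "mean_thickness": v.mean_thickness,
            }
            for name in regions:
                row[name] = v.values.get(name, np.nan)
            unknown = set(v.values) - set(regions)
            if unknown:
                raise SchemaError(
                    f"{v.subject_id}: measurements for undeclared regions {sorted(unknown)}"
                )
            rows.append(row)
        return cls(pd.DataFrame(rows), regions)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for name in self.regions:
            if name not in df.columns:
                raise SchemaError(f"region column missing from table: {name}")
            if not pd.api.types.is_numeric_dtype(df[name]):
                raise ParseError(f"region column {name} is not numeric")

        if df.duplicated(subset=["subject_id", "visit_index"]).any():
            dup = df[df.duplicated(subset=["subject_id", "visit_index"], keep=False)]
            key = dup.iloc[0]
            raise IntegrityError(
                f"duplicate (subject, visit): ({key['subject_id']}, {key['visit_index']})"
            )

        # accept shuffled input; re-establish canonical order
        df = df.sort_values(["subject_id", "visit_index"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.df = df

        for col, allowed in [
            ("group", GROUPS),
            ("sex", SEXES),
            ("cognitive_status", COGNITIVE_STATUSES),
            ("converter_label", CONVERTER_LABELS),
        ]:
            bad = ~df[col].isin(allowed)
            if bad.any():
                raise IntegrityError(
                    f"invalid value {df.loc[bad, col].iloc[0]!r} in column {col}"
                )

        if (df["icv"] <= 0).any():
            raise IntegrityError("icv must be positive")
        if ((df["baseline_age"] < 18) | (df["baseline_age"] > 110)).any():
            raise IntegrityError("baseline_age outside [18, 110]")
        if (df["education"] < 0).any():
            raise IntegrityError("negative education")
        nonpdn = df["group"] != "PDN"
        if (nonpdn & (df["converter_label"] != "NA")).any():
            raise IntegrityError("converter label on non-PDN subject")

        for sid, g in df.groupby("subject_id", sort=False):
            for col in SUBJECT_LEVEL_COLUMNS:
                if g[col].nunique(dropna=False) > 1:
                    raise IntegrityError(f"{sid}: subject-level column {col} varies across visits")
            vi = g["visit_index"].to_numpy()
            t = g["time_from_baseline"].to_numpy(dtype=float)
            if vi[0] != 0:
                raise IntegrityError(f"{sid}: no baseline visit (visit_index 0)")
            if abs(t[0]) > 1e-12:
                raise IntegrityError(f"{sid}: baseline visit has nonzero time {t[0]}")
            if (t[1:] < 0).any() or np.any(np.diff(t) <= 0):
                raise IntegrityError(f"{sid}: visit times not strictly increasing")
            age = g["age_at_visit"].to_numpy(dtype=float)
            expected = g["baseline_age"].to_numpy(dtype=float) + t
            if np.nanmax(np.abs(age - expected)) > 1e-6:
                raise IntegrityError(f"{sid}: age_at_visit inconsistent with baseline_age + time")

    # -- convenience ---------------------------------------------------

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject (metadata from the baseline visit)."""
        return self.df[self.df["visit_index"] == 0][
            ["subject_id"] + SUBJECT_LEVEL_COLUMNS
        ].reset_index(drop=True)

    def baseline(self) -> pd.DataFrame:
        return self.df[self.df["visit_index"] == 0].reset_index(drop=True)

    def copy(self) -> "LongTable":
        out = LongTable(self.df.copy(), dict(self.regions))
        out.normalized = self.normalized
        out.corrected = self.corrected
        return out

    def region_names(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return sorted(self.regions)
        return sorted(n for n, r in self.regions.items() if r.kind == kind)

    def __repr__(self) -> str:  # pragma: no cover
        n_subj = self.df["subject_id"].nunique()
        return (
            f"<LongTable {n_subj} subjects, {len(self.df)} visits, "
            f"{len(self.regions)} regions>"
        )


# ---------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------

def _column_order(df: pd.DataFrame, regions: Mapping[str, Region]) -> list[str]:
    extra = sorted(c for c in df.columns if c not in META_COLUMNS and c not in regions)
    return META_COLUMNS + extra + sorted(regions)


def read_long_table(path, regions: Mapping[str, Region]) -> LongTable:
    """Read a tab-separated long-format cohort table.

    Empty cells become missing values.  Rows may arrive in any order;
    the table is re-sorted by (subject, visit) and validated.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ParseError(f"could not parse {path}: {exc}") from exc

    required = [
        "subject_id", "group", "sex", "education", "baseline_age",
        "icv", "visit_index", "time_from_baseline",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    for name in regions:
        if name not in df.columns:
            raise SchemaError(f"region column missing from file: {name}")
        coerced = pd.to_numeric(df[name], errors="coerce")
        bad = coerced.isna() & df[name].notna() & (df[name].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[name].iloc[row]!r} in region {name}, data row {row + 1}"
            )
        df[name] = coerced
    if "age_at_visit" not in df.columns:
        df["age_at_visit"] = df["baseline_age"] + df["time_from_baseline"]
    for col in ("converter_label", "cognitive_status"):
        if col in df.columns:
            df[col] = df[col].fillna("NA")
    return LongTable(df, regions)


def write_long_table(table: LongTable, path) -> None:
    """Write a LongTable as TSV with deterministic column order.

    Metadata columns first, then extra columns and regions sorted
    lexicographically; missing values become empty cells.  The writer and
    :func:`read_long_table` round-trip exactly for finite values.
    """
    cols = _column_order(table.df, table.regions)
    out = table.df[cols]
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            out.to_csv(fh, sep="\t", index=False, na_rep="")
    else:
        out.to_csv(path, sep="\t", index=False, na_rep="")


def table_to_tsv_bytes(table: LongTable) -> bytes:
    buf = io.StringIO()
    write_long_table(table, buf)
    return buf.getvalue().encode("utf-8")


# ---------------------------------------------------------------------
# Converter labelling
# ---------------------------------------------------------------------

def label_converters(table: LongTable) -> LongTable:
    """Label PDN subjects as converters (cPDN) or nonconverters (nPDN).

    A PDN subject with at least one follow-up visit is labelled cPDN if
    any follow-up cognitive status is MCI or DEMENTIA, else nPDN.  PDN
    subjects with a baseline visit only keep the NA label and are
    excluded from converter analyses.  Idempotent: relabelling an
    already-labelled table reproduces the same labels.

    Raises
    ------
    IntegrityError
        If a non-PDN subject already carries a converter label (that is
        also rejected at validation time).
    """
    out = table.copy()
    df = out.df
    labels = {}
    for sid, g in df[df["group"] == "PDN"].groupby("subject_id", sort=False):
        follow = g[g["visit_index"] > 0]
        if len(follow) == 0:
            labels[sid] = "NA"
        elif follow["cognitive_status"].isin(["MCI", "DEMENTIA"]).any():
            labels[sid] = "cPDN"
        else:
            labels[sid] = "nPDN"
    is_pdn = df["group"] == "PDN"
    df.loc[is_pdn, "converter_label"] = df.loc[is_pdn, "subject_id"].map(labels)
    out._validate()
    return out
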