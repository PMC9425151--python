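"""Sharp-van der Heijde (SvH) scoring scheme as a validated data model.

The SvH method is the standard visual scoring system for radiographic joint
damage in rheumatoid arthritis.  Two damage types are scored per patient from
four posteroanterior radiographs (both hands/wrists, both feet):

* joint-space narrowing (JSN), scored 0-4 on 15 hand/wrist areas and 6 foot
  areas per side (42 locations in total);
* bone erosion, scored 0-5 on 16 hand/wrist areas per side and 0-10 on 6 foot
  joints per side (the two sides of each foot joint are scored together,
  hence the doubled cap; 44 locations in total).

Summing the per-location caps gives the maximum attainable total of 448
points.  This module encodes that scheme as an explicit registry of joint
areas, integer ground-truth score sheets, continuous-valued model
submissions, validation, and a documented CSV template.

The individual area names used here follow the standard SvH enumeration
(MCP/PIP/IP joints, carpal areas, MTP joints); only the cardinalities and
per-location caps are load-bearing for the evaluation metrics, so the names
are registry configuration rather than logic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from numbers import Integral, Real
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "JointArea",
    "JointAreaRegistry",
    "ScoreSheet",
    "SubmissionSet",
    "ValidationIssue",
    "ValidationReport",
    "SchemeError",
    "CsvFormatError",
    "build_registry",
    "max_total_score",
    "count_joint_scores",
    "validate_sheet",
    "cohort_joint_frame",
    "cohort_totals_frame",
    "read_scores_csv",
    "write_scores_csv",
    "MAX_TOTAL_SCORE",
    "TOTAL_COLUMNS",
    "PATIENT_ID_COLUMN",
]

REGIONS = ("hand_wrist", "foot")
SIDES = ("left", "right")
DAMAGE_TYPES = ("jsn", "erosion")

#: Maximum attainable overall SvH total (sum of all per-location caps).
MAX_TOTAL_SCORE = 448

PATIENT_ID_COLUMN = "Patient_ID"
#: Sub-total columns of the CSV template, in file order.
TOTAL_COLUMNS = ("Overall_narrowing", "Overall_erosion", "Overall_Tol")

_SIDE_CODES = {
    ("left", "hand_wrist"): "LH",
    ("right", "hand_wrist"): "RH",
    ("left", "foot"): "LF",
    ("right", "foot"): "RF",
}

# Standard SvH area enumeration.  15 JSN and 16 erosion areas per hand/wrist;
# 6 joints per foot for both damage types.
_HAND_WRIST_JSN = (
    "mcp1", "mcp2", "mcp3", "mcp4", "mcp5",
    "pip2", "pip3", "pip4", "pip5",
    "cmc3", "cmc4", "cmc5",
    "capitate_navicular_lunate", "multangular_navicular", "radiocarpal",
)
_HAND_WRIST_EROSION = (
    "ip1", "pip2", "pip3", "pip4", "pip5",
    "mcp1", "mcp2", "mcp3", "mcp4", "mcp5",
    "mc1_base", "multangular", "navicular", "lunate", "radius", "ulna",
)
_FOOT_JOINTS = ("mtp1", "mtp2", "mtp3", "mtp4", "mtp5", "ip1")


class SchemeError(ValueError):
    """A value violates the SvH scoring scheme or the data-model contracts."""


class CsvFormatError(SchemeError):
    """A CSV file does not conform to the documented score-sheet template."""


def _expected_cap(region: str, damage_type: str) -> int:
    if damage_type == "jsn":
        return 4
    return 5 if region == "hand_wrist" else 10


@dataclass(frozen=True)
class JointArea:
    """One scored location: a joint area on one side, for one damage type.

    ``max_score`` is fixed by the scheme: 4 for every JSN area, 5 for
    hand/wrist erosion areas, and 10 for foot erosion joints (both sides of
    the joint pre-summed).
    """

    region: str
    side: str
    name: str
    damage_type: str
    max_score: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SchemeError(f"unknown region {self.region!r}")
        if self.side not in SIDES:
            raise SchemeError(f"unknown side {self.side!r}")
        if self.damage_type not in DAMAGE_TYPES:
            raise SchemeError(f"unknown damage_type {self.damage_type!r}")
        cap = _expected_cap(self.region, self.damage_type)
        if self.max_score != cap:
            raise SchemeError(
                f"{self.damage_type} area in region {self.region!r} must have "
                f"max_score {cap}, got {self.max_score}"
            )

    @property
    def column_key(self) -> str:
        """CSV column name: ``{LH|RH|LF|RF}_{name}__{J|E}``."""
        code = _SIDE_CODES[(self.side, self.region)]
        suffix = "J" if self.damage_type == "jsn" else "E"
        return f"{code}_{self.name}__{suffix}"


class JointAreaRegistry(Sequence):
    """Ordered, uniqueness-checked collection of all scored joint areas.

    The canonical registry (see :func:`build_registry`) has 42 JSN and 44
    erosion locations over both sides, with per-location caps summing to 448.
    """

    def __init__(self, areas: Iterable[JointArea]):
        self._areas = tuple(areas)
        seen = set()
        for a in self._areas:
            key = (a.region, a.side, a.name, a.damage_type)
            if key in seen:
                raise SchemeError(f"duplicate joint area {key}")
            seen.add(key)
        self._by_column = {a.column_key: a for a in self._areas}

    def __len__(self) -> int:
        return len(self._areas)

    def __getitem__(self, i):
        return self._areas[i]

    def __iter__(self) -> Iterator[JointArea]:
        return iter(self._areas)

    @property
    def areas(self) -> tuple:
        return self._areas

    def areas_of(
        self,
        damage_type: Optional[str] = None,
        region: Optional[str] = None,
        side: Optional[str] = None,
    ) -> List[JointArea]:
        out = []
        for a in self._areas:
            if damage_type is not None and a.damage_type != damage_type:
                continue
            if region is not None and a.region != region:
                continue
            if side is not None and a.side != side:
                continue
            out.append(a)
        return out

    def column_keys(self, damage_type: Optional[str] = None) -> List[str]:
        return [a.column_key for a in self.areas_of(damage_type)]

    def area_for_column(self, key: str) -> JointArea:
        try:
            return self._by_column[key]
        except KeyError:
            raise SchemeError(f"unknown joint-area column {key!r}") from None

    def max_total(self, damage_type: str = "overall") -> int:
        if damage_type == "overall":
            return sum(a.max_score for a in self._areas)
        if damage_type not in DAMAGE_TYPES:
            raise SchemeError(f"unknown damage_type {damage_type!r}")
        return sum(a.max_score for a in self.areas_of(damage_type))


_DEFAULT_REGISTRY: Optional[JointAreaRegistry] = None


def build_registry() -> JointAreaRegistry:
    """Return the canonical SvH joint-area registry.

    Ordering is JSN areas first then erosion, left side before right within
    each damage type, hand/wrist before foot — this fixes the CSV column
    order of the template.
    """
    areas: List[JointArea] = []
    for damage_type in DAMAGE_TYPES:
        for side in SIDES:
            if damage_type == "jsn":
                hand_names, foot_names = _HAND_WRIST_JSN, _FOOT_JOINTS
            else:
                hand_names, foot_names = _HAND_WRIST_EROSION, _FOOT_JOINTS
            for name in hand_names:
                areas.append(JointArea("hand_wrist", side, name, damage_type,
                                       _expected_cap("hand_wrist", damage_type)))
            for name in foot_names:
                areas.append(JointArea("foot", side, name, damage_type,
                                       _expected_cap("foot", damage_type)))
    return JointAreaRegistry(areas)


def default_registry() -> JointAreaRegistry:
    """Module-level cached canonical registry (immutable, safe to share)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = build_registry()
    return _DEFAULT_REGISTRY


def max_total_score(registry: JointAreaRegistry, damage_type: str = "overall") -> int:
    """Sum of per-location caps over areas of ``damage_type`` (or everything)."""
    return registry.max_total(damage_type)


def count_joint_scores(
    n_patients: int,
    damage_type: str,
    registry: Optional[JointAreaRegistry] = None,
) -> int:
    """Number of individual joint scores of one damage type in a cohort.

    E.g. a 188-patient cohort carries ``188 * 42 = 7896`` JSN scores and
    ``188 * 44 = 8272`` erosion scores.
    """
    if not isinstance(n_patients, Integral) or n_patients < 1:
        raise SchemeError(f"n_patients must be a positive integer, got {n_patients!r}")
    registry = registry or default_registry()
    if damage_type not in DAMAGE_TYPES:
        raise SchemeError(f"unknown damage_type {damage_type!r}")
    return int(n_patients) * len(registry.areas_of(damage_type))


# ---------------------------------------------------------------------------
# Score sheets and submissions
# ---------------------------------------------------------------------------

@dataclass
class ScoreSheet:
    """One patient's ground-truth integer SvH scores, one entry per area."""

    patient_id: str
    scores: Dict[JointArea, int]

    def _total(self, damage_type: Optional[str]) -> int:
        return int(sum(
            v for a, v in self.scores.items()
            if damage_type is None or a.damage_type == damage_type
        ))

    @property
    def jsn_total(self) -> int:
        return self._total("jsn")

    @property
    def erosion_total(self) -> int:
        return self._total("erosion")

    @property
    def overall_total(self) -> int:
        return self._total(None)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str          # "missing_area" | "extra_area" | "not_integer" | "out_of_range"
    where: str         # column key of the offending area
    message: str


@dataclass
class ValidationReport:
    patient_id: str
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __iter__(self):
        return iter(self.issues)

    def __len__(self):
        return len(self.issues)


def validate_sheet(sheet: ScoreSheet, registry: JointAreaRegistry) -> ValidationReport:
    """Check a sheet against the registry; returns every violation found.

    The report is empty iff the sheet is valid: every registry area present
    exactly once, every score an integer within ``[0, max_score]``, and no
    scores for areas outside the registry.
    """
    report = ValidationReport(sheet.patient_id)
    registry_set = set(registry.areas)
    for area in registry:
        if area not in sheet.scores:
            report.issues.append(ValidationIssue(
                "missing_area", area.column_key, "no score for this area"))
    for area, value in sheet.scores.items():
        if area not in registry_set:
            report.issues.append(ValidationIssue(
                "extra_area", area.column_key, "area not in registry"))
            continue
        if isinstance(value, bool) or not isinstance(value, Integral):
            report.issues.append(ValidationIssue(
                "not_integer", area.column_key, f"score {value!r} is not an integer"))
            continue
        if not (0 <= value <= area.max_score):
            report.issues.append(ValidationIssue(
                "out_of_range", area.column_key,
                f"score {int(value)} outside [0, {area.max_score}]"))
    return report


@dataclass
class SubmissionSet:
    """One team's continuous predictions on a fixed patient/joint-area grid.

    ``joint_scores`` is indexed by patient id with one column per registry
    ``column_key``; ``overall`` holds the team's patient-level overall damage
    predictions (used by subchallenge 1), which need not equal the sum of the
    joint columns.
    """

    team_id: str
    joint_scores: pd.DataFrame
    overall: pd.Series

    def __post_init__(self) -> None:
        self.joint_scores = self.joint_scores.astype(float)
        self.overall = self.overall.astype(float).reindex(self.joint_scores.index)
        vals = self.joint_scores.to_numpy()
        if not np.all(np.isfinite(vals)) or not np.all(np.isfinite(self.overall.to_numpy())):
            raise SchemeError(f"submission {self.team_id!r} contains non-finite values")
        if (vals < 0).any() or (self.overall.to_numpy() < 0).any():
            raise SchemeError(f"submission {self.team_id!r} contains negative values")

    @property
    def patient_ids(self) -> List[str]:
        return list(self.joint_scores.index)

    def check_alignment(self, truth_ids: Sequence[str], registry: JointAreaRegistry) -> None:
        """Raise unless the grid matches the truth cohort exactly."""
        if set(self.joint_scores.index) != set(truth_ids):
            raise SchemeError(
                f"submission {self.team_id!r} patient set does not match cohort")
        expected = set(registry.column_keys())
        have = set(self.joint_scores.columns)
        if have != expected:
            missing = sorted(expected - have)[:3]
            extra = sorted(have - expected)[:3]
            raise SchemeError(
                f"submission {self.team_id!r} joint-area grid mismatch "
                f"(missing {missing}, extra {extra})")


# ---------------------------------------------------------------------------
# Cohort-level tabular views
# ---------------------------------------------------------------------------

def cohort_joint_frame(
    sheets: Sequence[ScoreSheet],
    registry: Optional[JointAreaRegistry] = None,
) -> pd.DataFrame:
    """Integer joint-score table: one row per patient, one column per area."""
    registry = registry or default_registry()
    cols = registry.column_keys()
    data = {
        s.patient_id: [s.scores[a] for a in registry]
        for s in sheets
    }
    frame = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    frame.index.name = PATIENT_ID_COLUMN
    return frame.astype(int)


def cohort_totals_frame(sheets: Sequence[ScoreSheet]) -> pd.DataFrame:
    """Per-patient JSN / erosion / overall totals."""
    rows = {
        s.patient_id: (s.jsn_total, s.erosion_total, s.overall_total)
        for s in sheets
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(TOTAL_COLUMNS))
    frame.index.name = PATIENT_ID_COLUMN
    return frame


# ---------------------------------------------------------------------------
# CSV template
# ---------------------------------------------------------------------------
#
# Template (UTF-8, header row, one row per radiographic set):
#   Patient_ID, <joint columns in registry order>, Overall_narrowing,
#   Overall_erosion, Overall_Tol
# Truth files carry integers; submission files real numbers.  Sub-totals are
# recomputed and cross-checked for truth files; for submissions the totals
# are independent predictions (subchallenge 1) and are only range-checked.

def _read_header(path: Path) -> List[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise CsvFormatError(f"{path}: duplicate columns {sorted(dupes)}")
    return header


def _check_columns(path: Path, header: Sequence[str], registry: JointAreaRegistry) -> None:
    expected = [PATIENT_ID_COLUMN] + registry.column_keys() + list(TOTAL_COLUMNS)
    missing = sorted(set(expected) - set(header))
    unknown = sorted(set(header) - set(expected))
    if missing:
        raise CsvFormatError(f"{path}: missing columns {missing}")
    if unknown:
        raise CsvFormatError(f"{path}: unknown columns {unknown}")


def read_scores_csv(
    path: Union[str, Path],
    role: str,
    registry: Optional[JointAreaRegistry] = None,
    team_id: Optional[str] = None,
) -> Union[List[ScoreSheet], SubmissionSet]:
    """Read a truth or submission CSV in the documented template.

    Parameters
    ----------
    role
        ``"truth"`` returns a list of :class:`ScoreSheet`; ``"submission"``
        returns a :class:`SubmissionSet` (``team_id`` defaults to the file
        stem).
    """
    path = Path(path)
    registry = registry or default_registry()
    if role not in ("truth", "submission"):
        raise SchemeError(f"unknown role {role!r}")
    header = _read_header(path)
    _check_columns(path, header, registry)
    frame = pd.read_csv(path, dtype={PATIENT_ID_COLUMN: str},
                        float_precision="round_trip")
    if frame[PATIENT_ID_COLUMN].duplicated().any():
        dupes = frame[PATIENT_ID_COLUMN][frame[PATIENT_ID_COLUMN].duplicated()].tolist()
        raise CsvFormatError(f"{path}: duplicate Patient_ID rows {dupes}")
    frame = frame.set_index(PATIENT_ID_COLUMN)

    value_cols = registry.column_keys() + list(TOTAL_COLUMNS)
    values = frame[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        pid = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[pid]][0]
        raise CsvFormatError(f"{path}: malformed number at row {pid!r}, column {col!r}")
    neg = values < 0
    if neg.to_numpy().any():
        pid = neg.index[neg.any(axis=1)][0]
        col = neg.columns[neg.loc[pid]][0]
        raise CsvFormatError(f"{path}: negative value at row {pid!r}, column {col!r}")

    if role == "submission":
        joints = values[registry.column_keys()]
        return SubmissionSet(
            team_id=team_id or path.stem,
            joint_scores=joints,
            overall=values["Overall_Tol"],
        )

    # truth: integer scores, caps, exact sub-total cross-check
    joint_cols = registry.column_keys()
    joints = values[joint_cols]
    frac = joints != np.floor(joints)
    if frac.to_numpy().any():
        pid = frac.index[frac.any(axis=1)][0]
        col = frac.columns[frac.loc[pid]][0]
        raise CsvFormatError(
            f"{path}: non-integer truth score at row {pid!r}, column {col!r}")
    sheets: List[ScoreSheet] = []
    for pid, row in joints.iterrows():
        sheet = ScoreSheet(
            patient_id=str(pid),
            scores={a: int(row[a.column_key]) for a in registry},
        )
        report = validate_sheet(sheet, registry)
        if not report.ok:
            issue = report.issues[0]
            raise CsvFormatError(
                f"{path}: row {pid!r}, column {issue.where!r}: {issue.message}")
        stored = values.loc[pid, list(TOTAL_COLUMNS)]
        recomputed = (sheet.jsn_total, sheet.erosion_total, sheet.overall_total)
        for col, want in zip(TOTAL_COLUMNS, recomputed):
            if abs(float(stored[col]) - want) > 1e-9:
                raise CsvFormatError(
                    f"{path}: sub-total mismatch at row {pid!r}, column {col!r}: "
                    f"stored {stored[col]}, recomputed {want}")
        sheets.append(sheet)
    return sheets


def write_scores_csv(
    obj: Union[Sequence[ScoreSheet], SubmissionSet],
    path: Union[str, Path],
    registry: Optional[JointAreaRegistry] = None,
) -> Path:
    """Write a truth cohort or a submission in the documented CSV template.

    Truth sheets round-trip bit-exactly through :func:`read_scores_csv`.
    """
    path = Path(path)
    registry = registry or default_registry()
    if isinstance(obj, SubmissionSet):
        frame = obj.joint_scores[registry.column_keys()].copy()
        # sub-totals: narrowing/erosion recomputed from joints, overall from
        # the submission's own patient-level predictions
        frame["Overall_narrowing"] = obj.joint_scores[registry.column_keys("jsn")].sum(axis=1)
        frame["Overall_erosion"] = obj.joint_scores[registry.column_keys("erosion")].sum(axis=1)
        frame["Overall_Tol"] = obj.overall
    else:
        frame = cohort_joint_frame(obj, registry)
        frame = frame.join(cohort_totals_frame(obj))
    frame.index.name = PATIENT_ID_COLUMN
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path)
    return path
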