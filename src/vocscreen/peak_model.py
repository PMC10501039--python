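"""Data model and I/O for GC-MS peak tables and cohort score tables.

The central object is :class:`PeakTable`: a dense subject x VOC grid of
peak measurements, each holding per-fragment ion areas (m/z -> area) and
an independently integrated total-ion-current (TIC) area.  The canonical
on-disk form is a long TSV with one row per subject x VOC x fragment;
a wide quantifier-area matrix is available as a convenience view.

"Not detected" is encoded as all-zero areas (never as missing values) so
that detection predicates are crisp; an optional detection floor converts
sub-floor areas to zero on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .exceptions import (
    DuplicateRecordError,
    EmptyTableError,
    NoSignalError,
    PeakTableFormatError,
    RetentionRangeError,
)

__all__ = [
    "VOCSpecies",
    "PeakTable",
    "CohortTable",
    "GroupSummary",
    "read_peak_table",
    "write_peak_table",
    "read_cohort_table",
    "write_cohort_table",
    "select_quantifier_ion",
    "compute_retention_index",
    "group_summary",
]

MZ_MIN, MZ_MAX = 35, 300  # quadrupole scan range of the acquisition method

PEAK_COLUMNS = [
    "subject_id",
    "group",
    "voc_id",
    "name",
    "cas",
    "retention_time_min",
    "mz",
    "fragment_area",
    "tic_area",
]

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age",
    "kihon_cl",
    "tmig_ic",
    "jst_ic",
    "dskc",
    "dskc_self",
    "sds",
    "grid_hamd",
    "serum_creatinine",
    "urinary_creatinine",
    "ucreat_per_weight",
    "specific_gravity",
]

# score variable -> (low, high); grid_hamd has no hard upper bound
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "kihon_cl": (0, 20),
    "tmig_ic": (0, 13),
    "jst_ic": (0, 16),
    "dskc": (0, 5),
    "dskc_self": (0, 5),
    "sds": (20, 80),
    "grid_hamd": (0, float("inf")),
}

GROUPS = ("control", "positive")


@dataclass
class VOCSpecies:
    """A VOC species with its chromatographic/spectral identity."""

    voc_id: str
    name: str
    retention_time: float  # minutes
    fragment_mzs: tuple[int, ...]
    cas_number: str = ""
    chemical_class: str = ""
    quantifier_mz: int | None = None
    confirmed_standard: bool = False

    def __post_init__(self) -> None:
        self.fragment_mzs = tuple(int(m) for m in self.fragment_mzs)
        if self.retention_time <= 0:
            raise ValueError(f"{self.voc_id}: retention time must be > 0")
        if not self.fragment_mzs:
            raise ValueError(f"{self.voc_id}: at least one fragment m/z required")
        for m in self.fragment_mzs:
            if not (MZ_MIN <= m <= MZ_MAX):
                raise ValueError(
                    f"{self.voc_id}: fragment m/z {m} outside scan range "
                    f"[{MZ_MIN}, {MZ_MAX}]"
                )
        if self.quantifier_mz is not None and self.quantifier_mz not in self.fragment_mzs:
            raise ValueError(
                f"{self.voc_id}: quantifier m/z {self.quantifier_mz} is not a fragment"
            )


@dataclass
class PeakTable:
    """Dense subject x VOC grid of fragment and TIC areas.

    ``subjects`` is a two-column frame (subject_id, group) preserving file
    order; ``measurements`` is the long frame with one row per
    (subject, voc, fragment m/z).  Every (subject, voc) pair carries a row
    for each fragment of that species; missing cells are zero-filled.
    """

    species: list[VOCSpecies]
    subjects: pd.DataFrame
    measurements: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        groups = set(self.subjects["group"])
        if not groups <= set(GROUPS):
            raise ValueError(f"unknown group labels: {groups - set(GROUPS)}")
        if len(groups) != 2:
            raise ValueError("subjects must span exactly two groups")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        if (self.measurements["fragment_area"] < 0).any() or (
            self.measurements["tic_area"] < 0
        ).any():
            raise ValueError("areas must be non-negative")

    # -- lookups ----------------------------------------------------------

    @property
    def species_by_id(self) -> dict[str, VOCSpecies]:
        return {s.voc_id: s for s in self.species}

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def group_members(self, group: str) -> list[str]:
        return list(self.subjects.loc[self.subjects["group"] == group, "subject_id"])

    def _voc_rows(self, voc_id: str) -> pd.DataFrame:
        rows = self.measurements[self.measurements["voc_id"] == voc_id]
        if rows.empty:
            raise KeyError(f"unknown voc_id {voc_id!r}")
        return rows

    def fragment_totals(self, voc_id: str) -> pd.Series:
        """Summed fragment area across all subjects, indexed by m/z."""
        rows = self._voc_rows(voc_id)
        return rows.groupby("mz")["fragment_area"].sum()

    def fragment_areas(self, voc_id: str, mz: int) -> pd.Series:
        """Per-subject area of one fragment, in subject order."""
        rows = self._voc_rows(voc_id)
        rows = rows[rows["mz"] == mz].set_index("subject_id")["fragment_area"]
        return rows.reindex(self.subject_ids).fillna(0.0)

    def quantifier_areas(self, voc_id: str) -> pd.Series:
        """Per-subject area of the species' quantifier ion (auto-selected
        if not yet set)."""
        sp = self.species_by_id[voc_id]
        mz = sp.quantifier_mz
        if mz is None:
            mz = select_quantifier_ion(sp, self)
        return self.fragment_areas(voc_id, mz)

    def tic_areas(self, voc_id: str) -> pd.Series:
        """Per-subject TIC area (constant across a species' fragment rows)."""
        rows = self._voc_rows(voc_id)
        ser = rows.groupby("subject_id")["tic_area"].first()
        return ser.reindex(self.subject_ids).fillna(0.0)

    def detected(self, voc_id: str) -> pd.Series:
        """Boolean per-subject detection (any nonzero area, fragment or TIC)."""
        rows = self._voc_rows(voc_id)
        frag = rows.groupby("subject_id")["fragment_area"].max()
        tic = rows.groupby("subject_id")["tic_area"].max()
        det = (frag > 0) | (tic > 0)
        return det.reindex(self.subject_ids).fillna(False)

    def group_values(self, values: pd.Series) -> dict[str, np.ndarray]:
        """Split a per-subject series into {'control': ..., 'positive': ...}."""
        return {
            g: values.loc[self.group_members(g)].to_numpy(dtype=float) for g in GROUPS
        }


@dataclass
class CohortTable:
    """Per-subject clinical, frailty and urine-chemistry scores."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise PeakTableFormatError(f"cohort table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        for var, (lo, hi) in SCORE_RANGES.items():
            vals = self.data[var].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"{var} outside documented range [{lo}, {hi}]")
        # clinician-rated depression severity is only determined for cases
        ctrl_hamd = self.data.loc[self.data["group"] == "control", "grid_hamd"]
        if ctrl_hamd.notna().any():
            raise ValueError("grid_hamd must be missing (n.d.) for controls")

    def scores(self, variable: str, group: str | None = None) -> pd.Series:
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df.set_index("subject_id")[variable]


@dataclass(frozen=True)
class GroupSummary:
    """Group means/SEMs with fold change and rank-test p-values."""

    variable: str
    mean_control: float
    sem_control: float
    mean_positive: float
    sem_positive: float
    fold: float  # positive / control mean; NaN when undefined
    fold_defined: bool
    p_two_tailed: float
    p_one_tailed: float

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "mean_control": self.mean_control,
            "sem_control": self.sem_control,
            "mean_positive": self.mean_positive,
            "sem_positive": self.sem_positive,
            "fold": self.fold,
            "fold_defined": self.fold_defined,
            "p_two_tailed": self.p_two_tailed,
            "p_one_tailed": self.p_one_tailed,
        }


def _sem(values: np.ndarray) -> float:
    # sample SD (denominator n-1) over sqrt(n)
    n = values.size
    if n < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(n))


def group_summary(
    values_by_group: Mapping[str, Sequence[float]], variable: str
) -> GroupSummary:
    """Mean, SEM, positive/control fold and Mann-Whitney p for one variable."""
    ctrl = np.asarray(values_by_group["control"], dtype=float)
    pos = np.asarray(values_by_group["positive"], dtype=float)
    if ctrl.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_c, mean_p = float(ctrl.mean()), float(pos.mean())
    fold_defined = mean_c > 0
    fold = mean_p / mean_c if fold_defined else float("nan")
    mw = stats_core.mann_whitney(pos, ctrl)
    return GroupSummary(
        variable=variable,
        mean_control=mean_c,
        sem_control=_sem(ctrl),
        mean_positive=mean_p,
        sem_positive=_sem(pos),
        fold=fold,
        fold_defined=fold_defined,
        p_two_tailed=mw.p_two_tailed,
        p_one_tailed=mw.p_one_tailed,
    )


def select_quantifier_ion(species: VOCSpecies, table: PeakTable) -> int:
    """Choose the quantifier ion: the fragment m/z with the largest summed
    area across all subjects (ties broken toward the smallest m/z).

    Sets ``species.quantifier_mz`` as a side effect.
    """
    totals = table.fragment_totals(species.voc_id)
    totals = totals.reindex(species.fragment_mzs).fillna(0.0)
    if (totals <= 0).all():
        raise NoSignalError(
            f"{species.voc_id}: all fragment areas are zero in this table"
        )
    best = int(totals.index[np.lexsort((totals.index, -totals.to_numpy()))][0])
    species.quantifier_mz = best
    return best


def compute_retention_index(rt: float, alkane_rts: Mapping[int, float]) -> float:
    """Kovats-style retention index by linear interpolation between the
    bracketing n-alkanes: RI = 100*(n + (rt - t_n)/(t_{n+1} - t_n))."""
    carbons = sorted(alkane_rts)
    times = [alkane_rts[c] for c in carbons]
    if len(carbons) < 2:
        raise ValueError("need at least two alkane anchors")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("alkane retention times must be strictly increasing")
    if rt < times[0] or rt > times[-1]:
        raise RetentionRangeError(
            f"rt {rt} outside alkane range [{times[0]}, {times[-1]}]"
        )
    for (c1, t1), (c2, t2) in zip(
        zip(carbons, times), zip(carbons[1:], times[1:])
    ):
        if t1 <= rt <= t2:
            return 100.0 * (c1 + (c2 - c1) * (rt - t1) / (t2 - t1))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _species_from_long(df: pd.DataFrame) -> list[VOCSpecies]:
    species = []
    for voc_id, rows in df.groupby("voc_id", sort=False):
        mzs = tuple(sorted(set(int(m) for m in rows["mz"])))
        species.append(
            VOCSpecies(
                voc_id=str(voc_id),
                name=str(rows["name"].iloc[0]),
                cas_number=str(rows["cas"].iloc[0]) if pd.notna(rows["cas"].iloc[0]) else "",
                retention_time=float(rows["retention_time_min"].iloc[0]),
                fragment_mzs=mzs,
            )
        )
    return species


def read_peak_table(
    path: str | Path,
    format: str = "long",
    detection_floor: float = 0.0,
) -> PeakTable:
    """Read a peak table.

    Long format: TSV with columns ``subject_id, group, voc_id, name, cas,
    retention_time_min, mz, fragment_area, tic_area``.  Missing
    (subject, voc) cells are zero-filled; subject order follows first
    appearance in the file.  Areas below ``detection_floor`` are zeroed.
    """
    path = Path(path)
    if format == "wide":
        return _read_wide(path, detection_floor)
    if format != "long":
        raise ValueError("format must be 'long' or 'wide'")
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str, "voc_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"peak table missing columns: {missing}")
    if df.empty:
        raise EmptyTableError(f"{path}: no data rows")
    dup = df.duplicated(subset=["subject_id", "voc_id", "mz"])
    if dup.any():
        first = df[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record for subject {first['subject_id']!r}, "
            f"voc {first['voc_id']!r}, m/z {first['mz']}"
        )
    subjects = df[["subject_id", "group"]].drop_duplicates("subject_id")
    species = _species_from_long(df)
    long = df[["subject_id", "voc_id", "mz", "fragment_area", "tic_area"]].copy()
    long["mz"] = long["mz"].astype(int)
    if detection_floor > 0:
        long.loc[long["fragment_area"] < detection_floor, "fragment_area"] = 0.0
        long.loc[long["tic_area"] < detection_floor, "tic_area"] = 0.0
    long = _densify(long, subjects["subject_id"], species)
    return PeakTable(species=species, subjects=subjects, measurements=long)


def _densify(
    long: pd.DataFrame, subject_ids: pd.Series, species: list[VOCSpecies]
) -> pd.DataFrame:
    """Ensure every (subject, voc, fragment) cell exists, zero-filling gaps."""
    full = pd.MultiIndex.from_tuples(
        [
            (sid, sp.voc_id, mz)
            for sid in subject_ids
            for sp in species
            for mz in sp.fragment_mzs
        ],
        names=["subject_id", "voc_id", "mz"],
    )
    dense = (
        long.set_index(["subject_id", "voc_id", "mz"])
        .reindex(full)
        .fillna({"fragment_area": 0.0, "tic_area": 0.0})
        .reset_index()
    )
    return dense


def write_peak_table(table: PeakTable, path: str | Path, format: str = "long") -> None:
    """Write a peak table; the long form round-trips the data grid exactly
    (areas rendered with ``repr`` precision)."""
    path = Path(path)
    if format == "wide":
        _write_wide(table, path)
        return
    if format != "long":
        raise ValueError("format must be 'long' or 'wide'")
    sp_map = table.species_by_id
    group_map = dict(zip(table.subjects["subject_id"], table.subjects["group"]))
    df = table.measurements.copy()
    df["group"] = df["subject_id"].map(group_map)
    df["name"] = df["voc_id"].map(lambda v: sp_map[v].name)
    df["cas"] = df["voc_id"].map(lambda v: sp_map[v].cas_number)
    df["retention_time_min"] = df["voc_id"].map(lambda v: sp_map[v].retention_time)
    df = df[PEAK_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def _write_wide(table: PeakTable, path: Path) -> None:
    cols: dict[str, pd.Series] = {}
    for sp in table.species:
        mz = sp.quantifier_mz or select_quantifier_ion(sp, table)
        cols[f"{sp.voc_id}:{mz}"] = table.fragment_areas(sp.voc_id, mz)
        cols[f"{sp.voc_id}:TIC"] = table.tic_areas(sp.voc_id)
    wide = pd.DataFrame(cols, index=pd.Index(table.subject_ids, name="subject_id"))
    wide.insert(
        0,
        "group",
        [dict(zip(table.subjects["subject_id"], table.subjects["group"]))[s]
         for s in table.subject_ids],
    )
    wide.to_csv(path, sep="\t")


def _read_wide(path: Path, detection_floor: float) -> PeakTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise PeakTableFormatError("wide table needs subject_id and group columns")
    if df.empty:
        raise EmptyTableError(f"{path}: no data rows")
    voc_cols = [c for c in df.columns if ":" in c and not c.endswith(":TIC")]
    if not voc_cols:
        raise PeakTableFormatError("wide table has no voc:mz columns")
    species = []
    records = []
    for col in voc_cols:
        voc_id, mz_s = col.rsplit(":", 1)
        mz = int(mz_s)
        # wide files carry no retention time; use a placeholder ordering
        species.append(
            VOCSpecies(
                voc_id=voc_id,
                name=voc_id,
                retention_time=float(len(species) + 1),
                fragment_mzs=(mz,),
                quantifier_mz=mz,
            )
        )
        tic_col = f"{voc_id}:TIC"
        for _, row in df.iterrows():
            area = float(row[col])
            tic = float(row[tic_col]) if tic_col in df.columns else 0.0
            if area < detection_floor:
                area = 0.0
            if tic < detection_floor:
                tic = 0.0
            records.append((row["subject_id"], voc_id, mz, area, tic))
    long = pd.DataFrame(
        records, columns=["subject_id", "voc_id", "mz", "fragment_area", "tic_area"]
    )
    subjects = df[["subject_id", "group"]]
    return PeakTable(species=species, subjects=subjects, measurements=long)


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"cohort table missing columns: {missing}")
    if df.empty:
        raise EmptyTableError(f"{path}: no data rows")
    return CohortTable(data=df)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.data[COHORT_COLUMNS].to_csv(path, index=False)
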