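"""Differential-VOC nomination cascade.

Candidate species are screened on the TIC channel with three rules —
(1) group-mean TIC area above a floor, (2) detection in a minimum number
of subjects, (3) positive/control fold outside a window — and the
survivors are then tested on their quantifier-ion areas with the exact
Mann-Whitney U test.  Significance for nomination uses the one-tailed p
(the published six-biomarker panel includes species starred only in the
one-tailed column); both p-values are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import stats_core
from .exceptions import ConfigError
from .peak_model import GroupSummary, PeakTable, VOCSpecies, group_summary, select_quantifier_ion

__all__ = [
    "FilterCriteria",
    "FilterResult",
    "DifferentialVOC",
    "BiomarkerSet",
    "apply_tic_filters",
    "test_candidates",
    "nominate_biomarkers",
    "extract_differential",
]

FILTER_AREA = "area"
FILTER_DETECTION = "detection"
FILTER_FOLD = "fold"
ALL_FILTERS = frozenset({FILTER_AREA, FILTER_DETECTION, FILTER_FOLD})


@dataclass(frozen=True)
class FilterCriteria:
    min_tic_area: float = 10_000.0
    min_detected_subjects: int = 3
    up_fold: float = 1.5
    down_fold: float = 0.7
    significance_alpha: float = 0.05
    # interpretation switches (documented choices, not tuning knobs)
    area_mode: str = "group_mean"  # or "any_sample"
    detection_scope: str = "either_group"  # or "pooled"

    def __post_init__(self) -> None:
        if self.min_tic_area <= 0:
            raise ConfigError("min_tic_area must be > 0")
        if not (self.up_fold > 1.0 > self.down_fold > 0.0):
            raise ConfigError("need up_fold > 1 > down_fold > 0")
        if not 0.0 < self.significance_alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.area_mode not in ("group_mean", "any_sample"):
            raise ConfigError("area_mode must be 'group_mean' or 'any_sample'")
        if self.detection_scope not in ("either_group", "pooled"):
            raise ConfigError("detection_scope must be 'either_group' or 'pooled'")


@dataclass(frozen=True)
class FilterResult:
    passed: tuple[str, ...]  # voc_ids passing all three rules, table order
    flags: dict[str, frozenset[str]]  # per-voc set of rules passed


@dataclass(frozen=True)
class DifferentialVOC:
    species: VOCSpecies
    quantifier_mz: int
    summary: GroupSummary  # on quantifier-ion areas
    mw: stats_core.MWTestResult
    passed_filters: frozenset[str]
    significant: bool

    @property
    def voc_id(self) -> str:
        return self.species.voc_id

    @property
    def fold(self) -> float:
        return self.summary.fold


@dataclass(frozen=True)
class BiomarkerSet:
    nominated: tuple[DifferentialVOC, ...]
    significant: tuple[DifferentialVOC, ...]
    combination_eligible: tuple[DifferentialVOC, ...]

    def ids(self, which: str = "nominated") -> tuple[str, ...]:
        return tuple(d.voc_id for d in getattr(self, which))


def apply_tic_filters(table: PeakTable, criteria: FilterCriteria | None = None) -> FilterResult:
    """Screen every species on the TIC channel with the three rules."""
    criteria = criteria or FilterCriteria()
    flags: dict[str, frozenset[str]] = {}
    passed: list[str] = []
    for sp in table.species:
        tic = table.tic_areas(sp.voc_id)
        by_group = table.group_values(tic)
        got: set[str] = set()

        if criteria.area_mode == "group_mean":
            area_ok = any(v.mean() > criteria.min_tic_area for v in by_group.values())
        else:
            area_ok = any(v.max() > criteria.min_tic_area for v in by_group.values())
        if area_ok:
            got.add(FILTER_AREA)

        det = {g: int((v > 0).sum()) for g, v in by_group.items()}
        if criteria.detection_scope == "either_group":
            det_ok = any(c >= criteria.min_detected_subjects for c in det.values())
        else:
            det_ok = sum(det.values()) >= criteria.min_detected_subjects
        if det_ok:
            got.add(FILTER_DETECTION)

        mean_c = by_group["control"].mean()
        mean_p = by_group["positive"].mean()
        if mean_c > 0:
            fold = mean_p / mean_c
            fold_ok = fold > criteria.up_fold or fold < criteria.down_fold
        else:
            fold_ok = mean_p > 0  # infinite increase
        if fold_ok:
            got.add(FILTER_FOLD)

        flags[sp.voc_id] = frozenset(got)
        if got == ALL_FILTERS:
            passed.append(sp.voc_id)
    return FilterResult(passed=tuple(passed), flags=flags)


def test_candidates(
    table: PeakTable,
    candidates: tuple[str, ...] | list[str],
    criteria: FilterCriteria | None = None,
    flags: dict[str, frozenset[str]] | None = None,
) -> list[DifferentialVOC]:
    """Quantifier-ion Mann-Whitney testing of the filter survivors."""
    criteria = criteria or FilterCriteria()
    species_by_id = table.species_by_id
    unknown = [c for c in candidates if c not in species_by_id]
    if unknown:
        raise KeyError(f"candidates not in table: {unknown}")
    out = []
    for voc_id in candidates:
        sp = species_by_id[voc_id]
        mz = sp.quantifier_mz or select_quantifier_ion(sp, table)
        values = table.fragment_areas(voc_id, mz)
        by_group = table.group_values(values)
        summary = group_summary(by_group, voc_id)
        mw = stats_core.mann_whitney(by_group["positive"], by_group["control"])
        passed = (flags or {}).get(voc_id, ALL_FILTERS)
        significant = passed == ALL_FILTERS and mw.p_one_tailed <= criteria.significance_alpha
        out.append(
            DifferentialVOC(
                species=sp,
                quantifier_mz=mz,
                summary=summary,
                mw=mw,
                passed_filters=frozenset(passed),
                significant=significant,
            )
        )
    return out


def nominate_biomarkers(diffs: list[DifferentialVOC]) -> BiomarkerSet:
    """Partition tested VOCs into nominated / significant /
    combination-eligible (significant and confirmed against a commercial
    standard)."""
    nominated = tuple(diffs)
    significant = tuple(d for d in diffs if d.significant)
    eligible = tuple(d for d in significant if d.species.confirmed_standard)
    return BiomarkerSet(nominated, significant, eligible)


def extract_differential(
    table: PeakTable, criteria: FilterCriteria | None = None
) -> BiomarkerSet:
    """Full cascade: TIC filters, quantifier testing, nomination."""
    criteria = criteria or FilterCriteria()
    res = apply_tic_filters(table, criteria)
    diffs = test_candidates(table, res.passed, criteria, res.flags)
    return nominate_biomarkers(diffs)
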