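"""Seeded synthetic peak-table and cohort generator.

The raw per-subject data of the pilot cohort are not deposited, so this
module generates subject x VOC tables carrying the statistical structure
the downstream analysis assumes, calibrated to the published summary
tables (:mod:`vocscreen.calibration`):

* 157 VOC species over 9 + 9 subjects; 20 named species with planted
  group effects matching the published quantifier-area means/SEMs, the
  rest as no-effect background;
* log-normal per-subject areas (positive, right-skewed); three heavily
  dispersed species use a bulk + single-outlier mixture because their
  published SEM ~ mean signature together with a non-significant rank
  test cannot arise from any moment-matched two-parameter lognormal;
* a TIC channel with planted group folds so the named species are
  recoverable by the TIC screening cascade (the TIC aggregates all
  fragments and its group contrast need not match the quantifier ion's);
* complete texanol group separation and a planted texanol / texanol-isomer
  Gaussian-copula correlation in the positive group;
* detection dropout in a few background species;
* cohort questionnaire and urine-chemistry scores matching the published
  group means/SEMs, clamped to their documented ranges.

In small-cohort mode (group sizes <= ``small_cohort_max_n``) the
generator additionally reproduces the *realized* rank-test outcomes of
the published table by redrawing a species until its exact one-tailed
Mann-Whitney p falls on the published side of alpha, the same
redraw-until device used for texanol separation.  At larger sizes both
devices are disabled so the unconditioned marginals can be checked for
parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri as _ndtri

from . import calibration as cal
from .exceptions import ConfigError
from .peak_model import COHORT_COLUMNS, CohortTable, PeakTable, VOCSpecies
from .stats_core import mann_whitney

__all__ = ["EffectSpec", "GeneratorConfig", "default_calibration", "generate",
           "sample_species_areas", "sample_copula_pair"]


@dataclass(frozen=True)
class EffectSpec:
    """Planted group effect for one named VOC species.

    ``sem_*`` are standard errors from a calibration cohort of ``sem_n``
    subjects per group; per-subject SDs are ``sem * sqrt(sem_n)``.
    ``tic_fold`` is the planted positive/control ratio of TIC means
    (default: the quantifier-area mean ratio).  ``outlier_group`` marks a
    group whose dispersion is dominated by a single extreme subject and is
    modelled as a bulk + outlier mixture.  ``planted_significant`` is the
    rank-test outcome to emulate in small-cohort mode (None = free).
    """

    voc_id: str
    mean_control: float
    sem_control: float
    mean_positive: float
    sem_positive: float
    detect_prob_control: float = 1.0
    detect_prob_positive: float = 1.0
    force_separation: bool = False
    tic_scale: float = 3.0
    tic_fold: float | None = None
    planted_significant: bool | None = None
    outlier_group: str | None = None
    outlier_bulk_fold: float = 1.0
    sem_n: int = cal.CALIBRATION_N

    def __post_init__(self) -> None:
        if self.detect_prob_control > 0 and self.mean_control <= 0:
            raise ConfigError(f"{self.voc_id}: control mean must be > 0")
        if self.detect_prob_positive > 0 and self.mean_positive <= 0:
            raise ConfigError(f"{self.voc_id}: positive mean must be > 0")
        for p in (self.detect_prob_control, self.detect_prob_positive):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("detection probabilities must be in [0, 1]")
        if self.outlier_group not in (None, "control", "positive"):
            raise ConfigError("outlier_group must be None, 'control' or 'positive'")

    @property
    def mean_ratio(self) -> float:
        return self.mean_positive / self.mean_control

    @property
    def effective_tic_fold(self) -> float:
        return self.tic_fold if self.tic_fold is not None else self.mean_ratio


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_positive: int = 9
    n_control: int = 9
    n_species: int = cal.N_SPECIES_TOTAL
    effects: tuple[EffectSpec, ...] = ()
    copula_rho: float = cal.TEXANOL_ISOMER_RHO
    copula_members: tuple[str, str] = cal.COMBINED_TWO
    background_mean_range: tuple[float, float] = (1e3, 1e6)
    background_cv: float = 0.2
    tic_scale: float = 3.0
    tic_cv: float = 0.15
    dropout_species: int = 3
    dropout_keep: int = 2
    cohort_calibration: tuple[cal.CohortVariableRow, ...] = cal.COHORT_CALIBRATION
    significance_alpha: float = 0.05
    small_cohort_max_n: int = 20
    max_redraws: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is required (reproducibility contract)")
        if self.n_species < len(self.effects):
            raise ConfigError("n_species must cover all named effects")
        if not 0.0 <= self.copula_rho < 1.0:
            raise ConfigError("copula_rho must be in [0, 1)")

    @property
    def small_cohort(self) -> bool:
        return max(self.n_positive, self.n_control) <= self.small_cohort_max_n

    # -- generator bookkeeping -------------------------------------------

    def planted_differential_ids(self) -> tuple[str, ...]:
        """Species planted to pass the TIC screening cascade (area floor,
        detection, fold window)."""
        out = []
        for e in self.effects:
            tic_c = e.tic_scale * e.mean_control
            tic_p = tic_c * e.effective_tic_fold
            if max(tic_c, tic_p) <= 10_000:
                continue
            fold = e.effective_tic_fold
            if not (fold > 1.5 or fold < 0.7):
                continue
            out.append(e.voc_id)
        return tuple(out)

    def planted_significant_ids(self) -> tuple[str, ...]:
        return tuple(e.voc_id for e in self.effects if e.planted_significant)


def _planted_tic_fold(ratio: float) -> float:
    # Within (0.5, 2.0) the quantifier ratio is too close to the screening
    # boundary to stand in for a reliably differential TIC; plant a clear
    # contrast in the same direction instead.
    if 0.5 < ratio < 2.0:
        return 3.0 if ratio > 1.0 else 1.0 / 3.0
    return ratio


_OUTLIER_ROWS = {
    # voc_id -> (group with the dominating subject, bulk fold vs other group)
    "allyl_itc": ("control", 1.0),
    "butene_itc": ("positive", 1.0),
    "dichlorophenol": ("positive", 2.0),
}


def default_calibration(seed: int = 2015) -> GeneratorConfig:
    """Generator configuration calibrated to the published pilot-cohort
    tables; the packaged default fixture uses seed 2015."""
    effects = []
    for row in cal.VOC_EFFECTS:
        outlier_group, bulk_fold = _OUTLIER_ROWS.get(row.voc_id, (None, 1.0))
        effects.append(
            EffectSpec(
                voc_id=row.voc_id,
                mean_control=row.mean_control,
                sem_control=row.sem_control,
                mean_positive=row.mean_positive,
                sem_positive=row.sem_positive,
                force_separation=(row.voc_id == "texanol"),
                tic_fold=_planted_tic_fold(row.mean_positive / row.mean_control),
                planted_significant=row.significant,
                outlier_group=outlier_group,
                outlier_bulk_fold=bulk_fold,
            )
        )
    return GeneratorConfig(seed=seed, effects=tuple(effects))


# ---------------------------------------------------------------------------
# Sampling kernels
# ---------------------------------------------------------------------------


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _ln_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_lognormal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    stratified: bool = False,
) -> np.ndarray:
    """Moment-matched lognormal draws.

    For large synthetic cohorts (``stratified=True``) the draws use
    stratified inverse-CDF sampling — one uniform per equal-probability
    stratum, shuffled — so that empirical group means converge to the
    configured means far faster than iid sampling allows for
    heavy-tailed species, while the marginal distribution is unchanged.
    """
    if sd <= 0:
        return np.full(n, mean)
    mu, sigma = _ln_params(mean, sd)
    if stratified:
        u = (np.arange(n) + rng.random(n)) / n
        vals = np.exp(mu + sigma * _ndtri(u))
        rng.shuffle(vals)
        return vals
    return np.exp(rng.normal(mu, sigma, size=n))


def _group_params(spec: EffectSpec, group: str) -> tuple[float, float]:
    if group == "control":
        return spec.mean_control, spec.sem_control * np.sqrt(spec.sem_n)
    return spec.mean_positive, spec.sem_positive * np.sqrt(spec.sem_n)


def _draw_group(
    spec: EffectSpec,
    group: str,
    n: int,
    rng: np.random.Generator,
    stratified: bool = False,
) -> np.ndarray:
    mean, sd = _group_params(spec, group)
    if spec.outlier_group == group:
        other = "positive" if group == "control" else "control"
        o_mean, o_sd = _group_params(spec, other)
        bulk_mean = o_mean * spec.outlier_bulk_fold
        bulk_sd = bulk_mean * (o_sd / o_mean)
        n_out = max(1, round(n / spec.sem_n))
        m1 = (mean * n - bulk_mean * (n - n_out)) / n_out
        if m1 > bulk_mean:
            vals = _draw_lognormal(rng, bulk_mean, bulk_sd, n, stratified)
            idx = rng.choice(n, size=n_out, replace=False)
            vals[idx] = _draw_lognormal(rng, m1, 0.1 * m1, n_out, stratified)
            return vals
    return _draw_lognormal(rng, mean, sd, n, stratified)


def _apply_dropout(vals: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    if prob >= 1.0:
        return vals
    keep = rng.random(vals.size) < prob
    return np.where(keep, vals, 0.0)


def sample_species_areas(
    spec: EffectSpec,
    n_control: int,
    n_positive: int,
    rng: np.random.Generator,
    *,
    small_cohort: bool = False,
    alpha: float = 0.05,
    max_redraws: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw quantifier-ion areas for one species: (control, positive).

    In small-cohort mode the draw is repeated until the planted
    separation / significance conditions hold (see module docstring).
    """
    attempts = max_redraws if small_cohort else 1
    ctrl = pos = None
    for _ in range(attempts):
        ctrl = _draw_group(spec, "control", n_control, rng, stratified=not small_cohort)
        pos = _draw_group(spec, "positive", n_positive, rng, stratified=not small_cohort)
        if not small_cohort or _conditions_met(spec, ctrl, pos, alpha):
            return ctrl, pos
    return ctrl, _force_separation_shift(spec, ctrl, pos)


def _conditions_met(spec: EffectSpec, ctrl: np.ndarray, pos: np.ndarray, alpha: float) -> bool:
    if spec.force_separation and pos.min() <= ctrl.max():
        return False
    if spec.planted_significant is not None:
        p1 = mann_whitney(pos, ctrl).p_one_tailed
        if (p1 <= alpha) != spec.planted_significant:
            return False
    return True


def _force_separation_shift(spec: EffectSpec, ctrl: np.ndarray, pos: np.ndarray) -> np.ndarray:
    if spec.force_separation and pos.min() <= ctrl.max():
        warnings.warn(
            f"{spec.voc_id}: separation not reached by redraw; shifting positives",
            stacklevel=2,
        )
        pos = pos + (ctrl.max() - pos.min()) + 0.01 * ctrl.max()
    return pos


def sample_copula_pair(
    spec_a: EffectSpec,
    spec_b: EffectSpec,
    rho: float,
    n_control: int,
    n_positive: int,
    rng: np.random.Generator,
    *,
    small_cohort: bool = False,
    alpha: float = 0.05,
    max_redraws: int = 500,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Draw two species jointly: a Gaussian copula with correlation ``rho``
    links their positive-group draws; controls are independent."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    def draw() -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
        ctrl_a = _draw_group(spec_a, "control", n_control, rng, stratified=not small_cohort)
        ctrl_b = _draw_group(spec_b, "control", n_control, rng, stratified=not small_cohort)
        z = chol @ rng.normal(size=(2, n_positive))
        pos = []
        for spec, zi in zip((spec_a, spec_b), z):
            mean, sd = _group_params(spec, "positive")
            mu, sigma = _ln_params(mean, sd)
            pos.append(np.exp(mu + sigma * zi))
        return (ctrl_a, pos[0]), (ctrl_b, pos[1])

    attempts = max_redraws if small_cohort else 1
    result = None
    for _ in range(attempts):
        result = draw()
        (ca, pa), (cb, pb) = result
        if not small_cohort or (
            _conditions_met(spec_a, ca, pa, alpha)
            and _conditions_met(spec_b, cb, pb, alpha)
        ):
            return result
    (ca, pa), (cb, pb) = result
    return (ca, _force_separation_shift(spec_a, ca, pa)), (
        cb,
        _force_separation_shift(spec_b, cb, pb),
    )


# ---------------------------------------------------------------------------
# Species metadata (seed-independent)
# ---------------------------------------------------------------------------


def _background_species(index: int) -> VOCSpecies:
    """Deterministic metadata for background species number ``index``
    (21-based to follow the named rows)."""
    base = 35 + (index * 53) % 180
    return VOCSpecies(
        voc_id=f"bg_{index:03d}",
        name=f"background VOC {index}",
        retention_time=5.0 + (index - 21) * 0.24,
        fragment_mzs=(base, base + 29, base + 57),
        quantifier_mz=base,
    )


def _effect_species(row: cal.VOCEffectRow) -> VOCSpecies:
    return VOCSpecies(
        voc_id=row.voc_id,
        name=row.name,
        cas_number=row.cas_number,
        chemical_class=row.chemical_class,
        retention_time=row.retention_time,
        fragment_mzs=row.fragment_mzs,
        quantifier_mz=row.quantifier_mz,
        confirmed_standard=row.confirmed_standard,
    )


_FRAGMENT_FRACTIONS = (0.55, 0.28)  # secondary fragment areas vs quantifier


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig) -> tuple[PeakTable, CohortTable]:
    """Generate a (PeakTable, CohortTable) pair; deterministic per seed.

    Randomness flows through named substreams of the single config seed
    (one substream per species plus one each for dropout and cohort), so
    changing one stage never perturbs another's draws.
    """
    if config.seed is None:  # pragma: no cover - guarded in __post_init__
        raise ConfigError("a seed is required")
    n_c, n_p = config.n_control, config.n_positive
    ctrl_ids = [f"C{i + 1:02d}" for i in range(n_c)]
    pos_ids = [f"P{i + 1:02d}" for i in range(n_p)]
    subjects = pd.DataFrame(
        {
            "subject_id": pos_ids + ctrl_ids,
            "group": ["positive"] * n_p + ["control"] * n_c,
        }
    )

    effect_rows = {r.voc_id: r for r in cal.VOC_EFFECTS}
    species: list[VOCSpecies] = []
    for e in config.effects:
        if e.voc_id in effect_rows:
            species.append(_effect_species(effect_rows[e.voc_id]))
        else:
            species.append(
                VOCSpecies(
                    voc_id=e.voc_id,
                    name=e.voc_id,
                    retention_time=10.0,
                    fragment_mzs=(60, 73, 87),
                    quantifier_mz=60,
                )
            )
    n_bg = config.n_species - len(config.effects)
    species += [_background_species(21 + i) for i in range(n_bg)]

    specs_by_id = {e.voc_id: e for e in config.effects}
    areas: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # copula-linked pair drawn jointly
    a_id, b_id = config.copula_members
    if a_id in specs_by_id and b_id in specs_by_id:
        idx = [i for i, sp in enumerate(species) if sp.voc_id in (a_id, b_id)]
        rng = _stream(config.seed, 1, min(idx))
        (areas[a_id], areas[b_id]) = sample_copula_pair(
            specs_by_id[a_id],
            specs_by_id[b_id],
            config.copula_rho,
            n_c,
            n_p,
            rng,
            small_cohort=config.small_cohort,
            alpha=config.significance_alpha,
            max_redraws=config.max_redraws,
        )

    bg_means: dict[str, float] = {}
    for i, sp in enumerate(species):
        if sp.voc_id in areas:
            continue
        rng = _stream(config.seed, 1, i)
        if sp.voc_id in specs_by_id:
            areas[sp.voc_id] = sample_species_areas(
                specs_by_id[sp.voc_id],
                n_c,
                n_p,
                rng,
                small_cohort=config.small_cohort,
                alpha=config.significance_alpha,
                max_redraws=config.max_redraws,
            )
        else:
            lo, hi = config.background_mean_range
            mean = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            bg_means[sp.voc_id] = mean
            sd = config.background_cv * mean
            areas[sp.voc_id] = (
                _draw_lognormal(rng, mean, sd, n_c),
                _draw_lognormal(rng, mean, sd, n_p),
            )

    # detection dropout on effect specs with detect_prob < 1
    for voc_id, e in specs_by_id.items():
        rng = _stream(config.seed, 2, list(specs_by_id).index(voc_id))
        ctrl, pos = areas[voc_id]
        areas[voc_id] = (
            _apply_dropout(ctrl, e.detect_prob_control, rng),
            _apply_dropout(pos, e.detect_prob_positive, rng),
        )

    # dropout: a few background species detected in only a couple of subjects
    rng_drop = _stream(config.seed, 3)
    bg_ids = [sp.voc_id for sp in species if sp.voc_id in bg_means]
    detected_mask: dict[str, np.ndarray] = {}
    if bg_ids and config.dropout_species > 0:
        chosen = rng_drop.choice(
            len(bg_ids), size=min(config.dropout_species, len(bg_ids)), replace=False
        )
        for ci in chosen:
            voc_id = bg_ids[ci]
            keep = rng_drop.choice(n_c + n_p, size=config.dropout_keep, replace=False)
            mask = np.zeros(n_c + n_p, dtype=bool)
            mask[keep] = True
            detected_mask[voc_id] = mask
            ctrl, pos = areas[voc_id]
            areas[voc_id] = (
                np.where(mask[n_p:], ctrl, 0.0),  # subjects ordered pos then ctrl
                np.where(mask[:n_p], pos, 0.0),
            )

    # TIC channel
    rng_tic = _stream(config.seed, 4)
    s_tic = np.sqrt(np.log1p(config.tic_cv**2))
    tic: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sp in species:
        if sp.voc_id in specs_by_id:
            e = specs_by_id[sp.voc_id]
            base_c = e.tic_scale * e.mean_control
            base_p = base_c * e.effective_tic_fold
        else:
            base_c = base_p = config.tic_scale * bg_means[sp.voc_id]
        noise_c = np.exp(rng_tic.normal(-s_tic**2 / 2, s_tic, n_c))
        noise_p = np.exp(rng_tic.normal(-s_tic**2 / 2, s_tic, n_p))
        ctrl_area, pos_area = areas[sp.voc_id]
        tic_c = np.where(ctrl_area > 0, base_c * noise_c, 0.0)
        tic_p = np.where(pos_area > 0, base_p * noise_p, 0.0)
        tic[sp.voc_id] = (tic_c, tic_p)

    # assemble the long measurement frame
    frames = []
    for sp in species:
        ctrl_area, pos_area = areas[sp.voc_id]
        quant = np.concatenate([pos_area, ctrl_area])  # subject order: pos, ctrl
        tic_c, tic_p = tic[sp.voc_id]
        tic_all = np.concatenate([tic_p, tic_c])
        frag_mzs = [sp.quantifier_mz] + [m for m in sp.fragment_mzs if m != sp.quantifier_mz]
        for k, mz in enumerate(frag_mzs):
            frac = 1.0 if k == 0 else _FRAGMENT_FRACTIONS[(k - 1) % len(_FRAGMENT_FRACTIONS)]
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects["subject_id"],
                        "voc_id": sp.voc_id,
                        "mz": mz,
                        "fragment_area": quant * frac,
                        "tic_area": tic_all,
                    }
                )
            )
    measurements = pd.concat(frames, ignore_index=True)
    table = PeakTable(species=species, subjects=subjects, measurements=measurements)

    cohort = _generate_cohort(config, pos_ids, ctrl_ids)
    return table, cohort


def _generate_cohort(
    config: GeneratorConfig, pos_ids: list[str], ctrl_ids: list[str]
) -> CohortTable:
    rng = _stream(config.seed, 5)
    n_p, n_c = len(pos_ids), len(ctrl_ids)
    if n_p == 9 and n_c == 9:
        ages_p, ages_c = list(cal.POSITIVE_AGES), list(cal.CONTROL_AGES)
        sex_p = sex_c = list(cal.SEXES)
    else:
        ages_p = list(rng.integers(66, 89, size=n_p))
        ages_c = list(rng.integers(66, 89, size=n_c))
        sex_p = ["M" if i % 2 == 0 else "F" for i in range(n_p)]
        sex_c = ["M" if i % 2 == 0 else "F" for i in range(n_c)]

    data: dict[str, list] = {
        "subject_id": pos_ids + ctrl_ids,
        "group": ["positive"] * n_p + ["control"] * n_c,
        "sex": sex_p + sex_c,
        "age": ages_p + ages_c,
    }
    for row in config.cohort_calibration:
        sd_p = row.sem_positive * np.sqrt(cal.CALIBRATION_N)
        vals_p = rng.normal(row.mean_positive, sd_p, size=n_p)
        if row.mean_control is None:
            vals_c = np.full(n_c, np.nan)
        else:
            sd_c = row.sem_control * np.sqrt(cal.CALIBRATION_N)
            vals_c = rng.normal(row.mean_control, sd_c, size=n_c)
        vals = np.concatenate([vals_p, vals_c])
        vals = np.clip(vals, row.low, row.high)
        if row.integer:
            with np.errstate(invalid="ignore"):
                vals = np.where(np.isnan(vals), np.nan, np.round(vals))
        else:
            vals = np.round(vals, 3)
        data[row.variable] = list(vals)
    df = pd.DataFrame(data)[COHORT_COLUMNS]
    return CohortTable(data=df)
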