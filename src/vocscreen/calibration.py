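"""Calibration constants describing the pilot cohort that the simulator
emulates.

The original study compared urinary headspace VOCs of 9 community-dwelling
elderly subjects with late-life major depressive disorder (MDD) and/or
agoraphobia against 9 age/sex-matched controls.  Its published summary
tables — per-VOC group means and SEMs of quantifier-ion areas, rank-test
p-values, cohort questionnaire scores, and the six-VOC quadratic
discriminant — are the only quantitative record of that cohort, so they
serve here as the generator's calibration and as reference fixtures for
structural tests.

All SEMs refer to groups of CALIBRATION_N = 9 subjects; per-subject SDs
are recovered as SEM * sqrt(9).
"""

from __future__ import annotations

from dataclasses import dataclass

CALIBRATION_N = 9

N_SPECIES_TOTAL = 157  # VOC species detected in the study
N_BACKGROUND = N_SPECIES_TOTAL - 20


@dataclass(frozen=True)
class VOCEffectRow:
    """One row of the published differential-VOC table."""

    voc_id: str
    name: str
    cas_number: str
    chemical_class: str
    retention_time: float  # minutes
    fragment_mzs: tuple[int, ...]
    quantifier_mz: int
    mean_control: float
    sem_control: float
    mean_positive: float
    sem_positive: float
    p_two_tailed: float
    p_one_tailed: float
    confirmed_standard: bool
    significant: bool  # printed one-tailed p <= 0.05


# The 20 differential VOC candidates (rows in study order).  Rows 1-16 were
# nominated by manual TIC comparison, rows 17-20 by automated feature
# extraction; both routes end in the same quantifier-area rank test.
VOC_EFFECTS: tuple[VOCEffectRow, ...] = (
    VOCEffectRow("acetyl_tetrazole", "2-acetyl-2H-tetrazole", "51410-11-8",
                 "Diarylethers", 15.97, (42, 43), 43,
                 896_619, 108_935, 1_188_273, 137_696, 0.0939, 0.0470, False, True),
    VOCEffectRow("octanedione", "2,3-Octanedione", "585-25-1",
                 "Alpha-diketone", 19.46, (43, 57, 71), 43,
                 17_480, 2_462, 31_273, 8_861, 0.2973, 0.1487, False, False),
    VOCEffectRow("allyl_itc", "Allyl isothiocyanate", "57-06-7",
                 "Organosulfur/isothiocyanate", 20.50, (41, 72, 99), 99,
                 667_199, 554_308, 171_145, 54_542, 0.9999, 0.5000, False, False),
    VOCEffectRow("ditertbutylbenzene", "Benzene, 1,3-bis(1,1-dimethylethyl)-",
                 "1014-60-4", "Benzenoids", 22.53, (41, 57, 175), 175,
                 32_371, 15_202, 16_238, 2_147, 0.3865, 0.1933, False, False),
    VOCEffectRow("acetic_acid", "Acetic acid", "64-19-7",
                 "Carboxylic acids and derivatives", 23.26, (43, 45, 60), 43,
                 343_894, 85_633, 385_236, 207_645, 0.2224, 0.1112, False, False),
    VOCEffectRow("butene_itc", "1-Butene 4-isothiocyanate", "3386-97-8",
                 "Organosulfur/isothiocyanate", 23.39, (55, 72, 113), 113,
                 29_243, 14_845, 1_306_697, 1_191_445, 0.1615, 0.0807, True, False),
    VOCEffectRow("dmso", "Dimethyl sulfoxide", "67-68-5",
                 "Sulfoxides", 25.99, (45, 63, 78), 63,
                 32_197, 6_114, 73_214, 21_273, 0.1135, 0.0567, True, False),
    VOCEffectRow("menthol", "Menthol", "15356-70-4",
                 "Prenol lipids", 28.17, (71, 81, 95), 71,
                 151_744, 59_924, 64_621, 23_668, 0.7304, 0.3652, False, False),
    VOCEffectRow("carvone", "(-)-Carvone", "6485-40-1",
                 "Prenol lipids", 30.28, (54, 82, 93), 82,
                 45_357, 30_608, 53_152, 23_399, 0.1903, 0.0951, False, False),
    VOCEffectRow("dimethyl_sulfone", "Dimethyl sulfone", "67-71-0",
                 "Sulfones", 33.89, (79, 94), 79,
                 660_288, 140_962, 1_328_412, 290_284, 0.0770, 0.0385, True, True),
    VOCEffectRow("benzothiazole", "Benzothiazole", "95-16-9",
                 "Benzenoids", 35.05, (82, 108, 135), 135,
                 19_864, 3_788, 17_627, 2_854, 0.7962, 0.3981, False, False),
    VOCEffectRow("phenol", "Phenol", "108-95-2",
                 "Benzenoids", 36.12, (65, 66, 94), 94,
                 43_106, 19_370, 39_801, 14_563, 0.6665, 0.3332, False, False),
    VOCEffectRow("p_cresol", "p-Cresol", "106-44-5",
                 "Benzenoids", 37.62, (77, 107, 108), 107,
                 31_128, 11_066, 65_472, 36_074, 0.4363, 0.2181, False, False),
    VOCEffectRow("methoxy_vinylphenol", "2-Methoxy-4-vinylphenol", "7786-61-0",
                 "Benzenoids", 39.79, (107, 135, 150), 150,
                 81_457, 29_571, 35_448, 10_739, 0.6665, 0.3332, False, False),
    VOCEffectRow("dichlorophenol", "2,5-Dichlorophenol", "583-78-8",
                 "Benzenoids", 39.86, (63, 162, 164), 162,
                 168_307, 57_814, 1_041_674, 587_894, 0.1359, 0.0680, True, False),
    VOCEffectRow("phenethyl_itc", "Phenethyl isothiocyanate", "2257-09-2",
                 "Benzenoids/isothiocyanate", 40.30, (91, 163), 91,
                 31_162, 8_863, 350_507, 179_957, 0.0078, 0.0039, True, True),
    VOCEffectRow("hexanoic_acid", "Hexanoic acid", "142-62-1",
                 "Medium-chain fatty acids", 32.89, (60, 73, 87), 60,
                 429_620, 32_655, 301_160, 30_979, 0.0106, 0.0053, True, True),
    VOCEffectRow("texanol", "2,2,4-trimethyl-1,3-pentanediol 1-monoisobutyrate",
                 "25265-77-4", "Hydrocarbon", 33.41, (56, 71, 89), 71,
                 293_552, 7_765, 355_679, 9_990, 0.0001, 0.0001, True, True),
    VOCEffectRow("texanol_isomer", "2,2,4-trimethyl-1,3-pentanediol 3-monoisobutyrate",
                 "", "Hydrocarbon", 33.70, (43, 71, 83), 71,
                 345_878, 10_438, 409_732, 12_109, 0.004, 0.002, True, True),
    VOCEffectRow("piperidinone", "2-Piperidinone", "675-20-7",
                 "Piperidine", 38.21, (55, 70, 99), 99,
                 107_248, 47_157, 93_972, 43_154, 0.9314, 0.4657, False, False),
)

SIGNIFICANT_VOC_IDS = tuple(r.voc_id for r in VOC_EFFECTS if r.significant)
# Six-feature quadratic discriminant panel (includes the one biomarker that
# lacked a commercial standard and is therefore not combination-eligible).
DISCRIMINANT_FEATURES = SIGNIFICANT_VOC_IDS
COMBINED_THREE = ("dimethyl_sulfone", "phenethyl_itc", "hexanoic_acid")
COMBINED_TWO = ("texanol", "texanol_isomer")
COMBINED_FIVE = COMBINED_THREE + COMBINED_TWO

# Planted texanol / texanol-isomer Pearson correlation in the positive group.
TEXANOL_ISOMER_RHO = 0.8094


@dataclass(frozen=True)
class CohortVariableRow:
    """Published group summary of one cohort variable."""

    variable: str
    mean_control: float | None
    sem_control: float | None
    mean_positive: float
    sem_positive: float
    fold: float | None  # as printed, 2 d.p.
    integer: bool
    low: float
    high: float


COHORT_CALIBRATION: tuple[CohortVariableRow, ...] = (
    CohortVariableRow("kihon_cl", 3.667, 0.943, 7.222, 1.164, 1.97, True, 0, 20),
    CohortVariableRow("tmig_ic", 12.00, 0.527, 11.22, 0.572, 0.94, True, 0, 13),
    CohortVariableRow("jst_ic", 11.33, 1.225, 9.222, 1.331, 0.81, True, 0, 16),
    CohortVariableRow("dskc", 1.000, 0.441, 2.667, 0.289, 2.67, True, 0, 5),
    CohortVariableRow("dskc_self", 0.667, 0.373, 3.556, 0.176, 5.33, True, 0, 5),
    CohortVariableRow("sds", 33.56, 2.615, 40.44, 2.652, 1.21, True, 20, 80),
    # clinician-rated depression severity: cases only (>= 7 by inclusion)
    CohortVariableRow("grid_hamd", None, None, 12.22, 1.526, None, True, 7, 52),
    CohortVariableRow("serum_creatinine", 0.720, 0.049, 0.769, 0.056, 1.07, False, 0.1, 5.0),
    CohortVariableRow("urinary_creatinine", 76.82, 13.65, 79.44, 11.76, 1.03, False, 1.0, 400.0),
    CohortVariableRow("ucreat_per_weight", 1.344, 0.199, 1.564, 0.300, 1.16, False, 0.05, 10.0),
    CohortVariableRow("specific_gravity", 1.014, 0.002, 1.014, 0.001, 1.00, False, 1.000, 1.060),
)

# Matched design: ages (years) and sexes of the two groups.
POSITIVE_AGES = (67, 73, 77, 78, 79, 84, 74, 77, 87)
CONTROL_AGES = (70, 73, 75, 78, 79, 85, 73, 77, 87)
SEXES = ("M", "M", "M", "M", "M", "M", "F", "F", "F")

# ---------------------------------------------------------------------------
# Published six-VOC quadratic discriminant (reference fixture).
# Feature order: 2-acetyl-2H-tetrazole, dimethyl sulfone, phenethyl
# isothiocyanate, hexanoic acid, texanol, texanol isomer.
# ---------------------------------------------------------------------------

REFERENCE_A0 = -4.838e1

REFERENCE_LINEAR = (
    4.832e-05, -3.924e-05, -6.685e-04, 1.356e-04, -3.441e-04, 3.574e-04,
)

# Quadratic block exactly as printed (rounding makes it slightly asymmetric).
REFERENCE_QUADRATIC = (
    (-1.041e-11, 6.300e-12, 5.600e-11, -4.000e-11, 1.905e-10, -2.000e-10),
    (6.336e-12, 1.500e-11, 1.500e-10, 4.700e-11, -3.546e-10, 2.530e-10),
    (5.626e-11, 1.500e-10, 2.700e-09, 5.900e-10, -1.718e-09, 1.020e-09),
    (-4.193e-11, 4.700e-11, 5.900e-10, -7.000e-11, 5.154e-10, -6.600e-10),
    (1.905e-10, -4.000e-10, -2.000e-09, 5.200e-10, -1.099e-09, 1.640e-09),
    (-1.956e-10, 2.500e-10, 1.000e-09, -7.000e-10, 1.641e-09, -1.400e-09),
)

# Per-subject discriminant scores reported for the original cohort
# (positive persons 1-9, control persons 10-18).
REFERENCE_SCORES_POSITIVE = (
    3.031, 76.077, 13.281, 3562.766, 203.738, 616.322, 21.570, 14.522, 4521.694,
)
REFERENCE_SCORES_CONTROL = (
    -12.478, -38.054, -19.532, -4.053, -7.130, -18.572, -13.173, -8.548, -13.075,
)
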