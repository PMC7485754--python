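"""Study configuration: time windows, diagnosis/drug code lists, dose table.

All algorithm constants published for the phenotyping algorithm (the 29–180
day switch-failure window, the Day-15 augmentation rule, the ±30-day
diagnosis window, the 1:4 matching ratio and 0.02 caliper) live here as named
constants so tests can exercise both sides of every boundary.

Durations stated in months by the study protocol are implemented day-exact:
"6 months" = 183 days, "12 months" = 365 days, "24 months" = 730 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import yaml

# --- phenotyping algorithm constants -------------------------------------

#: smallest whole-day gap (new drug start minus regimen start) that makes a
#: non-overlapping drug switch count as a failure of the prior drug
SWITCH_FAIL_MIN_GAP_DAYS = 29
#: largest such gap that still counts as a switch failure
SWITCH_FAIL_MAX_GAP_DAYS = 180
#: earliest day number (regimen start = Day 1) on which adding a drug while
#: the prior drug is still supplied counts as an augmentation failure
AUGMENT_FAIL_MIN_DAY = 15

#: matching defaults
MATCH_RATIO = 4
MATCH_CALIPER = 0.02

# drug classes usable as augmentation agents on top of an antidepressant
AUGMENTATION_CLASSES = frozenset(
    {"anticonvulsant", "antipsychotic", "lithium", "psychostimulant", "thyroid_hormone"}
)
ANTIDEPRESSANT = "antidepressant"


@dataclass(frozen=True)
class StudyWindows:
    """Day-exact study design windows anchored on the index date."""

    index_start: dt.date = dt.date(2013, 1, 1)
    index_end: dt.date = dt.date(2014, 9, 30)
    washout_days: int = 183          # pre-index treatment-free requirement
    baseline_days: int = 365         # covariate assessment window
    followup_days: int = 730         # outcome window (two 365-day years)
    diagnosis_window_days: int = 30  # MDD diagnosis within +/- this of index
    refill_gap_days: int = 30        # max coverage gap to the 2nd dispensing
    episode_gap_days: int = 180      # coverage gap that ends a MDD episode

    def with_abstract_index_window(self) -> "StudyWindows":
        """Variant with the shorter index-accrual window (through 2013-09-30)."""
        return replace(self, index_end=dt.date(2013, 9, 30))


def _norm(code: str) -> str:
    """Normalize an ICD code for prefix matching (uppercase, dots stripped)."""
    return code.replace(".", "").strip().upper()


# MDD / depression diagnosis codes: 296.2x, 296.3x (except 296.25, 296.30),
# 300.4, 309.0, 309.1, 311 — prefix semantics on normalized codes.
_MDD_PREFIXES = ("2962", "2963", "3004", "3090", "3091", "311")
_MDD_EXCLUDED = ("29625", "29630")

# reporting categories for the depression diagnosis, in tie-break priority
DIAGNOSIS_CATEGORIES = ("296.X", "300.X", "309.X", "311.X")


@dataclass(frozen=True)
class CodeLists:
    """Diagnosis/drug/procedure code configuration for cohort construction."""

    mdd_prefixes: tuple = _MDD_PREFIXES
    mdd_excluded_prefixes: tuple = _MDD_EXCLUDED
    # excluded at any time: psychosis, schizophrenia, mania, bipolar, dementia
    exclusion_dx_prefixes: tuple = (
        "295", "297", "298",                  # psychosis / schizophrenia
        "2960", "2961", "2964", "2965", "2966", "2967", "2968",  # mania/bipolar
        "290", "3310",                        # dementia
        "F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29",
        "F30", "F31", "F01", "F02", "F03",
    )
    # dispensings excluded within 6 months pre-index
    exclusion_drug_classes: frozenset = frozenset(
        {"lithium", "thyroid_hormone", "antipsychotic", "anticonvulsant"}
    )
    exclusion_procedures: frozenset = frozenset({"ECT", "TMS"})
    # "depression treatment" claims barred from the washout window
    washout_drug_classes: frozenset = frozenset({ANTIDEPRESSANT}) | AUGMENTATION_CLASSES
    washout_procedures: frozenset = frozenset({"ECT", "TMS", "PSYCHOTHERAPY"})
    # baseline comorbidity flags
    anxiety_prefixes: tuple = ("3000", "F41")
    personality_prefixes: tuple = ("301", "F60")
    substance_prefixes: tuple = ("303", "304", "3052", "3053", "3054", "3055", "F10", "F11")
    ptsd_prefixes: tuple = ("30981", "F431")

    def is_mdd(self, code: str) -> bool:
        c = _norm(code)
        if c.startswith(self.mdd_excluded_prefixes):
            return False
        return c.startswith(self.mdd_prefixes)

    def mdd_category(self, code: str) -> str:
        """Reporting category (296.X/300.X/309.X/311.X) of an MDD code."""
        c = _norm(code)
        if not self.is_mdd(c):
            raise ValueError(f"not an MDD diagnosis code: {code}")
        return c[:3] + ".X" if c[:3] in ("296", "300", "309", "311") else c[:3]

    def is_exclusion_dx(self, code: str) -> bool:
        return _norm(code).startswith(self.exclusion_dx_prefixes)


def _solid_tumor_prefixes() -> tuple:
    return tuple(str(i) for i in list(range(140, 173)) + list(range(174, 196)))


# 30-category comorbidity map (classic enumeration without the depression
# category, which every cohort member carries by construction). Prefix-based
# on normalized ICD-9 codes; implementer-supplied defaults, config-replaceable.
ELIXHAUSER_CATEGORIES: dict = {
    "congestive_heart_failure": ("428",),
    "cardiac_arrhythmias": ("4260", "4267", "4269", "427"),
    "valvular_disease": ("394", "395", "396", "397", "424"),
    "pulmonary_circulation": ("4150", "4151", "416", "417"),
    "peripheral_vascular": ("440", "441", "443"),
    "hypertension_uncomplicated": ("401",),
    "hypertension_complicated": ("402", "403", "404", "405"),
    "paralysis": ("342", "343", "344"),
    "other_neurological": ("330", "331", "332", "333", "334", "335", "340", "341", "345"),
    "chronic_pulmonary": tuple(str(i) for i in range(490, 497)) + tuple(str(i) for i in range(500, 506)),
    "diabetes_uncomplicated": ("2500", "2501", "2502", "2503"),
    "diabetes_complicated": ("2504", "2505", "2506", "2507", "2508", "2509"),
    "hypothyroidism": ("243", "244"),
    "renal_failure": ("585", "586", "5880"),
    "liver_disease": ("570", "571", "572", "5733"),
    "peptic_ulcer": ("531", "532", "533", "534"),
    "aids_hiv": ("042", "043", "044"),
    "lymphoma": ("200", "201", "202"),
    "metastatic_cancer": ("196", "197", "198", "199"),
    "solid_tumor": _solid_tumor_prefixes(),
    "rheumatoid_arthritis": ("446", "7010", "710", "714", "720", "725"),
    "coagulopathy": ("286", "2871", "2873", "2874", "2875"),
    "obesity": ("2780",),
    "weight_loss": ("260", "261", "262", "263"),
    "fluid_electrolyte": ("2536", "276"),
    "blood_loss_anemia": ("2800",),
    "deficiency_anemia": ("2801", "2808", "2809", "281"),
    "alcohol_abuse": ("2911", "303", "3050"),
    "drug_abuse": ("292", "304") + tuple(f"305{i}" for i in range(2, 10)),
    "psychoses": ("295", "297", "298"),
}
assert len(ELIXHAUSER_CATEGORIES) == 30

# Minimum adequate daily doses, mg/day. Implementer-supplied defaults in the
# spirit of guideline minimal therapeutic doses; every drug the synthetic
# generator emits has an entry. Replaceable via YAML (load_dose_table).
DEFAULT_DOSE_TABLE: dict = {
    "citalopram": 20.0,
    "escitalopram": 10.0,
    "fluoxetine": 20.0,
    "paroxetine": 20.0,
    "sertraline": 50.0,
    "fluvoxamine": 100.0,
    "venlafaxine": 75.0,
    "desvenlafaxine": 50.0,
    "duloxetine": 60.0,
    "levomilnacipran": 40.0,
    "bupropion": 300.0,
    "mirtazapine": 15.0,
    "vilazodone": 20.0,
    "vortioxetine": 10.0,
    "trazodone": 150.0,
    "nortriptyline": 50.0,
    "amitriptyline": 75.0,
}


def load_dose_table(path) -> dict:
    """Load a drug -> minimum-adequate-daily-dose mapping from YAML."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    bad = [d for d, v in table.items() if not (isinstance(v, (int, float)) and v > 0)]
    if bad:
        raise ValueError(f"non-positive minimum dose for: {', '.join(sorted(bad))}")
    return {str(k): float(v) for k, v in table.items()}


DEFAULT_CODE_LISTS = CodeLists()
DEFAULT_WINDOWS = StudyWindows()
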