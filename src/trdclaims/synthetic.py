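"""Synthetic administrative-claims generator with known ground truth.

Emulates the structure of a commercial claims extract — dated
antidepressant dispensings with dose and days-supply, dated medical
encounters with ICD codes and setting, payer/patient cost components, and
enrollment spells — so every downstream stage (cohort rules, TRD
phenotyping, matching, outcome models) can be tested against scripted
truth.

Drug histories are assembled from parameterized trajectory templates, not
free simulation, so classifier boundary cases are generated exactly: a
configurable fraction of patients receive histories that satisfy the TRD
definition (three regimen lines, the first two adequate in dose and
duration), and the remainder fail it in one targeted way (switch too early,
switch too late, inadequate dose on line 1 or 2, or fewer than three
lines).

Outcome ground truth is injected per patient-year: annual total costs are
gamma with the mean multiplied by ``cost_effect_ratio`` for TRD-trajectory
patients, outpatient-visit counts are negative-binomial with the mean
multiplied by ``utilization_effect_ratio``, and any-ED/any-hospitalization
indicators are Bernoulli with per-year odds ratios. Annual costs are drawn
directly and then spread across that year's generated claims, since the
models consume annual aggregates.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import DEFAULT_DOSE_TABLE, StudyWindows

TRAJECTORIES = (
    "trd_switch_switch", "trd_augment_switch",
    "single_regimen", "two_regimens", "early_switch", "late_switch",
    "inadequate_dose_first", "inadequate_dose_second",
)
TRD_TRAJECTORIES = ("trd_switch_switch", "trd_augment_switch")

_NON_TRD_WEIGHTS = {
    "single_regimen": 0.35, "two_regimens": 0.25, "early_switch": 0.15,
    "late_switch": 0.10, "inadequate_dose_first": 0.10, "inadequate_dose_second": 0.05,
}

_ANTIDEPRESSANTS = sorted(DEFAULT_DOSE_TABLE)
_AUGMENT_AGENTS = (
    ("aripiprazole", "antipsychotic"),
    ("lamotrigine", "anticonvulsant"),
    ("methylphenidate", "psychostimulant"),
)
_MDD_CODES = {"296.X": ("29622", "29632"), "300.X": ("3004",),
              "309.X": ("3090", "3091"), "311.X": ("311",)}
_DX_CATEGORY_PROBS = (("296.X", 0.45), ("300.X", 0.15), ("309.X", 0.25), ("311.X", 0.15))
# one representative code per comorbidity category safe to inject at baseline
# (never collides with exclusion or depression-flag code lists)
_COMORBIDITY_POOL = ("4280", "42731", "4240", "4011", "49390", "25000",
                     "2449", "27800", "2809", "2761")
_BENIGN_CODE = "V700"  # general medical examination


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the claims simulator; defaults are the study conditions."""

    n_patients: int = 1000
    trd_trajectory_fraction: float = 0.13
    cost_effect_ratio: float = 1.4
    utilization_effect_ratio: float = 1.35
    ed_effect_or: tuple = (1.7, 1.4)      # per follow-up year
    hosp_effect_or: tuple = (1.7, 1.4)
    baseline_cost_mean: float = 8000.0    # US$ per patient-year
    cost_shape: float = 1.5               # gamma shape of annual totals
    visit_base_mean: float = 8.0          # outpatient visits per year
    visit_dispersion: float = 0.8         # NB2 alpha
    ed_base_prob: float = 0.20
    hosp_base_prob: float = 0.10
    death_fraction: float = 0.01
    disenrolled_fraction: float = 0.0     # stress cases, flagged in ground truth
    confounded: bool = True               # covariate imbalance between arms
    pharmacy_cost_share: float = 0.15
    patient_cost_share: float = 0.15
    seed: int = 0
    study_window: StudyWindows = field(default_factory=StudyWindows)

    def __post_init__(self):
        def fail(name, why):
            raise ValueError(f"invalid SimulationConfig.{name}: {why}")
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 0):
            fail("n_patients", "must be a non-negative integer")
        for name in ("trd_trajectory_fraction", "ed_base_prob", "hosp_base_prob",
                     "death_fraction", "disenrolled_fraction",
                     "pharmacy_cost_share", "patient_cost_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                fail(name, f"probability/proportion {v} outside [0, 1]")
        for name in ("cost_effect_ratio", "utilization_effect_ratio",
                     "baseline_cost_mean", "cost_shape", "visit_base_mean"):
            if not getattr(self, name) > 0:
                fail(name, "must be strictly positive")
        if self.visit_dispersion < 0:
            fail("visit_dispersion", "must be non-negative")
        for name in ("ed_effect_or", "hosp_effect_or"):
            ors = getattr(self, name)
            if len(ors) != 2 or any(v <= 0 for v in ors):
                fail(name, "needs one positive odds ratio per follow-up year")

    def to_json(self) -> str:
        d = asdict(self)
        d["study_window"] = {k: v.isoformat() if isinstance(v, dt.date) else v
                             for k, v in asdict(self.study_window).items()}
        d["ed_effect_or"] = list(self.ed_effect_or)
        d["hosp_effect_or"] = list(self.hosp_effect_or)
        return json.dumps(d, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ClaimsBundle:
    patients: pd.DataFrame
    pharmacy_claims: pd.DataFrame
    medical_claims: pd.DataFrame
    enrollment: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig

    def tables(self) -> dict:
        return {"patients": self.patients, "pharmacy_claims": self.pharmacy_claims,
                "medical_claims": self.medical_claims, "enrollment": self.enrollment,
                "ground_truth": self.ground_truth}


# --- helpers --------------------------------------------------------------

def _nb_draw(rng, mean: float, alpha: float) -> int:
    if alpha <= 1e-12:
        return int(rng.poisson(mean))
    r = 1.0 / alpha
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _iso(day0: dt.date, offset: int) -> str:
    return (day0 + dt.timedelta(days=int(offset))).isoformat()


def _refill_offsets(start: int, horizon: int, supply: int) -> list:
    return list(range(start, max(horizon, start + 1), supply))


def _year_of(offset: int) -> int:
    if -365 <= offset <= -1:
        return 0
    if 1 <= offset <= 365:
        return 1
    if 366 <= offset <= 730:
        return 2
    return -1


class _PatientScript:
    """Accumulates one patient's claims before cost attribution."""

    def __init__(self, pid: str, index_date: dt.date):
        self.pid = pid
        self.index_date = index_date
        self.rx = []    # (offset, drug, class, dose, supply)
        self.med = []   # (offset, end_offset, setting, icd, proc)

    def fill(self, offset, drug, drug_class, dose, supply):
        self.rx.append((offset, drug, drug_class, float(dose), int(supply)))

    def visit(self, offset, icd=_BENIGN_CODE, setting="outpatient", end_offset=None, proc=""):
        self.med.append((offset, offset if end_offset is None else end_offset,
                         setting, icd, proc))


def _script_drug_history(script: _PatientScript, trajectory: str, rng, horizon: int):
    """Write the pharmacy-fill template for one trajectory onto the script."""
    drugs = list(rng.choice(_ANTIDEPRESSANTS, size=3, replace=False))
    a, b, c = drugs

    def dose(drug, adequate=True):
        mult = float(rng.choice([1.0, 1.5, 2.0])) if adequate else 0.5
        return DEFAULT_DOSE_TABLE[drug] * mult

    def maintain(drug, dose_v, start):
        for off in _refill_offsets(start, horizon, 30):
            script.fill(off, drug, "antidepressant", dose_v, 30)

    if trajectory == "single_regimen":
        maintain(a, dose(a), 0)
    elif trajectory == "two_regimens":
        g1 = int(rng.integers(29, 181))
        for off in (0, 14):
            script.fill(off, a, "antidepressant", dose(a), 14)
        maintain(b, dose(b), g1)
    elif trajectory == "early_switch":
        for off in (0, 7):
            script.fill(off, a, "antidepressant", dose(a), 7)
        maintain(b, dose(b), int(rng.integers(15, 29)))
    elif trajectory == "late_switch":
        for off in (0, 14):
            script.fill(off, a, "antidepressant", dose(a), 14)
        maintain(b, dose(b), int(rng.integers(209, 269)))
    elif trajectory in ("trd_switch_switch", "inadequate_dose_first", "inadequate_dose_second"):
        g1, g2 = int(rng.integers(29, 181)), int(rng.integers(29, 181))
        dose_a = dose(a, adequate=trajectory != "inadequate_dose_first")
        dose_b = dose(b, adequate=trajectory != "inadequate_dose_second")
        for off in (0, 14):
            script.fill(off, a, "antidepressant", dose_a, 14)
        for off in (g1, g1 + 14):
            script.fill(off, b, "antidepressant", dose_b, 14)
        maintain(c, dose(c), g1 + g2)
    elif trajectory == "trd_augment_switch":
        a1 = int(rng.integers(14, 31))      # augmentation on Day a1+1 (>= 15)
        g2 = int(rng.integers(47, 181))     # clears both drugs' supply tails
        for off in (0, 30):
            script.fill(off, a, "antidepressant", dose(a), 30)
        agent, agent_class = _AUGMENT_AGENTS[int(rng.integers(len(_AUGMENT_AGENTS)))]
        script.fill(a1, agent, agent_class, 5.0, 30)
        maintain(c, dose(c), a1 + g2)
    else:
        raise ValueError(f"unknown trajectory template: {trajectory}")


def generate_claims(config: SimulationConfig) -> ClaimsBundle:
    """Generate a claims bundle under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    win = config.study_window
    accrual_days = (win.index_end - win.index_start).days

    patients, rx_rows, med_rows, enroll_rows, truth_rows = [], [], [], [], []
    non_trd = sorted(_NON_TRD_WEIGHTS)
    non_trd_p = np.array([_NON_TRD_WEIGHTS[t] for t in non_trd])
    non_trd_p = non_trd_p / non_trd_p.sum()

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        index_date = win.index_start + dt.timedelta(days=int(rng.integers(0, accrual_days + 1)))
        is_trd_arm = bool(rng.random() < config.trd_trajectory_fraction)
        if is_trd_arm:
            trajectory = TRD_TRAJECTORIES[int(rng.random() < 0.4)]
        else:
            trajectory = str(rng.choice(non_trd, p=non_trd_p))

        conf = config.confounded and is_trd_arm
        age_mean = 39.0 if conf else 40.5
        age = int(np.clip(round(rng.normal(age_mean, 12.0)), 18, 63))
        birth_date = index_date - dt.timedelta(days=age * 365 + int(rng.integers(16, 320)))
        sex = "female" if rng.random() < (0.65 if conf else 0.61) else "male"

        died = bool(rng.random() < config.death_fraction)
        death_offset = int(rng.integers(460, 731)) if died else None
        horizon = death_offset if died else 730

        script = _PatientScript(pid, index_date)
        _script_drug_history(script, trajectory, rng, horizon)

        # depression diagnosis near the index date
        cats, probs = zip(*_DX_CATEGORY_PROBS)
        category = str(rng.choice(cats, p=np.array(probs)))
        dx_code = str(rng.choice(_MDD_CODES[category]))
        script.visit(int(rng.integers(-20, 21)), icd=dx_code)

        # baseline comorbidity profile (arm-shifted when confounding is on)
        flags = {
            "anxiety": ("30001", 0.45 if conf else 0.27),
            "personality": ("3019", 0.04 if conf else 0.02),
            "substance": ("30400", 0.12 if conf else 0.08),
            "ptsd": ("30981", 0.05 if conf else 0.02),
        }
        for code, p in flags.values():
            if rng.random() < p:
                script.visit(int(rng.integers(-365, 0)), icd=code)
        k = min(int(rng.poisson(1.6 if conf else 1.3)), len(_COMORBIDITY_POOL))
        for code in rng.choice(_COMORBIDITY_POOL, size=k, replace=False):
            script.visit(int(rng.integers(-365, 0)), icd=str(code))

        # two non-psychiatric fills so the baseline year carries pharmacy cost
        script.fill(-300, "multivitamin", "other", 1.0, 30)
        script.fill(-200, "multivitamin", "other", 1.0, 30)

        # utilization per year: baseline (0) and follow-up (1, 2)
        util_mult = config.utilization_effect_ratio if is_trd_arm else 1.0
        for year, (lo, hi) in ((0, (-365, -1)), (1, (1, 365)), (2, (366, 730))):
            if lo > horizon:
                continue
            hi = min(hi, horizon)
            n_visits = _nb_draw(rng, config.visit_base_mean * (util_mult if year else 1.0),
                                config.visit_dispersion)
            for off in rng.integers(lo, hi + 1, size=n_visits):
                script.visit(int(off))
            yi = year - 1
            if year:
                p_ed = float(expit(logit(config.ed_base_prob)
                                   + np.log(config.ed_effect_or[yi]) * is_trd_arm))
                p_hosp = float(expit(logit(config.hosp_base_prob)
                                     + np.log(config.hosp_effect_or[yi]) * is_trd_arm))
                if rng.random() < p_ed:
                    script.visit(int(rng.integers(lo, hi + 1)), setting="ed", icd=_BENIGN_CODE)
                if rng.random() < p_hosp:
                    los = 1 + int(rng.poisson(3.0))
                    start = int(rng.integers(lo, max(lo, hi - los) + 1))
                    script.visit(start, setting="inpatient", icd=_BENIGN_CODE,
                                 end_offset=min(start + los - 1, hi))

        # trim to the death date, then attribute annual costs across claims
        if died:
            script.rx = [f for f in script.rx if f[0] <= death_offset]
            script.med = [v for v in script.med if v[0] <= death_offset]
        cost_mult = config.cost_effect_ratio if is_trd_arm else 1.0
        year_costs = {
            yr: float(rng.gamma(config.cost_shape,
                                config.baseline_cost_mean * (cost_mult if yr else 1.0)
                                / config.cost_shape))
            for yr in (0, 1, 2)
        }
        rx_cost = {off_i: 0.0 for off_i in range(len(script.rx))}
        med_cost = {off_i: 0.0 for off_i in range(len(script.med))}
        for yr, total in year_costs.items():
            rx_in = [j for j, f in enumerate(script.rx) if _year_of(f[0]) == yr]
            med_in = [j for j, v in enumerate(script.med) if _year_of(v[0]) == yr]
            rx_share = total * config.pharmacy_cost_share
            med_share = total - rx_share
            if not med_in:
                rx_share, med_share = total, 0.0
            if not rx_in:
                rx_share, med_share = 0.0, (total if med_in else 0.0)
            for j in rx_in:
                rx_cost[j] += rx_share / len(rx_in)
            for j in med_in:
                med_cost[j] += med_share / len(med_in)

        oop = config.patient_cost_share
        for j, (off, drug, klass, dose_v, supply) in enumerate(script.rx):
            c = rx_cost[j]
            rx_rows.append((pid, _iso(index_date, off), drug, klass, dose_v, supply,
                            round(c * (1 - oop), 2), round(c * oop, 2)))
        for j, (off, end_off, setting, icd, proc) in enumerate(script.med):
            c = med_cost[j]
            med_rows.append((pid, _iso(index_date, off), _iso(index_date, end_off),
                             setting, icd, proc, round(c * (1 - oop), 2), round(c * oop, 2)))

        disenrolled = bool(rng.random() < config.disenrolled_fraction)
        enroll_start = index_date - dt.timedelta(days=400 + int(rng.integers(0, 100)))
        enroll_end_off = horizon if died else 760
        if disenrolled:
            enroll_end_off = 300  # follow-up coverage deliberately broken
        enroll_rows.append((pid, enroll_start.isoformat(), _iso(index_date, enroll_end_off),
                            True, True))
        patients.append((pid, birth_date.isoformat(), sex,
                         _iso(index_date, death_offset) if died else ""))
        truth_rows.append((pid, trajectory, is_trd_arm, index_date.isoformat(),
                           died, disenrolled, cost_mult,
                           util_mult if is_trd_arm else 1.0))

    bundle = ClaimsBundle(
        patients=pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex", "death_date"]),
        pharmacy_claims=pd.DataFrame(
            rx_rows, columns=["patient_id", "dispense_date", "drug_name", "drug_class",
                              "daily_dose", "days_supply", "payer_cost", "patient_cost"]),
        medical_claims=pd.DataFrame(
            med_rows, columns=["patient_id", "service_start", "service_end", "setting",
                               "icd_codes", "procedure_codes", "payer_cost", "patient_cost"]),
        enrollment=pd.DataFrame(
            enroll_rows, columns=["patient_id", "start", "end", "has_pharmacy", "has_medical"]),
        ground_truth=pd.DataFrame(
            truth_rows, columns=["patient_id", "trajectory", "is_trd", "index_date",
                                 "died", "disenrolled", "cost_effect_ratio",
                                 "utilization_effect_ratio"]),
        config=config,
    )
    for name, tab in bundle.tables().items():
        if name != "patients" and len(tab):
            unknown = set(tab["patient_id"]) - set(bundle.patients["patient_id"])
            assert not unknown, f"{name} references unknown patients"
    return bundle


def write_bundle(bundle: ClaimsBundle, directory, fmt: str = "csv") -> dict:
    """Write all bundle tables plus a JSON manifest; returns the manifest."""
    if fmt not in ("csv", "parquet"):
        raise ValueError(f"unsupported format: {fmt}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"format": fmt, "config_hash": bundle.config.digest(),
                "config": json.loads(bundle.config.to_json()), "files": {}}
    for name, table in bundle.tables().items():
        path = directory / f"{name}.{fmt}"
        if fmt == "csv":
            table.to_csv(path, index=False)
        else:
            table.to_parquet(path, index=False)
        manifest["files"][name] = {"path": path.name, "rows": int(len(table))}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_bundle(directory) -> ClaimsBundle:
    """Load a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tables = {}
    for name, info in manifest["files"].items():
        path = directory / info["path"]
        if manifest["format"] == "csv":
            tables[name] = pd.read_csv(path, keep_default_na=False, na_values=[],
                                       dtype={"icd_codes": str, "procedure_codes": str})
        else:
            tables[name] = pd.read_parquet(path)
    cfg = manifest["config"]
    sw = cfg.pop("study_window")
    windows = StudyWindows(**{k: dt.date.fromisoformat(v) if isinstance(v, str) else v
                              for k, v in sw.items()})
    cfg["ed_effect_or"] = tuple(cfg["ed_effect_or"])
    cfg["hosp_effect_or"] = tuple(cfg["hosp_effect_or"])
    config = SimulationConfig(study_window=windows, **cfg)
    return ClaimsBundle(config=config, patients=tables["patients"],
                        pharmacy_claims=tables["pharmacy_claims"],
                        medical_claims=tables["medical_claims"],
                        enrollment=tables["enrollment"],
                        ground_truth=tables["ground_truth"])
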