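"""Synthetic perioperative cohort generator.

Emulates the statistical structure of a preoperative-assessment database:
~1,190 elderly elective-surgery patients, each with 39 clinical features,
46 cardiorespiratory-fitness (CRF) features derived from cardiopulmonary
exercise testing, a binary day-3 morbidity outcome defined through the
nine-domain Post-Operative Morbidity Survey (POMS), and — for a subset —
full 1-Hz CPET waveforms.

The design is latent-variable: each patient carries a fitness latent ``z``
(higher = fitter) and a clinical-frailty latent ``c``.  CRF features load on
``z`` in correlated blocks (rest / anaerobic-threshold / peak / slopes);
clinical features load weakly on ``c``.  Outcome risk is the linear
predictor ``eta = -crf_effect*z + clinical_effect*c + noise``, fed through
per-domain logistic probabilities to nine conditionally independent POMS
domain indicators; the morbidity class is 1 when at least two non-excluded
domains are positive.  The per-domain intercept is calibrated by bisection
so the expected prevalence matches the configured target exactly.

CPET waveforms for the time-series subset are built from the *noise-free*
latent fitness targets, while the tabular CRF features carry measurement
noise — so the waveform view of a patient is mutually consistent with, and
slightly more informative than, the scalar view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cpet import CPETSeries

__all__ = [
    "GeneratorConfig",
    "POMSAssessment",
    "Cohort",
    "generate_cohort",
    "generate_poms",
    "generate_cpet_waveforms",
    "poms_class_probability",
    "OUTCOME_COLUMN",
]

OUTCOME_COLUMN = "poms_class_d3"

# Logit offsets of the nine POMS domains (pulmonary, infectious, renal,
# gastrointestinal, cardiovascular, neurological, haematological, wound,
# pain); common domains first. Relative ordering only — the overall level is
# re-calibrated to the prevalence target.
DOMAIN_OFFSETS = np.array([0.4, 0.1, -0.1, -0.3, -0.6, -0.9, -1.2, -1.5, -1.0])
DOMAIN_NAMES = ("pulmonary", "infectious", "renal", "gastrointestinal",
                "cardiovascular", "neurological", "haematological",
                "wound", "pain")
_DAY_SHIFT = {3: 0.0, 5: -0.5, 7: -0.8}


@dataclass
class GeneratorConfig:
    n_patients: int = 1190
    n_clinical: int = 39
    n_crf: int = 46
    prevalence_target: float = 633 / 1190
    crf_effect: float = 3.0        # calibrated so |r(vo2_kg_at, POMS count)| ~ corr_target
    clinical_effect: float = 0.45
    ts_effect: float = 0.6         # recovery-kinetics latent, visible only in waveforms
    noise_sd: float = 0.55         # patient-level risk noise (logit scale)
    corr_target: float = 0.69
    ts_fraction: float = 585 / 1190
    excluded_domains: tuple[int, ...] = ()
    measurement_sd: float = 0.35   # tabular CRF measurement noise (z units)
    waveform_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must lie strictly in (0, 1)")
        if not (0.0 <= self.ts_fraction <= 1.0):
            raise ValueError("ts_fraction must lie in [0, 1]")
        for name in ("n_patients", "n_clinical", "n_crf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("crf_effect", "clinical_effect", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class POMSAssessment:
    """One POMS screen: nine binary morbidity domains on a fixed day."""

    day: int
    domain_positive: tuple[bool, ...]
    excluded_domains: tuple[int, ...] = ()

    def __post_init__(self):
        if self.day not in (3, 5, 7):
            raise ValueError("POMS day must be one of {3, 5, 7}")
        if len(self.domain_positive) != 9:
            raise ValueError("POMS has exactly nine domains")

    @property
    def positive_count(self) -> int:
        return sum(bool(v) for i, v in enumerate(self.domain_positive)
                   if i not in self.excluded_domains)

    @property
    def morbidity_class(self) -> int:
        return int(self.positive_count >= 2)


def _domain_probs(latent_risk, intercept: float, day: int) -> np.ndarray:
    if day not in _DAY_SHIFT:
        raise ValueError("POMS day must be one of {3, 5, 7}")
    eta = np.asarray(latent_risk, dtype=float)
    logits = intercept + _DAY_SHIFT[day] + DOMAIN_OFFSETS + eta[..., None]
    return 1.0 / (1.0 + np.exp(-logits))


def poms_class_probability(latent_risk, intercept: float = -1.0, day: int = 3,
                           excluded_domains: tuple[int, ...] = ()) -> np.ndarray:
    """P(morbidity class = 1) = P(>= 2 positive non-excluded domains).

    Computed exactly from the Poisson-binomial distribution of the domain
    count; strictly increasing in ``latent_risk``.
    """
    p = _domain_probs(latent_risk, intercept, day)
    keep = [d for d in range(9) if d not in excluded_domains]
    p = p[..., keep]
    p0 = np.prod(1.0 - p, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p < 1.0, p / (1.0 - p), np.inf)
    p1 = p0 * np.sum(ratio, axis=-1)
    return 1.0 - p0 - p1


def generate_poms(latent_risk: float, day: int, rng: np.random.Generator,
                  intercept: float = -1.0,
                  excluded_domains: tuple[int, ...] = ()) -> POMSAssessment:
    """Draw one POMS assessment; domain probabilities rise with risk."""
    if not np.isfinite(latent_risk):
        raise ValueError("latent_risk must be finite")
    p = _domain_probs(float(latent_risk), intercept, day)
    hits = rng.random(9) < p
    return POMSAssessment(day=day, domain_positive=tuple(bool(h) for h in hits),
                          excluded_domains=tuple(excluded_domains))


def _calibrate_intercept(eta: np.ndarray, target: float, day: int,
                         excluded: tuple[int, ...]) -> float:
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        prev = float(np.mean(poms_class_probability(eta, mid, day, excluded)))
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# feature blocks
# ---------------------------------------------------------------------------

# CRF scalar features: (name, block, mean, scale, z-loading sign/strength)
_CRF_SPEC = [
    ("vo2_kg_at",     "at",    10.6, 2.4,  1.0),
    ("hr_at",         "at",    106, 15,    0.3),
    ("rer_at",        "at",    0.85, 0.06, 0.0),
    ("ve_vco2_at",    "at",    33,  4.5,  -0.6),
    ("vo2_at",        "at",    780, 170,   0.9),
    ("vco2_at",       "at",    680, 160,   0.8),
    ("work_rate_at",  "at",    70,  20,    0.7),
    ("o2_pulse_at",   "at",    9.0, 2.2,   0.7),
    ("ve_at",         "at",    28,  7,     0.4),
    ("petco2_at",     "at",    5.3, 0.5,   0.3),
    ("vo2_kg_peak",   "peak",  16.9, 3.4,  1.0),
    ("hr_peak",       "peak",  136, 17,    0.4),
    ("rer_peak",      "peak",  1.10, 0.08, 0.1),
    ("ve_vco2_peak",  "peak",  34,  4.5,  -0.6),
    ("work_rate_peak","peak",  110, 30,    0.8),
    ("ve_peak",       "peak",  55,  14,    0.5),
    ("o2_pulse_peak", "peak",  11.5, 2.8,  0.8),
    ("petco2_peak",   "peak",  5.0, 0.6,   0.3),
    ("rr_peak",       "peak",  32,  6,    -0.1),
    ("vt_peak",       "peak",  1.8, 0.5,   0.4),
    ("vo2_kg_rest",   "rest",  3.8, 0.55,  0.25),
    ("hr_rest",       "rest",  82,  11,   -0.25),
    ("rer_rest",      "rest",  0.82, 0.05, 0.0),
    ("ve_vco2_rest",  "rest",  31,  4,    -0.3),
    ("petco2_rest",   "rest",  5.1, 0.5,   0.2),
    ("peto2_rest",    "rest",  13.5, 0.7, -0.1),
    ("ve_vo2_slope",  "slope", 26,  4,    -0.5),
    ("ve_vco2_slope", "slope", 29,  4,    -0.6),
    ("o2_pulse_slope","slope", 0.10, 0.03, 0.6),
    ("met",           "slope", 4.5, 1.0,   0.9),
]

# clinical binary comorbidity / medication features with base prevalences
_CLIN_BINARY = [
    ("hypertension", 0.35), ("diabetes", 0.11), ("angina", 0.04),
    ("coronary_stent", 0.05), ("cabg", 0.03), ("cardiac_failure", 0.10),
    ("pvd", 0.02), ("cva_tia", 0.04), ("copd", 0.06), ("asthma", 0.08),
    ("prev_pe", 0.015), ("pulm_fibrosis", 0.01), ("smoking", 0.27),
    ("beta_blocker", 0.20), ("nitrate", 0.03), ("ace_inhibitor", 0.18),
    ("statin", 0.30),
]

# continuous laboratory values: (name, mean, sd)
_CLIN_LABS = [
    ("sodium", 141, 2.2), ("potassium", 4.3, 0.35), ("creatinine", 79, 22),
    ("urea", 6.1, 2.1), ("wbc", 7.7, 2.0), ("haemoglobin", 131, 16),
    ("egfr", 84, 26),
]

_SURGERY_PROBS = np.array([0.205, 0.165, 0.340, 0.213, 0.036, 0.041])


@dataclass
class Cohort:
    """Feature table, group tags, latent ground truth and configuration."""

    table: pd.DataFrame
    feature_groups: dict[str, str]
    categorical_mask: dict[str, bool]
    latent: pd.DataFrame
    config: GeneratorConfig

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.table.columns if c != OUTCOME_COLUMN
                and not c.startswith("poms_count")]

    @property
    def outcome(self) -> np.ndarray:
        return self.table[OUTCOME_COLUMN].to_numpy(dtype=int)

    @property
    def ts_patients(self) -> list[str]:
        return list(self.latent.index[self.latent["has_ts"]])

    def features(self, group: str | None = None) -> pd.DataFrame:
        names = self.feature_names
        if group is not None:
            names = [n for n in names if self.feature_groups[n] == group]
        return self.table[names]

    def write(self, directory) -> None:
        """Cohort CSV plus JSON sidecar with group/categorical metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "cohort.csv", index=True)
        sidecar = {"feature_groups": self.feature_groups,
                   "categorical_mask": self.categorical_mask,
                   "outcome_column": OUTCOME_COLUMN}
        (directory / "feature_groups.json").write_text(
            json.dumps(sidecar, indent=1))

    def waveforms(self, patients: list[str] | None = None) -> dict[str, CPETSeries]:
        """Deterministically regenerate 1-Hz recordings for the TS subset."""
        pids = patients if patients is not None else self.ts_patients
        out = {}
        for pid in pids:
            row = self.latent.loc[pid]
            rng = np.random.default_rng(
                (self.config.seed * 1_000_003 + int(row["wave_seed"])) % (2**31))
            out[pid] = generate_cpet_waveforms(
                row, rng, noise_sd=self.config.waveform_noise_sd)
        return out


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a complete cohort; identical config => identical table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    z = rng.normal(size=n)                 # fitness latent, higher = fitter
    c_lat = rng.normal(size=n)             # clinical frailty latent
    w = rng.normal(size=n)                 # recovery-kinetics latent (waveform only)
    eps = rng.normal(size=n)

    # ---------------- CRF features: correlated blocks loading on z --------
    blocks = sorted({b for _, b, *_ in _CRF_SPEC})
    block_factor = {b: rng.normal(size=n) for b in blocks}
    crf = {}
    true_values = {}
    spec = list(_CRF_SPEC)
    for k in range(len(spec), config.n_crf):
        base = _CRF_SPEC[k % len(_CRF_SPEC)]
        spec.append((f"crf_aux_{k - len(_CRF_SPEC):02d}", base[1], 0.0, 1.0,
                     0.4 * base[4]))
    spec = spec[: config.n_crf]
    for name, block, mean, scale, load in spec:
        lam_b = 0.55
        resid = max(0.05, 1.0 - load**2 - lam_b**2) ** 0.5
        latent_std = load * z + lam_b * block_factor[block] + resid * rng.normal(size=n)
        true = mean + scale * latent_std
        meas = true + scale * config.measurement_sd * rng.normal(size=n)
        crf[name] = meas
        true_values[name] = true
    # enforce the physiological ordering at <= peak in the true targets
    gap = np.maximum(0.8, true_values["vo2_kg_peak"] - true_values["vo2_kg_at"])
    true_values["vo2_kg_peak"] = true_values["vo2_kg_at"] + gap
    crf["vo2_kg_peak"] = (true_values["vo2_kg_peak"]
                          + 3.4 * config.measurement_sd * rng.normal(size=n))

    # ---------------- clinical features ----------------------------------
    clin = {}
    clin["age"] = np.round(70 - 3.2 * z + 3.5 * c_lat + 8.0 * rng.normal(size=n), 1)
    clin["sex_male"] = (rng.random(n) < 0.69).astype(int)
    clin["bmi"] = np.round(26.5 + 1.2 * c_lat + 3.8 * rng.normal(size=n), 1)
    clin["asa"] = np.clip(np.round(2.4 + 0.6 * c_lat - 0.3 * z
                                   + 0.5 * rng.normal(size=n)), 1, 5).astype(int)
    clin["dasi"] = np.clip(np.round(46 + 9 * z - 4 * c_lat
                                    + 9 * rng.normal(size=n), 1), 0, 58.2)
    clin["ppossum_physio"] = np.clip(np.round(18 + 2.2 * c_lat - 1.0 * z
                                              + 3.0 * rng.normal(size=n)), 12, 40)
    clin["ppossum_operative"] = np.clip(np.round(14 + 2.5 * rng.normal(size=n)), 6, 30)
    possum_logit = (-2.0 + 0.9 * c_lat - 0.4 * z + 0.6 * rng.normal(size=n))
    clin["ppossum_risk"] = np.round(1.0 / (1.0 + np.exp(-possum_logit)), 4)
    for name, base in _CLIN_BINARY:
        logit = np.log(base / (1 - base)) + 0.8 * c_lat
        clin[name] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    for name, mean, sd in _CLIN_LABS:
        clin[name] = np.round(mean + sd * rng.normal(size=n), 1)
    clin["surgery_type"] = rng.choice(np.arange(1, 7), size=n, p=_SURGERY_PROBS)
    clin["surgery_severity"] = np.clip(
        np.round(2.5 + 0.9 * rng.normal(size=n)), 1, 4).astype(int)
    names = list(clin)
    for k in range(len(names), config.n_clinical):
        clin[f"clin_aux_{k - len(names):02d}"] = np.round(rng.normal(size=n), 3)
    clin = dict(list(clin.items())[: config.n_clinical])

    # ---------------- outcome through the POMS mechanism ------------------
    eta = (-config.crf_effect * z + config.clinical_effect * c_lat
           - config.ts_effect * w + config.noise_sd * eps)
    intercept = _calibrate_intercept(eta, config.prevalence_target, 3,
                                     config.excluded_domains)
    keep = [d for d in range(9) if d not in config.excluded_domains]

    def draw_counts(latent_risk, day):
        p = _domain_probs(latent_risk, intercept, day)
        hits = rng.random((n, 9)) < p
        return hits[:, keep].sum(axis=1)

    count_d3 = draw_counts(eta, 3)
    rho = 0.8
    eta_late = rho * eta + np.sqrt(1 - rho**2) * rng.normal(size=n)
    count_d5 = draw_counts(eta_late, 5)
    count_d7 = draw_counts(0.95 * eta_late + 0.3 * rng.normal(size=n), 7)

    # ---------------- assemble -------------------------------------------
    pids = [f"P{i:04d}" for i in range(n)]
    table = pd.DataFrame({**clin, **crf}, index=pd.Index(pids, name="patient_id"))
    table["poms_count_d3"] = count_d3
    table["poms_count_d5"] = count_d5
    table["poms_count_d7"] = count_d7
    table[OUTCOME_COLUMN] = (count_d3 >= 2).astype(int)

    groups = {name: "clinical" for name in clin}
    groups.update({name: "crf" for name in crf})
    cat_mask = {name: False for name in groups}
    if "surgery_type" in cat_mask:
        cat_mask["surgery_type"] = True
    if "sex_male" in cat_mask:
        cat_mask["sex_male"] = True

    n_ts = int(round(config.ts_fraction * n))
    ts_idx = rng.choice(n, size=n_ts, replace=False) if n_ts else np.array([], int)
    has_ts = np.zeros(n, dtype=bool)
    has_ts[ts_idx] = True

    latent = pd.DataFrame({
        "z": z, "c_lat": c_lat, "eta": eta,
        "vo2_kg_rest": true_values["vo2_kg_rest"],
        "vo2_kg_at": true_values["vo2_kg_at"],
        "vo2_kg_peak": true_values["vo2_kg_peak"],
        "hr_rest": np.clip(true_values["hr_rest"], 45, 130),
        "hr_peak": np.clip(true_values["hr_peak"], 90, 200),
        "body_mass_kg": np.clip(26.5 + 1.2 * c_lat, 18, 45) * 1.7**2,
        "recovery_tau": np.clip(35 - 5 * z - 9 * w, 12, 70),
        "has_ts": has_ts,
        "wave_seed": rng.integers(0, 2**20, size=n),
        "intercept": intercept,
    }, index=table.index)

    return Cohort(table=table, feature_groups=groups,
                  categorical_mask=cat_mask, latent=latent, config=config)


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

REST_S, RAMP_S, PLATEAU_S, RECOVERY_S = 120, 440, 40, 120


def generate_cpet_waveforms(row, rng: np.random.Generator,
                            noise_sd: float = 0.0) -> CPETSeries:
    """Build a 15-channel 1-Hz recording from a patient's latent targets.

    The V̇O₂/kg trace holds a rest plateau, rises linearly through the ramp
    (crossing the planted anaerobic threshold at an exact sample), plateaus
    at the planted peak for the final seconds of exercise, and decays
    exponentially in recovery with a fitness-dependent time constant.  V̇CO₂
    follows the V-slope geometry: slope ~0.85 against V̇O₂ below the
    threshold sample, ~1.15 above it.
    """
    at = float(row["vo2_kg_at"])
    peak = float(row["vo2_kg_peak"])
    rest = float(row.get("vo2_kg_rest", 3.8))
    if at <= 0 or peak <= 0:
        raise ValueError("planted AT and peak targets must be positive")
    mass = float(row.get("body_mass_kg", 75.0))
    hr_rest = float(row.get("hr_rest", 82.0))
    hr_peak = float(row.get("hr_peak", 136.0))
    tau = float(row.get("recovery_tau", 35.0))

    n_ramp = RAMP_S
    total = REST_S + RAMP_S + PLATEAU_S + RECOVERY_S
    t = np.arange(total, dtype=float)

    # the AT sample within the linear ramp, kept away from the edges
    frac = np.clip((at - rest) / max(peak - rest, 1e-9), 0.18, 0.82)
    k_at = REST_S + int(round(frac * n_ramp))

    vo2_kg = np.empty(total)
    vo2_kg[:REST_S] = rest
    ramp_t = np.arange(n_ramp + 1)
    vo2_kg[REST_S:REST_S + n_ramp] = rest + (peak - rest) * ramp_t[:-1] / n_ramp
    vo2_kg[REST_S + n_ramp:REST_S + n_ramp + PLATEAU_S] = peak
    rec_t = np.arange(RECOVERY_S)
    vo2_kg[REST_S + n_ramp + PLATEAU_S:] = rest + (peak - rest) * np.exp(-rec_t / tau)

    vo2 = vo2_kg * mass
    vo2_at_sample = vo2[k_at]
    vco2 = np.where(np.arange(total) < k_at,
                    0.85 * vo2,
                    0.85 * vo2_at_sample + 1.15 * (vo2 - vo2_at_sample))
    # recovery retraces the sub-threshold relation once vo2 falls below AT
    rec_start = REST_S + n_ramp + PLATEAU_S
    below = (np.arange(total) >= rec_start) & (vo2 < vo2_at_sample)
    vco2[below] = 0.85 * vo2[below]

    hr = np.empty(total)
    hr[:REST_S] = hr_rest
    hr[REST_S:REST_S + n_ramp] = hr_rest + (hr_peak - hr_rest) * ramp_t[:-1] / n_ramp
    hr[REST_S + n_ramp:rec_start] = hr_peak
    hr[rec_start:] = hr_rest + (hr_peak - hr_rest) * np.exp(-rec_t / (0.9 * tau))

    ve = 0.026 * vco2 + 5.0
    rer = vco2 / np.maximum(vo2, 1e-9)
    work = np.zeros(total)
    work[REST_S:REST_S + n_ramp] = 10 + 140 * ramp_t[:-1] / n_ramp
    work[REST_S + n_ramp:rec_start] = 150.0

    channels = {
        "vo2": vo2,
        "vco2": vco2,
        "vo2_kg": vo2_kg,
        "vco2_kg": vco2 / mass,
        "ve": ve,
        "hr": hr,
        "rer": rer,
        "peto2": 13.0 + 1.8 * (rer - 0.85),
        "petco2": 5.3 - 0.6 * (rer - 0.85),
        "o2_pulse": vo2 / np.maximum(hr, 1e-9),
        "work_rate": work,
        "ve_vo2": ve / np.maximum(vo2 / 1000.0, 1e-9),
        "ve_vco2": ve / np.maximum(vco2 / 1000.0, 1e-9),
        "rr": 12.0 + 0.35 * ve,
        "spo2": np.full(total, 96.0),
    }
    if noise_sd > 0:
        for name, ch in channels.items():
            scale = max(np.std(ch), 1e-3)
            channels[name] = ch + noise_sd * scale * rng.normal(size=total)

    pid = str(row.name) if hasattr(row, "name") and row.name is not None else "P0000"
    return CPETSeries(
        patient_id=pid, t=t, channels=channels,
        phase_marks={"ramp_start": REST_S, "at": k_at,
                     "peak": REST_S + n_ramp + PLATEAU_S,
                     "recovery_start": rec_start},
        body_mass_kg=mass)
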