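"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes, for
parameter-recovery testing (no real patient data are modelled):

* latent METAVIR fibrosis stage F0-F4, activity grade A0-A3 (correlated
  with stage) and steatosis grade S0-S4 (correlated with disease; NAFLD
  and ALD shifted upward);
* blood scores = monotone map of the latent grade + truncated Gaussian
  noise, clipped to [0, 1];
* true stiffness = base_stiffness(stage) x (1 + a_dev*AT + b_dev*ST) x
  lognormal noise, with device-specific inflammation/steatosis inflation
  coefficients (transient elastography M probe inflated more than 2D-SWE);
* per-session shot sets (10-15 shots) from which mean/median/min/max, CV
  and IQR are computed organically, so the reliability rules have real
  summaries to act on;
* device-specific failure and unreliability mechanisms: TE failure
  probability increases with BMI (obesity), TE sessions can be noisy
  (IQR/M >= 0.30) or short (< 10 valid shots), and a 2D-SWE "dead signal"
  subgroup whose minimal region-of-interest value is drawn below 0.2 kPa
  and whose stiffness is re-drawn independently of fibrosis stage.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream in
the fixed order: disease, stage, grades, demographics, blood noise,
missingness flags, per-device stiffness/shots, failure/unreliability draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import Device, Disease, frame_to_cohort, MANDATORY_COLUMNS, OPTIONAL_COLUMNS

_DISEASES = [Disease.CHC, Disease.CHB, Disease.NAFLD, Disease.ALD, Disease.OTHER]

#: monotone grade -> expected blood score maps
FT_BY_STAGE = (0.12, 0.28, 0.46, 0.68, 0.86)
AT_BY_GRADE = (0.15, 0.35, 0.62, 0.85)
ST_BY_GRADE = (0.10, 0.30, 0.65, 0.80, 0.92)


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Cohort-generation parameters; defaults emulate the study population.

    ``n`` and the disease mix follow the investigated/concordance
    populations (2,251 patients; CHC 599, CHB 366, NAFLD 404, ALD 75 of
    1,588 in the concordance table); ``dead_signal_prob`` defaults to
    0.077 (132/1720); inflation coefficients are chosen so the M-probe is
    inflated more by inflammation and steatosis than 2D-SWE, and the XL
    probe sits between for inflammation but lowest for steatosis (the
    orderings the concordance analysis should recover - magnitudes are
    not identifiable from published values).
    """

    n: int = 2251
    seed: int = 12345
    stage_probs: tuple = (0.25, 0.25, 0.254, 0.15, 0.096)
    disease_probs: tuple = (0.377, 0.230, 0.254, 0.047, 0.092)  # CHC,CHB,NAFLD,ALD,OTHER
    base_stiffness_by_stage: tuple = (4.5, 5.5, 7.0, 9.5, 14.0)  # kPa medians
    inflation_inflam: dict = field(
        default_factory=lambda: {"swe": 0.40, "te_m": 1.20, "te_xl": 0.75}
    )
    inflation_steat: dict = field(
        default_factory=lambda: {"swe": 0.35, "te_m": 0.65, "te_xl": 0.25}
    )
    noise_sigma_log: dict = field(
        default_factory=lambda: {"swe": 0.20, "te_m": 0.20, "te_xl": 0.20}
    )
    # inflammation/steatosis stiffening scales with fibrosis stage
    stage_gain_base: float = 0.5
    stage_gain_slope: float = 0.35
    # activity grade distribution: flat below F3, rising with advanced stage
    inflam_base_prob: float = 0.20
    inflam_stage_slope: float = 0.15
    # 2D-SWE Qbox pixel-minimum tail (lognormal factor on session stiffness,
    # floored: reliable maps do not reach below ~0.2 kPa)
    swe_min_tail_mu: float = -2.0
    swe_min_tail_sd: float = 1.0
    swe_min_floor_kpa: float = 0.22
    shot_sigma_log: float = 0.12
    noisy_session_sigma_log: float = 0.55
    n_shots_range: tuple = (10, 15)
    blood_noise_sd: float = 0.08
    dead_signal_prob: float = 0.077
    swe_failure_prob: float = 0.009
    te_m_failure_intercept: float = -2.65
    te_m_failure_bmi_slope: float = 0.15
    te_xl_failure_prob: float = 0.028
    te_m_noisy_prob: float = 0.035
    te_m_short_prob: float = 0.015
    te_xl_noisy_prob: float = 0.060
    te_xl_short_prob: float = 0.025
    st_missing_prob: float = 0.20
    ft_unreliable_prob: float = 0.0053
    interval_long_prob: float = 0.033
    interval_noise_factor: float = 3.0

    def failure_prob_te_m(self, bmi):
        """Monotone-in-BMI failure probability of the M probe (obesity)."""
        return expit(self.te_m_failure_intercept + self.te_m_failure_bmi_slope * (np.asarray(bmi) - 25.0))

    def validate(self) -> None:
        for name in ("stage_probs", "disease_probs"):
            p = np.asarray(getattr(self, name), float)
            if p.min() < 0 or p.max() > 1:
                raise ConfigError(f"{name} entries must be in [0, 1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {p.sum()!r})")
        if len(self.stage_probs) != 5 or len(self.disease_probs) != 5:
            raise ConfigError("stage_probs and disease_probs must have 5 entries")
        base = np.asarray(self.base_stiffness_by_stage, float)
        if len(base) != 5 or np.any(np.diff(base) <= 0):
            raise ConfigError("base_stiffness_by_stage must be 5 strictly increasing values")
        for name in (
            "dead_signal_prob", "swe_failure_prob", "te_xl_failure_prob", "te_m_noisy_prob",
            "te_m_short_prob", "te_xl_noisy_prob", "te_xl_short_prob", "st_missing_prob",
            "ft_unreliable_prob", "interval_long_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n <= 0:
            raise ConfigError("n must be positive")

    # -- config (de)serialization ------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stage_probs", "disease_probs", "base_stiffness_by_stage", "n_shots_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown generator config keys: {sorted(extra)}")
        kwargs = dict(d)
        for k in ("stage_probs", "disease_probs", "base_stiffness_by_stage", "n_shots_range"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)


def paper_like_scenario() -> GeneratorConfig:
    """The documented default scenario (study-like population structure)."""
    cfg = GeneratorConfig()
    cfg.validate()
    return cfg


def _session_summaries(rng, true_stiff, n_shots, sigma, ceiling):
    """Simulate shot sets around per-patient stiffness; return summary arrays."""
    n = len(true_stiff)
    kmax = int(n_shots.max()) if n else 0
    shots = true_stiff[:, None] * np.exp(sigma[:, None] * rng.standard_normal((n, kmax)))
    shots = np.clip(shots, 0.0, ceiling)
    # mask shots beyond each session's count; row-wise stats via sorting
    # (quantiles interpolated linearly, matching numpy's default)
    mask = np.arange(kmax)[None, :] < n_shots[:, None]
    counts = n_shots.astype(float)
    mean = np.where(mask, shots, 0.0).sum(axis=1) / counts
    sd = np.sqrt(np.where(mask, (shots - mean[:, None]) ** 2, 0.0).sum(axis=1) / counts)
    srt = np.sort(np.where(mask, shots, np.inf), axis=1)
    rows = np.arange(n)

    def quantile(q):
        pos = q * (counts - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n_shots - 1)
        frac = pos - lo
        return srt[rows, lo] * (1 - frac) + srt[rows, hi] * frac

    median = quantile(0.5)
    mn = srt[:, 0]
    mx = srt[rows, n_shots - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    return mean, median, mn, mx, cv, quantile(0.75) - quantile(0.25)


def generate_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic cohort as the canonical flat analysis frame."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    disease_idx = rng.choice(5, size=n, p=np.asarray(config.disease_probs, float))
    disease = np.array([_DISEASES[i].value for i in disease_idx])
    stage = rng.choice(5, size=n, p=np.asarray(config.stage_probs, float))

    p_inflam = np.clip(
        config.inflam_base_prob + config.inflam_stage_slope * np.maximum(0, stage - 2), 0, 1
    )
    inflam = rng.binomial(3, p_inflam)
    p_steat = np.clip(
        0.12 + 0.28 * (disease == "NAFLD") + 0.10 * (disease == "ALD"), 0, 1
    )
    steat = rng.binomial(4, p_steat)

    age = np.clip(rng.normal(50, 13, n), 18, 90)
    sex = np.where(rng.random(n) < 0.60, "M", "F")
    bmi = np.clip(rng.normal(24.5, 3.5, n) + 4.5 * (disease == "NAFLD") + 1.5 * (disease == "ALD"), 16, 55)

    interval_long = rng.random(n) < config.interval_long_prob
    interval_days = np.where(interval_long, rng.uniform(31, 180, n), rng.uniform(0, 30, n))

    # blood scores: monotone map of latent grade + noise, clipped to [0, 1];
    # long test intervals get inflated noise (disease evolved between tests)
    noise_scale = np.where(interval_long, config.interval_noise_factor, 1.0) * config.blood_noise_sd
    ft = np.clip(np.take(FT_BY_STAGE, stage) + noise_scale * rng.standard_normal(n), 0, 1)
    at = np.clip(np.take(AT_BY_GRADE, inflam) + noise_scale * rng.standard_normal(n), 0, 1)
    st = np.clip(np.take(ST_BY_GRADE, steat) + noise_scale * rng.standard_normal(n), 0, 1)
    st_missing = rng.random(n) < config.st_missing_prob
    ft_reliable = rng.random(n) >= config.ft_unreliable_prob

    # latent (noise-free) activity/steatosis scores drive the physiology
    at_latent = np.take(AT_BY_GRADE, inflam)
    st_latent = np.take(ST_BY_GRADE, steat)
    base = np.take(np.asarray(config.base_stiffness_by_stage, float), stage)

    data: dict = {
        "id": np.array([f"P{i:05d}" for i in range(n)]),
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "disease": disease,
        "interval_days": interval_days,
        "fibrotest": ft,
        "actitest": at,
        "steatotest": np.where(st_missing, np.nan, st),
        "ft_reliable": ft_reliable,
    }

    dead = np.zeros(n, dtype=bool)
    te_m_cause = np.full(n, "NONE", dtype=object)

    stage_gain = config.stage_gain_base + config.stage_gain_slope * stage

    for dev in Device:
        key = dev.value
        ceiling = 300.0 if dev is Device.SWE else 75.0
        a = config.inflation_inflam[key]
        b = config.inflation_steat[key]
        true = base * (1.0 + (a * at_latent + b * st_latent) * stage_gain)
        true = true * np.exp(config.noise_sigma_log[key] * rng.standard_normal(n))
        true = np.clip(true, 0.0, ceiling)

        lo, hi = config.n_shots_range
        n_valid = rng.integers(lo, hi + 1, size=n)
        sigma = np.full(n, config.shot_sigma_log)

        if dev is Device.SWE:
            failed = rng.random(n) < config.swe_failure_prob
            dead = (~failed) & (rng.random(n) < config.dead_signal_prob)
            # dead-signal maps: stiffness carries no fibrosis information
            indep = np.exp(np.log(7.0) + 0.5 * rng.standard_normal(n))
            true = np.where(dead, np.clip(indep, 0.0, ceiling), true)
            n_attempts = n_valid.copy()
        else:
            if dev is Device.TE_M:
                p_fail = config.failure_prob_te_m(bmi)
                failed = rng.random(n) < p_fail
                te_m_cause = np.where(failed & (bmi >= 30), "OBESITY", np.where(failed, "OTHER", "NONE"))
            else:
                failed = rng.random(n) < config.te_xl_failure_prob
            noisy_p = config.te_m_noisy_prob if dev is Device.TE_M else config.te_xl_noisy_prob
            short_p = config.te_m_short_prob if dev is Device.TE_M else config.te_xl_short_prob
            noisy = rng.random(n) < noisy_p
            short = rng.random(n) < short_p
            sigma = np.where(noisy, config.noisy_session_sigma_log, sigma)
            n_valid = np.where(short, rng.integers(4, 10, size=n), n_valid)
            n_attempts = n_valid + rng.poisson(1.0, size=n)

        mean, median, mn, mx, cv, iqr = _session_summaries(rng, true, n_valid, sigma, ceiling)

        if dev is Device.SWE:
            # Qbox pixel minimum: long lower tail across all stages, floored
            # for reliable maps; dead-signal maps fall below 0.2 kPa
            tail = true * np.exp(
                config.swe_min_tail_mu + config.swe_min_tail_sd * rng.standard_normal(n)
            )
            mn = np.minimum(mn, np.maximum(config.swe_min_floor_kpa, tail))
            dead_min = rng.uniform(0.0, 0.2, n)
            mn = np.where(dead, dead_min, mn)

        depth = np.clip(rng.normal(30 + 0.6 * (bmi - 25), 6.0, n), 10, 80)
        nanify = lambda x: np.where(failed, np.nan, x)  # noqa: E731
        data[f"{key}_mean_kpa"] = nanify(mean)
        data[f"{key}_median_kpa"] = nanify(median)
        data[f"{key}_min_kpa"] = nanify(mn)
        data[f"{key}_max_kpa"] = nanify(mx)
        data[f"{key}_cv"] = nanify(cv)
        data[f"{key}_depth_mm"] = nanify(depth)
        data[f"{key}_n_valid"] = np.where(failed, 0, n_valid)
        data[f"{key}_n_attempts"] = np.where(failed, 0, n_attempts)
        data[f"{key}_iqr_kpa"] = nanify(iqr)
        data[f"{key}_failed"] = failed

    data["truth_stage"] = stage
    data["truth_inflam"] = inflam
    data["truth_steat"] = steat
    data["truth_swe_dead"] = dead
    data["truth_te_m_cause"] = te_m_cause
    return pd.DataFrame(data, columns=MANDATORY_COLUMNS + OPTIONAL_COLUMNS)


def generate(config: GeneratorConfig):
    """Generate a synthetic cohort as validated :class:`PatientRecord` list."""
    return frame_to_cohort(generate_frame(config))
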