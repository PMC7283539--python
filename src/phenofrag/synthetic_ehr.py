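"""Synthetic multi-institution EHR cohorts with latent disease status.

The generator emulates the study setting the evaluation pipeline needs: a
biobank-style cohort whose clinical events accrue over an eight-year window
and are *fragmented* across institutions. One institution (default
``"Mayo"``) is every patient's medical home; the second (default ``"REP"``)
plays the role of a record-linkage system that captures care delivered
outside the home institution plus a large share of home records. Each event
occurs at the home institution with per-patient probability ``p_home``
(drawn from the affinity distribution), otherwise at an outside provider —
whose records land in the linkage source. Directional duplication then
copies home events into the linkage source (default rate 0.9) and a small
share of outside records back into the home EHR (default 0.1), so the home
view is systematically less complete, the linkage view nearly complete, and
their union complete — the asymmetry the fragmentation analysis measures.
Setting ``duplication_rate`` to a scalar applies one rate in both directions;
``1.0`` removes fragmentation entirely (every view sees every event).

Latent RA / T2DM status is drawn at configured prevalences and stored in a
separate truth table that no classifier input encodes. Disease recipes give
affected patients event patterns that satisfy the corresponding phenotyping
algorithm on the union view with high probability, while "confuser" recipes
(isolated RA codes, prediabetes codes, abnormal labs without diagnoses,
diabetes supplies orders) populate the boundary of the rules. Event counts
are Poisson with configured means; lab values are Gaussian around
configured normal/abnormal levels.

Everything is driven by a single master seed; identical config and seed
reproduce byte-identical CSV output.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Literal, NamedTuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .ehr_model import EVENT_COLUMNS, ConfigError

__all__ = [
    "AffinityConfig",
    "EventRateParams",
    "LabValueParams",
    "SimulationConfig",
    "Cohort",
    "SweepEntry",
    "generate_cohort",
    "fragmentation_sweep",
    "load_sim_config",
]


class AffinityConfig(BaseModel):
    """Distribution of the per-patient home-source probability ``p_home``.

    ``beta`` draws p_home ~ Beta(mean*concentration, (1-mean)*concentration),
    modelling a mix of medical-home patients (p_home near 1) and transient or
    referral patients; ``fixed`` gives every patient the same value.
    """

    kind: Literal["beta", "fixed"] = "beta"
    mean: float = 0.8
    concentration: float = 10.0
    value: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "AffinityConfig":
        if self.kind == "fixed":
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError("fixed affinity requires value in [0, 1]")
        else:
            if not 0.0 < self.mean < 1.0 or self.concentration <= 0:
                raise ValueError("beta affinity requires mean in (0,1), concentration > 0")
        return self


class EventRateParams(BaseModel):
    """Per-status mean event counts (Poisson) and recipe rates."""

    # encounters (all patients); share flagged in-person
    encounters_min: int = Field(2, ge=0)
    encounters_mean: float = Field(8.0, ge=0)
    inperson_rate: float = Field(0.85, ge=0, le=1)

    # RA cases
    ra_dx_min: int = Field(2, ge=0)
    ra_dx_mean: float = Field(2.0, ge=0)
    ra_rf_lab_mean: float = Field(0.5, ge=0)  # on top of a guaranteed first test
    ra_rf_positive_rate: float = Field(0.9, ge=0, le=1)
    # non-RA screen noise: isolated RA codes / RF tests
    ra_screen_noise_rate: float = Field(0.04, ge=0, le=1)
    ra_exclusion_rate: float = Field(0.005, ge=0, le=1)

    # T2DM case recipe mixture (must sum to 1)
    t2dm_variant_shares: dict[str, float] = Field(
        default_factory=lambda: {
            "classic": 0.80,   # T2DM dx + T2DM med
            "dx_lab": 0.08,    # T2DM dx + abnormal lab, no med
            "med_lab": 0.04,   # T2DM med + abnormal lab, no dx
            "dual_rx": 0.05,   # T1DM dx + both meds, T2DM med first
            "t1_phys": 0.03,   # T1DM dx + T1DM med + >=2 physician T2DM dx
        }
    )
    t2dm_dx_mean: float = Field(1.0, ge=0)
    t2dm_med_mean: float = Field(0.7, ge=0)
    t2dm_abnormal_lab_rate: float = Field(0.6, ge=0, le=1)
    t2dm_abnormal_lab_mean: float = Field(0.5, ge=0)
    # glucose measurements (T2DM controls are guaranteed one)
    control_glucose_mean: float = Field(0.7, ge=0)
    # family history rates by T2DM status (controls are always False)
    family_history_case_rate: float = Field(0.5, ge=0, le=1)
    # how T2DM-neither patients fail the control screen (categorical shares)
    neither_disqualifier_shares: dict[str, float] = Field(
        default_factory=lambda: {
            "family_history": 0.55,
            "no_glucose_measure": 0.30,
            "dm_related_dx": 0.10,
            "abnormal_lab": 0.05,
        }
    )
    neither_supplies_rate: float = Field(0.03, ge=0, le=1)

    @field_validator("t2dm_variant_shares", "neither_disqualifier_shares")
    @classmethod
    def _shares_sum_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("shares must be non-negative and sum to 1")
        return v


class GaussianSpec(BaseModel):
    mean: float
    sd: float = Field(gt=0)
    lo: float | None = None
    hi: float | None = None


class LabValueParams(BaseModel):
    """Lab value distributions for diseased vs. healthy results."""

    rf_positive: GaussianSpec = GaussianSpec(mean=60, sd=20, lo=20)
    rf_negative: GaussianSpec = GaussianSpec(mean=6, sd=3, lo=0, hi=14.5)
    glucose_fasting_normal: GaussianSpec = GaussianSpec(mean=92, sd=8, lo=70, hi=124)
    glucose_random_normal: GaussianSpec = GaussianSpec(mean=110, sd=15, lo=70, hi=198)
    glucose_fasting_abnormal: GaussianSpec = GaussianSpec(mean=150, sd=20, lo=127)
    glucose_random_abnormal: GaussianSpec = GaussianSpec(mean=230, sd=25, lo=201)
    hba1c_abnormal: GaussianSpec = GaussianSpec(mean=7.5, sd=0.8, lo=6.6)


class SimulationConfig(BaseModel):
    """Complete, seedable description of a synthetic cohort."""

    n_patients: int = Field(2000, gt=0)
    seed: int = Field(0, ge=0)
    window_start: date = date(2010, 1, 1)
    window_end: date = date(2017, 12, 31)
    sources: list[str] = Field(default_factory=lambda: ["Mayo", "REP"])
    home_source: str = "Mayo"
    # benchmark prevalences follow the study cohort proportions:
    # 620/45,183 RA cases; 5,215/45,183 T2DM cases; 6,293/45,183 controls
    prevalence_ra: float = Field(620 / 45183, ge=0, le=1)
    prevalence_t2dm: float = Field(5215 / 45183, ge=0, le=1)
    prevalence_t2dm_control_eligible: float = Field(6293 / 45183, ge=0, le=1)
    affinity: AffinityConfig = Field(default_factory=AffinityConfig)
    duplication_rate: Union[float, dict[str, float]] = Field(
        default_factory=lambda: {"Mayo": 0.9, "REP": 0.1}
    )
    event_rate_params: EventRateParams = Field(default_factory=EventRateParams)
    abnormal_lab_params: LabValueParams = Field(default_factory=LabValueParams)
    #: probability an RA case also carries a confuser (SLE or PA) code
    miscoding_rate: float = Field(0.04, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if len(self.sources) < 2:
            raise ValueError("fragmentation studies require at least 2 sources")
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("sources must be distinct")
        if self.home_source not in self.sources:
            raise ValueError("home_source must be one of sources")
        if self.window_start > self.window_end:
            raise ValueError("window_start must be on or before window_end")
        if self.prevalence_t2dm + self.prevalence_t2dm_control_eligible > 1:
            raise ValueError("T2DM case + control prevalences exceed 1")
        if isinstance(self.duplication_rate, dict):
            unknown = set(self.duplication_rate) - set(self.sources)
            if unknown:
                raise ValueError(f"duplication_rate for unknown source(s): {sorted(unknown)}")
            rates = self.duplication_rate.values()
        else:
            rates = [self.duplication_rate]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("duplication rates must lie in [0, 1]")
        return self

    def duplication_for(self, source: str) -> float:
        if isinstance(self.duplication_rate, dict):
            return self.duplication_rate.get(source, 0.0)
        return self.duplication_rate


def load_sim_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"simulation config file not found: {path}")
    try:
        return SimulationConfig.model_validate(yaml.safe_load(path.read_text()) or {})
    except ValueError as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc


class Cohort(NamedTuple):
    patients: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame


class SweepEntry(NamedTuple):
    p_home: float
    seed: int
    cohort: Cohort


# concrete code pools aligned with the default code lists
_RA_DX = [("ICD9CM", "714.0"), ("ICD10CM", "M05.79"), ("ICD10CM", "M06.9")]
_SLE_DX = [("ICD9CM", "710.0"), ("ICD10CM", "M32.9")]
_PA_DX = [("ICD9CM", "696.0"), ("ICD10CM", "L40.50")]
_RA_EXCL = [("ICD10CM", "M08.3")]
_T2_DX = [("ICD9CM", "250.00"), ("ICD10CM", "E11.9"), ("ICD10CM", "E11.65")]
_T1_DX = [("ICD9CM", "250.01"), ("ICD10CM", "E10.9")]
_DM_RELATED_DX = [("ICD9CM", "790.29"), ("ICD10CM", "R73.03")]
_T2_MED = ["METFORMIN", "GLIPIZIDE", "GLYBURIDE"]
_T1_MED = ["INSULIN_GLARGINE", "INSULIN_LISPRO"]
_SUPPLIES = ["TEST_STRIPS", "LANCETS"]

_DX_ENTRY_MODES = (["billing", "physician", "nlp"], [0.7, 0.2, 0.1])
_MED_ENTRY_MODES = (["billing", "nlp"], [0.8, 0.2])


class _EventBuffer:
    """Column-wise accumulator for event blocks (kept vectorized)."""

    def __init__(self, patient_ids: np.ndarray, window: tuple[date, date]):
        self._pid = patient_ids
        self._start = np.datetime64(window[0])
        self._span_days = int((np.datetime64(window[1]) - self._start).astype(int)) + 1
        self.cols: dict[str, list[np.ndarray]] = {
            c: [] for c in ("patient_id", "event_type", "code_system", "code", "value", "date", "entry_mode")
        }

    def rand_dates(self, rng: np.random.Generator, size: int, lo: float = 0.0, hi: float = 1.0):
        lo_d, hi_d = int(lo * self._span_days), max(int(hi * self._span_days), int(lo * self._span_days) + 1)
        offsets = rng.integers(lo_d, hi_d, size=size)
        return self._start + offsets.astype("timedelta64[D]")

    def add(self, patient_idx, event_type, code_system, code, value, dates, entry_mode):
        size = len(patient_idx)
        if size == 0:
            return

        def as_arr(x, dtype=object):
            if np.ndim(x) == 0:
                return np.full(size, x, dtype=dtype)
            return np.asarray(x)

        self.cols["patient_id"].append(self._pid[np.asarray(patient_idx)])
        self.cols["event_type"].append(as_arr(event_type))
        self.cols["code_system"].append(as_arr(code_system))
        self.cols["code"].append(as_arr(code))
        self.cols["value"].append(as_arr(value, dtype=float))
        self.cols["date"].append(np.asarray(dates))
        self.cols["entry_mode"].append(as_arr(entry_mode))

    def frame(self) -> pd.DataFrame:
        if not self.cols["patient_id"]:
            return pd.DataFrame(columns=[c for c in EVENT_COLUMNS if c not in ("source_id", "linkage_key")])
        data = {k: np.concatenate(v) for k, v in self.cols.items()}
        frame = pd.DataFrame(data)
        frame["date"] = pd.to_datetime(frame["date"])
        return frame


def _gauss(rng: np.random.Generator, spec: GaussianSpec, size: int) -> np.ndarray:
    vals = rng.normal(spec.mean, spec.sd, size)
    if spec.lo is not None:
        vals = np.maximum(vals, spec.lo)
    if spec.hi is not None:
        vals = np.minimum(vals, spec.hi)
    return np.round(vals, 1)


def _pick_codes(rng: np.random.Generator, pool: list[tuple[str, str]], size: int):
    idx = rng.integers(0, len(pool), size)
    systems = np.array([p[0] for p in pool], dtype=object)[idx]
    codes = np.array([p[1] for p in pool], dtype=object)[idx]
    return systems, codes


def _dx_entries(rng: np.random.Generator, size: int):
    modes_list, probs = _DX_ENTRY_MODES
    modes = rng.choice(np.array(modes_list, dtype=object), size=size, p=probs)
    etype = np.where(modes == "nlp", "nlp_diagnosis", "diagnosis").astype(object)
    return etype, modes


def _repeat_idx(idx: np.ndarray, counts: np.ndarray) -> np.ndarray:
    return np.repeat(idx, counts)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate (patients, events, truth) for one synthetic cohort.

    Deterministic given ``config`` (including its seed). Events carry unique
    ``linkage_key`` values; cross-source duplicates of the same real-world
    event share a key.
    """
    n = config.n_patients
    p = config.event_rate_params
    labp = config.abnormal_lab_params
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_ev, rng_frag = (np.random.default_rng(s) for s in ss.spawn(3))

    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    all_idx = np.arange(n)

    # ----- latent truth ---------------------------------------------------
    ra_status = rng_truth.random(n) < config.prevalence_ra
    u = rng_truth.random(n)
    t2dm_status = np.where(
        u < config.prevalence_t2dm,
        "case",
        np.where(u < config.prevalence_t2dm + config.prevalence_t2dm_control_eligible, "control_eligible", "neither"),
    ).astype(object)

    family_history = np.zeros(n, dtype=bool)
    is_case = t2dm_status == "case"
    family_history[is_case] = rng_truth.random(is_case.sum()) < p.family_history_case_rate

    is_neither = t2dm_status == "neither"
    dq_names = list(p.neither_disqualifier_shares)
    dq_probs = [p.neither_disqualifier_shares[k] for k in dq_names]
    disqualifier = np.full(n, "", dtype=object)
    disqualifier[is_neither] = rng_truth.choice(
        np.array(dq_names, dtype=object), size=is_neither.sum(), p=dq_probs
    )
    family_history[disqualifier == "family_history"] = True

    buf = _EventBuffer(pid, (config.window_start, config.window_end))

    # ----- encounters (everyone) -----------------------------------------
    enc_counts = p.encounters_min + rng_ev.poisson(p.encounters_mean, n)
    enc_idx = _repeat_idx(all_idx, enc_counts)
    enc_codes = np.where(
        rng_ev.random(len(enc_idx)) < p.inperson_rate, "INPERSON", "VIRTUAL"
    ).astype(object)
    buf.add(enc_idx, "encounter", "NONE", enc_codes, np.nan,
            buf.rand_dates(rng_ev, len(enc_idx)), "billing")

    # ----- RA cases -------------------------------------------------------
    ra_idx = all_idx[ra_status]
    n_ra = len(ra_idx)
    ra_dx_counts = p.ra_dx_min + rng_ev.poisson(p.ra_dx_mean, n_ra)
    dx_rep = _repeat_idx(ra_idx, ra_dx_counts)
    systems, codes = _pick_codes(rng_ev, _RA_DX, len(dx_rep))
    etype, modes = _dx_entries(rng_ev, len(dx_rep))
    buf.add(dx_rep, etype, systems, codes, np.nan, buf.rand_dates(rng_ev, len(dx_rep)), modes)

    rf_counts = 1 + rng_ev.poisson(p.ra_rf_lab_mean, n_ra)
    rf_pos = rng_ev.binomial(rf_counts, p.ra_rf_positive_rate)
    # sparse-coded cases rely on serology: guarantee one positive RF test
    rf_pos = np.where((ra_dx_counts < 4) & (rf_pos == 0), 1, rf_pos)
    rf_neg = rf_counts - rf_pos
    pos_rep = _repeat_idx(ra_idx, rf_pos)
    neg_rep = _repeat_idx(ra_idx, rf_neg)
    buf.add(pos_rep, "lab", "LAB", "RF", _gauss(rng_ev, labp.rf_positive, len(pos_rep)),
            buf.rand_dates(rng_ev, len(pos_rep)), "billing")
    buf.add(neg_rep, "lab", "LAB", "RF", _gauss(rng_ev, labp.rf_negative, len(neg_rep)),
            buf.rand_dates(rng_ev, len(neg_rep)), "billing")

    confuser = ra_idx[rng_ev.random(n_ra) < config.miscoding_rate]
    systems, codes = _pick_codes(rng_ev, _SLE_DX + _PA_DX, len(confuser))
    etype, modes = _dx_entries(rng_ev, len(confuser))
    buf.add(confuser, etype, systems, codes, np.nan, buf.rand_dates(rng_ev, len(confuser)), modes)

    # ----- RA screen noise and exclusions (non-RA patients) ---------------
    non_ra = all_idx[~ra_status]
    noise_mask = rng_ev.random(len(non_ra)) < p.ra_screen_noise_rate
    noise_idx = non_ra[noise_mask]
    noise_dx = 1 + (rng_ev.random(len(noise_idx)) < 0.25).astype(int)
    dx_rep = _repeat_idx(noise_idx, noise_dx)
    systems, codes = _pick_codes(rng_ev, _RA_DX, len(dx_rep))
    etype, modes = _dx_entries(rng_ev, len(dx_rep))
    buf.add(dx_rep, etype, systems, codes, np.nan, buf.rand_dates(rng_ev, len(dx_rep)), modes)

    noise_rf = noise_idx[rng_ev.random(len(noise_idx)) < 0.2]
    noise_rf_pos = rng_ev.random(len(noise_rf)) < 0.1
    vals = np.where(
        noise_rf_pos,
        _gauss(rng_ev, labp.rf_positive, len(noise_rf)),
        _gauss(rng_ev, labp.rf_negative, len(noise_rf)),
    )
    buf.add(noise_rf, "lab", "LAB", "RF", vals, buf.rand_dates(rng_ev, len(noise_rf)), "billing")

    noise_confuser = noise_idx[rng_ev.random(len(noise_idx)) < 0.15]
    systems, codes = _pick_codes(rng_ev, _SLE_DX + _PA_DX, len(noise_confuser))
    etype, modes = _dx_entries(rng_ev, len(noise_confuser))
    buf.add(noise_confuser, etype, systems, codes, np.nan,
            buf.rand_dates(rng_ev, len(noise_confuser)), modes)

    excl_candidates = non_ra[~noise_mask]
    excl_idx = excl_candidates[rng_ev.random(len(excl_candidates)) < p.ra_exclusion_rate]
    systems, codes = _pick_codes(rng_ev, _RA_EXCL, len(excl_idx))
    buf.add(excl_idx, "diagnosis", systems, codes, np.nan,
            buf.rand_dates(rng_ev, len(excl_idx)), "billing")

    # ----- T2DM cases -----------------------------------------------------
    case_idx = all_idx[is_case]
    variant_names = list(p.t2dm_variant_shares)
    variant = rng_ev.choice(
        np.array(variant_names, dtype=object),
        size=len(case_idx),
        p=[p.t2dm_variant_shares[k] for k in variant_names],
    )

    def _add_dx(idx, pool, min_count, mean, lo=0.0, hi=1.0, entry=None):
        counts = min_count + rng_ev.poisson(mean, len(idx))
        rep = _repeat_idx(idx, counts)
        systems, codes = _pick_codes(rng_ev, pool, len(rep))
        if entry is None:
            etype, modes = _dx_entries(rng_ev, len(rep))
        else:
            modes = np.full(len(rep), entry, dtype=object)
            etype = np.where(modes == "nlp", "nlp_diagnosis", "diagnosis").astype(object)
        buf.add(rep, etype, systems, codes, np.nan, buf.rand_dates(rng_ev, len(rep), lo, hi), modes)
        return counts

    def _add_meds(idx, pool, min_count, mean, lo=0.0, hi=1.0):
        counts = min_count + rng_ev.poisson(mean, len(idx))
        rep = _repeat_idx(idx, counts)
        codes = np.array(pool, dtype=object)[rng_ev.integers(0, len(pool), len(rep))]
        modes_list, probs = _MED_ENTRY_MODES
        modes = rng_ev.choice(np.array(modes_list, dtype=object), size=len(rep), p=probs)
        buf.add(rep, "medication", "MED", codes, np.nan, buf.rand_dates(rng_ev, len(rep), lo, hi), modes)

    def _add_abnormal(idx, count_min, count_mean):
        counts = count_min + rng_ev.poisson(count_mean, len(idx))
        rep = _repeat_idx(idx, counts)
        analyte = rng_ev.integers(0, 3, len(rep))
        codes = np.array(["GLU_FASTING", "GLU_RANDOM", "HBA1C"], dtype=object)[analyte]
        vals = np.empty(len(rep))
        vals[analyte == 0] = _gauss(rng_ev, labp.glucose_fasting_abnormal, int((analyte == 0).sum()))
        vals[analyte == 1] = _gauss(rng_ev, labp.glucose_random_abnormal, int((analyte == 1).sum()))
        vals[analyte == 2] = _gauss(rng_ev, labp.hba1c_abnormal, int((analyte == 2).sum()))
        buf.add(rep, "lab", "LAB", codes, vals, buf.rand_dates(rng_ev, len(rep)), "billing")

    def _add_normal_glucose(idx, count_min, count_mean):
        counts = count_min + rng_ev.poisson(count_mean, len(idx))
        rep = _repeat_idx(idx, counts)
        fasting = rng_ev.random(len(rep)) < 0.5
        codes = np.where(fasting, "GLU_FASTING", "GLU_RANDOM").astype(object)
        vals = np.where(
            fasting,
            _gauss(rng_ev, labp.glucose_fasting_normal, len(rep)),
            _gauss(rng_ev, labp.glucose_random_normal, len(rep)),
        )
        buf.add(rep, "lab", "LAB", codes, vals, buf.rand_dates(rng_ev, len(rep)), "billing")

    for name in variant_names:
        idx = case_idx[variant == name]
        if name == "classic":
            _add_dx(idx, _T2_DX, 1, p.t2dm_dx_mean)
            _add_meds(idx, _T2_MED, 1, p.t2dm_med_mean)
            abn = idx[rng_ev.random(len(idx)) < p.t2dm_abnormal_lab_rate]
            _add_abnormal(abn, 1, p.t2dm_abnormal_lab_mean)
            _add_normal_glucose(idx, 0, 0.5)
        elif name == "dx_lab":
            _add_dx(idx, _T2_DX, 1, p.t2dm_dx_mean)
            _add_abnormal(idx, 1, p.t2dm_abnormal_lab_mean)
            _add_normal_glucose(idx, 0, 0.5)
        elif name == "med_lab":
            _add_meds(idx, _T2_MED, 1, 0.5)
            _add_abnormal(idx, 1, p.t2dm_abnormal_lab_mean)
        elif name == "dual_rx":
            _add_dx(idx, _T1_DX, 1, 0.5)
            _add_dx(idx, _T2_DX, 1, 0.5)
            # T2DM therapy strictly precedes insulin: disjoint date ranges
            _add_meds(idx, _T2_MED, 1, 0.3, lo=0.0, hi=0.45)
            _add_meds(idx, _T1_MED, 1, 0.3, lo=0.55, hi=1.0)
            abn = idx[rng_ev.random(len(idx)) < 0.5]
            _add_abnormal(abn, 1, 0.3)
        elif name == "t1_phys":
            _add_dx(idx, _T1_DX, 1, 0.5)
            # physician-asserted T2DM diagnoses (chart + NLP-extracted)
            counts = 2 + rng_ev.poisson(0.5, len(idx))
            rep = _repeat_idx(idx, counts)
            systems, codes = _pick_codes(rng_ev, _T2_DX, len(rep))
            modes = rng_ev.choice(np.array(["physician", "nlp"], dtype=object), size=len(rep), p=[0.6, 0.4])
            etype = np.where(modes == "nlp", "nlp_diagnosis", "diagnosis").astype(object)
            buf.add(rep, etype, systems, codes, np.nan, buf.rand_dates(rng_ev, len(rep)), modes)
            _add_dx(idx, _T2_DX, 0, 0.5, entry="billing")
            _add_meds(idx, _T1_MED, 1, 0.3)
            abn = idx[rng_ev.random(len(idx)) < 0.5]
            _add_abnormal(abn, 1, 0.3)

    # ----- T2DM controls --------------------------------------------------
    ctrl_idx = all_idx[t2dm_status == "control_eligible"]
    _add_normal_glucose(ctrl_idx, 1, p.control_glucose_mean)

    # ----- T2DM neither: disqualifier recipes ------------------------------
    dq_fam = all_idx[disqualifier == "family_history"]
    _add_normal_glucose(dq_fam, 0, 0.8)
    dq_dm = all_idx[disqualifier == "dm_related_dx"]
    systems, codes = _pick_codes(rng_ev, _DM_RELATED_DX, len(dq_dm))
    buf.add(dq_dm, "diagnosis", systems, codes, np.nan, buf.rand_dates(rng_ev, len(dq_dm)), "billing")
    _add_normal_glucose(dq_dm, 1, 0.5)
    dq_abn = all_idx[disqualifier == "abnormal_lab"]
    _add_abnormal(dq_abn, 1, 0.0)
    _add_normal_glucose(dq_abn, 0, 0.5)
    # "no_glucose_measure" patients simply receive no glucose labs

    neither_idx = all_idx[is_neither]
    supplies_idx = neither_idx[rng_ev.random(len(neither_idx)) < p.neither_supplies_rate]
    codes = np.array(_SUPPLIES, dtype=object)[rng_ev.integers(0, len(_SUPPLIES), len(supplies_idx))]
    buf.add(supplies_idx, "medication", "MED", codes, np.nan,
            buf.rand_dates(rng_ev, len(supplies_idx)), "billing")

    # ----- source assignment and duplication ------------------------------
    events = buf.frame()
    m = len(events)
    events["linkage_key"] = [f"E{i:08d}" for i in range(m)]

    if config.affinity.kind == "fixed":
        p_home = np.full(n, float(config.affinity.value))
    else:
        a = config.affinity.mean * config.affinity.concentration
        b = (1 - config.affinity.mean) * config.affinity.concentration
        p_home = rng_frag.beta(a, b, n)

    pid_to_idx = {s: i for i, s in enumerate(pid)}
    ev_pat = events["patient_id"].map(pid_to_idx).to_numpy()
    at_home = rng_frag.random(m) < p_home[ev_pat]

    others = [s for s in config.sources if s != config.home_source]
    primary = np.full(m, config.home_source, dtype=object)
    away = ~at_home
    if len(others) == 1:
        primary[away] = others[0]
    else:
        primary[away] = rng_frag.choice(np.array(others, dtype=object), size=int(away.sum()))
    events["source_id"] = primary

    dup_frames = [events]
    for src in config.sources:
        rate = config.duplication_for(src)
        if rate <= 0:
            continue
        src_rows = events[events["source_id"] == src]
        for other in config.sources:
            if other == src:
                continue
            copied = src_rows[rng_frag.random(len(src_rows)) < rate].copy()
            copied["source_id"] = other
            dup_frames.append(copied)

    full = pd.concat(dup_frames, ignore_index=True)
    full = full.sort_values(
        ["patient_id", "date", "linkage_key", "source_id"], kind="stable"
    ).reset_index(drop=True)
    full = full[EVENT_COLUMNS]

    patients = pd.DataFrame({"patient_id": pid, "family_history_dm": family_history})
    truth = pd.DataFrame({"patient_id": pid, "ra_status": ra_status, "t2dm_status": t2dm_status})
    return Cohort(patients=patients, events=full, truth=truth)


def fragmentation_sweep(
    config: SimulationConfig, p_home_values: list[float]
) -> list[SweepEntry]:
    """One cohort per home-affinity value, with reproducibly derived seeds.

    Each entry fixes every patient's ``p_home`` to the given value; all other
    parameters come from ``config``. Seeds are spawned from the base seed so
    entries are independent but fully reproducible.
    """
    if not p_home_values:
        raise ValueError("p_home_values must be non-empty")
    for v in p_home_values:
        if not 0.5 <= v <= 1.0:
            raise ValueError(f"p_home value {v} outside [0.5, 1.0]")
    children = np.random.SeedSequence(config.seed).spawn(len(p_home_values))
    entries = []
    for v, child in zip(p_home_values, children):
        seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        sub = config.model_copy(
            update={
                "seed": seed,
                "affinity": AffinityConfig(kind="fixed", value=float(v)),
            }
        )
        entries.append(SweepEntry(p_home=float(v), seed=seed, cohort=generate_cohort(sub)))
    return entries
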