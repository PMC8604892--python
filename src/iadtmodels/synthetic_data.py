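"""Synthetic PSA cohorts with the statistical structure of an IADT trial.

The generator emulates the data layout of an intermittent
androgen-deprivation trial: per patient, up to 5 on/off treatment cycles
(on-treatment duration centered on ≈35.5 weeks, off-treatment between 25.6
and 53.7 weeks), PSA sampled at an irregular ~14-day visit cadence with
additive Gaussian assay noise (default sd 0.1 µg/L) and a 0.1 µg/L
detection floor.  Relapsing (Ω) patients are drawn from a "resistant"
region of parameter space — for the default H10 generative model, an
elevated irreversibly androgen-independent channel — and continuing
responders (¬Ω) from a "responsive" region.

Ground-truth parameters, initial states and group labels are attached to
the generated cohort so closed-loop recovery experiments can score fits
against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import DETECTION_FLOOR, Cohort, PatientRecord
from .model_zoo import get_model
from .schedule import TreatmentSchedule
from .simulator import SimulationError, simulate_psa

__all__ = ["GeneratorConfig", "RelapseRule", "generate_cohort", "label_relapse"]

WEEK = 7.0  # days


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic trial."""

    n_patients: int = 20
    model_id: str = "H10"
    cycles_max: int = 5
    on_weeks_center: float = 35.5        # median on-treatment duration target
    on_weeks_sd: float = 2.5
    off_weeks_range: tuple[float, float] = (25.6, 53.7)
    sampling_interval_days: float = 14.0
    sampling_jitter_days: float = 3.0
    noise_sd: float = 0.1                # µg/L, additive Gaussian
    relapse_fraction: float = 0.5
    detection_floor: float = DETECTION_FLOOR
    error_assigned: float = 0.1          # per-point PSA error recorded, µg/L
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self):
        if not 0.0 <= self.relapse_fraction <= 1.0:
            raise ValueError("relapse_fraction must lie in [0, 1]")
        if self.cycles_max < 1 or self.n_patients < 1:
            raise ValueError("cycles_max and n_patients must be positive")


@dataclass
class RelapseRule:
    """Ω iff some later on-treatment cycle minimum exceeds factor × the
    first-cycle minimum (the response fails to return to its initial depth)."""

    factor: float = 2.0

    def to_dict(self) -> dict:
        return {"rule": "cycle_minimum_ratio", "factor": self.factor}


# ---------------------------------------------------------------------------
# schedule sampling
# ---------------------------------------------------------------------------

def _draw_schedule(rng: np.random.Generator, cfg: GeneratorConfig,
                   patient_id: str) -> TreatmentSchedule:
    n_cycles = int(rng.integers(2, cfg.cycles_max + 1))
    pairs = []
    for _ in range(n_cycles):
        on_w = rng.normal(cfg.on_weeks_center, cfg.on_weeks_sd)
        on_w = float(np.clip(on_w, cfg.on_weeks_center - 3 * cfg.on_weeks_sd,
                             cfg.on_weeks_center + 3 * cfg.on_weeks_sd))
        off_w = float(rng.uniform(*cfg.off_weeks_range))
        pairs.append((on_w * WEEK, off_w * WEEK))
    return TreatmentSchedule.from_durations(0.0, pairs, patient_id=patient_id)


def _draw_times(rng: np.random.Generator, cfg: GeneratorConfig,
                t_max: float) -> np.ndarray:
    times = [0.0]
    lo = cfg.sampling_interval_days - cfg.sampling_jitter_days
    hi = cfg.sampling_interval_days + cfg.sampling_jitter_days
    t = 0.0
    while True:
        t += rng.uniform(lo, hi)
        if t >= t_max:
            break
        times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# per-model parameter samplers (responsive vs resistant regions)
# ---------------------------------------------------------------------------

def _sample_h10(rng, group, schedule):
    n_cyc = schedule.n_cycles
    on_mean = schedule.on_duration / n_cyc
    off_mean = (schedule.t_max - schedule.t_min
                - schedule.on_duration) / n_cyc
    # calibrate the androgen-dependent kinetics to the cycle durations: PSA
    # falls by ~2-3 dex over one on-phase and regrows to near baseline over
    # one off-phase (the clinical picture of a responding IADT cycle);
    # mutation couplings are kept small so they perturb rather than drive
    # the cycle-to-cycle dynamics
    drop_ln = rng.uniform(5.0, 7.0)
    rise_ln = drop_ln + rng.uniform(-1.2, 0.3)
    base = dict(
        gamma_D_on=-drop_ln / on_mean,
        gamma_D_off=rise_ln / off_mean,
        gamma_I_on=rng.uniform(-0.004, -0.001),
        gamma_I_off=rng.uniform(-0.001, 0.001),
        mu_ID=rng.uniform(2e-5, 1e-4),
        mu_DI=rng.uniform(2e-5, 1e-4),
        w_D=1.0, w_I=1.0, w_Irr=1.0,
    )
    if group == "omega":
        # irreversible channel compounds to a few tens of µg/L over the study
        g_irr = rng.uniform(0.0012, 0.002)
        base.update(
            gamma_Irr_on=g_irr, gamma_Irr_off=g_irr,
            mu_DIrr=rng.uniform(2e-5, 1e-4),
            mu_IIrr=rng.uniform(2e-5, 1e-4),
        )
        n_irr0 = rng.uniform(0.1, 0.3)
    else:
        g_irr = rng.uniform(0.0, 0.0003)
        base.update(
            gamma_Irr_on=g_irr, gamma_Irr_off=g_irr,
            mu_DIrr=rng.uniform(0.0, 2e-5),
            mu_IIrr=rng.uniform(0.0, 2e-5),
        )
        n_irr0 = rng.uniform(0.001, 0.02)
    init = np.array([rng.uniform(5.0, 15.0), rng.uniform(0.2, 0.6), n_irr0])
    return base, init


def _sample_b20(rng, group, schedule):
    if group == "omega":
        p_S = rng.uniform(0.02, 0.06)   # stem-cell enrichment drives relapse
    else:
        p_S = rng.uniform(0.002, 0.01)
    params = dict(
        p_S=p_S,
        delta_D=rng.uniform(0.02, 0.05),
        gamma_PSA=rng.uniform(0.05, 0.2),
        delta_PSA=rng.uniform(0.08, 0.2),
    )
    n_D0 = rng.uniform(5.0, 15.0)
    init = np.array([
        rng.uniform(0.01, 0.1), n_D0,
        params["gamma_PSA"] * n_D0 / params["delta_PSA"],
    ])
    return params, init


def _sample_p12a(rng, group, schedule):
    from .model_zoo import _DEFAULTS
    base = dict(_DEFAULTS["P12A"])
    for key in ("v_max", "delta_q", "gamma_max", "delta_D", "delta_I",
                "gamma_PSA0", "gamma_PSA_D", "gamma_PSA_I", "delta_PSA"):
        base[key] *= rng.uniform(0.8, 1.2)
    if group == "omega":
        base["mu_DI_max"] = rng.uniform(0.001, 0.003)
    else:
        base["mu_DI_max"] = rng.uniform(0.0, 0.0002)
    q0 = base["q_max"] * rng.uniform(0.5, 0.9)
    init = np.array([rng.uniform(5.0, 15.0), rng.uniform(0.1, 0.5), q0,
                     rng.uniform(5.0, 20.0)])
    return base, init


_PARAM_SAMPLERS = {"H10": _sample_h10, "B20": _sample_b20, "P12A": _sample_p12a}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a reproducible synthetic cohort with attached ground truth.

    Per patient: draw the Ω/¬Ω group, a treatment schedule and model
    parameters from the group's region, simulate the generative model,
    sample PSA at irregular visit times, add Gaussian noise and clamp at
    the detection floor.  Parameter draws whose simulation fails are
    redrawn (counted in the provenance, capped at ``max_redraws``).
    """
    cfg = config
    md = get_model(cfg.model_id)
    if cfg.model_id not in _PARAM_SAMPLERS:
        raise ValueError(
            f"no parameter sampler for generative model {cfg.model_id!r}; "
            f"available: {sorted(_PARAM_SAMPLERS)}"
        )
    sampler = _PARAM_SAMPLERS[cfg.model_id]
    rng = np.random.default_rng(cfg.seed)

    records, truth = [], {}
    redraws = 0
    for i in range(cfg.n_patients):
        pid = f"SYN{i:03d}"
        group = "omega" if rng.random() < cfg.relapse_fraction else "not_omega"
        for attempt in range(cfg.max_redraws + 1):
            schedule = _draw_schedule(rng, cfg, pid)
            pdict, init = sampler(rng, group, schedule)
            params = md.pvector(pdict)
            times = _draw_times(rng, cfg, schedule.t_max)
            try:
                clean = simulate_psa(cfg.model_id, params, init, schedule,
                                     times,
                                     solver_opts={"rtol": 1e-8, "atol": 1e-10})
            except (SimulationError, ValueError):
                redraws += 1
                continue
            break
        else:
            raise RuntimeError(
                f"{pid}: exceeded {cfg.max_redraws} parameter redraws"
            )
        noise = (rng.normal(0.0, cfg.noise_sd, size=times.size)
                 if cfg.noise_sd > 0 else np.zeros(times.size))
        psa = np.maximum(clean + noise, cfg.detection_floor)
        rec = PatientRecord(
            patient_id=pid,
            times=times,
            psa=psa,
            errors=np.full(times.size, cfg.error_assigned),
            on_flag=np.asarray(schedule.indicator(times), dtype=int),
            label=group,
            schedule=schedule,
        )
        records.append(rec)
        truth[pid] = {
            "model_id": cfg.model_id,
            "params": {k: float(v) for k, v in pdict.items()},
            "init_state": init.tolist(),
            "group": group,
            "clean_psa": clean.tolist(),
        }
    return Cohort(
        records=records,
        provenance={
            "source": f"synthetic:{cfg.model_id}",
            "seed": cfg.seed,
            "redraws": redraws,
            "filters": [],
        },
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# relapse labeling
# ---------------------------------------------------------------------------

def label_relapse(record: PatientRecord, rule: RelapseRule | None = None) -> str:
    """Label a record Ω/¬Ω from its on-treatment cycle minima.

    Requires at least two treatment cycles with data; otherwise returns
    "unknown".
    """
    rule = rule or RelapseRule()
    minima = []
    for iv in record.schedule.intervals:
        mask = (record.times >= iv.start) & (record.times < iv.end)
        if mask.any():
            minima.append(float(record.psa[mask].min()))
        else:
            minima.append(math.nan)
    usable = [m for m in minima if not math.isnan(m)]
    if len(usable) < 2 or math.isnan(minima[0]):
        return "unknown"
    first = minima[0]
    for m in minima[1:]:
        if not math.isnan(m) and m > rule.factor * first:
            return "omega"
    return "not_omega"
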