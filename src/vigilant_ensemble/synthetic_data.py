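"""Synthetic cohorts with the statistical structure of a long-duration
spaceflight vigilance study.

The generator emulates a cohort of ~24 crew members on ~160-day missions who
complete a Reaction Self-Test (survey + sleep diary + 3-minute reaction-time
bout) twice per testing day, every 4 days, alongside continuously logged
cabin environment streams.  It is first-class, tested code: every downstream
stage (scoring, fusion, modelling, validation, importance ranking) is
exercised against cohorts whose generating truth is known and stored.

Generating model for the outcome (the LRM-50 alertness score, lower =
better) at participant *i*'s *j*-th test::

    y_ij = beta0 + sum_p beta_p * x_ij^(p)
           + sum_p gamma_p * sin(2*pi*t_ij) * x_ij^(p)   (optional, time-varying)
           + b_i + e_ij + spike_ij

with person random intercepts ``b_i ~ N(0, sigma_person^2)``, AR(1) errors
``e_ij = rho * e_{i,j-1} + eta_ij`` (``eta`` innovation sd ``sigma_eps``,
stationary start), and rare one-sided spikes — additive positive
(performance-worsening) exponential shifts, mirroring the unanticipated
high-score excursions real crews show.

Environmental streams carry sinusoidal diurnal cycles plus AR noise at
realistic cadences: daily radiation (mGy/day), 10-minute temperature (per
module), CO₂ and O₂ (mmHg), and sparse 24-hour acoustic dosimeter sessions
(dBA, per module) roughly every other month — so noise is structurally
unobserved at almost every test time, as in flight.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import DAY_START_HOUR, NODE2, USLAB, EnvStream

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_env_streams",
    "generate_outcomes",
    "inject_missingness",
    "simulate",
    "RATING_COLUMNS",
]

RATING_COLUMNS = (
    "sleepy",
    "tired",
    "mentally_fatigued",
    "physically_exhausted",
    "stressed",
    "workload",
    "sleep_quality",
)

_DEFAULT_BETAS = {
    "temperature": 1.0,
    "co2": 2.0,
    "radiation": 12.0,
    "stress_latent": 1.5,
    "caffeine_doses": -0.8,
}

_DEFAULT_MISSINGNESS = {
    "rst": 0.16,  # in-flight non-adherence ≈ 1 − 0.838
    "temperature": 0.02,
    "co2": 0.02,
    "o2": 0.02,
    "radiation": 0.05,
    "noise": 0.0,  # sessions are already structurally sparse
    "sleep": 0.10,
}


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort.

    Defaults mirror the study design being emulated: 24 participants,
    160-day missions, tests twice per day every 4 days, an outcome centred
    near −33 with total SD ≈ 12, and environment streams at flight-like
    cadences.  Spike rate and magnitude are free parameters (no published
    calibration exists); see the methods note.
    """

    n_participants: int = 24
    mission_days: int = 160
    rst_cycle_days: int = 4
    rst_per_test_day: int = 2
    beta0: float = -33.0
    truth_betas: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BETAS)
    )
    #: optional time-varying effects: variable -> amplitude of a
    #: sin(2*pi*t) modulation of that variable's coefficient
    time_varying_betas: dict[str, float] = field(default_factory=dict)
    sigma_person: float = 6.0
    rho_ar1: float = 0.4
    sigma_eps: float = 6.0
    spike_prob: float = 0.02
    spike_scale: float = 15.0
    noise_session_cadence_days: int = 60
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    start_date: str = "2011-03-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.mission_days < 1:
            raise ValueError("mission_days must be >= 1")
        if self.rst_cycle_days < 1:
            raise ValueError("rst_cycle_days must be >= 1")
        if not (0.0 <= self.rho_ar1 < 1.0):
            raise ValueError("rho_ar1 must lie in [0, 1)")
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ValueError("spike_prob must lie in [0, 1]")
        if self.sigma_person < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_person and sigma_eps must be nonnegative")
        if self.spike_scale <= 0:
            raise ValueError("spike_scale must be positive")
        for k, v in self.missingness.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"missingness rate for {k!r} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """A generated cohort: self-test table, sensor streams, demographics and
    the generating truth (stored verbatim, for recovery tests)."""

    rst: pd.DataFrame
    env_streams: list[EnvStream]
    demographics: pd.DataFrame
    truth: dict
    config: CohortConfig

    def write_csv(self, out_dir) -> dict[str, str]:
        """Write rst/env/demographics CSVs plus a JSON sidecar with
        config + truth; returns the mapping of logical name to path."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        rst_path = os.path.join(out_dir, "rst_records.csv")
        self.rst.to_csv(rst_path, index=False)
        paths["rst_records"] = rst_path
        env_rows = []
        for st in self.env_streams:
            s = st.samples.copy()
            s["variable"] = st.variable
            s["location"] = st.location
            env_rows.append(s)
        env_path = os.path.join(out_dir, "env_streams.csv")
        pd.concat(env_rows, ignore_index=True)[
            ["variable", "location", "timestamp", "value"]
        ].to_csv(env_path, index=False)
        paths["env_streams"] = env_path
        demo_path = os.path.join(out_dir, "demographics.csv")
        self.demographics.to_csv(demo_path, index=False)
        paths["demographics"] = demo_path
        sidecar = os.path.join(out_dir, "truth.json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"config": self.config.to_dict(), "truth": _jsonable(self.truth)},
                fh,
                indent=2,
                default=str,
            )
        paths["truth"] = sidecar
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# deterministic environmental mean functions (the generating "truth" curves)
# --------------------------------------------------------------------------

_TEMP_BASE = {NODE2: 22.3, USLAB: 23.0}
_NOISE_DAY = {NODE2: 61.0, USLAB: 59.0}
_NOISE_NIGHT = {NODE2: 54.0, USLAB: 52.0}


def env_truth(variable: str, hours: np.ndarray, location: str | None = None):
    """Deterministic mean value of a stream at ``hours`` since mission start.

    These closed-form curves are what the sampled streams fluctuate around;
    tests compare interpolators and hourly averages against them.
    """
    h = np.asarray(hours, dtype=float)
    day = h / 24.0
    hod = np.mod(h, 24.0)  # hour of (UTC) day
    if variable == "temperature":
        base = _TEMP_BASE.get(location, 22.5)
        return base + 0.5 * np.sin(2 * np.pi * (hod - 10.0) / 24.0) + 0.3 * np.sin(
            2 * np.pi * day / 90.0
        )
    if variable == "co2":
        return 3.2 + 0.4 * np.sin(2 * np.pi * (hod - 12.0) / 24.0)
    if variable == "o2":
        return 162.0 + 1.5 * np.sin(2 * np.pi * day / 60.0)
    if variable == "radiation":
        return 0.25 + 0.05 * np.sin(2 * np.pi * day / 120.0)
    if variable == "noise":
        is_day = (hod >= DAY_START_HOUR) & (hod < 23.0)
        d = _NOISE_DAY.get(location, 60.0)
        n = _NOISE_NIGHT.get(location, 53.0)
        return np.where(is_day, d, n) + 1.0 * np.sin(2 * np.pi * (hod - 13.0) / 24.0)
    if variable == "occupancy":
        # 6 crew nominally; brief 9-crew handovers every ~8 weeks
        return np.where(np.mod(day, 56.0) < 7.0, 9.0, 6.0)
    raise ValueError(f"unknown variable {variable!r}")


_STREAM_NOISE_SD = {
    "temperature": 0.15,
    "co2": 0.10,
    "o2": 0.30,
    "radiation": 0.02,
    "noise": 1.5,
    "occupancy": 0.0,
}


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float = 0.8):
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    eta = rng.normal(0.0, innov_sd, size=n - 1)
    for j in range(1, n):
        e[j] = rho * e[j - 1] + eta[j - 1]
    return e


def generate_env_streams(
    config: CohortConfig, *, noise_sd_scale: float = 1.0
) -> list[EnvStream]:
    """Sample the sensor streams for one mission.

    Radiation and occupancy daily; temperature/CO₂/O₂ every 10 minutes
    (temperature per module); noise as 24-hour 1-minute dBA sessions every
    ``noise_session_cadence_days`` per module.  ``noise_sd_scale=0`` yields
    the deterministic mean functions exactly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    origin = pd.Timestamp(config.start_date, tz="UTC")
    total_h = config.mission_days * 24.0
    streams: list[EnvStream] = []

    def _mk(variable, hours, location=None):
        truth = env_truth(variable, hours, location)
        sd = _STREAM_NOISE_SD[variable] * noise_sd_scale
        vals = truth + _ar1_noise(rng, len(hours), sd)
        ts = origin + pd.to_timedelta(hours, unit="h")
        return EnvStream(
            variable=variable,
            location=location,
            samples=pd.DataFrame({"timestamp": ts, "value": vals}),
        )

    daily_h = np.arange(config.mission_days) * 24.0 + 12.0
    streams.append(_mk("radiation", daily_h))
    occ = EnvStream(
        variable="occupancy",
        samples=pd.DataFrame(
            {
                "timestamp": origin + pd.to_timedelta(daily_h, unit="h"),
                "value": env_truth("occupancy", daily_h),
            }
        ),
    )
    streams.append(occ)

    subhourly = np.arange(0.0, total_h, 1.0 / 6.0)  # 10-minute cadence
    for loc in (NODE2, USLAB):
        streams.append(_mk("temperature", subhourly, loc))
    streams.append(_mk("co2", subhourly))
    streams.append(_mk("o2", subhourly))

    session_starts = np.arange(10, config.mission_days, config.noise_session_cadence_days)
    minutes = np.arange(0.0, 24.0, 1.0 / 60.0)
    for loc in (NODE2, USLAB):
        for d0 in session_starts:
            streams.append(_mk("noise", d0 * 24.0 + minutes, loc))
    return streams


# --------------------------------------------------------------------------
# cohort schedule, surveys, diaries, demographics
# --------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the RST schedule with surveys, diaries and covariates
    (outcomes unfilled), the environment streams and demographics.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical cohort.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 202])
    rng = np.random.default_rng(ss)
    origin = pd.Timestamp(config.start_date, tz="UTC")

    # demographics emulate the published cohort summary
    ids = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    demographics = pd.DataFrame(
        {
            "participant": ids,
            "age": np.round(rng.normal(48.2, 4.78, config.n_participants), 1),
            "sex": rng.choice(
                ["M", "F"], size=config.n_participants, p=[0.792, 0.208]
            ),
            "preflight_ops": np.clip(
                rng.normal(0.95, 0.02, config.n_participants), 0.80, 1.0
            ),
            "prior_missions": rng.poisson(1.29, config.n_participants),
        }
    )

    env_streams = generate_env_streams(config)

    rows = []
    test_days = np.arange(0, config.mission_days, config.rst_cycle_days)
    track_hours = {"morning": 7.5, "evening": 21.0}
    tracks = ["morning", "evening"][: config.rst_per_test_day]
    for pid in ids:
        # per-person latent stress/fatigue trajectory over test days (AR)
        latent = 4.0 + _ar1_noise(rng, len(test_days), sd=1.2, rho=0.7)
        # habitual sleep timing
        bed_h = rng.normal(23.0, 0.5)
        wake_h = rng.normal(6.8, 0.4)
        for d_idx, d in enumerate(test_days):
            for track in tracks:
                hod = track_hours[track] + rng.normal(0.0, 0.6)
                hod = float(np.clip(hod, 0.0, 23.95))
                hours = d * 24.0 + hod
                if hours >= config.mission_days * 24.0:
                    continue
                ts = origin + pd.Timedelta(hours=hours)
                z = latent[d_idx] + rng.normal(0.0, 0.3)
                ratings = {
                    c: float(np.clip(np.round(z + rng.normal(0.0, 1.0)), 0, 10))
                    for c in (
                        "sleepy",
                        "tired",
                        "mentally_fatigued",
                        "physically_exhausted",
                        "stressed",
                    )
                }
                # workload is uncorrelated with the latent state (its PCA
                # loading should come out negligible); one rating per track
                ratings["workload"] = (
                    float(np.clip(np.round(rng.normal(4.5, 2.0)), 0, 10))
                    if track == "evening"
                    else np.nan
                )
                ratings["sleep_quality"] = (
                    float(np.clip(np.round(z + rng.normal(0.0, 1.2)), 0, 10))
                    if track == "morning"
                    else np.nan
                )
                # previous night's sleep episode
                bed = origin + pd.Timedelta(
                    hours=(d - 1) * 24.0 + bed_h + rng.normal(0.0, 0.7)
                )
                wake = origin + pd.Timedelta(
                    hours=d * 24.0 + wake_h + rng.normal(0.0, 0.5)
                )
                meds = _draw_meds(rng)
                loc = rng.choice([NODE2, USLAB, "other"], p=[0.6, 0.2, 0.2])
                env_vals = {
                    var: float(
                        env_truth(var, np.array([hours]), loc if var in
                                  ("temperature", "noise") else None)[0]
                        + rng.normal(0.0, _STREAM_NOISE_SD[var])
                    )
                    for var in ("temperature", "co2", "o2", "radiation", "noise")
                }
                env_vals["occupancy"] = float(env_truth("occupancy", np.array([hours]))[0])
                rows.append(
                    {
                        "participant": pid,
                        "timestamp": ts,
                        "mission_day": int(d),
                        "mission_frac": hours / (config.mission_days * 24.0),
                        "track": track,
                        "location": loc,
                        **ratings,
                        "bedtime": bed,
                        "waketime": wake,
                        "sleep_latency_min": float(np.round(rng.exponential(15.0), 1)),
                        "waso_min": float(np.round(rng.exponential(20.0), 1)),
                        "time_in_bed_after_wake_min": float(
                            np.round(rng.exponential(10.0), 1)
                        ),
                        "meds_text": meds,
                        "caffeine_doses": int(rng.poisson(2.0)),
                        "stress_latent": z,
                        **env_vals,
                    }
                )
    rst = pd.DataFrame(rows).sort_values(["participant", "timestamp"]).reset_index(
        drop=True
    )
    truth = {
        "beta0": config.beta0,
        "betas": dict(config.truth_betas),
        "time_varying_betas": dict(config.time_varying_betas),
        "sigma_person": config.sigma_person,
        "rho_ar1": config.rho_ar1,
        "sigma_eps": config.sigma_eps,
        "spike_prob": config.spike_prob,
        "spike_scale": config.spike_scale,
    }
    return SyntheticCohort(
        rst=rst,
        env_streams=env_streams,
        demographics=demographics,
        truth=truth,
        config=config,
    )


_MED_POOL = (
    "ibuprofen 400mg",
    "acetaminophen 500mg",
    "zolpidem 5mg",
    "melatonin",
    "pseudoephedrine 30mg",
    "loratadine 10mg",
    "zolpidem; loratadine",
)


def _draw_meds(rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.88:
        return "None"
    if u < 0.90:
        return "Decline to answer"
    return str(rng.choice(_MED_POOL))


#: fixed nominal centres used when applying truth betas, so that ``beta0``
#: is the cohort-level outcome centre regardless of which effects are on
_NOMINAL_MEANS = {
    "temperature": 22.5,
    "co2": 3.2,
    "o2": 162.0,
    "radiation": 0.25,
    "noise": 58.0,
    "occupancy": 6.0,
    "stress_latent": 4.0,
    "caffeine_doses": 2.0,
    "preflight_ops": 0.95,
    "age": 48.2,
}


def generate_outcomes(cohort: SyntheticCohort, config: CohortConfig | None = None):
    """Fill the outcome column ``lrm50`` from the stored generating truth.

    ``y = beta0 + (X − c) beta (+ time-varying terms) + b_i + AR(1) + spikes``
    with fixed nominal centres ``c`` per covariate, so ``beta0`` stays the
    outcome's centre.  Covariates named in ``truth_betas`` must exist as
    columns of the RST table (or demographics).  Returns the cohort with
    outcomes and the drawn ``b_i`` added to ``truth``.
    """
    config = config or cohort.config
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    rst = cohort.rst
    demo = cohort.demographics.set_index("participant")

    def _factors(name: str) -> list[str]:
        return [f.strip() for f in name.split("*")]

    missing = sorted(
        {
            f
            for v in list(config.truth_betas) + list(config.time_varying_betas)
            for f in _factors(v)
            if f not in rst.columns and f not in demo.columns
        }
    )
    if missing:
        raise ValueError(f"truth_betas name absent covariates: {missing}")

    def _col(var: str) -> np.ndarray:
        """Centred covariate; ``a*b`` names mean products of centred
        factors (``x*x`` gives a quadratic, ``a*b`` an interaction)."""
        out = np.ones(len(rst))
        for f in _factors(var):
            x = (
                rst[f].to_numpy(dtype=float)
                if f in rst.columns
                else rst["participant"].map(demo[f]).to_numpy(dtype=float)
            )
            out = out * (x - _NOMINAL_MEANS.get(f, 0.0))
        return out

    fixed = np.full(len(rst), config.beta0)
    for var, beta in config.truth_betas.items():
        fixed += beta * _col(var)
    for var, amp in config.time_varying_betas.items():
        fixed += amp * np.sin(2 * np.pi * rst["mission_frac"].to_numpy()) * _col(var)

    ids = demo.index.tolist()
    b = dict(zip(ids, rng.normal(0.0, config.sigma_person, len(ids))))
    y = fixed + rst["participant"].map(b).to_numpy(dtype=float)

    # AR(1) error per participant in observation order (rst is sorted)
    err = np.empty(len(rst))
    for pid, idx in rst.groupby("participant").indices.items():
        n = len(idx)
        rho, se = config.rho_ar1, config.sigma_eps
        e = np.empty(n)
        stat_sd = se / np.sqrt(1.0 - rho**2) if rho > 0 else se
        e[0] = rng.normal(0.0, stat_sd)
        eta = rng.normal(0.0, se, size=n - 1)
        for j in range(1, n):
            e[j] = rho * e[j - 1] + eta[j - 1]
        err[idx] = e
    spikes = np.where(
        rng.random(len(rst)) < config.spike_prob,
        rng.exponential(config.spike_scale, len(rst)),
        0.0,
    )
    rst = rst.copy()
    rst["lrm50"] = y + err + spikes
    rst["spike"] = spikes
    truth = dict(cohort.truth)
    truth["b_i"] = b
    return SyntheticCohort(
        rst=rst,
        env_streams=cohort.env_streams,
        demographics=cohort.demographics,
        truth=truth,
        config=config,
    )


def inject_missingness(
    cohort: SyntheticCohort, rates: dict[str, float] | None = None
) -> SyntheticCohort:
    """Remove values at random (seeded) to emulate non-adherence and sensor
    gaps; removal audit flags are kept in ``truth['removed']``.

    Rates keyed by ``"rst"`` (whole test rows), stream variable names
    (stream samples), and ``"sleep"`` (diary fields).
    """
    config = cohort.config
    rates = dict(config.missingness if rates is None else rates)
    for k, v in rates.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"missingness rate for {k!r} must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    removed: dict[str, int] = {}

    rst = cohort.rst.copy()
    r = rates.get("rst", 0.0)
    keep = rng.random(len(rst)) >= r
    removed["rst_rows"] = int((~keep).sum())
    rst = rst[keep].reset_index(drop=True)

    r = rates.get("sleep", 0.0)
    blank = rng.random(len(rst)) < r
    removed["sleep_rows"] = int(blank.sum())
    sleep_cols = [
        "bedtime",
        "waketime",
        "sleep_latency_min",
        "waso_min",
        "time_in_bed_after_wake_min",
    ]
    rst.loc[blank, sleep_cols] = np.nan

    streams = []
    for st in cohort.env_streams:
        r = rates.get(st.variable, 0.0)
        if r == 0.0:
            streams.append(st)
            continue
        if r >= 1.0:
            keep_mask = np.zeros(len(st.samples), dtype=bool)
        else:
            keep_mask = rng.random(len(st.samples)) >= r
        removed[f"{st.variable}:{st.location}"] = int((~keep_mask).sum())
        streams.append(
            EnvStream(
                variable=st.variable,
                location=st.location,
                samples=st.samples[keep_mask].reset_index(drop=True),
                units=st.units,
            )
        )
    truth = dict(cohort.truth)
    truth["removed"] = removed
    return SyntheticCohort(
        rst=rst,
        env_streams=streams,
        demographics=cohort.demographics,
        truth=truth,
        config=config,
    )


def simulate(config: CohortConfig) -> SyntheticCohort:
    """Full generation pipeline: schedule/covariates → outcomes → missingness."""
    cohort = generate_cohort(config)
    cohort = generate_outcomes(cohort)
    return inject_missingness(cohort)
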