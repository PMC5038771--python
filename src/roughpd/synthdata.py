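"""Seeded generator of synthetic Parkinson's-disease examination cohorts.

The generator emulates the repeated-measures structure of a DBS cohort
measured in four treatment sessions (S1 med off / stim off, S2 off/on,
S3 on/off, S4 on/on): strong session effects on the UPDRS scales and on
reflexive-saccade latency, a shared patient-level random factor that
makes good and bad responders consistent across scales, and saccade
amplitude / duration / velocity that do not depend on the session.

Model, per patient p with standard-normal factor z_p and session s:

    value = mu_vs + sigma_vs * (rho_v * z_p + sqrt(1 - rho_v^2) * eps)

for v in {total UPDRS, latency}; UPDRS III follows the total through a
correlation-0.9 proportional coupling, UPDRS II/IV and the clinical
staging scales (Hoehn-Yahr, Schwab-England) are derived from the total,
and the well-being scales (PDQ-39, AIMS, Epworth) are patient-level
with small session jitter.  Scores are clamped to their scale ranges
and rounded to the scale's resolution.

:func:`calibrated_cohort` additionally adjusts the integer scores so
that the per-session sample means of age, disease duration, UPDRS,
UPDRS III and latency equal the published cohort summary exactly.  It
is a *synthetic* stand-in for the study's (unpublished) full data table
and is the fixture all dataset-level experiments run on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .tables import AttributeSpec, DecisionTable, InformationTable, as_decision_table

__all__ = ["CohortParams", "default_params", "generate_cohort", "calibrated_cohort",
           "COHORT_SCHEMA"]

SESSIONS = ("1", "2", "3", "4")

COHORT_SCHEMA = [
    AttributeSpec("Pat", "nominal", "condition", ""),
    AttributeSpec("age", "numeric", "condition", "years"),
    AttributeSpec("sex", "nominal", "condition", "0=female,1=male"),
    AttributeSpec("t_dur", "numeric", "condition", "years"),
    AttributeSpec("Sess", "nominal", "condition", "S1-S4"),
    AttributeSpec("UPDRS", "numeric", "condition", "score points"),
    AttributeSpec("UPDRS_II", "numeric", "condition", "score points"),
    AttributeSpec("UPDRS_III", "numeric", "condition", "score points"),
    AttributeSpec("UPDRS_IV", "numeric", "condition", "score points"),
    AttributeSpec("HYsc", "numeric", "condition", "stage"),
    AttributeSpec("SEngs", "numeric", "condition", "%"),
    AttributeSpec("PDQ39", "numeric", "condition", "score points"),
    AttributeSpec("AIMS", "numeric", "condition", "score points"),
    AttributeSpec("Epworth", "numeric", "condition", "score points"),
    AttributeSpec("SccDur", "numeric", "condition", "ms"),
    AttributeSpec("SccLat", "numeric", "condition", "ms"),
    AttributeSpec("SccAmp", "numeric", "condition", "deg"),
    AttributeSpec("SccVel", "numeric", "condition", "deg/s"),
]


@dataclass
class CohortParams:
    """Cohort-level means/SDs (per session where the quantity is
    session-dependent) and the two coupling shares."""

    n_patients: int = 10
    age_mean: float = 51.1
    age_sd: float = 10.2
    duration_mean: float = 11.3
    duration_sd: float = 3.2
    updrs_mean: tuple = (66.6, 30.0, 58.1, 22.3)
    updrs_sd: tuple = (13.8, 16.3, 13.5, 13.6)
    updrs3_mean: tuple = (42.7, 17.8, 34.1, 10.9)
    updrs3_sd: tuple = (11.3, 10.6, 10.8, 8.3)
    latency_mean: tuple = (291.2, 199.6, 232.9, 183.2)
    latency_sd: tuple = (93.1, 39.5, 82.7, 30.0)
    #: share of each scale's SD carried by the patient random effect;
    #: 0.85 mirrors the high test-retest stability of patient severity
    #: rankings on the UPDRS (within-patient correlation rho^2 ~ 0.7)
    rho: float = 0.85
    #: share of latency SD carried by the same patient factor (>0 makes
    #: latency and UPDRS move in parallel across patients and sessions)
    gamma: float = 0.5
    amplitude_mean: float = 10.5
    amplitude_sd: float = 1.5
    scc_duration_mean: float = 44.0
    scc_duration_sd: float = 3.0
    velocity_slope: float = 46.0  # deg/s per deg of amplitude
    velocity_sd: float = 50.0
    pdq39_mean: float = 72.0
    pdq39_sd: float = 18.0
    aims_mean: float = 8.0
    aims_sd: float = 5.0
    epworth_mean: float = 9.0
    epworth_sd: float = 4.0
    #: scales the auxiliary noise terms (UPDRS II/IV residuals,
    #: Schwab-England noise, session jitter of the well-being scales);
    #: 0 together with zero SDs gives a fully deterministic cohort
    aux_noise: float = 1.0
    integer_scores: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        for name in ("updrs_sd", "updrs3_sd", "latency_sd"):
            if any(s < 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be nonnegative")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortParams":
        raw = yaml.safe_load(text)
        for key in ("updrs_mean", "updrs_sd", "updrs3_mean", "updrs3_sd",
                    "latency_mean", "latency_sd"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_params() -> CohortParams:
    """The published cohort parameterization (10 patients, 4 sessions)."""
    return CohortParams()


def _score(x: float, lo: float, hi: float, step: float, integer: bool) -> float:
    x = min(max(x, lo), hi)
    if integer:
        return round(x / step) * step
    return x


def generate_cohort(
    params: CohortParams | None = None,
    seed: int = 0,
) -> DecisionTable:
    """Draw one synthetic cohort (n_patients x 4 sessions, one record
    per examination); deterministic given (params, seed)."""
    p = params or default_params()
    rng = np.random.default_rng(seed)
    rnd = p.integer_scores
    records = []
    for pat in range(p.n_patients):
        z = rng.standard_normal()  # shared patient factor
        age = _score(p.age_mean + p.age_sd * rng.standard_normal(), 18, 90, 1, rnd)
        dur = _score(p.duration_mean + p.duration_sd * rng.standard_normal(),
                     1, 40, 1, rnd)
        sex = str(int(rng.integers(2)))
        pdq = p.pdq39_mean + p.pdq39_sd * rng.standard_normal()
        aims = p.aims_mean + p.aims_sd * rng.standard_normal()
        epw = p.epworth_mean + p.epworth_sd * rng.standard_normal()
        for s, sess in enumerate(SESSIONS):
            eps = rng.standard_normal()
            t_std = p.rho * z + np.sqrt(1 - p.rho**2) * eps
            total_c = p.updrs_mean[s] + p.updrs_sd[s] * t_std
            # UPDRS III: correlation-0.9 coupling to the total's deviation
            u3_std = 0.9 * t_std + np.sqrt(1 - 0.81) * rng.standard_normal()
            u3_c = p.updrs3_mean[s] + p.updrs3_sd[s] * u3_std
            lat_std = p.gamma * z + np.sqrt(1 - p.gamma**2) * rng.standard_normal()
            lat_c = p.latency_mean[s] + p.latency_sd[s] * lat_std
            amp = _score(p.amplitude_mean + p.amplitude_sd * rng.standard_normal(),
                         5, 15, 0.1, rnd)
            sdur = _score(
                p.scc_duration_mean + p.scc_duration_sd * rng.standard_normal(),
                30, 60, 1, rnd)
            vel = _score(p.velocity_slope * amp + p.velocity_sd * rng.standard_normal(),
                         340, 700, 0.1, rnd)
            total = _score(total_c, 0, 108, 1, rnd)
            records.append({
                "Pat": str(pat + 1),
                "age": age,
                "sex": sex,
                "t_dur": dur,
                "Sess": sess,
                "UPDRS": total,
                "UPDRS_II": _score(0.22 * total_c + 2.0 * p.aux_noise * rng.standard_normal(),
                                   0, 52, 1, rnd),
                "UPDRS_III": _score(u3_c, 0, 108, 1, rnd),
                "UPDRS_IV": _score(0.08 * total_c + 1.5 * p.aux_noise * rng.standard_normal(),
                                   0, 16, 1, rnd),
                "HYsc": _score(0.03 * total_c + 0.3, 0, 5, 0.5, rnd),
                "SEngs": _score(95 - 0.45 * total_c + 5 * p.aux_noise * rng.standard_normal(),
                                0, 100, 10, rnd),
                "PDQ39": _score(pdq + 4 * p.aux_noise * rng.standard_normal(), 0, 156, 1, rnd),
                "AIMS": _score(aims + 1.5 * p.aux_noise * rng.standard_normal(), 0, 42, 1, rnd),
                "Epworth": _score(epw + 1.5 * p.aux_noise * rng.standard_normal(), 0, 24, 1, rnd),
                "SccDur": sdur,
                "SccLat": _score(lat_c, 80, 800, 1, rnd),
                "SccAmp": amp,
                "SccVel": vel,
            })
    table = InformationTable(COHORT_SCHEMA, records)
    return as_decision_table(table, "UPDRS")


def _adjust_sum(values: list[float], target_sum: float, step: float = 1.0) -> list[float]:
    """Shift entries by +-step until the sum hits the target (largest
    shifts spread round-robin across entries)."""
    values = list(values)
    delta = round((target_sum - sum(values)) / step)
    sign = 1 if delta > 0 else -1
    for i in range(abs(int(delta))):
        values[i % len(values)] += sign * step
    return values


def calibrated_cohort(seed: int = 0, params: CohortParams | None = None) -> DecisionTable:
    """Synthetic stand-in for the study's full data table: a generated
    cohort whose sample means of age, disease duration and per-session
    UPDRS / UPDRS III / latency are adjusted to equal the published
    summary statistics exactly (integer largest-remainder shifts)."""
    p = params or default_params()
    dt = generate_cohort(p, seed)
    records = [dict(r) for r in dt.base.records]
    n = p.n_patients

    # patient-level quantities: each patient contributes one value x 4 rows
    for attr, mean in (("age", p.age_mean), ("t_dur", p.duration_mean)):
        per_pat = [records[4 * i][attr] for i in range(n)]
        adjusted = _adjust_sum(per_pat, round(mean * n))
        for i in range(n):
            for s in range(4):
                records[4 * i + s][attr] = adjusted[i]

    # session-level quantities
    for attr, means in (
        ("UPDRS", p.updrs_mean),
        ("UPDRS_III", p.updrs3_mean),
        ("SccLat", p.latency_mean),
    ):
        for s in range(4):
            idx = [4 * i + s for i in range(n)]
            vals = [records[j][attr] for j in idx]
            adjusted = _adjust_sum(vals, round(means[s] * n))
            for j, v in zip(idx, adjusted):
                records[j][attr] = v

    table = InformationTable(dt.base.schema, records, dt.base.ids)
    return DecisionTable(table, dt.decision)
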