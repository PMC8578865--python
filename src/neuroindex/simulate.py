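"""Synthetic two-trial generator with a linear-Gaussian latent structure.

No patient-level data accompany the study design this package analyses, so
every downstream stage is exercised on synthetic cohorts built to carry the
statistical structure the analyses presuppose:

* patients start with lower serum BDNF than healthy controls;
* a stable per-subject *neuroplasticity trait* raises BDNF and lowers
  HAMD-24 at every visit, inducing the negative baseline BDNF-HAMD
  correlation and the strong NI autocorrelation across visits;
* a per-subject *treatment responsiveness* amplitude scales the arm's mean
  trajectory in both modalities, coupling early NI enhancement to the final
  HAMD-24 reduction (the basis of the prediction ROC);
* enrollment floors (HAMD-24 >= 20, QIDS-SR16 >= 5 at day 0) are enforced by
  resampling, keeping the baseline distribution smooth;
* per arm, a fixed number of subjects is missing *all* BDNF draws (whole-
  subject missingness, as when blood was never taken).

Model, per patient subject i of arm a with latent draws
t_i, s_i ~ N(0,1) and g_i ~ N(1, sigma_g^2):

    L_i      = sigma_h * (-c * t_i + sqrt(1 - c^2) * s_i)        (HAMD level)
    HAMD_id  = round(mu_H + dH_a(d) * g_i + L_i + e_id),  e ~ N(0, sd_H^2)
    BDNF_id  = mu_B - deficit + dB_a(d) * g_i + tau * t_i + u_id, u ~ N(0, sd_B^2)

with HAMD floored at 0, BDNF floored at 1 pg/ml, dH_a(0) = dB_a(0) = 0, and
the subject resampled in full until HAMD_i0 >= 20 and QIDS_i0 >= 5.  QIDS and
PHQ-9 are noisy affine functions of the same within-visit severity state.
Healthy controls contribute a single day-0 BDNF draw.

:func:`expected_structure` evaluates the population summaries this model
implies (baseline means, the truncated baseline BDNF-HAMD correlation, and
NI autocorrelations) by closed-form truncated-Gaussian algebra and
deterministic Gauss-Hermite/Gauss-Legendre quadrature -- no sampling -- so
parameter-recovery tests have an oracle independent of the sampler.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .io import TrialDataset

PATIENT_ARMS = ("yueju", "escitalopram")


def default_arm_profiles() -> dict:
    """Per-arm, per-day mean changes from baseline (HAMD-24 points; BDNF pg/ml).

    The yueju-like arm improves symptomatically from day 4 and raises BDNF at
    every blood draw; the escitalopram-like arm improves more modestly and
    leaves BDNF flat by day 28 (with a mild early dip).  The escitalopram
    trajectory is deliberately calibrated so that subjects rarely reach a 60%
    HAMD-24 reduction, reproducing the scarcity of responders that makes a
    prediction ROC infeasible for that arm.
    """
    return {
        "yueju": {
            "hamd": {0: 0.0, 4: -8.0, 7: -10.0, 14: -14.0, 28: -16.5},
            "bdnf": {0: 0.0, 4: 2500.0, 7: 3000.0, 28: 4500.0},
        },
        "escitalopram": {
            "hamd": {0: 0.0, 4: -4.0, 7: -5.5, 14: -6.5, 28: -7.5},
            "bdnf": {0: 0.0, 4: -800.0, 7: -400.0, 28: 0.0},
        },
    }


def default_schedules() -> dict:
    return {
        "trial1": {"scales": [0, 7, 14, 28], "blood": [0, 7, 28]},
        "trial2": {"scales": [0, 4, 7, 14, 28], "blood": [0, 4, 28]},
    }


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohorts.

    Units: BDNF quantities in pg/ml, HAMD quantities in scale points.
    ``trait_coupling`` in [0, 1] sets how strongly the latent trait that
    raises BDNF also lowers HAMD-24; ``response_dispersion`` is the SD of the
    per-subject amplitude multiplying the arm's mean trajectory.
    """

    seed: int = 0
    n_per_arm: int = 18
    n_controls: int = 11
    n_trial1: int = 15
    control_bdnf_mean: float = 26000.0
    control_bdnf_sd: float = 3400.0
    patient_bdnf_deficit: float = 8000.0
    hamd_baseline_mean: float = 26.0
    hamd_baseline_sd: float = 4.0
    trait_sd: float = 3000.0
    trait_coupling: float = 0.8
    response_dispersion: float = 0.35
    measurement_sd_hamd: float = 2.0
    measurement_sd_bdnf: float = 1500.0
    missing_bdnf_per_arm: int = 4
    missing_bdnf_trial1: int = 1
    min_hamd: int = 20
    min_qids: int = 5
    qids_scale: float = 0.45
    qids_sd: float = 1.5
    phq_scale: float = 0.35
    phq_sd: float = 1.5
    bdnf_floor: float = 1.0
    arm_profiles: dict = dataclasses.field(default_factory=default_arm_profiles)
    schedules: dict = dataclasses.field(default_factory=default_schedules)

    def __post_init__(self) -> None:
        for name in ("control_bdnf_sd", "hamd_baseline_sd", "trait_sd",
                     "response_dispersion", "measurement_sd_hamd",
                     "measurement_sd_bdnf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.trait_coupling <= 1.0:
            raise ValueError("trait_coupling must be in [0, 1]")
        if self.n_per_arm <= self.missing_bdnf_per_arm:
            raise ValueError("n_per_arm must exceed missing_bdnf_per_arm")
        if self.n_trial1 <= self.missing_bdnf_trial1:
            raise ValueError("n_trial1 must exceed missing_bdnf_trial1")

    # -------------------------------------------------------------- yaml io
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _profile_delta(cfg: GeneratorConfig, arm: str, kind: str, day: int) -> float:
    return float(cfg.arm_profiles[arm][kind].get(day, 0.0))


def _draw_patients(
    cfg: GeneratorConfig, trial: str, arm: str, n: int,
    n_missing: int, prefix: str, rng: np.random.Generator,
) -> pd.DataFrame:
    if arm not in cfg.arm_profiles:
        raise KeyError(f"arm {arm!r} has no profile")
    sched = cfg.schedules[trial]
    scale_days = [int(d) for d in sched["scales"]]
    blood_days = [int(d) for d in sched["blood"]]
    c = cfg.trait_coupling
    sh = cfg.hamd_baseline_sd

    # Rejection-sample the baseline-determining draws until the enrollment
    # floors hold (equivalent to resampling the whole subject).
    t = np.empty(0)
    s = np.empty(0)
    e0 = np.empty(0)
    q0 = np.empty(0, dtype=int)
    while t.size < n:
        m = max(2 * (n - t.size) + 16, 32)
        tb = rng.standard_normal(m)
        sb = rng.standard_normal(m)
        e0b = rng.normal(0.0, cfg.measurement_sd_hamd, m)
        Lb = sh * (-c * tb + np.sqrt(1.0 - c * c) * sb)
        h0raw = cfg.hamd_baseline_mean + Lb + e0b
        q0b = np.clip(
            np.rint(cfg.qids_scale * h0raw + rng.normal(0.0, cfg.qids_sd, m)),
            0, 27,
        ).astype(int)
        ok = (np.rint(h0raw) >= cfg.min_hamd) & (q0b >= cfg.min_qids)
        t = np.concatenate([t, tb[ok]])
        s = np.concatenate([s, sb[ok]])
        e0 = np.concatenate([e0, e0b[ok]])
        q0 = np.concatenate([q0, q0b[ok]])
    t, s, e0, q0 = t[:n], s[:n], e0[:n], q0[:n]
    L = sh * (-c * t + np.sqrt(1.0 - c * c) * s)
    g = rng.normal(1.0, cfg.response_dispersion, n)

    mB = cfg.control_bdnf_mean - cfg.patient_bdnf_deficit
    missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist())

    rows = []
    sids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    hamd = {}
    qids = {}
    phq = {}
    for d in scale_days:
        dh = _profile_delta(cfg, arm, "hamd", d)
        e_d = e0 if d == 0 else rng.normal(0.0, cfg.measurement_sd_hamd, n)
        hraw = cfg.hamd_baseline_mean + dh * g + L + e_d
        hamd[d] = np.maximum(np.rint(hraw), 0).astype(int)
        if d == 0:
            qids[d] = q0
        else:
            qids[d] = np.clip(
                np.rint(cfg.qids_scale * hraw + rng.normal(0.0, cfg.qids_sd, n)),
                0, 27,
            ).astype(int)
        phq[d] = np.clip(
            np.rint(cfg.phq_scale * hraw + rng.normal(0.0, cfg.phq_sd, n)),
            0, 27,
        ).astype(int)
    bdnf = {}
    for d in blood_days:
        db = _profile_delta(cfg, arm, "bdnf", d)
        u_d = rng.normal(0.0, cfg.measurement_sd_bdnf, n)
        bdnf[d] = np.maximum(mB + db * g + cfg.trait_sd * t + u_d, cfg.bdnf_floor)

    for i, sid in enumerate(sids):
        for d in scale_days:
            b = bdnf[d][i] if (d in bdnf and i not in missing_idx) else np.nan
            rows.append(
                {"subject_id": sid, "trial": trial, "arm": arm, "day": d,
                 "hamd24": float(hamd[d][i]), "qids_sr16": float(qids[d][i]),
                 "phq9": float(phq[d][i]), "bdnf_pg_ml": b}
            )
    return pd.DataFrame(rows)


def simulate_subject(
    cfg: GeneratorConfig, arm: str, rng: np.random.Generator,
    trial: str = "trial2",
) -> pd.DataFrame:
    """Per-day records of a single simulated subject (no BDNF missingness)."""
    return _draw_patients(cfg, trial, arm, 1, 0, "S", rng)


def _trial_rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


def simulate_trial(
    cfg: GeneratorConfig, trial: str, rng: np.random.Generator | None = None
) -> TrialDataset:
    """One full trial cohort as a validated :class:`TrialDataset`.

    ``trial1`` is the single-arm cohort (``n_trial1`` subjects, scales on
    days 0/7/14/28, blood on 0/7/28); ``trial2`` the two-arm cohort
    (``n_per_arm`` per arm, scales on 0/4/7/14/28, blood on 0/4/28, with
    ``missing_bdnf_per_arm`` subjects per arm missing all BDNF).
    """
    if trial not in ("trial1", "trial2"):
        raise ValueError("trial must be 'trial1' or 'trial2'")
    if rng is None:
        rng = _trial_rng(cfg, 1 if trial == "trial1" else 2)
    if trial == "trial1":
        frames = [
            _draw_patients(cfg, "trial1", "yueju", cfg.n_trial1,
                           cfg.missing_bdnf_trial1, "T1Y", rng)
        ]
    else:
        frames = [
            _draw_patients(cfg, "trial2", "yueju", cfg.n_per_arm,
                           cfg.missing_bdnf_per_arm, "T2Y", rng),
            _draw_patients(cfg, "trial2", "escitalopram", cfg.n_per_arm,
                           cfg.missing_bdnf_per_arm, "T2E", rng),
        ]
    return TrialDataset(pd.concat(frames, ignore_index=True))


def simulate_controls(
    cfg: GeneratorConfig, trial: str = "trial1",
    rng: np.random.Generator | None = None,
) -> TrialDataset:
    """Healthy-control BDNF draws (day 0 only, no scale scores)."""
    if rng is None:
        rng = _trial_rng(cfg, 0)
    b = np.maximum(
        rng.normal(cfg.control_bdnf_mean, cfg.control_bdnf_sd, cfg.n_controls),
        cfg.bdnf_floor,
    )
    frame = pd.DataFrame(
        {
            "subject_id": [f"HC{i + 1:03d}" for i in range(cfg.n_controls)],
            "trial": trial,
            "arm": "healthy_control",
            "day": 0,
            "hamd24": np.nan,
            "qids_sr16": np.nan,
            "phq9": np.nan,
            "bdnf_pg_ml": b,
        }
    )
    return TrialDataset(frame)


def simulate_bundle(cfg: GeneratorConfig) -> dict[str, TrialDataset]:
    """The full study: trial1, trial2 and the healthy-control table."""
    return {
        "trial1": simulate_trial(cfg, "trial1"),
        "trial2": simulate_trial(cfg, "trial2"),
        "controls": simulate_controls(cfg),
    }


# --------------------------------------------------------------------------
# Analytic population structure (the parameter-recovery oracle)
# --------------------------------------------------------------------------

def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled for a standard normal measure."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def expected_structure(cfg: GeneratorConfig, trial: str = "trial2") -> dict:
    """Population summaries implied by the generator's latent model.

    Returns closed-form / quadrature values (no sampling):

    * ``control_bdnf_mean`` -- healthy-control population mean;
    * ``patient_bdnf_mean_day0`` and ``patient_hamd_mean_day0`` -- baseline
      means after the enrollment truncation (Mills-ratio shift);
    * ``bdnf_hamd_corr_day0`` -- the truncated-Gaussian baseline correlation
      (identical across patient arms, which share the baseline model);
    * ``ni_autocorr`` -- per-arm population correlation between NI at day 0
      and NI at the trial's early blood day, by deterministic quadrature over
      the latents (continuous model; integer rounding of scores is ignored,
      a < 1% effect at these noise levels);
    * ``early_day`` -- the early blood day used.

    The truncation condition is the continuous-score event
    ``HAMD_0 >= min_hamd - 0.5`` (the rounding boundary); the QIDS floor,
    which co-truncates < 1% of subjects at the defaults, is ignored.
    """
    sched = cfg.schedules[trial]
    blood_days = [int(d) for d in sched["blood"]]
    early = blood_days[1]
    arms = ["yueju"] if trial == "trial1" else list(PATIENT_ARMS)

    c = cfg.trait_coupling
    sh = cfg.hamd_baseline_sd
    sd_h = cfg.measurement_sd_hamd
    sd_b = cfg.measurement_sd_bdnf
    tau = cfg.trait_sd
    mH = cfg.hamd_baseline_mean
    mB0 = cfg.control_bdnf_mean - cfg.patient_bdnf_deficit
    a = cfg.min_hamd - 0.5

    # --- closed-form baseline block (one-sided truncation on HAMD_0) ---
    var_h0 = sh * sh + sd_h * sd_h
    sd_h0 = np.sqrt(var_h0)
    alpha = (a - mH) / sd_h0
    lam = norm.pdf(alpha) / norm.sf(alpha)          # Mills ratio
    kfac = 1.0 + alpha * lam - lam * lam            # truncated variance factor
    hamd0_mean = mH + sd_h0 * lam
    cov_bh = -tau * c * sh                          # Cov(BDNF_0, HAMD_0)
    var_b0 = tau * tau + sd_b * sd_b
    beta = cov_bh / var_h0
    bdnf0_mean = mB0 + beta * sd_h0 * lam
    var_h0_t = var_h0 * kfac
    var_b0_t = beta * beta * var_h0_t + (var_b0 - beta * beta * var_h0)
    corr0 = beta * var_h0_t / np.sqrt(var_b0_t * var_h0_t)

    # --- NI autocorrelation day 0 <-> early, by quadrature per arm ---
    tn, tw = _gh_nodes(48)
    sn, sw = _gh_nodes(48)
    gn, gw = _gh_nodes(24)
    ni_autocorr = {}
    for arm in arms:
        dh_e = _profile_delta(cfg, arm, "hamd", early)
        db_e = _profile_delta(cfg, arm, "bdnf", early)
        t = tn[:, None, None]
        s = sn[None, :, None]
        gz = gn[None, None, :]
        w3 = tw[:, None, None] * sw[None, :, None] * gw[None, None, :]
        g = 1.0 + cfg.response_dispersion * gz
        L = sh * (-c * t + np.sqrt(1.0 - c * c) * s)
        C0 = mH + L + 0.0 * gz           # day-0 HAMD conditional mean
        Ce = mH + dh_e * g + L           # early-day HAMD conditional mean
        m0 = mB0 + tau * t + 0.0 * s + 0.0 * gz
        me = mB0 + db_e * g + tau * t + 0.0 * s

        P0 = _trunc_prob(C0, sd_h, a)
        I1 = _gauss_recip_moment(C0, sd_h, 1, lo=a)
        I2 = _gauss_recip_moment(C0, sd_h, 2, lo=a)
        J1 = _gauss_recip_moment(Ce, sd_h, 1, lo=0.5)
        J2 = _gauss_recip_moment(Ce, sd_h, 2, lo=0.5)

        Z = float((w3 * P0).sum())
        EN0 = float((w3 * m0 * I1).sum()) / Z
        EN0sq = float((w3 * (m0 * m0 + sd_b * sd_b) * I2).sum()) / Z
        ENe = float((w3 * P0 * me * J1).sum()) / Z
        ENesq = float((w3 * P0 * (me * me + sd_b * sd_b) * J2).sum()) / Z
        EN0Ne = float((w3 * m0 * me * I1 * J1).sum()) / Z
        var0 = EN0sq - EN0 * EN0
        vare = ENesq - ENe * ENe
        ni_autocorr[arm] = (EN0Ne - EN0 * ENe) / np.sqrt(var0 * vare)

    return {
        "control_bdnf_mean": float(cfg.control_bdnf_mean),
        "patient_bdnf_mean_day0": float(bdnf0_mean),
        "patient_hamd_mean_day0": float(hamd0_mean),
        "bdnf_hamd_corr_day0": float(corr0),
        "ni_autocorr": {arm: float(v) for arm, v in ni_autocorr.items()},
        "early_day": early,
    }


def _trunc_prob(mean: np.ndarray, sd: float, lo: float) -> np.ndarray:
    if sd == 0.0:
        return (mean >= lo).astype(float)
    return norm.sf((lo - mean) / sd)


def _gauss_recip_moment(
    mean: np.ndarray, sd: float, power: int, lo: float, n_nodes: int = 80
) -> np.ndarray:
    """E[ 1/H^power * 1{H >= lo} ] for H ~ N(mean, sd^2), by Gauss-Legendre.

    Integrates over [lo, mean + 12 sd]; mass below ``lo`` is excluded, which
    for the NI integrals encodes that a zero score leaves the index undefined.
    """
    mean = np.asarray(mean, dtype=float)
    if sd == 0.0:
        with np.errstate(divide="ignore"):
            out = np.where(mean >= lo, 1.0 / np.maximum(mean, 1e-300) ** power, 0.0)
        return out
    x, w = _gl_nodes(n_nodes)
    hi = np.maximum(mean + 12.0 * sd, lo + sd)
    half = (hi - lo) / 2.0
    mid = (hi + lo) / 2.0
    h = mid[..., None] + half[..., None] * x          # (..., n_nodes)
    dens = norm.pdf((h - mean[..., None]) / sd) / sd
    vals = dens / h**power
    return (vals * w).sum(axis=-1) * half
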