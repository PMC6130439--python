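"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the analysis assumes: children scanned
one to three times roughly 1.5 years apart between ages 7 and 15, with a
latent default-mode / task-positive anticorrelation that is modulated by
diagnostic group, sex, age, a subject-level random intercept and scan-level
noise; head motion with occasional spikes that leak a global artifact into
the BOLD signal; and an identical-pairs CPT whose sensitivity is coupled to
the connectivity metric.

The anticorrelation is injected at the level of two latent network factors
rather than edge by edge: per scan, the default-mode factor and the
task-positive factor are bivariate standard normal with correlation
``rho = tanh(zeta)``, and every ROI loads on its own network's factor.
This gives every between-network edge the same expected Pearson correlation

    E[r] = rho * lambda^2 / (lambda^2 + sigma_roi^2),

a closed form used as the validation oracle throughout the test suite.

Two output granularities are supported: the full per-scan artifact set
(time series, motion, CPT trial logs) for end-to-end pipeline runs, and a
records-only fast path that draws the per-scan analysis rows directly from
the same latent model, used for the large simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import CptCounts, score_cpt, sdt_response_probs, simulate_trials
from .types import MotionTrace, Parcellation, ScanTimeSeries

_MAX_ABS_ZETA = np.arctanh(0.999)


def toy_parcellation(
    n_default: int = 4, n_taskpos: int = 6, n_other: int = 2
) -> Parcellation:
    """A small parcellation for simulation: Default, task-positive, other."""
    tp_nets = ["CinguloOperc", "DorsalAttn", "FrontoParietal"]
    nets = ["Default"] * n_default
    nets += [tp_nets[i % len(tp_nets)] for i in range(n_taskpos)]
    nets += ["Other"] * n_other
    return Parcellation(networks=tuple(nets))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic cohort.

    Defaults target a cohort resembling the developmental ADHD setting the
    package is built for: ~150 children per group aged 7-11 at baseline,
    follow-up scans about 1.5 years apart reaching age 15, a male-biased
    ADHD group, a baseline latent anticorrelation of ``z0 = -0.60``
    (so the averaged Fisher-z metric sits near -0.28 under the default
    loadings), an ADHD shift of +0.06 toward zero, a female shift of -0.05,
    and a small negative age slope (connectivity grows more negative with
    development).
    """

    n_subjects_per_group: int = 150
    p_wave2: float = 0.30
    p_wave3: float = 0.10  # conditional on having a wave-2 scan
    baseline_age_range: tuple[float, float] = (7.0, 11.0)
    lag_mean_years: float = 1.5
    lag_jitter_years: float = 0.2
    male_fraction: dict = field(
        default_factory=lambda: {"control": 0.5, "adhd": 0.7}
    )
    age_ref: float = 10.0

    # latent connectivity model (Fisher-z scale)
    z0: float = -0.60
    delta_group: float = 0.06
    delta_sex: float = -0.05
    beta_age: float = -0.01
    tau_subject: float = 0.08
    sigma_scan: float = 0.05
    lambda_loading: float = 1.0
    sigma_roi: float = 1.0
    #: scan-level measurement noise of the averaged metric in records-only
    #: mode (stands in for finite-frame, finite-edge estimation error)
    sigma_metric_noise: float = 0.02

    # time-series geometry
    parcellation: Parcellation = field(default_factory=toy_parcellation)
    n_frames: int = 450
    tr_seconds: float = 2.0

    # motion model
    fd_base_mean: float = 0.10
    spike_prob: float = 0.05
    spike_mag_mm: float = 0.5
    artifact_gain: float = 1.0

    # behavior model
    a_easy: float = 1.97
    a_difficult: float = 0.56
    b_conn: float = 2.8
    sigma_dprime: float = 0.8
    criterion: float = 0.0
    n_trials: int = 300
    target_frac: float = 0.20
    catch_frac: float = 0.20

    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.p_wave2, self.p_wave3, self.target_frac, self.catch_frac):
            if not 0 <= frac <= 1:
                raise ValueError("probabilities/fractions must be in [0, 1]")
        if self.target_frac + self.catch_frac > 1:
            raise ValueError("target_frac + catch_frac must not exceed 1")
        for s in (self.tau_subject, self.sigma_scan, self.sigma_roi,
                  self.sigma_dprime, self.sigma_metric_noise):
            if s < 0:
                raise ValueError("standard deviations must be non-negative")
        lo, hi = self.baseline_age_range
        spread = (
            abs(self.z0)
            + abs(self.delta_group)
            + abs(self.delta_sex)
            + abs(self.beta_age) * max(abs(lo - self.age_ref), abs(hi + 4 - self.age_ref))
            + 3 * (self.tau_subject + self.sigma_scan)
        )
        if spread >= _MAX_ABS_ZETA:
            raise ValueError(
                "config places non-negligible mass on |latent correlation| >= 1 "
                f"(|zeta| bound {spread:.2f} >= {_MAX_ABS_ZETA:.2f})"
            )

    @property
    def design(self) -> dict[str, int]:
        n_target = round(self.n_trials * self.target_frac)
        n_catch = round(self.n_trials * self.catch_frac)
        return {
            "target": n_target,
            "catch": n_catch,
            "stim": self.n_trials - n_target - n_catch,
        }


def expected_edge_r(config: SyntheticConfig, zeta: float | np.ndarray) -> float | np.ndarray:
    """Expected between-network edge Pearson r at latent value ``zeta``.

    The factor correlation ``tanh(zeta)`` is attenuated by the ROI-level
    noise: ``r = tanh(zeta) * lambda^2 / (lambda^2 + sigma_roi^2)``.
    """
    lam2 = config.lambda_loading**2
    return np.tanh(zeta) * lam2 / (lam2 + config.sigma_roi**2)


def expected_avg_z(config: SyntheticConfig, zeta: float | np.ndarray) -> float | np.ndarray:
    """Expected averaged metric (Fisher-z) at latent value ``zeta``."""
    return np.arctanh(expected_edge_r(config, zeta))


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` produces for one seed."""

    config: SyntheticConfig
    records: pd.DataFrame  # one row per scan, analysis-ready
    truth: pd.DataFrame  # latent zeta, rho, expected metric, true d'
    timeseries: dict[str, ScanTimeSeries] = field(default_factory=dict)
    motion: dict[str, MotionTrace] = field(default_factory=dict)
    trials: dict[str, pd.DataFrame] = field(default_factory=dict)


def _draw_phenotypes(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.baseline_age_range
    rows = []
    for group in ("control", "adhd"):
        male_frac = config.male_fraction[group]
        for i in range(config.n_subjects_per_group):
            sid = f"{group[0]}{i:04d}"
            sex = "M" if rng.random() < male_frac else "F"
            age0 = rng.uniform(lo, hi)
            n_waves = 1
            if rng.random() < config.p_wave2:
                n_waves = 2
                if rng.random() < config.p_wave3:
                    n_waves = 3
            age = age0
            for wave in range(1, n_waves + 1):
                if wave > 1:
                    lag = np.clip(
                        rng.normal(config.lag_mean_years, config.lag_jitter_years),
                        1.0,
                        2.0,
                    )
                    age = age + lag
                rows.append(
                    {
                        "subject_id": sid,
                        "wave": wave,
                        "group": group,
                        "sex": sex,
                        "age": float(age),
                    }
                )
    return pd.DataFrame(rows)


def _latent_zeta(
    config: SyntheticConfig, pheno: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    subjects = pheno["subject_id"].unique()
    u = dict(zip(subjects, rng.normal(0.0, config.tau_subject, size=len(subjects))))
    eps = rng.normal(0.0, config.sigma_scan, size=len(pheno))
    zeta = (
        config.z0
        + config.delta_group * (pheno["group"] == "adhd").to_numpy()
        + config.delta_sex * (pheno["sex"] == "F").to_numpy()
        + config.beta_age * (pheno["age"].to_numpy() - config.age_ref)
        + pheno["subject_id"].map(u).to_numpy()
        + eps
    )
    return np.clip(zeta, -_MAX_ABS_ZETA, _MAX_ABS_ZETA)


def _scan_timeseries_and_motion(
    config: SyntheticConfig, rho: float, rng: np.random.Generator
) -> tuple[ScanTimeSeries, MotionTrace]:
    parc = config.parcellation
    n, t = parc.n_rois, config.n_frames

    # three network factors: default-mode, task-positive, other
    cov = np.array([[1.0, rho], [rho, 1.0]])
    f_dt = rng.multivariate_normal([0.0, 0.0], cov, size=t, method="cholesky")
    f_other = rng.normal(size=t)
    factor = np.empty((t, n))
    nets = np.asarray(parc.networks)
    is_d = nets == "Default"
    is_tp = np.isin(nets, list({"CinguloOperc", "Salience", "DorsalAttn",
                                "VentralAttn", "FrontoParietal"}))
    factor[:, is_d] = f_dt[:, [0]]
    factor[:, is_tp] = f_dt[:, [1]]
    factor[:, ~(is_d | is_tp)] = f_other[:, None]
    data = config.lambda_loading * factor + rng.normal(0.0, config.sigma_roi, size=(t, n))

    # motion: per-frame displacement budget with spikes, split across the
    # six realignment channels (rotation shares become radians on a 50 mm
    # sphere); spike frames add a global artifact to all ROI signals
    fd_target = rng.exponential(config.fd_base_mean, size=t - 1)
    spikes = rng.random(t - 1) < config.spike_prob
    spike_size = rng.exponential(config.spike_mag_mm, size=t - 1)
    fd_target = fd_target + spikes * spike_size
    shares = rng.dirichlet(np.ones(6), size=t - 1)
    signs = rng.choice([-1.0, 1.0], size=(t - 1, 6))
    increments = shares * fd_target[:, None] * signs
    increments[:, 3:] /= 50.0
    params = np.vstack([np.zeros(6), np.cumsum(increments, axis=0)])

    artifact = np.zeros(t)
    artifact[1:][spikes] = config.artifact_gain * spike_size[spikes]
    data = data + artifact[:, None]

    ts = ScanTimeSeries(data=data, tr_seconds=config.tr_seconds)
    return ts, MotionTrace(params=params)


def generate_cohort(config: SyntheticConfig, emit_timeseries: bool = True) -> Cohort:
    """Generate a full synthetic cohort from a single seed.

    With ``emit_timeseries=True`` every scan gets a BOLD time-series matrix,
    a motion trace and a CPT trial log, and the record table leaves the
    measured columns (mean_fd, avg_neg_conn) empty for the pipeline to fill
    in. With ``emit_timeseries=False`` the records are drawn directly from
    the latent model — the metric is its expectation plus scan-level
    measurement noise, and d' comes from scoring binomially drawn trial
    counts — which preserves the cohort's statistical structure at a tiny
    fraction of the cost.

    All randomness derives from ``config.seed``; identical configs produce
    bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    ss_pheno, ss_latent, ss_scans, ss_behavior = root.spawn(4)
    pheno = _draw_phenotypes(config, np.random.default_rng(ss_pheno))
    zeta = _latent_zeta(config, pheno, np.random.default_rng(ss_latent))
    rho = np.tanh(zeta)
    exp_metric = np.asarray(expected_avg_z(config, zeta))

    scan_ids = [
        f"{row.subject_id}_w{row.wave}" for row in pheno.itertuples(index=False)
    ]
    rng_beh = np.random.default_rng(ss_behavior)
    true_d_easy = (
        config.a_easy
        + config.b_conn * (-exp_metric)
        + rng_beh.normal(0.0, config.sigma_dprime, size=len(pheno))
    )
    true_d_diff = (
        config.a_difficult
        + config.b_conn * (-exp_metric)
        + rng_beh.normal(0.0, config.sigma_dprime, size=len(pheno))
    )

    truth = pd.DataFrame(
        {
            "scan_id": scan_ids,
            "subject_id": pheno["subject_id"],
            "wave": pheno["wave"],
            "zeta": zeta,
            "rho": rho,
            "expected_avg_z": exp_metric,
            "true_dprime_easy": true_d_easy,
            "true_dprime_difficult": true_d_diff,
        }
    )

    records = pheno.copy()
    records.insert(0, "scan_id", scan_ids)
    cohort = Cohort(config=config, records=records, truth=truth)

    design = config.design
    if emit_timeseries:
        scan_streams = ss_scans.spawn(len(pheno))
        for k, scan_id in enumerate(scan_ids):
            rng_scan = np.random.default_rng(scan_streams[k])
            ts, trace = _scan_timeseries_and_motion(config, float(rho[k]), rng_scan)
            ts.scan_id = scan_id
            ts.subject_id = records["subject_id"].iloc[k]
            cohort.timeseries[scan_id] = ts
            cohort.motion[scan_id] = trace
            cohort.trials[scan_id] = simulate_trials(
                float(true_d_easy[k]),
                float(true_d_diff[k]),
                config.criterion,
                design=design,
                rng=rng_scan,
            )
    else:
        rng_fast = np.random.default_rng(ss_scans)
        records["mean_fd"] = 0.2 * rng_fast.beta(6.0, 4.0, size=len(pheno))
        records["avg_neg_conn"] = exp_metric + rng_fast.normal(
            0.0, config.sigma_metric_noise, size=len(pheno)
        )
        d_easy = np.empty(len(pheno))
        d_diff = np.empty(len(pheno))
        for k in range(len(pheno)):
            hit_p, fa_easy_p = sdt_response_probs(true_d_easy[k], config.criterion)
            _, fa_diff_p = sdt_response_probs(true_d_diff[k], config.criterion)
            counts = CptCounts(
                n_target=design["target"],
                n_hit=int(rng_fast.binomial(design["target"], hit_p)),
                n_stim=design["stim"],
                n_fa_easy=int(rng_fast.binomial(design["stim"], fa_easy_p)),
                n_catch=design["catch"],
                n_fa_difficult=int(rng_fast.binomial(design["catch"], fa_diff_p)),
            )
            result = score_cpt(counts)
            d_easy[k] = result.dprime_easy
            d_diff[k] = result.dprime_difficult
        records["dprime_easy"] = d_easy
        records["dprime_difficult"] = d_diff

    return cohort


def null_config(**overrides) -> SyntheticConfig:
    """A config with every systematic effect zeroed (type-I calibration)."""
    base = SyntheticConfig(delta_group=0.0, delta_sex=0.0, beta_age=0.0, b_conn=0.0)
    return replace(base, **overrides) if overrides else base
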