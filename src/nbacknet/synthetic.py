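"""Synthetic n-back cohorts with planted band-specific network effects.

The generator emulates the study conditions downstream stages expect:
28 subjects, 80 cortical regions, two task conditions (0-back control,
2-back working memory) by two frequency bands (theta, alpha), with
roughly 42 correct trials per subject in the 0-back and 37 in the
2-back condition.  Trial-wise region power is drawn from a latent
Gaussian copula with lognormal marginals (power is positive and
right-skewed).  The latent correlation combines a modular block
structure (``rho_within`` inside equally sized region modules,
``rho_between`` outside) with a slowly decaying spatial kernel over
neighboring regions that emulates source-leakage autocorrelation and
guarantees that proportionally thresholded networks stay connected down
to 10% sparsity, matching the behavior of real recordings at
these densities.

Condition effects are planted on the latent correlations:

* theta band, 2-back: between-module correlations are raised by
  ``delta_integration`` (plus a subject-level random effect), which
  lets long-range edges displace short-range ones under proportional
  thresholding - shorter paths, higher global efficiency, i.e. higher
  integration under memory load;
* alpha band, 2-back: within-module correlations and the local spatial
  coupling are lowered by ``delta_segregation`` (plus a subject
  effect), draining short-range, triangle-rich edges from the
  thresholded graph - lower clustering, i.e. lower segregation under
  load.

Behavior is coupled to each subject's own network topology: reaction
times load negatively on the subject's integrated theta-band normalized
path length and integrated alpha-band clustering, with a positive
2-back offset, so slower responses co-occur with higher load and the
planted negative brain-behavior correlations emerge in group analysis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream as _substream

from .network import (
    BANDS,
    CONDITIONS,
    PowerSeriesMatrix,
    SparsityGrid,
    pearson_connectivity,
    sweep_sparsity,
)
from .metrics import characteristic_path_length, clustering_coefficient
from .nulls import surrogate_ensemble
from .stats import MetricCurve, integrate_over_sparsity

__all__ = [
    "BehaviorCouplingConfig",
    "CohortConfig",
    "SubjectRecord",
    "SyntheticCohort",
    "build_condition_covariance",
    "simulate_power_matrix",
    "simulate_behavior",
    "generate_cohort",
]

RT_FLOOR_MS = 150.0
MIN_TRIALS = 10
# subject-level effect draws are truncated at this many SDs so the
# latent correlation weights can never leave the PSD cone
_EFFECT_CLIP_SD = 3.0


@dataclass
class BehaviorCouplingConfig:
    """How reaction time and accuracy are tied to network topology.

    Reaction time (ms), per condition:
    ``rt = rt_intercept + rt_condition_offset * [2-back]
    + coef_lambda_theta * integrated theta lambda
    + coef_c_alpha * integrated alpha clustering + noise``, floored at
    150 ms.  Both coefficients default negative, planting the observed
    negative RT-network correlations; accuracy drops under load.
    """

    rt_intercept: float = 650.0
    rt_condition_offset: float = 120.0
    coef_lambda_theta: float = -300.0
    coef_c_alpha: float = -200.0
    rt_noise_sd: float = 40.0
    rt_nontarget_offset: float = -25.0
    acc_baseline: float = 0.94
    acc_condition_drop: float = 0.12
    acc_noise_sd: float = 0.05
    acc_nontarget_baseline: float = 0.987
    acc_nontarget_drop: float = 0.036
    acc_nontarget_noise_sd: float = 0.018

    def __post_init__(self) -> None:
        if self.rt_noise_sd <= 0:
            raise ValueError("rt_noise_sd must be positive")
        for name in ("acc_baseline", "acc_nontarget_baseline"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.acc_baseline - self.acc_condition_drop <= 1:
            raise ValueError("acc_baseline - acc_condition_drop outside [0, 1]")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 28
    n_rois: int = 80
    n_modules: int = 8
    rho_within: float = 0.60
    rho_between: float = 0.35
    spatial_weight: float = 0.92
    spatial_decay: float = 0.94
    delta_integration: float = 0.12
    delta_segregation: float = 0.12
    subject_sd: float = 0.03
    trial_mean_0back: float = 42.30
    trial_mean_2back: float = 36.95
    trial_sd_0back: float = 2.3
    trial_sd_2back: float = 4.6
    power_log_mean: float = 2.0
    power_log_sd: float = 0.3
    coupling_grid_step: float = 0.05
    coupling_surrogates: int = 20
    coupling_swap_factor: int = 5
    min_connected_sparsity: float | None = 0.10
    # network-coupled behavior is part of the study conditions; turning
    # it off skips the coupling pipeline for purely structural studies
    simulate_behavior_data: bool = True
    behavior: BehaviorCouplingConfig = field(
        default_factory=BehaviorCouplingConfig
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.behavior, dict):
            self.behavior = BehaviorCouplingConfig(**self.behavior)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_rois % self.n_modules != 0:
            raise ValueError("n_rois must be divisible by n_modules")
        if not (self.rho_within > self.rho_between >= 0):
            raise ValueError("require rho_within > rho_between >= 0")
        if self.rho_within >= 1:
            raise ValueError("rho_within must lie in [0, 1)")
        if not (0 <= self.spatial_weight < 1):
            raise ValueError("spatial_weight must lie in [0, 1)")
        if not (0 <= self.spatial_decay < 1):
            raise ValueError("spatial_decay must lie in [0, 1)")
        module_share = self.rho_within - self.rho_between
        margin = max(self.delta_integration, self.delta_segregation) \
            + _EFFECT_CLIP_SD * self.subject_sd
        if module_share < margin:
            raise ValueError(
                "rho_within - rho_between must exceed the largest condition "
                f"delta plus {_EFFECT_CLIP_SD} subject-effect SDs "
                f"({margin:.3f}) so modules stay meaningful in every cell"
            )
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        for name in ("trial_mean_0back", "trial_mean_2back"):
            if getattr(self, name) < MIN_TRIALS:
                raise ValueError(f"{name} must be >= {MIN_TRIALS}")
        if self.power_log_sd < 0:
            raise ValueError("power_log_sd must be non-negative")
        # All four condition x band correlation matrices must be PSD
        # (checked with the subject effect at zero; per-subject draws are
        # re-checked, and repaired at most once, at generation time).
        for band in BANDS:
            for condition in CONDITIONS:
                build_condition_covariance(self, band, condition, 0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class SubjectRecord:
    """All simulated data of one subject."""

    subject_id: str
    power: dict  # (condition, band) -> PowerSeriesMatrix
    behavior: dict  # condition -> {rt_target_ms, ..., n_trials}
    n_trials: dict  # condition -> int
    network_summaries: dict  # condition -> {lambda_theta_int, c_alpha_int}


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    config: CohortConfig
    seed_used: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def behavior_frame(self) -> pd.DataFrame:
        rows = []
        for sub in self.subjects:
            for condition in CONDITIONS:
                if condition not in sub.behavior:
                    continue
                rec = sub.behavior[condition]
                rows.append({"subject": sub.subject_id,
                             "condition": condition, **rec})
        return pd.DataFrame(rows)

    def to_directory(self, path: str | Path) -> Path:
        from .io import write_power_matrix  # local import avoids a cycle

        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        for sub in self.subjects:
            for condition in CONDITIONS:
                d = root / sub.subject_id / condition
                d.mkdir(parents=True, exist_ok=True)
                for band in BANDS:
                    write_power_matrix(sub.power[(condition, band)],
                                       d / f"{band}_power.tsv")
        self.behavior_frame().to_csv(root / "behavior.tsv", sep="\t",
                                     index=False)
        echo = {"config": self.config.to_dict(), "seed": self.seed_used}
        (root / "config.json").write_text(json.dumps(echo, indent=2))
        return root

    @classmethod
    def from_directory(cls, path: str | Path) -> "SyntheticCohort":
        from .io import read_power_matrix

        root = Path(path)
        echo = json.loads((root / "config.json").read_text())
        config = CohortConfig.from_dict(echo["config"])
        behavior = pd.read_csv(root / "behavior.tsv", sep="\t")
        subjects = []
        for sub_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            sid = sub_dir.name
            power, n_trials = {}, {}
            for condition in CONDITIONS:
                for band in BANDS:
                    psm = read_power_matrix(
                        sub_dir / condition / f"{band}_power.tsv",
                        band=band, condition=condition, subject_id=sid,
                    )
                    power[(condition, band)] = psm
                    n_trials[condition] = psm.n_trials
            beh = {}
            for condition in CONDITIONS:
                row = behavior[(behavior.subject == sid)
                               & (behavior.condition == condition)]
                if len(row) != 1:
                    raise ValueError(f"missing behavior for {sid}/{condition}")
                beh[condition] = {
                    k: row.iloc[0][k]
                    for k in ("rt_target_ms", "rt_nontarget_ms",
                              "acc_target", "acc_nontarget", "n_trials")
                }
            subjects.append(SubjectRecord(sid, power, beh, n_trials, {}))
        return cls(subjects, config, echo["seed"])


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Project to the nearest PSD matrix (eigenvalue clipping), unit diag."""
    vals, vecs = np.linalg.eigh(mat)
    repaired = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def build_condition_covariance(
    config: CohortConfig,
    band: str,
    condition: str,
    subject_effect: float = 0.0,
) -> np.ndarray:
    """Latent correlation matrix for one condition x band cell.

    The block part has ``rho_within`` inside the equal-sized modules
    and ``rho_between`` outside; the (theta, 2-back) cell uses
    ``rho_between + delta_integration + subject_effect`` off-block, the
    (alpha, 2-back) cell ``rho_within - delta_segregation -
    subject_effect`` within-block.  The final matrix is the elementwise
    maximum of the block part and a slowly decaying spatial kernel
    ``spatial_weight * spatial_decay**(d-1)`` over circular region
    distance d.  The kernel emulates the strong short-range
    autocorrelation that source leakage imprints on neighboring
    parcels; because the nearest-neighbor shells are then uniformly the
    strongest entries, every proportionally thresholded network
    contains a connected lattice backbone down to 10% sparsity even at
    realistic (noisy) trial counts.  Unit diagonal; projected to the
    nearest PSD matrix (one eigenvalue-clipping pass) if needed.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}, expected one of {BANDS}")
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}, expected one of {CONDITIONS}"
        )
    n = config.n_rois
    within = config.rho_within
    between = config.rho_between
    spatial_weight = config.spatial_weight
    if band == "theta" and condition == "2back":
        between = between + config.delta_integration + subject_effect
    if band == "alpha" and condition == "2back":
        d = config.delta_segregation + subject_effect
        within = within - d
        # local (short-range) coupling weakens along with module
        # coherence: under rank-based thresholding this is what actually
        # lowers the binary clustering coefficient
        spatial_weight = max(0.0, spatial_weight - d / 2.0)
    if not (0 <= between <= within < 1):
        raise ValueError(
            "condition deltas pushed the block correlations outside "
            f"0 <= between <= within < 1 (band={band}, "
            f"condition={condition}, within={within:.4f}, "
            f"between={between:.4f})"
        )
    block = n // config.n_modules
    module = np.repeat(np.arange(config.n_modules), block)
    same = module[:, None] == module[None, :]
    corr = np.where(same, within, between).astype(float)
    if spatial_weight > 0:
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        dist = np.minimum(dist, n - dist)
        ring = np.where(
            dist > 0,
            spatial_weight * config.spatial_decay ** (dist - 1.0),
            0.0,
        )
        corr = np.maximum(corr, ring)
    np.fill_diagonal(corr, 1.0)
    min_eig = np.linalg.eigvalsh(corr)[0]
    if min_eig < -1e-10:
        corr = _nearest_psd(corr)
        if np.linalg.eigvalsh(corr)[0] < -1e-8:
            raise ValueError(
                "latent correlation matrix is not PSD after one repair "
                f"(band={band}, condition={condition})"
            )
    return corr


def simulate_power_matrix(
    latent_corr: np.ndarray,
    n_trials: int,
    power_log_mean: float,
    power_log_sd: float,
    rng: np.random.Generator,
    roi_labels: list[str] | None = None,
    **meta: str,
) -> PowerSeriesMatrix:
    """Trial-wise lognormal power with a latent Gaussian correlation.

    Each trial column is ``exp(mu + sd * z)`` with ``z`` drawn from a
    zero-mean Gaussian with correlation ``latent_corr``; entries are
    strictly positive by construction.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    corr = np.asarray(latent_corr, dtype=float)
    n = corr.shape[0]
    try:
        factor = np.linalg.cholesky(corr + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(corr)
        if vals[-1] <= 0:
            raise np.linalg.LinAlgError(
                "latent correlation matrix has no positive eigenvalues"
            )
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = factor @ rng.standard_normal((n, int(n_trials)))
    values = np.exp(power_log_mean + power_log_sd * z)
    if roi_labels is None:
        roi_labels = [f"R{i + 1:03d}" for i in range(n)]
    return PowerSeriesMatrix(values, roi_labels, **meta)


def simulate_behavior(
    summaries: dict,
    config: BehaviorCouplingConfig,
    rng: np.random.Generator,
    n_trials: dict | None = None,
) -> dict:
    """Behavioral records coupled to per-condition network summaries.

    ``summaries`` maps condition -> {"lambda_theta_int", "c_alpha_int"}.
    """
    out = {}
    for condition in CONDITIONS:
        s = summaries[condition]
        is_wm = 1.0 if condition == "2back" else 0.0
        rt = (
            config.rt_intercept
            + config.rt_condition_offset * is_wm
            + config.coef_lambda_theta * s["lambda_theta_int"]
            + config.coef_c_alpha * s["c_alpha_int"]
            + config.rt_noise_sd * rng.standard_normal()
        )
        rt_nt = (
            rt
            + config.rt_nontarget_offset
            + 0.5 * config.rt_noise_sd * rng.standard_normal()
        )
        acc = np.clip(
            config.acc_baseline
            - config.acc_condition_drop * is_wm
            + config.acc_noise_sd * rng.standard_normal(),
            0.0, 1.0,
        )
        acc_nt = np.clip(
            config.acc_nontarget_baseline
            - config.acc_nontarget_drop * is_wm
            + config.acc_nontarget_noise_sd * rng.standard_normal(),
            0.0, 1.0,
        )
        out[condition] = {
            "rt_target_ms": float(max(RT_FLOOR_MS, rt)),
            "rt_nontarget_ms": float(max(RT_FLOOR_MS, rt_nt)),
            "acc_target": float(acc),
            "acc_nontarget": float(acc_nt),
            "n_trials": int(n_trials[condition]) if n_trials else 0,
        }
    return out


def _coupling_summaries(
    power: dict,
    config: CohortConfig,
    coupling_rng: dict,
) -> dict:
    """Integrated theta lambda and alpha clustering, per condition.

    Runs the same construction used for analysis (Pearson -> sparsity
    sweep -> surrogate-normalized path length / clustering -> area under
    the curve) on the subject's own simulated data, so that behavior can
    be coupled to genuine network topology rather than to the latent
    parameters.
    """
    grid = SparsityGrid.from_step(step=config.coupling_grid_step)
    out: dict = {}
    for condition in CONDITIONS:
        # theta: normalized characteristic path length.  Grid points
        # whose network is disconnected (possible only for very small
        # test networks; full-size cohorts are conditioned on
        # reachability) are dropped; nestedness makes the usable points
        # a suffix of the grid.
        ens = sweep_sparsity(pearson_connectivity(power[(condition, "theta")]),
                             grid)
        usable = np.nonzero(ens.connected)[0]
        if usable.size < 2:
            raise ValueError(
                "fewer than 2 connected sparsity levels for the behavior "
                "coupling; increase n_rois or the sparsity range"
            )
        svals = grid.values[usable]
        lam = np.empty(usable.size)
        rng = coupling_rng[condition]
        for k, idx in enumerate(usable):
            net = ens.networks[idx]
            L = characteristic_path_length(net)
            surr = surrogate_ensemble(
                net, config.coupling_surrogates, rng,
                swap_factor=config.coupling_swap_factor,
            )
            lam[k] = L / surr.L_rand
        lam_int = integrate_over_sparsity(
            MetricCurve("lambda", svals, lam, condition=condition)
        ).value
        # alpha: plain clustering coefficient (no surrogates needed)
        ens_a = sweep_sparsity(
            pearson_connectivity(power[(condition, "alpha")]), grid
        )
        C = np.array([clustering_coefficient(ens_a.networks[i])
                      for i in usable])
        c_int = integrate_over_sparsity(
            MetricCurve("C", svals, C, condition=condition)
        ).value
        out[condition] = {"lambda_theta_int": lam_int, "c_alpha_int": c_int}
    return out


_MAX_POWER_REDRAWS = 64


def _draw_connected_power(
    corr: np.ndarray,
    n_trials: int,
    config: CohortConfig,
    seed: int,
    sid: str,
    condition: str,
    band: str,
    labels: list[str],
) -> PowerSeriesMatrix:
    """Simulate one cell's power matrix, conditioned on network reachability.

    Real cortical power correlations yield fully connected thresholded
    networks over the whole sparsity range, and downstream path metrics
    assume as much; because the edge sets of one sweep are nested, it is
    enough to require connectedness at the lowest sparsity.  Sampling-noise draws that violate the property
    (rare at the default parameters) are rejected and redrawn from the
    next substream, keeping the generator deterministic under its seed.
    """
    from .network import binarize_at_sparsity  # deferred: tiny helper

    check = config.min_connected_sparsity
    if check is not None:
        n = corr.shape[0]
        # a graph cannot be connected with fewer than n-1 edges; tiny
        # test networks then skip the reachability conditioning
        if round(check * n * (n - 1) / 2.0) < n - 1:
            check = None
    for attempt in range(_MAX_POWER_REDRAWS):
        rng = _substream(seed, sid, condition, band, "power", attempt)
        psm = simulate_power_matrix(
            corr, n_trials, config.power_log_mean, config.power_log_sd,
            rng, roi_labels=labels,
            band=band, condition=condition, subject_id=sid,
        )
        if check is None:
            return psm
        net = binarize_at_sparsity(pearson_connectivity(psm), check)
        if net.is_connected():
            return psm
    raise RuntimeError(
        f"no connected network at sparsity {config.min_connected_sparsity} "
        f"after {_MAX_POWER_REDRAWS} draws for {sid}/{condition}/{band}; "
        "the latent correlation structure is too weak for the trial count"
    )


def _roi_labels(n_rois: int) -> list[str]:
    if n_rois == 80:
        from .io import load_region_table

        return list(load_region_table()["abbreviation"])
    return [f"R{i + 1:03d}" for i in range(n_rois)]


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Simulate a full cohort; deterministic under a fixed (config, seed)."""
    config = config or CohortConfig()
    labels = _roi_labels(config.n_rois)
    seed = config.seed
    trial_means = {"0back": (config.trial_mean_0back, config.trial_sd_0back),
                   "2back": (config.trial_mean_2back, config.trial_sd_2back)}
    subjects = []
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:02d}"
        eff_rng = _substream(seed, sid, "effects")
        clip = _EFFECT_CLIP_SD * config.subject_sd
        eff_int, eff_seg = np.clip(
            config.subject_sd * eff_rng.standard_normal(2), -clip, clip
        )
        n_trials = {}
        for condition in CONDITIONS:
            mean, sd = trial_means[condition]
            draw = _substream(seed, sid, condition, "trials").normal(mean, sd)
            n_trials[condition] = max(MIN_TRIALS, int(round(draw)))
        power = {}
        for condition in CONDITIONS:
            for band in BANDS:
                effect = eff_int if band == "theta" else eff_seg
                corr = build_condition_covariance(config, band, condition,
                                                 effect)
                power[(condition, band)] = _draw_connected_power(
                    corr, n_trials[condition], config, seed, sid,
                    condition, band, labels,
                )
        if config.simulate_behavior_data:
            coupling_rng = {c: _substream(seed, sid, c, "coupling")
                            for c in CONDITIONS}
            summaries = _coupling_summaries(power, config, coupling_rng)
            behavior = simulate_behavior(summaries, config.behavior,
                                         _substream(seed, sid, "behavior"),
                                         n_trials=n_trials)
        else:
            summaries, behavior = {}, {}
        subjects.append(SubjectRecord(sid, power, behavior, n_trials,
                                      summaries))
    return SyntheticCohort(subjects, config, seed)
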