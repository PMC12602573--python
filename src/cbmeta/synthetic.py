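"""Synthetic foci and behavioral summary tables with known ground truth.

Two generators make every downstream stage testable without any external
download:

* :func:`gen_foci_dataset` builds coordinate-table experiment sets whose
  foci are drawn around known truth centers (isotropic Gaussian scatter,
  rejection-resampled at the mask boundary) plus a fixed number of uniform
  noise foci per experiment — mirroring the "identical properties" matching
  used by the cluster-level FWE null.
* :func:`gen_behavioral_dataset` builds study-nested reaction-time summary
  tables (means, SDs, optional between-condition correlation) whose implied
  repeated-measures standardized effect equals a drawn true effect up to
  sampling error at the stated sample size. Data are generated at the
  summary-statistic level because only summaries enter the analysis.

Both generators are deterministic given their seed, and each returns a
:class:`GroundTruth` sidecar that can be serialized next to the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from cbmeta.io import BrainGrid, Experiment, ExperimentSet, Focus


@dataclass(frozen=True)
class TruthCenter:
    """A ground-truth activation center and how experiments report it."""

    x: float
    y: float
    z: float
    report_probability: float = 1.0
    scatter_sd: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.report_probability <= 1.0:
            raise ValueError("report_probability must be in [0, 1]")
        if self.scatter_sd <= 0:
            raise ValueError("scatter_sd must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class FociSimConfig:
    """Configuration of the foci generator.

    ``moderator_assignment`` optionally maps levels of a single moderator
    column (named ``moderator_name``) to the indices of ``truth_centers``
    active for experiments carrying that level; levels are assigned to
    experiments cyclically. Without it, all centers are active everywhere.
    """

    n_experiments: int = 20
    n_range: tuple[int, int] = (15, 40)
    truth_centers: list[TruthCenter] = field(default_factory=list)
    n_noise_foci: int = 8
    moderator_name: str = "material"
    moderator_assignment: dict[str, list[int]] | None = None
    seed: int = 0


@dataclass
class BehavSimConfig:
    """Configuration of the behavioral summary-table generator.

    True per-experiment effects are ``mu_g`` plus moderator shifts plus a
    study-level and an experiment-level random component with total SD
    ``tau`` and within-study correlation ``rho_within``. ``r_subject`` is
    the within-subject correlation between condition RTs, reported for a
    ``prob_r_observed`` fraction of experiments.
    """

    n_studies: int = 68
    es_per_study: tuple[int, int] = (1, 4)
    n_es_total: int | None = None
    mu_g: float = 0.64
    tau: float = 0.2
    rho_within: float = 0.8
    r_subject: float = 0.91
    n_range: tuple[int, int] = (15, 60)
    base_rt_ms: float = 700.0
    base_sd_ms: float = 120.0
    moderator_effects: dict[str, dict[str, float]] | None = None
    prob_r_observed: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not -1.0 < self.r_subject < 1.0:
            raise ValueError("r_subject must be in (-1, 1)")
        if not -1.0 < self.rho_within < 1.0:
            raise ValueError("rho_within must be in (-1, 1)")


@dataclass
class GroundTruth:
    """What the generator actually drew, for downstream recovery checks."""

    seed: int
    true_centers: list[dict] = field(default_factory=list)
    true_g: dict[str, float] = field(default_factory=dict)
    true_moderator_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _draw_scattered_focus(rng: np.random.Generator, center: TruthCenter,
                          grid: BrainGrid, max_tries: int = 1000) -> np.ndarray:
    """Center + isotropic Gaussian scatter, redrawn until inside the mask."""
    mu = center.as_array()
    for _ in range(max_tries):
        xyz = mu + rng.normal(0.0, center.scatter_sd, size=3)
        if grid.contains_mm(xyz[None, :])[0]:
            return xyz
    raise RuntimeError("could not draw an in-mask focus; scatter_sd too large?")


def gen_foci_dataset(cfg: FociSimConfig,
                     grid: BrainGrid) -> tuple[ExperimentSet, GroundTruth]:
    """Generate an experiment set of truth-derived plus uniform-noise foci."""
    if grid.n_voxels_in_mask == 0:
        raise ValueError("mask is empty")
    centers_xyz = np.array([c.as_array() for c in cfg.truth_centers]).reshape(-1, 3)
    if len(centers_xyz) and not grid.contains_mm(centers_xyz).all():
        raise ValueError("all truth centers must lie inside the mask")

    rng = np.random.default_rng(cfg.seed)
    mask_mm = grid.mask_voxel_centers_mm()
    levels = sorted(cfg.moderator_assignment) if cfg.moderator_assignment else None

    experiments = []
    for i in range(cfg.n_experiments):
        n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        if levels is not None:
            level = levels[i % len(levels)]
            active = cfg.moderator_assignment[level]
            moderators = {cfg.moderator_name: level}
        else:
            level, active = None, range(len(cfg.truth_centers))
            moderators = {}
        foci = []
        for ci in active:
            center = cfg.truth_centers[ci]
            if rng.random() < center.report_probability:
                foci.append(Focus(*_draw_scattered_focus(rng, center, grid)))
        idx = rng.integers(0, len(mask_mm), size=cfg.n_noise_foci)
        foci.extend(Focus(*mask_mm[j]) for j in idx)
        if not foci:
            # degenerate config (all report probabilities 0, no noise):
            # still give the experiment one uniform focus so it is valid
            foci.append(Focus(*mask_mm[rng.integers(0, len(mask_mm))]))
        experiments.append(Experiment(
            study_id=f"S{i:03d}", experiment_id=f"E{i:03d}", n=n,
            foci=foci, moderators=moderators,
        ))
    truth = GroundTruth(
        seed=cfg.seed,
        true_centers=[asdict(c) for c in cfg.truth_centers],
        extra={"moderator_assignment": cfg.moderator_assignment,
               "n_noise_foci": cfg.n_noise_foci},
    )
    return ExperimentSet(experiments, grid), truth


def gen_behavioral_dataset(cfg: BehavSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a study-nested behavioral summary table.

    Per experiment the table carries n, condition means and SDs, and (for a
    ``prob_r_observed`` fraction) an observed correlation; the implied
    repeated-measures standardized effect equals the drawn true effect up
    to sampling error. Condition SDs are drawn from the chi-square sampling
    law and observed correlations on the Fisher-z scale, so downstream
    recovery tests face realistic estimation noise.
    """
    rng = np.random.default_rng(cfg.seed)
    k_lo, k_hi = cfg.es_per_study
    k_per_study = rng.integers(k_lo, k_hi + 1, size=cfg.n_studies)
    if cfg.n_es_total is not None:
        # nudge random studies up/down until the total matches exactly
        while k_per_study.sum() != cfg.n_es_total:
            j = rng.integers(0, cfg.n_studies)
            if k_per_study.sum() < cfg.n_es_total:
                k_per_study[j] += 1
            elif k_per_study[j] > 1:
                k_per_study[j] -= 1

    mod_effects = cfg.moderator_effects or {}
    sd_between = np.sqrt(cfg.rho_within) * cfg.tau
    sd_within = np.sqrt(1.0 - cfg.rho_within) * cfg.tau

    rows, true_g = [], {}
    for j in range(cfg.n_studies):
        study_id = f"ST{j:03d}"
        b_j = rng.normal(0.0, sd_between)
        for i in range(k_per_study[j]):
            exp_id = f"{study_id}_{i}"
            theta = cfg.mu_g + b_j + rng.normal(0.0, sd_within)
            moderators = {}
            for col, effects in mod_effects.items():
                level = sorted(effects)[rng.integers(0, len(effects))]
                moderators[col] = level
                theta += effects[level]
            n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
            base_sd = cfg.base_sd_ms * float(np.exp(rng.normal(0.0, 0.15)))
            r = cfg.r_subject
            sd_diff_true = base_sd * np.sqrt(2.0 * (1.0 - r))
            delta_true = theta * base_sd  # equal condition SDs: SD_within = base_sd
            delta_hat = rng.normal(delta_true, sd_diff_true / np.sqrt(n))
            mean_c = rng.normal(cfg.base_rt_ms, 60.0)
            # sample SDs via the chi-square sampling law; both condition SDs
            # come from the same subjects, so they share a common component
            # (their sampling correlation is ~r^2 for bivariate-normal scores)
            f_common = rng.chisquare(n - 1) / (n - 1)
            w = r**2
            sd_i = base_sd * np.sqrt(w * f_common
                                     + (1 - w) * rng.chisquare(n - 1) / (n - 1))
            sd_c = base_sd * np.sqrt(w * f_common
                                     + (1 - w) * rng.chisquare(n - 1) / (n - 1))
            r_hat = np.tanh(rng.normal(np.arctanh(r), 1.0 / np.sqrt(max(n - 3, 1))))
            row = {
                "study_id": study_id, "experiment_id": exp_id, "n": n,
                "mean_I": mean_c + delta_hat, "sd_I": sd_i,
                "mean_C": mean_c, "sd_C": sd_c,
                "r": r_hat if rng.random() < cfg.prob_r_observed else np.nan,
                "sd_is_se": False,
            }
            row.update(moderators)
            rows.append(row)
            true_g[exp_id] = float(theta)
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        seed=cfg.seed, true_g=true_g,
        true_moderator_effects=mod_effects,
        extra={"mu_g": cfg.mu_g, "tau": cfg.tau, "r_subject": cfg.r_subject,
               "rho_within": cfg.rho_within,
               "n_es": int(k_per_study.sum())},
    )
    return table, truth
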