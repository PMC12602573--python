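"""Repeated-measures standardized effect sizes for reaction-time costs.

The interference cost is a within-subject contrast (incongruent minus
control RT), so standardizing it needs the correlation ``r`` between the two
condition scores, which primary studies rarely report. This module

* recovers ``r`` from a paired t-statistic or the SD of difference scores
  when either is available,
* imputes an aggregate ``r`` across experiments that do report one (an
  intercept-only robust-variance meta-analysis honoring study clustering),
* computes the repeated-measures standardized mean difference with the
  small-sample (Hedges) correction:
  ``SD_diff = sqrt(sd_I^2 + sd_C^2 - 2 r sd_I sd_C)``,
  ``SD_within = SD_diff / sqrt(2 (1 - r))``, ``d = (m_I - m_C)/SD_within``,
  ``Var_d = (1/n + d^2/(2n)) * 2(1-r)``, ``J = 1 - 3/(4(n-1) - 1)``,
  ``g = J d``, ``Var_g = J^2 Var_d``,
* assembles the analysis table under three r-assignment strategies:
  observed r plus the imputed aggregate for the rest; observed r plus a
  plausible floor (default 0.6) for the rest; or the imputed aggregate for
  every experiment.

Positive ``g`` means longer reaction times in the incongruent condition
(an interference cost). Condition spreads reported as standard errors are
converted to SDs (``SD = SE * sqrt(n)``) before use, under an explicit
``sd_is_se`` flag, never inferred from magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_CLAMP = 0.999
STRATEGIES = ("observed_plus_imputed", "observed_plus_floor", "all_imputed")


@dataclass
class BehavioralRecord:
    """Summary statistics of one experiment's reaction-time interference."""

    study_id: str
    experiment_id: str
    n: int
    mean_I: float
    sd_I: float
    mean_C: float
    sd_C: float
    r: float | None = None
    t_paired: float | None = None
    sd_diff: float | None = None
    sd_is_se: bool = False
    moderators: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.experiment_id}: n must be >= 2")
        if self.sd_I <= 0 or self.sd_C <= 0:
            raise ValueError(f"{self.experiment_id}: condition SDs must be positive")
        if self.r is not None and not abs(self.r) < 1:
            raise ValueError(f"{self.experiment_id}: |r| must be < 1")

    def condition_sds(self) -> tuple[float, float]:
        """Condition SDs, converting from SEs when flagged."""
        if self.sd_is_se:
            return self.sd_I * np.sqrt(self.n), self.sd_C * np.sqrt(self.n)
        return self.sd_I, self.sd_C


@dataclass
class EffectSizeRecord:
    """Hedges g of one experiment with its provenance."""

    study_id: str
    experiment_id: str
    n: int
    g: float
    var_g: float
    r_used: float
    r_source: str  # observed | derived_from_t | derived_from_sd_diff | imputed | floor
    moderators: dict[str, str] = field(default_factory=dict)

    @property
    def se_g(self) -> float:
        return float(np.sqrt(self.var_g))


def r_from_paired_stats(rec: BehavioralRecord) -> float:
    """Pearson correlation between conditions from paired t or SD of differences.

    From a paired t: ``SD_diff = |m_I - m_C| * sqrt(n) / t``; then
    ``r = (sd_I^2 + sd_C^2 - SD_diff^2) / (2 sd_I sd_C)``, clamped into
    (-0.999, 0.999) with a warning if outside.
    """
    sd_i, sd_c = rec.condition_sds()
    if rec.sd_diff is not None:
        sd_diff = rec.sd_diff * np.sqrt(rec.n) if rec.sd_is_se else rec.sd_diff
    elif rec.t_paired is not None:
        mean_diff = rec.mean_I - rec.mean_C
        if rec.t_paired == 0:
            raise ValueError(
                f"{rec.experiment_id}: t = 0 with mean difference {mean_diff}"
            )
        sd_diff = abs(mean_diff) * np.sqrt(rec.n) / abs(rec.t_paired)
    else:
        raise ValueError(f"{rec.experiment_id}: neither t_paired nor sd_diff present")
    r = (sd_i**2 + sd_c**2 - sd_diff**2) / (2.0 * sd_i * sd_c)
    if abs(r) > R_CLAMP:
        warnings.warn(
            f"{rec.experiment_id}: derived r={r:.4f} outside ({-R_CLAMP}, {R_CLAMP}); clamped"
        )
        r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(r)


def var_of_r(r: float, n: int) -> float:
    """Large-sample sampling variance of a Pearson correlation."""
    return (1.0 - r**2) ** 2 / max(n - 1, 1)


def impute_r(observed: list[tuple[float, str, int]], rho: float = 0.8) -> float:
    """Aggregate mean correlation across experiments that report one.

    ``observed`` holds (r, study_id, n) triples. The aggregate is the
    intercept of an intercept-only robust-variance meta-analysis on the raw
    r scale with large-sample variances, honoring study clustering. (A
    Fisher-z aggregation is available via :func:`impute_r_fisher_z`.)
    """
    if len(observed) < 2:
        raise ValueError("need at least 2 observed correlations to impute")
    from cbmeta.rve import fit_rve

    r = np.array([o[0] for o in observed], dtype=float)
    study = np.array([o[1] for o in observed])
    v = np.array([var_of_r(ri, o[2]) for ri, o in zip(r, observed)])
    fit = fit_rve(r, v, study, rho=rho)
    return float(fit.coefficients[0])


def impute_r_fisher_z(observed: list[tuple[float, str, int]],
                      rho: float = 0.8) -> float:
    """Fisher-z-scale variant of :func:`impute_r`, back-transformed."""
    if len(observed) < 2:
        raise ValueError("need at least 2 observed correlations to impute")
    from cbmeta.rve import fit_rve

    z = np.arctanh([o[0] for o in observed])
    study = np.array([o[1] for o in observed])
    v = np.array([1.0 / max(o[2] - 3, 1) for o in observed])
    fit = fit_rve(z, v, study, rho=rho)
    return float(np.tanh(fit.coefficients[0]))


def g_repeated_measures(rec: BehavioralRecord, r_used: float,
                        r_source: str = "observed") -> EffectSizeRecord:
    """Small-sample-corrected standardized mean difference for paired RTs."""
    if not -1.0 < r_used < 1.0:
        raise ValueError(f"r_used must be in (-1, 1), got {r_used}")
    sd_i, sd_c = rec.condition_sds()
    sd_diff_sq = sd_i**2 + sd_c**2 - 2.0 * r_used * sd_i * sd_c
    if sd_diff_sq <= 0:
        raise ValueError(f"{rec.experiment_id}: nonpositive SD of differences")
    sd_diff = np.sqrt(sd_diff_sq)
    sd_within = sd_diff / np.sqrt(2.0 * (1.0 - r_used))
    d = (rec.mean_I - rec.mean_C) / sd_within
    var_d = (1.0 / rec.n + d**2 / (2.0 * rec.n)) * 2.0 * (1.0 - r_used)
    j = 1.0 - 3.0 / (4.0 * (rec.n - 1) - 1.0)
    return EffectSizeRecord(
        study_id=rec.study_id, experiment_id=rec.experiment_id, n=rec.n,
        g=float(j * d), var_g=float(j**2 * var_d),
        r_used=float(r_used), r_source=r_source, moderators=dict(rec.moderators),
    )


def records_from_frame(df: pd.DataFrame,
                       moderator_cols: list[str] | None = None) -> list[BehavioralRecord]:
    """Convert a behavioral summary table into records.

    Any column that is not one of the reserved statistics columns is treated
    as a moderator unless ``moderator_cols`` restricts the set.
    """
    reserved = {"study_id", "experiment_id", "n", "mean_I", "sd_I", "mean_C",
                "sd_C", "r", "t_paired", "sd_diff", "sd_is_se"}
    if moderator_cols is None:
        moderator_cols = [c for c in df.columns if c not in reserved]
    records = []
    for _, row in df.iterrows():
        def _opt(col):
            val = row.get(col)
            return None if val is None or (isinstance(val, float) and np.isnan(val)) else float(val)

        se_flag = row.get("sd_is_se", False)
        if isinstance(se_flag, str):
            se_flag = se_flag.strip().lower() in ("1", "true", "yes")
        elif pd.isna(se_flag):
            se_flag = False

        records.append(BehavioralRecord(
            study_id=str(row["study_id"]),
            experiment_id=str(row["experiment_id"]),
            n=int(row["n"]),
            mean_I=float(row["mean_I"]), sd_I=float(row["sd_I"]),
            mean_C=float(row["mean_C"]), sd_C=float(row["sd_C"]),
            r=_opt("r"), t_paired=_opt("t_paired"), sd_diff=_opt("sd_diff"),
            sd_is_se=bool(se_flag),
            moderators={c: str(row[c]) for c in moderator_cols if pd.notna(row.get(c))},
        ))
    return records


def observed_correlations(records: list[BehavioralRecord]) -> list[tuple[float, str, int]]:
    """(r, study_id, n) for every record with an observed or derivable r."""
    out = []
    for rec in records:
        if rec.r is not None:
            out.append((rec.r, rec.study_id, rec.n))
        elif rec.t_paired is not None or rec.sd_diff is not None:
            out.append((r_from_paired_stats(rec), rec.study_id, rec.n))
    return out


def build_es_table(records: list[BehavioralRecord],
                   strategy: str = "observed_plus_imputed",
                   imputed_r: float | None = None,
                   floor: float = 0.6,
                   rho: float = 0.8) -> list[EffectSizeRecord]:
    """Assemble effect sizes under one of the three r-assignment strategies.

    * ``observed_plus_imputed`` — observed (or derived) r where available,
      the aggregate imputed r otherwise;
    * ``observed_plus_floor`` — observed r where available, a plausible
      minimum (default 0.6) otherwise;
    * ``all_imputed`` — the aggregate imputed r for every experiment.

    ``imputed_r`` may be supplied directly (e.g., a published aggregate);
    otherwise it is computed from the records that report r.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    needs_imputed = strategy in ("observed_plus_imputed", "all_imputed")
    if needs_imputed and imputed_r is None:
        imputed_r = impute_r(observed_correlations(records), rho=rho)

    out = []
    for rec in records:
        if strategy == "all_imputed":
            r_used, src = imputed_r, "imputed"
        elif rec.r is not None:
            r_used, src = rec.r, "observed"
        elif rec.t_paired is not None:
            r_used, src = r_from_paired_stats(rec), "derived_from_t"
        elif rec.sd_diff is not None:
            r_used, src = r_from_paired_stats(rec), "derived_from_sd_diff"
        elif strategy == "observed_plus_imputed":
            r_used, src = imputed_r, "imputed"
        else:
            r_used, src = floor, "floor"
        out.append(g_repeated_measures(rec, r_used, r_source=src))
    return out


def es_table_to_frame(records: list[EffectSizeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "study_id": rec.study_id, "experiment_id": rec.experiment_id,
            "n": rec.n, "g": rec.g, "var_g": rec.var_g, "se_g": rec.se_g,
            "r_used": rec.r_used, "r_source": rec.r_source,
        }
        row.update(rec.moderators)
        rows.append(row)
    return pd.DataFrame(rows)
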