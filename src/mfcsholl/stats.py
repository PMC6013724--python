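"""Aggregation and comparison of Sholl profiles across chambers.

Treatments are compared with a two-way mixed (split-plot) repeated-measures
ANOVA: treatment is the between-subject factor, grid-line distance the
within-subject factor, and the subject is either a chamber or one
compartment side, depending on the experimental design (when the two
compartments of one chamber receive different treatments, the side is the
subject). Distance bins of one profile are strongly autocorrelated, so the
within-subject tests are reported both uncorrected and with the
Greenhouse–Geisser sphericity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .sholl import ShollProfile, outermost_gridline


@dataclass
class ExperimentSet:
    """Labelled profiles plus the design mapping chambers/sides to treatments.

    ``design`` keys are either ``chamber_id`` (whole-chamber treatment) or
    ``(chamber_id, side)`` (per-compartment treatment, the two-compartment
    contrast paradigm).
    """

    profiles: list
    design: dict

    def __post_init__(self):
        if not self.profiles:
            raise ValidationError("ExperimentSet needs at least one profile")
        grids = {tuple(np.round(p.distances_um, 6)) for p in self.profiles}
        if len(grids) != 1:
            raise ValidationError("all profiles must share one distance grid")
        for p in self.profiles:
            if self.treatment_of(p) is None:
                raise ValidationError(
                    f"no treatment assigned to chamber {p.chamber_id!r} side {p.side!r}")

    @property
    def distances_um(self) -> np.ndarray:
        return self.profiles[0].distances_um

    def treatment_of(self, profile: ShollProfile):
        key = (profile.chamber_id, profile.side)
        if key in self.design:
            return self.design[key]
        return self.design.get(profile.chamber_id)

    def treatments(self) -> list:
        seen = []
        for p in self.profiles:
            t = self.treatment_of(p)
            if t not in seen:
                seen.append(t)
        return seen

    def subject_table(self, unit: str = "side") -> pd.DataFrame:
        """Long-format table (treatment, subject, distance_um, value).

        ``unit='side'`` treats each compartment as a subject;
        ``unit='chamber'`` first averages the two sides of a chamber (only
        valid when both sides share the chamber's treatment).
        """
        if unit not in ("side", "chamber"):
            raise ValidationError("unit must be 'side' or 'chamber'")
        rows = []
        for p in self.profiles:
            t = self.treatment_of(p)
            subject = (p.chamber_id, p.side) if unit == "side" else p.chamber_id
            for d, v in zip(p.distances_um, p.normalized):
                rows.append({"treatment": t, "subject": subject,
                             "distance_um": float(d), "value": float(v)})
        df = pd.DataFrame(rows)
        if unit == "chamber":
            tdist = df.groupby("subject")["treatment"].nunique()
            mixed = tdist[tdist > 1]
            if len(mixed):
                raise ValidationError(
                    f"chambers {list(mixed.index)} carry two treatments; "
                    "use unit='side'")
            df = (df.groupby(["treatment", "subject", "distance_um"],
                             as_index=False)["value"].mean())
        return df


@dataclass
class EffectTest:
    """One ANOVA effect: F statistic, degrees of freedom and p-values."""

    name: str
    ss: float
    df1: float
    df2: float
    F: float
    p: float
    df1_gg: float = None
    df2_gg: float = None
    p_gg: float = None


@dataclass
class ComparisonResult:
    """Mixed-ANOVA decomposition plus the per-distance group summaries."""

    effects: dict
    group_stats: pd.DataFrame
    epsilon_gg: float
    unit: str


def aggregate(expset: ExperimentSet, unit: str = "side") -> pd.DataFrame:
    """Per-treatment mean ± SEM of normalized intersections per distance.

    SEM is sample SD / sqrt(n); with a single subject SEM is reported as 0
    with a warning (rather than NaN).
    """
    df = expset.subject_table(unit=unit)
    out = (df.groupby(["treatment", "distance_um"])["value"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
             .reset_index())
    if (out["n"] == 1).any():
        warnings.warn("single-subject treatment: SEM reported as 0", stacklevel=2)
    out["sem"] = np.where(out["n"] > 1, out["sd"] / np.sqrt(out["n"]), 0.0)
    return out.drop(columns="sd")


def _subject_matrices(expset: ExperimentSet, unit: str):
    """Per-treatment (n_subjects, n_distances) value matrices."""
    df = expset.subject_table(unit=unit)
    dists = np.sort(df["distance_um"].unique())
    groups = {}
    for t, grp in df.groupby("treatment", sort=False):
        wide = grp.pivot(index="subject", columns="distance_um", values="value")
        wide = wide.reindex(columns=dists)
        if wide.isna().any().any():
            raise ValidationError(f"treatment {t!r} has missing distance cells")
        groups[t] = wide.to_numpy(dtype=float)
    return groups, dists


def compare_treatments(expset: ExperimentSet, unit: str = "side") -> ComparisonResult:
    """Two-way mixed repeated-measures ANOVA of normalized profiles.

    Between factor: treatment; within factor: distance; subjects nested in
    treatments. Returns the treatment, distance and treatment×distance
    effects with raw and Greenhouse–Geisser-corrected within-subject tests.
    """
    groups, _ = _subject_matrices(expset, unit)
    effects, eps = mixed_anova(groups)
    stats_df = aggregate(expset, unit=unit)
    return ComparisonResult(effects=effects, group_stats=stats_df,
                            epsilon_gg=float(eps), unit=unit)


def mixed_anova(groups: dict):
    """Split-plot ANOVA on per-treatment (subjects × repeats) matrices.

    ``groups`` maps treatment label to an (n_subjects, n_repeats) array.
    Returns ``(effects, epsilon_gg)`` where effects holds the treatment,
    distance (within) and interaction tests.
    """
    a = len(groups)
    if a < 2:
        raise ValidationError("need at least 2 treatments to compare")
    for t, mat in groups.items():
        if mat.shape[0] < 2:
            raise ValidationError(f"treatment {t!r} has fewer than 2 subjects")
    d = next(iter(groups.values())).shape[1]
    if d < 2 or any(m.shape[1] != d for m in groups.values()):
        raise ValidationError("all groups need the same >= 2 repeated measures")

    mats = [np.asarray(m, dtype=float) for m in groups.values()]
    ns = np.array([m.shape[0] for m in mats])
    N = int(ns.sum())
    all_y = np.concatenate(mats, axis=0)          # (N, d)
    gm = all_y.mean()
    subj_means = all_y.mean(axis=1)               # (N,)
    dist_means = all_y.mean(axis=0)               # (d,)
    group_means = np.array([m.mean() for m in mats])
    cell_means = np.stack([m.mean(axis=0) for m in mats])  # (a, d)
    group_of = np.repeat(np.arange(a), ns)

    ss_treat = d * float(np.sum(ns * (group_means - gm) ** 2))
    ss_subj = d * float(np.sum((subj_means - group_means[group_of]) ** 2))
    ss_dist = N * float(np.sum((dist_means - gm) ** 2))
    ss_inter = float(np.sum(ns[:, None] * (cell_means - group_means[:, None]
                                           - dist_means[None, :] + gm) ** 2))
    resid = (all_y - cell_means[group_of]
             - subj_means[:, None] + group_means[group_of][:, None])
    ss_err = float(np.sum(resid ** 2))

    df_treat, df_subj = a - 1, N - a
    df_dist, df_inter = d - 1, (a - 1) * (d - 1)
    df_err = (d - 1) * (N - a)

    ms = lambda ss, df: ss / df if df > 0 else np.nan
    f_treat = ms(ss_treat, df_treat) / ms(ss_subj, df_subj)
    f_dist = ms(ss_dist, df_dist) / ms(ss_err, df_err)
    f_inter = ms(ss_inter, df_inter) / ms(ss_err, df_err)

    eps = _gg_epsilon(mats)

    def _p(f, df1, df2):
        if not np.isfinite(f):
            return np.nan
        return float(sps.f.sf(max(f, 0.0), df1, df2))

    effects = {
        "treatment": EffectTest("treatment", ss_treat, df_treat, df_subj,
                                float(f_treat), _p(f_treat, df_treat, df_subj)),
        "distance": EffectTest("distance", ss_dist, df_dist, df_err,
                               float(f_dist), _p(f_dist, df_dist, df_err),
                               df1_gg=eps * df_dist, df2_gg=eps * df_err,
                               p_gg=_p(f_dist, eps * df_dist, eps * df_err)),
        "interaction": EffectTest("interaction", ss_inter, df_inter, df_err,
                                  float(f_inter), _p(f_inter, df_inter, df_err),
                                  df1_gg=eps * df_inter, df2_gg=eps * df_err,
                                  p_gg=_p(f_inter, eps * df_inter, eps * df_err)),
    }
    return effects, eps


def _gg_epsilon(mats) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance."""
    d = mats[0].shape[1]
    pooled = np.zeros((d, d))
    dof = 0
    for m in mats:
        dev = m - m.mean(axis=0)
        pooled += dev.T @ dev
        dof += m.shape[0] - 1
    if dof == 0:
        return 1.0
    S = pooled / dof
    # double-center, then epsilon from the eigenvalue concentration
    row = S.mean(axis=0)
    Sdc = S - row[None, :] - row[:, None] + S.mean()
    tr = np.trace(Sdc)
    denom = (d - 1) * np.sum(Sdc ** 2)
    if denom <= 0:
        return 1.0
    eps = tr ** 2 / denom
    return float(np.clip(eps, 1.0 / (d - 1), 1.0))


def median_outermost(expset: ExperimentSet, treatment):
    """Median over replicates of the outermost grid line with intersections.

    Grid distances are discrete, so the median of an even count is the lower
    of the two central values. Profiles without any intersection carry no
    outermost line and are excluded; if every profile of the treatment is
    all-zero the result is undefined and None is returned with a warning.
    """
    values = []
    for p in expset.profiles:
        if expset.treatment_of(p) == treatment:
            v = outermost_gridline(p)
            if v is not None:
                values.append(v)
    if not values:
        warnings.warn(f"treatment {treatment!r}: all profiles are zero; "
                      "outermost grid line undefined", stacklevel=2)
        return None
    values.sort()
    return float(values[(len(values) - 1) // 2])
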