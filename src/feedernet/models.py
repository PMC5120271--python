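"""Model-ready design matrices, hurdle fits, and pooled cross-network fits.

Two statistical layers:

1. Per-network hurdle GLMMs.  The zero part is a binomial GLMM on the
   complete presence/absence grid (species × pair × season); the count
   part is a zero-truncated Poisson GLMM on per-bird pair-season counts
   where at least one connection was made.  Fixed effects: standardized
   vegetation cover, pair distance and ringing-site distance; road-gap
   class (baseline 0 gaps); season (baseline summer); species (baseline
   blue tit).  Random effects: a multi-membership feeder intercept (both
   feeders of the pair share one variance component), plus a tag
   intercept in the count part.  The two parts factorize, so they are
   fitted independently and their log-likelihoods add.

2. Pooled cross-network comparison.  Connections are pooled over seasons
   and species to one row per feeder pair; quasi-binomial (presence) and
   quasi-Poisson (counts where ≥1) GLMs with network (3-level factor) and
   raw pair distance in metres, an analysis of deviance for the network
   term (deviance reduction scaled by the Pearson dispersion, 2 df) and
   McFadden's pseudo-R² on the unscaled likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from feedernet.errors import ValidationError
from feedernet.glmm import BinomialGLMM, TruncatedPoissonGLMM, r2_glmm
from feedernet.io import SPECIES_LEVELS
from feedernet.seasons import SEASON_LEVELS

PAIR_KEY = ["network_id", "feeder_a", "feeder_b"]

#: Continuous covariates standardized before per-network fits.
CONTINUOUS = {"veg_cover_pct": "veg_z", "distance_m": "dist_z",
              "ringing_dist_m": "ring_z"}


def standardize(x) -> tuple[np.ndarray, float, float]:
    """z-score a numeric vector (mean 0, SD 1 with the n−1 denominator).

    Returns ``(z, mean, sd)`` so the transform can be inverted; raises on
    constant input, which cannot be standardized.
    """
    x = np.asarray(x, float)
    if x.size < 2 or np.ptp(x) == 0.0:
        raise ValidationError("cannot standardize a constant column")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return (x - mean) / sd, mean, sd


def destandardize(z, mean: float, sd: float) -> np.ndarray:
    return np.asarray(z, float) * sd + mean


def build_design(
    df: pd.DataFrame,
    standardize_continuous: bool = True,
    drop_empty_levels: bool = False,
):
    """Fixed-effect design matrix for the per-network models.

    Expects the covariate columns from the pair-features table joined to
    a structural or functional record table.  Factor codings keep the
    stated baselines: 0 road gaps, summer, blue tit.  With
    ``drop_empty_levels`` (used when fitting), dummy columns for factor
    levels absent from the data are removed so the design stays full
    rank.  Returns the design DataFrame and the scaler dict used for the
    continuous columns.
    """
    out = pd.DataFrame(index=df.index)
    scalers = {}
    for col, name in CONTINUOUS.items():
        if standardize_continuous:
            z, mean, sd = standardize(df[col])
            out[name] = z
            scalers[col] = (mean, sd)
        else:
            out[name] = df[col].to_numpy(float)
    rg = df["road_gap_class"].astype(int)
    out["road_gap_1"] = (rg == 1).astype(float)
    out["road_gap_2"] = (rg == 2).astype(float)
    for season in SEASON_LEVELS[1:]:  # baseline: summer
        out[f"season_{season}"] = (df["season"] == season).astype(float)
    out["species_great_tit"] = (df["species"] == SPECIES_LEVELS[1]).astype(float)
    if drop_empty_levels:
        factor_cols = [c for c in out.columns if c.startswith(("road_gap_",
                       "season_", "species_"))]
        degenerate = [c for c in factor_cols if out[c].nunique() < 2]
        out = out.drop(columns=degenerate)
    return out, scalers


def _join_features(records: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    joined = records.merge(features, on=PAIR_KEY, how="left", validate="m:1")
    missing = joined["distance_m"].isna()
    if missing.any():
        bad = joined.loc[missing, PAIR_KEY].drop_duplicates().head()
        raise ValidationError(f"records without pair features, e.g.\n{bad}")
    return joined


def feeder_memberships(df: pd.DataFrame) -> np.ndarray:
    """(n, 2) multi-membership level array: both feeders of each row."""
    return df[["feeder_a", "feeder_b"]].to_numpy()


def fit_binomial_glmm(
    structural: pd.DataFrame,
    features: pd.DataFrame,
    vc_fixed: dict | None = None,
    **kwargs,
) -> BinomialGLMM:
    """Fit the structural-connectivity (presence/absence) GLMM for one
    network's complete grid joined to its pair features."""
    df = _join_features(structural, features)
    X, scalers = build_design(df, drop_empty_levels=True)
    model = BinomialGLMM(vc_fixed=vc_fixed, **kwargs)
    model.fit(X, df["presence"].to_numpy(float),
              memberships={"feeder": feeder_memberships(df)})
    model.scalers_ = scalers
    model.r2_marginal_, model.r2_conditional_ = r2_glmm(model)
    return model


def fit_truncated_poisson_glmm(
    functional: pd.DataFrame,
    features: pd.DataFrame,
    vc_fixed: dict | None = None,
    count_family: str = "truncated_poisson",
    **kwargs,
) -> TruncatedPoissonGLMM:
    """Fit the functional-connectivity (frequency) GLMM on per-bird
    pair-season counts (all ≥ 1).

    The default family is the zero-truncated Poisson, which matches the
    sampling design; ``count_family="poisson"`` fits the plain-Poisson
    comparison model instead.
    """
    from feedernet.glmm import PoissonGLMM

    df = _join_features(functional, features)
    X, scalers = build_design(df, drop_empty_levels=True)
    cls = {"truncated_poisson": TruncatedPoissonGLMM,
           "poisson": PoissonGLMM}[count_family]
    model = cls(vc_fixed=vc_fixed, **kwargs)
    model.fit(
        X,
        df["count"].to_numpy(float),
        memberships={
            "feeder": feeder_memberships(df),
            "tag": df["tag_id"].to_numpy(),
        },
    )
    model.scalers_ = scalers
    model.r2_marginal_, model.r2_conditional_ = r2_glmm(model)
    return model


@dataclass
class HurdleFit:
    """The two independently fitted parts of the hurdle model."""

    zero: BinomialGLMM
    count: TruncatedPoissonGLMM

    @property
    def loglik(self) -> float:
        # the hurdle likelihood factorizes into its two parts
        return self.zero.loglik_ + self.count.loglik_

    def report(self) -> str:
        return (
            "Hurdle model — structural (binomial) part\n"
            + table2_report(self.zero)
            + "\nHurdle model — functional (zero-truncated Poisson) part\n"
            + table2_report(self.count)
        )


def fit_hurdle(
    structural: pd.DataFrame,
    functional: pd.DataFrame,
    features: pd.DataFrame,
    count_family: str = "truncated_poisson",
    **kwargs,
) -> HurdleFit:
    """Fit both hurdle parts for one network (independent fits; the joint
    log-likelihood is their sum)."""
    return HurdleFit(
        zero=fit_binomial_glmm(structural, features, **kwargs),
        count=fit_truncated_poisson_glmm(
            functional, features, count_family=count_family, **kwargs
        ),
    )


def raw_scale_effects(fit) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Back-transform a fit's effects to the raw covariate scale.

    Standardization is a linear reparameterization, so maximum-likelihood
    estimates transform exactly: a z-scored slope divides by the column
    SD, and the intercept absorbs the means.  Returns (estimates, SEs,
    covariance) on the raw scale; factor effects are unchanged.
    """
    names = list(fit.beta_.index)
    T = np.eye(len(names))
    i0 = names.index("intercept")
    for col, zname in CONTINUOUS.items():
        if zname in names and col in fit.scalers_:
            j = names.index(zname)
            mean, sd = fit.scalers_[col]
            T[j, j] = 1.0 / sd
            T[i0, j] = -mean / sd
    beta_raw = T @ fit.beta_.to_numpy()
    cov_raw = T @ fit.cov_.to_numpy() @ T.T
    rename = {z: c for c, z in CONTINUOUS.items()}
    raw_names = [rename.get(nm, nm) for nm in names]
    return (
        pd.Series(beta_raw, index=raw_names),
        pd.Series(np.sqrt(np.diag(cov_raw)), index=raw_names),
        pd.DataFrame(cov_raw, index=raw_names, columns=raw_names),
    )


def table2_report(fit) -> str:
    """Fixed-width per-network coefficient table: estimate (±se), stars,
    95% CI, variance components and marginal/conditional R²."""
    sig = fit.significance()
    lines = [f"{'term':<22}{'estimate (±se)':<22}{'CI 2.5%':>10}{'CI 97.5%':>10}"]
    for name in sig.index:
        est, se, stars = sig.loc[name, ["estimate", "se", "stars"]]
        lo, hi = fit.conf_int_.loc[name]
        lines.append(
            f"{name:<22}{f'{est:.2f} (±{se:.2f}){stars}':<22}{lo:>10.2f}{hi:>10.2f}"
        )
    for name, s2 in fit.vc_.items():
        lines.append(f"{'sigma2_' + name:<22}{s2:<22.3f}")
    if hasattr(fit, "r2_marginal_"):
        lines.append(f"{'R2 marginal':<22}{fit.r2_marginal_:<22.2f}")
        lines.append(f"{'R2 conditional':<22}{fit.r2_conditional_:<22.2f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pooled cross-network quasi-likelihood comparison
# ---------------------------------------------------------------------------

def pooled_pair_table(events: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """One row per unordered feeder pair, pooled over seasons and species:
    total connection count, presence indicator and raw pair distance."""
    from feedernet.connectivity import all_pairs, _unordered_pairs

    pairs = all_pairs(stations)
    coords = stations.set_index("feeder_id")[["x", "y"]]
    xy_a = coords.loc[pairs["feeder_a"]].to_numpy(float)
    xy_b = coords.loc[pairs["feeder_b"]].to_numpy(float)
    pairs["distance_m"] = np.hypot(*(xy_a - xy_b).T)
    if len(events):
        counts = (
            _unordered_pairs(events)
            .groupby(PAIR_KEY, as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
        pairs = pairs.merge(counts, on=PAIR_KEY, how="left")
        pairs["count"] = pairs["count"].fillna(0).astype(int)
    else:
        pairs["count"] = 0
    pairs["presence"] = (pairs["count"] > 0).astype(int)
    return pairs


@dataclass
class PooledFit:
    """Quasi-binomial or quasi-Poisson cross-network fit."""

    family: str
    params: pd.Series
    bse: pd.Series  # quasi (dispersion-scaled) standard errors
    tvalues: pd.Series
    conf_int: pd.DataFrame
    dispersion: float  # Pearson chi2 / df_resid
    deviance: float
    anova_chi2: float  # network term: deviance reduction / dispersion
    anova_df: int
    anova_p: float
    mcfadden_r2: float  # on the unscaled likelihood
    n_obs: int

    def report(self) -> str:
        lines = [
            f"Pooled {self.family} model (n = {self.n_obs}, "
            f"dispersion = {self.dispersion:.2f})",
            f"{'term':<24}{'estimate (±se)':<22}{'t':>8}{'CI 2.5%':>10}"
            f"{'CI 97.5%':>10}",
        ]
        for name in self.params.index:
            est, se, t = self.params[name], self.bse[name], self.tvalues[name]
            lo, hi = self.conf_int.loc[name]
            lines.append(
                f"{name:<24}{f'{est:.3f} (±{se:.3f})':<22}{t:>8.1f}"
                f"{lo:>10.3f}{hi:>10.3f}"
            )
        lines.append(
            f"network ANODEV: chi2 = {self.anova_chi2:.1f}, "
            f"df = {self.anova_df}, p = {self.anova_p:.2g}"
        )
        lines.append(f"McFadden pseudo-R2 = {self.mcfadden_r2:.2f}")
        return "\n".join(lines) + "\n"


def analysis_of_deviance(dev_reduced: float, dev_full: float, dispersion: float,
                         df: int) -> tuple[float, float]:
    """Quasi-likelihood analysis of deviance for a dropped term: the
    deviance reduction scaled by the dispersion, referred to chi-square
    on ``df`` degrees of freedom."""
    stat = (dev_reduced - dev_full) / dispersion
    return float(stat), float(chi2.sf(stat, df))


def mcfadden_r2(ll_full: float, ll_null: float) -> float:
    """McFadden's pseudo-R²: 1 − lnL_full / lnL_null (unscaled)."""
    return 1.0 - ll_full / ll_null if ll_null != 0.0 else 0.0


def fit_pooled(pair_table: pd.DataFrame, family: str = "quasibinomial",
               baseline_network: str | None = None) -> PooledFit:
    """Cross-network quasi-likelihood GLM on the pooled per-pair table.

    ``family`` is ``"quasibinomial"`` (response: presence) or
    ``"quasipoisson"`` (response: count, rows with count ≥ 1 only).
    Predictors: network as a factor (baseline: ``baseline_network`` or the
    last network id sorted, mirroring a high-fragmentation reference) and
    raw pair distance in metres.
    """
    networks = sorted(pair_table["network_id"].unique())
    if len(networks) < 2:
        raise ValidationError("pooled comparison requires >= 2 networks")
    base = baseline_network or networks[-1]
    others = [g for g in networks if g != base]

    if family == "quasibinomial":
        df = pair_table
        y = df["presence"].to_numpy(float)
        sm_family = sm.families.Binomial()
    elif family == "quasipoisson":
        df = pair_table[pair_table["count"] >= 1]
        y = df["count"].to_numpy(float)
        sm_family = sm.families.Poisson()
    else:
        raise ValidationError(f"unknown pooled family {family!r}")

    X = pd.DataFrame(index=df.index)
    for g in others:
        X[f"network_{g}"] = (df["network_id"] == g).astype(float)
    X["distance_m"] = df["distance_m"].to_numpy(float)
    Xc = sm.add_constant(X, prepend=True)

    full = sm.GLM(y, Xc, family=sm_family).fit(scale="X2")
    reduced = sm.GLM(
        y, Xc.drop(columns=[f"network_{g}" for g in others]), family=sm_family
    ).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm_family).fit()

    phi = float(full.scale)  # Pearson chi2 / df_resid
    df_net = len(others)
    chi2_stat, p_net = analysis_of_deviance(
        float(reduced.deviance), float(full.deviance), phi, df_net
    )
    # unscaled log-likelihoods for McFadden's pseudo-R2
    ll_full = float(sm.GLM(y, Xc, family=sm_family).fit().llf)
    ll_null = float(null.llf)
    mcfadden = mcfadden_r2(ll_full, ll_null)

    return PooledFit(
        family=family,
        params=full.params,
        bse=full.bse,
        tvalues=full.tvalues,
        conf_int=full.conf_int().rename(columns={0: "lower", 1: "upper"}),
        dispersion=phi,
        deviance=float(full.deviance),
        anova_chi2=chi2_stat,
        anova_df=df_net,
        anova_p=p_net,
        mcfadden_r2=mcfadden,
        n_obs=len(df),
    )
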