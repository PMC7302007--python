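"""Simulation study: validate the summary-level estimators against
individual-level fits and characterize their bias sources.

Each replicate simulates one SNP for a cohort: genotypes G ~ Binomial(2, MAF)
with MAF drawn uniformly per replicate, a binary exposure E ~ Bernoulli(p)
with p drawn uniformly, and a phenotype

    Y = beta_G * G + beta_E * E + beta_GE * G * E + eps,  eps ~ N(0, sigma^2)

(for binary traits, Y ~ Bernoulli with a logistic model on the same linear
predictor plus the noise term). The "true" statistics come from regressions
on the individual-level data (stratified by exposure, and marginal); the
"estimated" statistics come from applying the closed-form conversion to the
joint interaction fit. Agreement is measured with the intraclass correlation
coefficient; under a null model the empirical type-I error and the
proportion of Bonferroni-discordant replicates quantify practical impact.

Bias scenarios:
  * ``ge_corr`` — exposure drawn conditionally on genotype (logistic link),
    violating the G-E independence assumption behind the marginal formula;
  * ``misspecified_mu`` — the estimator is fed the full-cohort exposure
    frequency while the variant was genotyped in an exposure-imbalanced
    subsample (mimicking differential missingness);
  * ``heteroscedastic`` — extra phenotype noise in exposed individuals, so
    the joint fit's pooled residual variance misrepresents both strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimators import derive_record
from .records import (ComputationError, ConfigurationError, JointRecord,
                      StudyDesign, ValidationError)

__all__ = [
    "SimScenario", "ReplicateData", "ModelFit", "JointFit", "FitResult",
    "AgreementReport", "simulate_replicate", "fit_all_models", "icc",
    "run_accuracy_study", "run_bias_study", "run_null_study",
    "accuracy_scenario", "bias_scenario", "null_scenario", "BIAS_KINDS",
]

BIAS_KINDS = ("ge_corr", "misspecified_mu", "heteroscedastic")

ANALYSES = ("unexposed", "exposed", "marginal")


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulation study.

    Bias knobs are upper bounds of per-replicate uniform draws (a study
    needs a spread of bias magnitudes to stratify results by quintile):
    ``ge_corr`` bounds the target G-E point-biserial correlation;
    ``subsample_fraction`` is the minimum retained fraction of individuals;
    ``exposed_removal_fraction`` bounds the extra fraction of retained
    exposed individuals removed; ``exposed_extra_noise_sd`` bounds the SD of
    extra phenotype noise added to exposed individuals. A knob at 0 (or
    subsample_fraction at 0) disables its mechanism.
    """

    n_individuals: int = 10_000
    n_replicates: int = 1_000
    maf_range: tuple[float, float] = (0.01, 0.50)
    exposure_prob_range: tuple[float, float] = (0.1, 0.5)
    effect_range: tuple[float, float] = (0.05, 0.2)
    noise_sd: float = 1.0
    trait_type: str = "quantitative"
    ge_corr: float = 0.0
    subsample_fraction: float = 0.0
    exposed_removal_fraction: float = 0.0
    exposed_extra_noise_sd: float = 0.0
    null_model: bool = False
    logit_sign: str = "conventional"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ConfigurationError(f"maf_range must be within (0, 0.5], got "
                                     f"{self.maf_range}")
        lo, hi = self.exposure_prob_range
        if not 0 < lo <= hi < 1:
            raise ConfigurationError("exposure_prob_range must be within "
                                     f"(0, 1), got {self.exposure_prob_range}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.logit_sign not in ("conventional", "as-printed"):
            raise ConfigurationError(f"unknown logit_sign {self.logit_sign!r}")
        if self.n_individuals < 10 or self.n_replicates < 1:
            raise ConfigurationError("scenario too small to simulate")


def accuracy_scenario(**overrides) -> SimScenario:
    """Headline accuracy study: 1000 replicates of 10,000 individuals
    (10,000 replicates for the binary-trait variant)."""
    if overrides.get("trait_type") == "binary":
        overrides.setdefault("n_replicates", 10_000)
    return SimScenario(**overrides)


def bias_scenario(kind: str, **overrides) -> SimScenario:
    """Bias study defaults: 10,000 replicates of 50,000 individuals with
    the requested bias mechanism engaged at its default magnitude cap."""
    knobs = {
        "ge_corr": {"ge_corr": 0.25},
        "misspecified_mu": {"subsample_fraction": 0.5,
                            "exposed_removal_fraction": 0.5},
        "heteroscedastic": {"exposed_extra_noise_sd": 1.0},
    }
    if kind not in knobs:
        raise ConfigurationError(f"unknown bias kind {kind!r}; "
                                 f"expected one of {BIAS_KINDS}")
    params = {"n_individuals": 50_000, "n_replicates": 10_000, **knobs[kind]}
    params.update(overrides)
    return SimScenario(**params)


def null_scenario(**overrides) -> SimScenario:
    """Type-I-error study: no genetic or interaction effect."""
    params = {"n_individuals": 50_000, "n_replicates": 10_000,
              "null_model": True}
    params.update(overrides)
    return SimScenario(**params)


@dataclass(frozen=True)
class ReplicateData:
    """One simulated SNP's individual-level data (possibly subsampled)."""

    G: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    n_full: int
    n_exposed_full: int
    bias_value: float = math.nan
    params: dict = field(default_factory=dict)

    @property
    def design(self) -> StudyDesign:
        """The design the estimator is fed (full-cohort N and N_e)."""
        return StudyDesign(n_total=self.n_full, n_exposed=self.n_exposed_full)


# ---------------------------------------------------------------------------
# Exposure-given-genotype calibration for the G-E correlation scenario.
# ---------------------------------------------------------------------------

def _max_attainable_corr(maf: float, p: float) -> float:
    """Point-biserial corr(G, E) of the comonotone coupling of the marginals.

    G ~ Binomial(2, maf) has three atoms; assigning E = 1 to the largest
    genotypes first maximizes E[G E] at fixed marginals (Frechet bound).
    """
    q = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    mu_g, var_g = 2 * maf, 2 * maf * (1 - maf)
    mass = p
    ege = 2 * min(mass, q[2])
    mass = max(mass - q[2], 0.0)
    ege += 1 * min(mass, q[1])
    return (ege - mu_g * p) / math.sqrt(var_g * p * (1 - p))


def _calibrate_exposure_model(maf: float, p: float,
                              rho: float) -> tuple[float, float]:
    """Solve for (a, b) such that E|G ~ Bernoulli(logistic(a + b G)) has
    exposure frequency p and point-biserial corr(G, E) = rho.

    Expectations are exact sums over the three genotype atoms, so this is a
    cheap 2-d root-find started at the independent solution (logit(p), 0).
    """
    q = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    g = np.array([0.0, 1.0, 2.0])
    mu_g, var_g = 2 * maf, 2 * maf * (1 - maf)

    def equations(ab: np.ndarray) -> list[float]:
        a, b = ab
        pe_g = 1.0 / (1.0 + np.exp(-(a + b * g)))
        pe = float(q @ pe_g)
        ege = float(q @ (g * pe_g))
        pe_c = min(max(pe, 1e-12), 1 - 1e-12)
        corr = (ege - mu_g * pe) / math.sqrt(var_g * pe_c * (1 - pe_c))
        return [pe - p, corr - rho]

    target = rho
    for _ in range(6):
        sol, info, ier, _msg = optimize.fsolve(
            equations, x0=[math.log(p / (1 - p)), 0.0], full_output=True)
        if ier == 1:
            return float(sol[0]), float(sol[1])
        target *= 0.5
        rho = target
    raise ComputationError(
        f"could not calibrate exposure model for maf={maf}, p={p}, rho={rho}")


# ---------------------------------------------------------------------------
# Data generation.
# ---------------------------------------------------------------------------

def simulate_replicate(scn: SimScenario, rep_index: int) -> ReplicateData:
    """Generate one replicate's individual-level dataset, deterministically
    from (scenario seed, replicate index)."""
    rng = np.random.default_rng(np.random.SeedSequence([scn.seed, rep_index]))
    n = scn.n_individuals

    maf = rng.uniform(*scn.maf_range)
    p_exposed = rng.uniform(*scn.exposure_prob_range)
    lo, hi = scn.effect_range

    def draw_effect() -> float:
        return rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])

    beta_g = 0.0 if scn.null_model else draw_effect()
    beta_e = draw_effect()
    beta_ge = 0.0 if scn.null_model else draw_effect()

    G = rng.binomial(2, maf, size=n).astype(float)

    rho_target = math.nan
    if scn.ge_corr > 0:
        rho_target = rng.uniform(0.0, scn.ge_corr)
        rho_target = min(rho_target,
                         0.8 * _max_attainable_corr(maf, p_exposed))
        a, b = _calibrate_exposure_model(maf, p_exposed, rho_target)
        E = (rng.random(n) < 1.0 / (1.0 + np.exp(-(a + b * G)))).astype(float)
    else:
        E = (rng.random(n) < p_exposed).astype(float)

    extra_sd = 0.0
    if scn.exposed_extra_noise_sd > 0:
        extra_sd = rng.uniform(0.0, scn.exposed_extra_noise_sd)

    eta = beta_g * G + beta_e * E + beta_ge * G * E \
        + rng.normal(0.0, scn.noise_sd, size=n)
    if extra_sd > 0:
        eta = eta + E * rng.normal(0.0, extra_sd, size=n)

    if scn.trait_type == "quantitative":
        Y = eta
    else:
        sign = -1.0 if scn.logit_sign == "conventional" else 1.0
        prob = 1.0 / (1.0 + np.exp(sign * eta))
        Y = (rng.random(n) < prob).astype(float)

    n_exposed_full = int(E.sum())
    bias_value = math.nan
    params = {"maf": maf, "p_exposed": p_exposed, "beta_g": beta_g,
              "beta_e": beta_e, "beta_ge": beta_ge,
              "sigma": scn.noise_sd, "extra_sd": extra_sd,
              "rho_target": rho_target}

    if scn.ge_corr > 0:
        sd_g, sd_e = G.std(), E.std()
        params["rho_realized"] = (
            float(np.mean(G * E) - G.mean() * E.mean()) / (sd_g * sd_e)
            if sd_g > 0 and sd_e > 0 else math.nan)
        bias_value = abs(params["rho_realized"])
    if extra_sd > 0:
        # realized gap in phenotypic SD between the strata
        bias_value = abs(float(eta[E == 1].std() - eta[E == 0].std()))

    if scn.subsample_fraction > 0 or scn.exposed_removal_fraction > 0:
        keep_frac = rng.uniform(max(scn.subsample_fraction, 0.05), 1.0)
        keep = rng.random(n) < keep_frac
        if scn.exposed_removal_fraction > 0:
            drop_frac = rng.uniform(0.0, scn.exposed_removal_fraction)
            keep &= ~((E == 1) & (rng.random(n) < drop_frac))
        G_s, E_s, Y_s = G[keep], E[keep], Y[keep]
        mu_full = n_exposed_full / n
        m_e = float(E_s.mean())
        bias_value = abs(mu_full - m_e) / mu_full
        return ReplicateData(G=G_s, E=E_s, Y=Y_s, n_full=n,
                             n_exposed_full=n_exposed_full,
                             bias_value=bias_value, params=params)

    return ReplicateData(G=G, E=E, Y=Y, n_full=n,
                         n_exposed_full=n_exposed_full,
                         bias_value=bias_value, params=params)


# ---------------------------------------------------------------------------
# Model fitting ("true" statistics from individual-level data).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    beta: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class JointFit:
    beta: float
    delta: float
    se_beta: float
    se_delta: float
    corr: float


@dataclass(frozen=True)
class FitResult:
    joint: JointFit
    stratified_unexp: ModelFit
    stratified_exp: ModelFit
    marginal: ModelFit
    realized_mu_e: float


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and covariance s^2 (X'X)^-1 via the normal equations.

    Design matrices here are tiny (2-4 columns) and well-conditioned, so a
    direct solve is accurate and far faster than a general-purpose fitter.
    """
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ComputationError("not enough observations for OLS")
    s2 = float(resid @ resid) / dof
    return coef, s2 * np.linalg.inv(XtX)


def _wald(beta: float, se: float) -> ModelFit:
    z = beta / se
    return ModelFit(beta=beta, se=se, z=z,
                    p=max(2.0 * stats.norm.sf(abs(z)), 5e-324))


def _fit_linear(G: np.ndarray, E: np.ndarray, Y: np.ndarray) -> FitResult:
    ones = np.ones_like(G)
    for e in (0, 1):
        m = E == e
        if not m.any():
            raise ComputationError(f"empty stratum E={e}")
        if G[m].min() == G[m].max():
            raise ComputationError(f"constant genotype in stratum E={e}")
    X = np.column_stack([ones, G, E, G * E])
    coef, cov = _ols(X, Y)
    se_b, se_d = math.sqrt(cov[1, 1]), math.sqrt(cov[3, 3])
    joint = JointFit(beta=coef[1], delta=coef[3], se_beta=se_b,
                     se_delta=se_d, corr=cov[1, 3] / (se_b * se_d))

    strat = []
    for e in (0, 1):
        m = E == e
        if not m.any():
            raise ComputationError(f"empty stratum E={e}")
        Gs = G[m]
        if Gs.min() == Gs.max():
            raise ComputationError(f"constant genotype in stratum E={e}")
        c, v = _ols(np.column_stack([np.ones(m.sum()), Gs]), Y[m])
        strat.append(_wald(c[1], math.sqrt(v[1, 1])))

    c, v = _ols(np.column_stack([ones, G, E]), Y)
    marg = _wald(c[1], math.sqrt(v[1, 1]))
    return FitResult(joint=joint, stratified_unexp=strat[0],
                     stratified_exp=strat[1], marginal=marg,
                     realized_mu_e=float(E.mean()))


def _logit_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # perfect separation, non-convergence
        raise ComputationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ComputationError("logistic fit did not converge")
    return np.asarray(res.params), np.asarray(res.cov_params())


def _fit_logistic(G: np.ndarray, E: np.ndarray, Y: np.ndarray) -> FitResult:
    ones = np.ones_like(G)
    for e in (0, 1):
        m = E == e
        if not m.any():
            raise ComputationError(f"empty stratum E={e}")
        if G[m].min() == G[m].max():
            raise ComputationError(f"constant genotype in stratum E={e}")

    coef, cov = _logit_fit(np.column_stack([ones, G, E, G * E]), Y)
    se_b, se_d = math.sqrt(cov[1, 1]), math.sqrt(cov[3, 3])
    joint = JointFit(beta=coef[1], delta=coef[3], se_beta=se_b,
                     se_delta=se_d, corr=cov[1, 3] / (se_b * se_d))

    strat = []
    for e in (0, 1):
        m = E == e
        c, v = _logit_fit(np.column_stack([np.ones(m.sum()), G[m]]), Y[m])
        strat.append(_wald(c[1], math.sqrt(v[1, 1])))

    c, v = _logit_fit(np.column_stack([ones, G, E]), Y)
    marg = _wald(c[1], math.sqrt(v[1, 1]))
    return FitResult(joint=joint, stratified_unexp=strat[0],
                     stratified_exp=strat[1], marginal=marg,
                     realized_mu_e=float(E.mean()))


def fit_all_models(data: ReplicateData,
                   trait_type: str = "quantitative") -> FitResult:
    """Fit the joint interaction model, both stratified models and the
    marginal model on individual-level data."""
    if trait_type == "quantitative":
        return _fit_linear(data.G, data.E, data.Y)
    return _fit_logistic(data.G, data.E, data.Y)


def derived_from_joint(joint: JointFit, n_variant: float,
                       design: StudyDesign):
    """Run the summary-level estimators on one joint fit."""
    rec = JointRecord(variant_id="sim", beta=joint.beta,
                      se_beta=joint.se_beta, delta=joint.delta,
                      se_delta=joint.se_delta,
                      corr_beta_delta=joint.corr, n_variant=n_variant)
    return derive_record(rec, design)


# ---------------------------------------------------------------------------
# Agreement metrics.
# ---------------------------------------------------------------------------

def icc(x, y) -> float:
    """Intraclass correlation, two-way random effects, absolute agreement,
    single measurement (ICC(2,1)).

    Treats the paired vectors as n subjects rated by k = 2 raters and
    returns (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)). Absolute
    agreement (rather than consistency) penalizes systematic shifts between
    the two raters, which is the point when comparing "true" with
    "estimated" statistics. Returns NaN when total variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("icc needs two equal-length vectors, n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("icc inputs must be finite")
    M = np.column_stack([x, y])
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_total = float(((M - grand) ** 2).sum())
    if ss_total == 0.0:
        return math.nan
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return math.nan
    return (msr - mse) / denom


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between individual-level and summary-derived statistics.

    ``icc_z`` / ``icc_beta`` / ``icc_se`` hold per-analysis ICCs of the Wald
    statistics, effect sizes and SEs; null studies add per-analysis type-I
    error rates and the Bonferroni significance-discordance proportion;
    bias studies add a per-quintile table.
    """

    icc_z: dict
    icc_beta: dict
    icc_se: dict
    n_replicates: int
    n_skipped: int
    typeI_true: dict | None = None
    typeI_estimated: dict | None = None
    discordance: dict | None = None
    quintiles: pd.DataFrame | None = None

    @property
    def icc_unexp(self) -> float:
        return self.icc_z["unexposed"]

    @property
    def icc_exp(self) -> float:
        return self.icc_z["exposed"]

    @property
    def icc_marg(self) -> float:
        return self.icc_z["marginal"]


def _collect(scn: SimScenario) -> pd.DataFrame:
    """Run all replicates; one row of paired true/estimated statistics each."""
    rows = []
    n_skipped = 0
    for i in range(scn.n_replicates):
        data = simulate_replicate(scn, i)
        try:
            fit = fit_all_models(data, scn.trait_type)
        except ComputationError:
            n_skipped += 1
            continue
        der = derived_from_joint(fit.joint, len(data.G), data.design)
        est = {"unexposed": der.unexposed, "exposed": der.exposed,
               "marginal": der.marginal}
        true = {"unexposed": fit.stratified_unexp,
                "exposed": fit.stratified_exp, "marginal": fit.marginal}
        row = {"bias_value": data.bias_value}
        for name in ANALYSES:
            row[f"true_beta_{name}"] = true[name].beta
            row[f"true_se_{name}"] = true[name].se
            row[f"true_z_{name}"] = true[name].z
            row[f"true_p_{name}"] = true[name].p
            row[f"est_beta_{name}"] = est[name].beta_hat
            row[f"est_se_{name}"] = est[name].se_hat
            row[f"est_z_{name}"] = est[name].z
            row[f"est_p_{name}"] = est[name].p
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_skipped"] = n_skipped
    return df


def _icc_dicts(df: pd.DataFrame) -> tuple[dict, dict, dict]:
    icc_z, icc_beta, icc_se = {}, {}, {}
    for name in ANALYSES:
        icc_z[name] = icc(df[f"true_z_{name}"], df[f"est_z_{name}"])
        icc_beta[name] = icc(df[f"true_beta_{name}"], df[f"est_beta_{name}"])
        icc_se[name] = icc(df[f"true_se_{name}"], df[f"est_se_{name}"])
    return icc_z, icc_beta, icc_se


def run_accuracy_study(scn: SimScenario) -> AgreementReport:
    """Estimator-accuracy study: ICC between true and estimated statistics
    across replicates, for each analysis."""
    if scn.ge_corr > 0 or scn.subsample_fraction > 0 \
            or scn.exposed_extra_noise_sd > 0:
        raise ConfigurationError("accuracy study expects all bias knobs off")
    df = _collect(scn)
    if len(df) < 2:
        raise ComputationError("fewer than 2 usable replicates")
    icc_z, icc_beta, icc_se = _icc_dicts(df)
    return AgreementReport(icc_z=icc_z, icc_beta=icc_beta, icc_se=icc_se,
                           n_replicates=len(df),
                           n_skipped=df.attrs["n_skipped"])


def run_bias_study(scn: SimScenario, bias_kind: str) -> AgreementReport:
    """Bias study: overall ICCs plus a table stratified by quintile of the
    realized bias magnitude (|corr(G,E)|, |mu_E - m_E|/mu_E, or the
    between-stratum phenotypic-SD gap)."""
    knob_ok = {
        "ge_corr": scn.ge_corr > 0,
        "misspecified_mu": scn.subsample_fraction > 0
        or scn.exposed_removal_fraction > 0,
        "heteroscedastic": scn.exposed_extra_noise_sd > 0,
    }
    if bias_kind not in knob_ok:
        raise ConfigurationError(f"unknown bias kind {bias_kind!r}")
    if not knob_ok[bias_kind]:
        raise ConfigurationError(
            f"scenario does not engage the {bias_kind} mechanism")
    df = _collect(scn)
    if len(df) < 10:
        raise ComputationError("fewer than 10 usable replicates")
    icc_z, icc_beta, icc_se = _icc_dicts(df)

    df = df.sort_values("bias_value").reset_index(drop=True)
    df["quintile"] = pd.qcut(df["bias_value"], 5, labels=False,
                             duplicates="drop") + 1
    qrows = []
    for q, grp in df.groupby("quintile"):
        row = {"quintile": int(q),
               "bias_lo": float(grp["bias_value"].min()),
               "bias_hi": float(grp["bias_value"].max()),
               "n": len(grp)}
        for name in ANALYSES:
            row[f"icc_z_{name}"] = icc(grp[f"true_z_{name}"],
                                       grp[f"est_z_{name}"])
            err = grp[f"est_se_{name}"] - grp[f"true_se_{name}"]
            row[f"mean_se_err_{name}"] = float(err.mean())
            row[f"mean_abs_se_err_{name}"] = float(err.abs().mean())
        qrows.append(row)
    return AgreementReport(icc_z=icc_z, icc_beta=icc_beta, icc_se=icc_se,
                           n_replicates=len(df),
                           n_skipped=df.attrs["n_skipped"],
                           quintiles=pd.DataFrame(qrows))


def run_null_study(scn: SimScenario, alpha: float = 0.05) -> AgreementReport:
    """Type-I-error study under the null (beta_G = beta_GE = 0).

    Reports the empirical rejection rate at ``alpha`` for the true and
    summary-derived statistics in each analysis, and the proportion of
    replicates significant under a Bonferroni-adjusted threshold
    (alpha / n_replicates, the per-SNP screening framing) with exactly one
    of the two methods.
    """
    if not scn.null_model:
        raise ConfigurationError("null study requires null_model=True")
    if not 0 < alpha <= 1:
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    df = _collect(scn)
    if len(df) < 2:
        raise ComputationError("fewer than 2 usable replicates")
    icc_z, icc_beta, icc_se = _icc_dicts(df)
    bonf = alpha / len(df)
    typeI_true, typeI_est, disc = {}, {}, {}
    for name in ANALYSES:
        tp = df[f"true_p_{name}"].to_numpy()
        ep = df[f"est_p_{name}"].to_numpy()
        typeI_true[name] = float((tp < alpha).mean())
        typeI_est[name] = float((ep < alpha).mean())
        disc[name] = float(((tp < bonf) ^ (ep < bonf)).mean())

    quintiles = None
    if np.isfinite(df["bias_value"]).all() and df["bias_value"].nunique() > 5:
        df = df.sort_values("bias_value").reset_index(drop=True)
        df["quintile"] = pd.qcut(df["bias_value"], 5, labels=False,
                                 duplicates="drop") + 1
        qrows = []
        for q, grp in df.groupby("quintile"):
            row = {"quintile": int(q), "n": len(grp),
                   "bias_lo": float(grp["bias_value"].min()),
                   "bias_hi": float(grp["bias_value"].max())}
            for name in ANALYSES:
                row[f"typeI_true_{name}"] = \
                    float((grp[f"true_p_{name}"] < alpha).mean())
                row[f"typeI_est_{name}"] = \
                    float((grp[f"est_p_{name}"] < alpha).mean())
            qrows.append(row)
        quintiles = pd.DataFrame(qrows)

    return AgreementReport(icc_z=icc_z, icc_beta=icc_beta, icc_se=icc_se,
                           n_replicates=len(df),
                           n_skipped=df.attrs["n_skipped"],
                           typeI_true=typeI_true, typeI_estimated=typeI_est,
                           discordance=disc, quintiles=quintiles)
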