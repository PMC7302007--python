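"""Closed-form conversion of joint-model summary statistics.

With a binary exposure the interaction model is saturated in E, so the
joint-model coefficients map exactly onto per-stratum genetic effects:

    beta_unexp = beta                      se_unexp = se_beta
    beta_exp   = beta + delta              se_exp   = sqrt(s_b^2 + s_d^2 + 2 c)
    beta_marg  = beta + delta * mu_e       se_marg  = sqrt(s_b^2 + mu_e^2 s_d^2
                                                           + 2 mu_e c)

where c = cov(beta_hat, delta_hat) and mu_e = N_e / N is the exposure
frequency. The marginal mapping additionally assumes genotype and exposure
are independent. Per-variant stratum sample sizes are inferred by
proportional allocation of the per-variant size N_v, and variants whose N_v
falls below (9th decile of the N_v distribution) / 1.5 are flagged, since
exposure-imbalanced missingness makes mu_e a poor stand-in for the
subsample's realized exposure mean at low relative sample size.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (ComputationError, DerivedRecord, JointRecord,
                      StratumStats, StudyDesign, ValidationError)

__all__ = [
    "cov_from_corr", "wald_test", "derive_unexposed", "derive_exposed",
    "derive_marginal", "derive_record", "infer_stratum_sizes",
    "sample_size_threshold", "filter_low_sample_size", "derive_frame",
]

#: Smallest positive float; two-sided normal p-values are clamped here so
#: that p stays in (0, 1] even for |z| beyond the underflow point.
_TINY = 5e-324

#: Relative-sample-size filter: drop N_v below quantile(N_v, Q)/DIVISOR.
FILTER_QUANTILE = 0.9
FILTER_DIVISOR = 1.5


def cov_from_corr(r: float, s1: float, s2: float) -> float:
    """Covariance of two estimates from their correlation and SEs: r*s1*s2."""
    if not math.isnan(r) and not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if (not math.isnan(s1) and s1 < 0) or (not math.isnan(s2) and s2 < 0):
        raise ValidationError("standard errors must be >= 0")
    return r * s1 * s2


def wald_test(beta_hat: float, se_hat: float) -> tuple[float, float]:
    """Wald z = beta/se and its two-sided standard-normal p-value.

    Returns (nan, nan) when the SE is zero, negative or missing: the test
    is undefined but the effect estimate itself is still reportable.
    """
    if math.isnan(beta_hat) or math.isnan(se_hat) or se_hat <= 0:
        return (math.nan, math.nan)
    z = beta_hat / se_hat
    p = 2.0 * stats.norm.sf(abs(z))
    return z, max(p, _TINY)


def infer_stratum_sizes(n_variant: float,
                        design: StudyDesign) -> tuple[float, float]:
    """Proportional per-variant stratum sizes (n_unexposed, n_exposed).

    n_exposed = N_v * (N_e / N) and n_unexposed = N_v - n_exposed, so the
    two sum back to N_v exactly for the integer-valued per-variant sizes
    meta-analysis files carry (and to machine precision otherwise). Sizes
    are expectations under exposure-balanced missingness and are left
    unrounded.
    """
    if not n_variant > 0:
        raise ValidationError(f"n_variant must be > 0, got {n_variant}")
    n_exp = n_variant * (design.n_exposed / design.n_total)
    return n_variant - n_exp, n_exp


def _stats_from(beta: float, se: float, n: float) -> StratumStats:
    z, p = wald_test(beta, se)
    return StratumStats(beta_hat=beta, se_hat=se, n_stratum=n, z=z, p=p)


def derive_unexposed(rec: JointRecord,
                     design: StudyDesign | None = None) -> StratumStats:
    """Genetic effect among unexposed individuals: the joint main effect."""
    n = math.nan
    if design is not None:
        n = infer_stratum_sizes(rec.n_variant, design)[0]
    return _stats_from(rec.beta, rec.se_beta, n)


def derive_exposed(rec: JointRecord,
                   design: StudyDesign | None = None) -> StratumStats:
    """Genetic effect among exposed individuals: beta + delta.

    The variance sums the two estimation variances plus twice their
    covariance; for a valid correlation in [-1, 1] the quadratic form is a
    completed square and cannot go negative.
    """
    beta = rec.beta + rec.delta
    var = rec.se_beta**2 + rec.se_delta**2 + 2.0 * rec.covariance
    if not math.isnan(var) and var < 0:
        # only reachable with a corrupt explicit covariance column
        raise ComputationError(
            f"variant {rec.variant_id!r}: negative variance ({var}) for the "
            "exposed-stratum effect; check the covariance column")
    n = math.nan
    if design is not None:
        n = infer_stratum_sizes(rec.n_variant, design)[1]
    return _stats_from(beta, math.sqrt(var) if not math.isnan(var) else math.nan, n)


def derive_marginal(rec: JointRecord, design: StudyDesign) -> StratumStats:
    """Marginal (no-interaction) genetic effect: beta + delta * mu_e.

    Valid under genotype-exposure independence; mu_e in {0, 1} is rejected
    because the marginal model then coincides with a single stratum.
    """
    design.require_two_strata()
    mu = design.mu_e
    beta = rec.beta + rec.delta * mu
    var = rec.se_beta**2 + mu**2 * rec.se_delta**2 + 2.0 * mu * rec.covariance
    if not math.isnan(var) and var < 0:
        raise ComputationError(
            f"variant {rec.variant_id!r}: negative variance ({var}) for the "
            "marginal effect; check the covariance column")
    return _stats_from(beta, math.sqrt(var) if not math.isnan(var) else math.nan,
                       float(rec.n_variant))


def derive_record(rec: JointRecord, design: StudyDesign) -> DerivedRecord:
    """All three derived summaries for one variant."""
    return DerivedRecord(
        variant_id=rec.variant_id,
        unexposed=derive_unexposed(rec, design),
        exposed=derive_exposed(rec, design),
        marginal=derive_marginal(rec, design),
        filtered=rec.filtered,
    )


def sample_size_threshold(n_values: Sequence[float]) -> float:
    """Filter threshold: 0.9-quantile of per-variant sizes divided by 1.5.

    The quantile uses linear interpolation between order statistics (the
    numpy default convention).
    """
    arr = np.asarray(n_values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("no records with a usable sample size")
    return float(np.quantile(arr, FILTER_QUANTILE)) / FILTER_DIVISOR


def filter_low_sample_size(records: Sequence[JointRecord]) -> list[JointRecord]:
    """Flag variants with low relative sample size; nothing is deleted.

    A record is flagged when n_variant < (9th decile of all n_variant)/1.5;
    downstream writers decide whether flagged rows are dropped or kept.
    """
    if len(records) == 0:
        raise ValidationError("no records to filter")
    thr = sample_size_threshold([r.n_variant for r in records])
    return [replace(r, filtered=bool(r.n_variant < thr)) for r in records]


# ---------------------------------------------------------------------------
# Vectorized path used by the file pipeline (identical arithmetic).
# ---------------------------------------------------------------------------

def derive_frame(df: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Vectorized `derive_record` over a canonical-column DataFrame.

    Expects columns ``variant_id, beta, se_beta, delta, se_delta,
    corr_beta_delta, cov_beta_delta, n_variant, filtered`` (NaN where
    missing) and returns the flat output table with one row per input row.
    """
    design.require_two_strata()
    mu = design.mu_e
    beta = df["beta"].to_numpy(float)
    se_b = df["se_beta"].to_numpy(float)
    delta = df["delta"].to_numpy(float)
    se_d = df["se_delta"].to_numpy(float)
    corr = df["corr_beta_delta"].to_numpy(float)
    cov = df["cov_beta_delta"].to_numpy(float)
    cov = np.where(np.isfinite(cov), cov, corr * se_b * se_d)
    n_v = df["n_variant"].to_numpy(float)

    n_exp = n_v * (design.n_exposed / design.n_total)
    n_unexp = n_v - n_exp

    def zp(b: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
        z = np.where(ok, b / np.where(ok, s, 1.0), np.nan)
        with np.errstate(invalid="ignore"):
            p = np.where(ok, np.maximum(2.0 * stats.norm.sf(np.abs(z)), _TINY),
                         np.nan)
        return z, p

    def safe_sqrt(v: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(v >= 0, np.sqrt(np.abs(v)), np.nan)

    se_unexp = se_b
    b_exp = beta + delta
    se_exp = safe_sqrt(se_b**2 + se_d**2 + 2.0 * cov)
    b_marg = beta + delta * mu
    se_marg = safe_sqrt(se_b**2 + mu**2 * se_d**2 + 2.0 * mu * cov)

    z_u, p_u = zp(beta, se_unexp)
    z_e, p_e = zp(b_exp, se_exp)
    z_m, p_m = zp(b_marg, se_marg)

    return pd.DataFrame({
        "variant_id": df["variant_id"].to_numpy(),
        "n_unexp": n_unexp, "beta_unexp": beta, "se_unexp": se_unexp,
        "z_unexp": z_u, "p_unexp": p_u,
        "n_exp": n_exp, "beta_exp": b_exp, "se_exp": se_exp,
        "z_exp": z_e, "p_exp": p_e,
        "n_marg": n_v, "beta_marg": b_marg, "se_marg": se_marg,
        "z_marg": z_m, "p_marg": p_m,
        "filtered": df["filtered"].to_numpy(bool),
    })
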