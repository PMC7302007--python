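"""Unit and property tests for the closed-form summary-level estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from jointstrat import (ComputationError, ConfigurationError, JointRecord,
                        StudyDesign, ValidationError, cov_from_corr,
                        derive_exposed, derive_frame, derive_marginal,
                        derive_record, derive_unexposed,
                        filter_low_sample_size, infer_stratum_sizes,
                        sample_size_threshold, wald_test)


def rec(variant_id="rs1", beta=0.1, se_beta=0.03, delta=0.05, se_delta=0.04,
        corr=0.0, n=1000.0, **kw):
    return JointRecord(variant_id=variant_id, beta=beta, se_beta=se_beta,
                       delta=delta, se_delta=se_delta,
                       corr_beta_delta=corr, n_variant=n, **kw)


# ---------------------------------------------------------------------------
# covariance from correlation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r,s1,s2,expected", [
    (0.0, 0.1, 0.2, 0.0),
    (1.0, 0.1, 0.2, 0.02),
    (-0.3, 0.05, 0.04, -0.0006),
])
def test_cov_from_corr(r, s1, s2, expected):
    assert cov_from_corr(r, s1, s2) == pytest.approx(expected, abs=1e-15)


def test_cov_from_corr_rejects_out_of_range():
    with pytest.raises(ValidationError):
        cov_from_corr(1.5, 0.1, 0.1)
    with pytest.raises(ValidationError):
        cov_from_corr(0.5, -0.1, 0.1)


def test_record_rejects_out_of_range_correlation():
    with pytest.raises(ValidationError, match="rsX"):
        rec(variant_id="rsX", corr=-1.01)


def test_explicit_covariance_column_wins_over_correlation():
    r = rec(corr=0.5, cov_beta_delta=-0.0002)
    assert r.covariance == -0.0002


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def test_wald_null_effect():
    z, p = wald_test(0.0, 0.1)
    assert z == 0.0 and p == 1.0


def test_wald_matches_normal_quantile():
    z, p = wald_test(0.196, 0.1)
    assert z == pytest.approx(1.96)
    assert p == pytest.approx(0.05, abs=1e-3)


def test_wald_against_erfc_oracle():
    z, p = wald_test(-0.3, 0.1)
    assert z == pytest.approx(-3.0)
    assert p == pytest.approx(math.erfc(3.0 / math.sqrt(2.0)), rel=1e-12)


def test_wald_zero_se_is_missing_sentinel():
    z, p = wald_test(0.1, 0.0)
    assert math.isnan(z) and math.isnan(p)


# ---------------------------------------------------------------------------
# stratified / marginal derivations
# ---------------------------------------------------------------------------

def test_unexposed_is_identity_on_main_effect():
    s = derive_unexposed(rec(beta=0.12, se_beta=0.03, delta=0.7))
    assert s.beta_hat == 0.12 and s.se_hat == 0.03
    assert s.z == pytest.approx(4.0)


def test_unexposed_zero_se_keeps_record_with_sentinels():
    s = derive_unexposed(rec(beta=0.05, se_beta=0.0))
    assert s.beta_hat == 0.05
    assert math.isnan(s.z) and math.isnan(s.p)


@pytest.mark.parametrize("kw,beta,se", [
    (dict(beta=0.1, delta=0.0, se_beta=0.03, se_delta=0.0, corr=0.0),
     0.1, 0.03),
    (dict(beta=0.1, delta=-0.1, se_beta=0.03, se_delta=0.04, corr=-1.0),
     0.0, 0.01),
])
def test_exposed_examples(kw, beta, se):
    s = derive_exposed(rec(**kw))
    assert s.beta_hat == pytest.approx(beta, abs=1e-15)
    assert s.se_hat == pytest.approx(se, abs=1e-12)


def test_exposed_negative_variance_from_corrupt_covariance():
    with pytest.raises(ComputationError, match="rs1"):
        derive_exposed(rec(se_beta=0.01, se_delta=0.01,
                           cov_beta_delta=-0.5))


def test_marginal_example_near_exposed_limit():
    design = StudyDesign(n_total=10**8, n_exposed=10**8 - 1)
    s = derive_marginal(rec(beta=0.1, delta=0.2, se_beta=0.03, se_delta=0.04,
                            corr=0.0), design)
    assert s.beta_hat == pytest.approx(0.3, abs=1e-6)
    assert s.se_hat == pytest.approx(0.05, abs=1e-6)


def test_marginal_degenerate_design_rejected():
    r = rec()
    with pytest.raises(ConfigurationError):
        derive_marginal(r, StudyDesign(n_total=100, n_exposed=0))
    with pytest.raises(ConfigurationError):
        derive_marginal(r, StudyDesign(n_total=100, n_exposed=100))


def test_marginal_collapses_continuously_to_strata():
    """As mu_e -> 0 (resp. 1) the marginal statistics approach the
    unexposed (resp. exposed) stratum's."""
    r = rec(beta=0.1, delta=0.2, se_beta=0.03, se_delta=0.04, corr=0.3)
    lo = derive_marginal(r, StudyDesign(n_total=10**8, n_exposed=1))
    unexp = derive_unexposed(r)
    assert lo.beta_hat == pytest.approx(unexp.beta_hat, abs=1e-8)
    assert lo.se_hat == pytest.approx(unexp.se_hat, abs=1e-8)
    hi = derive_marginal(r, StudyDesign(n_total=10**8, n_exposed=10**8 - 1))
    ex = derive_exposed(r)
    assert hi.beta_hat == pytest.approx(ex.beta_hat, abs=1e-8)
    assert hi.se_hat == pytest.approx(ex.se_hat, abs=1e-8)


@given(r=st.floats(-1, 1), s1=st.floats(0, 10), s2=st.floats(0, 10),
       mu=st.floats(0.01, 0.99))
def test_variances_are_completed_squares(r, s1, s2, mu):
    """For any correlation in [-1, 1] the exposed and marginal variance
    expressions are non-negative, so the SEs are always real."""
    c = cov_from_corr(r, s1, s2)
    assert s1**2 + s2**2 + 2 * c >= -1e-12
    assert s1**2 + mu**2 * s2**2 + 2 * mu * c >= -1e-12


# ---------------------------------------------------------------------------
# saturation identity against an independent least-squares oracle
# ---------------------------------------------------------------------------

def test_saturation_identity_against_statsmodels(rng):
    """Feeding the joint OLS fit through the converter reproduces the
    stratified OLS point estimates to machine precision, and the marginal
    conversion tracks the marginal OLS fit closely (linear trait, G and E
    independent)."""
    import statsmodels.api as sm

    n = 4000
    G = rng.binomial(2, 0.3, n).astype(float)
    E = (rng.random(n) < 0.4).astype(float)
    Y = 0.1 * G - 0.15 * E + 0.12 * G * E + rng.normal(0, 1, n)

    X = sm.add_constant(np.column_stack([G, E, G * E]))
    fit = sm.OLS(Y, X).fit()
    cov = fit.cov_params()
    r = JointRecord(variant_id="sim", beta=fit.params[1],
                    se_beta=fit.bse[1], delta=fit.params[3],
                    se_delta=fit.bse[3],
                    corr_beta_delta=cov[1, 3] / (fit.bse[1] * fit.bse[3]),
                    n_variant=n)
    design = StudyDesign(n_total=n, n_exposed=int(E.sum()))

    f0 = sm.OLS(Y[E == 0], sm.add_constant(G[E == 0])).fit()
    f1 = sm.OLS(Y[E == 1], sm.add_constant(G[E == 1])).fit()
    fm = sm.OLS(Y, sm.add_constant(np.column_stack([G, E]))).fit()

    d = derive_record(r, design)
    assert d.unexposed.beta_hat == pytest.approx(f0.params[1], rel=1e-12)
    assert d.exposed.beta_hat == pytest.approx(f1.params[1], rel=1e-12)
    # SEs differ only through pooled vs per-stratum residual variance
    assert d.unexposed.se_hat == pytest.approx(f0.bse[1], rel=0.05)
    assert d.exposed.se_hat == pytest.approx(f1.bse[1], rel=0.05)
    # marginal agreement is approximate (sampling-level, G independent of E)
    assert d.marginal.beta_hat == pytest.approx(fm.params[1], abs=0.02)


# ---------------------------------------------------------------------------
# stratum sample sizes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_v,N,Ne,expected", [
    (1000, 1000, 300, (700.0, 300.0)),
    (500, 1000, 300, (350.0, 150.0)),
    (999, 1000, 300, (699.3, 299.7)),
])
def test_infer_stratum_sizes_examples(n_v, N, Ne, expected):
    got = infer_stratum_sizes(n_v, StudyDesign(n_total=N, n_exposed=Ne))
    assert got == pytest.approx(expected, rel=1e-12)


@given(n_v=st.integers(1, 10**7), N=st.integers(2, 10**7),
       frac=st.floats(0, 1))
def test_stratum_sizes_conserve_exactly(n_v, N, frac):
    """Integer-valued per-variant sizes (the meta-analysis case) split into
    strata that sum back exactly; sizes are never negative."""
    Ne = int(frac * N)
    n0, n1 = infer_stratum_sizes(float(n_v),
                                 StudyDesign(n_total=N, n_exposed=Ne))
    assert n0 + n1 == n_v
    assert n0 >= 0 and n1 >= 0


@given(n_v=st.floats(1, 1e7), N=st.integers(2, 10**6), frac=st.floats(0, 1))
def test_stratum_sizes_conserve_for_fractional_sizes(n_v, N, frac):
    Ne = int(frac * N)
    n0, n1 = infer_stratum_sizes(n_v, StudyDesign(n_total=N, n_exposed=Ne))
    assert n0 + n1 == pytest.approx(n_v, rel=1e-14)
    assert n0 >= 0 and n1 >= 0


# ---------------------------------------------------------------------------
# relative-sample-size filter
# ---------------------------------------------------------------------------

def brute_force_threshold(sizes):
    """Independent linear-interpolation order-statistic 0.9-quantile."""
    xs = sorted(sizes)
    h = (len(xs) - 1) * 0.9
    lo = math.floor(h)
    frac = h - lo
    q = xs[lo] if frac == 0 else xs[lo] + (xs[lo + 1] - xs[lo]) * frac
    return q / 1.5


def test_filter_homogeneous_sizes_keeps_everything():
    records = [rec(variant_id=f"rs{i}", n=100) for i in range(20)]
    assert not any(r.filtered for r in filter_low_sample_size(records))


def test_filter_flags_single_low_coverage_variant():
    records = [rec(variant_id=f"rs{i}", n=1000) for i in range(150)]
    records.append(rec(variant_id="low", n=500))
    flagged = [r.variant_id for r in filter_low_sample_size(records)
               if r.filtered]
    assert flagged == ["low"]


def test_filter_matches_order_statistic_oracle():
    sizes = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
    records = [rec(variant_id=f"rs{i}", n=s) for i, s in enumerate(sizes)]
    thr = brute_force_threshold(sizes)
    assert sample_size_threshold(sizes) == pytest.approx(thr)
    got = {r.variant_id for r in filter_low_sample_size(records) if r.filtered}
    want = {f"rs{i}" for i, s in enumerate(sizes) if s < thr}
    assert got == want


def test_filter_empty_input_rejected():
    with pytest.raises(ValidationError):
        filter_low_sample_size([])


@given(st.lists(st.integers(10, 10_000), min_size=2, max_size=40),
       st.integers(10_001, 50_000))
def test_filter_monotonicity(sizes, big):
    """Adding a record above the current maximum never un-filters a record
    that was already retained, and only rows below the oracle threshold are
    ever flagged."""
    records = [rec(variant_id=f"rs{i}", n=s) for i, s in enumerate(sizes)]
    before = {r.variant_id for r in filter_low_sample_size(records)
              if r.filtered}
    after_records = filter_low_sample_size(
        records + [rec(variant_id="big", n=big)])
    after = {r.variant_id for r in after_records if r.filtered}
    assert before <= after
    thr = brute_force_threshold(sizes + [big])
    assert after == {r.variant_id for r in after_records
                     if r.n_variant < thr}


# ---------------------------------------------------------------------------
# vectorized frame path agrees with the scalar path
# ---------------------------------------------------------------------------

def test_derive_frame_matches_scalar_derivations(rng):
    import pandas as pd
    n = 40
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)],
        "beta": rng.normal(0, 0.1, n),
        "se_beta": rng.uniform(0.01, 0.1, n),
        "delta": rng.normal(0, 0.1, n),
        "se_delta": rng.uniform(0.01, 0.1, n),
        "corr_beta_delta": rng.uniform(-0.9, 0.9, n),
        "cov_beta_delta": np.nan,
        "n_variant": rng.integers(500, 1500, n).astype(float),
        "filtered": False,
    })
    design = StudyDesign(n_total=1500, n_exposed=600)
    out = derive_frame(df, design)
    for i in rng.choice(n, 8, replace=False):
        row = df.iloc[i]
        d = derive_record(JointRecord(
            variant_id=row.variant_id, beta=row.beta, se_beta=row.se_beta,
            delta=row.delta, se_delta=row.se_delta,
            corr_beta_delta=row.corr_beta_delta,
            n_variant=row.n_variant), design)
        o = out.iloc[i]
        assert o.beta_exp == pytest.approx(d.exposed.beta_hat, rel=1e-12)
        assert o.se_exp == pytest.approx(d.exposed.se_hat, rel=1e-12)
        assert o.beta_marg == pytest.approx(d.marginal.beta_hat, rel=1e-12)
        assert o.se_marg == pytest.approx(d.marginal.se_hat, rel=1e-12)
        assert o.z_unexp == pytest.approx(d.unexposed.z, rel=1e-12)
        assert o.p_marg == pytest.approx(d.marginal.p, rel=1e-12)
        assert o.n_unexp + o.n_exp == o.n_marg
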