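"""Domain records for joint-model input rows and derived stratified output.

A *joint model* here is the generalized linear model

    g(E[Y | G, E]) = alpha + beta*G + gamma*E + delta*G*E

fitted genome-wide with a binary exposure E; meta-analysis tools emit, per
variant, the genetic main effect ``beta``, the interaction effect ``delta``,
their standard errors, the correlation between the two estimates, and a
per-variant sample size. These records carry that row, the study design
(total and exposed sample sizes), and the derived per-stratum statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping


class JointStratError(Exception):
    """Base class for all package errors."""


class ValidationError(JointStratError):
    """Input data violates a field-level invariant (bad row or file)."""


class ConfigurationError(JointStratError):
    """Run configuration is unusable (bad design, missing column, ...)."""


class ComputationError(JointStratError):
    """A derivation or model fit cannot be carried out on these values."""


def _is_missing(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class JointRecord:
    """One variant's summary statistics from the joint interaction model.

    ``corr_beta_delta`` is the correlation between the main-effect and
    interaction estimates; alternatively ``cov_beta_delta`` may be supplied
    directly (some meta-analysis outputs carry a covariance column instead).
    Missing values (NaN) are tolerated — derived statistics become missing —
    but finite out-of-range values are rejected at construction.
    """

    variant_id: str
    beta: float
    se_beta: float
    delta: float
    se_delta: float
    n_variant: float
    corr_beta_delta: float = math.nan
    cov_beta_delta: float = math.nan
    extras: Mapping[str, object] = field(default_factory=dict)
    filtered: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.n_variant, (int, float))
                and math.isfinite(self.n_variant) and self.n_variant > 0):
            raise ValidationError(
                f"variant {self.variant_id!r}: sample size must be a finite "
                f"positive number, got {self.n_variant!r}")
        for name in ("se_beta", "se_delta"):
            v = getattr(self, name)
            if not _is_missing(v) and v < 0:
                raise ValidationError(
                    f"variant {self.variant_id!r}: {name} must be >= 0, got {v}")
        r = self.corr_beta_delta
        if not _is_missing(r) and not -1.0 <= r <= 1.0:
            raise ValidationError(
                f"variant {self.variant_id!r}: correlation between effect "
                f"estimates must lie in [-1, 1], got {r}")

    @property
    def covariance(self) -> float:
        """cov(beta_hat, delta_hat): explicit column if given, else r*s1*s2."""
        if not _is_missing(self.cov_beta_delta):
            return self.cov_beta_delta
        if _is_missing(self.corr_beta_delta):
            return math.nan
        return self.corr_beta_delta * self.se_beta * self.se_delta

    @property
    def is_complete(self) -> bool:
        """True when every field needed for derivation is present."""
        return not any(_is_missing(v) for v in (
            self.beta, self.se_beta, self.delta, self.se_delta,
            self.covariance))


@dataclass(frozen=True)
class StudyDesign:
    """Total study size N and number of exposed individuals N_e.

    The exposure frequency mu_e = N_e / N is what the marginal derivation
    needs; stratum sample sizes are inferred proportionally from it.
    """

    n_total: int
    n_exposed: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError(f"n_total must be > 0, got {self.n_total}")
        if not 0 <= self.n_exposed <= self.n_total:
            raise ConfigurationError(
                f"n_exposed must lie in [0, n_total], got "
                f"{self.n_exposed} with n_total={self.n_total}")

    @property
    def mu_e(self) -> float:
        """Exposure frequency N_e / N."""
        return self.n_exposed / self.n_total

    def require_two_strata(self) -> None:
        if not 0 < self.mu_e < 1:
            raise ConfigurationError(
                f"degenerate design: mu_e={self.mu_e} leaves one exposure "
                "stratum empty; marginal and exposed derivations need "
                "0 < N_e < N")


@dataclass(frozen=True)
class StratumStats:
    """Genetic effect estimate within one stratum (or marginally)."""

    beta_hat: float
    se_hat: float
    n_stratum: float
    z: float
    p: float


@dataclass(frozen=True)
class DerivedRecord:
    """One variant's derived unexposed / exposed / marginal statistics."""

    variant_id: str
    unexposed: StratumStats
    exposed: StratumStats
    marginal: StratumStats
    filtered: bool = False
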