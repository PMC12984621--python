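"""Strand-aware beta-binomial error-corrected NGS variant caller.

Deep targeted sequencing of low-burden samples is limited by the per-site,
per-strand error floor of the library chemistry.  The caller models that
floor with a beta-binomial background fitted per site and strand from
reference (variant-negative) samples, and treats an observation as a variant
only when the supporting read counts on *both* strands are individually
inconsistent with the background (a tail probability below 1 %) and at least
three unique alternative observations (distinct consensus read families,
UAO) support it.

Reads are classified binarily as supporting / not supporting a variant, so
substitutions, insertions and phased variants are handled identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EcngsSite",
    "StrandBackground",
    "SiteBackground",
    "fit_strand_background",
    "fit_background",
    "posterior_error",
    "call_variant",
    "sensitivity_probe",
]

MU_FLOOR = 1e-6
RHO_FLOOR = 1e-9


@dataclass
class EcngsSite:
    """Per-strand read support for one variant in one sample."""

    variant: str
    fwd_supporting: int
    fwd_total: int
    rev_supporting: int
    rev_total: int
    uao: int
    posterior: float | None = None
    called: bool | None = None

    def __post_init__(self) -> None:
        if self.fwd_supporting > self.fwd_total or self.rev_supporting > self.rev_total:
            raise ValueError("supporting reads exceed total reads")
        if self.uao > self.fwd_supporting + self.rev_supporting:
            raise ValueError("UAO exceeds total supporting reads")


@dataclass
class StrandBackground:
    """Beta-binomial error model for one strand: mean error rate ``mu`` and
    overdispersion ``rho`` (intra-class correlation in (0, 1))."""

    mu: float
    rho: float

    def __post_init__(self) -> None:
        if not 0 < self.mu < 1:
            raise ValueError("mu must lie in (0, 1)")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class SiteBackground:
    fwd: StrandBackground
    rev: StrandBackground


def fit_strand_background(
    supporting: np.ndarray,
    totals: np.ndarray,
    trim: float = 0.0,
    mu_floor: float = MU_FLOOR,
) -> StrandBackground:
    """Method-of-moments beta-binomial fit from reference samples.

    ``trim`` cuts that fraction of the highest and lowest per-sample error
    fractions before estimating the mean, so a single contaminated reference
    inflates the dispersion estimate rather than the mean.  The mean is
    floored (default 1e-6) so an all-zero reference panel still yields a
    usable, maximally strict model.
    """
    k = np.asarray(supporting, dtype=float)
    n = np.asarray(totals, dtype=float)
    if k.size < 3:
        raise ValueError("need >= 3 reference samples per site")
    if np.any(n <= 0):
        raise ValueError("totals must be positive")
    p = k / n
    mu = float(stats.trim_mean(p, trim)) if trim > 0 else float(p.mean())
    mu = max(mu, mu_floor)
    mu = min(mu, 1.0 - mu_floor)
    # Var(p_i) = mu(1-mu) * [rho + (1-rho) * E(1/n)] under the beta-binomial
    s2 = float(p.var(ddof=1))
    m1 = float(np.mean(1.0 / n))
    denom = 1.0 - m1
    rho = (s2 / (mu * (1.0 - mu)) - m1) / denom if denom > 0 else 0.0
    rho = float(np.clip(rho, RHO_FLOOR, 0.99))
    return StrandBackground(mu=mu, rho=rho)


def fit_background(
    fwd_supporting: np.ndarray,
    fwd_totals: np.ndarray,
    rev_supporting: np.ndarray,
    rev_totals: np.ndarray,
    trim: float = 0.0,
) -> SiteBackground:
    """Fit both strands of one site from reference samples."""
    return SiteBackground(
        fwd=fit_strand_background(fwd_supporting, fwd_totals, trim=trim),
        rev=fit_strand_background(rev_supporting, rev_totals, trim=trim),
    )


def _tail_probability(k: int, n: int, model: StrandBackground) -> float:
    """P(X >= k) for X ~ BetaBinomial(n, mu, rho); 1 when k == 0.

    ``betabinom.sf`` is computed as 1 - cdf and loses all precision below
    ~1e-10, so deep tails are summed directly from the log-gamma form of the
    pmf, stopping once terms no longer contribute.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if model.rho <= 1e-8:
        return float(stats.binom.sf(k - 1, n, model.mu))
    a = model.mu * (1.0 - model.rho) / model.rho
    b = (1.0 - model.mu) * (1.0 - model.rho) / model.rho
    p = float(stats.betabinom.sf(k - 1, n, a, b))
    if p > 1e-6:
        return p
    # deep tail: pmf is decreasing here (k is far above the mean), so the
    # series can be truncated once terms stop contributing
    const = (
        math.lgamma(n + 1)
        + math.lgamma(a + b)
        - math.lgamma(n + a + b)
        - math.lgamma(a)
        - math.lgamma(b)
    )
    total = 0.0
    for x in range(k, n + 1):
        term = math.exp(
            const
            - math.lgamma(x + 1)
            - math.lgamma(n - x + 1)
            + math.lgamma(x + a)
            + math.lgamma(n - x + b)
        )
        total += term
        if term == 0.0 or term < total * 1e-17:
            break
    return total


def posterior_error(site: EcngsSite, model: SiteBackground) -> float:
    """Probability that counts at least this supportive arise from background.

    Strand-aware AND: each strand is scored against its own background and
    the *larger* (less significant) of the two tail probabilities is
    returned, so a site supported on only one strand can never be called.
    """
    fwd = _tail_probability(site.fwd_supporting, site.fwd_total, model.fwd)
    rev = _tail_probability(site.rev_supporting, site.rev_total, model.rev)
    return max(fwd, rev)


def call_variant(
    site: EcngsSite,
    model: SiteBackground,
    uao_min: int = 3,
    threshold: float = 0.01,
) -> EcngsSite:
    """Call a site when the posterior error probability is below ``threshold``
    and the unique-alternative-observation count reaches ``uao_min``."""
    post = posterior_error(site, model)
    site.posterior = post
    site.called = bool(post < threshold and site.uao >= uao_min)
    return site


def sensitivity_probe(
    fwd_total: int,
    rev_total: int,
    model: SiteBackground,
    uao_min: int = 3,
    threshold: float = 0.01,
) -> int | None:
    """Minimal total supporting reads needed for a call at fixed depth.

    Supporting reads are distributed over the strands proportionally to the
    strand depths (totals held constant) and the caller is scanned upward in
    k; each supporting read counts as one consensus family, so UAO = k.
    Returns ``None`` when no k up to the full depth yields a call.
    """
    total = fwd_total + rev_total
    if total <= 0:
        raise ValueError("totals must be positive")
    for k in range(0, total + 1):
        k_fwd = (k * fwd_total) // total
        k_rev = k - k_fwd
        if k_rev > rev_total or k_fwd > fwd_total:
            continue
        site = EcngsSite(
            variant="probe",
            fwd_supporting=k_fwd,
            fwd_total=fwd_total,
            rev_supporting=k_rev,
            rev_total=rev_total,
            uao=k,
        )
        if call_variant(site, model, uao_min=uao_min, threshold=threshold).called:
            return k
    return None
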