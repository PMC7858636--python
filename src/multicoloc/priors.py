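"""Causal-configuration priors.

Two schemes are supported for the prior odds of a causal configuration
against the null configuration (no causal variant for any trait):

* ``variant_level`` — a per-variant prior built from two interpretable
  parameters: ``p``, the probability that a variant is causal for one trait,
  and ``pc``, the conditional colocalization prior, i.e. the probability
  that a variant is causal for a second trait given it is causal for one.
  Writing ``gamma = 1 - pc``, the probability that one variant is causal
  for a specific set of k traits is

      p_{12...k} = p * prod_{i=2..k} (1 - gamma^(i-1)),

  so 1 - gamma^2 is the chance of being causal for a third trait given two,
  and so on. A configuration's prior odds is the product of one such factor
  per distinct causal variant (divided by the null per-variant mass p0).

* ``conditionally_uniform`` — every configuration within a hypothesis class
  gets equal prior odds 1/|S_H|, where the class size counts Q choices for
  a single shared variant and, for multi-group hypotheses, the number of
  ways to pick the trait partition times ordered distinct variants.

For two traits the variant-level scheme reduces to the familiar pairwise
parameterisation {p1 = p2 = p, p12 = p*pc}; the conditional prior relates
to the pairwise colocalization prior via pc = p12 / (p12 + p1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriorSpec",
    "pc_from_p12",
    "p12_from_pc",
    "variant_prior",
    "log_variant_prior",
    "uniform_class_size",
    "log_config_prior_odds",
    "config_prior_odds",
    "variant_prior_total_mass",
]

_SCHEMES = ("variant_level", "conditionally_uniform")
_P0_POLICIES = ("unit", "normalized")


def pc_from_p12(p12: float, p1: float) -> float:
    """Conditional colocalization prior implied by pairwise priors:
    pc = p12 / (p12 + p1)."""
    if not (p12 > 0 and p1 > 0 and p12 + p1 < 1):
        raise ValueError("need p12 > 0, p1 > 0 and p12 + p1 < 1")
    return p12 / (p12 + p1)


def p12_from_pc(pc: float, p1: float) -> float:
    """Inverse of :func:`pc_from_p12`: p12 = p1 * pc / (1 - pc)."""
    if not (0 < pc < 1 and 0 < p1 < 1):
        raise ValueError("pc and p1 must lie in (0, 1)")
    return p1 * pc / (1.0 - pc)


@dataclass(frozen=True)
class PriorSpec:
    """Configuration-prior parameters.

    Parameters
    ----------
    scheme:
        ``"variant_level"`` (default) or ``"conditionally_uniform"``.
    p:
        Probability a variant is causal for one trait (default 1e-4).
    pc:
        Conditional colocalization prior (default 0.02). Ignored by the
        conditionally-uniform scheme.
    p0_policy:
        ``"unit"`` treats the null per-variant mass p0 as 1 in prior odds
        (the correction is <0.01% at default parameters); ``"normalized"``
        computes p0 exactly from the per-variant partition for a given m.
    """

    scheme: str = "variant_level"
    p: float = 1e-4
    pc: float = 0.02
    p0_policy: str = "unit"

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown prior scheme {self.scheme!r}")
        if self.p0_policy not in _P0_POLICIES:
            raise ValueError(f"unknown p0 policy {self.p0_policy!r}")
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie in (0, 1)")
        if not (0.0 < self.pc < 1.0):
            raise ValueError("pc must lie in (0, 1)")

    @classmethod
    def from_p12(cls, p12: float, p: float = 1e-4, **kwargs) -> "PriorSpec":
        """Build a spec from the pairwise colocalization prior p12."""
        return cls(p=p, pc=pc_from_p12(p12, p), **kwargs)

    @property
    def gamma(self) -> float:
        return 1.0 - self.pc

    @property
    def p12(self) -> float:
        """Pairwise p12 implied by (p, pc) via the conditional relation."""
        return p12_from_pc(self.pc, self.p)

    def validate_for(self, m: int) -> None:
        """Check the per-variant probability partition is proper for m traits.

        Only the ``normalized`` p0 policy needs the Eq.-style per-variant
        partition to have mass below one (so that p0 = 1 - mass exists). The
        default ``unit`` policy uses the factors as prior *odds* against the
        null and stays well defined for any m — at default parameters the
        binomial growth of trait subsets pushes the nominal partition mass
        past one around m = 82, which is why odds form is the default.
        """
        if self.scheme != "variant_level" or self.p0_policy != "normalized":
            return
        if variant_prior_total_mass(m, self) > 1.0:
            raise ValueError(
                f"variant-level prior mass exceeds 1 for m={m} with p={self.p}, "
                f"pc={self.pc}; use p0_policy='unit'"
            )


def log_variant_prior(k: int, spec: PriorSpec) -> float:
    """log of p_{12...k} = p * prod_{i=2..k}(1 - gamma^(i-1)); k=1 gives log p."""
    if k < 1:
        raise ValueError("k must be >= 1")
    gamma = spec.gamma
    out = math.log(spec.p)
    for i in range(2, k + 1):
        out += math.log1p(-(gamma ** (i - 1)))
    return out


def variant_prior(k: int, spec: PriorSpec) -> float:
    """Prior probability that one variant is causal for a specific set of k traits."""
    return math.exp(log_variant_prior(k, spec))


def variant_prior_total_mass(m: int, spec: PriorSpec) -> float:
    """Total per-variant causal mass 1 - p0 for m traits:
    sum_k C(m, k) * p_{12...k} (log-space accumulation)."""
    logs = [
        math.log(math.comb(m, k)) + log_variant_prior(k, spec) for k in range(1, m + 1)
    ]
    mx = max(logs)
    return math.exp(mx) * sum(math.exp(v - mx) for v in logs)


def _log_p0(m: int, spec: PriorSpec) -> float:
    if spec.p0_policy == "unit":
        return 0.0
    mass = variant_prior_total_mass(m, spec)
    if mass >= 1.0:
        raise ValueError("per-variant prior mass >= 1; cannot normalize p0")
    return math.log1p(-mass)


def uniform_class_size(sizes: tuple[int, ...], m: int, Q: int) -> int:
    """Configuration count |S_H| used by the conditionally-uniform scheme.

    ``sizes`` lists the colocalized-group sizes of the hypothesis shape
    (traits not covered are null). A single shared-variant group of any size
    has Q configurations. Multi-group shapes are counted at the level of the
    hypothesis set: the number of ways to partition the m traits into groups
    of those sizes, times ordered assignments of distinct variants, e.g.
    Q(Q-1) for two traits with distinct variants and m*Q*(Q-1) for the
    (m-1,1) shape with m > 2.
    """
    sizes = tuple(s for s in sizes if s > 0)
    if any(s < 1 for s in sizes) or sum(sizes) > m:
        raise ValueError("invalid hypothesis shape")
    g = len(sizes)
    if g == 0:
        return 1
    if g == 1:
        return Q
    # trait-partition multiplicity: multinomial over group sizes and nulls,
    # divided by permutations of equal-sized groups
    mult = math.factorial(m)
    for s in sizes:
        mult //= math.factorial(s)
    mult //= math.factorial(m - sum(sizes))
    for c in {s: sizes.count(s) for s in sizes}.values():
        mult //= math.factorial(c)
    falling = 1
    for i in range(g):
        falling *= Q - i
    return mult * falling


def log_config_prior_odds(
    sizes: tuple[int, ...], m: int, Q: int, spec: PriorSpec
) -> float:
    """Log prior odds p(S)/p(S0) for one configuration whose distinct causal
    variants cover trait groups of the given sizes.

    Variant-level scheme: sum over groups of log(p_{12...k}) - log(p0).
    Conditionally-uniform scheme: -log |S_H| for the configuration's class.
    """
    sizes = tuple(s for s in sizes if s > 0)
    if sum(sizes) > m:
        raise ValueError("group sizes exceed trait count")
    if not sizes:
        return 0.0
    if spec.scheme == "variant_level":
        lp0 = _log_p0(m, spec)
        return sum(log_variant_prior(k, spec) - lp0 for k in sizes)
    return -math.log(uniform_class_size(sizes, m, Q))


def config_prior_odds(
    hypothesis_class: str, k: int, m: int, Q: int, spec: PriorSpec
) -> float:
    """Per-configuration prior odds against the null for the named class.

    ``"H0"`` — no causal variants; ``"Hk"`` — k traits share one causal
    variant, the rest are null; ``"H_m1_1"`` — m-1 traits share a variant
    and the remaining trait has a distinct one (k is ignored).
    """
    if hypothesis_class == "H0":
        return 1.0
    if hypothesis_class == "Hk":
        return math.exp(log_config_prior_odds((k,), m, Q, spec))
    if hypothesis_class == "H_m1_1":
        return math.exp(log_config_prior_odds((m - 1, 1), m, Q, spec))
    raise ValueError(f"unsupported hypothesis class {hypothesis_class!r}")
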