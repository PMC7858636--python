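"""Posterior engine: regional and alignment probabilities, the fast
full-colocalization approximation, per-SNP fine-mapping shares, and the
exhaustive-enumeration oracle.

The full-colocalization posterior over all (Q+1)^m causal configurations is
approximated by the product of two cheap probabilities:

* the regional association probability ``P_R`` — the posterior share of the
  full-colocalization class within the restricted hypothesis space
  {null, one trait null + the rest sharing a variant, all sharing}, costing
  O(mQ) configurations, and
* the alignment probability ``P_A`` — the full-colocalization class against
  the classes where m-1 traits share a variant and the remaining trait is
  causal at a *different* variant, costing O(mQ^2) configurations.

``PPFC_hat = P_R * P_A`` approximates the exhaustive posterior with error of
order delta_A^2 + delta_R*delta_A (delta = 1 - probability), so it is tight
exactly in the regime where colocalization would be declared. The exhaustive
enumerator in this module is the oracle used to validate the approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .bayes import CorrelationModel, joint_log_abf, log_abf_matrix
from .priors import PriorSpec, log_config_prior_odds
from .utils import logsumexp_excluding

__all__ = [
    "Configuration",
    "PosteriorBreakdown",
    "ExhaustiveResult",
    "regional_probability",
    "alignment_probability",
    "ppfc",
    "refined_regional",
    "exhaustive_posterior",
    "full_hypothesis",
]


@dataclass(frozen=True)
class Configuration:
    """Causal-variant assignment: per trait, a 0-based SNP index or None
    (no causal variant). At most one causal SNP per trait."""

    assignment: tuple

    @property
    def m(self) -> int:
        return len(self.assignment)

    def snp_labels(self, region) -> tuple:
        return tuple(
            None if j is None else region.snp_ids[j] for j in self.assignment
        )


@dataclass
class PosteriorBreakdown:
    """Decomposed colocalization posterior for one trait cluster.

    ``snp_share[j]`` is the proportion of the full-colocalization posterior
    carried by SNP j (sums to one); ``ppe`` is the share of the top SNP —
    the per-SNP fine-mapping score.
    """

    p_r: float
    p_a: float
    ppfc: float
    regional_branch_evidence: np.ndarray
    alignment_branch_evidence: np.ndarray
    snp_share: np.ndarray
    best_config: Configuration

    @property
    def top_snp_index(self) -> int:
        return int(np.argmax(self.snp_share))

    @property
    def ppe(self) -> float:
        return float(self.snp_share[self.top_snp_index])


def _check_region(region) -> None:
    if region.m < 2:
        raise ValueError("colocalization requires at least two traits")


def _trait_w(region) -> np.ndarray:
    return np.asarray([t.prior_sd for t in region.traits], dtype=float)


class _ClassTerms:
    """Per-class log(BF x prior-odds) terms relative to the null config.

    Computes, lazily, the arrays the posterior quantities are assembled
    from. With no correlation model the per-trait Wakefield log-ABF matrix
    factorizes every class; with a correlation model each configuration's
    data term is a product over same-SNP trait groups of joint ABFs on the
    group sub-blocks (groups at distinct SNPs are independent: the
    overlap-induced covariance of estimates at unlinked SNPs is
    negligible, and modelling it as the full trait-level correlation would
    manufacture evidence from discordant far-apart estimates).
    """

    def __init__(self, region, priors: PriorSpec, corr: CorrelationModel | None):
        _check_region(region)
        priors.validate_for(region.m)
        self.region = region
        self.priors = priors
        self.corr = corr
        m, Q = region.m, region.Q
        self.lp_full = log_config_prior_odds((m,), m, Q, priors)
        self.lp_drop1 = log_config_prior_odds((m - 1,), m, Q, priors)
        self.lp_align = log_config_prior_odds((m - 1, 1), m, Q, priors)
        if corr is None:
            self.L = log_abf_matrix(region)
            self.colsum = self.L.sum(axis=0)
        else:
            if corr.m != m:
                raise ValueError("correlation model size must equal the trait count")
            self.L = None
        self._full = None
        self._drop1 = None

    # -- full colocalization class -------------------------------------
    @property
    def log_full_terms(self) -> np.ndarray:
        """(Q,) log terms for the configurations where all traits share SNP j."""
        if self._full is None:
            if self.corr is None:
                self._full = self.colsum + self.lp_full
            else:
                r, w = self.region, _trait_w(self.region)
                self._full = np.array(
                    [
                        joint_log_abf(r.beta[:, j], r.se[:, j], self.corr, w)
                        for j in range(r.Q)
                    ]
                ) + self.lp_full
        return self._full

    @property
    def log_full_mass(self) -> float:
        return float(logsumexp(self.log_full_terms))

    # -- drop-one-trait-null class -------------------------------------
    @property
    def log_drop1_terms(self) -> np.ndarray:
        """(m, Q) log terms: row i has trait i null, the others share SNP j."""
        if self._drop1 is None:
            if self.corr is None:
                self._drop1 = (self.colsum[None, :] - self.L) + self.lp_drop1
            else:
                r, w = self.region, _trait_w(self.region)
                m = r.m
                out = np.empty((m, r.Q))
                for i in range(m):
                    keep = [t for t in range(m) if t != i]
                    sub = self.corr.subset(keep)
                    for j in range(r.Q):
                        out[i, j] = joint_log_abf(
                            r.beta[keep, j], r.se[keep, j], sub, w[keep]
                        )
                self._drop1 = out + self.lp_drop1
        return self._drop1

    # -- drop-one-trait-elsewhere (alignment) class --------------------
    def alignment_branches(self) -> tuple[np.ndarray, float, list]:
        """Branch log-masses (m,), the class log-mass, and per-branch argmax
        assignments [(logterm, j, k), ...].

        For m = 2 the two branches enumerate the same ordered SNP pairs, so
        the class mass is a single branch's mass, matching the Q(Q-1) count;
        for m > 2 the branches are disjoint and the class is their union.

        With a correlation model the data term factorizes over same-SNP
        groups: the shared group's joint ABF (already in the drop-one terms)
        plus the displaced trait's single-trait Wakefield ABF.
        """
        r = self.region
        m, Q = r.m, r.Q
        if Q < 2:
            return np.full(m, -np.inf), -np.inf, []
        branch = np.empty(m)
        best = []
        single = self.L if self.corr is None else self._single_L()
        drop1_logbf = self.log_drop1_terms - self.lp_drop1
        for i in range(m):
            r_i = logsumexp_excluding(single[i])
            terms = drop1_logbf[i] + r_i + self.lp_align
            branch[i] = logsumexp(terms)
            # argmax over (j, k != j) via the top-2 SNPs of trait i
            order = np.argsort(single[i])
            k1, k2 = int(order[-1]), int(order[-2])
            kbest = np.where(np.arange(Q) == k1, k2, k1)
            pt = drop1_logbf[i] + single[i, kbest] + self.lp_align
            jb = int(np.argmax(pt))
            best.append((float(pt[jb]), jb, int(kbest[jb])))
        class_mass = branch[0] if m == 2 else float(logsumexp(branch))
        return branch, float(class_mass), best

    def _single_L(self) -> np.ndarray:
        if getattr(self, "_L_single", None) is None:
            self._L_single = log_abf_matrix(self.region)
        return self._L_single


def regional_probability(region, priors: PriorSpec, corr: CorrelationModel | None = None):
    """Regional association probability P_R and per-branch evidence.

    P_R is the posterior share of the full-colocalization class within the
    single-shared-variant space {H0, drop-one-trait-null, full}; branch
    evidence i is the posterior mass of the class that excludes trait i.
    """
    terms = _ClassTerms(region, priors, corr)
    return _regional_from_terms(terms)


def _regional_from_terms(terms: _ClassTerms):
    drop1 = terms.log_drop1_terms
    branch_mass = logsumexp(drop1, axis=1)
    log_scv = float(logsumexp(np.concatenate(([0.0], branch_mass, [terms.log_full_mass]))))
    p_r = math.exp(terms.log_full_mass - log_scv)
    evidence = np.exp(branch_mass - log_scv)
    return p_r, evidence


def alignment_probability(region, priors: PriorSpec, corr: CorrelationModel | None = None):
    """Alignment probability P_A and per-branch evidence.

    P_A weighs the full-colocalization class against the configurations in
    which m-1 traits share a SNP and the remaining trait is causal at a
    different SNP. With a single SNP no competing class exists and P_A = 1.
    """
    terms = _ClassTerms(region, priors, corr)
    return _alignment_from_terms(terms)


def _alignment_from_terms(terms: _ClassTerms):
    m = terms.region.m
    if terms.region.Q < 2:
        return 1.0, np.zeros(m)
    branch, class_mass, _ = terms.alignment_branches()
    denom = float(logsumexp([terms.log_full_mass, class_mass]))
    p_a = math.exp(terms.log_full_mass - denom)
    evidence = np.exp(branch - denom)
    return p_a, evidence


def ppfc(region, priors: PriorSpec, corr: CorrelationModel | None = None) -> PosteriorBreakdown:
    """Full posterior breakdown: P_R, P_A, their product, per-SNP shares of
    the colocalization posterior, branch evidence, and the single best
    configuration among the enumerated classes (ties broken toward the
    lowest SNP index)."""
    terms = _ClassTerms(region, priors, corr)
    p_r, reg_ev = _regional_from_terms(terms)
    m, Q = region.m, region.Q

    full_terms = terms.log_full_terms
    snp_share = softmax(full_terms)

    if Q >= 2:
        branch, class_mass, align_best = terms.alignment_branches()
        denom = float(logsumexp([terms.log_full_mass, class_mass]))
        p_a = math.exp(terms.log_full_mass - denom)
        align_ev = np.exp(branch - denom)
    else:
        p_a, align_ev, align_best = 1.0, np.zeros(m), []

    # best configuration across the enumerated classes
    best_val = 0.0  # null configuration
    best_assign = tuple([None] * m)
    jf = int(np.argmax(full_terms))
    if full_terms[jf] > best_val:
        best_val = float(full_terms[jf])
        best_assign = tuple([jf] * m)
    drop1 = terms.log_drop1_terms
    for i in range(m):
        j = int(np.argmax(drop1[i]))
        if drop1[i, j] > best_val:
            best_val = float(drop1[i, j])
            best_assign = tuple(None if t == i else j for t in range(m))
    for i, (val, j, k) in enumerate(align_best):
        if val > best_val:
            best_val = val
            best_assign = tuple(k if t == i else j for t in range(m))

    return PosteriorBreakdown(
        p_r=p_r,
        p_a=p_a,
        ppfc=p_r * p_a,
        regional_branch_evidence=reg_ev,
        alignment_branch_evidence=align_ev,
        snp_share=snp_share,
        best_config=Configuration(best_assign),
    )


def refined_regional(region, priors: PriorSpec, corr: CorrelationModel | None = None) -> float:
    """Refined regional probability: P_R recomputed with the classes where
    two traits are null added to the denominator (O(m^2 Q) configurations).
    A diagnostic for the quality of P_R; for m = 2 it equals P_R since no
    new class exists."""
    terms = _ClassTerms(region, priors, corr)
    m, Q = region.m, region.Q
    drop1_mass = logsumexp(terms.log_drop1_terms, axis=1)
    pieces = [np.array([0.0]), drop1_mass, np.array([terms.log_full_mass])]
    if m >= 3:
        lp2 = log_config_prior_odds((m - 2,), m, Q, priors)
        pair_mass = []
        if terms.corr is None:
            for i1, i2 in itertools.combinations(range(m), 2):
                t = terms.colsum - terms.L[i1] - terms.L[i2] + lp2
                pair_mass.append(logsumexp(t))
        else:
            w = _trait_w(region)
            for i1, i2 in itertools.combinations(range(m), 2):
                keep = [t for t in range(m) if t not in (i1, i2)]
                sub = terms.corr.subset(keep)
                t = np.array(
                    [
                        joint_log_abf(region.beta[keep, j], region.se[keep, j], sub, w[keep])
                        for j in range(Q)
                    ]
                ) + lp2
                pair_mass.append(logsumexp(t))
        pieces.append(np.asarray(pair_mass))
    denom = float(logsumexp(np.concatenate(pieces)))
    return math.exp(terms.log_full_mass - denom)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def full_hypothesis(m: int) -> frozenset:
    """Hypothesis key for 'all m traits share one causal variant'."""
    return frozenset({frozenset(range(m))})


@dataclass
class ExhaustiveResult:
    """Posterior over every hypothesis, from complete enumeration.

    ``posterior`` maps a hypothesis — a frozenset of frozensets, each inner
    set being one group of traits sharing a causal variant (traits in no
    group have none; the empty set is the global null) — to its posterior
    probability. ``snp_share`` decomposes the full-colocalization class by
    SNP with the same numerator terms as the fast path.
    """

    posterior: dict
    snp_share: np.ndarray
    log_evidence: float

    @property
    def total(self) -> float:
        return float(sum(self.posterior.values()))

    def hypothesis_class(self, sizes: tuple[int, ...]) -> float:
        """Total posterior of all hypotheses whose group-size multiset
        (ignoring which traits) equals ``sizes``."""
        want = tuple(sorted(sizes, reverse=True))
        out = 0.0
        for key, val in self.posterior.items():
            got = tuple(sorted((len(g) for g in key), reverse=True))
            if got == want:
                out += val
        return out


def _decode_partition(code: int, m: int) -> tuple:
    """Invert the leader-digit code into (hypothesis key, group sizes)."""
    groups: dict[int, list[int]] = {}
    for i in range(m):
        digit = code % (m + 1)
        code //= m + 1
        if digit > 0:
            groups.setdefault(digit - 1, []).append(i)
    key = frozenset(frozenset(v) for v in groups.values())
    sizes = tuple(len(v) for v in groups.values())
    return key, sizes


def exhaustive_posterior(
    region,
    priors: PriorSpec,
    corr: CorrelationModel | None = None,
    budget: float = 1e8,
) -> ExhaustiveResult:
    """Enumerate every causal configuration, group by hypothesis, normalize.

    Intended for m <= 4 as the oracle for the fast approximation. The
    correlated-study path evaluates a joint ABF per configuration and is
    restricted to small regions (budget 2e5 configurations).
    """
    _check_region(region)
    priors.validate_for(region.m)
    m, Q = region.m, region.Q
    n_cfg = (Q + 1) ** m
    if corr is not None:
        if n_cfg > 2e5:
            raise ValueError("exhaustive enumeration with correlation limited to (Q+1)^m <= 2e5")
        return _exhaustive_corr(region, priors, corr)
    if n_cfg > budget:
        raise ValueError(f"(Q+1)^m = {n_cfg:.3g} exceeds the enumeration budget {budget:.3g}")

    L = log_abf_matrix(region)
    lpad = np.concatenate([np.zeros((m, 1)), L], axis=1)
    idx = np.arange(n_cfg, dtype=np.int64)
    S = np.empty((m, n_cfg), dtype=np.int32)
    logbf = np.zeros(n_cfg)
    for i in range(m):
        S[i] = (idx // (Q + 1) ** (m - 1 - i)) % (Q + 1)
        logbf += lpad[i][S[i]]

    # partition code: digit i is 0 when trait i is inactive, else 1 + the
    # smallest trait index assigned the same SNP (the group leader)
    code = np.zeros(n_cfg, dtype=np.int64)
    for i in range(m):
        active = S[i] > 0
        gi = np.where(active, i + 1, 0).astype(np.int64)
        for jj in range(i - 1, -1, -1):
            gi = np.where(active & (S[jj] == S[i]), jj + 1, gi)
        code += gi * (m + 1) ** i
    del idx

    codes, inverse = np.unique(code, return_inverse=True)
    keys = []
    lprior = np.empty(len(codes))
    for c_i, c in enumerate(codes):
        key, sizes = _decode_partition(int(c), m)
        keys.append(key)
        lprior[c_i] = log_config_prior_odds(sizes, m, Q, priors)

    logpost = logbf + lprior[inverse]
    mx = float(logpost.max())
    wgt = np.exp(logpost - mx)
    z = float(wgt.sum())
    mass = np.bincount(inverse, weights=wgt, minlength=len(codes))
    posterior = {key: float(v / z) for key, v in zip(keys, mass)}

    lp_full = log_config_prior_odds((m,), m, Q, priors)
    snp_share = softmax(L.sum(axis=0) + lp_full)
    return ExhaustiveResult(
        posterior=posterior, snp_share=snp_share, log_evidence=mx + math.log(z)
    )


def _exhaustive_corr(region, priors, corr) -> ExhaustiveResult:
    m, Q = region.m, region.Q
    w = _trait_w(region)
    acc: dict[frozenset, list] = {}
    full_terms = np.full(Q, -np.inf)
    for assign in itertools.product(range(Q + 1), repeat=m):
        active = [i for i in range(m) if assign[i] > 0]
        if not active:
            key, logterm = frozenset(), 0.0
        else:
            groups: dict[int, list[int]] = {}
            for i in active:
                groups.setdefault(assign[i] - 1, []).append(i)
            key = frozenset(frozenset(v) for v in groups.values())
            sizes = tuple(len(v) for v in groups.values())
            # joint ABF per same-SNP trait group; groups at distinct SNPs
            # are treated as independent blocks
            logterm = log_config_prior_odds(sizes, m, Q, priors)
            for snp, members in groups.items():
                logterm += joint_log_abf(
                    region.beta[members, snp], region.se[members, snp],
                    corr.subset(members), w[members],
                )
            if len(active) == m and len(groups) == 1:
                j = assign[0] - 1
                full_terms[j] = logterm
        acc.setdefault(key, []).append(logterm)
    key_mass = {k: float(logsumexp(v)) for k, v in acc.items()}
    log_z = float(logsumexp(list(key_mass.values())))
    posterior = {k: math.exp(v - log_z) for k, v in key_mass.items()}
    return ExhaustiveResult(
        posterior=posterior, snp_share=softmax(full_terms), log_evidence=log_z
    )
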