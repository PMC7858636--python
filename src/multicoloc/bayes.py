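"""Log-scale (joint) approximate Bayes factors for SNP-trait associations.

The single-trait evidence unit is Wakefield's approximate Bayes factor for
a normal prior N(0, w^2) on the effect size, computed from the estimate's
Z-statistic ``z`` and standard error ``v``:

    ln ABF = 1/2 ln( v^2 / (v^2 + w^2) ) + (z^2 / 2) * w^2 / (v^2 + w^2).

For studies with overlapping participants the per-configuration evidence is
a joint ABF over the active traits with observed covariance
Sigma_bhat = V rho_hat V and prior covariance Sigma_b = W rho W, where
rho_hat is the correlation of the effect estimates across traits and rho the
prior trait correlation. Everything is accumulated in log space: Z-statistics
up to ~40 produce Bayes factors of order e^800, far beyond double range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import check_correlation, nearest_psd

__all__ = [
    "CorrelationModel",
    "log_abf",
    "log_abf_matrix",
    "config_log_abf",
    "joint_log_abf",
    "estimate_rho_hat",
]


@dataclass(frozen=True)
class CorrelationModel:
    """Observed (rho_hat) and prior (rho) trait-trait correlation matrices.

    ``rho_hat`` is the correlation of the effect estimates induced by
    participant overlap; ``rho_prior`` is the prior correlation of the true
    effects and defaults to ``rho_hat``.
    """

    rho_hat: np.ndarray
    rho_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rho_hat", check_correlation(self.rho_hat, "rho_hat")
        )
        rp = self.rho_hat if self.rho_prior is None else check_correlation(
            np.asarray(self.rho_prior, float), "rho_prior"
        )
        object.__setattr__(self, "rho_prior", rp)

    @property
    def m(self) -> int:
        return self.rho_hat.shape[0]

    def subset(self, idx) -> "CorrelationModel":
        idx = np.asarray(idx)
        return CorrelationModel(
            self.rho_hat[np.ix_(idx, idx)], self.rho_prior[np.ix_(idx, idx)]
        )


def log_abf(z, v, w):
    """ln of Wakefield's approximate Bayes factor (vectorized).

    Parameters: ``z`` Z-statistic, ``v`` standard error (> 0), ``w`` prior
    SD of the effect (>= 0; w = 0 is the point-mass prior, ln ABF = 0).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
        raise ValueError("log_abf requires finite inputs")
    if np.any(v <= 0) or np.any(w < 0):
        raise ValueError("need v > 0 and w >= 0")
    shrink = w * w / (v * v + w * w)
    return 0.5 * np.log1p(-shrink) + 0.5 * z * z * shrink


def log_abf_matrix(region) -> np.ndarray:
    """m x Q matrix of per-trait, per-SNP ln ABF values for a region."""
    w = np.asarray([t.prior_sd for t in region.traits], dtype=float)
    return log_abf(region.z, region.se, w[:, None])


def config_log_abf(region, assignment) -> float:
    """ln Bayes factor of a causal configuration under independent studies.

    ``assignment`` gives, per trait, either ``None`` (no causal variant,
    contributing BF 1) or a 0-based SNP index; the configuration BF is the
    product of the per-trait Wakefield ABFs at the assigned SNPs.
    """
    L = log_abf_matrix(region)
    total = 0.0
    for i, j in enumerate(assignment):
        if j is None or j < 0:
            continue
        if j >= region.Q:
            raise IndexError(f"SNP index {j} out of range for Q={region.Q}")
        total += L[i, j]
    return float(total)


def joint_log_abf(beta_vec, se_vec, corr: CorrelationModel, w_vec) -> float:
    """ln of the joint ABF for a vector of effect estimates across traits.

    Sigma_bhat = V rho_hat V, Sigma_b = W rho W with V = diag(se) and
    W = diag(w). Returns

        1/2 ln(|Sigma_bhat| / |Sigma_bhat + Sigma_b|)
        + 1/2 bhat^T (Sigma_bhat + Sigma_b)^-1 Sigma_b Sigma_bhat^-1 bhat.

    With identity correlations this factorizes into the sum of the
    per-trait Wakefield log-ABFs; with one trait it reduces to ``log_abf``.
    """
    b = np.atleast_1d(np.asarray(beta_vec, dtype=float))
    v = np.atleast_1d(np.asarray(se_vec, dtype=float))
    w = np.atleast_1d(np.asarray(w_vec, dtype=float))
    k = b.shape[0]
    if corr.m != k:
        raise ValueError(
            f"correlation model is {corr.m}x{corr.m} but the trait vector has "
            f"length {k}; use CorrelationModel.subset for sub-configurations"
        )
    rho_hat = corr.rho_hat
    rho = corr.rho_prior
    sig_obs = rho_hat * np.outer(v, v)
    sig_pri = rho * np.outer(w, w)
    sign_o, logdet_o = np.linalg.slogdet(sig_obs)
    sign_s, logdet_s = np.linalg.slogdet(sig_obs + sig_pri)
    if sign_o <= 0:
        raise np.linalg.LinAlgError("observed covariance is singular")
    u = np.linalg.solve(sig_obs, b)
    r = np.linalg.solve(sig_obs + sig_pri, sig_pri @ u)
    return float(0.5 * (logdet_o - logdet_s) + 0.5 * b @ r)


def estimate_rho_hat(
    null_z_panel: np.ndarray, z_cut: float = 2.0, min_snps: int = 50
) -> np.ndarray:
    """Estimate the effect-estimate correlation from null-SNP Z-statistics.

    Keeps panel columns where every trait has |z| below ``z_cut`` and takes
    the empirical correlation across those SNPs (asymptotically the overlap-
    induced correlation for continuous traits), projected to the nearest PSD
    correlation matrix.
    """
    panel = np.asarray(null_z_panel, dtype=float)
    if panel.ndim != 2:
        raise ValueError("expected an m x K panel of z-scores")
    keep = np.all(np.abs(panel) < z_cut, axis=0)
    panel = panel[:, keep]
    if panel.shape[1] < min_snps:
        raise ValueError(
            f"only {panel.shape[1]} null SNPs below |z| < {z_cut}; need >= {min_snps}"
        )
    sd = panel.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant z-score rows cannot be correlated")
    est = np.corrcoef(panel)
    return nearest_psd(est)
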