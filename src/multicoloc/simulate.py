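"""Synthetic multi-trait GWAS regions with known causal structure.

Two generation paths produce regional summary statistics for m traits over
Q SNPs with LD matrix R:

* direct (default): marginal Z-statistics are drawn from a matrix normal —
  row covariance the cross-trait null correlation induced by participant
  overlap, column covariance R — around non-centralities
  ncp_j = sum_c r(j, c) * sqrt(n * v_c / (1 - v_c)) aggregated over that
  trait's causal variants c with variance-explained fractions v_c;
  standard errors are back-filled from the sample size and allele
  frequency as se = 1 / sqrt(n * 2 f (1 - f)).
* individual: genotype dosages are simulated per study (Gaussian dosages
  matching the target LD exactly, or a thresholded Gaussian-copula variant
  with discrete 0/1/2 dosages), a phenotype y = sum_c beta_c g_c + eps is
  built with beta_c calibrated so each causal variant explains its stated
  variance fraction, and per-SNP OLS regressions are summarized.

Every region is emitted together with its ground truth (causal variants and
the planted trait partition). Pairwise classification metrics for comparing
an inferred clustering against the planted partition live here too.
"""

from __future__ import annotations

import functools
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .clustering import AlgorithmConfig, ClusterResult, bb_cluster
from .priors import PriorSpec
from .region import RegionData, TraitMeta
from .utils import nearest_psd

__all__ = [
    "SimScenario",
    "SimTruth",
    "ClassificationCounts",
    "simulate_ld",
    "simulate_region",
    "load_haplotypes_vcf",
    "classification_metrics",
    "run_scenario_battery",
    "summarize_battery",
    "builtin_scenario",
    "load_scenario_file",
    "SAMPLE_SIZE_SET",
]

SAMPLE_SIZE_SET = (1000, 5000, 10000, 15000, 20000)


def simulate_ld(
    model: str = "ar1",
    Q: int | None = None,
    rho: float = 0.95,
    block_size: int = 25,
    haplotypes: np.ndarray | None = None,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Build a Q x Q SNP correlation matrix.

    ``ar1``: r(j, k) = rho^|j-k| (distance-decaying LD, the desk-scale
    stand-in for resampled reference-panel regions). ``block``: constant
    within-block correlation ``rho`` in blocks of ``block_size``.
    ``haplotype_resample``: empirical correlation of a user-supplied phased
    0/1 haplotype panel (haplotypes x SNPs) after dropping variants with
    MAF below ``maf_min``; repaired to PSD if needed.
    """
    if model == "ar1":
        if Q is None:
            raise ValueError("Q is required for the ar1 model")
        d = np.abs(np.subtract.outer(np.arange(Q), np.arange(Q)))
        return rho ** d
    if model == "block":
        if Q is None:
            raise ValueError("Q is required for the block model")
        R = np.eye(Q)
        for start in range(0, Q, block_size):
            stop = min(start + block_size, Q)
            R[start:stop, start:stop] = rho
        np.fill_diagonal(R, 1.0)
        return nearest_psd(R)
    if model == "haplotype_resample":
        if haplotypes is None:
            raise ValueError("haplotype panel is required")
        H = np.asarray(haplotypes, dtype=float)
        freq = H.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        H = H[:, maf >= maf_min]
        if H.shape[1] < 2:
            raise ValueError("fewer than two SNPs survive the MAF filter")
        return nearest_psd(np.corrcoef(H.T))
    raise ValueError(f"unknown LD model {model!r}")


@functools.lru_cache(maxsize=8)
def _ar1_chol(rho: float, Q: int) -> np.ndarray:
    return np.linalg.cholesky(simulate_ld("ar1", Q, rho=rho) + 1e-10 * np.eye(Q))


def load_haplotypes_vcf(path) -> np.ndarray:
    """Read a phased VCF into a 0/1 haplotype panel (haplotypes x SNPs)
    for the ``haplotype_resample`` LD model. Multiallelic sites and
    missing genotypes are rejected."""
    from cyvcf2 import VCF

    columns = []
    for variant in VCF(str(path)):
        if len(variant.ALT) != 1:
            raise ValueError(f"multiallelic site at {variant.POS}")
        gt = np.asarray(variant.genotypes)[:, :2]
        if np.any(gt < 0):
            raise ValueError(f"missing genotype at {variant.POS}")
        columns.append(gt.reshape(-1))
    if not columns:
        raise ValueError("no variants in VCF")
    return np.asarray(columns).T


@dataclass(frozen=True)
class SimScenario:
    """Declarative description of one synthetic region.

    ``clusters`` lists trait groups sharing a causal variant (0-based trait
    indices; traits in no group have no causal variant). ``secondary`` maps
    a trait index to the variance fraction of an extra, distinct causal
    variant, used to violate the single-causal-variant assumption.
    ``sample_sizes`` may be one integer for all traits, a per-trait tuple,
    or None to draw each study's n from ``sample_size_set`` (mirroring
    mixed-cohort analyses). Participant overlap is expressed as the shared
    fraction of the smaller study and a phenotype correlation, inducing
    null-SNP z correlation n_ov * r / sqrt(n_i * n_j).
    """

    m: int
    Q: int = 500
    clusters: tuple = ()
    causal_snps: tuple | None = None
    variance_explained: float = 0.01
    secondary: tuple = ()  # pairs (trait_index, variance_fraction)
    sample_sizes: int | tuple | None = None
    sample_size_set: tuple = SAMPLE_SIZE_SET
    overlap_fraction: float = 0.0
    pheno_corr: float = 0.0
    ld_model: str = "ar1"
    ld_rho: float = 0.95
    maf_min: float = 0.05
    maf_max: float = 0.5
    method: str = "direct"
    genotypes: str = "gaussian"  # individual path: gaussian | copula
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for group in self.clusters:
            for t in group:
                if t in seen:
                    raise ValueError("trait appears in two clusters")
                if not 0 <= t < self.m:
                    raise ValueError("cluster trait index out of range")
                seen.add(t)
        for t, v in self.secondary:
            if not 0.0 < v <= 0.05:
                raise ValueError("variance fractions must lie in (0, 0.05]")
        if not 0.0 < self.variance_explained <= 0.05:
            raise ValueError("variance fractions must lie in (0, 0.05]")

    @classmethod
    def from_dict(cls, data: dict) -> "SimScenario":
        data = dict(data)
        for key in ("clusters",):
            if key in data:
                data[key] = tuple(tuple(g) for g in data[key])
        if "secondary" in data:
            data["secondary"] = tuple(
                (int(t), float(v)) for t, v in
                (data["secondary"].items() if isinstance(data["secondary"], dict)
                 else data["secondary"])
            )
        for key in ("causal_snps", "sample_sizes", "sample_size_set"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth emitted with every synthetic region."""

    causal: dict  # trait index -> tuple of causal SNP indices (primary first)
    partition: list  # list of sets: the planted colocalization clusters
    ld: np.ndarray
    mafs: np.ndarray
    sample_sizes: np.ndarray

    def partition_sets(self) -> list:
        return [set(g) for g in self.partition]


def _resolve_sample_sizes(scn: SimScenario, rng) -> np.ndarray:
    if scn.sample_sizes is None:
        return rng.choice(scn.sample_size_set, size=scn.m)
    if np.isscalar(scn.sample_sizes):
        return np.full(scn.m, int(scn.sample_sizes))
    sizes = np.asarray(scn.sample_sizes, dtype=int)
    if sizes.shape != (scn.m,):
        raise ValueError("sample_sizes must be scalar or per-trait")
    return sizes


def _overlap_corr(scn: SimScenario, n: np.ndarray) -> np.ndarray:
    C = np.eye(scn.m)
    if scn.overlap_fraction and scn.pheno_corr:
        for i, j in itertools.combinations(range(scn.m), 2):
            n_ov = scn.overlap_fraction * min(n[i], n[j])
            C[i, j] = C[j, i] = n_ov * scn.pheno_corr / math.sqrt(n[i] * n[j])
        C = nearest_psd(C)
    return C


def _assign_causals(scn: SimScenario, rng) -> dict:
    """Draw causal SNPs: one shared variant per cluster (distinct across
    clusters; LD between them is whatever the LD model gives) plus distinct
    per-trait secondary variants where requested."""
    n_primary = len(scn.clusters)
    n_secondary = len(scn.secondary)
    if scn.causal_snps is not None:
        primaries = list(scn.causal_snps)
        if len(primaries) != n_primary:
            raise ValueError("causal_snps must list one SNP per cluster")
        pool = [j for j in range(scn.Q) if j not in primaries]
        extras = list(rng.choice(pool, size=n_secondary, replace=False)) if n_secondary else []
    else:
        draw = rng.choice(scn.Q, size=n_primary + n_secondary, replace=False)
        primaries = list(draw[:n_primary])
        extras = list(draw[n_primary:])
    causal: dict[int, list] = {t: [] for t in range(scn.m)}
    for group, snp in zip(scn.clusters, primaries):
        for t in group:
            causal[t].append((int(snp), scn.variance_explained))
    for (t, v), snp in zip(scn.secondary, extras):
        causal[t].append((int(snp), float(v)))
    return causal


def simulate_region(scn: SimScenario, rng=None) -> tuple[RegionData, SimTruth]:
    """Generate one synthetic region plus its ground truth.

    Fully seeded: the same scenario and seed reproduce the region
    bit-for-bit. Pass an existing ``numpy.random.Generator`` to draw from a
    caller-managed stream instead of ``scn.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(scn.seed)
    m, Q = scn.m, scn.Q
    if scn.ld_model == "ar1":
        R = simulate_ld("ar1", Q, rho=scn.ld_rho)
        chol = _ar1_chol(scn.ld_rho, Q)
    else:
        R = simulate_ld(scn.ld_model, Q, rho=scn.ld_rho)
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(Q))
    mafs = rng.uniform(scn.maf_min, scn.maf_max, size=Q)
    n = _resolve_sample_sizes(scn, rng)
    causal = _assign_causals(scn, rng)

    if scn.method == "direct":
        beta, se = _direct_path(scn, rng, R, chol, mafs, n, causal)
    elif scn.method == "individual":
        if scn.overlap_fraction:
            raise ValueError("participant overlap is supported on the direct path only")
        beta, se = _individual_path(scn, rng, chol, mafs, n, causal)
    else:
        raise ValueError(f"unknown generation method {scn.method!r}")

    traits = [
        TraitMeta(name=f"trait_{i+1}", sample_size=int(n[i])) for i in range(m)
    ]
    region = RegionData(
        snp_ids=[f"snp_{j+1}" for j in range(Q)], beta=beta, se=se,
        traits=traits, ld=R,
    )
    truth = SimTruth(
        causal={t: tuple(s for s, _ in v) for t, v in causal.items() if v},
        partition=[set(g) for g in scn.clusters],
        ld=R,
        mafs=mafs,
        sample_sizes=n,
    )
    return region, truth


def _direct_path(scn, rng, R, chol, mafs, n, causal):
    m, Q = scn.m, scn.Q
    ncp = np.zeros((m, Q))
    for t, variants in causal.items():
        for snp, vexp in variants:
            ncp[t] += R[:, snp] * math.sqrt(n[t] * vexp / (1 - vexp))
    C = _overlap_corr(scn, n)
    row_chol = np.linalg.cholesky(C + 1e-12 * np.eye(m))
    z = ncp + row_chol @ rng.standard_normal((m, Q)) @ chol.T
    se = 1.0 / np.sqrt(np.outer(n, 2 * mafs * (1 - mafs)))
    return z * se, se


def _individual_path(scn, rng, chol, mafs, n, causal):
    m, Q = scn.m, scn.Q
    beta = np.empty((m, Q))
    se = np.empty((m, Q))
    gvar = 2 * mafs * (1 - mafs)
    for t in range(m):
        ni = int(n[t])
        if scn.genotypes == "gaussian":
            X = 2 * mafs + np.sqrt(gvar) * (rng.standard_normal((ni, Q)) @ chol.T)
        elif scn.genotypes == "copula":
            thresh = norm.ppf(mafs)
            h1 = rng.standard_normal((ni, Q)) @ chol.T < thresh
            h2 = rng.standard_normal((ni, Q)) @ chol.T < thresh
            X = (h1 + h2).astype(float)
        else:
            raise ValueError(f"unknown genotype model {scn.genotypes!r}")
        variants = causal.get(t, [])
        total_vexp = sum(v for _, v in variants)
        y = rng.standard_normal(ni) * math.sqrt(max(1.0 - total_vexp, 1e-12))
        for snp, vexp in variants:
            y = y + math.sqrt(vexp / gvar[snp]) * X[:, snp]
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sxx = (xc ** 2).sum(axis=0)
        sxy = xc.T @ yc
        bhat = sxy / sxx
        resid_ss = (yc ** 2).sum() - bhat * sxy
        sigma2 = resid_ss / (ni - 2)
        beta[t] = bhat
        se[t] = np.sqrt(sigma2 / sxx)
    return beta, se


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationCounts:
    """Pairwise confusion counts of an inferred trait clustering against a
    planted partition, aggregated over unordered trait pairs."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else float("nan")


def _pair_map(groups, universe) -> set:
    together = set()
    for g in groups:
        g = sorted(set(g) & universe)
        for a, b in itertools.combinations(g, 2):
            together.add((a, b))
    return together


def classification_metrics(
    truth_partition, inferred_clusters, traits=None
) -> ClassificationCounts:
    """Pairwise confusion counts: a pair is positive when both traits sit in
    the same cluster. ``traits`` restricts scoring to a subset (used when
    excluding traits whose clusters fall below the reporting threshold).
    Both partitions must be defined over the same trait universe; traits
    listed in neither group are singletons.
    """
    truth_groups = [set(g) for g in truth_partition]
    inferred_groups = [
        set(c.trait_indices) if isinstance(c, ClusterResult) else set(c)
        for c in inferred_clusters
    ]
    inferred_universe = set().union(*inferred_groups) if inferred_groups else set()
    if traits is None:
        universe = set().union(*truth_groups) if truth_groups else set()
        universe |= inferred_universe
    else:
        universe = set(traits)
        if not inferred_universe <= universe | set().union(*truth_groups, set()):
            raise ValueError("inferred clusters reference traits outside the truth set")
    truth_pairs = _pair_map(truth_groups, universe)
    inferred_pairs = _pair_map(inferred_groups, universe)
    tp = tn = fp = fn = 0
    for a, b in itertools.combinations(sorted(universe), 2):
        in_truth = (a, b) in truth_pairs
        in_inf = (a, b) in inferred_pairs
        tp += in_truth and in_inf
        fp += in_inf and not in_truth
        fn += in_truth and not in_inf
        tn += not in_truth and not in_inf
    return ClassificationCounts(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# scenario battery
# ---------------------------------------------------------------------------

_BUILTIN = {
    # single-causal-variant designs with 10 traits
    "i": dict(clusters=(tuple(range(10)),)),
    "ii": dict(clusters=((0, 1, 2), (3, 4, 5))),
    "iii": dict(clusters=((0, 1, 2), (3, 4, 5), (6, 7), (8, 9))),
    # violation designs: half of each cluster gains a secondary distinct
    # causal variant explaining ~0.75% or ~1% of trait variance
    "i_viol": dict(
        clusters=(tuple(range(10)),),
        secondary=((0, 0.0075), (1, 0.01), (2, 0.0075), (3, 0.01), (4, 0.0075)),
    ),
    "ii_viol": dict(
        clusters=((0, 1, 2, 3, 4, 5),),
        secondary=((0, 0.0075), (1, 0.01), (2, 0.0075)),
    ),
    "iii_viol": dict(
        clusters=((0, 1, 2, 3, 4, 5), (6, 7, 8, 9)),
        secondary=((0, 0.0075), (1, 0.01), (2, 0.0075), (6, 0.01), (7, 0.0075)),
    ),
}


def builtin_scenario(name: str, m: int = 10, Q: int = 500, **overrides) -> SimScenario:
    """Named study designs: 'i' one cluster of 10 colocalized traits; 'ii'
    two clusters of 3 with 4 null traits; 'iii' four clusters sized
    (3, 3, 2, 2); '*_viol' variants add secondary distinct causal variants
    to half of each cluster."""
    if name not in _BUILTIN:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_BUILTIN)}")
    spec = dict(_BUILTIN[name])
    spec.update(m=m, Q=Q)
    spec.update(overrides)
    return SimScenario(**spec)


def load_scenario_file(path) -> dict:
    """Read a YAML/JSON scenario file: a mapping of scenario name to either
    a builtin name plus overrides or a full scenario specification."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out = {}
    for name, spec in data.items():
        if isinstance(spec, str):
            out[name] = builtin_scenario(spec)
        elif "builtin" in spec:
            spec = dict(spec)
            base = spec.pop("builtin")
            out[name] = builtin_scenario(base, **spec)
        else:
            out[name] = SimScenario.from_dict(spec)
    return out


def run_scenario_battery(
    scenarios: dict,
    replicates: int,
    seed: int,
    pc_values=(0.05, 0.02, 0.01),
    p: float = 1e-4,
    config: AlgorithmConfig | None = None,
) -> pd.DataFrame:
    """Run the clustering pipeline over seeded replicates of each scenario
    and prior setting; returns one row per (scenario, pc, replicate,
    filtered) with pairwise classification metrics. ``filtered=True`` rows
    score only traits belonging to clusters whose PPFC clears the report
    threshold. One master seed spawns independent per-replicate streams.
    """
    config = config or AlgorithmConfig()
    rows = []
    root = np.random.SeedSequence(seed)
    for name, scn in scenarios.items():
        streams = root.spawn(replicates)
        for rep in range(replicates):
            rng = np.random.default_rng(streams[rep])
            region, truth = simulate_region(scn, rng=rng)
            for pc in pc_values:
                priors = PriorSpec(p=p, pc=pc)
                clusters, _ = bb_cluster(region, priors, config)
                all_sets = [set(c.trait_indices) for c in clusters]
                passing = [c for c in clusters if c.passes_report_threshold]
                kept_traits = set().union(*(set(c.trait_indices) for c in passing)) \
                    if passing else set()
                for filtered, sets, universe in (
                    (False, all_sets, set(range(scn.m))),
                    (True, [set(c.trait_indices) for c in passing], kept_traits),
                ):
                    if filtered and len(universe) < 2:
                        counts = ClassificationCounts(0, 0, 0, 0)
                    else:
                        counts = classification_metrics(
                            truth.partition_sets(), sets, traits=universe
                        )
                    rows.append(
                        dict(
                            scenario=name, pc=pc, replicate=rep, filtered=filtered,
                            tp=counts.tp, tn=counts.tn, fp=counts.fp, fn=counts.fn,
                            accuracy=counts.accuracy, tpr=counts.tpr, fpr=counts.fpr,
                            n_clusters=len(sets),
                            n_passing=len(passing),
                        )
                    )
    return pd.DataFrame(rows)


def summarize_battery(results: pd.DataFrame) -> pd.DataFrame:
    """1st-decile / median / 9th-decile summaries of the battery metrics per
    (scenario, pc, filtered), ignoring undefined (NaN) replicate metrics."""
    def dec(series, q):
        s = series.dropna()
        return float(np.quantile(s, q)) if len(s) else float("nan")

    rows = []
    for (name, pc, filt), grp in results.groupby(["scenario", "pc", "filtered"]):
        row = dict(scenario=name, pc=pc, filtered=filt, replicates=len(grp))
        for metric in ("accuracy", "tpr", "fpr"):
            for label, q in (("d1", 0.1), ("median", 0.5), ("d9", 0.9)):
                row[f"{metric}_{label}"] = dec(grp[metric], q)
        rows.append(row)
    return pd.DataFrame(rows)
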