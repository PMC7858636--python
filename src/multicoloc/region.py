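"""Regional multi-trait summary-statistic data model and I/O.

A region is an m x Q panel of GWAS regression coefficients and standard
errors (log-odds scale for binary traits), one row per trait, over a shared
set of Q SNPs, with optional LD. SNPs are opaque labels: regions are
user-defined and no coordinate arithmetic is done here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import check_correlation

__all__ = [
    "TraitMeta",
    "RegionData",
    "load_region",
    "harmonize_alleles",
    "write_region",
    "read_region_bundle",
    "load_ld",
    "write_ld",
    "DEFAULT_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "snp": "snp",
    "beta": "beta",
    "se": "se",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_DEFAULT_PRIOR_SD = {"continuous": 0.15, "binary": 0.2}


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait metadata.

    ``prior_sd`` is the SD of the normal effect-size prior used by the
    Wakefield ABF; it defaults to 0.15 for continuous traits and 0.2 for
    binary traits (log-odds scale).
    """

    name: str
    trait_type: str = "continuous"
    prior_sd: float | None = None
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in _DEFAULT_PRIOR_SD:
            raise ValueError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        if self.prior_sd is None:
            object.__setattr__(self, "prior_sd", _DEFAULT_PRIOR_SD[self.trait_type])
        if not self.prior_sd > 0:
            raise ValueError("prior_sd must be positive")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValueError("sample_size must be positive")


@dataclass
class RegionData:
    """Harmonized m x Q panel of effect sizes and standard errors.

    ``trait_alleles`` (optional) carries per-trait (effect, other) allele
    arrays prior to harmonization; after :func:`harmonize_alleles` a single
    region-level orientation remains in ``effect_allele``/``other_allele``.
    """

    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    traits: list[TraitMeta]
    ld: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    trait_alleles: list[tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.snp_ids = [str(s) for s in self.snp_ids]
        m, q = self.beta.shape
        if self.se.shape != (m, q):
            raise ValueError("beta and se must have identical shape")
        if len(self.traits) != m:
            raise ValueError("trait metadata length must match beta rows")
        if len(self.snp_ids) != q:
            raise ValueError("snp_ids length must match beta columns")
        if len(set(self.snp_ids)) != q:
            raise ValueError("snp_ids must be unique")
        if q < 1:
            raise ValueError("a region needs at least one SNP")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta contains non-finite values")
        if not np.all(np.isfinite(self.se)) or np.any(self.se <= 0):
            raise ValueError("se must be finite and strictly positive")
        if self.ld is not None:
            self.ld = check_correlation(np.asarray(self.ld, float), "ld")
            if self.ld.shape[0] != q:
                raise ValueError("LD matrix size must match Q")

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    @property
    def Q(self) -> int:
        return self.beta.shape[1]

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def subset_traits(self, idx) -> "RegionData":
        """Region restricted to the given trait indices (SNPs unchanged)."""
        idx = list(idx)
        ta = None
        if self.trait_alleles is not None:
            ta = [self.trait_alleles[i] for i in idx]
        return RegionData(
            snp_ids=list(self.snp_ids),
            beta=self.beta[idx],
            se=self.se[idx],
            traits=[self.traits[i] for i in idx],
            ld=self.ld,
            effect_allele=self.effect_allele,
            other_allele=self.other_allele,
            trait_alleles=ta,
        )


def _read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [columns[c] for c in ("snp", "beta", "se") if columns[c] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_region(
    paths,
    trait_meta: list[TraitMeta] | None = None,
    columns: dict | None = None,
    ld_path=None,
) -> RegionData:
    """Read per-trait summary-statistic tables and align them on the SNP
    intersection, preserving the SNP order of the first trait.

    ``paths`` is a sequence of delimited-text paths (or a mapping of trait
    name to path). Each table needs (snp, beta, se) columns and may carry
    (effect_allele, other_allele); ``columns`` remaps header names so common
    GWAS export dialects load without preprocessing. A SNP missing in any
    trait is excluded: every trait must be observed at every configuration
    SNP.
    """
    columns = {**DEFAULT_COLUMNS, **(columns or {})}
    if isinstance(paths, dict):
        names = list(paths.keys())
        paths = list(paths.values())
    else:
        paths = list(paths)
        names = [Path(p).stem for p in paths]
    if trait_meta is None:
        trait_meta = [TraitMeta(name=n) for n in names]
    if len(trait_meta) != len(paths):
        raise ValueError("trait_meta length must match the number of tables")

    tables = []
    for path in paths:
        df = _read_table(path, columns)
        snp_col = columns["snp"]
        if df[snp_col].duplicated().any():
            raise ValueError(f"{path}: duplicate SNP identifiers")
        tables.append(df.set_index(df[snp_col].astype(str)))

    shared = set(tables[0].index)
    for df in tables[1:]:
        shared &= set(df.index)
    if not shared:
        raise ValueError("empty SNP intersection across traits")
    order = [s for s in tables[0].index if s in shared]

    beta = np.vstack([df.loc[order, columns["beta"]].to_numpy(float) for df in tables])
    se = np.vstack([df.loc[order, columns["se"]].to_numpy(float) for df in tables])

    have_alleles = all(
        columns["effect_allele"] in df.columns and columns["other_allele"] in df.columns
        for df in tables
    )
    trait_alleles = None
    ea = oa = None
    if have_alleles:
        trait_alleles = [
            (
                df.loc[order, columns["effect_allele"]].astype(str).str.upper().to_numpy(),
                df.loc[order, columns["other_allele"]].astype(str).str.upper().to_numpy(),
            )
            for df in tables
        ]
        ea, oa = trait_alleles[0]

    ld = None
    if ld_path is not None:
        ld = load_ld(ld_path, snp_ids=order)

    return RegionData(
        snp_ids=order,
        beta=beta,
        se=se,
        traits=list(trait_meta),
        ld=ld,
        effect_allele=ea,
        other_allele=oa,
        trait_alleles=trait_alleles,
    )


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    try:
        return _COMPLEMENT[ea], _COMPLEMENT[oa]
    except KeyError:
        raise ValueError(f"non-ACGT allele pair ({ea}, {oa})") from None


def harmonize_alleles(region: RegionData) -> RegionData:
    """Align every trait's effect alleles to the first trait's orientation.

    For SNPs where a trait reports the alleles swapped (directly or on the
    opposite strand), that trait's beta sign is flipped. Palindromic SNPs
    (A/T or C/G) whose observed orientation is consistent with both keeping
    and flipping are unresolvable and are dropped, with the count logged.
    Applying the function twice equals applying it once.
    """
    if region.trait_alleles is None:
        raise ValueError("allele columns are required for harmonization")
    ref_ea, ref_oa = region.trait_alleles[0]
    beta = region.beta.copy()
    q = region.Q
    drop = np.zeros(q, dtype=bool)
    for i, (ea, oa) in enumerate(region.trait_alleles):
        for j in range(q):
            pair = (ea[j], oa[j])
            ref = (ref_ea[j], ref_oa[j])
            ref_c = _complement_pair(*ref)
            palindromic = ref == ref_c[::-1]  # e.g. (A, T): swap == strand flip
            if pair in (ref, ref_c):
                if palindromic and pair != ref:
                    drop[j] = True
                continue
            if pair in (ref[::-1], ref_c[::-1]):
                if palindromic:
                    drop[j] = True
                else:
                    beta[i, j] = -beta[i, j]
                continue
            raise ValueError(
                f"trait {region.traits[i].name!r}, SNP {region.snp_ids[j]!r}: "
                f"alleles {pair} match neither orientation nor complement of {ref}"
            )
    if drop.any():
        logger.info("dropping %d strand-ambiguous SNP(s)", int(drop.sum()))
    keep = ~drop
    keep_idx = np.flatnonzero(keep)
    ld = region.ld[np.ix_(keep_idx, keep_idx)] if region.ld is not None else None
    aligned = [
        (ref_ea[keep].copy(), ref_oa[keep].copy()) for _ in region.trait_alleles
    ]
    return RegionData(
        snp_ids=[s for s, k in zip(region.snp_ids, keep) if k],
        beta=beta[:, keep],
        se=region.se[:, keep],
        traits=list(region.traits),
        ld=ld,
        effect_allele=ref_ea[keep].copy(),
        other_allele=ref_oa[keep].copy(),
        trait_alleles=aligned,
    )


def write_region(region: RegionData, prefix) -> tuple[Path, Path]:
    """Write the canonical region bundle: a long-format TSV of summary
    statistics plus a JSON sidecar of trait metadata and SNP order."""
    prefix = Path(prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    rows = []
    for i, t in enumerate(region.traits):
        for j, snp in enumerate(region.snp_ids):
            row = {
                "trait": t.name,
                "snp": snp,
                "beta": region.beta[i, j],
                "se": region.se[i, j],
            }
            if region.effect_allele is not None:
                row["effect_allele"] = region.effect_allele[j]
                row["other_allele"] = region.other_allele[j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "schema_version": 1,
        "snp_ids": list(region.snp_ids),
        "traits": [
            {
                "name": t.name,
                "trait_type": t.trait_type,
                "prior_sd": t.prior_sd,
                "sample_size": t.sample_size,
            }
            for t in region.traits
        ],
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return tsv_path, json_path


def read_region_bundle(tsv_path, ld_path=None) -> RegionData:
    """Read a region bundle written by :func:`write_region` (the JSON
    sidecar is looked up next to the TSV)."""
    tsv_path = Path(tsv_path)
    json_path = tsv_path.with_suffix(".json")
    df = pd.read_csv(
        tsv_path, sep="\t", dtype={"snp": str, "trait": str},
        float_precision="round_trip",
    )
    if json_path.exists():
        meta = json.loads(json_path.read_text())
        snp_ids = [str(s) for s in meta["snp_ids"]]
        traits = [
            TraitMeta(
                name=t["name"],
                trait_type=t.get("trait_type", "continuous"),
                prior_sd=t.get("prior_sd"),
                sample_size=t.get("sample_size"),
            )
            for t in meta["traits"]
        ]
    else:
        snp_ids = list(dict.fromkeys(df["snp"]))
        traits = [TraitMeta(name=n) for n in dict.fromkeys(df["trait"])]
    name_order = [t.name for t in traits]
    beta = np.empty((len(traits), len(snp_ids)))
    se = np.empty_like(beta)
    snp_pos = {s: j for j, s in enumerate(snp_ids)}
    for i, name in enumerate(name_order):
        sub = df[df["trait"] == name]
        idx = [snp_pos[s] for s in sub["snp"]]
        beta[i, idx] = sub["beta"].to_numpy(float)
        se[i, idx] = sub["se"].to_numpy(float)
    ea = oa = None
    if "effect_allele" in df.columns:
        first = df[df["trait"] == name_order[0]].set_index("snp")
        ea = first.loc[snp_ids, "effect_allele"].to_numpy(str)
        oa = first.loc[snp_ids, "other_allele"].to_numpy(str)
    ld = load_ld(ld_path, snp_ids=snp_ids) if ld_path is not None else None
    return RegionData(
        snp_ids=snp_ids, beta=beta, se=se, traits=traits, ld=ld,
        effect_allele=ea, other_allele=oa,
    )


def load_ld(path, snp_ids: list[str] | None = None) -> np.ndarray:
    """Read a whitespace-delimited Q x Q LD correlation matrix whose header
    row lists SNP identifiers; reordered to ``snp_ids`` when given."""
    df = pd.read_csv(path, sep=r"\s+")
    df.index = [str(c) for c in df.columns]
    if snp_ids is not None:
        missing = [s for s in snp_ids if s not in df.index]
        if missing:
            raise ValueError(f"LD matrix is missing SNPs: {missing[:5]}")
        df = df.loc[snp_ids, snp_ids]
    return check_correlation(df.to_numpy(float), "ld")


def write_ld(ld: np.ndarray, snp_ids: list[str], path) -> Path:
    path = Path(path)
    pd.DataFrame(ld, columns=snp_ids).to_csv(
        path, sep=" ", index=False, float_format="%.10g"
    )
    return path
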