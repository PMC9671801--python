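"""Synthetic two-cohort metabolomics-GWAS data with planted genetic architecture.

The generator emulates the data a plasma-metabolome GWAS consumes: LD-structured
hard-call genotype dosages across common to rare variants, log-normal metabolite
abundances with planted per-allele genetic effects at controlled variance
explained, covariate main effects, missing values, and binary disease phenotypes
(phecodes) drawn from a logistic liability model.  A :class:`TruthTable` records
the planted architecture so downstream stages can be scored against it.

Genotypes come from a thresholded latent Gaussian: per chromosome, haplotype
latents have correlation ``exp(-ld_decay * distance)`` and each is dichotomised
at the normal quantile of the target minor-allele frequency; the two haplotype
indicators sum to a {0, 1, 2} dosage.  This yields Hardy-Weinberg genotypes with
a tunable allele-frequency spectrum and monotone LD decay, which are the only
genotype properties the association stages consume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VariantSpec",
    "CausalEntry",
    "PlantedGim",
    "PhecodeEffect",
    "TruthTable",
    "CohortData",
    "StudyConfig",
    "SimulatedStudy",
    "beta_for_variance",
    "simulate_genotypes",
    "simulate_metabolites",
    "simulate_phecodes",
    "split_cohorts",
    "simulate_study",
]


# distinct per-operation RNG stream salts: reusing one seed across the
# generator's operations must never correlate their draws
_STREAM_GENOTYPES = 1
_STREAM_METABOLITES = 2
_STREAM_PHECODES = 3
_STREAM_SPLIT = 4


@dataclass(frozen=True)
class VariantSpec:
    """One biallelic variant with a target minor-allele frequency."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"
    maf_target: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_target <= 0.5:
            raise ValueError(
                f"maf_target must be in (0, 0.5], got {self.maf_target} "
                f"(monomorphic variants are unsupported)"
            )
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CausalEntry:
    """A planted variant -> metabolite effect.

    ``beta`` is the per-allele effect on the standardized (unit-variance latent)
    metabolite scale; ``variance_explained`` is the fraction of metabolite
    variance the variant is targeted to explain, i.e. ``beta**2 * var(dosage)``.
    """

    variant: str
    metabolite: str
    beta: float
    variance_explained: float


@dataclass(frozen=True)
class PlantedGim:
    region_id: str
    variants: tuple[str, ...]
    metabolites: tuple[str, ...]


@dataclass(frozen=True)
class PhecodeEffect:
    metabolite: str
    phecode: str
    log_odds: float  # per s.d. of metabolite liability


@dataclass
class TruthTable:
    """The planted simulation architecture, used as the recovery oracle."""

    causal_entries: list[CausalEntry] = field(default_factory=list)
    planted_gims: list[PlantedGim] = field(default_factory=list)
    phecode_effects: list[PhecodeEffect] = field(default_factory=list)

    def validate(self) -> None:
        for met, entries in self.entries_by_metabolite().items():
            total = sum(e.variance_explained for e in entries)
            if total >= 1.0:
                raise ValueError(
                    f"variance_explained targets for metabolite {met!r} "
                    f"sum to {total:.3f} >= 1"
                )

    def entries_by_metabolite(self) -> dict[str, list[CausalEntry]]:
        out: dict[str, list[CausalEntry]] = {}
        for e in self.causal_entries:
            out.setdefault(e.metabolite, []).append(e)
        return out

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.causal_entries:
            seen.setdefault(e.metabolite)
        return list(seen)

    @property
    def causal_variants(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.causal_entries:
            seen.setdefault(e.variant)
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "causal_entries": [vars(e).copy() for e in self.causal_entries],
            "planted_gims": [
                {"region_id": g.region_id, "variants": list(g.variants),
                 "metabolites": list(g.metabolites)}
                for g in self.planted_gims
            ],
            "phecode_effects": [vars(e).copy() for e in self.phecode_effects],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(
            causal_entries=[CausalEntry(**e) for e in d.get("causal_entries", [])],
            planted_gims=[
                PlantedGim(g["region_id"], tuple(g["variants"]), tuple(g["metabolites"]))
                for g in d.get("planted_gims", [])
            ],
            phecode_effects=[PhecodeEffect(**e) for e in d.get("phecode_effects", [])],
        )


@dataclass
class CohortData:
    """Aligned genotype, metabolite and covariate tables for one cohort."""

    dosages: pd.DataFrame
    metabolites: pd.DataFrame
    covariates: pd.DataFrame
    cohort_id: str
    phecodes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.dosages)
        if len(self.metabolites) != n or len(self.covariates) != n:
            raise ValueError("dosages, metabolites and covariates must share rows")
        if not (self.dosages.index.equals(self.metabolites.index)
                and self.dosages.index.equals(self.covariates.index)):
            raise ValueError("sample indices of the three tables must agree")
        if self.phecodes is not None and not self.dosages.index.equals(
                self.phecodes.index):
            raise ValueError("phecode table index must match the other tables")

    @property
    def n_samples(self) -> int:
        return len(self.dosages)


def beta_for_variance(variance_explained: float, maf: float) -> float:
    """Per-allele effect size achieving a variance-explained target.

    Under Hardy-Weinberg, ``var(dosage) = 2 * maf * (1 - maf)``, so an effect of
    ``beta`` s.d. per allele explains ``beta**2 * 2 * maf * (1 - maf)`` of a
    unit-variance trait.
    """
    if not 0.0 <= variance_explained < 1.0:
        raise ValueError("variance_explained must be in [0, 1)")
    return float(np.sqrt(variance_explained / (2.0 * maf * (1.0 - maf))))


def _check_sorted(variants: list[VariantSpec]) -> None:
    by_chrom: dict[str, int] = {}
    for v in variants:
        prev = by_chrom.get(v.chrom)
        if prev is not None and v.pos <= prev:
            raise ValueError(
                f"variants must be strictly increasing in position per "
                f"chromosome; {v.chrom}:{v.pos} follows {v.chrom}:{prev}"
            )
        by_chrom[v.chrom] = v.pos


def simulate_genotypes(
    variants: list[VariantSpec],
    n_samples: int,
    ld_decay: float = 1e-5,
    seed: int = 0,
) -> pd.DataFrame:
    """Hard-call dosages from a thresholded latent Gaussian.

    Parameters
    ----------
    variants : position-sorted variant specifications.
    n_samples : number of diploid individuals (>= 2).
    ld_decay : per-bp exponential decay rate of the latent haplotype
        correlation; 0 gives near-perfect LD within a chromosome.
    seed : RNG seed; output is a pure function of (inputs, seed).

    Returns
    -------
    DataFrame of shape (n_samples, n_variants) with values in {0, 1, 2},
    columns keyed by ``chrom:pos:ref:alt``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if ld_decay < 0:
        raise ValueError("ld_decay must be >= 0")
    _check_sorted(variants)
    rng = np.random.default_rng([seed, _STREAM_GENOTYPES])
    cols: dict[str, np.ndarray] = {}
    for chrom, group_iter in itertools.groupby(variants, key=lambda v: v.chrom):
        group = list(group_iter)
        pos = np.array([v.pos for v in group], dtype=float)
        corr = np.exp(-ld_decay * np.abs(pos[:, None] - pos[None, :]))
        # jitter keeps the Cholesky stable when variants are (nearly) duplicated
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(group)))
        thresh = stats.norm.ppf([v.maf_target for v in group])
        dosage = np.zeros((n_samples, len(group)), dtype=np.int8)
        for _hap in range(2):
            latent = rng.standard_normal((n_samples, len(group))) @ chol.T
            dosage += (latent < thresh).astype(np.int8)
        for j, v in enumerate(group):
            cols[v.vid] = dosage[:, j]
    return pd.DataFrame(cols, index=pd.RangeIndex(n_samples, name="sample"))


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric columns standardized, categoricals dummy-coded (drop-first)."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            sd = s.std(ddof=1)
            parts.append(((s - s.mean()) / sd if sd > 0 else s * 0.0).rename(col))
        else:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=covariates.index)


def simulate_metabolites(
    dosages: pd.DataFrame,
    truth: TruthTable,
    covariates: pd.DataFrame | None = None,
    noise_sd: float | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    metabolites: list[str] | None = None,
    covariate_effect: float = 0.2,
    missing_fn=None,
) -> pd.DataFrame:
    """Raw-scale metabolite abundances with planted per-allele genetic effects.

    On the standardized latent scale each causal variant contributes its
    ``beta`` per allele; when ``noise_sd`` is None the residual s.d. is chosen
    per metabolite so the latent has unit variance, making the realized genetic
    R^2 match the planted variance-explained targets.  The latent is
    exponentiated to a positive, log-normal abundance scale (median ~1, as for
    median-scaled platform data).  Entries are then set missing completely at
    random at ``missing_rate``; passing ``missing_fn(latent_df, rng)`` instead
    installs an arbitrary (e.g. MAR) missingness mask.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    truth.validate()
    rng = np.random.default_rng([seed, _STREAM_METABOLITES])
    names = list(metabolites) if metabolites is not None else truth.metabolites
    by_met = truth.entries_by_metabolite()
    cov_design = _covariate_design(covariates) if covariates is not None else None

    out = {}
    for met in names:
        entries = by_met.get(met, [])
        genetic = np.zeros(len(dosages))
        explained = 0.0
        for e in entries:
            if e.variant not in dosages.columns:
                raise KeyError(f"causal variant {e.variant!r} missing from dosages")
            g = dosages[e.variant].to_numpy(dtype=float)
            genetic += e.beta * g
            explained += e.beta**2 * g.var(ddof=0)
        if noise_sd is None:
            if explained >= 1.0:
                raise ValueError(
                    f"planted effects for {met!r} already exceed unit variance"
                )
            sd = float(np.sqrt(1.0 - explained))
        else:
            sd = float(noise_sd)
        latent = genetic - genetic.mean() + rng.normal(0.0, sd, size=len(dosages))
        if cov_design is not None and cov_design.shape[1]:
            latent = latent + cov_design.to_numpy() @ np.full(
                cov_design.shape[1], covariate_effect
            )
        out[met] = np.exp(latent)
    df = pd.DataFrame(out, index=dosages.index)
    if missing_fn is not None:
        mask = np.asarray(missing_fn(df, rng), dtype=bool)
        df = df.mask(mask)
    elif missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return df


def simulate_phecodes(
    metabolite_liabilities: pd.DataFrame,
    truth: TruthTable,
    baseline_prevalence: float = 0.1,
    seed: int = 0,
    phecodes: list[str] | None = None,
) -> pd.DataFrame:
    """Binary phecodes from a logistic liability model.

    For each phecode, the linear predictor sums the planted log-odds per s.d.
    of each contributing metabolite liability (columns of
    ``metabolite_liabilities`` are standardized internally); the intercept is
    calibrated numerically so the expected prevalence equals
    ``baseline_prevalence``.
    """
    if not 0.0 < baseline_prevalence < 1.0:
        raise ValueError("baseline_prevalence must be in (0, 1)")
    rng = np.random.default_rng([seed, _STREAM_PHECODES])
    by_code: dict[str, list[PhecodeEffect]] = {}
    for e in truth.phecode_effects:
        by_code.setdefault(e.phecode, []).append(e)
    names = list(phecodes) if phecodes is not None else list(by_code)

    liab = metabolite_liabilities
    z = (liab - liab.mean()) / liab.std(ddof=1).replace(0.0, 1.0)
    z = z.fillna(0.0)

    out = {}
    for code in names:
        eta = np.zeros(len(liab))
        for e in by_code.get(code, []):
            if e.metabolite not in z.columns:
                raise KeyError(f"metabolite {e.metabolite!r} absent from liabilities")
            eta += e.log_odds * z[e.metabolite].to_numpy()

        def mean_prev(c: float, eta=eta) -> float:
            return float(np.mean(stats.logistic.cdf(c + eta))) - baseline_prevalence

        intercept = optimize.brentq(mean_prev, -30.0, 30.0)
        p = stats.logistic.cdf(intercept + eta)
        out[code] = (rng.random(len(liab)) < p).astype(np.int8)
    return pd.DataFrame(out, index=liab.index)


def split_cohorts(
    dosages: pd.DataFrame,
    metabolites: pd.DataFrame,
    covariates: pd.DataFrame,
    sizes: tuple[int, int, int],
    seed: int = 0,
    cohort_ids: tuple[str, ...] = ("discovery1", "discovery2", "validation"),
    batch_shift: float = 0.0,
    phecodes: pd.DataFrame | None = None,
) -> dict[str, CohortData]:
    """Disjoint random split of one population into named cohorts.

    Adds a cohort-specific ``batch`` covariate column; a non-zero
    ``batch_shift`` applies a multiplicative per-cohort technical shift
    ``exp(batch_shift * cohort_index)`` to the metabolite abundances
    (removed downstream by covariate adjustment).
    """
    if len(sizes) != len(cohort_ids):
        raise ValueError("sizes and cohort_ids must have the same length")
    n = len(dosages)
    if sum(sizes) > n:
        raise ValueError(f"requested {sum(sizes)} samples from {n} available")
    rng = np.random.default_rng([seed, _STREAM_SPLIT])
    order = rng.permutation(n)
    out: dict[str, CohortData] = {}
    offset = 0
    for k, (size, cid) in enumerate(zip(sizes, cohort_ids)):
        idx = np.sort(order[offset:offset + size])
        offset += size
        cov = covariates.iloc[idx].copy()
        cov["batch"] = cid
        met = metabolites.iloc[idx] * float(np.exp(batch_shift * k))
        out[cid] = CohortData(
            dosages=dosages.iloc[idx],
            metabolites=met,
            covariates=cov,
            cohort_id=cid,
            phecodes=None if phecodes is None else phecodes.iloc[idx],
        )
    return out


# ---------------------------------------------------------------------------
# Whole-study generator
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Planted study architecture: regions of GIMs on separate chromosomes.

    Defaults mirror the emulated two-stage design: two discovery cohorts
    (8,455 + 5,841 samples) plus a 5,698-sample validation cohort, regional
    loci each containing a few co-regulated variant/metabolite clusters
    (GIMs), LD proxies around every causal variant, and a small fraction of
    rare (MAF <= 1%) causal alleles with correspondingly larger per-allele
    effects.
    """

    cohort_sizes: tuple[int, int, int] = (8455, 5841, 5698)
    n_regions: int = 3
    gims_per_region: tuple[int, int] = (2, 3)         # inclusive range
    variants_per_gim: tuple[int, int] = (1, 2)
    metabolites_per_gim: tuple[int, int] = (2, 3)
    proxies_per_causal: int = 4
    variance_explained: float = 0.02                  # per causal variant
    maf_range: tuple[float, float] = (0.05, 0.45)
    rare_maf: float = 0.005
    rare_causal_fraction: float = 0.1
    ld_decay: float = 1e-5                            # per bp
    causal_spacing: int = 500_000                     # bp between causal variants
    proxy_max_offset: int = 30_000                    # bp, proxies near causal
    n_null_metabolites: int = 2
    missing_rate: float = 0.02
    batch_shift: float = 0.0
    n_phecodes: int = 4
    phecode_log_odds: float = 0.3
    phecode_prevalence: float = 0.1


@dataclass
class SimulatedStudy:
    cohorts: dict[str, CohortData]
    truth: TruthTable
    variants: list[VariantSpec]
    config: StudyConfig

    @property
    def discovery_ids(self) -> tuple[str, str]:
        return ("discovery1", "discovery2")

    @property
    def validation_id(self) -> str:
        return "validation"


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Generate a full two-stage study with planted regional GIM architecture.

    Each region sits on its own synthetic chromosome.  Within a region, GIMs
    are sets of causal variants (spaced far enough apart to be effectively
    unlinked) acting on disjoint metabolite sets; each causal variant carries
    LD proxies within ``proxy_max_offset`` bp.  Metabolite liabilities feed a
    logistic phecode model; the first ``n_phecodes`` planted effects cycle
    through the causal metabolites.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)

    variants: list[VariantSpec] = []
    truth = TruthTable()
    met_counter = 0
    for r in range(cfg.n_regions):
        chrom = str(r + 1)
        region_id = f"R{r + 1}"
        n_gims = int(rng.integers(cfg.gims_per_region[0], cfg.gims_per_region[1] + 1))
        pos_cursor = 1_000_000
        region_variants: list[VariantSpec] = []
        for _g in range(n_gims):
            n_causal = int(rng.integers(cfg.variants_per_gim[0],
                                        cfg.variants_per_gim[1] + 1))
            n_mets = int(rng.integers(cfg.metabolites_per_gim[0],
                                      cfg.metabolites_per_gim[1] + 1))
            mets = [f"M{met_counter + j + 1:03d}" for j in range(n_mets)]
            met_counter += n_mets
            gim_variants = []
            for _c in range(n_causal):
                if rng.random() < cfg.rare_causal_fraction:
                    maf = cfg.rare_maf
                else:
                    maf = float(rng.uniform(*cfg.maf_range))
                causal = VariantSpec(chrom=chrom, pos=pos_cursor, maf_target=maf)
                gim_variants.append(causal)
                region_variants.append(causal)
                # LD proxies flanking the causal variant
                offsets = rng.choice(
                    np.arange(500, cfg.proxy_max_offset, 500),
                    size=cfg.proxies_per_causal, replace=False)
                for off in np.sort(offsets):
                    region_variants.append(VariantSpec(
                        chrom=chrom, pos=pos_cursor + int(off),
                        maf_target=float(np.clip(maf * rng.uniform(0.8, 1.2),
                                                 0.001, 0.5))))
                pos_cursor += cfg.causal_spacing
            sign_pool = rng.choice([-1.0, 1.0], size=(len(gim_variants), len(mets)))
            for ci, causal in enumerate(gim_variants):
                for mj, met in enumerate(mets):
                    beta = beta_for_variance(cfg.variance_explained,
                                             causal.maf_target)
                    truth.causal_entries.append(CausalEntry(
                        variant=causal.vid, metabolite=met,
                        beta=float(sign_pool[ci, mj]) * beta,
                        variance_explained=cfg.variance_explained))
            truth.planted_gims.append(PlantedGim(
                region_id=region_id,
                variants=tuple(v.vid for v in gim_variants),
                metabolites=tuple(mets)))
        region_variants.sort(key=lambda v: v.pos)
        variants.extend(region_variants)

    null_mets = [f"M{met_counter + j + 1:03d}" for j in range(cfg.n_null_metabolites)]
    all_mets = truth.metabolites + null_mets

    causal_mets = truth.metabolites
    for j in range(cfg.n_phecodes):
        met = causal_mets[j % len(causal_mets)] if causal_mets else None
        if met is None:
            break
        truth.phecode_effects.append(PhecodeEffect(
            metabolite=met, phecode=f"P{j + 1:03d}",
            log_odds=cfg.phecode_log_odds))

    n_total = sum(cfg.cohort_sizes)
    sub = rng.integers(0, 2**31 - 1, size=4)
    dosages = simulate_genotypes(variants, n_total, ld_decay=cfg.ld_decay,
                                 seed=int(sub[0]))
    covariates = pd.DataFrame({
        "age": rng.normal(55.0, 8.0, size=n_total).round(1),
        "sex": rng.choice(["F", "M"], size=n_total),
    }, index=dosages.index)
    mets = simulate_metabolites(
        dosages, truth, covariates=covariates,
        missing_rate=cfg.missing_rate, seed=int(sub[1]),
        metabolites=all_mets)
    # liabilities on the log scale (pre-missingness abundances are log-normal)
    liabilities = np.log(simulate_metabolites(
        dosages, truth, covariates=None, missing_rate=0.0, seed=int(sub[1]),
        metabolites=all_mets))
    phecodes = simulate_phecodes(
        liabilities, truth, baseline_prevalence=cfg.phecode_prevalence,
        seed=int(sub[2]))

    cohorts = split_cohorts(dosages, mets, covariates, cfg.cohort_sizes,
                            seed=int(sub[3]), batch_shift=cfg.batch_shift,
                            phecodes=phecodes)
    return SimulatedStudy(cohorts=cohorts, truth=truth, variants=variants,
                          config=cfg)
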