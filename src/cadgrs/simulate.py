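"""Synthetic case-control cohort generation.

Emulates the statistical structure the downstream analysis assumes:
biallelic loci in (or deliberately out of) Hardy-Weinberg equilibrium,
optional high-LD duplicate loci and per-assay missingness, correlated
binary traditional risk factors, a logistic disease model on the
odds-ratio scale, and case-control ascertainment frequency-matched on sex
and 5-year age bands from a large simulated population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import Cohort
from .panel import CovariateSpec, SnpPanel, default_covariates, default_panel

# continuous covariates carried for adjustment presets; null disease
# effect unless a per-unit OR is configured
_CONTINUOUS_COVARIATES = {
    # name: (mean, sd)
    "heart_rate": (70.0, 12.0),
    "pwv": (8.5, 1.8),
    "bmi": (28.3, 4.3),
    "alcohol": (21.0, 38.0),
}

MALE_FRACTION = 0.77
AGE_MEAN, AGE_SD, AGE_MAX, AGE_MIN = 53.0, 8.0, 65.0, 30.0


@dataclass
class SimConfig:
    """Study-design parameters for cohort simulation.

    Defaults mirror a registry-style CAD case-control study: 1,566 cases
    and 1,322 controls matched for gender and age, drawn from a source
    population with 10% disease prevalence.
    """

    n_cases: int = 1566
    n_controls: int = 1322
    target_prevalence: float = 0.10
    seed: int = 0
    matching: bool = True
    population_multiplier: float = 50.0
    latent_correlation: np.ndarray | None = None  # among binary covariates

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_cases + self.n_controls < 2:
            raise ValueError("need at least one case and one control")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must be in (0, 1)")


def simulate_genotypes(
    panel: SnpPanel,
    n: int,
    seed: int | np.random.Generator,
    apply_missingness: bool = True,
) -> pd.DataFrame:
    """Draw an n x m risk-allele dosage matrix for a panel.

    Loci with inbreeding coefficient F have genotype proportions
    (q^2+pqF, 2pq(1-F), p^2+pqF) for risk-allele frequency p; F = 0 is
    Hardy-Weinberg equilibrium.  An LD duplicate copies its parent's
    dosage and re-draws a fraction 1 - sqrt(target r^2) of entries from
    its own marginal, which puts the empirical dosage r^2 near the
    target.  Missingness (NaN) is applied per-locus at 1 - call_rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for spec in panel:
        p = spec.risk_allele_freq
        q = 1.0 - p
        f = spec.hwe_inbreeding_f
        probs = np.array([q * q + p * q * f, 2 * p * q * (1 - f), p * p + p * q * f])
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        own = rng.choice(3, size=n, p=probs).astype(float)
        if spec.ld_parent is not None and spec.ld_target_r2 > 0:
            redraw_frac = 1.0 - np.sqrt(spec.ld_target_r2)
            dos = cols[spec.ld_parent].copy()
            # parent may already carry missing entries; duplicate from the
            # non-missing pattern, re-drawing where the parent is missing
            parent_nan = np.isnan(dos)
            redraw = (rng.random(n) < redraw_frac) | parent_nan
            dos[redraw] = own[redraw]
        else:
            dos = own
        if apply_missingness and spec.call_rate < 1.0:
            dos = dos.copy()
            dos[rng.random(n) >= spec.call_rate] = np.nan
        cols[spec.snp_id] = dos
    return pd.DataFrame(cols, columns=panel.snp_ids)


def simulate_covariates(
    specs: list[CovariateSpec],
    n: int,
    seed: int | np.random.Generator,
    latent_correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate sex, age, binary risk factors and continuous vitals.

    Binary covariates come from a latent multivariate normal thresholded
    at each covariate's prevalence quantile (identity correlation unless
    configured).  Age is normal (mean 53, SD 8) truncated to [30, 65];
    sex is male with probability 0.77, reflecting the male predominance
    of angiographic CAD registries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(specs)
    if latent_correlation is None:
        z = rng.standard_normal((n, k))
    else:
        corr = np.asarray(latent_correlation, dtype=float)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError("latent_correlation must be a symmetric k x k matrix")
        np.linalg.cholesky(corr)  # raises if not positive definite
        z = rng.multivariate_normal(np.zeros(k), corr, size=n)
    from scipy.stats import norm

    data: dict[str, np.ndarray] = {}
    data["sex_male"] = (rng.random(n) < MALE_FRACTION).astype(float)
    age = rng.normal(AGE_MEAN, AGE_SD, size=n)
    while True:  # truncation by redraw
        bad = (age > AGE_MAX) | (age < AGE_MIN)
        if not bad.any():
            break
        age[bad] = rng.normal(AGE_MEAN, AGE_SD, size=int(bad.sum()))
    data["age"] = age
    for j, spec in enumerate(specs):
        thresh = norm.ppf(1.0 - spec.prevalence)
        data[spec.name] = (z[:, j] > thresh).astype(float)
    for name, (mu, sd) in _CONTINUOUS_COVARIATES.items():
        data[name] = np.clip(rng.normal(mu, sd, size=n), 0.0, None)
    return pd.DataFrame(data)


def _genetic_log_odds(genotypes: pd.DataFrame, panel: SnpPanel) -> np.ndarray:
    """Per-subject genetic contribution to the disease log-odds, following
    each locus's inheritance pattern; a missing dosage contributes the
    log of the locus's HWE-expected mean relative risk."""
    eta = np.zeros(len(genotypes))
    for spec in panel:
        if spec.snp_id not in genotypes.columns:
            continue
        r = np.log(np.asarray(spec.genotype_relative_risks()))
        g = genotypes[spec.snp_id].to_numpy()
        p = spec.risk_allele_freq
        q = 1.0 - p
        expected = np.log(q * q * 1.0
                          + 2 * p * q * spec.genotype_relative_risks()[1]
                          + p * p * spec.genotype_relative_risks()[2])
        contrib = np.where(np.isnan(g), expected, r[np.nan_to_num(g).astype(int)])
        eta += contrib
    return eta


def assign_phenotype(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    panel: SnpPanel,
    covariate_specs: list[CovariateSpec],
    target_prevalence: float,
    seed: int | np.random.Generator,
    max_iter: int = 100,
) -> pd.Series:
    """Draw case/control status from a logistic disease model.

    P(case) = expit(b0 + genetic log-odds + sum_j x_j ln OR_j), with the
    intercept b0 calibrated by bisection so the population mean risk
    equals the target prevalence (within 0.5 percentage points).
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = _genetic_log_odds(genotypes, panel)
    for spec in covariate_specs:
        if spec.or_cad != 1.0:
            eta = eta + covariates[spec.name].to_numpy() * np.log(spec.or_cad)

    lo, hi = logit(target_prevalence) - 30.0, logit(target_prevalence) + 30.0
    if not (expit(lo + eta).mean() <= target_prevalence <= expit(hi + eta).mean()):
        raise RuntimeError(
            f"intercept bisection bracket [{lo:.2f}, {hi:.2f}] does not "
            f"contain the target prevalence {target_prevalence}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        prev = expit(mid + eta).mean()
        if abs(prev - target_prevalence) < 1e-10:
            break
        if prev < target_prevalence:
            lo = mid
        else:
            hi = mid
    else:
        if abs(prev - target_prevalence) > 0.005:
            raise RuntimeError(
                f"intercept bisection did not converge: bracket [{lo}, {hi}], "
                f"prevalence {prev:.4f} vs target {target_prevalence}"
            )
    p = expit(mid + eta)
    y = (rng.random(len(p)) < p).astype(int)
    return pd.Series(y, index=genotypes.index, name="status")


def _age_band(age: np.ndarray, width: int = 5) -> np.ndarray:
    return (np.asarray(age) // width).astype(int)


def sample_case_control(population: Cohort, config: SimConfig,
                        seed: int | np.random.Generator | None = None) -> Cohort:
    """Ascertain a case-control cohort from a simulated population.

    Returns exactly ``n_cases`` cases and ``n_controls`` controls.  With
    matching on, controls are frequency-matched to the sampled cases'
    sex x 5-year-age-band distribution by largest-remainder allocation.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed + 1 if seed is None else seed))
    is_case = population.is_case
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < config.n_cases:
        raise ValueError(
            f"population supplies only {len(case_idx)} cases, "
            f"{config.n_cases} requested"
        )
    if len(ctrl_idx) < config.n_controls:
        raise ValueError(
            f"population supplies only {len(ctrl_idx)} controls, "
            f"{config.n_controls} requested"
        )
    chosen_cases = rng.choice(case_idx, size=config.n_cases, replace=False)

    if not config.matching:
        chosen_ctrls = rng.choice(ctrl_idx, size=config.n_controls, replace=False)
    else:
        sex = population.covariates["sex_male"].to_numpy()
        band = _age_band(population.covariates["age"].to_numpy())
        strata_of = [(int(s), int(b)) for s, b in zip(sex, band)]
        from collections import Counter

        case_strata = Counter(strata_of[i] for i in chosen_cases)
        # largest-remainder allocation of control counts per stratum
        raw = {s: c * config.n_controls / config.n_cases
               for s, c in case_strata.items()}
        counts = {s: int(v) for s, v in raw.items()}
        short = config.n_controls - sum(counts.values())
        if short > 0:
            order = sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)
            for stratum in order[:short]:
                counts[stratum] += 1
        chosen_ctrls = []
        ctrl_pool: dict[tuple, list] = {}
        for i in ctrl_idx:
            ctrl_pool.setdefault(strata_of[i], []).append(i)
        for stratum, cnt in counts.items():
            pool = ctrl_pool.get(stratum, [])
            if len(pool) < cnt:
                raise ValueError(
                    f"control stratum (sex_male, age_band)={stratum} exhausted: "
                    f"need {cnt}, have {len(pool)}"
                )
            chosen_ctrls.extend(rng.choice(pool, size=cnt, replace=False))
        chosen_ctrls = np.asarray(chosen_ctrls)

    order = np.concatenate([np.sort(chosen_cases), np.sort(chosen_ctrls)])
    geno = population.genotypes.iloc[order].reset_index(drop=True)
    pheno = population.phenotype.iloc[order].reset_index(drop=True)
    covar = population.covariates.iloc[order].reset_index(drop=True)
    geno.index = pheno.index = covar.index = pd.Index(
        [f"S{i:06d}" for i in range(len(order))], name="subject_id"
    )
    return Cohort(geno, pheno, covar)


def simulate_cohort(
    config: SimConfig | None = None,
    panel: SnpPanel | None = None,
    covariate_specs: list[CovariateSpec] | None = None,
) -> Cohort:
    """One-call simulation: population genotypes + covariates, logistic
    phenotype, case-control ascertainment, then assay missingness.

    The source population is ``population_multiplier`` times the requested
    cohort size so that case ascertainment at the target prevalence does
    not exhaust the pool.
    """
    config = config or SimConfig()
    panel = panel or default_panel()
    covariate_specs = default_covariates() if covariate_specs is None else covariate_specs
    rng = np.random.default_rng(config.seed)
    n_pop = int(config.population_multiplier * (config.n_cases + config.n_controls))
    # phenotype is assigned on complete genotypes; missingness is an
    # assay property applied afterwards
    geno = simulate_genotypes(panel, n_pop, rng, apply_missingness=False)
    covar = simulate_covariates(covariate_specs, n_pop, rng,
                                config.latent_correlation)
    pheno = assign_phenotype(geno, covar, panel, covariate_specs,
                             config.target_prevalence, rng)
    population = Cohort(geno, pheno, covar)
    cohort = sample_case_control(population, config, seed=rng)
    masked = cohort.genotypes.copy()
    for spec in panel:
        if spec.call_rate < 1.0:
            miss = rng.random(len(masked)) >= spec.call_rate
            masked.loc[miss, spec.snp_id] = np.nan
    return Cohort(masked, cohort.phenotype, cohort.covariates)
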