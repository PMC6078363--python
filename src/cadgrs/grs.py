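"""Genetic risk scores.

Two scores per subject over an m-SNP panel of risk-allele dosages:

* additive GRS (AGRS): the accumulated sum of risk-allele dosages, range
  0..2m (0-62 for a 31-SNP panel);
* multiplicative GRS (MGRS): the product over loci of the genotype
  relative risk, where each locus contributes (1, w, w^2), (1, w, w) or
  (1, 1, w) for additive, dominant or recessive inheritance with
  per-allele odds ratio w.  With normalisation on (the default), each
  locus factor is divided by its HWE-expected mean relative risk, so a
  reference population has mean factor 1 per locus and the cohort MGRS
  distribution sits around (and below) 1 rather than growing with panel
  size.

Quantile assignment (quartiles for the main risk-gradient model, deciles
for finer gradients) uses sample quantiles of a configurable basis
(combined cohort by default, controls only as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .panel import SnpPanel


@dataclass(frozen=True)
class GenotypeWeights:
    """Per-locus genotype relative-risk triples (r0, r1, r2), r0 = 1."""

    weights: dict[str, tuple[float, float, float]]
    #: HWE-expected mean relative risk per locus, for normalisation and
    #: missing-genotype handling
    expected_mean: dict[str, float]

    @classmethod
    def from_panel(cls, panel: SnpPanel) -> "GenotypeWeights":
        w, em = {}, {}
        for spec in panel:
            r = spec.genotype_relative_risks()
            if min(r) <= 0:
                raise ValueError(f"{spec.snp_id}: non-positive relative risk {r}")
            p = spec.risk_allele_freq
            q = 1.0 - p
            w[spec.snp_id] = r
            em[spec.snp_id] = q * q * r[0] + 2 * p * q * r[1] + p * p * r[2]
        return cls(w, em)


@dataclass
class GrsVector:
    """Per-subject scores plus a count of missing loci entering each."""

    scores: pd.Series
    score_type: str  # "additive" | "multiplicative"
    n_missing_loci: pd.Series
    unscorable: pd.Index  # subjects with every locus missing

    def __len__(self) -> int:
        return len(self.scores)


def additive_grs(genotypes: pd.DataFrame,
                 locus_means: pd.Series | None = None) -> GrsVector:
    """Sum of risk-allele dosages per subject.

    A missing dosage is imputed with the cohort mean dosage at that
    locus, keeping scores comparable across subjects; a subject missing
    every locus is flagged unscorable (score NaN) for downstream
    exclusion.  Pass ``locus_means`` (e.g. from the full cohort) to make
    the computation per-subject deterministic under subsetting.
    """
    g = genotypes.to_numpy(dtype=float)
    n_missing = np.isnan(g).sum(axis=1)
    if locus_means is not None:
        col_mean = locus_means.reindex(genotypes.columns).to_numpy(dtype=float)
    else:
        col_mean = np.nanmean(g, axis=0)
    filled = np.where(np.isnan(g), col_mean, g)
    scores = filled.sum(axis=1)
    unscorable = n_missing == g.shape[1]
    scores[unscorable] = np.nan
    return GrsVector(
        pd.Series(scores, index=genotypes.index, name="score_additive"),
        "additive",
        pd.Series(n_missing, index=genotypes.index, name="n_missing_loci"),
        genotypes.index[unscorable],
    )


def multiplicative_grs(
    genotypes: pd.DataFrame,
    weights: GenotypeWeights,
    normalize: bool = True,
) -> GrsVector:
    """Product over loci of the genotype relative risk.

    With ``normalize`` each factor is divided by the locus's HWE-expected
    mean relative risk.  A missing dosage contributes the expected mean
    relative risk (i.e. a factor of exactly 1 when normalised).
    """
    missing_cols = [c for c in genotypes.columns if c not in weights.weights]
    if missing_cols:
        raise ValueError(f"weights missing for SNPs: {missing_cols}")
    bad = [c for c in genotypes.columns if min(weights.weights[c]) <= 0]
    if bad:
        raise ValueError(f"non-positive relative risks for SNPs: {bad}")
    g = genotypes.to_numpy(dtype=float)
    log_score = np.zeros(len(genotypes))
    for j, snp in enumerate(genotypes.columns):
        r = np.log(np.asarray(weights.weights[snp], dtype=float))
        em = np.log(weights.expected_mean[snp])
        col = g[:, j]
        contrib = np.where(np.isnan(col), em, r[np.nan_to_num(col).astype(int)])
        if normalize:
            contrib = contrib - em
        log_score += contrib
    n_missing = np.isnan(g).sum(axis=1)
    unscorable = n_missing == g.shape[1]
    scores = np.exp(log_score)
    scores[unscorable] = np.nan
    return GrsVector(
        pd.Series(scores, index=genotypes.index, name="score_mgrs"),
        "multiplicative",
        pd.Series(n_missing, index=genotypes.index, name="n_missing_loci"),
        genotypes.index[unscorable],
    )


@dataclass
class QuantileAssignment:
    """1-based quantile bin per subject, with the cutpoints that made it."""

    bins: pd.Series
    cutpoints: np.ndarray
    k: int
    basis: str  # "combined" | "controls"


def quantile_assign(
    scores: pd.Series,
    k: int = 4,
    basis: str = "combined",
    is_case: np.ndarray | None = None,
) -> QuantileAssignment:
    """Assign subjects to k quantile bins of the score.

    Cutpoints are the i/k sample quantiles (linear interpolation between
    order statistics) of the basis sample: the combined cohort by
    default, or controls only (requires ``is_case``).  A value exactly at
    a cutpoint goes to the lower bin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if basis not in ("combined", "controls"):
        raise ValueError("basis must be 'combined' or 'controls'")
    vals = scores.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if basis == "controls":
        if is_case is None:
            raise ValueError("controls basis requires is_case mask")
        base = scores.to_numpy(dtype=float)[~np.asarray(is_case, bool)]
        base = base[~np.isnan(base)]
    else:
        base = finite
    if len(np.unique(base)) < k:
        raise ValueError(
            f"only {len(np.unique(base))} distinct score values; "
            f"cannot form {k} quantile bins — use a smaller k"
        )
    cutpoints = np.quantile(base, np.arange(1, k) / k, method="linear")
    if len(np.unique(cutpoints)) < len(cutpoints):
        raise ValueError("tied quantile cutpoints; use a smaller k")
    # bin i (1-based) iff c_{i-1} < x <= c_i  (ties go to the lower bin)
    bins = np.searchsorted(cutpoints, vals, side="left") + 1
    bins = np.where(np.isnan(vals), -1, bins)
    return QuantileAssignment(
        pd.Series(bins.astype(int), index=scores.index, name=f"q{k}"),
        cutpoints, k, basis,
    )


def validate_subsample(
    genotypes: pd.DataFrame,
    score_fn,
    fraction: float = 0.2,
    seed: int = 0,
    reference: pd.Series | None = None,
) -> dict:
    """Recompute scores on a random subsample and demand bit-identical
    agreement with the full-cohort computation restricted to those
    subjects — the determinism check run on 20% of subjects in the
    original analysis workflow.

    ``score_fn`` maps a genotype DataFrame to a :class:`GrsVector`;
    ``reference`` defaults to scoring the full cohort.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(genotypes)
    m = max(1, int(round(fraction * n)))
    idx = np.sort(rng.choice(n, size=m, replace=False))
    sub = genotypes.iloc[idx]
    if reference is None:
        reference = score_fn(genotypes).scores
    resc = score_fn(sub).scores
    ref = reference.iloc[idx]
    both_nan = ref.isna().to_numpy() & resc.isna().to_numpy()
    agree = (ref.to_numpy() == resc.to_numpy()) | both_nan
    mismatched = list(sub.index[~agree])
    return {
        "n_checked": m,
        "n_mismatch": len(mismatched),
        "mismatched_subjects": mismatched,
        "ok": not mismatched,
    }
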