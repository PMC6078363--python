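"""SNP-panel quality control.

Filters a candidate panel down to the analysable set: per-locus call
rate, minor allele frequency, a 1-df chi-square test of Hardy-Weinberg
equilibrium (HWE), and pairwise LD pruning on the squared dosage
correlation.  Filters are applied in a fixed order (call rate -> MAF ->
HWE -> LD) so every exclusion has a deterministic reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import Cohort
from .panel import SnpPanel

KEPT = "kept"
EXCLUDED_HWE = "excluded_hwe"
EXCLUDED_LD = "excluded_ld"
EXCLUDED_MAF = "excluded_maf"
EXCLUDED_CALLRATE = "excluded_callrate"


@dataclass(frozen=True)
class QcThresholds:
    """Default thresholds: keep HWE p >= 0.002 (a Bonferroni-style cut
    for a panel of ~33 candidates), MAF > 5%, call rate >= 95%, and
    prune pairs with dosage r^2 >= 0.8."""

    hwe_p: float = 0.002
    maf: float = 0.05
    call_rate: float = 0.95
    ld_r2: float = 0.8


@dataclass(frozen=True)
class HweResult:
    """1-df chi-square goodness-of-fit test of HWE from genotype counts.

    ``observed`` are counts (n0, n1, n2) by risk-allele dosage;
    ``expected`` the HWE counts at the estimated allele frequency.
    """

    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    allele_freq: float
    chi_square: float
    p_value: float
    monomorphic: bool = False

    df: int = 1


def hwe_chisq_test(counts: tuple[int, int, int]) -> HweResult:
    """Chi-square HWE test from dosage genotype counts (n0, n1, n2).

    The risk-allele frequency is estimated as p = (2 n2 + n1) / 2N and
    compared against expected counts (N q^2, 2 N p q, N p^2).  A
    monomorphic locus returns chi-square 0, p 1, flagged.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p in (0.0, 1.0):
        exp = (n * q * q, 2 * n * p * q, n * p * p)
        return HweResult((n0, n1, n2), exp, p, 0.0, 1.0, monomorphic=True)
    exp = (n * q * q, 2 * n * p * q, n * p * p)
    stat = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
    pval = float(chi2.sf(stat, df=1))
    return HweResult((n0, n1, n2), exp, p, float(stat), pval)


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> tuple[float, bool]:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Missing entries are handled pairwise-complete.  Returns ``(r2,
    monomorphic)``; a vector with zero variance yields r2 = 0 with the
    monomorphic flag set.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0.0 or b.std() == 0.0:
        return 0.0, True
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r), False


@dataclass
class QcReport:
    """Per-SNP QC statistics and keep/exclude status."""

    table: pd.DataFrame  # snp_id, maf, call_rate, hwe_p, max_r2, status, reason
    thresholds: QcThresholds

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table.status == KEPT, "snp_id"])

    @property
    def excluded(self) -> pd.DataFrame:
        return self.table[self.table.status != KEPT]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def summary_counts(self) -> dict[str, int]:
        return self.table.status.value_counts().to_dict()

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump({"n_input": len(self.table),
                           "counts": self.summary_counts(),
                           "thresholds": vars(self.thresholds)}, fh, indent=2)


def filter_panel(
    cohort: Cohort,
    panel: SnpPanel,
    thresholds: QcThresholds | None = None,
    hwe_basis: str = "controls",
) -> QcReport:
    """Apply the QC filters to a cohort's genotype matrix.

    HWE is tested in controls only by default (``hwe_basis`` may be
    "all"); LD pruning keeps the earlier-listed SNP of an offending pair.
    Raises if nothing survives.
    """
    th = thresholds or QcThresholds()
    if hwe_basis not in ("controls", "all"):
        raise ValueError("hwe_basis must be 'controls' or 'all'")
    geno = cohort.genotypes
    hwe_geno = cohort.controls().genotypes if hwe_basis == "controls" else geno

    rows = []
    status: dict[str, tuple[str, str]] = {}
    stats: dict[str, dict] = {}
    for spec in panel:
        g = geno[spec.snp_id].to_numpy()
        call_rate = float(np.mean(~np.isnan(g)))
        freq = np.nanmean(g) / 2.0 if call_rate > 0 else np.nan
        maf = float(min(freq, 1.0 - freq)) if np.isfinite(freq) else np.nan
        hg = hwe_geno[spec.snp_id].to_numpy()
        counts = tuple(int(np.nansum(hg == k)) for k in (0, 1, 2))
        hwe = hwe_chisq_test(counts) if sum(counts) > 0 else None
        hwe_p = hwe.p_value if hwe is not None else np.nan
        stats[spec.snp_id] = dict(maf=maf, call_rate=call_rate, hwe_p=hwe_p)
        if call_rate < th.call_rate:
            status[spec.snp_id] = (EXCLUDED_CALLRATE,
                                   f"call rate {call_rate:.3f} < {th.call_rate}")
        elif not maf > th.maf:
            status[spec.snp_id] = (EXCLUDED_MAF, f"MAF {maf:.3f} <= {th.maf}")
        elif hwe_p < th.hwe_p:
            status[spec.snp_id] = (EXCLUDED_HWE,
                                   f"HWE p {hwe_p:.2e} < {th.hwe_p}")
        else:
            status[spec.snp_id] = (KEPT, "")

    # LD pruning among survivors, keeping the earlier-listed SNP
    survivors = [s for s in panel.snp_ids if status[s][0] == KEPT]
    max_r2 = {s: 0.0 for s in panel.snp_ids}
    for i, a in enumerate(survivors):
        if status[a][0] != KEPT:
            continue
        for b in survivors[i + 1:]:
            if status[b][0] != KEPT:
                continue
            r2, mono = pairwise_r2(geno[a].to_numpy(), geno[b].to_numpy())
            max_r2[a] = max(max_r2[a], r2)
            max_r2[b] = max(max_r2[b], r2)
            if not mono and r2 >= th.ld_r2:
                status[b] = (EXCLUDED_LD, f"r^2 {r2:.3f} with {a} >= {th.ld_r2}")

    for spec in panel:
        st, reason = status[spec.snp_id]
        rows.append({"snp_id": spec.snp_id, **stats[spec.snp_id],
                     "max_r2": max_r2[spec.snp_id], "status": st, "reason": reason})
    table = pd.DataFrame(rows)
    report = QcReport(table, th)
    if report.n_kept == 0:
        raise ValueError("no SNPs survive QC filtering")
    return report
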