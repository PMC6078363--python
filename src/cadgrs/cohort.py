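"""Case-control cohort container and delimited-text / VCF input.

A :class:`Cohort` holds three aligned pieces: a genotype dosage matrix
(subjects x SNPs, values 0/1/2 counting risk alleles, NaN = missing), a
binary phenotype vector (case = 1, control = 0), and a covariate table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DOSAGE_HEADER = "#dosage=risk_allele"


class Cohort:
    def __init__(
        self,
        genotypes: pd.DataFrame,
        phenotype: pd.Series,
        covariates: pd.DataFrame | None = None,
    ):
        if covariates is None:
            covariates = pd.DataFrame(index=genotypes.index)
        if not (len(genotypes) == len(phenotype) == len(covariates)):
            raise ValueError(
                f"row counts differ: genotypes {len(genotypes)}, "
                f"phenotype {len(phenotype)}, covariates {len(covariates)}"
            )
        vals = genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"genotype dosages must be 0/1/2 or missing; found {bad}")
        ph = phenotype.to_numpy()
        if not np.isin(ph, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")
        self.genotypes = genotypes.astype(float)
        self.phenotype = phenotype.astype(int)
        self.covariates = covariates

    # -- basic views ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.genotypes)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype.to_numpy() == 1

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_cases

    def controls(self) -> "Cohort":
        mask = ~self.is_case
        return self._mask(mask)

    def cases(self) -> "Cohort":
        return self._mask(self.is_case)

    def _mask(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.genotypes.loc[mask], self.phenotype.loc[mask],
                      self.covariates.loc[mask])

    def subset_snps(self, snp_ids: Sequence[str]) -> "Cohort":
        return Cohort(self.genotypes[list(snp_ids)], self.phenotype, self.covariates)

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.genotypes.index,
                           "status": self.phenotype.to_numpy()})
        df = pd.concat([df.set_index("subject_id"), self.covariates,
                        self.genotypes], axis=1)
        return df.reset_index().rename(columns={"index": "subject_id"})

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write as delimited text with a metadata line recording the
        dosage convention (risk-allele counts)."""
        with open(path, "w") as fh:
            fh.write(DOSAGE_HEADER + "\n")
            self.to_frame().to_csv(fh, sep=sep, index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path, snp_ids: Sequence[str], sep: str = "\t") -> "Cohort":
        df = pd.read_csv(path, sep=sep, comment="#", na_values=["NA"])
        df = df.set_index("subject_id")
        missing = set(snp_ids) - set(df.columns)
        if missing:
            raise ValueError(f"cohort file missing genotype columns: {sorted(missing)}")
        geno = df[list(snp_ids)]
        pheno = df["status"]
        covar = df.drop(columns=list(snp_ids) + ["status"])
        return cls(geno, pheno, covar)


def dosage_from_vcf(path: str | Path, panel) -> pd.DataFrame:
    """Risk-allele dosage matrix from a (plain-text or bgzipped) VCF.

    Only biallelic records whose ID matches a panel SNP are used.  Dosage
    counts copies of the panel's configured risk allele, whichever of
    REF/ALT it is; a record whose alleles do not include both panel
    alleles is a hard error.
    """
    import pysam

    wanted = {s.snp_id: s for s in panel}
    seen: dict[str, np.ndarray] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.id not in wanted:
                continue
            spec = wanted[rec.id]
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.id}: only biallelic records are supported")
            alleles = {rec.ref, rec.alts[0]}
            if {spec.risk_allele, spec.other_allele} != alleles:
                raise ValueError(
                    f"{rec.id}: VCF alleles {sorted(alleles)} do not match panel "
                    f"alleles {sorted({spec.risk_allele, spec.other_allele})}"
                )
            dos = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                calls = [rec.alleles[a] for a in gt]
                dos[i] = sum(c == spec.risk_allele for c in calls)
            seen[rec.id] = dos
    missing = set(wanted) - set(seen)
    if missing:
        raise ValueError(f"VCF lacks panel SNPs: {sorted(missing)}")
    return pd.DataFrame(seen, index=samples)[list(wanted)]
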