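"""SNP panel and covariate definitions.

A panel row describes one biallelic locus used in a genetic risk score
(GRS): its risk allele, risk-allele frequency, per-allele odds ratio and
inheritance pattern, plus simulation-only knobs (Hardy-Weinberg inbreeding
coefficient, an optional LD parent, and an assay call rate).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

INHERITANCE_PATTERNS = ("additive", "dominant", "recessive")

_PANEL_COLUMNS = [
    "snp_id", "gene", "risk_allele", "other_allele", "maf",
    "risk_is_minor", "per_allele_or", "inheritance", "hwe_inbreeding_f",
    "ld_parent", "ld_target_r2", "call_rate",
]


@dataclass(frozen=True)
class SnpSpec:
    """Definition of one biallelic locus.

    Parameters
    ----------
    snp_id : str
        rsID (or any unique locus label).
    gene : str
        Gene or region label, informational only.
    risk_allele, other_allele : str
        Single-character allele codes; dosage counts copies of
        ``risk_allele``.
    maf : float
        Minor allele frequency, in (0, 0.5].
    risk_is_minor : bool
        Whether the risk allele is the minor allele.  The risk-allele
        frequency used in simulation and HWE normalisation is ``maf`` when
        True, else ``1 - maf`` (risk alleles reported for disease loci are
        not always minor).
    per_allele_or : float
        Odds ratio per copy of the risk allele (> 0).
    inheritance : str
        One of ``additive``, ``dominant``, ``recessive``; controls how
        genotype relative risks are derived from ``per_allele_or``.
    hwe_inbreeding_f : float
        Inbreeding coefficient F in [-1, 1]; 0 means Hardy-Weinberg
        equilibrium.  Genotype proportions become (q^2+pqF, 2pq(1-F),
        p^2+pqF).
    ld_parent : str or None
        rsID of an earlier panel SNP this locus duplicates in linkage
        disequilibrium; simulated by copying the parent dosage and
        re-drawing entries to hit ``ld_target_r2``.
    ld_target_r2 : float
        Target squared dosage correlation with the LD parent, in [0, 1].
    call_rate : float
        Fraction of subjects with a non-missing genotype, in (0, 1].
    """

    snp_id: str
    gene: str = ""
    risk_allele: str = "A"
    other_allele: str = "G"
    maf: float = 0.25
    risk_is_minor: bool = True
    per_allele_or: float = 1.0
    inheritance: str = "additive"
    hwe_inbreeding_f: float = 0.0
    ld_parent: str | None = None
    ld_target_r2: float = 0.0
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.per_allele_or <= 0:
            raise ValueError(f"{self.snp_id}: per_allele_or must be > 0")
        if self.inheritance not in INHERITANCE_PATTERNS:
            raise ValueError(
                f"{self.snp_id}: inheritance must be one of {INHERITANCE_PATTERNS}, "
                f"got {self.inheritance!r}"
            )
        if not (-1.0 <= self.hwe_inbreeding_f <= 1.0):
            raise ValueError(f"{self.snp_id}: hwe_inbreeding_f must be in [-1, 1]")
        if not (0.0 <= self.ld_target_r2 <= 1.0):
            raise ValueError(f"{self.snp_id}: ld_target_r2 must be in [0, 1]")
        if not (0.0 < self.call_rate <= 1.0):
            raise ValueError(f"{self.snp_id}: call_rate must be in (0, 1]")
        # genotype proportions must be a valid distribution under F
        p = self.risk_allele_freq
        q = 1.0 - p
        probs = np.array([
            q * q + p * q * self.hwe_inbreeding_f,
            2.0 * p * q * (1.0 - self.hwe_inbreeding_f),
            p * p + p * q * self.hwe_inbreeding_f,
        ])
        if (probs < -1e-12).any():
            raise ValueError(
                f"{self.snp_id}: inbreeding F={self.hwe_inbreeding_f} with "
                f"risk-allele frequency {p} yields negative genotype proportions"
            )

    @property
    def risk_allele_freq(self) -> float:
        """Population frequency of the risk allele."""
        return self.maf if self.risk_is_minor else 1.0 - self.maf

    def genotype_relative_risks(self) -> tuple[float, float, float]:
        """Relative risks (r0, r1, r2) for dosage 0/1/2 under the locus's
        inheritance pattern: additive (1, w, w^2), dominant (1, w, w),
        recessive (1, 1, w), where w is the per-allele OR."""
        w = self.per_allele_or
        if self.inheritance == "additive":
            return (1.0, w, w * w)
        if self.inheritance == "dominant":
            return (1.0, w, w)
        return (1.0, 1.0, w)


class SnpPanel:
    """Ordered collection of :class:`SnpSpec`, with delimited-text I/O."""

    def __init__(self, snps: Iterable[SnpSpec]):
        self.snps: list[SnpSpec] = list(snps)
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id in panel: {dup}")
        seen: set[str] = set()
        for s in self.snps:
            if s.ld_parent is not None and s.ld_parent not in seen:
                raise ValueError(
                    f"{s.snp_id}: ld_parent {s.ld_parent!r} must precede it in panel order"
                )
            seen.add(s.snp_id)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpSpec]:
        return iter(self.snps)

    def __getitem__(self, snp_id: str) -> SnpSpec:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset(self, snp_ids: Sequence[str]) -> "SnpPanel":
        keep = set(snp_ids)
        return SnpPanel([s for s in self.snps if s.snp_id in keep])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.snps:
            rows.append({
                "snp_id": s.snp_id, "gene": s.gene,
                "risk_allele": s.risk_allele, "other_allele": s.other_allele,
                "maf": s.maf, "risk_is_minor": int(s.risk_is_minor),
                "per_allele_or": s.per_allele_or, "inheritance": s.inheritance,
                "hwe_inbreeding_f": s.hwe_inbreeding_f,
                "ld_parent": s.ld_parent if s.ld_parent is not None else ".",
                "ld_target_r2": s.ld_target_r2, "call_rate": s.call_rate,
            })
        return pd.DataFrame(rows, columns=_PANEL_COLUMNS)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path | io.TextIOBase, sep: str = "\t") -> "SnpPanel":
        df = pd.read_csv(path, sep=sep, dtype={"snp_id": str, "ld_parent": str})
        missing = {"snp_id", "maf", "per_allele_or", "inheritance"} - set(df.columns)
        if missing:
            raise ValueError(f"panel file missing required columns: {sorted(missing)}")
        snps = []
        for _, row in df.iterrows():
            parent = row.get("ld_parent", ".")
            if pd.isna(parent) or parent == ".":
                parent = None
            snps.append(SnpSpec(
                snp_id=str(row["snp_id"]),
                gene=str(row.get("gene", "") or ""),
                risk_allele=str(row.get("risk_allele", "A")),
                other_allele=str(row.get("other_allele", "G")),
                maf=float(row["maf"]),
                risk_is_minor=bool(int(row.get("risk_is_minor", 1))),
                per_allele_or=float(row["per_allele_or"]),
                inheritance=str(row["inheritance"]),
                hwe_inbreeding_f=float(row.get("hwe_inbreeding_f", 0.0)),
                ld_parent=parent,
                ld_target_r2=float(row.get("ld_target_r2", 0.0) or 0.0),
                call_rate=float(row.get("call_rate", 1.0)),
            ))
        return cls(snps)


@dataclass(frozen=True)
class CovariateSpec:
    """A binary risk-factor covariate for simulation.

    ``prevalence`` is the marginal population frequency; ``or_cad`` the
    odds ratio for disease.  Dependence between covariates is induced by a
    latent multivariate normal thresholded at the prevalence quantile; the
    latent correlations live in the simulation config, not here.
    """

    name: str
    prevalence: float
    or_cad: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        if self.or_cad <= 0:
            raise ValueError(f"{self.name}: or_cad must be > 0")


def default_panel() -> SnpPanel:
    """The bundled 33-variant candidate panel.

    Thirty-three loci previously associated with coronary artery disease
    (cell-cycle/inflammation, pro-oxidative and metabolic pathways; the
    APOE rs7412/rs429358 pair is modelled as one composite biallelic
    locus).  MAFs and per-allele ORs are illustrative placeholder values
    chosen in the ranges the selection criteria demand (OR >= 1.1,
    MAF > 5%); they do not claim to reproduce any study's per-SNP inputs.

    Two loci exercise the QC filters: the LPA variant carries inflated
    homozygosity (inbreeding F = 0.35, failing the HWE test), and the
    CDKN2B variant duplicates rs1333049 (9p21) at r^2 ~ 0.99, so default
    filtering reduces 33 candidates to 31 analysed SNPs.
    """
    base = [
        # snp_id, gene, maf, or, inheritance
        ("rs1333049", "9p21.3", 0.47, 1.29, "additive"),
        ("rs4977574", "CDKN2B", 0.46, 1.25, "additive"),
        ("rs618675", "GJA4", 0.20, 1.12, "additive"),
        ("rs17228212", "SMAD3", 0.28, 1.15, "additive"),
        ("rs17465637", "MIA3", 0.30, 1.14, "additive"),
        ("rs12190287", "TCF21", 0.38, 1.12, "additive"),
        ("rs3825807", "ADAMTS7", 0.43, 1.13, "additive"),
        ("rs11556924", "ZC3HC1", 0.38, 1.11, "additive"),
        ("rs12526453", "PHACTR1", 0.33, 1.12, "additive"),
        ("rs1801133", "MTHFR677", 0.35, 1.14, "recessive"),
        ("rs1801131", "MTHFR1298", 0.31, 1.10, "additive"),
        ("rs705379", "PON1", 0.48, 1.12, "additive"),
        ("rs662", "PON192", 0.30, 1.13, "additive"),
        ("rs854560", "PON55", 0.36, 1.11, "additive"),
        ("rs6922269", "MTHFD1L", 0.26, 1.16, "additive"),
        ("rs3798220", "LPA", 0.08, 1.30, "additive"),
        ("rs2114580", "PCSK9", 0.32, 1.13, "additive"),
        ("rs20455", "KIF6", 0.36, 1.12, "dominant"),
        ("rs7412_rs429358", "APOE", 0.15, 1.20, "additive"),
        ("rs964184", "ZNF259", 0.14, 1.17, "additive"),
        ("rs599839", "PSRC1", 0.22, 1.13, "additive"),
        ("rs5186", "AT1R", 0.29, 1.11, "additive"),
        ("rs699", "AGT", 0.41, 1.11, "additive"),
        ("rs4340", "ACE", 0.46, 1.14, "additive"),
        ("rs4402960", "IGF2BP2", 0.31, 1.12, "additive"),
        ("rs1326634", "SLC30A8", 0.28, 1.11, "additive"),
        ("rs266729", "ADIPOQ", 0.27, 1.10, "additive"),
        ("rs7903146", "TCF7L2", 0.29, 1.15, "additive"),
        ("rs17782313", "MC4R", 0.24, 1.10, "additive"),
        ("rs1801282", "PPARG", 0.12, 1.12, "dominant"),
        ("rs1884613", "HNF4A", 0.16, 1.11, "additive"),
        ("rs8050136", "FTO", 0.40, 1.11, "additive"),
        ("rs1376251", "TAS2R50", 0.23, 1.12, "additive"),
    ]
    snps = []
    for snp_id, gene, maf, or_, inh in base:
        kwargs = dict(snp_id=snp_id, gene=gene, maf=maf, per_allele_or=or_,
                      inheritance=inh, call_rate=0.99)
        if snp_id == "rs3798220":  # HWE violator exercised by the QC filter
            kwargs["hwe_inbreeding_f"] = 0.35
        if snp_id == "rs4977574":  # near-perfect LD duplicate of the 9p21 lead SNP
            kwargs["ld_parent"] = "rs1333049"
            kwargs["ld_target_r2"] = 0.99
        snps.append(SnpSpec(**kwargs))
    return SnpPanel(snps)


def default_covariates() -> list[CovariateSpec]:
    """Binary traditional-risk-factor specs with control-population
    prevalences and disease odds ratios of the magnitudes seen in
    case-control CAD registries."""
    return [
        CovariateSpec("smoking", prevalence=0.234, or_cad=3.440),
        CovariateSpec("diabetes", prevalence=0.132, or_cad=3.138),
        CovariateSpec("hypertension", prevalence=0.530, or_cad=2.067),
        CovariateSpec("dyslipidemia", prevalence=0.834, or_cad=1.298),
        CovariateSpec("low_exercise", prevalence=0.424, or_cad=1.0),
        CovariateSpec("family_history", prevalence=0.126, or_cad=1.0),
    ]
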