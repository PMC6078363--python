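"""End-to-end genetic-risk-score analysis as a model/results pair.

:class:`GrsRiskModel` is built from a case-control :class:`~.cohort.Cohort`
and a candidate :class:`~.panel.SnpPanel`; its :meth:`~GrsRiskModel.fit`
runs the full analysis sequence — panel QC, additive and multiplicative
GRS, quantile risk-gradient logistic models (unadjusted and adjusted),
baseline vs baseline+GRS model fits, the DeLong paired ROC comparison,
reclassification metrics (categorical NRI, category-free NRI, IDI) and
calibration/collinearity diagnostics — and returns a
:class:`GrsRiskResults` carrying every table, with ``summary()`` and
``save_report()``.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (ADJUSTMENT_PRESETS, CollinearityReport,
                          HosmerLemeshowResult, LogisticFit, QuantileOrResult,
                          collinearity, fit_logistic, hosmer_lemeshow,
                          quartile_or)
from .cohort import Cohort
from .discrimination import RocComparison, delong_paired_test, roc_points
from .grs import (GenotypeWeights, GrsVector, QuantileAssignment,
                  additive_grs, multiplicative_grs, quantile_assign,
                  validate_subsample)
from .panel import SnpPanel, default_panel
from .qc import QcReport, QcThresholds, filter_panel
from .reclassification import (DEFAULT_CUTPOINTS, IdiResult, NriResult,
                               ReclassTable, build_reclass_table,
                               categorical_nri, cfnri, idi)

DEFAULT_BASE_COVARIATES = ("smoking", "diabetes", "hypertension", "dyslipidemia")


class GrsRiskModel:
    """Genetic-risk-score incremental-value analysis for a case-control
    cohort.

    Parameters
    ----------
    cohort : Cohort
        Genotype dosages, case/control status and covariates.
    panel : SnpPanel
        Candidate SNP definitions (risk alleles, frequencies, per-allele
        ORs, inheritance patterns).
    qc_thresholds : QcThresholds, optional
        Call-rate / MAF / HWE / LD filters applied before scoring.
    score_type : str
        Score entering the risk-gradient and incremental-value models:
        "multiplicative" (default) or "additive".
    k : int
        Number of score quantile bins for the risk gradient (4 =
        quartiles, first quartile as reference).
    adjustment : str or list of str
        Adjustment preset (see ``ADJUSTMENT_PRESETS``) or explicit
        covariate list for the adjusted quantile model.
    base_covariates : sequence of str
        Traditional risk factors forming the baseline model that the GRS
        is asked to improve.
    risk_cutpoints : tuple of float
        Risk categories for the categorical NRI.
    """

    def __init__(
        self,
        cohort: Cohort,
        panel: SnpPanel | None = None,
        *,
        qc_thresholds: QcThresholds | None = None,
        hwe_basis: str = "controls",
        score_type: str = "multiplicative",
        normalize_mgrs: bool = True,
        k: int = 4,
        quantile_basis: str = "combined",
        adjustment: str | list[str] = "age_sex",
        base_covariates: tuple[str, ...] = DEFAULT_BASE_COVARIATES,
        risk_cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS,
        validation_fraction: float = 0.2,
        decile_reference: int = 5,
        seed: int = 0,
    ):
        if score_type not in ("multiplicative", "additive"):
            raise ValueError("score_type must be 'multiplicative' or 'additive'")
        missing = set(base_covariates) - set(cohort.covariates.columns)
        if missing:
            raise ValueError(f"cohort lacks base covariates: {sorted(missing)}")
        self.cohort = cohort
        self.panel = panel or default_panel()
        self.qc_thresholds = qc_thresholds or QcThresholds()
        self.hwe_basis = hwe_basis
        self.score_type = score_type
        self.normalize_mgrs = normalize_mgrs
        self.k = k
        self.quantile_basis = quantile_basis
        self.adjustment = adjustment
        self.base_covariates = tuple(base_covariates)
        self.risk_cutpoints = tuple(risk_cutpoints)
        self.validation_fraction = validation_fraction
        self.decile_reference = decile_reference
        self.seed = seed

    # -- constructors --------------------------------------------------
    @classmethod
    def from_files(cls, panel_path, cohort_path, **kwargs) -> "GrsRiskModel":
        panel = SnpPanel.read(panel_path)
        cohort = Cohort.read(cohort_path, panel.snp_ids)
        return cls(cohort, panel, **kwargs)

    @classmethod
    def from_simulation(cls, config=None, panel=None, covariate_specs=None,
                        **kwargs) -> "GrsRiskModel":
        from .simulate import SimConfig, simulate_cohort

        config = config or SimConfig()
        panel = panel or default_panel()
        cohort = simulate_cohort(config, panel, covariate_specs)
        kwargs.setdefault("seed", config.seed)
        return cls(cohort, panel, **kwargs)

    # -- fitting -------------------------------------------------------
    def fit(self) -> "GrsRiskResults":
        log: list[str] = []
        log.append(f"cadgrs {__version__} | python {platform.python_version()}")
        log.append(f"seed={self.seed} n_subjects={self.cohort.n_subjects} "
                   f"cases={self.cohort.n_cases} controls={self.cohort.n_controls}")

        # 1. panel QC
        qc = filter_panel(self.cohort, self.panel, self.qc_thresholds,
                          self.hwe_basis)
        for _, row in qc.excluded.iterrows():
            log.append(f"QC excluded {row.snp_id}: {row.reason}")
        log.append(f"QC kept {qc.n_kept}/{len(self.panel)} SNPs")
        kept_panel = self.panel.subset(qc.kept)
        geno = self.cohort.genotypes[qc.kept]

        # 2. scores
        locus_means = geno.mean(skipna=True)
        agrs = additive_grs(geno, locus_means=locus_means)
        weights = GenotypeWeights.from_panel(kept_panel)
        mgrs = multiplicative_grs(geno, weights, normalize=self.normalize_mgrs)
        for subj in agrs.unscorable:
            log.append(f"subject {subj} unscorable (all loci missing); excluded")
        score = mgrs if self.score_type == "multiplicative" else agrs

        # 3. scoring validation on a random subsample
        if self.score_type == "multiplicative":
            score_fn = lambda g: multiplicative_grs(g, weights,
                                                    normalize=self.normalize_mgrs)
        else:
            score_fn = lambda g: additive_grs(g, locus_means=locus_means)
        validation = validate_subsample(geno, score_fn,
                                        fraction=self.validation_fraction,
                                        seed=self.seed,
                                        reference=score.scores)
        if not validation["ok"]:
            raise RuntimeError(
                f"score validation failed for subjects "
                f"{validation['mismatched_subjects']}"
            )
        log.append(f"score validation: {validation['n_checked']} subjects, "
                   f"0 mismatches")

        # 4. quantile risk gradient
        quartiles = quantile_assign(score.scores, k=self.k,
                                    basis=self.quantile_basis,
                                    is_case=self.cohort.is_case)
        qor_unadj = quartile_or(self.cohort, quartiles, adjust=None)
        qor_adj = quartile_or(self.cohort, quartiles, adjust=self.adjustment)
        deciles = quantile_assign(score.scores, k=10, basis="controls",
                                  is_case=self.cohort.is_case)
        try:
            decile_or = quartile_or(self.cohort, deciles, adjust=None,
                                    ref=self.decile_reference)
        except ValueError as exc:  # small cohorts can leave a decile empty
            decile_or = None
            log.append(f"decile gradient skipped: {exc}")

        # 5. baseline vs baseline + GRS-quartile models
        ok = quartiles.bins.to_numpy() > 0
        y = self.cohort.phenotype.to_numpy()[ok]
        Xbase = self.cohort.covariates.loc[ok, list(self.base_covariates)].copy()
        fit_base = fit_logistic(Xbase, y)
        Xnew = Xbase.copy()
        bins_ok = quartiles.bins.to_numpy()[ok]
        for b in range(2, self.k + 1):
            Xnew[f"grs_q{b}"] = (bins_ok == b).astype(float)
        fit_new = fit_logistic(Xnew, y)
        pred_base = fit_base.fittedvalues
        pred_new = fit_new.fittedvalues

        # 6. discrimination
        delong = delong_paired_test(pred_base, pred_new, y)
        roc_base = roc_points(pred_base, y)
        roc_new = roc_points(pred_new, y)

        # 7. reclassification
        reclass = build_reclass_table(pred_base, pred_new, y,
                                      cutpoints=self.risk_cutpoints)
        nri_cat = categorical_nri(reclass)
        nri_cf = cfnri(pred_base, pred_new, y)
        idi_res = idi(pred_base, pred_new, y)

        # 8. diagnostics on the extended model
        hl = hosmer_lemeshow(pred_new, y)
        vif = collinearity(Xnew)

        return GrsRiskResults(
            model=self, qc=qc, additive=agrs, multiplicative=mgrs,
            quartiles=quartiles, deciles=deciles,
            quartile_or_unadjusted=qor_unadj, quartile_or_adjusted=qor_adj,
            decile_or=decile_or, fit_base=fit_base, fit_new=fit_new,
            pred_base=pred_base, pred_new=pred_new, outcome=y,
            delong=delong, roc_base=roc_base, roc_new=roc_new,
            reclass_table=reclass, nri_categorical=nri_cat,
            nri_continuous=nri_cf, idi=idi_res, hosmer_lemeshow=hl,
            collinearity=vif, validation=validation, log=log,
        )


@dataclass
class GrsRiskResults:
    """Everything the fitted analysis produced."""

    model: GrsRiskModel
    qc: QcReport
    additive: GrsVector
    multiplicative: GrsVector
    quartiles: QuantileAssignment
    deciles: QuantileAssignment
    quartile_or_unadjusted: QuantileOrResult
    quartile_or_adjusted: QuantileOrResult
    decile_or: QuantileOrResult | None
    fit_base: LogisticFit
    fit_new: LogisticFit
    pred_base: np.ndarray
    pred_new: np.ndarray
    outcome: np.ndarray
    delong: RocComparison
    roc_base: pd.DataFrame
    roc_new: pd.DataFrame
    reclass_table: ReclassTable
    nri_categorical: NriResult
    nri_continuous: NriResult
    idi: IdiResult
    hosmer_lemeshow: HosmerLemeshowResult
    collinearity: CollinearityReport
    validation: dict
    log: list[str] = field(default_factory=list)

    # -- convenient scalars -------------------------------------------
    @property
    def auc_base(self) -> float:
        return self.delong.auc_base

    @property
    def auc_new(self) -> float:
        return self.delong.auc_new

    def score_frame(self) -> pd.DataFrame:
        """Per-subject scores and bin assignments."""
        return pd.DataFrame({
            "subject_id": self.additive.scores.index,
            "score_additive": self.additive.scores.to_numpy(),
            "score_mgrs": self.multiplicative.scores.to_numpy(),
            "quartile": self.quartiles.bins.to_numpy(),
            "decile": self.deciles.bins.to_numpy(),
            "n_missing_loci": self.additive.n_missing_loci.to_numpy(),
        })

    def summary_dict(self) -> dict:
        nri_cat = self.nri_categorical
        nri_cf = self.nri_continuous
        return {
            "n_subjects": self.model.cohort.n_subjects,
            "n_cases": self.model.cohort.n_cases,
            "n_controls": self.model.cohort.n_controls,
            "seed": self.model.seed,
            "qc": {"n_input": len(self.model.panel), "n_kept": self.qc.n_kept,
                   "counts": self.qc.summary_counts()},
            "score_type": self.model.score_type,
            "quartile_or": self.quartile_or_unadjusted.table.to_dict("records"),
            "quartile_or_adjusted": {
                "adjusted_for": self.quartile_or_adjusted.adjusted_for,
                "table": self.quartile_or_adjusted.table.to_dict("records"),
            },
            "auc_base": self.auc_base, "auc_new": self.auc_new,
            "delong": {"z": self.delong.z, "p": self.delong.p_value,
                       "degenerate": self.delong.degenerate},
            "nri_categorical": nri_cat.summary_frame().to_dict("records"),
            "nri_continuous": nri_cf.summary_frame().to_dict("records"),
            "idi": {"estimate": self.idi.idi, "se": self.idi.se,
                    "ci": list(self.idi.ci), "p": self.idi.p_value},
            "hosmer_lemeshow": {"statistic": self.hosmer_lemeshow.statistic,
                                "df": self.hosmer_lemeshow.df,
                                "p": self.hosmer_lemeshow.p_value},
            "max_vif": self.collinearity.max_vif(),
            "converged": {"base": self.fit_base.converged,
                          "new": self.fit_new.converged},
        }

    def summary(self) -> str:
        """Human-readable report, statsmodels-style."""
        m = self.model
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Genetic Risk Score incremental-value analysis".center(w))
        lines.append("=" * w)
        lines.append(f"Subjects: {m.cohort.n_subjects} "
                     f"({m.cohort.n_cases} cases / {m.cohort.n_controls} controls)"
                     f"    Score: {m.score_type} GRS, {m.k} quantile bins")
        lines.append(f"Panel QC: {self.qc.n_kept}/{len(m.panel)} SNPs kept "
                     f"({', '.join(f'{k}={v}' for k, v in sorted(self.qc.summary_counts().items()) if k != 'kept') or 'no exclusions'})")
        lines.append("-" * w)
        lines.append("Score quantile odds ratios (vs first quantile)")
        lines.append(f"{'bin':>4} {'OR':>8} {'95% CI':>19} {'p':>10}   "
                     f"{'OR adj':>8} {'95% CI':>19}")
        tu = self.quartile_or_unadjusted.table
        ta = self.quartile_or_adjusted.table
        for (_, u), (_, a) in zip(tu.iterrows(), ta.iterrows()):
            if u.bin == 1:
                lines.append(f"{int(u.bin):>4} {'1 (ref)':>8}")
                continue
            lines.append(
                f"{int(u.bin):>4} {u['or']:>8.3f} "
                f"({u.ci_low:>7.3f}-{u.ci_high:>7.3f}) {u.p:>10.3g}   "
                f"{a['or']:>8.3f} ({a.ci_low:>7.3f}-{a.ci_high:>7.3f})"
            )
        lines.append(f"  adjusted for: "
                     f"{', '.join(self.quartile_or_adjusted.adjusted_for) or 'nothing'}")
        lines.append("-" * w)
        lines.append("Discrimination (baseline TRF model vs TRF + GRS quartiles)")
        lines.append(f"  AUC {self.auc_base:.3f} -> {self.auc_new:.3f}   "
                     f"DeLong z = {self.delong.z:.3f}, p = {self.delong.p_value:.3g}")
        lines.append("Reclassification")
        nc = self.nri_categorical
        nf = self.nri_continuous
        lines.append(f"  categorical NRI: events {100*nc.event_component:.1f}%, "
                     f"nonevents {100*nc.nonevent_component:.1f}%, "
                     f"total {100*nc.total:.1f}%")
        cf_sf = nf.summary_frame().set_index("component")
        tot = cf_sf.loc["total"]
        lines.append(f"  category-free NRI: events {100*nf.event_component:.1f}%, "
                     f"nonevents {100*nf.nonevent_component:.1f}%, "
                     f"total {100*nf.total:.1f}% "
                     f"(95% CI {100*tot.ci_low:.1f}-{100*tot.ci_high:.1f}%, "
                     f"p = {tot.p:.3g})")
        ci = self.idi.ci
        lines.append(f"  IDI: {100*self.idi.idi:.1f}% "
                     f"(95% CI {100*ci[0]:.1f}-{100*ci[1]:.1f}%, "
                     f"p = {self.idi.p_value:.3g})")
        lines.append("Diagnostics")
        hl = self.hosmer_lemeshow
        lines.append(f"  Hosmer-Lemeshow chi2({hl.df}) = {hl.statistic:.2f}, "
                     f"p = {hl.p_value:.3f}   max VIF = "
                     f"{self.collinearity.max_vif():.2f}")
        lines.append("=" * w)
        return "\n".join(lines)

    def save_report(self, outdir: str | Path) -> dict[str, Path]:
        """Write every table as TSV plus a single JSON summary and a
        plain-text log; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _tsv(name: str, df: pd.DataFrame):
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[name] = p

        self.qc.write(outdir / "qc_report.tsv", outdir / "qc_summary.json")
        paths["qc_report"] = outdir / "qc_report.tsv"
        _tsv("scores", self.score_frame())
        _tsv("quartile_or_unadjusted", self.quartile_or_unadjusted.table)
        _tsv("quartile_or_adjusted", self.quartile_or_adjusted.table)
        if self.decile_or is not None:
            _tsv("decile_or", self.decile_or.table)
        _tsv("model_base", self.fit_base.summary_frame())
        _tsv("model_with_grs", self.fit_new.summary_frame())
        _tsv("roc_base", self.roc_base)
        _tsv("roc_with_grs", self.roc_new)
        _tsv("reclassification_table", self.reclass_table.to_frame())
        _tsv("nri_categorical", self.nri_categorical.summary_frame())
        _tsv("nri_continuous", self.nri_continuous.summary_frame())
        p = outdir / "summary.json"
        with open(p, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=float)
        paths["summary"] = p
        p = outdir / "run.log"
        with open(p, "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        paths["log"] = p
        p = outdir / "summary.txt"
        with open(p, "w") as fh:
            fh.write(self.summary() + "\n")
        paths["summary_txt"] = p
        return paths
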