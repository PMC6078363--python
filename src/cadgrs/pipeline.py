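"""Pipeline configuration, orchestration and fixture generation.

``run_pipeline`` executes the full analysis (QC -> scoring -> quantile
association -> baseline vs baseline+GRS -> DeLong -> NRI/IDI ->
diagnostics) from a :class:`RunConfig`, writing every table as TSV, a
single JSON summary, and a plain-text log.  ``make_fixtures`` writes the
bundled 33-SNP panel, a small simulated cohort, and the worked-example
reclassification count files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .model import DEFAULT_BASE_COVARIATES, GrsRiskModel
from .panel import SnpPanel, default_panel
from .qc import QcThresholds
from .reclassification import DEFAULT_CUTPOINTS
from .simulate import SimConfig, simulate_cohort
from .worked_example import (CFNRI_EVENTS, CFNRI_NONEVENTS, RECLASS_EVENTS,
                             RECLASS_NONEVENTS)


@dataclass
class RunConfig:
    """Flat key-value run configuration.

    ``panel``/``cohort`` are input paths; leave ``cohort`` empty to
    simulate one (``n_cases``/``n_controls``/``prevalence`` control the
    design).  Thresholds and analysis knobs mirror the model defaults.
    """

    panel: str = ""
    cohort: str = ""
    out: str = "cadgrs_report"
    seed: int = 0
    # simulation design (used when no cohort file is given)
    n_cases: int = 1566
    n_controls: int = 1322
    prevalence: float = 0.10
    population_multiplier: float = 50.0
    null_effects: bool = False  # zero out all genetic/covariate effects
    # QC thresholds
    hwe_p: float = 0.002
    maf: float = 0.05
    call_rate: float = 0.95
    ld_r2: float = 0.8
    hwe_basis: str = "controls"
    # analysis
    score_type: str = "multiplicative"
    k: int = 4
    adjustment: str = "age_sex"
    risk_cutpoints: tuple = DEFAULT_CUTPOINTS
    log_level: str = "info"

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key = value`` text file (# comments allowed)."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            elif isinstance(default, tuple):
                kwargs[key] = tuple(float(x) for x in val.split(","))
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(hwe_p=self.hwe_p, maf=self.maf,
                            call_rate=self.call_rate, ld_r2=self.ld_r2)


def _load_or_simulate(config: RunConfig) -> tuple[SnpPanel, Cohort]:
    panel = SnpPanel.read(config.panel) if config.panel else default_panel()
    if config.cohort:
        cohort = Cohort.read(config.cohort, panel.snp_ids)
    else:
        if config.null_effects:
            # type-I-error mode: the phenotype is generated with every
            # genetic effect nulled, but scoring still uses the panel's
            # stated weights, so the GRS is pure noise with a realistic
            # distribution
            from dataclasses import replace

            gen_panel = SnpPanel([replace(s, per_allele_or=1.0) for s in panel])
        else:
            gen_panel = panel
        sim = SimConfig(n_cases=config.n_cases, n_controls=config.n_controls,
                        target_prevalence=config.prevalence, seed=config.seed,
                        population_multiplier=config.population_multiplier)
        cohort = simulate_cohort(sim, gen_panel)
    return panel, cohort


def run_pipeline(config: RunConfig):
    """Run the full analysis and write the report bundle.

    Returns the fitted :class:`~.model.GrsRiskResults`.  Any stage
    failure propagates with the stage recorded in the exception notes.
    """
    stage = "input"
    try:
        panel, cohort = _load_or_simulate(config)
        stage = "analysis"
        model = GrsRiskModel(
            cohort, panel,
            qc_thresholds=config.qc_thresholds(),
            hwe_basis=config.hwe_basis,
            score_type=config.score_type,
            k=config.k,
            adjustment=config.adjustment,
            risk_cutpoints=tuple(config.risk_cutpoints),
            seed=config.seed,
        )
        results = model.fit()
        stage = "report"
        results.save_report(config.out)
        return results
    except Exception as exc:
        exc.add_note(f"pipeline stage: {stage}")
        raise


def make_fixtures(outdir: str | Path, seed: int = 0,
                  n_cases: int = 160, n_controls: int = 140) -> dict[str, Path]:
    """Write self-contained fixture files: the bundled 33-SNP panel, a
    small simulated cohort, and the worked-example reclassification
    counts.  Deterministic: the same seed yields identical bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    panel = default_panel()
    paths["panel"] = outdir / "panel.tsv"
    panel.write(paths["panel"])
    sim = SimConfig(n_cases=n_cases, n_controls=n_controls, seed=seed,
                    population_multiplier=30.0)
    cohort = simulate_cohort(sim, panel)
    paths["cohort"] = outdir / "cohort.tsv"
    cohort.write(paths["cohort"])

    labels = ["<25%", "25-50%", "50-75%", "75-100%"]
    for name, counts in (("reclass_events", RECLASS_EVENTS),
                         ("reclass_nonevents", RECLASS_NONEVENTS)):
        df = pd.DataFrame(counts, columns=labels)
        df.insert(0, "old_category", labels)
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    cf = pd.DataFrame([
        {"group": "events", "n": CFNRI_EVENTS[0], "up": CFNRI_EVENTS[1],
         "down": CFNRI_EVENTS[2]},
        {"group": "nonevents", "n": CFNRI_NONEVENTS[0],
         "up": CFNRI_NONEVENTS[1], "down": CFNRI_NONEVENTS[2]},
    ])
    paths["cfnri_counts"] = outdir / "cfnri_counts.tsv"
    cf.to_csv(paths["cfnri_counts"], sep="\t", index=False)
    return paths
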