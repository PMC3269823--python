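"""End-to-end orchestration: panel + cohort + genotypes -> reclassification report.

``run_pipeline`` wires the stages together: load (or simulate) the inputs,
compute the four genetic summaries, evaluate baseline 10-year risk, fold
the chosen genetic term into the risk, and write the score/risk CSVs plus
the reclassification TSV/JSON.  Everything is deterministic under a fixed
seed and configuration.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_cohort as sc
from .errors import ValidationError
from .framingham import FraminghamModel, cohort_risk, default_model
from .genetic_score import compute_scores
from .reclassification import (
    G_KINDS,
    ci_sensitivity,
    render_tables,
    score_frs_independence,
    summarize_reclassification,
    tables_summary_json,
)
from .snp_panel import SnpPanel, default_panel, load_panel

log = logging.getLogger("chdrisk")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one cohort source (``cohort_path`` or ``simulate_n``) and one
    genotype source (``genotype_path`` or simulation) must be given; a seed
    is required whenever anything is simulated.
    """

    panel_path: str | None = None
    cohort_path: str | None = None
    genotype_path: str | None = None
    simulate_n: int | None = None
    seed: int | None = None
    g_kind: str = "gamma_g"
    or_column: str = "point"
    raf_source: str = "observed"
    fallback_reported_raf: bool = False
    impute_missing: bool = False
    model_path: str | None = None
    output_dir: str = "chdrisk_out"

    def validate(self) -> None:
        if (self.cohort_path is None) == (self.simulate_n is None):
            raise ValidationError(
                "exactly one cohort source required: cohort_path or simulate_n"
            )
        if self.genotype_path is None and self.simulate_n is None:
            raise ValidationError(
                "genotypes must come from genotype_path or from simulation"
            )
        if self.simulate_n is not None and self.seed is None:
            raise ValidationError("seed is required when simulation is requested")
        if self.g_kind not in G_KINDS:
            raise ValidationError(f"g_kind must be one of {G_KINDS}")
        if self.or_column not in ("point", "lower", "upper"):
            raise ValidationError("or_column must be point, lower or upper")
        if self.raf_source not in ("observed", "reported"):
            raise ValidationError("raf_source must be observed or reported")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)


def _load_inputs(config: RunConfig):
    if config.panel_path is not None:
        panel = load_panel(config.panel_path, config.fallback_reported_raf)
    else:
        panel = default_panel(config.fallback_reported_raf)
    if config.simulate_n is not None:
        # independent child streams for genotypes and risk factors
        ss = np.random.SeedSequence(config.seed)
        geno_seed, rf_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        genotypes = sc.simulate_genotypes(
            panel, config.simulate_n, geno_seed, raf_source=config.raf_source
        )
        cohort = sc.simulate_risk_factors(
            sc.CohortSpec(n=config.simulate_n, seed=rf_seed)
        )
    else:
        cohort = sc.read_cohort(config.cohort_path)
        genotypes = sc.read_genotypes_csv(config.genotype_path)
        cids, gids = set(cohort["id"]), set(genotypes.individual_ids)
        if cids != gids:
            raise ValidationError(
                f"cohort/genotype ID mismatch: {sorted(cids ^ gids)[:20]}"
            )
    return panel, cohort, genotypes


def run_pipeline(config: RunConfig, model: FraminghamModel | None = None) -> dict:
    """Run the full pipeline and write the report files.

    Writes ``scores.csv``, ``risks.csv``, ``reclassification.tsv`` and
    ``summary.json`` under ``config.output_dir`` and returns the summary
    record.
    """
    config.validate()
    if model is None:
        model = (FraminghamModel.from_json(config.model_path)
                 if config.model_path else default_model())
    panel, cohort, genotypes = _load_inputs(config)
    log.info(
        "panel k=%d raf_source=%s g_kind=%s or_column=%s seed=%s n=%d",
        panel.k, config.raf_source, config.g_kind, config.or_column,
        config.seed, len(cohort),
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    scores = compute_scores(
        genotypes, panel, or_column=config.or_column,
        raf_source=config.raf_source, impute_missing=config.impute_missing,
    )
    scores.to_csv(out / "scores.csv", index=False)

    risks = cohort_risk(cohort, model)
    risks[["id", "frs_A", "frs_risk", "frs_category"]].to_csv(
        out / "risks.csv", index=False
    )

    # align score rows to cohort order before combining
    scores_idx = scores.set_index("id").loc[risks["id"]]
    tables = ci_sensitivity(
        risks["frs_A"].to_numpy(), genotypes, panel, risks["s10"].to_numpy(),
        g_kind=config.g_kind, raf_source=config.raf_source,
        impute_missing=config.impute_missing,
    )
    (out / "reclassification.tsv").write_text(render_tables(tables))
    (out / "summary.json").write_text(tables_summary_json(tables))

    indep = score_frs_independence(
        scores_idx["grs_weighted"].to_numpy(), risks["frs_risk"].to_numpy()
    )
    summary = {
        "n": int(len(cohort)),
        "k": int(panel.k),
        "g_kind": config.g_kind,
        "seed": config.seed,
        "score_frs_correlation": indep,
        "reclassification": {
            which: summarize_reclassification(t) for which, t in tables.items()
        },
        "outputs": {p.name: str(p) for p in sorted(out.iterdir())},
    }
    s = summary["reclassification"][config.or_column]
    log.info(
        "done: n=%d reclassified=%d (%.1f%%) up=%d down=%d",
        summary["n"], s["n_up"] + s["n_down"], 100 * s["rate_overall"],
        s["n_up"], s["n_down"],
    )
    return summary
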