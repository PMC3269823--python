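"""Risk reclassification after adding a genetic term to absolute risk.

The genetic log-term ``G`` (either the combined log odds ``gamma_g`` or the
log combined relative risk ``ln pRR``) enters the absolute-risk equation as
an additional log-hazard:

    P' = 1 - s(10) ** exp(A + G).

Individuals are cross-tabulated by initial versus updated risk category;
the table records who moved up, who moved down, the overall and
per-initial-category reclassification rates, and moves that skip a
category.  A sensitivity analysis recomputes everything with every SNP's
odds ratio replaced simultaneously by its lower or upper 95% confidence
limit.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .framingham import RISK_CATEGORIES, assign_category, ten_year_risk
from .genetic_score import combined_prr, gamma_g
from .snp_panel import GenotypeMatrix, SnpPanel

__all__ = [
    "updated_risk",
    "ReclassificationTable",
    "reclassification_table",
    "summarize_reclassification",
    "ci_sensitivity",
    "score_frs_independence",
    "render_tables",
]

G_KINDS = ("gamma_g", "log_prr")


def updated_risk(A, G, s10):
    """Updated absolute risk ``P' = 1 - s10 ** exp(A + G)``.

    Identical to the base 10-year risk evaluated at ``A + G``; ``G = 0``
    reproduces the base risk exactly.
    """
    A = np.asarray(A, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(~np.isfinite(A)) or np.any(~np.isfinite(G)):
        raise ValidationError("A and G must be finite")
    return ten_year_risk(A + G, s10)


@dataclass(frozen=True)
class ReclassificationTable:
    """4x4 cross-tab of initial (rows) versus updated (columns) categories."""

    counts: np.ndarray
    categories: tuple[str, ...] = RISK_CATEGORIES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        m = len(self.categories)
        if c.shape != (m, m) or np.any(c < 0):
            raise ValidationError(f"counts must be a non-negative {m}x{m} matrix")
        object.__setattr__(self, "counts", c)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_up(self) -> int:
        """Individuals moving to any strictly higher ordered category."""
        return int(np.triu(self.counts, k=1).sum())

    @property
    def n_down(self) -> int:
        return int(np.tril(self.counts, k=-1).sum())

    @property
    def rate_overall(self) -> float:
        if self.n_total == 0:
            return 0.0
        return (self.n_up + self.n_down) / self.n_total

    @property
    def rate_by_initial_category(self) -> np.ndarray:
        """Off-diagonal fraction per initial-category row (nan for empty rows)."""
        totals = self.row_totals.astype(float)
        moved = totals - np.diag(self.counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, moved / totals, np.nan)

    @property
    def nonadjacent_moves(self) -> int:
        """Moves that skip at least one ordered category."""
        m = len(self.categories)
        i, j = np.indices((m, m))
        return int(self.counts[np.abs(i - j) >= 2].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories),
                            columns=list(self.categories))


def reclassification_table(
    initial: Sequence[str],
    updated: Sequence[str],
    categories: tuple[str, ...] = RISK_CATEGORIES,
) -> ReclassificationTable:
    """Cross-tabulate two equal-length category vectors."""
    initial = np.asarray(initial, dtype=object)
    updated = np.asarray(updated, dtype=object)
    if initial.shape != updated.shape:
        raise ValidationError(
            f"category vectors differ in length: {initial.shape} vs {updated.shape}"
        )
    order = {c: i for i, c in enumerate(categories)}
    unknown = (set(initial) | set(updated)) - set(categories)
    if unknown:
        raise ValidationError(f"unknown category label(s): {sorted(unknown)}")
    m = len(categories)
    counts = np.zeros((m, m), dtype=int)
    for a, b in zip(initial, updated):
        counts[order[a], order[b]] += 1
    return ReclassificationTable(counts, categories)


def summarize_reclassification(table: ReclassificationTable) -> dict:
    """Summary record: totals, up/down moves, overall and per-category rates."""
    rates = table.rate_by_initial_category
    return {
        "n_total": table.n_total,
        "n_up": table.n_up,
        "n_down": table.n_down,
        "rate_overall": table.rate_overall,
        "rate_by_category": {
            cat: (None if np.isnan(r) else float(r))
            for cat, r in zip(table.categories, rates)
        },
        "nonadjacent_moves": table.nonadjacent_moves,
    }


def ci_sensitivity(
    A: np.ndarray,
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    s10,
    g_kind: str = "gamma_g",
    raf_source: str = "observed",
    impute_missing: bool = False,
) -> dict[str, ReclassificationTable]:
    """Reclassification tables at the point estimates and both CI limits.

    For each of the three OR columns (point, lower, upper) the per-SNP
    weights are recomputed for *all* SNPs simultaneously, the genetic term
    rebuilt, and the updated categories cross-tabulated against the
    (unchanged) initial categories.  ``s10`` may be a scalar or a
    per-individual array (sex-specific baselines).
    """
    if g_kind not in G_KINDS:
        raise ValidationError(f"g_kind must be one of {G_KINDS}, got {g_kind!r}")
    if panel.k < 1:
        raise ValidationError("panel has no usable SNPs with OR confidence limits")
    for snp in panel.usable_snps:
        if snp.or_lower is None or snp.or_upper is None:
            raise ValidationError(f"{snp.rsid}: panel lacks CI columns for sensitivity")
    A = np.asarray(A, dtype=float)
    aligned = genotypes.aligned_to(panel)
    p = panel.rafs(raf_source)
    initial = assign_category(ten_year_risk(A, s10))
    out = {}
    for which in ("point", "lower", "upper"):
        w = panel.log_weights(which)
        if g_kind == "gamma_g":
            G = gamma_g(aligned, w, p, impute_missing=impute_missing)
        else:
            G = combined_prr(aligned, w, p, impute_missing=impute_missing, log=True)
        upd = assign_category(updated_risk(A, G, s10))
        out[which] = reclassification_table(initial, upd)
    return out


def score_frs_independence(scores, frs_values) -> dict:
    """Pearson correlation between a genetic score and the FRS, with p-value.

    Used to check that the genetic and conventional components carry
    independent information; under the simulator they are independent by
    construction.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(frs_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and FRS values must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": int(x.size)}


def render_tables(tables: Mapping[str, ReclassificationTable]) -> str:
    """TSV rendering of the point/lower/upper cross-tabs.

    One block per sensitivity level: initial-category rows, updated-category
    columns, a trailing Total row with column percentages.
    """
    buf = io.StringIO()
    for which, table in tables.items():
        cats = list(table.categories)
        print(f"# block: {which}", file=buf)
        print("\t".join(["initial\\updated"] + cats + ["row_total", "row_pct"]), file=buf)
        n = table.n_total
        for i, cat in enumerate(cats):
            row = table.counts[i]
            pct = 100.0 * table.row_totals[i] / n if n else 0.0
            print("\t".join([cat] + [str(int(v)) for v in row]
                            + [str(int(table.row_totals[i])), f"{pct:.1f}%"]), file=buf)
        col_pcts = [100.0 * t / n if n else 0.0 for t in table.col_totals]
        print("\t".join(["Total"] + [f"{int(t)} ({p:.1f}%)" for t, p in
                                     zip(table.col_totals, col_pcts)]
                        + [str(n), "100.0%"]), file=buf)
        print("", file=buf)
    return buf.getvalue()


def tables_summary_json(tables: Mapping[str, ReclassificationTable]) -> str:
    """JSON document with one summary record per sensitivity level."""
    return json.dumps({k: summarize_reclassification(t) for k, t in tables.items()},
                      indent=2)
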