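"""Susceptibility-SNP panel: data model, I/O and fixed-effects pooling.

A panel is an ordered list of CHD susceptibility loci, each carrying a
per-allele odds ratio with its 95% confidence interval and the risk-allele
frequency (RAF) as reported in the discovery literature and as observed in
the target sample.  The per-SNP weight used by the scoring module is the
log odds ratio ``w_i = ln(OR_i)``.

Panel order is file order; every downstream vector (weights, RAFs, genotype
columns) aligns to it, so results are order-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PanelFormatError, ValidationError

__all__ = [
    "SnpEffect",
    "SnpPanel",
    "GenotypeMatrix",
    "load_panel",
    "write_panel",
    "default_panel",
    "pool_fixed_effects",
    "log_weights",
]

#: Normal quantile used to convert a 95% CI to a standard error.  Kept at
#: 1.96 exactly so hand checks on two-decimal published CIs reproduce.
Z_95 = 1.96

PANEL_COLUMNS = [
    "rsid",
    "chrom",
    "gene",
    "risk_allele",
    "or_point",
    "or_lower",
    "or_upper",
    "raf_reported",
    "raf_observed",
]

_OR_WHICH = {"point": "or_point", "lower": "or_lower", "upper": "or_upper"}


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SnpEffect:
    """One susceptibility locus: risk allele, OR with 95% CI, and RAFs.

    ``raf_observed`` may be absent (None) when the locus could not be typed
    or imputed in the target sample; such a locus is excluded from scoring
    unless the panel opts into the reported-RAF fallback.
    """

    rsid: str
    chrom: str
    gene: str
    risk_allele: str
    or_point: float | None
    or_lower: float | None
    or_upper: float | None
    raf_reported: float | None
    raf_observed: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("SNP record with empty rsid")
        ors = (self.or_point, self.or_lower, self.or_upper)
        if not all(_is_missing(v) for v in ors):
            if any(_is_missing(v) for v in ors):
                raise ValidationError(
                    f"{self.rsid}: odds ratio and CI must be given together"
                )
            if not (0 < self.or_lower <= self.or_point <= self.or_upper):
                raise ValidationError(
                    f"{self.rsid}: odds-ratio CI must satisfy "
                    f"0 < lower <= point <= upper, got "
                    f"({self.or_lower}, {self.or_point}, {self.or_upper})"
                )
        for name in ("raf_reported", "raf_observed"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.rsid}: {name}={v} outside [0, 1]")

    @property
    def has_or(self) -> bool:
        return not _is_missing(self.or_point)

    def raf(self, source: str = "observed", fallback_reported: bool = False) -> float | None:
        """Risk-allele frequency from the requested source.

        ``source`` is ``"observed"`` or ``"reported"``; with
        ``fallback_reported=True`` an absent observed RAF falls back to the
        reported one.
        """
        if source == "reported":
            return self.raf_reported
        if source != "observed":
            raise ValidationError(f"unknown RAF source {source!r}")
        if self.raf_observed is None and fallback_reported:
            return self.raf_reported
        return self.raf_observed

    def log_or(self, which: str = "point") -> float:
        if which not in _OR_WHICH:
            raise ValidationError(
                f"which must be one of {sorted(_OR_WHICH)}, got {which!r}"
            )
        value = getattr(self, _OR_WHICH[which])
        if _is_missing(value):
            raise ValidationError(f"{self.rsid}: no odds ratio available")
        return math.log(value)


@dataclass(frozen=True)
class SnpPanel:
    """Ordered collection of :class:`SnpEffect` records.

    ``k`` counts the *usable* SNPs: those with an odds ratio and a usable
    RAF.  By default only the observed RAF qualifies; set
    ``fallback_reported=True`` to let the reported RAF stand in where the
    observed one is absent.
    """

    snps: tuple[SnpEffect, ...]
    fallback_reported: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise ValidationError(f"duplicate rsid(s) in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def _usable(self, snp: SnpEffect) -> bool:
        return snp.has_or and snp.raf("observed", self.fallback_reported) is not None

    @property
    def usable_snps(self) -> tuple[SnpEffect, ...]:
        return tuple(s for s in self.snps if self._usable(s))

    @property
    def k(self) -> int:
        return len(self.usable_snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.usable_snps]

    def rafs(self, source: str = "observed") -> np.ndarray:
        """RAF vector over usable SNPs, panel order."""
        out = []
        for s in self.usable_snps:
            p = s.raf(source, self.fallback_reported)
            if p is None:
                raise ValidationError(f"{s.rsid}: no {source} RAF available")
            out.append(p)
        return np.asarray(out, dtype=float)

    def log_weights(self, which: str = "point") -> np.ndarray:
        """``w_i = ln(OR_i)`` over usable SNPs for the chosen OR column."""
        return np.asarray([s.log_or(which) for s in self.usable_snps], dtype=float)

    def with_fallback(self, fallback_reported: bool) -> "SnpPanel":
        return replace(self, fallback_reported=fallback_reported)


def log_weights(panel: SnpPanel, which: str = "point") -> np.ndarray:
    """Module-level alias for :meth:`SnpPanel.log_weights`."""
    return panel.log_weights(which)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs risk-allele counts or dosages.

    ``counts`` holds values in [0, 2]; ``nan`` marks a missing genotype.
    Column order matches the panel the matrix was built against.
    """

    individual_ids: list[str]
    rsids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.rsids = list(self.rsids)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("genotype counts must be a 2-D array")
        n, k = self.counts.shape
        if n != len(self.individual_ids):
            raise ValidationError(
                f"{len(self.individual_ids)} ids but {n} genotype rows"
            )
        if k != len(self.rsids):
            raise ValidationError(f"{len(self.rsids)} rsids but {k} genotype columns")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual ids are not unique")
        finite = self.counts[np.isfinite(self.counts)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("genotype entries must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def hard_calls(self) -> bool:
        """True when every non-missing entry is an integer count in {0, 1, 2}."""
        finite = self.counts[np.isfinite(self.counts)]
        return bool(np.all(finite == np.round(finite)))

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.counts).any())

    def aligned_to(self, panel: SnpPanel) -> "GenotypeMatrix":
        """Reorder/subset columns to the panel's usable SNPs.

        Raises if any usable panel SNP is absent from the matrix.
        """
        want = panel.rsids
        pos = {r: j for j, r in enumerate(self.rsids)}
        missing = [r for r in want if r not in pos]
        if missing:
            raise ValidationError(f"genotypes lack panel SNP(s): {missing}")
        idx = [pos[r] for r in want]
        return GenotypeMatrix(self.individual_ids, want, self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.rsids)
        df.insert(0, "id", self.individual_ids)
        return df


# ---------------------------------------------------------------------------
# Panel I/O


def _cell(row, col):
    v = row[col]
    if pd.isna(v):
        return None
    return float(v)


def load_panel(path: str | Path, fallback_reported: bool = False) -> SnpPanel:
    """Read a tab-separated panel file.

    Expected header: ``rsid chrom gene risk_allele or_point or_lower
    or_upper raf_reported raf_observed``; the literal string ``NA`` marks an
    absent value.  Rows lacking an OR or a usable RAF are retained but do
    not count toward ``k``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str, "gene": str,
                                            "risk_allele": str},
                     na_values=["NA"], keep_default_na=True)
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelFormatError(
            f"panel file {path} missing required column(s): {missing_cols}"
        )
    snps = []
    for _, row in df.iterrows():
        snps.append(
            SnpEffect(
                rsid=str(row["rsid"]),
                chrom=str(row["chrom"]),
                gene=str(row["gene"]),
                risk_allele=str(row["risk_allele"]),
                or_point=_cell(row, "or_point"),
                or_lower=_cell(row, "or_lower"),
                or_upper=_cell(row, "or_upper"),
                raf_reported=_cell(row, "raf_reported"),
                raf_observed=_cell(row, "raf_observed"),
            )
        )
    return SnpPanel(tuple(snps), fallback_reported=fallback_reported)


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel back to the tab-separated layout read by load_panel."""
    rows = []
    for s in panel.snps:
        rows.append({
            "rsid": s.rsid, "chrom": s.chrom, "gene": s.gene,
            "risk_allele": s.risk_allele,
            "or_point": s.or_point, "or_lower": s.or_lower,
            "or_upper": s.or_upper,
            "raf_reported": s.raf_reported, "raf_observed": s.raf_observed,
        })
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def default_panel(fallback_reported: bool = False) -> SnpPanel:
    """The packaged panel of 12 GWAS CHD susceptibility SNPs (11 usable)."""
    ref = resources.files("chdrisk.data").joinpath("chd_snp_panel.tsv")
    with resources.as_file(ref) as p:
        return load_panel(p, fallback_reported=fallback_reported)


# ---------------------------------------------------------------------------
# Fixed-effects meta-analysis


def pool_fixed_effects(
    estimates: Sequence[tuple[float, float, float]],
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effects pooling of odds ratios.

    Each estimate is an ``(or_point, or_lower, or_upper)`` triple with a 95%
    CI.  Pooling is done on the log-OR scale: the per-study standard error
    is recovered as ``(ln U - ln L) / (2 * 1.96)``, the pooled log-OR is the
    precision-weighted mean, and the pooled CI is
    ``exp(pooled +- 1.96 * pooled SE)``.

    Returns the pooled ``(or_point, or_lower, or_upper)`` triple.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValidationError("pool_fixed_effects requires at least one estimate")
    if len(estimates) == 1:
        # A one-study "pool" is the study itself; returning it verbatim
        # preserves CIs that are asymmetric on the log scale after printing
        # at two decimals.
        point, lower, upper = estimates[0]
        if not (0 < lower <= point <= upper):
            raise ValidationError(
                f"estimate #0: CI must satisfy 0 < lower <= point <= upper, "
                f"got ({point}, {lower}, {upper})"
            )
        if lower == upper:
            raise ValidationError("estimate #0: degenerate CI (lower == upper) has zero SE")
        return (float(point), float(lower), float(upper))
    log_points = []
    weights = []
    for i, (point, lower, upper) in enumerate(estimates):
        if not (0 < lower <= point <= upper):
            raise ValidationError(
                f"estimate #{i}: CI must satisfy 0 < lower <= point <= upper, "
                f"got ({point}, {lower}, {upper})"
            )
        se = (math.log(upper) - math.log(lower)) / (2 * Z_95)
        if se <= 0:
            raise ValidationError(
                f"estimate #{i}: degenerate CI (lower == upper) has zero SE"
            )
        log_points.append(math.log(point))
        weights.append(1.0 / se**2)
    w = np.asarray(weights)
    lp = np.asarray(log_points)
    pooled_log = float(np.sum(w * lp) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    return (
        math.exp(pooled_log),
        math.exp(pooled_log - Z_95 * pooled_se),
        math.exp(pooled_log + Z_95 * pooled_se),
    )
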