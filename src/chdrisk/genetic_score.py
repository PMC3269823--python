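"""Per-individual genetic summaries for a multi-SNP susceptibility panel.

Four summaries are computed under an additive per-allele model with
log-odds-ratio weights ``w_i = ln(OR_i)`` and risk-allele frequencies
``p_i``:

* ``grs_count`` — the plain risk-allele count ``sum_i n_i``;
* ``grs_weighted`` — the weighted count rescaled to the 0..2k allele scale,
  ``(k / sum_i w_i) * sum_i w_i n_i``;
* ``gamma_g`` — the combined log odds relative to the population average,
  ``sum_i (n_i - 2 p_i) w_i``;
* ``log_prr`` — the log of the combined risk relative to the general
  population, ``sum_i [n_i w_i - ln R_i]``, where
  ``R_i = e^{2w} p^2 + 2 e^{w} p (1-p) + (1-p)^2`` is the population-average
  relative risk of SNP *i* under HWE.

``ln pRR - gamma_g`` equals ``sum_i (2 p_i w_i - ln R_i)``, a constant of
the panel: across individuals the two combined summaries differ only by an
offset, so their exponentials are perfectly rank- and Pearson-correlated.

Fractional dosages in [0, 2] are accepted everywhere; the per-SNP relative
risk uses the continuous extension ``e^{n w} / R_i``, which coincides with
the genotype-wise definition at n in {0, 1, 2}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .snp_panel import GenotypeMatrix, SnpPanel

__all__ = [
    "allele_count_score",
    "weighted_score",
    "gamma_g",
    "population_average_risk",
    "per_snp_prr",
    "combined_prr",
    "compute_scores",
    "prr_offset",
]


def _counts(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.counts
    return np.asarray(genotypes, dtype=float)


def _resolve_missing(counts: np.ndarray, rafs: np.ndarray | None, impute_missing: bool) -> np.ndarray:
    mask = np.isnan(counts)
    if not mask.any():
        return counts
    if not impute_missing:
        n_bad = int(mask.any(axis=1).sum())
        raise ValidationError(
            f"{n_bad} individual(s) have missing genotypes; pass "
            "impute_missing=True to substitute the HWE mean 2*p_i"
        )
    if rafs is None:
        raise ValidationError("mean imputation requires risk-allele frequencies")
    filled = counts.copy()
    fill = np.broadcast_to(2.0 * np.asarray(rafs, dtype=float), counts.shape)
    filled[mask] = fill[mask]
    return filled


def _check_aligned(counts: np.ndarray, *vectors: np.ndarray) -> None:
    k = counts.shape[1]
    for v in vectors:
        if v.shape != (k,):
            raise ValidationError(
                f"vector of length {v.shape} does not match {k} genotype columns"
            )


def allele_count_score(
    genotypes: GenotypeMatrix | np.ndarray,
    rafs: np.ndarray | None = None,
    impute_missing: bool = False,
) -> np.ndarray:
    """Total risk-allele count per individual (range 0..2k)."""
    counts = _counts(genotypes)
    counts = _resolve_missing(counts, rafs, impute_missing)
    return counts.sum(axis=1)


def weighted_score(
    genotypes: GenotypeMatrix | np.ndarray,
    weights: np.ndarray,
    k: int | None = None,
    rafs: np.ndarray | None = None,
    impute_missing: bool = False,
) -> np.ndarray:
    """Log-OR-weighted allele count rescaled to the 0..2k allele scale.

    The rescaling factor ``k / sum(w)`` makes the score directly comparable
    with the plain allele count; with equal weights the two coincide.
    """
    counts = _counts(genotypes)
    w = np.asarray(weights, dtype=float)
    _check_aligned(counts, w)
    counts = _resolve_missing(counts, rafs, impute_missing)
    if k is None:
        k = counts.shape[1]
    wsum = w.sum()
    if wsum <= 0:
        raise ValidationError(f"sum of weights must be positive, got {wsum}")
    return (k / wsum) * (counts @ w)


def gamma_g(
    genotypes: GenotypeMatrix | np.ndarray,
    weights: np.ndarray,
    rafs: np.ndarray,
    impute_missing: bool = False,
) -> np.ndarray:
    """Combined log odds relative to the population average.

    Sums, over SNPs, the departure of the individual's allele count from
    its HWE expectation ``2 p_i``, weighted by the log odds ratio.
    ``exp(gamma_g)`` is the individual's combined odds ratio relative to an
    average member of the population.
    """
    counts = _counts(genotypes)
    w = np.asarray(weights, dtype=float)
    p = np.asarray(rafs, dtype=float)
    _check_aligned(counts, w, p)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("risk-allele frequencies must lie in [0, 1]")
    counts = _resolve_missing(counts, p, impute_missing)
    return (counts - 2.0 * p) @ w


def population_average_risk(weight, raf):
    """Average relative risk ``R_i`` contributed by one SNP under HWE.

    Averages the genotype relative risks ``(1, e^w, e^{2w})`` over the HWE
    genotype distribution at frequency ``p``; equals 1 when the SNP is null
    (w = 0) or the risk allele absent (p = 0).  Accepts scalars or arrays.
    """
    w = np.asarray(weight, dtype=float)
    p = np.asarray(raf, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("risk-allele frequencies must lie in [0, 1]")
    r = np.exp(2 * w) * p**2 + 2 * np.exp(w) * p * (1 - p) + (1 - p) ** 2
    if r.ndim == 0:
        return float(r)
    return r


def per_snp_prr(n, weight, raf):
    """Genotype risk relative to the population average for one SNP.

    ``e^{n w} / R_i`` — the continuous extension of the genotype-wise
    values ``(1/R, e^w/R, e^{2w}/R)`` to fractional dosages n in [0, 2].
    """
    n = np.asarray(n, dtype=float)
    w = np.asarray(weight, dtype=float)
    r = population_average_risk(w, raf)
    out = np.exp(n * w) / r
    if out.ndim == 0:
        return float(out)
    return out


def prr_offset(weights: np.ndarray, rafs: np.ndarray) -> float:
    """The panel constant ``ln pRR - gamma_g = sum_i (2 p_i w_i - ln R_i)``."""
    w = np.asarray(weights, dtype=float)
    p = np.asarray(rafs, dtype=float)
    return float(np.sum(2 * p * w - np.log(population_average_risk(w, p))))


def combined_prr(
    genotypes: GenotypeMatrix | np.ndarray,
    weights: np.ndarray,
    rafs: np.ndarray,
    impute_missing: bool = False,
    log: bool = False,
) -> np.ndarray:
    """Combined relative risk across SNPs, ``prod_i pRR(n_i)``.

    Computed as a sum of logs for numerical stability; set ``log=True`` to
    return ``ln pRR`` directly.
    """
    counts = _counts(genotypes)
    w = np.asarray(weights, dtype=float)
    p = np.asarray(rafs, dtype=float)
    _check_aligned(counts, w, p)
    counts = _resolve_missing(counts, p, impute_missing)
    log_prr = counts @ w - np.sum(np.log(population_average_risk(w, p)))
    return log_prr if log else np.exp(log_prr)


def compute_scores(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    or_column: str = "point",
    raf_source: str = "observed",
    impute_missing: bool = False,
) -> pd.DataFrame:
    """All four genetic summaries for a cohort, aligned to a panel.

    Returns a DataFrame with columns ``id, grs_count, grs_weighted,
    gamma_g, combined_or, prr`` where ``combined_or = exp(gamma_g)``.
    """
    aligned = genotypes.aligned_to(panel)
    w = panel.log_weights(or_column)
    p = panel.rafs(raf_source)
    counts = _resolve_missing(aligned.counts, p, impute_missing)
    g = gamma_g(counts, w, p)
    return pd.DataFrame(
        {
            "id": aligned.individual_ids,
            "grs_count": allele_count_score(counts),
            "grs_weighted": weighted_score(counts, w, k=panel.k),
            "gamma_g": g,
            "combined_or": np.exp(g),
            "prr": combined_prr(counts, w, p),
        }
    )
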