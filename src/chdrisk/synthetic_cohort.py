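"""Synthetic cohorts: HWE genotypes and conventional risk-factor marginals.

The generator stands in for an EMR-linked genotyped cohort.  Genotypes are
drawn per SNP as independent ``Binomial(2, p_i)`` counts — Hardy-Weinberg
equilibrium at the panel's risk-allele frequencies, no linkage
disequilibrium.  Conventional risk factors are drawn independently of the
genotypes (and of each other): truncated normals for the continuous
variables, Bernoulli for the binaries.  Defaults reproduce the marginal
summary statistics of a 1243-person CHD-free referral cohort (mean age
60.2 y, 39.9% female, 12.9% diabetic, 37.1% smokers).

Draw order is documented and fixed — genotypes SNP-major, risk factors
variable-major in the order sex, age, tc, hdl, ldl, sbp, dbp, diabetes,
smoker — so a given seed yields bit-identical cohorts across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .snp_panel import GenotypeMatrix, SnpPanel

__all__ = [
    "CohortSpec",
    "simulate_genotypes",
    "simulate_risk_factors",
    "write_cohort",
    "read_cohort",
    "read_genotypes_csv",
    "read_genotypes_vcf",
]

COHORT_COLUMNS = ["id", "sex", "age", "tc", "hdl", "ldl", "sbp", "dbp", "diabetes", "smoker"]

#: Truncation keeps simulated covariates inside the absolute-risk engine's
#: defined range (age window of the underlying Cox model, physiological
#: bounds elsewhere).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (30.0, 74.0),
    "tc": (100.0, 405.0),
    "hdl": (10.0, 100.0),
    "ldl": (30.0, 300.0),
    "sbp": (80.0, 220.0),
    "dbp": (40.0, 130.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Marginal distributions for a simulated risk-factor cohort.

    Continuous variables are (mean, SD) pairs in conventional clinical
    units (years, mg/dL, mmHg); binaries are population proportions.
    """

    n: int = 1243
    seed: int = 0
    age_mean: float = 60.2
    age_sd: float = 7.1
    tc_mean: float = 205.6
    tc_sd: float = 36.8
    hdl_mean: float = 57.0
    hdl_sd: float = 17.5
    ldl_mean: float = 121.0
    ldl_sd: float = 32.4
    sbp_mean: float = 128.1
    sbp_sd: float = 17.5
    dbp_mean: float = 77.7
    dbp_sd: float = 15.2
    prop_female: float = 0.399
    prop_diabetes: float = 0.129
    prop_smoker: float = 0.371
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"cohort size n={self.n} must be >= 0")
        for name in ("age", "tc", "hdl", "ldl", "sbp", "dbp"):
            if getattr(self, f"{name}_sd") < 0:
                raise ValidationError(f"{name}_sd must be >= 0")
        for name in ("prop_female", "prop_diabetes", "prop_smoker"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValidationError(f"truncation bounds for {name} not ordered: ({lo}, {hi})")


def simulate_genotypes(
    panel: SnpPanel,
    n: int,
    seed: int | np.random.Generator,
    raf_source: str = "observed",
) -> GenotypeMatrix:
    """Draw hard-call genotypes for ``n`` individuals under HWE.

    Each usable panel SNP is drawn independently as ``Binomial(2, p_i)``
    with ``p_i`` taken from the requested RAF column, SNP-major so column
    ``j`` consumes the ``j``-th block of the random stream.
    """
    if n < 0:
        raise ValidationError(f"cohort size n={n} must be >= 0")
    if panel.k < 1:
        raise ValidationError("panel has no usable SNPs")
    rng = np.random.default_rng(seed)
    p = panel.rafs(raf_source)
    counts = np.empty((n, panel.k), dtype=float)
    for j, pj in enumerate(p):
        counts[:, j] = rng.binomial(2, pj, size=n)
    ids = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(ids, panel.rsids, counts)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_risk_factors(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a conventional risk-factor table.

    Returns a DataFrame with columns ``id, sex, age, tc, hdl, ldl, sbp,
    dbp, diabetes, smoker``; sex coded ``F``/``M``, binaries 0/1.  All
    variables are mutually independent.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sex = np.where(rng.random(n) < spec.prop_female, "F", "M")
    cont = {}
    for name in ("age", "tc", "hdl", "ldl", "sbp", "dbp"):
        lo, hi = spec.bounds[name]
        cont[name] = _trunc_normal(
            rng, getattr(spec, f"{name}_mean"), getattr(spec, f"{name}_sd"), lo, hi, n
        )
    diabetes = (rng.random(n) < spec.prop_diabetes).astype(int)
    smoker = (rng.random(n) < spec.prop_smoker).astype(int)
    df = pd.DataFrame(
        {
            "id": [f"S{i + 1:06d}" for i in range(n)],
            "sex": sex,
            "age": cont["age"],
            "tc": cont["tc"],
            "hdl": cont["hdl"],
            "ldl": cont["ldl"],
            "sbp": cont["sbp"],
            "dbp": cont["dbp"],
            "diabetes": diabetes,
            "smoker": smoker,
        }
    )
    # HDL above TC is physiologically impossible; clamp the rare collision
    # (independent draws) to keep profiles valid.
    clash = df["hdl"] >= df["tc"]
    df.loc[clash, "hdl"] = 0.3 * df.loc[clash, "tc"]
    return df


# ---------------------------------------------------------------------------
# I/O


def write_cohort(
    cohort: pd.DataFrame | None,
    genotypes: GenotypeMatrix | None,
    path: str | Path,
) -> dict[str, Path]:
    """Write cohort and/or genotype CSVs into directory ``path``.

    When both tables are given their ID sets must match; offending IDs are
    listed in the error.  Returns the paths written.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if cohort is not None and genotypes is not None:
        cids = set(cohort["id"].astype(str))
        gids = set(genotypes.individual_ids)
        if cids != gids:
            odd = sorted(cids.symmetric_difference(gids))
            raise ValidationError(f"cohort/genotype ID mismatch: {odd[:20]}")
    written = {}
    if cohort is not None:
        out = path / "cohort.csv"
        cohort.to_csv(out, index=False)
        written["cohort"] = out
    if genotypes is not None:
        out = path / "genotypes.csv"
        genotypes.to_frame().to_csv(out, index=False)
        written["genotypes"] = out
    return written


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating the documented schema."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    required = [c for c in COHORT_COLUMNS if c != "ldl"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file {path} missing column(s): {missing}")
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"cohort sex column has values outside F/M: {sorted(bad_sex)}")
    return df


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    """Read a genotype CSV (``id`` column plus one numeric column per rsid)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValidationError(f"genotype file {path} lacks an 'id' column")
    rsids = [c for c in df.columns if c != "id"]
    return GenotypeMatrix(df["id"].tolist(), rsids, df[rsids].to_numpy(dtype=float))


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Count risk alleles from the GT field of a VCF for the panel's SNPs.

    Only bi-allelic records whose ID matches a usable panel rsid are used.
    The panel's risk allele must equal REF or ALT verbatim — strand flips
    are never attempted and any mismatch is an error.  Missing genotypes
    become ``nan``; panel SNPs absent from the file yield all-missing
    columns.
    """
    from cyvcf2 import VCF  # optional dependency, imported on use

    want = {rsid: j for j, rsid in enumerate(panel.rsids)}
    alleles = {s.rsid: s.risk_allele for s in panel.usable_snps}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    counts = np.full((len(samples), len(want)), np.nan)
    for rec in vcf:
        rsid = rec.ID
        if rsid not in want:
            continue
        if len(rec.ALT) != 1:
            raise ValidationError(f"{rsid}: VCF record is not bi-allelic")
        risk = alleles[rsid]
        if risk == rec.ALT[0]:
            risk_is_alt = True
        elif risk == rec.REF:
            risk_is_alt = False
        else:
            raise ValidationError(
                f"{rsid}: risk allele {risk} matches neither REF={rec.REF} "
                f"nor ALT={rec.ALT[0]} (strand flips are not attempted)"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        alt_count = np.choose(rec.gt_types, [0.0, 1.0, np.nan, 2.0])
        col = alt_count if risk_is_alt else 2.0 - alt_count
        counts[:, want[rsid]] = col
    return GenotypeMatrix(samples, list(want), counts)
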