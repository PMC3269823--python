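# Methods

## Scope and model

`chdrisk` estimates how genotype information at a small panel of GWAS
susceptibility SNPs changes 10-year absolute CHD risk computed from
conventional risk factors, and quantifies the resulting movement between
clinical risk categories.  Three modelling layers are involved.

**Genetic layer.**  An additive per-allele model: each SNP contributes its
risk-allele count `n_i ∈ [0, 2]` weighted by `w_i = ln(OR_i)`.  Four
per-individual summaries are computed: the raw allele count, the weighted
count rescaled by `k / Σw_i` so it lives on the same 0..2k scale, the
population-centred log odds `γ_G = Σ(n_i − 2p_i)w_i`, and the combined
relative risk `pRR = Π e^{n_i w_i}/R_i` with
`R_i = e^{2w}p² + 2e^{w}p(1−p) + (1−p)²` the average population risk of the
SNP under HWE.  `ln pRR − γ_G = Σ(2p_i w_i − ln R_i)` is a constant of the
panel, so the two centred summaries are identical up to an offset: their
exponentials correlate perfectly on any cohort.  For the packaged panel the
offset is ≈ −0.0513.  SNP effects are assumed independent (no LD, no
epistasis); non-additive genetic models are out of scope.

**Absolute-risk layer.**  A proportional-hazards transform
`P = 1 − s(10)^{exp(A)}` with a sex-specific centred linear predictor *A*.
The engine is coefficient-agnostic; bundles are JSON documents with
per-sex term lists (polynomial, categorical-by-edges, blood-pressure
staging, binary), a reference value subtracted to centre *A*, and the
baseline survival `s10`.  The packaged bundle transcribes the published
Framingham total-cholesterol equations (Wilson et al., Circulation 1998):
continuous age (quadratic in women), NCEP cholesterol and HDL categories,
JNC-V blood-pressure stages, diabetes and smoking indicators;
`s10 = 0.90015` (men) / `0.96246` (women).  When SBP and DBP fall in
different stages the higher stage wins, the standard staging convention.
The total-cholesterol sheet (not the LDL variant) is the default because
the risk-factor schema carries TC and HDL as primary lipids; any other
bundle can be supplied as JSON.

**Reclassification layer.**  The genetic term `G` — `γ_G` by default,
`ln pRR` selectable; the two are parallel analyses, not alternatives to be
mixed — enters as `P′ = 1 − s(10)^{exp(A+G)}`.  Categories use the
half-open partition [0, 5%), [5%, 10%), [10%, 20%), [20%, 100%], one shared
constant across modules.  The prose definitions ("less than 5%", "20% or
higher") are taken as operational; table-style labels such as "(≤5%)" that
conflict with them are not used.  The cross-tab records moves up/down,
overall and per-initial-category rates, and non-adjacent moves (reported,
never suppressed).  The sensitivity analysis substitutes the lower or upper
95% confidence limit for *every* SNP simultaneously — a deliberate
worst/best-case bracket, not a per-SNP perturbation — leaving initial
categories untouched, so row margins are invariant across the three blocks.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `or_column` | `point` | which OR column feeds the weights (point/lower/upper) |
| `raf_source` | `observed` | RAF column for `2p_i` centring and `R_i`; population-relative quantities should use the target sample's own frequencies, with `reported` as an explicit fallback |
| `fallback_reported` | off | lets a SNP without an observed RAF count toward `k` using the reported RAF |
| `g_kind` | `gamma_g` | genetic term entering the updated risk |
| `impute_missing` | off | missing genotypes are a hard error by default; opting in substitutes the HWE mean `2p_i`, which shrinks `γ_G` toward 0 — silent imputation would do that invisibly |

Fixed-effects pooling recovers the per-study SE as `(ln U − ln L)/(2·1.96)`
— 1.96 exactly, since published CIs are printed at two decimals and a more
precise quantile would only obscure hand checks.  A single-study "pool"
returns the study verbatim: printed CIs are rarely exactly log-symmetric,
and re-symmetrizing them would change values without adding information.

## The synthetic-cohort generator

The generator emulates the *marginals* of an EMR-derived referral cohort of
1243 adults free of known cardiovascular disease: mean (SD) age 60.2 (7.1)
years, total cholesterol 205.6 (36.8) mg/dL, HDL 57.0 (17.5), LDL 121.0
(32.4), SBP 128.1 (17.5), DBP 77.7 (15.2) mmHg; 39.9% female, 12.9%
diabetic, 37.1% smokers.  Genotypes are independent `Binomial(2, p_i)`
draws at the panel's observed risk-allele frequencies (HWE).  Continuous
risk factors are truncated normals — age 30–74 (the Cox model's
applicability window), TC 100–405, HDL 10–100, SBP 80–220, DBP 40–130 —
and binaries are Bernoulli.  Draw order is fixed (genotypes SNP-major,
risk factors variable-major) with one seeded `numpy` Generator per call,
so cohorts are bit-reproducible.

What the generator does **not** emulate: LD between SNPs, dosage
uncertainty from imputation (it emits hard calls only, though the scoring
layer accepts fractional dosages), covariance among risk factors, and any
genotype–phenotype association.  Consequently a passing pipeline
demonstrates the arithmetic and the distributional behaviour of the scores
under independence — it says nothing about calibration or discriminative
accuracy in real cohorts, which require outcome follow-up.  Truncation
shifts the realized age mean about 0.4 y below the nominal 60.2 (the upper
bound is only 1.9 SD away); tests therefore compare simulated means to the
analytic truncated-normal mean.  Because risk factors are independent, a
rare draw can place HDL above TC; such draws are clamped to 0.3·TC to keep
profiles physiologically valid.

## Numerical choices

* `pRR` is computed as `exp(Σ n_i w_i − Σ ln R_i)`; sums of logs avoid
  underflow for large panels.
* Category assignment uses `searchsorted` on the shared edge constant with
  right-open bins, so boundary values (exactly 5%, 10%, 20%) fall in the
  upper category — matching the "less than" prose.
* Genotype columns are aligned to the panel by rsid before any scoring;
  panel order is file order and is never re-sorted.
* Dosages outside [0, 2], inverted CIs, frequencies outside [0, 1] and
  mismatched ID sets are hard validation errors, not warnings.
* VCF ingestion matches the panel's risk allele against REF/ALT verbatim;
  strand flips are never attempted and a mismatch is an error, because a
  silent flip on an A/T or C/G SNP would invert the score.

## Problem sizes

The test suite simulates up to 100 000 individuals for distributional
checks (allele-frequency convergence, score correlations) and 250–2000 for
pipeline-level checks; the acceptance script uses 100 000 for correlations
and 1243 — the emulated study size — for score means.  At these sizes the
Monte-Carlo standard error of the reported means is below 0.06 score units.

## Known limitations

* Odds ratios are used where hazard ratios would be proper; for common
  outcomes ORs overstate relative risk, so `exp(γ_G)` and `pRR` are
  approximations of genetic hazard ratios.
* Reclassification here is purely a model-update statistic.  Without
  observed events it cannot be scored for correctness (no net
  reclassification improvement, C-statistic or calibration).
* The packaged panel derives from European-ancestry GWAS; effect sizes and
  frequencies need not transfer to other populations.
* The confidence-limit bracket moves all SNPs jointly and so overstates
  the uncertainty relative to independent per-SNP sampling.
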