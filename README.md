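# nmrmeat

¹H-NMR metabolomics of beef aging: a tested, fully synthetic-data-driven
re-implementation of the complete analysis chain used to study how aging
time (0–28 days), aging type (dry vs. wet) and cattle type (cow vs. heifer)
shape the polar metabolome of bovine strip loin.

## Who this is for

Meat scientists and metabolomics practitioners who want a reproducible,
scriptable version of the standard ¹H-NMR chemometrics workflow —
bucketing, autoscaling, PCA / PLS-R / OPLS-DA / PCA-LDA with cross-validated
quality metrics and VIP scores, internal-standard qNMR quantification,
linear-mixed-model screening and pathway over-representation — together
with a generator that simulates the whole study (animals, aging runs,
concentration trajectories, raw spectra), so every stage can be tested
without access to any measured data.

## The models at the core

**qNMR quantification.** A signal with integral $I_a$, $N_a$ protons and
molar mass $M_a$ is quantified against the maleic-acid internal standard
(mass $m_s$, purity $P_s$, $N_s = 2$, $M_s = 116.07$ g/mol):

$$P_{analyte} = \frac{I_a}{I_s}\cdot\frac{N_s}{N_a}\cdot\frac{M_a}{M_s}\cdot\frac{m_s}{m_a}\cdot P_s,
\qquad n_a\,[\mu mol] = \frac{I_a}{I_s}\cdot\frac{N_s}{N_a}\cdot n_s .$$

Concentrations are reported in µmol per g wet tissue.

**Chemometrics.** Spectra are normalized to the maleic-acid signal, then
integrated into fixed-width buckets (250 buckets over 0.50–4.67 ppm for the
aging-time and cattle-type analyses; 200 buckets over 1.1–9.0 ppm with the
4.7–5.2 and 6.8–8.0 ppm windows excluded for the aging-type analysis) and
autoscaled per bucket. PLS-R (NIPALS) predicts the aging day and reports
$R^2$, RMSEC and the cross-validated $Q^2 = 1 - \mathrm{PRESS}/\mathrm{TSS}$
and RMSECV; VIP scores satisfy $\sum_j \mathrm{VIP}_j^2 = p$. OPLS-DA strips
class-orthogonal variation before a one-component discriminant PLS;
PCA-reduced Fisher LDA (95 % retained variance) classifies dry vs. wet.
All cross-validation refits scaling and model inside each training fold.

**Screening.** Per metabolite, a linear mixed model
`conc ~ day * (cattle_type + aging_type) + (1|animal) + (1|run)` is
simplified by backward selection; factor significance is a likelihood-ratio
test, Bonferroni-gated across the 30-metabolite panel. Nonparametric
screening (Spearman r vs. day, Friedman over animal×aging-type blocks,
Kruskal–Wallis with Dunn/Bonferroni post-hocs) runs alongside, gated by a
Shapiro–Wilk normality check. Significant cattle-type metabolites feed a
hypergeometric pathway over-representation analysis against a bundled
KEGG-style library.

## Worked example

```bash
nmrmeat run-all --seed 1 --outdir demo
```

simulates the default study (8 heifers + 7 cows × 5 aging days × dry/wet =
150 samples, 4 aging runs), renders and normalizes 150 spectra, and runs the
whole battery. It prints (abbreviated):

```json
{
  "Q2": 0.9324,
  "RMSECV": 2.5805,
  "oplsda_day0_accuracy": 0.8667,
  "pca_lda_accuracy": 0.75,
  "significant": { "n_aging_time": 28, "n_cattle_type": 7, "n_aging_type": 6 }
}
```

Reading: the aging day of a sample can be predicted from its bucketed
spectrum to about ±2.6 days out-of-sample ($Q^2 = 0.93$); cow and heifer
day-0 samples separate with 87 % cross-validated OPLS-DA accuracy; 28 of
the 30 panel metabolites show a significant aging-time effect — exactly the
set the generator embeds (all but the stable dipeptides carnosine and
anserine). `demo/` holds the metadata, bucket tables, VIP scores,
quantified concentrations, screening table and ORA results as TSV, plus a
`summary.json` stamped with the config hash and seed.

The same stages are available piecewise (`nmrmeat simulate`, `preprocess`,
`fit-pca`, `fit-pls`, `fit-oplsda`, `fit-lda`, `quantify`, `screen`, `ora`)
and as library functions (`nmrmeat.run_study`, `nmrmeat.pls_cross_validate`,
…). Configuration is a TOML/YAML file overriding the built-in defaults.

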