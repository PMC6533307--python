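# Methods

## Response-surface stage

The extraction experiment is a circumscribed central composite design in
three factors: 8 factorial corners at coded ±1, 6 axial points at ±α
(default α = 1.68, matching the printed design levels rather than the
rotatable 1.682), and replicated centre points (default 6), giving the
20-run layout used throughout. Factors are always modelled in coded units
$x = (X - c)/s$; uncoded displays are derived. The solid/liquid ratio is
parameterized by the continuous denominator $D$ of "1:$D$ g/mL" (centre
20, step 10), so coded ±1 are 1:10 and 1:30. Axial uncoded values are
carried at full precision (e.g. 46.8 min), with tabulated integers treated
as display rounding.

The full 10-term quadratic is fitted by ordinary least squares
(statsmodels OLS behind `fit_quadratic`); no stepwise reduction is
attempted, since a reduced model was not specified for this experiment. On
the packaged design the full model gives R² = 0.9203 with model
p = 0.0002; the originating analysis printed R² = 0.9211 without its
coefficient table, so a backward-reduced fit cannot be excluded — the full
fit is the package's single definition, and both figures agree to the
third decimal. The ANOVA splits residual variation into lack-of-fit and
pure error from the centre replicates; with fewer than two centre
replicates the lack-of-fit rows are NaN-flagged rather than raising,
because the model fit itself is still well defined.

**Optimization.** The fitted surface is maximized over a finite coded box
(default the factorial cube [−1,1]³; the axial cube is available via the
region argument — the reported optimum lies on factorial-cube faces, which
is why that cube is the default). A dense grid scan at 0.01 coded units,
evaluated by broadcasting over sparse axes and scanned in ascending
lexicographic order so ties resolve to the smallest coded point, locates
the incumbent; a bounded L-BFGS-B polish refines it and is kept only when
it improves the grid value, so the result dominates the grid maximum by
construction. The procedure is entirely deterministic.

## Identification stage

Spectral trees carry a deprotonated precursor, PDA λ_max values, and
nested fragment stages with intensities relative to each stage's base
peak. All m/z comparisons use a 0.5 Da window: the data are unit-resolution
ion-trap spectra reported at nominal mass.

Detectors fire in a fixed priority order — flavone, quinic acid ester,
oleuropein derivative, small hydroxybenzoic acids (precursors 187/173),
the precursor-453 rule, hydroxy fatty acid — and the first match wins.
This mirrors analyst practice: an aglycone match outranks generic loss
matching. Trees without usable fragments are returned unknown rather than
guessed at.

* **UV windows** (heuristic, inferred from the observed band table): a
  flavone needs a band in 330–360 nm plus one in 240–280 nm; a
  hydroxycinnamate a band in 300–335 nm; a hydroxybenzoate either all
  bands below 330 nm or the 250/270/320 triple. Windows are inclusive —
  a spectrum may admit several candidate classes, and the cascade order
  disambiguates — because several observed hydroxycinnamate and fatty-acid
  spectra share bands with the flavone region. An empty band list is
  uninformative and admits every class.
* **Flavones**: precursor match against the aglycone library (285
  luteolin, 269 apigenin, 283 acacetin, 299 chrysoeriol, 329 tricin); the
  methoxylated aglycones additionally require their chain of 15 Da
  base-peak losses (one stage for chrysoeriol, two for tricin). A 162 Da
  loss landing on a library aglycone yields the O-glucoside. Luteolin,
  apigenin and acacetin carry standard-matched confidence; deductions and
  isomer calls are labelled accordingly.
* **Quinic acid esters**: require the *m/z* 191 quinate marker somewhere
  in the tree; names are keyed to the precursor (499 mixed
  caffeoyl/coumaroyl diester with a 146 Da loss; 515 dicaffeoyl ester; 533
  its monohydrate, 18 Da heavier, same cascade). The 3,5-regiochemistry is
  assigned by a simplified intensity key — MS2 base peak 353 whose own
  spectrum has base 191 with the 179 satellite at ≥ 10% — standing in for
  the full hierarchical intensity schemes in the specialist literature;
  without the key the ester is reported as an unplaced isomer.
* **Oleuropein derivatives**: an acyl loss from the precursor onto
  *m/z* 539 whose next stage has base 377 (glucosyl cleavage off the
  oleuropein skeleton). A precursor 30 Da above oleuropein that lacks the
  539/377 signature is reported as a methoxyoleuropein isomer, tentative.
* **Precursor 453**: a 60 Da loss to the MS2 base ion 393 is read as two
  methoxy units, reproducing the published decision rule for
  prenyl-dimethoxy-caffeoyl-*p*-coumaric acid; the annotation carries a
  note that this mass arithmetic is chemically loose, kept as stated
  rather than corrected.
* **Hydroxy fatty acids**: nominal-mass lookup in 290–320 Da (293, 295,
  297, 309, 313) gated on an 18 Da water loss in MS2 (consecutive
  dehydration of the aliphatic chain) and on the precursor not being a
  flavone aglycone. The 293 Da entry keeps its published name spelling,
  flagged in the annotation notes as a likely typographic variant.
* **Batch behaviour**: duplicate peak ids raise; distinct peaks resolving
  to the same name (positional isomers separated in time) get Roman-numeral
  suffixes in retention order. Results are order-independent and
  deterministic.

## Quantification stage

External-standard compounds invert their calibration line; negative
back-calculations clamp to zero with a flag (blank-level areas below the
intercept are routine, not errors). RRF quantification implements
RRF = (A_k/A_i)/(C_k/C_i) and conc = (A/A_i)·C_i/RRF/R exactly; the
recovery correction R defaults to 1.0 per compound because no specific
standard's recovery is designated for the RRF-quantified compounds, and it
is configurable per compound (accepted range (0, 1.2]). The
internal-standard assignment map is fixed: protocatechuic acid for the
small-acid group, ferulic acid for the hydroxycinnamates, hesperidin for
the glycosylated/methoxylated flavones; apigenin, acacetin and luteolin
use their own curves.

LOD and LOQ are 3σ/slope and 10σ/slope from a supplied baseline-noise σ in
area units — the instrument-derived signal-to-noise values behind the
published limits are not recomputable from tabulated data, so σ is an
input. RSD uses the sample (n−1) standard deviation, the analytical
convention for small replicate sets (n = 3–5). Contents convert as
mg/g DW = conc·dilution·volume/mass/1000 with defaults 15 mL and 0.5 g
(the optimal 1:30 ratio); the Folin-Ciocalteu total-phenolic conversion
divides by a further 10 to land on g GAE/100 g DW. Class aggregation sums
in a canonical record order so results are exactly permutation-invariant;
the phenolic total covers the hydroxybenzoic, hydroxycinnamic and
flavonoid classes, and the most-abundant-compound ratio is reported
against this chromatographic total (not the Folin TP value, which measures
a different, broader pool).

## Synthetic data

* Surface responses: polynomial value plus additive Gaussian noise
  (default off), seeded.
* Spectral trees: realized from per-compound templates (the 20 named
  compounds plus the 3 unknown peaks as distractors). The m/z perturbation
  is one uniform mass-axis offset per tree, bounded by the jitter
  parameter — the dominant error mode of a drifting unit-resolution trap —
  so absolute masses move while neutral-loss differences are preserved.
  Intensity noise is multiplicative lognormal on non-base fragments
  (stage base peaks stay at 100% by definition).
* Peak areas: the quantification relations run in reverse (line
  evaluation, or conc·RRF·R·A_i/C_i) times mean-one lognormal noise with a
  specified CV.

These choices are the simplest models consistent with instrument
behaviour; none was specified by the study. What passing round-trip tests
show is that the cascade and quantifier invert the generator's idealized
process, including under calibration offsets up to ±0.3 Da and 1% area
noise. They do not show robustness to co-elution, per-ion mass errors
larger than the matching window, missing fragment stages, or detector
saturation, none of which the generator emulates.

## Numerical choices and problem sizes

Optimizer grid 0.01 coded units with lexicographic tie-break; polish kept
only on improvement. m/z tolerance 0.5 Da everywhere. Monte-Carlo test
sizes — 200 surface refits, 200 quantification replicates, 50 random
optimizer models, 5–10 seeded trees per library compound — are large
enough to pin the tested biases well inside their tolerances while keeping
the default suite fast. All generators take explicit integer seeds and are
bit-reproducible.

## Known limitations

The annotator covers exactly the compound families observed in this
flower matrix; it is a decision cascade, not a general spectral-library
search, and new families require new rules. Regiochemistry beyond the
3,5-diacyl key, elemental-formula decomposition, isotope patterns and
positive-ion mode are out of scope. Quantification assumes supplied peak
areas (no chromatogram integration) and propagates no uncertainty beyond
replicate RSD. The published ±SD figures on contents are measurement
replicates and are carried as data, not recomputed.
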