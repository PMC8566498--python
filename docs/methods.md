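# Methods

## Mass and ion arithmetic

Monoisotopic masses use IUPAC/CODATA values (C 12.000000, H 1.0078250,
²H 2.0141018, N 14.0030740, O 15.9949146, ¹⁸O 17.9991596, P 30.9737615 Da;
electron 0.0005486 Da). Ion m/z is electron-corrected: an anion gains one
electron mass and a cation loses one, folded into the ±1.00728 proton
constants and the formate-anion constant 44.99820. With these constants
every reference precursor and fragment m/z handled by the package agrees
with its 4-decimal printed form within ±5 ppm — the tolerance used
throughout for precursor matching, mirroring high-resolution Orbitrap
practice. Fragment matching defaults to 10 ppm, since observed product-ion
values in centroided MS/MS deviate further from theory than precursors do.
All species are singly charged; multiply charged ions are out of scope.

A PC is assembled as the glycerophosphocholine backbone C8H20NO6P plus two
fatty acyls counted as free acids, minus two waters. An acyl with `c`
carbons, `d` double bonds, `a` added oxygens and hydrogen delta `h`
(0 or −2) has composition C(c)H(2c−2d+h)O(2+a). The truncated carboxyl
terminus (`;COOH`) is encoded as a = 2, h = −2, which reproduces e.g.
azelaic acid C9H16O4 for `9:0;COOH`.

## The bundled catalogue and the 465-entry library

The shipped catalogue (`data/default_catalogue.csv`) holds 155 oxidized
sn-2 acyls: for each parent PUFA (18:2, 20:4, 22:6) the eight full-length
classes (`;O-H2`, `;oxo`, `;O`, `;O2-H2`, `;OOH`, `;O2` epoxy-hydroxide,
`;O3-H2`, `;O3`) plus chain-truncated aldehyde, hydroxy-aldehyde,
keto-aldehyde and carboxyl series over the cleavage lengths reachable from
each parent's double-bond pattern, deduplicated globally, with further
unsaturation variants of the truncated series filling the set to exactly
155. Exemplars with direct literature anchors (`8:1;O`, `9:0;COOH`,
`17:3;O2`) are forced members. Expansion over sn-1 {16:0, 18:0, 18:1}
yields 465 entries with unique names. Membership beyond the anchored
exemplars and class taxonomy is a fixture convention of this package:
alternative but equally valid truncation sets exist, and the catalogue
file can be replaced wholesale.

`;OOH` and the epoxy-hydroxide `;O2` (and likewise `;oxo` vs `;O-H2`)
are deliberate isobaric twins: identical elemental composition and
identical negative-mode fragments, distinct only in functional class and
positive-mode neutral-loss behaviour. Negative-mode annotation therefore
cannot separate them, and every negative-mode recall or accuracy figure
in the tests counts a hit at the elemental-composition level; the
positive-mode H₂O₂-before-H₂O discrimination (hydroperoxides can also
dehydrate, so the more specific loss wins) is validated separately.

## Feature workflow

Detection chains centroids across consecutive MS1 scans within 5 ppm,
then gates on ≥3 scans, apex ≥10⁴ counts, apex/noise ≥3 (noise = median
intensity of same-window centroids outside the chain, floored at 1), and
a co-eluting, lower-intensity +1.00336 Da partner; partner chains are
dropped as isotopologues. Peak area is the trapezoidal integral
(intensity·min). Alignment replaces the vendor's undocumented adaptive
RT warp with a per-run median shift estimated from mutual best matches
inside the ±0.1 min window, followed by greedy closest-pair grouping on
the combined (ppm, ΔRT) distance — a simplification that retains the
scientifically meaningful parameters (the tolerances) and recovers a
systematic drift slightly beyond the window whenever some anchors fall
inside it. Background subtraction keeps compounds with
oxidized/nonoxidized area ratio strictly above 2.0; a compound absent
from the nonoxidized channel counts as retained, since the screen is a
presence filter and division by zero must not silently drop genuine
oxidation products.

## Semiquantification and normalization

Quant values are dimensionless area ratios against the PC15:0/18:1-d7
internal standard, which cancels per-sample instrument response. The oxPC
fraction is 100·ΣoxPC/(ΣoxPC+ΣPC) per sample. Heat-map normalization is
log₁₀ followed by per-compound autoscaling with the population standard
deviation (the MetaboAnalyst convention), so output rows are exactly
zero-mean, unit-sd. Values below a configurable detection floor are
reported missing rather than zero to keep the log defined; no imputation
is applied. Tissue wet weight enters only as an optional per-sample
divisor.

## ¹⁸O labeling and imaging

Oxidation under ¹⁸O₂ makes every oxidation-added oxygen heavy; only those
oxygens are treated as exchangeable (ester and phosphate oxygens are not).
Imaging transitions pair the labeled [M+H]⁺ with its H₂¹⁸O-loss product
(−20.0148 Da); which oxygen departs from a doubly labeled epoxy-hydroxide
is chemically ambiguous, but the labeled-loss channel is the one whose
nominal pairs (e.g. 794.5 → 774.5, Δ = 20.0) match practice. Nominal
transition m/z values are quoted at one decimal by truncation — the
ion-trap convention of citing the lower boundary of the unit isolation
window — which is why 794.5682 is quoted as 794.5, not 794.6.

Labeling efficiency is estimated from the isotopologue envelope I₀…Iₙ as
p̂ = Σk·Iₖ/(n·ΣIₖ), the maximum-likelihood estimate under a binomial
single-p model across exchangeable oxygens (both added oxygens derive from
the same O₂ pool). The estimator is scale-invariant and unbiased; the test
suite verifies recovery of p = 0.722 within ±0.02 from a 10,000-ion
simulated envelope. No closed-form reference for this estimator exists in
the source material; the binomial model is this package's definition,
validated by simulation self-consistency only.

Ion images are linearly rescaled so the maximum pixel is 100 and zero
stays 0 (all-zero grids render all-zero). The artificial-oxidation screen
flags a transition when its unlabeled (¹⁶O) channel carries more than 5%
(configurable) of the labeled channel's signal in a no-stimulation
control — an informational flag for workup- or laser-induced oxidation,
not a filter.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's structural conditions at desk scale:
paired runs sharing a nonoxidized PC matrix (the three PUFA-PCs plus
PC16:0/18:1 at ~2×10⁶ counts) with oxPC spikes (~5×10⁵ counts, scaled by
inducer class weights) only in the oxidized channel; Gaussian elution
(σ = 0.05 min) sampled every 0.012 min, about ten points across the FWHM;
a single +1 ¹³C partner at 1.1% per carbon; 10% multiplicative log-normal
abundance noise; uniform-random decoy MS/MS peaks excluded within 20 ppm
of true fragments; and MSI grids with elevated pericentral disks
(contrast 8, noise CV 10%) mimicking zonated accumulation around central
veins. Inducer presets weight both spike selection and abundance:
radical/autoxidation systems favour hydroperoxides strongly (weight 6/5
vs < 1), metal systems favour their secondary decomposition products
(epoxides/hydroxides, ketones, truncations). Spiked precursors are kept
≥20 ppm apart so ground truth stays unambiguous.

Not emulated: full isotope envelopes beyond +1, ion suppression,
profile-mode peak shapes, chromatographic tailing, co-eluting isomers and
real inter-sample biology. Passing closure tests therefore demonstrates
correctness of the bookkeeping and rules on idealized signals, not
performance on real tissue extracts.

Pipeline closure in the tests and CLI uses 12 spikes per pair with 40
decoy peaks per MS/MS spectrum and 50 noise centroids per run, which
keeps a full simulate → detect → align → subtract → annotate cycle under
a second while exercising every stage; recall is ≥95% at the
composition level across seeds.

## Numerical choices and degenerate inputs

Empty compositions have mass zero; composition subtraction raises rather
than clip at zero. Mixed-polarity runs, negative areas and all-zero
isotopologue envelopes are rejected with named errors. RT windows are
symmetric (chromatography has no natural orientation). Annotation ties on
score break on the smaller |precursor ppm|, then on name order for full
determinism; fragments predicted at indistinguishable m/z (the catalogue's
[oxFA]⁻ annotation duplicating rule R2) are counted once. All generator
randomness flows from one integer seed through numpy's PCG64.

## Known limitations

* Regiochemistry (e.g. C9 vs C12 oxygenation of linoleate) is not
  derived; it enters only through catalogue-supplied fragment formulas.
* Ether/plasmalogen PCs and non-PC lipid classes are out of scope.
* The mzML reader/writer speaks a minimal PSI-MS vocabulary (centroided
  spectra, selected precursor, 32/64-bit float arrays, optional zlib on
  read); vendor raw formats and profile data are unsupported.
* The head-group demethylation channel is computed as formate adduct
  minus methyl formate (60.0211), the standard PC channel; the label
  "[M−CH₃]⁻" follows field convention.
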