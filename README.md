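# oxpclib

A toolkit for the structural analysis of **oxidized phosphatidylcholines
(oxPCs)** by high-resolution mass spectrometry. Peroxidation of the
polyunsaturated sn-2 acyl of a PC produces a large family of hydroperoxides,
epoxides/hydroxides, ketones and chain-truncated aldehyde/carboxyl species;
most of them are absent from general-purpose lipid databases, so nontargeted
studies of lipid peroxidation need a purpose-built structural library and
annotation rules. `oxpclib` provides:

* **Exact-mass and adduct arithmetic** (`oxpclib.chem`) — elemental
  compositions with distinct ²H/¹⁸O symbols, monoisotopic masses,
  electron-corrected m/z for [M+HCOO]⁻, [M−H]⁻ and [M+H]⁺, and ¹⁸O
  substitution (+2.00425 Da per label).
* **A structural library builder** (`oxpclib.library`) — a parser for the
  shorthand grammar (`PC16:0_18:2;O2`, `;OOH`, `;oxo`, `;O-H2`, `;COOH` …),
  a bundled 155-entry modification catalogue covering the oxidation classes
  of linoleate, arachidonate and docosahexaenoate, and its expansion over
  sn-1 chains {16:0, 18:0, 18:1} into a 465-species MS/MS library with
  rule-predicted diagnostic fragments:
  * negative mode (from [M+HCOO]⁻): sn-1 carboxylate, oxidized-acyl
    carboxylate [oxFA]⁻ and its water loss, and head-group demethylation
    [M−CH₃]⁻ (−60.0211 from the formate adduct);
  * carboxyl-terminated species (from [M−H]⁻): trimethylamine loss
    [M−H−N(CH₃)₃]⁻ (−59.0735) and the methylated acyl [oxFA+CH₂]⁻;
  * positive mode (from [M+H]⁺): H₂O loss for epoxides/hydroxides, H₂O₂
    loss for hydroperoxides — the neutral losses that split these isobaric
    +2O functional isomers.
* **A differential feature workflow** (`oxpclib.peakproc`) — centroid
  feature detection (5 ppm, S/N 3, minimum intensity 10⁴, ≥3 scans,
  +1.00336 Da isotopologue check), median-shift RT alignment (±0.1 min),
  [M−H]⁻/[M+HCOO]⁻ adduct grouping and the oxidized/nonoxidized
  area-ratio > 2.0 background subtraction.
* **Annotation** (`oxpclib.annotate`) — precursor matching, diagnostic-ion
  scoring with an evidence floor (sn-1 ion plus one other diagnostic), and
  positive-mode functional-isomer discrimination (H₂O₂ loss takes
  precedence over H₂O loss).
* **Semiquantification** (`oxpclib.quant`) — peak-area ratios against the
  PC15:0/18:1-d7 internal standard ([M+H]⁺ 753.6134, derived from its
  composition), oxPC percentage of total PC signal, and log₁₀ + autoscale
  normalization for heat maps.
* **¹⁸O labeling and MS imaging** (`oxpclib.labeling`) — MALDI-MS/MS
  transition design for ¹⁸O-labeled oxPCs (e.g. PC34:2;¹⁸O2
  794.5 → 774.5 via loss of H₂¹⁸O), binomial labeling-efficiency
  estimation from isotopologue envelopes, 0–100 pseudocolor ion-image
  rendering and an artificial-oxidation screen.
* **A synthetic-data generator** (`oxpclib.synthetic`) — seeded,
  ground-truthed paired runs, DDA-style MS/MS with decoys, and zonated
  MSI grids, used throughout the test suite.

## Worked example

Predict the diagnostic ions of a truncated carboxyl-terminated oxPC:

```
$ oxpc predict-fragments 'PC16:0_9:0;COOH' --polarity neg
PC16:0_9:0;COOH  C33H64NO10P  [M-H]- m/z 664.4195
    R1    255.2330  [16:0]-
    R5    605.3460  [M-H-N(CH3)3]-
    R6    201.1132  [9:0;COOH+CH2]-
```

The species ionizes as the deprotonated anion (m/z 664.4195); the sn-1
palmitate anion (255.2330), the trimethylamine loss (605.3460) and the
methylated azelaoyl fragment (201.1132) are the three ions an analyst
would check to accept the annotation. For the ¹⁸O-labeled imaging
transition of the doubly oxygenated PC 34:2:

```
$ oxpc label 'PC16:0_18:2;O2' --n-labels 2
PC16:0_18:2;O2;[18O]2: 794.5 -> 774.5 (-H2[18O], isolation 1.0)
```

i.e. monitor the labeled [M+H]⁺ at nominal m/z 794.5 and its H₂¹⁸O-loss
product at 774.5. A full synthetic screen runs end to end with:

```sh
oxpc simulate --seed 7 --n-spikes 10 --decoys 40 --out-dir runs/
oxpc screen runs/oxidized.mzML runs/nonoxidized.mzML --out screen.csv
```

`screen.csv` lists each retained compound with its m/z, RT, areas in both
channels and the best library annotation with its evidence score.

## Layout

```
src/oxpclib/        chem, library, peakproc, annotate, quant,
                    labeling, synthetic, msio, cli
src/oxpclib/data/   default_catalogue.csv (155 oxidized-acyl entries)
docs/methods.md     models, parameters, design choices, limitations
tests/              unit, property and acceptance tests
```
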