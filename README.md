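# metalscreen

Analysis toolkit for combinatorial "click-to-metal-complex" screening
campaigns: it enumerates triazole-ligand libraries from building-block
registries, assembles metal-complex compositions, characterizes them from
LC-MS runs (target-ion matching, UV peak integration, conversion%), analyses
plate-based antibacterial/toxicity/catalysis screens (MIC calling, 4PL
CC50/HC10 fits, therapeutic indices, transfer-hydrogenation endpoints), and
trains a fingerprint-SVM activity model. A synthetic-data module generates
every input the pipeline consumes — with ground truth attached — so the whole
workflow is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `metalscreen.library_design` | building blocks, triazole coupling (amine + alkyne + 2N − 2H), Cartesian enumeration, scaffold compatibility, complex assembly, plate maps |
| `metalscreen.formula` | exact integer elemental-composition arithmetic, Hill notation |
| `metalscreen.mass_iso` | monoisotopic masses, isotope-pattern convolution (Ru/Ir/Re/Br envelopes), expected ion species (parent cation, MeCN-adduct dication), m/z |
| `metalscreen.lcms_pipeline` | peak detection, EIC extraction, UV↔MS matching, conversion% (area-percent / aggregate / normalized-total), library characterization tables |
| `metalscreen.screening_analytics` | dilution grids, % of control, MIC calling, activity/toxicity classification, 4PL dose-response fits, therapeutic indices |
| `metalscreen.kinetics` | Δfl / Δabs endpoint summaries, hit thresholds, solution-stability % change |
| `metalscreen.ml_sar` | 598-bit fingerprint emulation, stratified 5-fold linear-SVM CV, support-vector feature importance, descriptor correlations |
| `metalscreen.synthetic_data` | seeded generators: chromatograms, MIC plates, dose-response curves, bit-rule activity datasets |

## CLI

```bash
metalscreen enumerate --class Tz-4-P --out ligands.csv
metalscreen assemble --ligands ligands.csv --out complexes.csv
metalscreen masses --complexes complexes.csv --out ions.csv
metalscreen lcms --runs runs/ --complexes complexes.csv --mode area-percent --out characterization.csv
metalscreen mic --plates plates.csv --threshold 10 --out mic.csv
metalscreen ti --out ti.csv                      # shipped lead-compound table
metalscreen kinetics --traces traces.csv --assay coumarin --out summary.csv
metalscreen sar train --data dataset.csv --folds 5 --seed 7 --out report.json
metalscreen simulate --conversion 75 --noise-sd 0.5 --seed 1 --out simdir/
```

Chromatogram runs use a plain two-file dialect per compound:
`<id>.uv.csv` (`time_min,a254`) and `<id>.ms.csv`
(`scan_time_min,mz,intensity`, long format).

Registries are CSV (`id,role,smiles,formula,name`); formulas use Hill
notation (`C14H12N4`). Default registries for the 24×4 and 8×12 campaigns
and the five metal scaffolds ship with the package
(`metalscreen.registry`); building blocks not identifiable by name are
marked `placeholder` and can be edited freely — enumeration counts and
pipeline behaviour do not depend on the specific formulas.

## Notes on conventions

- MIC: lowest concentration of the contiguous fully-inhibited block
  (growth ≤ 10 % of control, configurable) reaching the top of the grid;
  no inhibition at the top ⇒ censored, rendered `-`.
- Therapeutic index: `min(CC50, HC10) / MIC`, rounded half away from zero;
  censored HC10 drops out of the numerator; MIC ranges give TI ranges.
- Dilution-grid reporting: ≥ 1 µM to 3 significant figures, < 1 µM to 2
  (50, 25, 12.5, 6.25, 3.13, 1.56, 0.78, 0.39, …).
- Conversion%: matched UV peak area over total UV peak area at 254 nm;
  `aggregate` adds parent + adduct species, `normalized-total` renormalizes
  over MS-identified peaks only.
- m/z includes the electron mass (`(m − z·mₑ)/z`); isotope patterns are
  centroid-merged at 0.01 Th and pruned at 1e-4 of the base peak by default.
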