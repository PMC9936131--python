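# flashmap

Analysis pipeline for time-resolved serial crystallography of ligand
release: isomorphous difference maps, Pearson-correlation segmentation
of pump-probe time delays, apo-normalized ligand-release curves,
extrapolated structure factors with photoactivation-level estimation,
and backbone displacement fields.

The scientific setting is a protein-ligand complex in which a
photoswitchable ligand (an azobenzene analogue bound at the colchicine
site of the tubulin dimer is the motivating system) is flipped by a
laser pulse from its high-affinity *cis* to its low-affinity *trans*
form inside the crystal.  Only a fraction A of molecules is activated,
so every "light" dataset is a population average.  The pipeline answers
three questions from merged amplitudes alone:

1. **When does what happen?**  Difference maps
   (F_obs^light − F_obs^dark) with dark-model phases are integrated
   around atoms and the per-atom integrals of every delay pair are
   Pearson-correlated; blocks of elevated correlation mark delays
   sharing one structural intermediate.
2. **When does the ligand leave?**  Negative density around the ligand
   (1.5 Å, 3 σ), normalized between the quietest delay (0) and the
   occupancy-rescaled apo dataset (1).
3. **How much was activated?**  Extrapolated amplitudes
   F_extra = (100/A)(F_light − F_dark) + F_calc are scanned over
   decreasing A; negative density on the ligand nitrogens in
   2F_extra − F_calc maps stays at zero until the dark state is
   over-subtracted, and the intersection of the two linear parts of
   that curve (fitted against the multiplier 100/A) gives A.  A control
   estimator uses the re-appearance of dark-state features as positive
   density.

A seeded synthetic two-state toy crystal (30 pseudo-residue scatterers
plus an 8-atom ligand, nine log-spaced delays from 1 ns to 100 ms,
complex-structure-factor population mixing, √N merging noise) provides
ground truth for every stage; `docs/methods.md` describes the model and
its limits.

## Worked example

```python
import flashmap as fm
from flashmap.synth import SyntheticScenario, simulate_dataset

data = simulate_dataset(SyntheticScenario(seed=1))   # truth: A = 22%
report = fm.run_timeline(data)
print(report.blocks)
print([round(a, 1) for a in report.activation_per_delay[:3]])
print(report.release.normalized.round(3))
```

prints

```
[[0, 1, 2], [3, 4, 5], [6, 7, 8]]
[23.6, 20.2, 22.3]
[0.037 0.017 0.031 0.    0.013 0.001 0.265 0.253 0.275]
```

i.e. the nine delays segment into the three designed kinetic blocks
(ligand relaxed → pocket open → apo), the first-block activation
estimates bracket the true 22% (the per-delay spread over all nine
delays is 14–24%, mean 19.1%, with the re-appearance control at
21.8%), and the release curve is quiet through the microseconds before
jumping when the ligand leaves in the millisecond block.

The same analysis as a narrative, with tables and figures under
`results/`:

```bash
python analysis/01_simulate.py            # models + MTZ + manifest
python analysis/02_difference_maps.py     # k/B scaling + CCP4 maps
python analysis/03_timeline_correlation.py# correlation blocks + release
python analysis/04_activation_level.py    # activation scans per delay
python analysis/05_backbone_and_thermo.py # displacement vectors, ~4300x
```

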