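# chromarch

Analytics and modelling for the 3D organisation of early-embryo genomes:
how heterochromatin-protein (HP1-class) interactions establish
pericentromeric clustering (the Rabl configuration) and the B
compartment, and what is lost when they are depleted.

The package has three layers, all exercisable on synthetic data with
planted, recoverable structure:

1. **Hi-C analytics** — binned contact maps (dense text / triplet TSV),
   ICE balancing, contact-probability scaling P(s) with exponent fits,
   log2 differential maps, A/B compartment scores (leading eigenvector of
   the per-arm O/E correlation matrix), score-sorted saddle matrices with
   corner compartment strengths (strength_B = BB/AB, strength_A = AA/AB,
   overall = sqrt(AA·BB)/AB), compartment switching, and diamond
   insulation with TAD-boundary calls.
2. **A/B/C copolymer nuclear model** — chromosomes as chains of
   compartment (A/B) and pericentromeric/telomeric (C) beads in a
   cylindrical nucleus whose apical cap attracts C beads; Metropolis
   Monte Carlo with square-well attractions; a *mutant transform* that
   scales the C-C and C-surface attractions (heterochromatin loss)
   while leaving arm energies untouched; ensemble contact/distance maps
   and phase sweeps of attraction strength.
3. **Inverse energy inference** — damped iterative Boltzmann inversion
   of per-pair bead interaction energies (40-kb beads) so that the
   simulated map reproduces a target contact map, with per-class
   (A-A / A-B / B-B) summaries.

Genomic peak/annotation statistics (BED dialects, overlap partition,
box-plot width summaries, peak-to-compartment assignment) round out the
pipeline.

## Worked example

Generate a control/knockdown-like pair of synthetic Hi-C maps sharing a
compartment profile, where the perturbed condition has selectively
weakened B-B contacts (factor 0.8) — then recover that factor with the
compartment pipeline:

```python
import numpy as np
from chromarch import (SyntheticMapSpec, paired_condition_maps, balance,
                       compartment_score, saddle)

spec = SyntheticMapSpec(n_bins=200, depth=1_000_000, seed=1)
(ctrl, truth), (kd, _) = paired_condition_maps(spec, b_weakening=0.8)

reports = []
for cmap in (ctrl, kd):
    m = balance(cmap, method="none")          # generator has uniform coverage
    track = compartment_score(m, orientation=truth.scores)
    reports.append(saddle(m, track, n_quantiles=10).strength())

print(f"strength_B control  {reports[0].strength_B:.3f}")
print(f"strength_B weakened {reports[1].strength_B:.3f}")
print(f"ratio               {reports[1].strength_B / reports[0].strength_B:.3f}")
```

Output:

```
strength_B control  2.134
strength_B weakened 1.646
ratio               0.771
```

The B-compartment strength ratio recovers the planted 0.80 within the
sampling noise of the Poisson counts (averaging replicate map pairs
tightens it to 0.80 +- 0.01), while strength_A stays within a few
percent of unchanged — a selective B-compartment effect, the map
signature this package is built to quantify.

The same stages are available from the shell:

```sh
chromarch synth pair --seed 1 --out demo        # paired maps + ground truth
chromarch compartments --map demo.control.txt --out demo.ctrl
chromarch saddle --map demo.control.txt --track demo.truth.bedgraph --out demo.sad
chromarch simulate --template genome --mutant-factor 0.2 --seed 1 --out demo.mut
```

Every command writes a `*.manifest.json` recording the subcommand,
resolved parameters, input digests and seed.

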