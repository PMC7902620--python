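# idpchain

Analysis toolkit for conformational ensembles of intrinsically disordered
proteins (IDPs), with synthetic polymer-chain generators that provide exact
ground truth for validating every analysis step.

IDPs do not fold into a single structure; they are described by ensembles of
conformations, typically produced by molecular-dynamics sampling and
validated against ensemble-averaged experiments (small-angle X-ray
scattering, NMR chemical shifts). `idpchain` implements the quantitative
layer of that workflow for Cα-trace ensembles:

- **Global size** — per-frame radius of gyration R<sub>g</sub> and its
  distribution.
- **Chain stiffness** — the bond-vector orientational correlation
  C(s) = ⟨**n**<sub>i</sub> · **n**<sub>i+s</sub>⟩, fitted at small s by
  C(s) = e<sup>−s/k</sup>; the persistence length is l<sub>p</sub> = k ×
  0.38 nm (0.38 nm is the consecutive Cα–Cα spacing). A log–log tail fit
  detects power-law decay C(s) ~ s<sup>a</sup> in stiffer chains.
- **Scaling statistics** — mean internal distances R<sub>s</sub> fitted by
  the Flory law R<sub>s</sub> = R<sub>0</sub>s<sup>ν</sup> in two
  residue-separation regimes (s ≤ 10 and s > 10), since IDPs show common
  local statistics but sequence-dependent global scaling. Reference values:
  ν = 0.5 for an ideal Gaussian coil, ν ≈ 0.588 for a self-avoiding walk.
- **Scattering agreement** — the reduced
  χ² = (k−1)<sup>−1</sup> Σ [(I<sub>expt</sub> − (c·I<sub>sim</sub> +
  bgd))/σ]² with scale c and flat background bgd fitted in closed form;
  plus a Gaussian-chain (Debye) form factor and a point-scatterer Debye sum
  over coordinates for desk-scale intensity calculation, and a
  growing-prefix χ² convergence diagnostic.
- **Chemical shifts** — secondary shifts ΔCS = CS − CS<sup>RC</sup>
  (random-coil reference), per-atom referencing-offset correction
  CS<sup>calc</sup> → CS<sup>calc</sup> + O (O from a slope-1 regression),
  and the per-atom RMSE between experimental and calculated ΔCS.
- **Replica-exchange planning** — the solute-tempering ladder
  λ<sub>i</sub> = exp(−i/(n−1) · ln(T<sub>max</sub>/T<sub>0</sub>)),
  exchange-probability bookkeeping, five-block standard errors, and
  normalised autocorrelation functions for comparing sampling efficiency.
- **Synthetic ensembles** — freely jointed, freely rotating (exact
  C(s) = g<sup>s</sup>) and pivot-sampled self-avoiding chains, plus paired
  synthetic SAXS and shift data with known scale/background/offset, used as
  oracles throughout the test suite.

## Worked example

Generate a semiflexible chain whose ground-truth stiffness matches a
persistence length of 0.61 nm (successive-bond cosine g = 0.535, so
k = −1/ln g ≈ 1.60), then recover it:

```python
import numpy as np
from idpchain import (ChainModelSpec, generate_freely_rotating,
                      orientational_correlation, fit_persistence,
                      internal_distance_profile, fit_flory_two_regime)

spec = ChainModelSpec(n_residues=101, n_frames=5000, bond_cos=0.535, seed=1)
ens = generate_freely_rotating(spec)

cs = orientational_correlation(ens, s_max=6)
fit = fit_persistence(cs, s_fit_max=4)
print(f"k = {fit.k:.2f}, l_p = {fit.l_p:.3f} nm")

flory = fit_flory_two_regime(internal_distance_profile(ens), split=10)
tail = flory.regimes[1]
print(f"tail exponent nu = {tail.nu:.3f} +/- {tail.nu_stderr:.3f}")
```

prints

```
k = 1.61, l_p = 0.612 nm
tail exponent nu = 0.511 +/- 0.000
```

`l_p` ≈ 0.61 nm recovers the generator's stiffness (k ≈ 1.60 Cα pairs ×
0.38 nm), and the tail Flory exponent ≈ 0.5 confirms the chain behaves as
an ideal coil at large separations — a freely rotating chain has local
stiffness but no excluded volume (the small excess over 0.5 is the residual
short-range stiffness inside the s ∈ (10, 100] fit window).

The same pipeline is available from a shell:

```bash
idpchain generate --model frc --n-res 101 --n-frames 5000 --g 0.535 \
         --seed 1 --out traj.pdb
idpchain chainstats --traj traj.pdb --out stats.json
idpchain hremd --t0 300 --tmax 450 --n 10 --out ladder.tsv
```

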