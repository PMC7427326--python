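# polconvoy

Stochastic convoy model of RNA polymerase I (RNAPI) transcription
elongation, with the profile analytics needed to compare it against
nucleotide-resolution polymerase occupancy data.

## The problem

RNAPI transcribes the ~7 kb pre-rRNA gene carrying ~50 engaged polymerases
at a time. Occupancy maps of elongating RNAPI (CRAC/NET-seq-style 3′-end
densities) show a strong 5′ bias and a striking ~80-nt periodicity of peaks
and troughs over the structured 5′ leader, implying sequence-programmed
variation in elongation speed. This package implements a quantitative model
of that behaviour for anyone studying polymerase traffic, cotranscriptional
RNA folding, or torsional coupling on highly loaded genes.

## The model

Each polymerase performs a Brownian-ratchet walk: at every time step
(dt = 0.008 s) it draws a velocity from a two-component Gaussian mixture

    V ~ (1-p) N(V_int, (0.4 V_int)^2) + p N(0.9, 1.5^2),   p = 0.078,  V_int = 50 nt/s

and jumps ±1 nt with probability min(1, |V| dt) in the direction of
sign(V). Three modifiers shape V:

* **DNA torsion.** The rDNA rotates through the polymerase array, so
  relative displacement of neighbours over/underwinds the intervening
  helix. With anchor separations x⁺, x⁻ recorded at engagement, current
  gaps dx⁺, dx⁻, bubble size b = 11 nt and stiffness c = 500
  (c = −V_int / (100/(100+r) − 100/(100−r)) at r = 5 % overwind):

      V ← V + c(1 − (x⁺−b)/(dx⁺−b)) − c(1 − (x⁻−b)/(dx⁻−b))

* **Low-entrainment region (LER).** Over the first 2 kb polymerases can
  still rotate around the template: torsion engages linearly with position
  (50 % at +1000), anchors relax toward current geometry, and a ≤20 %
  friction penalty applies to the intrinsic velocity.

* **Nascent-RNA elements.** Strong structure folding behind the enzyme
  (rolling 65-nt window, offset 15 nt; threshold ΔG ≤ −11 kcal/mol)
  promotes forward translocation with strength 1.25·|ΔG|; the 8-nt RNA:DNA
  hybrid in the bubble opposes it with strength 0.48·1.25·|ΔG|.

Initiation is stochastic (0.8 s⁻¹) gated by a clear 100-nt initiation
region; a 38-nt footprint enforces hard-core exclusion; blocked forward
jumps are logged as collisions and successful backward jumps as backtrack
steps.

Everything runs on synthetic data with known ground truth: hairpin-cassette
units (ten strong stems, 80-nt apex spacing), analytic and
sequence-computed folding-energy tracks, occupancy profiles with planted
peaks, and intron genes with planted splice motifs. Analytics include the
erf detection cutoff, in-silico read sampling, Blackman smoothing,
peak/trough calling, metaplots, autocorrelation, landscape perturbations, a
3⁵ parameter sweep, and the 3′-splice-site ΔΔG window-of-opportunity
analysis.

## Worked example

```python
import polconvoy as pc
from polconvoy.simulate import run_replicates
from polconvoy.observe import occupancy_profile, backtrack_collision_stats
from polconvoy.profiles import smooth_blackman, call_extrema, autocorrelation

seq, truth, landscape = pc.study_landscape()        # 7-kb synthetic unit
params = pc.ModelParams.variant("full")             # torsion + LER + RNA elements
ensemble = run_replicates(landscape, params, n_replicates=8, base_seed=1)

profile = smooth_blackman(occupancy_profile(ensemble), 20)
peaks, troughs = call_extrema(profile, order=35)
_, spacing = autocorrelation(profile.values[:2000], max_lag=200)
stats = backtrack_collision_stats(ensemble)

print(f"engaged polymerases per unit: {ensemble.mean_polymerase_count():.1f}")
print(f"backtracked fraction:         {stats['backtracked_fraction']:.4f}")
print(f"called peaks / troughs:       {len(peaks)} / {len(troughs)}")
print(f"dominant peak spacing (5' 2 kb): {spacing} nt")
```

prints

```
engaged polymerases per unit: 44.7
backtracked fraction:         0.0084
called peaks / troughs:       89 / 90
dominant peak spacing (5' 2 kb): 80 nt
```

i.e. the full model loads ~45–50 polymerases on the unit (the
electron-microscopy calibration), keeps ~1 % of them in a backtracked
state, and its occupancy profile inherits the 80-nt periodicity of the
folding landscape.

The same stages are scriptable from the shell:

```bash
polconvoy synth --kind hairpin-unit --seed 1 --out unit.fasta
polconvoy tracks unit.fasta --window 65 --offset 15 --out-prefix unit
polconvoy simulate --landscape unit.fold.bedgraph --replicates 8 --seed 1 --out-prefix run
polconvoy analyze run.occupancy.bedgraph --order 35 --out-prefix run
```

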