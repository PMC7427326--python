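# Methods

## Model

One transcription unit of `unit_length` = 7000 nt carries a variable
number of polymerases, each described by its active-site position, its
historical maximum position, and two torsional anchors (the separations to
its downstream and upstream neighbours recorded at engagement). Time
advances in steps of `dt` = 0.008 s = 1/120 s, chosen so that no plausible
velocity draw moves more than one nucleotide per step; per step and per
polymerase (in a fresh random order each step) a velocity is assembled as

    V = V_random · (1 − 0.2·e) + e·T + S − H

with

* `V_random` — mixture draw: with probability 0.078 from N(0.9, 1.5²)
  (paused), otherwise from N(50, 20²) (elongating); draws may be negative.
* `e` — torsional engagement, min(1, pos/2000): the low-entrainment region
  (LER) where enzymes can still rotate around the template. The (1−0.2·e)
  factor is the rotation-friction penalty, applied progressively and
  retained at 20 % beyond the LER; together with the RNA-element terms it
  puts the full model's mean velocity near the ~40 nt/s overall average
  implied by cellular ribosome output.
* `T` — elastic-rod torsion, `c(1−(x⁺−b)/(dx⁺−b)) − c(1−(x⁻−b)/(dx⁻−b))`
  with c = 500 and bubble b = 11 nt; a side is zero when that neighbour is
  absent. While e < 1 the anchors relax toward the current gaps with rate
  (1−e) s⁻¹, and anchors are re-recorded whenever a neighbour appears or
  disappears, so the relaxed state (T = 0) is always well defined.
* `S` — structure term, 1.25·|ΔG_fold| where the folding track at the
  current position is at or below −11 kcal/mol, else 0.
* `H` — hybrid term, 0.48·1.25·|ΔG_hybrid| (always opposing).

The enzyme jumps one nucleotide in the direction of sign(V) with
probability min(1, |V|·dt). Forward jumps that would bring the downstream
gap under the 38-nt footprint are blocked and logged as collisions;
backward jumps are blocked at position 0 or against the upstream footprint,
and successful ones are logged as backtrack steps (the historical maximum
is retained, so a polymerase is "backtracked" while pos < max_pos).
Initiation attempts occur at rate 0.8 s⁻¹ and succeed when no polymerase
occupies the first 100 nt; this initiation region, taken from the
three-polymerase stall geometry (initial separation 100 nt), reproduces the
observed loading of ~50 enzymes per unit and ~140-nt mean spacing, which a
footprint-sized clearance region cannot. Runoff removes enzymes at the 3′
end. Two default-off options exist: premature termination within the LER
(rate `p_term`), and topoisomerase-I action that moves an anchor one full
turn (10.5 nt) toward the current gap when the gap exceeds 25 nt.

Replicates are independent seeded runs of 2000 s; 200 equally spaced
snapshots are recorded and the first 500 s are excluded from summaries as
burn-in. The stepping loop is implemented twice with identical update
rules: a readable pure-Python `Convoy` (the reference, used by the unit
tests, including a freeze-a-polymerase hook for exclusion tests) and a
numba kernel used by `run_replicates` for production scale; the two are
reconciled statistically (single-enzyme mean velocity, loading, event
rates) since they consume different random streams.

## Energy tracks

The folding track assigns to template position i the minimum free energy
of the `window` = 65 transcript nucleotides extruded behind an active site
at i, skipping the `offset` = 15 nt still inside the enzyme:
value(i) = MFE(seq[i−offset−window+1 … i−offset]); the first
window+offset−1 positions are undefined. The window-end-minus-offset
convention is a declared ±1 choice. The builtin MFE engine is an exact
dynamic program over nested Watson-Crick structures scoring only
consecutive stacked pairs with the published RNA/RNA nearest-neighbor
stack table, minimum hairpin loop 3, no pseudoknots, no GU wobble, and no
loop penalties: a deliberately transparent model that is provably equal to
exhaustive enumeration (a property the tests assert on ≤12-nt sequences).
Because it omits loop costs it over-stabilizes: random 65-nt windows score
around −25 to −30 kcal/mol where a full thermodynamic folder gives −10 to
−15. External folders (anything printing a ΔG, e.g. hybrid-ss-min or
RNAfold) and precomputed tracks plug in through the same backend contract.
The hybrid track sums published RNA/DNA nearest-neighbor duplex energies
over an 8-nt rolling window. GC features report the G+C fraction 10 nt
upstream (the transcription-bubble side), downstream, or both. Tracks use
0-based half-open coordinates internally, bedGraph 0-based and wiggle
1-based on disk.

## Synthetic study conditions

`gen_hairpin_unit` plants ten perfect inverted repeats (stem 25, loop 6,
GC 0.7) with 80-nt apex spacing starting at position 100 in a uniform
random 7-kb unit — the geometry of the structured 5′ leader. Two
landscapes drive the simulations:

* `study_landscape` — the analytic surrogate: a piecewise-linear sawtooth
  between −20 (strong, aligned with where a planted stem has fully
  emerged: apex + stem + offset) and −2 kcal/mol (weak), period 80 nt,
  spanning the measured amplitude range of the structured leader so the
  −11 kcal/mol threshold is crossed every period; it is zero before the
  first stem emerges (~position 128), matching both the rolling-window
  geometry and the observed weakness of 5′-proximal structure. Paired
  with the sequence-derived hybrid track. Used for the loading
  calibration, the occupancy-extrema analysis and the leader-weakening
  perturbations: its velocity budget reproduces the ~40 nt/s overall
  average and ~45–50 enzymes per unit.
* `computed_landscape` — the builtin rolling-MFE track of the generated
  sequence. Structure sits below threshold almost everywhere (the builtin
  scale is strong), which mirrors the genuine folding profile's coverage;
  used for the model-variant ordering analysis (backtracking/collision
  phenomenology), where it reproduces the orderings robustly. Its
  over-strong ΔG scale under-loads the unit (~30 enzymes), which is why it
  is not used for the loading calibration — a documented limitation of the
  stacks-only folder, not of the simulator.

The sawtooth surrogate emulates amplitude, period and phase of the real
folding profile but not its irregularity, and the generators draw linkers
uniformly at random, so passing tests demonstrate mechanism and
implementation correctness, not genome-scale realism. Intron fixtures
plant consensus motifs (donor GTATGT, branch point TACTAAC, acceptor AG)
at exact offsets and rejection-sample the background so no accidental
donor/branch-point exists anywhere and no accidental acceptor exists
between branch point and 3′SS; decoys are planted relative to the branch
point. Read-count fixtures are single multinomial draws (counts conserve
the read total exactly).

## Observation and analytics

Occupancy is the unit-area histogram of post-burn-in active-site
positions (no footprint smearing; the experimental 3′-end signal is
point-like). The detection cutoff multiplies by 0.5(1+erf((ρ−ρ₀)/σ)) and
renormalizes; defaults are scale-free (ρ₀ = 20th percentile of positive
values, σ = ρ₀/2). In-silico reads are multinomial. Backtracked fraction
is the share of polymerase-snapshots behind their historical maximum;
colliding fraction the share in hard contact (downstream gap equal to the
footprint); blocked forward attempts are reported separately as a rate per
polymerase-second, since "collision" has no unique operational definition.
For regional perturbations both fractions are scoped to the perturbed
interval — a 700-nt effect is otherwise diluted ten-fold on a 7-kb unit.

Profile analytics follow the experimental pipeline: fraction-of-reads
normalization with a 10⁻⁷ pseudocount, centered Blackman smoothing
(window 10, reflection padding — edges therefore lose a little mass),
strict local-extremum calling within ±order (typical orders 50, 35, 20;
plateaus report their leftmost point; boundary positions never qualify),
feature-centered metaplots with boundary truncation and optional
per-window normalization, mean-subtracted autocorrelation with the first
positive-lag local maximum as the dominant spacing, and a shuffle control
re-processed identically. Rank tests wrap the standard two-sided
Wilcoxon/Mann-Whitney machinery (exact for n ≤ 20 without ties, normal
approximation with continuity correction otherwise) and Student's t.

The contribution decomposition averages |S|, |H| and |e·T| per visited
nucleotide and reports each as a percentage of their sum.

## Splice-site analysis

Intron prediction is branch-point-first: every branch-point motif hit is
paired with the nearest upstream non-overlapping donor and the first
acceptor at least 4 nt past the branch point's last nucleotide; calls
longer than `max_intron_len` (default 1000 nt, a configurable assumption —
no maximum donor–branch-point distance is inherent to the algorithm) are
dropped. Skipped-acceptor candidates are consensus acceptors between
branch point + 4 and 40 nt short of the annotated 3′SS. The kinetic
"window of opportunity" is quantified as ΔΔG(x) = ΔG(3′SS+x) − ΔG(3′SS)
and compared between site classes by rank-sum on per-curve means within
±10 nt of +60 nt. Strict consensus strings stand in for trained
position-weight matrices (the matrices are not published); the annotated
genome-wide benchmark is therefore out of scope here.

## Numerical choices and limitations

* Sign convention: ΔG is stored signed (negative = stable); the simulator
  uses magnitudes with directions fixed by the stated physics (structure
  promotes, hybrid opposes).
* Torsion terms are capped at ±5·V_int; gaps at or below the bubble length
  (unreachable while the footprint holds) saturate at the cap.
* Velocity is resampled every step (no persistence); the sampled value,
  not just the mean, carries the LER friction penalty.
* Random per-step update order avoids directional bias; all randomness is
  generator-seeded and replicates use consecutive seeds.
* dt-halving (0.004 vs 0.008) leaves particle number, mean separation and
  the backward-jump rates of the torsion-free components unchanged within
  Monte-Carlo error. The backtracked-state *fraction* of torsion-coupled
  models is not dt-robust (~30 % shift): it depends on the tail of the
  neighbour-gap distribution, which carries an O(dt) discretization error
  from the sequential update. Comparisons of that statistic are therefore
  only made between models run at the same dt.
* Backtrack depth is unbounded; there is no explicit transcript-cleavage
  state. Continuous polymer mechanics, writhe/R-loops (captured implicitly
  via the folding track) and nucleosomes are out of scope.
* The sweep grid (3⁵ = 243 combinations over initiation rate, stiffness,
  structure strength, hybrid ratio and threshold) reports a scalar profile
  shape as the 5′ bias ratio: mean occupancy over the first 1500 nt over
  the mean of the remainder — threshold-free and monotone in the visible
  bias.
* Default test and acceptance runs use 4–16 replicates of 600–2000 s;
  these sizes give stable summary statistics for every asserted property
  (convergence checks showed no material change with more replicates).
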