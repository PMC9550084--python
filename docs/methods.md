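# Methods

## Model and assumptions

The package treats a folded structural unit as a statistical object: a
cloud of one effective atom per residue (the unweighted mean of the
residue's atom coordinates, hydrogens included when the file resolves
them).  The aqueous-folding ideal is a 3D Gaussian hydrophobicity field
over that cloud; the structure's actual hydrophobicity arrangement is
the per-residue sum of Levitt's pairwise contact function weighted by
intrinsic residue hydrophobicities.  Both are normalised into discrete
probability distributions over the residues, so Kullback–Leibler
divergence entropy (base 2; the ratio statistics are base-invariant and
this is tested) is a meaningful comparison.  The model assumes the unit
is compact enough for a single tri-axial Gaussian to be a sensible
ideal — it is weakest for highly elongated or multi-lobed units, which
is precisely why domains may be supplied as explicit residue ranges and
scored as their own units.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| Levitt cutoff `c` | 9.0 | Å | contact range of the pairwise hydrophobic interaction; `w(c) = 0` exactly |
| sigma convention | `max|coord_j|/3` | Å | after centring and rotating to principal axes, each σ makes the molecule span ±3σ |
| `--sigma-margin` | 0.0 | Å | optional padding added to the extent before the /3, widening the Gaussian support |
| K grid | 0.0–5.0 step 0.1 | — | search grid for the environment coefficient; reported optima in this class of analysis are multiples of 0.1 and K = 3 is already an extreme, so 5.0 leaves headroom |
| RD cut-off | 0.5 | — | `RD < 0.5` ⇒ hydrophobic core present; exactly 0.5 counts as no core (the criterion is strict `<`) |
| SS threshold | 2.3 | Å | maximal SG–SG distance accepted as a disulfide bond (standard bond geometry ≈ 2.05 Å) |
| hydrophobicity scale | Kyte–Doolittle, min–max scaled to [0,1] | — | any published scale can be substituted via a two-column file; O is invariant under positive rescaling, so only ordering/spacing matter |

## Numerical choices

- **PCA determinism.** Principal axes are ordered by descending
  variance and each axis's sign is fixed so its largest-magnitude
  loading is positive; degenerate (collinear/coincident) clouds raise
  instead of returning an arbitrary frame.
- **K-scan ties** break toward the smallest K: the least environmental
  modification consistent with the data (parsimony, and deterministic).
- **Epsilon floor.** Residues isolated beyond the contact cutoff (and
  the slight negative dip of Levitt's polynomial just inside `r = c`)
  can give zero or negative raw O entries; they are floored at 1e-12
  before normalisation, logged when triggered, so divergences stay
  finite.  The floor only matters for sparse synthetic clouds; compact
  proteins never trigger it.
- **Flat T.** If every `T_i` equals `T_MAX` the inverted complement is
  identically zero and `M(K) = T` for all K (the 0/0 inner
  normalisation is defined away); logged.
- **Fragment scoring.** The unit's field is reused unchanged; T and O
  are evaluated over the whole unit (O therefore includes interactions
  with residues outside the fragment), restricted to the fragment and
  renormalised; `T_MAX` in M is the fragment-local maximum.  Because
  the inner normalisation of `(T_MAX - T)` is scale-invariant, it is
  equivalent to compute it before or after the fragment renormalisation.
- **Profile-sum tolerance** is 1e-9; multi-model files use model 1 only
  and alternate locations keep conformer A (or blank).
- **Residue selection.** Author numbering with inclusive ranges, as
  fragment bounds are conventionally printed.  Range endpoints must
  exist; unresolved residues inside a range are skipped and reported,
  since IDRs frequently have unresolved stretches.  Waters are dropped;
  modified residues map to their parent type through an extensible
  table (MSE→MET etc.).

## Design decisions that were genuinely open

- The sigma convention is stated in the FOD literature only as
  "determined from the molecule"; the three-sigma principal-axis
  convention adopted here makes the molecule exactly fill the
  Gaussian's effective support, with `--sigma-margin` exposed for
  sensitivity checks.
- The self-term `j = i` is excluded from O: the contact function models
  pairwise interactions, and a self-term would add a constant
  `2·H_i^r` spike.
- The cohort outlier-elimination step replaces by-eye removal with a
  deterministic largest-|residual| loop (refit, recompute Pearson r,
  stop at the target).  It is reproducible but will not reproduce any
  particular hand-curated retained set, so published post-elimination
  correlation coefficients are demonstration outputs here, not test
  targets.
- Group labels at the `(RD_unit, RD_IDR)` quadrant boundaries follow
  strict `< 0.5` for core presence on both axes.

## The synthetic generator

`fodm.synthetic` emulates effective-atom clouds, not proteins: an
anisotropic Gaussian globule whose scale follows the `R ~ n^(1/3)`
packing law (axis ratios 1.2 : 1.0 : 0.85), or an ideal helix-like
curve (2.3 Å radius, 1.5 Å rise, 100°/residue).  Intrinsic
hydrophobicities are drawn from the active scale's 20 values and then
arranged: `core_sorted` ranks them by descending theoretical-profile
value (an ideal micelle), `inverted` by ascending (membrane-like
exposure), `shuffled` permutes them, and `k_target` manufactures O
outright as `M(K*)`, optionally blurred with Dirichlet noise
(concentration 5e4 in the shipped checks ≈ 0.4% relative perturbation
per residue).  Default condition sizes: 60 residues, 20 seeds per
regime.  What passing tests show: the statistics respond correctly to
known core geometry and recover known K.  What they do not show:
behaviour on real side-chain packing, secondary structure, or crystal
artefacts — no sterics or chain connectivity are modelled, and RD for a
regime is directional truth (low vs high), not a fixed number, because
it depends on the geometric realisation.

## Limitations

- Published per-structure RD/K values can only be matched within
  tolerances (±0.05 RD, ±0.3 K): the original intrinsic-hydrophobicity
  scale and exact sigma convention are not public.  The integration
  script performs this comparison when structure files are available;
  it is excluded from the offline suite.
- The Gaussian ideal is fitted, not optimised: no attempt is made to
  reweight σ or re-centre to maximise fit, by design.
- No solvent accessibility, no per-atom fields, no continuous
  (off-grid) K optimisation.
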