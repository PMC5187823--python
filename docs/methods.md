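# Methods

## Scope and model

The package analyses conformational ensembles of MaSp1(71–121)
mini-fibrils: 15 identical strands (3 stacked sheet planes × 5 strands,
antiparallel within each plane; AP = parallel stacking between planes,
AA = antiparallel) of the consensus sequence
`GQGAGAAAAAAGGAGQGGYGGLGSQGAGRGGLGGQGAGAAAAAAAGGAGQG`, with two
poly(Ala) crystal blocks (residues 71–81 and 108–121) flanking the
disordered Gly-rich spacer (82–107). Real ensembles of this system come
from microsecond temperature-replica-exchange MD; because no
trajectories are deposited, a synthetic generator reproduces the
*statistical structure* of the 300 K ensembles — which states the spacer
residues occupy and with what dihedral spread — without any force-field
dynamics.

## Backbone construction

Chains are built from internal coordinates by sequential natural
extension of reference frame (NeRF) placement with fixed ideal geometry
(Engh–Huber-like): N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
N–H 1.00 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
CA–C–O 120.8°. ω defaults to 180° (trans). The carbonyl O is placed in
the peptide plane anti to the next amide N; the amide H sits on the
external bisector of C(i−1)–N–CA, also in-plane. Terminal residues carry
undefined φ (first) / ψ (last), represented as NaN. Acetyl/amine caps
are not modelled; they affect none of the computed statistics.
Recomputing (φ, ψ, ω) from built coordinates reproduces the inputs to
< 1e-6° (property-tested), and the dihedral sign convention matches
biotite's reader on round-tripped PDB files.

Fibril assembly places copies of one extended-β strand
((φ, ψ) = (−135°, 135°)) on a rectangular lattice: 4.8 Å apart along the
in-sheet hydrogen-bond direction, 5.3 Å between stacked planes — the
standard β-sheet packing distances for polyalanine silk crystals. The
strand is first rotated into a canonical frame (long axis → x, mean
alternating carbonyl direction → y) so neighbouring strands face each
other with their amides; alternate strands are flipped 180° about the
stacking axis, and the axial register of flipped strands is chosen by a
deterministic scan (±4 Å, 0.25 Å steps) maximising inter-strand hydrogen
bonds, ties broken by steric clearance. Because ideal extended strands
twist, the rigid 51-residue template hydrogen-bonds (and is assigned E)
only over its central ~20 residues; this only affects the *starting*
structure, not sampled ensembles.

## Conformational states and sampling

Each state is a (φ, ψ) centre with Gaussian spread σ (degrees) and an
occupancy. Centres: β (−135, 135); PGII/3₁ (−90, 150); 3₁₀ right/left
(−70, −25)/(70, 25) — the observed ensemble peaks, offset from the ideal
(−60, −30)/(60, 30); α (−57, −47); turn (type I central residues
(−60, −30) then (−90, 0)); coil = uniform over the Ramachandran basin
rectangles I, II and their mirror images. Basin III (the 3₁₀/α region)
is *excluded* from coil deliberately: it is the territory of the explicit
helical states, and a coil state covering it would plant helical
dihedrals in ~a third of coil residues and corrupt every helix-recovery
statistic. Default σ = 10°.

Sampling is run-based by default: a run's state is drawn with
probability ∝ occupancy / run-length and extends over the state's
natural run length (3 residues for 3₁₀ and PGII — silk 3₁- and
3₁₀-helices are three residues long — 6 for α, 2 for turn, 1 for β and
coil). This weighting leaves each residue's *marginal* state probability
exactly equal to the library occupancy while producing contiguous
helical segments that can actually hydrogen-bond; fully independent
per-residue sampling (`mode="independent"`) is also available but
produces isolated helical residues that no hydrogen-bond-based assigner
can (or should) label as helix. Run-based sampling triples the variance
of occupancy estimates for 3-residue states (design effect = run
length), which the recovery tests account for. Two small edge effects
additionally make *assigned* helix fractions sit a few percent
(relative) below the state occupancy: runs clipped at the region
boundary can be 1–2 residues long (counted as state ground truth but
too short to be a helix), and assignment needs the full window
geometry; recovered 3₁₀ fractions for a 4.1% occupancy therefore centre
near 3.8–3.9%. Each chain is rebuilt
from its dihedrals and re-anchored by superposing its leading poly(Ala)
block on the template, so spacer disorder propagates to the second block
— the physical origin of fibril bending.

## Hydrogen bonds and secondary structure

Backbone H-bonds use the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, with a
strict conjunction of gates: E ≤ −0.5 kcal/mol, H···O ≤ 2.5 Å,
∠N–H···O ≥ 120°. Donors missing an amide H (chain-initial residues, or
PDB input without hydrogens) get the placement convention above. At most
the best-energy bond per donor is kept; intra-chain pairs with
|i−j| < 2 are excluded.

Assignment priority is H > G > E > B > T > C:

* **H** — two consecutive i→i+4 bonds mark residues i+1..i+4.
* **G** — two consecutive i→i+3 bonds mark i+1..i+3; in addition, any
  4-residue window carrying an i→i+3 bond or Cα(i)–Cα(i+3) < 7 Å whose
  central dihedrals match the type-III turn canon (±30°, one angle up to
  45°) is merged into the 3₁₀ class — type III *is* one turn of
  3₁₀-helix — marking the window residues whose own dihedrals lie within
  45° of the hand-consistent (∓60, ∓30). G runs shorter than 3 residues
  are dissolved (helices have length ≥ 3). Handedness per segment is the
  sign of the median φ (right < 0), with an ambiguity flag for
  mixed-sign segments with |median φ| < 10°.
* **E/B** — Kabsch–Sander parallel/antiparallel bridge patterns;
  ladders of ≥ 2 adjacent bridges become sheet (E), isolated bridges B.
* **T** — remaining turn windows typed by nearest Thornton canon
  (I (−60,−30,−90,0), I′, II (−60,120,80,0), II′, mirror images) with
  the ±30°/45° windows; no match → type IV. Type III is never reported
  as a turn.

Reported region fractions pool residue-frames:
100 × (residue-frames labelled ℓ) / (region residues × frames). Bridges
and π-helices are not reported (B residues count toward neither class,
so reported fractions sum to ≤ 100%).

## 3₁-helix (polyglycine II) detection

A residue qualifies ("X") when |φ| ∈ [70°, 90°] and |ψ| ∈ [140°, 150°]
(inclusive — the model-peptide centre (−90°, 150°) sits on the boundary
and must qualify); a 3-residue window is 3₁-helical when ≥ 2 residues
qualify *with a common φ sign* (a mixed-handedness triplet is not a
helix; the absolute values exist to admit both hands, not mixed
windows). Overlapping same-hand windows merge into maximal segments.
Occurrence over an ensemble replaces the original visual inspection with
this deterministic rule applied to a uniform random sample of frames
(default 400; without replacement when the sample fits), reported both
as the fraction of frames containing ≥ 1 segment and as segments per
frame, with 95% percentile-bootstrap intervals (default 1000 resamples)
over the sampled indicators. Composition tables tally qualifying-residue
identities separately for XX (adjacent) and XYX (separated) window
patterns, with bootstrap-over-frames errors.

Note the built-in tension inherited from the definitions themselves: the
PGII state centre (−90°, 150°) lies at the *corner* of the detection
window, so under Gaussian noise only ~25% of generated PGII residues
qualify per draw; occurrence estimates are therefore calibrated against
planted ground truth, not interpreted as absolute state populations.

## Fibril metrics

Each poly(Ala) block gets a right-handed frame from the SVD of its Cα
cloud: axis = first principal component (oriented N→C along the first
chain), sheet normal = third component. Bending total = angle between
block axes; out-of-plane = |asin| of axis-2's component along block-1's
normal; in-plane = angle between axis 1 and axis 2 projected onto
block-1's sheet plane. Block 1 anchors the decomposition. Constructed
pure bends of 5–60° are recovered within 2° (tested). Region RMSD
superposes each frame on the *full* backbone against the iteratively
converged ensemble average (superpose-all → re-mean, to < 1e-6 Å change,
max 100 iterations), so spacer values express mobility relative to the
global fibril frame. Superposition is always least-squares Kabsch with
proper rotations; RMSD summaries use the population (n) standard
deviation over frames.

## Chemical-shift classification

The packaged reference table stores every value as a closed ppm
interval (points are zero-width). Distance of an observed shift to a
class is 0 inside the interval, else the gap to the nearest endpoint
(minimum over multiple records of one class); classes are ranked
ascending and a difference < 0.2 ppm between the top two — the order of
the reported shift precision — sets the ambiguity flag. Secondary shift
Δδ = observed − coil reference midpoint. The Ala Cβ observed resonance
is kept as its two components (17.4 and 20.9 ppm: the disordered-3₁ and
β-sheet populations), never averaged. Gln Cα 52.7 ppm is genuinely
equidistant (1.3 ppm) from the β-sheet edge and coil; the classifier
reports that tie rather than resolving it.

## Numerical and scale choices

* Recovery ensembles in the acceptance suite use 500 frames of a single
  strand at σ = 5°: recovery contracts are stated in the small-noise
  regime where generated state identity is unambiguous, and a single
  strand suffices because all spacer statistics are intra-chain.
* Bootstrap defaults: 1000 resamples, percentile CIs, seeded.
* All stage randomness derives from one root seed split per stage
  (generation, frame sampling, bootstrap), making pipeline reports
  bit-reproducible.
* Collinearity guards use absolute thresholds (second singular value
  < 1e-8 Å) because extended strands are nearly one-dimensional.

## What the generator does and does not emulate

It reproduces per-residue state occupancies, contiguous helical runs,
dihedral spread about state centres, and the geometric consequences of
spacer disorder (bending, region RMSD contrast). It does *not* reproduce
force-field energetics, sequence-dependent state preferences (states are
placed independently of residue identity unless configured), inter-state
kinetics, β-sheet extension of the poly(Ala) blocks into the spacer, or
inter-strand correlations of spacer conformations. Passing recovery
tests therefore validate the *estimators* — assignment, detection,
occurrence and error statistics — not any claim about real silk
ensembles. Reported ensemble statistics from the original microsecond
trajectories (overall RMSD ≈ 9–11 Å, bending angles, Table-style spacer
percentages) are reachable only with real MD; the package's contracts
are parameter-recovery and property-based instead.
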