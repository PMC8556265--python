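# Methods

This note records the models behind each `chw` stage, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Structure handling and superposition

Parsing is delegated to gemmi; both PDB and mmCIF are read, and **author**
chain ids and residue numbers are canonical everywhere (channel residues are
conventionally cited in author numbering, e.g. Thr65 or Arg222 in Lsi1).
Alternate conformers are all retained; the highest-occupancy one (ties:
first encountered) is flagged primary, and every census, B-factor mean, and
geometric analysis uses primary conformers only. Hydrogens, when present,
are excluded from counts and B means. The entity census satisfies the
closure macromolecule + ligand + water atoms = non-H total by construction.

`superpose` aligns two chains' one-letter sequences with Biopython's
`PairwiseAligner` (global; match +1, mismatch −1, gap −2 — the compared
aquaporins are similar enough that any sensible scheme yields the same Cα
pairing, and the parameters are exposed for the cases where it would not),
then solves the least-squares rotation for the aligned Cα pairs with the
Kabsch/SVD method (via `scipy.spatial.transform.Rotation.align_vectors`).
One optional round of >2×RMSD outlier rejection with refit exists but is off
by default: published aquaporin-to-aquaporin RMSD values rarely state their
rejection scheme, so the default is the plainest definition, single-monomer
Cα with no trimming, and comparisons against published values carry a
±0.3 Å tolerance for this methodological ambiguity.

NPA-motif spacing is counted strictly between the last residue of the first
motif and the first residue of the second. When a sequence contains more
than two NPA occurrences, the pore pair is selected inside a spacing window
of [60, 200] residues (which covers both the aquaporin-like 108 and the
aquaglyceroporin-like 132); among in-window pairs the most centrally placed
wins, and a tie between pairs with different spacings is an error rather
than a guess.

## Lattice-translocation-defect model

Two identical lattices offset by a fractional translation t_d with
population fractions κ and 1−κ give

    f(h) = (2κ² − 2κ + 1) + 2κ(1−κ) cos(2π h·t_d)
         = (1−2κ)² + 4κ(1−κ) cos²(π h·t_d)  ∈  [(1−2κ)², 1].

Two degeneracies are inherent and handled canonically: κ and 1−κ are
indistinguishable (κ ≤ 0.5 is the stored form), and t_d and (1−t_d) mod 1
produce identical factors (the lexicographically smaller representative is
reported).

**Correction.** I_unit = I_total / f(h), with σ propagated as σ/f — the
simplest defensible choice; re-estimating σ from phase-class scatter would
conflate defect modulation with genuine intensity variation. Reflections
with f below a floor (default 0.05) are flagged rather than divided, because
the correction amplifies noise as 1/f.

**Estimation.** Candidate vectors are small rationals (denominators ≤ 4 per
component; real translocation vectors are low-order rational, and the list
is configurable). For each candidate, reflections are binned into phase
classes x = h·t_d mod 1 (24 classes suffice for the rational grid) and the
full per-reflection sum of squares Σᵢ (Iᵢ − s·f(xᵢ; κ))² is minimized over
a κ grid (step 0.005) plus bounded local refinement, with the scale s solved
in closed form. Scoring by *per-reflection* residuals, not bin-mean
residuals, is essential: a wrong candidate that merges differently modulated
reflections into one class hides the modulation from the bin means but not
from the within-class variance. With no true defect, the best of ~200
candidates still improves the flat model slightly by chance, so a defect is
only accepted when the relative SSE gain exceeds 2 %; below that the crystal
is reported defect-free (κ = 0). Intensities may be negative (standard after
background subtraction) and enter the class statistics untouched; a
non-positive class mean is surfaced as a warning. No resolution dependence
of κ is modelled.

On synthetic Wilson-like data (exponential I_unit, n = 5000), recovery is
exact in t_d and within ±0.01 in κ noise-free, and within ±0.05 in κ at a
noise standard deviation of 10 % of the mean intensity.

## Pore profiling

The profile is HOLE-style: at each axial position z (step 0.25 Å default),
the sphere center is optimized in the plane normal to the axis to maximize
min over wall atoms of (distance − vdW radius). The optimizer is a 0.2 Å
coarse grid over a disc of radius 8 Å followed by eight-direction
pattern search with step halving down to 0.02 Å — fully deterministic,
replacing HOLE's simulated annealing because reproducibility matters more
here than escape from pathological local optima (the coarse grid already
provides the global view at 0.2 Å resolution). van der Waals radii come
from gemmi's Bondi-style element table, overridable per element. Walls are
polymer heavy atoms only by default; ligands and waters are opt-in, and
`profile_with_wall_waters` adds named water oxygens (r = 1.52 Å) to the
wall, which can only narrow the profile (a tested monotonicity invariant).
Planes with no atom in reach report a capped radius (10 Å) with an open
flag.

The default axis runs through the midpoint of the two NPA asparagines'
side-chain amide nitrogens, with direction from the least-squares line
through labelled channel-water oxygens when ≥ 4 exist, else through the
anchors' Cα; for structures without NPA anchors (toys) the water line alone
defines the axis. The sign convention places the extracellular side at
negative z; the convention is a configuration choice echoed in outputs.

One geometric fact worth recording: past the mouth of a cylindrical pore of
wall radius R, the inscribed-sphere radius does not jump to bulk but grows
as √(R² + Δz²) − r_vdW, limited by the rim ring. A "30 Å" toy channel
therefore measures ~32 Å between bulk-threshold crossings; the same
continuation, a couple of Å per side, applies to any real channel profile
and is why pore lengths quoted to the nearest Å are method-dependent.

## Water networks

Hydrogen bonds are distance-only (polar heavy atoms O and N; S is opt-in):
≤ 2.8 Å is a typical bond, ≤ 3.4 Å still counts, beyond that the
interaction is treated as broken. Both cutoffs are *inclusive*: the
literature quotes "shorter than 2.8" and "more than 3.4" without defining
equality, so equality is decided once, here, as bonded. No angular term is
used — defensible for a structure without deposited hydrogens, and a
documented limitation. Pairs within one residue are excluded as covalent.

Waters are classified by axial interval (channel, two vestibules) plus a
lateral rule: in-region if the off-axis distance is at most the local pore
radius plus a margin of 1.4 Å (one water radius). The interval boundaries
are calibration knobs with no unique published definition; for Lsi1-like
channels the channel interval is calibrated from the selectivity-filter
arginine Cζ plane to the second NPA asparagine, ±2 Å, with vestibules
extending 10–12 Å beyond, and the boundaries used are echoed into every
report. Channel-water labels (Wat1, Wat2, …) are assigned by z-order within
the channel and are explicitly *putative*: the mapping from published
channel-water names to deposited water residue numbers is not printed
anywhere recoverable, so reports flag the labels as operational.

Mutually exclusive pairs use a 2.5 Å cutoff — strictly between the 2.3 Å
exemplar of two alternately occupied half-sites and the 2.8 Å typical
hydrogen bond — and transitive closure merges pairs into exclusion groups.
Single-file segmentation sorts channel waters by z, breaks runs at O–O gaps
> 3.4 Å, and downgrades a run to multi-file when two of its waters share a
z-window (1 Å) but sit farther apart laterally than 2 Å. Orientation
inference is rule-based: a water donating two bonds to acceptor-only
partners (backbone carbonyls, carboxylates, amide oxygens) on its wall side
points its oxygen lone pairs to the lumen; everything else is ambiguous, and
every verdict carries a rationale string for audit.

## Silicic-acid placement

The Si(OH)₄ template is ideal geometry — Si–O 1.63 Å at the tetrahedral
angle, O–O edge 2.662 Å — rather than a licensed small-molecule deposition;
the difference from the experimental small-molecule geometry is below
0.02 Å and irrelevant at crystallographic water precision. Placement
superposes 2–4 template oxygens onto water oxygens over *all* injective
assignments (≤ 4!·binomials — brute force is exact and cheap), choosing by
(rmsd, clash count). With two waters the rotation about the O–O axis is a
free parameter; it is resolved by scanning the torsion in 10° steps,
minimizing clashes and then maximizing potential hydrogen-bond partners. A
clash is a protein heavy atom within (vdW sum − 0.4 Å) of Si or any O.
Candidate subsets for enumeration are z-contiguous windows of 2–4 channel
waters (the axial ladder a permeating substrate would occupy), with a full
combinatorial mode behind a flag; surviving placements are ranked by mapped
oxygen count then rmsd, and near-duplicate silicon positions (< 2 Å) are
deduplicated. Hydroxyl hydrogens are not modelled; every hydroxyl is assumed
donor-capable, which matches how such placements are reasoned about at
1.8 Å resolution.

A geometric caveat that shaped the test fixtures: three *collinear* water
positions admit no congruent triple of tetrahedron vertices (best achievable
rmsd ≈ 1.4 Å at 2.7 Å spacing), so a strictly on-axis water ladder cannot
host three-oxygen overlays. The placement fixtures therefore use a zig-zag
ladder whose consecutive O–O distance equals the tetrahedron edge, making
every consecutive triple an exact face — which is also how channel waters
actually sit (off-axis, alternating) in wide selectivity filters.

## MD statistics

The trajectory container is a frame-major coordinate array with dt in ns;
multi-frame XYZ and multi-model PDB round-trip through MDAnalysis. A site is
occupied in a frame when ≥ 1 candidate atom lies within the site radius
(default 1.4 Å — one water radius around the crystallographic position; the
notion of "occupying a cavity" has no unique published definition, so the
radius is a config knob echoed in outputs). The occupant is the nearest such
atom. The exchange time τ is the mean length of maximal same-occupant
residence episodes; vacancies up to `gap_tolerance` frames (default 1) are
merged to suppress single-frame flicker. The merge introduces a small upward
bias when re-entries frequently pick the same occupant (~+3 % in the
94 %-occupancy scenario with a 32-candidate pool); `gap_tolerance=0` removes
it for flicker-free data.

Permeation counting requires a full crossing: enter across one boundary
plane, exit across the other without re-crossing the entry plane in between;
partial entries are discarded, and time reversal maps the event list onto
itself with directions swapped (a tested invariant). With a periodic box the
axial coordinate is unwrapped by minimum image before crossing detection.
Axial density is a per-frame-normalized histogram; a bottleneck is a
contiguous run of bins below 0.25 × median density flanked by higher
density on both sides — the threshold flags the scripted three-gap
reconstructions exactly and is configurable.

## Synthetic generators and what passing tests mean

The generators reproduce the *statistical structure* each estimator assumes,
not the physics that produces it. Reflection sets use exponential
(acentric-Wilson) I_unit with additive Gaussian noise — adequate because the
estimator consumes only per-class first and second moments. Site occupancy
is a two-state Markov chain with geometric dwell (the discrete analogue of a
single exponential residence time); requested (P_occ, dwell) pairs that are
infeasible in a discrete chain (entry probability > 1; e.g. P = 0.94 with
dwell 15 would need sub-frame vacancies) are clamped, and the generator
reports its *achievable* stationary truth (0.9375 for that pair), which is
what recovery tests compare against. Scenario scales mirror the channel-water
study conditions: occupancies of 44/60/94 %, slow-site dwell 1.5 ns at
0.1 ns/frame, two scripted full permeations among partial entries, three
density gaps. Occupancy runs use 6 000 frames and the τ run 20 000 frames
(~1 250 episodes), sizes at which a 3-standard-error or 10 % bound is a
3–4 σ check rather than a coin flip. Toy pores are stacked pseudo-atom
rings (three concentric shells so the wall is radially solid like a real
protein cross-section) with waters placed at prescribed (z, lateral)
offsets. None of this emulates force-field dynamics, solvent structure, or
diffraction beyond the modulation model — passing tests certify the
estimators against their stated models, not against nature.

## Deposition-anchored checks

The reference checks against the deposited silicon-channel structure and its
comparators (entity census 14 182 non-H atoms / 984 waters / 1 731 residues,
mean B 28.6 Å², NPA spacings 108 and 132, ~3.5 Å constriction, 16 channel
waters, 2.3 Å exclusive pair, ~6 Å stable-water separation, Cα RMSDs 1.4
and 1.7 Å) live in one test that fetches the mmCIF entries from the PDB
into `data/depositions/` and runs entirely from the cache afterwards. In an
offline environment without a staged cache this test fails at the fetch
step by design; all other checks are synthetic and self-contained.

## Known limitations

- No electron-density or symmetry handling beyond reading cell and space
  group; no refinement statistics against a model.
- Hydrogen-bond detection is purely metric; donor/acceptor calls are
  rule-based and conservative (ambiguous unless the rules fire).
- The pore profiler finds one channel along one axis; branched or strongly
  curved pores would need a curved-axis extension.
- The LTD estimator assumes a single defect vector and κ constant across
  resolution; shell diagnostics are reported so violations are visible, but
  they are not modelled.
- Trajectory statistics assume the channel axis is fixed in the trajectory
  frame (or recomputed upstream); large-scale protein drift should be
  removed before analysis.
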