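# Model and methods

## System

The hairpin is the 12-nt GNRA-tetraloop sequence 5'-GGGCGCAAGCCU-3' with
native stem pairs (1G-12U), (2G-11C), (3G-10C), (4C-9G) and loop residues
5-8. Per-pair hydrogen-bond multiplicities follow pair type — 3 for C-G,
2 for A-U and for the G-U wobble — giving 11 native hydrogen bonds (9 from
the three C-G pairs, 2 from the wobble). Units are Å, ps, kcal/mol and amu
throughout, with k_B = 0.0019872041 kcal/mol/K and the acceleration
conversion 1 kcal/mol = 418.4 amu Å²/ps². Residues are numbered 1-based;
bead indices are 0-based and never exposed in outputs.

## Coarse-grained representation

Three beads per nucleotide — phosphate P (95 amu), sugar S (100 amu), base
B (120 amu); 36 beads for the 12-mer, including a 5'-terminal phosphate
for uniformity. Bonds connect P(i)-S(i) (3.8 Å), S(i)-B(i) (4.3 Å) and
S(i)-P(i+1) (3.8 Å); these lengths are fixed construction constants shared
by the topology and both deterministic conformation builders.

Two reference conformations are generated in code:

* **Extended chain** — residue i centred near x = (n−i)·5.9 Å with the 5'
  end at the largest x, backbone zig-zagging in y so the P-S and S-P'
  distances equal the bond lengths exactly at the default rise, bases
  offset above the sugars. It is the initial structure of every run and
  the anchor set of the transcription restraints.
* **Idealized native hairpin** — the stem is a regular helix (twist 32°,
  rise 3.3 Å, sugars at radius 8.5 Å, bases at 4.6 Å facing each other
  across the axis, a 75° phase shift between strands); the loop bridges
  the strand tops along a circular arc sized so each step matches the
  natural sugar-sugar span (5.5 Å), with loop bases pointing outward and
  loop phosphates pushed 2.5 Å off the sugar chord so every backbone angle
  is clearly bent (torsions around the loop junction stay well defined).
  Beads are placed sequentially with exact bond lengths, each step aiming
  at its guide position, so the output is byte-reproducible.

The wall, restraint and analysis machinery is force-field-agnostic: an
all-atom representation could be substituted without touching it.

## Energy function

Gō-type, with the native structure as ground state:

| term | form | default |
| --- | --- | --- |
| bonds | k(r−r₀)² | k = 20 kcal/mol/Å² |
| angles | k(θ−θ₀)², θ₀ from native | k = 10 kcal/mol/rad² |
| torsions | k(1−cos(φ−φ₀)), φ₀ from native | k = 8 kcal/mol |
| excluded volume | WCA, cut-shifted at 2^{1/6}σ | σ = 4.0 Å, ε = 1.0 |
| base-pair contacts | ε[(r₀/r)¹² − 2(r₀/r)⁶] | ε = eps_hb × multiplicity, eps_hb = 2.0 |
| stacking contacts | same 12-6 form | eps_stack = 1.2 |
| tertiary contacts | same 12-6 form | eps_other = 1.0 |
| non-native pairing | 12-6 at r₀ = 5.0 Å | eps_nonnative = 0.6 × multiplicity |

Angle, torsion and contact equilibria are measured from the idealized
native structure. Contacts comprise: one base-base well per native pair
(depth proportional to its hydrogen-bond count, so C-G binds more strongly
than G-U); adjacent-base stacking wells where the native distance is
≤ 6.5 Å (a 12-6 well with a long r₀ has unphysically stiff repulsion, so
the loop-junction "stacks" at 8-10 Å are not contacts); tertiary wells for
every remaining non-bonded bead pair within 6.5 Å in the native structure;
and weak non-native pairing wells between complementary bases (Watson-
Crick or wobble letters, sequence separation ≥ 3) that are not native
partners. Excluded volume skips 1-2/1-3 bonded neighbours and all contact
pairs (each 12-6 well carries its own repulsion).

Design notes on the terms that were genuinely open:

* **Torsions are load-bearing.** With bonds, angles and contacts alone the
  folded stem is torsionally floppy — the strands spin about the backbone
  and the stem RMSD equilibrates at 4-6 Å even with every pair formed, so
  the 2 Å folding criterion is unreachable. Pseudo-dihedrals along the
  bond graph (P-S-P'-S', B-S-P'-S', S-P'-S'-P'') restore helical rigidity,
  as in standard three-bead RNA models. Torsions whose native bond angles
  are nearly collinear (sin² < 0.05) are dropped at build time: such a
  torsion is geometrically ill-defined, and its regularized forces are
  chronically non-conservative (this showed up as a persistent +7%
  kinetic-energy excess before the loop geometry was bent away from
  collinearity).
* **Tertiary contacts pin the two strands.** The four base-base wells
  alone act as a free hinge between otherwise rigid strands.
* **Non-native pairing** represents the mispaired compact intermediates
  seen in atomistic work. At strengths compatible with a stable native
  state (wells 1.2-1.8 kcal/mol) these traps live for ~ns, which matters
  for kinetics but cannot outlast a slow transcription phase (see
  Limitations).
* **Calibration.** Defaults were set, before any acceptance test existed,
  on two regime properties: the native basin keeps stem RMSD < 2 Å for
  ~70-80% of equilibrium frames at 300 K, and all of a pilot set of
  free-folding seeds reach the folded state. Shallower wells
  (eps_hb ≤ 1.2) let the native state melt; they do not slow folding,
  because the downhill drive comes from the native-equilibrium angle and
  torsion terms, not the well depths.

Forces are the exact analytic negative gradient of every term (verified
against central finite differences to ~1e-10 relative error); near-
collinear torsion denominators are floored at sin² = 0.01 as a safety
bound on the force. The heavy loops are numba-compiled.

## Dynamics

BAOAB-splitting Langevin at T = 300 K, friction γ = 0.5 ps⁻¹, step
dt = 0.02 ps, velocities initialized from Maxwell-Boltzmann with the run
seed. With γ = 0 and T = 0 the step reduces exactly to velocity-Verlet
(the symplectic NVE limit is tested). All noise flows from one seeded
`numpy` generator in fixed-size chunks, so runs are reproducible
bit-for-bit, and the generic (Python callback) external-force path and the
fused compiled path produce identical trajectories. Frames are recorded
every 1000 steps (20 ps) by default.

The γ and dt values are coarse-grained tuning choices, not mapped to the
all-atom thermostat; at this friction the 36-bead chain collapses from the
extended state in ~0.2-0.4 ns, so coarse-grained nanoseconds are *not*
atomistic nanoseconds. The equipartition acceptance check runs at
dt = 0.003 ps, where BAOAB's O(dt²) kinetic-temperature bias (about −1.2%
at the production step) is far below the 3-standard-error resolution of a
10⁶-step average.

## Transcription scheme

A `TranscriptionSchedule` holds one event per residue: at t = (i−1)Δt
residue i's harmonic anchors (U = k|r−r₀|², k = 10 kcal/mol/Å², the
restraint convention in which a 1 Å displacement gives a 20 kcal/mol/Å
force) are removed and the plane jumps to just left of residue i's
anchored beads (their minimum x minus a 2 Å gap — the offset is not
physically pinned and is exposed in the schedule). The plane reflects
*released* beads only: a bead found left of the plane after a step is
mirrored (x → 2x_plane − x) and an inward normal velocity is reversed,
preserving its speed exactly; anchored beads sit left of the plane by
construction and never interact with it. At (n−1)Δt the last anchor and
the plane are removed and the run continues as free folding; Δt = 0
degenerates exactly (bit-for-bit) to the FF run with the same seed.

Anchored beads are not strictly immobile: on top of the ~0.3 Å thermal
width (√(3k_BT/2k)), the native-equilibrium angle/torsion terms exert a
static pull of up to ~1.3 Å at the extended anchor geometry. Tests bound
the anchored deviation at 2 Å, an order of magnitude below post-release
motion.

The three transcription speeds studied are Δt = 0.02, 0.2 and 2.0 ns
(fast/medium/slow): the ladder spans transcription faster than the chain
collapse time to much slower, the analog of the three-decade Δt ladder in
atomistic work.

## Analysis pipeline

* **Stem RMSD**: Kabsch superposition (SVD, proper rotation enforced) over
  all beads of the paired residues {1-4, 9-12}, then RMSD. Superposition
  is applied because RMSD-to-native is meaningless without it for a
  freely diffusing molecule; `superpose=False` (the CLI's `--no-fit`
  ancestor) evaluates the raw coordinate formula. Degenerate (collinear)
  subsets are rejected.
* **RoG**: unweighted root-mean-square distance to the arithmetic mean
  point, matching the printed unweighted formula; a mass-weighted variant
  is available (the two differ by < 2% for this bead-mass range).
* **Folding**: first frame whose stem RMSD < 2 Å sustained for 5
  consecutive frames (persistence window exposed; 1 recovers a
  single-crossing criterion).
* **Pair formation** (coarse-grained): a pair is formed when its base-bead
  distance ≤ 1.2 × its native distance; formation events are debounced by
  the same 5-frame window, ordered by time with ties broken by ascending
  5' residue index and flagged. Atomistic mode instead requires all of a
  pair's hydrogen bonds (3.5 Å / 120° geometric criterion on explicit
  donor-H-acceptor triples) simultaneously.
* **Pathway call**: PATH I if the loop-adjacent pair (4,9) is first in the
  formation order and the trajectory folds; PATH II if it folds with (4,9)
  later; UNCLASSIFIED if it never folds or (4,9) never persists (the
  explicit third label keeps unfolded trajectories out of the fractions).
* **T_F alignment**: T_F = t − (n−1)Δt for CTF, t for FF; frames with
  T_F < 0 (during transcription) are excluded from T_F-indexed ensembles.
  Ensemble statistics take the frame nearest each T_F target within half a
  frame interval and report mean, sample SD (n−1; flagged 0 when n = 1)
  and n. Landscapes are normalized 2-D occupancy histograms over
  (stem RMSD, RoG), optionally restricted to folded trajectories.

## Synthetic data and file formats

Everything the tests consume is generated programmatically: the two
reference conformations, hand-scripted trajectories that form the pairs in
a prescribed order (stages of the native structure with not-yet-formed
pairs parked 15+ Å away, each held past the debounce window, with optional
sub-window "flicker" frames), a never-folding variant, and a four-triple
atomistic mini-structure probing both sides of the hydrogen-bond distance
and angle thresholds. Trajectories are written as extended-XYZ (full
precision, lossless round trip) or multi-model PDB (3-decimal fixed width,
~1e-3 Å round trip); run directories include the config snapshot, seed,
package version and the schedule event log, enough to reproduce a run
byte-identically.

The scripted fixtures exercise the *analysis* contracts exactly; what
passing them shows about real data is limited to bookkeeping correctness —
they say nothing about force-field realism, which is probed separately by
the ensemble-level tests.

## Study conditions for the CTF-vs-FF comparison

20 seeds per condition; FF runs 6 ns; CTF runs (n−1)Δt + 4 ns at
Δt ∈ {0.02, 2.0} ns; frames every 5 ps for chronology resolution. These
sizes keep the full comparison around five minutes on one CPU while every
FF seed reaches its verdict (the model folds in 0.1-4 ns).

## Known limitations

* **Kinetic regime.** A native-centric coarse-grained chain folds downhill
  once collapsed; folding (0.1-4 ns) is never much slower than
  transcription, whereas in the atomistic reality folding (tens of μs) is
  far slower than even the slowest transcription studied. Consequences:
  the compaction effect of transcription (CTF ensembles at T_F = 0 far
  more compact than FF at t = 0, gap growing with Δt) reproduces robustly,
  but the pathway-mix effect does not — with transcription slower than
  collapse, 4C-9G is the only native pair whose partners coexist during
  synthesis, so slow-Δt CTF funnels entirely into PATH I, while free
  folding shows the expected zipper preference with a 20-35% PATH II
  minority. The corresponding directional acceptance test is left failing
  rather than re-scoped; the trade-off is structural (the steering that
  keeps the folded basin under 2 Å also removes the folding barrier).
* Non-native structure is only partially representable: base-base wells
  between complementary letters, with no geometry of a duplex register
  and lifetimes of ~ns at native-compatible depths.
* The loop is held by generic bonded terms plus short-range contacts; its
  conformational ensemble is not calibrated against the real GNRA loop.
* No electrostatics, ions or solvent; constant volume, no pressure
  coupling; a single hairpin in vacuum-like conditions.
* Time has no absolute mapping to physical seconds; only ratios of
  coarse-grained timescales are meaningful.
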