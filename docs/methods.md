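# Methods

`helixbundle` builds and evaluates desk-scale models of lipid-free
apolipoprotein A-I (apo A-I), the 243-residue protein of high-density
lipoprotein. The target architecture is a bundled four-helix N-terminal
domain (residues 1–192) with a short mobile two-helix C-terminal hairpin
(193–243). The package reproduces the *construct–assemble–evaluate*
modelling workflow for this system: idealized helices are assembled as
rigid bodies over enumerated bundle topologies, loops are closed
geometrically, a seeded stochastic refinement stands in for molecular-
dynamics relaxation, and every candidate is scored against the
experimental restraint classes used for lipid-free apo A-I — lysine
cross-links, salt bridges, hydrophobic solvent exposure, secondary
structure and named inter-residue distances.

## Idealized helices

Helices are built residue-by-residue with the natural-extension
reference-frame construction from fixed internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; CA–C–N 116.2°,
C–N–CA 121.7°, N–CA–C 110.0°; ω = 180°). The default dihedrals are
φ = −63.8°, ψ = −41.5°. These were chosen, once, so that the default
helix realizes the *18/5 α-helix* exactly — 18 residues per 5 turns,
i.e. 100° angular advance and 1.5 Å rise per residue, which is the
defining geometry of the construction — and they coincide with the mean
dihedrals observed in real protein helices. The textbook −57/−47 pair
under exact trans-peptide idealized geometry yields a slightly stretched
helix (≈ 1.56 Å rise); both geometry targets cannot be met at once with
an N–CA–C angle of 111.2°, which is why 110.0° is used.

Side chains are reduced to a tetrahedral Cβ (improper N–C–CA–CB = +120°,
L-chirality, verified against standard residue templates) plus a single
charged "tip" pseudo-atom for Lys (NZ, 3.9 Å beyond Cβ), Arg (NH1,
4.1 Å), Asp (OD1, 2.5 Å) and Glu (OE1, 3.1 Å). By default the tip lies
along the CA→Cβ direction; for residues participating in *planted* salt
bridges the generator treats the tip direction as a one-angle rotamer:
it may sit anywhere at its canonical length from Cβ within a 125° cone
about the CA→Cβ axis, and a deterministic direction-grid search points
each involved tip so it lands 2.5–3.4 Å from its partners' tips. This
mirrors the conformational freedom of real charged side chains; strict
radial placement makes several experimentally observed bridges
geometrically impossible for rigid idealized helices. The tips reuse
real side-chain atom names, so salt-bridge detection treats synthetic
structures and full-atom PDB input identically.

## Topology enumeration

The antiparallel up-down bundle family is modelled as snake paths of the
chain through a two-row grid of helix axis positions (odd helix counts
drop the last grid cell). Configurations are Hamiltonian nearest-
neighbour paths, deduplicated modulo chain reversal, ordered
deterministically and given stable pattern ids. Six helices admit
exactly eight such configurations; four admit four. The convention was
fixed before any evaluation and is cross-checked in the tests against a
brute-force permutation enumeration.

## Assembly and fixtures

Each helix is canonicalized (fitted axis → +z through the origin, axis
fitted by principal components of the Cα trace), flipped for odd chain
positions (consecutive helices antiparallel), spun so its hydrophobicity-
weighted Cβ direction faces the bundle centroid, and translated to its
grid cell at the packing distance (default 10.5 Å axis-to-axis, a
typical helix-bundle packing; no published value exists for this
system). Assembly is exactly rigid per helix.

Ground-truth fixtures (`make_fixture`) refine the placements against the
planted interactions with a trust-region least-squares search over one
spin and a three-axis translation per helix (orientations stay fixed).
The residuals are smooth hinges: planted cross-links (site distance ≤
cutoff − 3 Å), planted salt bridges (Cβ–Cβ ≤ tip lengths + 2 Å, floor
4.5 Å — the tips are aimed afterwards), loop-closure feasibility per
junction (anchor C···N within a fraction of the loop's maximal span,
3.4 Å per residue; widened short loops get a hard 7 Å cap because their
frame-matching closure is only reliable below that), reachability of
loop/tail-resident plants from their span anchors, a Cα-proxy steric
term, a tip-overlap term, and a weak translation regularizer. The
initialization is informed: z-offsets stagger consecutive junctions,
plant-bearing helices are spun so the planted Cβ faces its partner
(circular mean of "face votes"), and z-offsets are corrected by plant
height mismatches; a small seeded jitter keeps distinct seeds distinct.
Plants the optimizer leaves violated are reweighted ×5 (capped ×40) and
re-optimized; if a loop then fails to close, the pass is retried with a
tighter feasibility hinge, and finally from a different deterministically
derived starting point. After closure, planted tips are aimed
(direction-grid rotamer step) and any still-unformed bridge triggers a
targeted re-closure of its span pulling toward the partner's aimed tip.
Every fixture verifies its own plants, plus a steric bound on the rigid
helix core, before it is returned; failure raises a generation error
rather than emitting a bad fixture. The full nine-bridge apo A-I plant
is a hard constraint-satisfaction instance and does not succeed from
every starting seed; `build_apoa1_model` therefore tries a few
deterministically derived sub-seeds.

## Loop closure

Loops are closed by cyclic coordinate descent (CCD) on the backbone
torsions, from an initial path interpolated between compact and extended
torsions according to the span/length ratio (several deterministic
alternative starts are tried; the selection keeps the closure with the
fewest steric contacts, counting both contacts with the rest of the
structure and the loop's own self-contacts). Rotatable axes are the
loop φ/ψ torsions plus the anchor ψ and the virtual target φ; ω stays
trans. The moving copies of the downstream anchor's N/CA/C are matched
to their real positions (early sweeps chase N only); closure requires
the final C–N peptide bond within 0.3 Å of 1.329 Å. Every third sweep
adds push-apart pseudo-targets for backbone atoms within 3.2 Å of each
other or 3.0 Å of the surrounding structure (self-avoidance); when a
loop nevertheless fails to close, it is retried with a larger sweep
budget and finally with the repulsion disabled — closure always
outranks loop sterics. A short untangling phase and, for spans carrying
pull restraints, a closure polish run afterwards. O, Cβ and tips are
re-derived from the final backbone. N- and C-terminal tails grow by the
same construction run in reverse (bond/angle roles swapped), with no
closure target.

Loops shorter than four residues are widened by borrowing flanking
helix residues before closure: matching a three-atom target frame needs
more torsional freedom than a one- or two-residue loop possesses (exact
one-residue closure is generically unreachable), so the junction
residues are allowed to fray — as real helix termini do. Pull
restraints bias closure so planted interactions on loop or tail
residues are satisfied. Loop conformations are geometrically valid and
closure-exact but *not* sterically refined: on large models some
intra-loop contacts below the 2.4 Å clash threshold remain, and the
clash score reports them; the generator's own acceptance gate therefore
checks the rigid helix core, where sterics are trustworthy.

## Perturbation and refinement

`perturb` applies an independent random rigid displacement to every
helix segment (rotation ≤ m degrees about a random axis through the
segment centroid, translation ≤ m Å, both drawn from a seeded
generator), then re-closes all loops. It is the package's desk-scale
surrogate for thermal relaxation: it explores rigid-body rearrangements
of the bundle, not internal helix deformation, fraying kinetics or
solvent effects — results about refinement therefore speak to restraint-
guided rigid-body search, not to molecular dynamics. `iterative_refine`
is a greedy perturb-and-select loop: a perturbation is kept only if the
composite score does not decrease, so the score trace is monotone and a
fixed seed reproduces the trajectory bit for bit. Greedy acceptance
(rather than, say, Metropolis) keeps well-scoring portions and replaces
poorer arrangements deterministically.

## Evaluation battery

* **Cross-links** — site distances (Lys → Cβ; "NT", the N-terminal
  amine, → backbone N of residue 1; otherwise Cα) against a 20 Å cutoff.
  On ensembles a restraint is satisfied when it holds in ≥ 50% of
  frames; the per-frame series is always attached.
* **Salt bridges** — minimum O···N distance between Asp/Glu carboxylate
  oxygens and Lys NZ / Arg NE,NH1,NH2 at a 4.1 Å cutoff; His excluded.
  Trailing-window detection averages the per-frame minimum distance.
  Classification against a helix segmentation: intra-helix, inter-helix,
  or involves-loop; loop partners count as inter because they constrain
  the tertiary arrangement the same way.
* **SASA** — Shrake–Rupley sphere sampling, 960 golden-spiral test
  points per atom by default, probe 1.4 Å, hydrogens excluded, van der
  Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å (1.70 Å otherwise).
  The dense-grid variant of the area integral survives only as a test
  oracle (agreement asserted within 3%); sampling is the standard fast
  choice. The headline statistic is the mean accessible area per
  hydrophobic residue over the eight-type class
  {Ala, Leu, Val, Ile, Pro, Phe, Met, Trp} — per frame the class mean,
  then averaged over frames.
* **Secondary structure** — hydrogen bonds by the Kabsch–Sander
  electrostatic energy (0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
  kcal/mol, bond when E < −0.5) with the amide H imputed 1 Å from N
  opposite the preceding carbonyl; α/3₁₀/π turns folded into H, ladder
  patterns into E, everything else C. Helix content is the percentage of
  H. Different assigners (DSSP-family vs STRIDE-family) disagree by a
  few percentage points on real structures, so helix-content comparisons
  across assigners should carry a ±5 point tolerance.
* **Clash score** — non-bonded heavy-atom pairs (sequence separation
  ≥ 2) below 2.4 Å; a cheap steric surrogate for a potential-energy
  check, which is out of scope.
* **Composite score** — mean of normalized criteria: cross-link fraction;
  inter-helix bridge count capped at 12 and scaled; mean hydrophobic
  SASA mapped linearly from [80, 40] Å² to [0, 1] (compact is better);
  1/(1+clashes). Weights default to equal and are configurable. Named
  FRET-comparison distances (Cα 50–83 and 50–173) are report-only and
  never enter the score.

## The apo A-I reconstruction

`apoa1.build_apoa1_model` rebuilds the full-length lipid-free model from
the mature 243-residue sequence with the six construction helix ranges
(H1 7–46, H2 48–82, H3 94–121, H4 143–180, H5 195–212, H6 220–240); the
measurement segmentation used for classification differs (H1 7–39,
H2 50–79, H3 98–123, H4 140–186, H5 195–218, H6 223–238) — the two sets
come from the construction recipe and from measurements on the relaxed
model respectively, and they genuinely disagree about helix 5 (195–212
vs 195–218); the package keeps both and defaults to the measurement set
for classification. The default topology (`updown6-2`) places the four
N-domain helices as a square bundle with the C-domain hairpin alongside
— the arrangement in which every named interaction pair sits on nearest
or diagonal grid positions. Planted ground truth: the three named
interpeptide cross-links (NT–Lys96, Lys23–Lys59, Lys96–Lys226 at 20 Å
Cβ) and the nine named inter-helix salt bridges (the N-terminal network
Glu2/Asp1–Lys96/Lys94, Glu76–Lys94, Glu92/Asp89–Arg177, and the three
domain linkers Glu223–Arg160, Glu212–Lys106, Asp103–Lys208).

This reconstruction is a synthetic stand-in built by the package's own
pipeline, not a copy of any deposited coordinate set: coordinate-level
agreement with published models is neither expected nor claimed. What it
demonstrates is that the published interaction network is geometrically
realizable by an idealized four-helix bundle plus hairpin, and it gives
the measurement battery a full-size, fully annotated input. Checks that
depend only on the sequence are exact regardless of coordinates — the
eight-type hydrophobic class counts 92 residues in the full-length chain
and 68 in its 1–184 truncation (the C-terminally truncated crystallized
construct). An extended helical-hairpin stand-in
(`apoa1.build_extended_standin`, two idealized arms 1–120/124–243) serves
as the non-bundled comparison: it violates the Lys23–Lys59 cross-link
that the bundle satisfies and exposes more hydrophobic surface — both
checked as orderings, not as the published numbers, since those require
the original coordinates and trajectories.

## Problem sizes

The packaged experiments are sized for a single CPU: fixtures use
18-residue helices (four-helix bundles, ~500 atoms), SASA uses 240–960
points per atom depending on context, refinement experiments run up to
200 rounds with early stopping once the planted restraints are
recovered, and the reconstruction optimizes 24 rigid-body parameters
with a bounded Powell budget and a small number of deterministic
retries. Published trajectory-scale quantities (equilibration RMSD
levels, trajectory-averaged SASA and bridge counts over nanoseconds) are
out of scope by construction.

## Known limitations

* No rotamers, no hydrogen atoms, no force field: energetics are
  represented only by steric hinges and the clash count.
* Loops are geometrically valid but not energy-scored; the fixture
  optimizer treats them as passive connectors except where pull
  restraints apply.
* The refinement explores rigid-body space only; helix bending (for
  example the documented flexing of helix 2) appears in the data model
  but not in the move set.
* Salt-bridge geometry uses distance only — no angular term — matching
  the convention of common analysis tools.
* The synthetic generator emulates amphipathic helix bundles with
  planted interactions; it does not emulate crystallographic disorder,
  alternate conformers (beyond parsing them), solvent structure, or
  experimental noise in restraint lists. Tests passing on these fixtures
  certify the measurement and search machinery, not agreement with any
  particular experimental structure.
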