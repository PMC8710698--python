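# Methods

This note documents the models and numerical choices behind `phf6agg`:
what each analyzer computes, what the synthetic-conformer generator does
and does not emulate, and where the design was genuinely open.

## System and units

The package targets small capped peptide assemblies, concretely the tau
core hexapeptide PHF6\* (275-VQIINK-280) simulated as twelve chains with an
ACE (CH3CO–) cap at the N-terminus and an –NH2 cap at the C-terminus, in a
cubic periodic box of 6.88 nm, optionally with the lysine replaced by
acetyl-lysine (ALY). Internal units are nm, ps, K and kcal/mol. Author
residue numbering (275–280) is kept as display metadata; indices are
0-based internally. The caps are classified as *mainchain*: they are
backbone extensions without sidechains, so the MC/SC decomposition of
H-bonds and contacts treats their atoms as mainchain. ALY follows the
chemical-component dictionary, with the acetyl carbonyl oxygen renamed to
`OI2` (the name used in H-bond occupancy tables for this system); its NZ
retains one amide hydrogen as donor and `OI2` is an acceptor.

Whenever a frame carries a box, all distance criteria use the orthorhombic
minimum-image convention; analyses of boxless frames use plain distances.
(A flag disables minimum imaging if a trajectory is known to be whole.)

## Secondary structure

`secondary_structure` implements the Kabsch–Sander algorithm: the
electrostatic H-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol (distances in Å, energy clamped at −9.9 to guard the 1/r
singularity), a bond at E < −0.5 kcal/mol, n-turns for n = 3..5, parallel
and antiparallel bridges, ladders (≥ 2 consecutive bridges → E, isolated
bridge → B), bends (Cα virtual angle > 70°) and the priority
H > E/B > G > I > T > S. Amide hydrogens are taken from the structure when
explicit and otherwise reconstructed 0.10 nm from N opposite the preceding
carbonyl (the standard DSSP construction; the ACE carbonyl serves the first
residue). Caps never receive codes and never act as pattern residues.

Two deliberate dialect choices:

* Bridge patterns are evaluated with clause-local bounds checks rather
  than a blanket "interior residues only" rule, matching the behaviour of
  the reference DSSP implementation at chain termini (the antiparallel
  narrow pattern references only i and j, so terminal residues can form
  bridges). On the synthetic panels agreement with `mdtraj.compute_dssp`
  is 100% of residues; the acceptance threshold is 95% to leave room for
  edge-of-segment dialect differences on less idealised geometry.
* Beta-bulges and the modern DSSP-4 π-helix preference are not
  reproduced; hexapeptides cannot express them meaningfully.

Report categories are {coil, β-sheet = E, β-bridge = B, bend = S,
turn = T}; helical codes fold into coil by default (capped hexapeptides
have no meaningful helix content) and the grouping is configurable.
β-strand lengths are maximal within-chain E-runs; the probability of
length L is normalised per (frame × chain) observation by default, with a
per-strand alternative, since the published normalisation of such
distributions is conventionally left unstated.

## Interactions

H-bond: donor-heavy to acceptor-heavy (N···O) distance < 0.35 nm *and*
D–H···A angle at the hydrogen > 150°. Donors are the backbone amide N–H,
the NH2 cap, and sidechain N–H of Asn/Gln/Lys/ALY; acceptors are all
carbonyl/amide/acetyl oxygens. Pairs within one residue, and
backbone–backbone pairs of sequence-adjacent residues, are excluded as
covalently constrained. Contact: two heavy atoms of non-sequential
residues (|Δseq| ≥ 2 within a chain; all inter-chain pairs qualify) within
0.54 nm when at least one is carbon, 0.46 nm otherwise. Both detectors are
validated by exact set equality against exhaustive-pair brute-force
references on random 12-chain frames.

Residue-pair maps are 6×6 over the standard residues: entries are total
counts over frames and chain pairs divided by (n_frames × n_chains),
matching how published H-bond maps are normalised ("averaged over twelve
peptide chains"). MC-SC maps are directional — rows are the sidechain
role — so the SC→MC map is the transpose. Specific-pair occupancies (for
example `N279@ND2 → K280@O`) count, per frame, every (donor chain,
acceptor chain) instance of the named atoms, intra-chain included; because
the published denominator convention is unstated, percentages are reported
both per observed pair and per all chain pairs. Count PDFs default to
inter-chain bonds only (assembly statistics); intra-chain bonds are
included via a flag.

## Assembly

Chains are joined in the oligomer graph when they share at least one
atomic contact (configurable, since single-contact graphs can
over-connect). Oligomer size distributions are reported per component
(default) and chain-weighted, the published normalisation being unstated.
Strand pairing operates on the Kabsch–Sander output: nodes are maximal
E-segments, and two segments are paired when they share ≥ 2 bridges —
i.e. when they form a DSSP ladder. This is deliberately the same bond set
that defines the segments; one bridge is a transient contact, two are a
ladder rung. Pair orientation comes from the dot product of the two
strand direction vectors (first→last Cα). A closed β-barrel is a pairing
component that is a single cycle with every strand of degree exactly 2
and ≥ 4 members; near-cycles missing one edge can be reported as open
barrels but are excluded from size distributions by default.

## Clustering

Kabsch superposition (SVD with reflection correction) minimises RMSD over
proper rotations; it is cross-checked against the Horn quaternion method.
Daura clustering computes the full pairwise superposed Cα-RMSD matrix
(all chains, fixed atom order — no chain-permutation matching, mirroring
standard trajectory-clustering tools; block evaluation keeps memory flat
for long runs) and repeatedly extracts the frame with the most neighbours
within the 0.45 nm cutoff together with its neighbours. Ties break toward
the lowest frame index; clusters are relabelled by decreasing population.
The RMSD is symmetric and zero on identical frames; the triangle
inequality is not assumed anywhere.

## Observables

* Rg is mass-weighted about the selection's centre of mass; the default
  selection is every peptide heavy atom of all chains (one assembly-level
  Rg per frame). Per-component Rg is available via explicit selections.
* End-to-end distance is Cα(first standard residue) to Cα(last), caps
  excluded, minimum-imaged when periodic.
* SASA is Shrake–Rupley with Bondi radii (overridable), probe 0.14 nm and
  960 quasi-uniform sphere points (golden-spiral construction, giving the
  isolated-sphere area to < 1%); waters are excluded as surface and as
  occluders. Periodic images are not considered occluders.
* Solvation counts water molecules (by their oxygen, whole-molecule by
  flag) within 0.35 nm of the heavy atoms of a residue's mainchain or
  sidechain, averaged over frames and the twelve chain instances.
* The free-energy surface is −RT ln H(x, y) over the normalised 2-D
  histogram of the inter-chain H-bond count (unit-width integer bins) and
  Rg (0.02 nm bins), R = 0.0019872 kcal/(mol·K), analysis temperature
  310 K; the surface is shifted so the lowest occupied bin is zero and
  empty bins are +inf, never numeric.
* Convergence reports compare two time windows on the overall SS
  categories, per-residue β-sheet, and the PDFs of H-bond count, Rg
  (0.1 nm bins) and end-to-end distance (0.1 nm bins), each summarised by
  the Jensen–Shannon divergence in nats and the maximum absolute
  difference. Exactly identical windows are allowed (a self-check that
  must return zero); partially overlapping windows are rejected.

## Synthetic conformers

The generator supplies ground-truth-labelled stand-ins for simulation
data. Chains are built by NeRF extension from ideal internal coordinates
(N–Cα 0.1458, Cα–C 0.1525, C–N 0.1329, C=O 0.1231, N–H 0.100 nm; standard
angles; ω = 180°) with sidechains grafted rigidly from the
chemical-component dictionary; only heavy atoms and polar hydrogens are
produced. Ideal strands use (φ, ψ) = (−139°, 135°); coils draw dihedrals
uniformly from broad basins that exclude both the β core and the α core,
so planted classes stay separable.

Sheets place successive strands with a rigid transform calibrated once by
least squares against the canonical backbone H-bond registry (N···O
0.29 nm, N–H···O collinear) plus steric floors; barrels place n copies of
a single template strand with n-fold rotational symmetry about the barrel
axis, the template's placement *and* per-residue dihedrals solved by
continuation from n = 12 (nearly flat) down to n = 4 (strongly curved —
the strands coil, as real barrel strands do). The solutions are frozen in
`data/builder_params.json` (regenerate with
`python -m phf6agg._calibration`), so construction is fast and
bit-reproducible. Mixture ensembles draw frame classes i.i.d. from
configurable weights (defaults: coil 0.40, sheet 0.30, bilayer 0.15,
barrel 0.15 — a sheet-forming but disorder-dominated regime), sample coil
conformers from a per-ensemble pool of 48 for tractability, place
structured blocks at random orientations, and isolate leftover chains
beyond every interaction cutoff so that planted component sizes are exact.
Optional Gaussian coordinate noise (σ = 0.01 nm keeps analyzer recovery
above 95%) roughens the geometry.

What the generator does **not** emulate: thermodynamically weighted
conformational ensembles, force-field energetics, realistic sidechain
rotamer relaxation (barrel interiors of the smallest sizes are sterically
crowded), partial/frayed sheets, or genuine temperature dependence.
Passing tests therefore establish that the *analyzers* are correct on
structures with known labels — not that any simulation result is
reproduced.

## Validation strategy and problem sizes

Because the original trajectories behind the published numbers are not
deposited, validation is property-based: exact oracle equivalence for the
detectors (100 random frames), ≥ 95% DSSP agreement on a 20-frame panel,
exact reproduction of the greedy clustering rule (20 × 50-frame
ensembles), closed-form SASA and free-energy checks, 100% planted-barrel
recovery (sizes 4–8, 50 orientations each), binomial-interval recovery of
mixture weights (500 frames), Jensen–Shannon bounds for same-distribution
windows (50 seeds × 2 × 500 frames, 0.1 nm Rg bins — the 0.02 nat bound
comfortably exceeds the ~(k−1)/4n multinomial expectation), and an
end-to-end two-system contrast whose difference maps must carry the
planted sign everywhere. `scripts/acceptance.py` recomputes all headline
quantities from scratch under a user seed; the two-system experiment there
uses 80 frames per system, enough for stable category percentages on
synthetic mixtures while keeping the full run under a minute.

## Known limitations

* The Kabsch–Sander implementation targets the classic algorithm; DSSP-4
  refinements (π-helix preference, PPII) are out of scope.
* Chain-permutation-aware RMSD is not implemented; clustering treats the
  chain order as fixed, as standard tools do.
* SASA ignores periodic images; solvation and interaction analyses do not.
* `build_barrel` accepts only radii near the calibrated value for each
  strand count — arbitrary radii cannot preserve a closed H-bond
  registry — and raises the overlap error below 80% of it.
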