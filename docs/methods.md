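# Methods

This note documents the models and procedures implemented in `ifaceprof`,
the defaults they use, and the choices made where the design was genuinely
open.  It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and units

An ensemble is a fixed topology (one record per atom: chain, residue
number/insertion code, residue name, atom name, element) plus an
`(n_frames, n_atoms, 3)` coordinate array.  The internal length unit is the
nanometre — the unit in which all interaction criteria are stated — and PDB
angstroms are converted on read and reconverted on write.  Multi-model PDB
parsing and serialisation are delegated to gemmi; on top of it the package
enforces the ensemble contract (every MODEL block must present the identical
atom-identity sequence, with the first divergent model named in the error),
applies the alternate-location policy (blank or `A` kept; MD-written frames
have no alt-locs, and crystal inputs need one deterministic rule),
normalises rotated hydrogen names (`1HH1` → `HH11`), and infers elements
from atom names when the element column is blank.  Periodic-boundary
imaging is out of scope: inputs are assumed whole molecules, and a
coordinate extent beyond 50 nm triggers a warning that the trajectory may be
wrapped.

Residue identity is `(chain, res_seq, i_code)` with numbering taken as-is;
all defaults use STAT5A numbering.  The region scheme defaults to
SH2 = 589–687, L = 688–693, PTM = 694–706, nTAD = 707–714 (inclusive,
validated non-overlapping).

### Residue chemistry table

Donor/acceptor/side-chain/charge/aromatic atom sets for the 20 standard
residues plus phosphotyrosine (PTR: acceptors and negative charge group on
the phosphate O1P/O2P/O3P/P, aromatic ring CG–CZ, no side-chain donor) ship
as an editable TSV.  Backbone chemistry (N–H donor, O/OXT acceptors) is a
wildcard applied to every residue, masked for proline's nitrogen.  Unknown
residue codes soft-fail: they are excluded from detection with a logged
warning, so a stray ligand does not abort an analysis.  Atomic masses are
per-element (H 1.008, C 12.011, N 14.007, O 15.999, S 32.06, P 30.974).

## Contact detectors

All four detectors operate per frame, exclude intra-residue pairs, report
both intra- and inter-chain contacts, and use strict inequalities at the
cutoffs (the criteria are phrased as "below"/"smaller than"); events are
returned in canonical residue-pair order so identical inputs give identical
output regardless of atom order.

* **Hydrogen bonds** — one event per (donor heavy atom, bonded hydrogen,
  acceptor) triple with donor–acceptor distance < 0.35 nm and
  hydrogen–donor–acceptor angle (vertex at the donor) < 30°.  Donors with no
  resolvable hydrogen in the frame are skipped with a warning (strict mode
  raises), since the angle is undefined without the hydrogen.
* **Hydrophobic contacts** — side-chain centre-of-mass distance < 0.5 nm.
  The criterion is purely geometric and applies to *all* residue types with
  a non-empty side chain; the SH2 pocket's polar βD5/βD7 residues form
  exactly such contacts with the phosphotyrosine ring.  The COM is
  mass-weighted over the side-chain heavy atoms listed in the chemistry
  table plus every hydrogen not bonded to the backbone (H/H1–H3/HA/HA2/HA3
  are backbone); hydrogens are included because a centre of mass with no
  stated exclusion means all atoms present.  Whether to use ring-only COMs
  for aromatic side chains is exposed through the table (edit the side-chain
  set); whole-side-chain is the default.
* **Salt bridges** — no single convention dominates the literature, so the
  package adopts the Barlow–Thornton minimum heavy-atom criterion: the
  smallest distance between any positive-group nitrogen (Arg NE/NH1/NH2,
  Lys NZ, His ND1/NE2 when flagged protonated) and any negative-group
  oxygen (Asp, Glu, PTR phosphate) below 0.4 nm, configurable.  This keeps
  "salt bridge" a category distinct from the 0.35 nm/30° hydrogen bond.
  Histidine protonation is an input flag because protonation states are
  fixed upstream of this package.
* **Aromatic contacts** — the subset of hydrophobic-criterion contacts where
  both residues carry a ring (Phe, Tyr, Trp, His, PTR), re-labelled and
  reported with the unweighted ring-centroid distance.  No ring-plane angle
  term (π-stacking classification is a non-goal): aromatic persistence is
  quantified as occupancy of the underlying hydrophobic contact.

## Occupancies, interfaces, asymmetry

Occupancy of a (pair, kind) is `100 · n_present / n_frames`, where a frame
counts once however many simultaneous events link the pair (two
donor–acceptor triples in one frame are one present-frame).  Pairs never
present are not enumerated — the candidate universe is unbounded, and
contact tables report observed pairs only.  A persistence label
(persistent/transient) is attached at a configurable cutoff, default 25%;
the boundary between "transient" and "large persistence" is conventional,
so the label is reported alongside the raw occupancy and is never
load-bearing.

Interface partition of a residue pair under the region scheme, for a
declared two-chain dimer: different chains with one residue in PTM∪nTAD and
the other in SH2 → interface 1 (orientation = the PTM-donating chain); both
in PTM∪nTAD on different chains → interface 2; the same pattern within one
chain → interface 3; otherwise any residue in L → linker; else other.  nTAD
is grouped with the PTM because the tail acts as one percolating unit and
the F706 anchor's neighbours sit at the PTM/nTAD boundary.

The asymmetry score for interface 1 (or 3) matches records across the two
orientations by (kind, PTM-side residue number, partner residue number) and
averages |Δoccupancy| over the union of matched keys, a missing partner
counting as 0%.  The score is 0 for perfectly symmetric monomers and is
invariant under chain relabelling.  The metric is a package choice: it
turns a qualitative "local structural asymmetry" observation into a single
comparable number without weighting decisions.

## Clustering and the representative structure

Superposition is the least-squares optimal proper rotation (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`), requiring ≥3
non-collinear atoms; RMSD is unweighted over the selection, defaulting to
the backbone atoms N, CA, C, O (Cβ is deliberately not included; the
table-driven selection makes the alternative a one-line change).
Clustering is GROMOS neighbour-counting on the pairwise post-fit RMSD
matrix: the frame with most neighbours within the cutoff becomes a
centroid, it and its neighbours are removed, repeat; ties break to the
lowest frame index, making the result deterministic and frame-order
invariant up to ties.  Default cutoff 0.2 nm on backbone atoms — the
standard scale for calling a "most representative structure".  The
representative is the largest cluster's centroid, returned together with
the coverage fraction so the "more than half of sampled conformations"
condition is explicitly checkable.  Selecting an equilibrated window is the
caller's decision (a frame range), not auto-detected.

## Convergence diagnostics

Covariance analysis superposes all frames onto the ensemble mean with a
single fit-to-mean iteration (fit to frame 0, recompute mean, refit —
standard practice; full iterative convergence changes little and costs a
pass per iteration), then diagonalises the 3N×3N positional covariance.
No mass-weighting, consistent with unweighted backbone RMSD.  Eigenvalues
are clipped at 0 (they are variances; round-off can produce −1e-17) and
their sum equals the total positional variance of the fitted ensemble
(trace conservation, asserted to 1e-9 in the tests).  A `superpose=False`
path analyses raw coordinates, for pre-aligned input or when a designed
internal motion must not be mixed with the compensating rigid-body
component the fit introduces.

The cosine content of projection i is the discrete (trapezoidal) form of
`c_i = (2/T)(∫ p(t) cos(iπt/T) dt)² / ∫ p(t)² dt`, bounded in [0, 1] by
Cauchy–Schwarz: 1 for a pure half-cosine of order i — the signature of
random diffusion, i.e. unconverged sampling — and ≈0 for fluctuation about
an equilibrium.  An identically-zero projection (a frozen mode) is reported
as content 0 rather than an error in the aggregate report.  No numeric
acceptance target exists for this quantity on real trajectories; the tests
pin the closed-form cases (cosine → 1, constant → 0, cross-mode
orthogonality) and the rank property that random walks score far above
white noise.

## Variant mapping

An interface catalogue stores the residue pockets the ensemble analysis
identifies: the phosphotyrosine coordination shell {R618, K600, S620, S622,
T628, N642, K644} and the V695 pocket {W631, W641, L643} (interface 1), the
intramolecular F706-acceptor surface {W631, F633, W641, L663, Y665, L666}
(interface 3), and the PTM–PTM positions pY+3…pY+11 (interface 2, with F706
as the interface-3 donor).  Annotating a variant attaches its region label,
pocket memberships and interface classes; positions outside the modelled
fragment (589–714) raise, or are flagged and skipped in table mode.

The built-in STAT5A variant table stores cohort carrier/total counts and the
percentage as printed in the source reports, at its printed precision.
Frequencies are always recomputed as `100·carriers/total`, rounded half-up
(the convention that reproduces the printed clinical values, e.g.
5/68 → 7.4).  One source inconsistency is preserved rather than resolved:
the I699L rows are printed as 2.0% but their counts give 1/94 = 1.1% and
1/68 = 1.5%; they carry a `count_mismatch` flag and are excluded from
printed-value comparisons.  STAT5B numbering equivalences are free-text
notes only.

## Synthetic data: what it does and does not emulate

The generator exists to make every stage testable with exact ground truth.
Designed pairs are built from minimal idealized residue templates (fixed
internal geometry, explicit hydrogens where donors need them, PTR with its
phosphate) placed in cells 6 nm apart, so contacts between different
designed pairs are geometrically impossible.  The governing distance of
each pair is drawn inside margin bands — present frames at 65–85% of the
cutoff, tilt ≤ 12° off the donor axis; absent frames at 130–190% — and
per-atom Gaussian jitter (default 0.003 nm) is redrawn for a frame if it
ever flips the designed state (verified by re-evaluating the pair's own
criterion), so detection recovers designed occupancies *exactly*, not
statistically.  Truth-table exactness is defined per designed (pair, kind):
a close hydrogen bond also implies a side-chain COM contact, and such
incidental events of other kinds are deterministic consequences of the
designed state (mirrored schedules therefore yield exactly mirrored
profiles) but are not listed in the truth table.

The cluster fixture builds two conformers whose post-fit RMSD is rescaled
to the requested separation, with per-frame wobble of RMS amplitude
`wobble` (so within-group pairwise RMSD < 2·wobble); wobble ≥ separation/4
is rejected.  ALA-chain templates keep a full backbone so default backbone
selections work.

None of this is physically realistic: no force field, no solvent, no
correlated dynamics, no crowded environment in which competing contacts
blur criteria boundaries.  Passing tests therefore demonstrate the
*correctness of the measurement machinery* — detectors, aggregation,
partition, clustering, diagnostics — not that any particular biological
ensemble has particular occupancies.

## Problem sizes and numerical choices

Test and acceptance runs use 100 random frames of ≤ 50 residues for
detector–oracle equivalence, 500 frames for occupancy recovery, 120-frame
mirrored dimers, a 50-frame (30/20) clustering fixture and 1000-point
projection series — sizes at which exhaustive brute-force oracles remain
cheap while every code path is exercised.  Strict `<` comparisons at all
cutoffs; hydrogen-bond angles computed via a clipped arccos; degenerate
geometry (coincident donor/hydrogen, < 3 or collinear fit atoms, all-zero
projection series) raises typed errors rather than returning NaN.  All
randomness flows through `numpy.random.default_rng` seeds supplied by the
caller; identical spec + seed reproduces byte-identical generated PDB
output.

## Known limitations

* No periodic-boundary reimaging, no trajectory formats (XTC/DCD), no mmCIF.
* No π-stacking geometry classes, cation-π, or water-mediated bridges.
* Protonation is an input, not predicted; His charge is a flag.
* The asymmetry score treats pairs independently (no weighting by contact
  kind or occupancy magnitude).
* Occupancies are frame-count fractions; no autocorrelation-based error
  bars or effective sample sizes are attached.
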