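# Methods

## Fragmentation model

The target system is divided into mutually exclusive families of atoms
("fragments") whose union covers every non-solvent, non-ion atom exactly
once.  The cuts are chemically motivated:

- **Nucleotides** split at the glycosidic bond.  The base fragment keeps
  the ring system, all exocyclic substituents and the glycosidic nitrogen
  (N9 for purines, N1 for pyrimidines); the sugar+phosphate fragment keeps
  C1′/H1′, the sugar, and the residue's own 5′-phosphate (OP1/OP2/OP3 and
  any phosphate protons travel with their phosphorus; the bridging O3′
  stays with its own sugar).  A 5′-terminal residue without phosphate still
  forms one sugar-kind fragment, so an n-residue chain always yields 2n
  fragments.  A residue in which no glycosidic bond can be found in the
  bond graph (heavily modified nucleotides) is kept whole as a single
  ligand-kind fragment with a warning.
- **Amino acids** split into a backbone fragment (N, H, CA, HA, C, O and
  terminal variants) and a side-chain fragment; glycine has no side chain.
- **Ligands** split into fused-ring systems (rings sharing atoms merge) and
  acyclic substituent arms.  An arm with at least two heavy atoms is its
  own fragment; a single-heavy-atom substituent (with its hydrogens) joins
  the ring it hangs off, which keeps the fragment count low without
  creating chemically meaningless one-atom QM jobs.

Exclusivity and exhaustiveness are asserted on every partition, and the
partition is a function of topology only — atom order and model choice do
not affect it.

## Parent molecules and capping

The QM region for a fragment (its "parent molecule") is the fragment plus
every other fragment having at least one atom — hydrogens included — within
a cutoff of any central-fragment atom, with an inclusive comparison at the
boundary.  The default cutoff is 5 Å, chosen as the radius at which
through-space ring-current and electrostatic effects on ¹H shieldings decay
below the method's other error sources; the selection is symmetric and
monotone in the cutoff by construction.

Each covalent bond crossing the QM boundary is saturated by exactly one cap
group placed along the broken-bond direction with fixed standard lengths
(no geometry optimization, so parents are bit-reproducible):

| severed bond | cap | lengths |
|---|---|---|
| C–X | H on C | 1.09 Å |
| N–X | H on N | 1.01 Å |
| O–X | H on O | 0.96 Å |
| P–O3′ (bridge, P inside) | O–H on P | P–O 1.60 Å, O–H 0.96 Å |

The O–H cap completes the phosphate when a bridging oxygen leaves with its
residue; on the opposite side of the same cut the sugar's O3′ receives a
plain H, which *is* the hydroxyl group there.  The O–H cap proton is placed
at a tetrahedral angle with a deterministic reference frame.  Caps closer
than 0.8 Å to an existing QM atom, or 0.5 Å to another cap, abort parent
construction with the offending bond named — this guards against malformed
input geometry rather than being expected in practice.

The parent's net charge is the sum of formal charges of its real atoms.
Formal charges are name-based: each bare terminal phosphate oxygen beyond
the first (no HOPx partner) carries −1, so an internal phosphodiester
contributes −1.  Multiplicity is fixed at 1; open-shell systems are out of
scope.

## Charge embedding

Partial charges follow Gasteiger's partial equalization of orbital
electronegativity (PEOE): six damped iterations with damping (1/2)^k, the
classic σ-framework electronegativity polynomials per element and
hybridization, hydrogen's special cation electronegativity 20.02, and
charge flowing along each bond toward the more electronegative atom,
normalized by the donor's cation electronegativity.  This matches an
independent implementation (RDKit, same iteration count) to ~1e-15 e on
σ-framework molecules; conjugated hydroxyl oxygens (carboxylic acids) are
typed sp³ here where some implementations promote them to sp², a
sub-0.2 e divergence that is immaterial for embedding purposes and
documented as implementation-defined.  The π-refinement of the original
Gasteiger–Hückel scheme is omitted — the σ charges are the dominant term at
embedding distances — and externally computed charges can be supplied
instead wherever a `full_charges` mapping is accepted.

Charges are computed once on the intact molecule per model, then sliced per
parent, which avoids artificial open valences at fragment boundaries.
Because the iteration moves a few tenths of an electron across what later
becomes a QM boundary, the raw remainder slice would drift from the
remainder's formal charge; a uniform charge-conservation correction
(~1e-3 e per atom) restores the exact total, so a remainder omitting k
deprotonated phosphates carries exactly the complementary −k bookkeeping.
Solvent and monoatomic ions are excluded from both fragments and point
charges by default.

## QM jobs and the mock backend

Decks are Gaussian-style: route line requesting `NMR=GIAO` at
mPW1PW91/6-311G(d) with `SCRF=(IEFPCM,Solvent=water)` by default, charge
and multiplicity, Cartesian coordinates (central fragment first, then
surroundings, then caps), and a trailing x y z q point-charge block.
Coordinates and charges print with six decimals so identical inputs give
byte-identical decks.  No cavity keywords are passed for the point charges:
the PCM cavity is built from the QM atoms only.  The parser extracts
per-atom isotropic shieldings, maps them back to structure atoms by input
order, marks caps, and treats an atom-count mismatch or a missing
normal-termination mark as a hard failure; batch runs isolate failures per
job and proceed on the surviving central-fragment records.

The mock backend is a deterministic surrogate for testing, *not* physics:

    σ_i = σ₀(el_i) − 0.05 Σ_j Z_j/d²_ij − 1.0 Σ_k q_k/d_ik   (+ optional seeded noise)

with σ₀(H) = 31.0 ppm.  It is smooth in geometry, sensitive to both the QM
neighborhood and the embedding charges, and identical for identical
spec+seed, which is what the pipeline contracts need.

## Referencing and statistics

σ_Standard = mean(δ_exp + σ_calc) over the matched protons of the selected
entity, and δ_calc = σ_Standard − σ_calc.  The plus sign is the unique
choice consistent with the conversion formula: it makes the mean signed
error vanish identically, which is the point of an internal standard
(systematic offsets of the functional/basis combination cancel).  This
identity is asserted to 1e-9 ppm on every report.  The regression is
δ_exp (y) on σ_calc (x), so a perfect prediction has slope −1; MAD, R²,
slope and intercept come from ordinary least squares.  Statistics can be
recomputed with a user-supplied exclusion list; there is no automatic
outlier rejection.

Ensemble predictions average shieldings atom-by-atom across models before a
single referencing pass; since referencing is affine, this equals
referencing each model and averaging the shifts (asserted to 1e-9 ppm).
Atoms missing from any model are excluded and listed.

The swap scan considers prochiral amino pairs (G H21/H22, C H41/H42,
A H61/H62; the table is extensible).  For each fully assigned pair it
computes the drop in summed absolute error upon interchanging the two
experimental values and flags drops above 0.1 ppm — the scale of the
internal-vs-external-standard discrepancy, i.e. the smallest difference the
referencing itself can resolve.  Pairs whose experimental values invert the
deposition convention (first member upfield of 7 ppm, second downfield) are
flagged separately; half-assigned pairs are reported untestable.

Decoy discrimination computes the 2×2 MAD matrix between two prediction
sets and two experimental tables, each cell with its own internal standard;
each table's verdict is the argmin prediction set.  Hydrogen bonds are
detected geometrically (N/O donors and acceptors, H···A ≤ 2.5 Å,
D–H···A ≥ 120°); the correlation report pairs each donor proton's shortest
H···A distance with its signed error and returns the Pearson r when at
least three non-degenerate points exist.

## Synthetic data

Toy nucleic-acid structures are assembled from CCD ideal-coordinate residue
templates, linked by placing each residue's vacant OP3 site on the previous
O3′ (preserving the tetrahedral phosphate) and choosing, per residue, the
first of a deterministic set of candidate orientations that leaves at least
1.45 Å between non-bonded atoms.  The result is valence-complete, clash-free
and compact enough that every fragment has neighbors within 5 Å — but it is
not a physically accurate helix: there is no base pairing, no realistic
backbone torsion distribution, and duplex strands are simply juxtaposed at
~4 Å closest approach.  Passing tests therefore demonstrate the pipeline's
bookkeeping, geometry handling and statistical machinery, not prediction
accuracy on real nucleic acids, which depends on the external QM engine and
on conformational sampling that is out of scope here.  Multi-model
ensembles add seeded Gaussian coordinate jitter (default 0) to emulate NMR
model scatter.

Synthetic shift tables set δ_exp = σ_true − σ_mock + N(0, noise) per
central-fragment proton, optionally exchange listed prochiral pairs, and
serialize to NMR-STAR (values quantized to 1e-4 ppm).  Prochiral amino
pairs receive a ±0.6 ppm split between members (1.2 ppm separation, the
scale of observed amino-proton splittings) — without distinguishable
predictions a swap would be undetectable in principle.  A swap exchanges
two experimental values, so it perturbs neither their sum nor σ_Standard;
it surfaces purely as paired errors, which is exactly what the scan keys on.

## Problem sizes and numerical choices

Tests and the acceptance script run on 4–24-residue fixtures (up to ~750
atoms), where each stage completes in milliseconds and the whole suite in
seconds; the pipeline itself is O(N²) in the distance scans and has no
size-specific constants.  Bond perception uses CCD templates with a
covalent-radius fallback (tolerance 0.45 Å, hydrogens keep their nearest
heavy atom); residue numbering is taken verbatim from the input; altloc
handling keeps the highest occupancy; coordinates are Å and charges e
throughout.  Known limitations: no hydrogen placement, no mmCIF input, no
π-refined charges, no pseudo-atom PCM cavity extension, single-reference
closed-shell systems only, and the mock backend must never be mistaken for
a shielding model.
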