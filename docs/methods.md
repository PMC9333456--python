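# Methods

## Scope

`c2map` annotates C2 β-sandwich domains in user-supplied coordinate models
and computes the associated sequence analytics.  It deliberately does *not*
produce the models themselves: RoseTTAFold / AlphaFold2 inference, Modeller
assembly, molecular dynamics relaxation, QMEAN / MolProbity model-quality
scoring, circular dichroism measurement or prediction, and TM-span
prediction beyond a simple hydropathy screen are all out of scope.  The
package consumes models and span annotations produced by such tools.

## Hydrogen-bond model

Amide hydrogens are rebuilt at N + 1.0 Å·unit(C_prev − O_prev); prolines
and chain-leading residues (including residues following a Cα–Cα gap
> 4.5 Å) receive none.  Donor–acceptor pairs are scored with the
Kabsch–Sander electrostatic energy with the standard coupling
0.084·332 kcal·Å/mol; a pair with any inter-atom distance below 0.5 Å is a
clash and returns a "no bond" sentinel.  Bonds are accepted below
−0.5 kcal/mol, at most two acceptors per donor, and only at sequence
separation ≥ 2.  The −0.5 kcal/mol cutoff and the coupling constant are
fixed, not tunable: they define what "contributes to the backbone hydrogen
bond pattern" means everywhere downstream, including the domain-boundary
rule.

## Strands, bulges, sheets

β-bridges follow the classical two-pattern definitions for parallel and
antiparallel geometry.  Bridges chain into ladders; two ladders merge
across a β-bulge when the interruption is at most 1 residue on one strand
and at most 4 on the other (the classical asymmetric allowance — a pure
1-residue rule at residue level cannot merge a textbook bulge, because the
narrow-pair bridge adjacent to the bulge necessarily fails as well).
Merged runs of ≥ 3 residues become strands.  Pairing orientation is the
majority vote of the underlying bridges; sheets are connected components of
the pairing graph.

## C2 recognition, typing, boundaries, loops

A C2 candidate is a pair of four-stranded sheets whose faces pack within a
mean nearest-Cα distance of 11 Å (typical β-sandwich packing; exposed as a
parameter).  Strands over-split by the assignment are merged first when
separated by ≤ 2 residues and paired to the same partner.  Overlapping
candidates are resolved greedily, earlier sequence start first.

The two C2 connectivities are encoded as data: spatial sheet orders
(4-1-8-5 / 3-2-7-6) for Type-I and its single-step circular permutation
(3-8-7-4 / 2-1-6-5) for Type-II.  Classification counts how many observed
strand adjacencies match each template; ties or zero matches are
`ambiguous`.  Under the Type-II arrangement strands 1 and 2 are sheet
neighbours, which is why loop 1 of a Type-II domain is the β1-2 hairpin.

Boundaries follow the H-bond rule: the first residue of strand 1
participating (as donor or acceptor) in a backbone bond to a paired strand,
through the last such residue of strand 8.  Because terminal strand
residues cannot complete a full bridge pattern, detected boundaries sit one
residue inside the constructed strand ends; all recovery guarantees are
therefore stated at ±1 residue.

Loops are the inter-strand segments β1-2 … β7-8.  The pocket face is found
geometrically: the strand axis is the mean of sign-aligned per-strand
end-to-end vectors, and a loop belongs to the pocket face when its Cα
majority falls on the same side of the sandwich mid-plane as the β1-2
segment.  The first three pocket-face loops in sequence order are named
loop1–loop3.  Loop-to-strand assignments of loops 2 and 3 are thus derived,
never hard-coded.

## Comparison and subdomains

Rigid superposition uses the SVD (Kabsch) solution with a determinant
correction so reflections are never returned; fewer than three points or
collinear input raise a degeneracy error.  An independent quaternion
(Horn) implementation serves as a cross-check in the tests and the
acceptance script, with agreement required to 1e-9 Å.

Two annotated domains align strand-by-strand (ordinal 1↔1 … 8↔8),
residues paired positionally from each strand start up to the shorter
strand; loops pair likewise up to the shorter loop.  RMSD is over
strand-paired Cα.  Domains of different topology types are refused.
Insertion length at a loop is the candidate-minus-reference loop-length
difference (floored at zero), i.e. lengths are measured *relative to the
reference domain*, and the insertion interval is the unpaired trailing part
of the candidate loop.

A subdomain is called at a host loop iff at least two paralogs carry an
insertion strictly longer than 20 residues there and their
secondary-structure classes agree.  The class of an insertion is
helix-rich (> 40 % H), sheet-rich (> 40 % E) or coil; "conserved secondary
structure" is operationalised as class agreement because no quantitative
criterion is established for it.  With a single paralog the rule cannot be
evaluated and candidates are returned flagged unconfirmed.

Fragment stitching requires ≥ 10 shared residues per junction, superposes
each next fragment onto the growing assembly over the shared Cα, keeps
overlap coordinates from the earlier fragment, and warns (but proceeds)
above a 2.0 Å junction RMSD.

The packaged reference C2 domain is **synthetic**: a noise-free generator
sandwich whose six pocket slots (the central two residues of each
pocket-face hairpin) carry acidic residues.  It stands in for an
experimentally anchored reference structure, which users can substitute;
the pocket census then counts candidate residues aligned to those slots
that are D/E, calling "binding-likely" at ≥ 4 acidic slots (configurable).

## Sequence analytics

The isoelectric point uses Biopython's ProtParam implementation of the
Bjellqvist pKa set (including the terminal-residue pKa adjustments) for the
Henderson–Hasselbalch net charge, but bisects the full pH 0–14 range to
|charge| < 1e-4.  Full-range bisection matters: the stock ProtParam-module
bracket starts at pH 4.05 and silently clips strongly acidic segments —
two of the six FerI motifs have pI below 4.05.  With this one fixed table
all six FerI values reproduce their sequence-consistent printed values to
±0.005 pH (the asserted tolerance is ±0.15 to cover table rounding and
pKa-set drift).

The 280 nm extinction coefficient uses the Gill & von Hippel increments;
both the all-cystine (⌊nCys/2⌋ pairs) and all-reduced conventions are
reportable.  Alignment identity uses, per pair, columns with at least one
residue as denominator; similarity classes are
{ILVM, FWY, KRH, DE, ST, NQ, AG, C, P}, one common choice, documented here
because the original similarity-server classes are not published.

TM-span arithmetic is convention-locked after verifying them against every
printed table cell: span length is inclusive (last − first + 1), the
extracellular count is exclusive (last − first).  The conserved hinge
proline is searched from the span end forward (10 residues), falling back
to the nearest proline inside the span — required for the otoferlin row,
whose shifted span prediction places the hinge proline inside the membrane.

### Printed-table reconciliation

The packaged FerI and TM tables ship cell-for-cell as printed, and the
loaders surface two internal inconsistencies rather than hiding them.
In the FerI table the otoferlin and myoferlin rows have their scalar
columns (Length and pI) transposed: each row's printed length matches the
*other* row's actual sequence length, and the computed pI values match the
printed pair only after the same swap (to ±0.005, versus ±0.35–0.47 as
printed).  Sequences are authoritative; records expose both `pi_printed`
and the sequence-consistent `pi_expected`, flagged `reconciled`.  In the TM
table two span ends disagree by one digit with the row's own printed
length/count (which every other row satisfies exactly); the ends are
reconstructed from the row's printed scalars and flagged likewise.

## The synthetic generator

The generator emulates exactly the features the pipeline keys on, and no
more:

* **Strands** on a shared axial grid (3.3 Å rise, Cα pleat giving
  ~3.8 Å Cα–Cα), sheet neighbours 4.8 Å apart with N/C/O displaced so that
  registered antiparallel pairs form near-ideal reciprocal N–H···O=C bonds
  (≈ −3 kcal/mol); sheets 10 Å apart.  Strand direction alternates with
  sequence ordinal, making every template adjacency antiparallel.
* **Loops** as circular arcs (3.8 Å Cα spacing) bulging away from the
  domain centre, with backbone atoms along the local tangent and carbonyls
  pointing outward to avoid stray bonds.  Infeasible loop lengths (arc
  shorter than the chord) raise a specification error.
* **Insertions** extend a host loop by a requested length, either as coil
  (a longer arc) or helix-rich: an ideal α-helix (φ = −57°, ψ = −47°,
  built by internal-coordinate chaining) entering from outside the domain
  and returning through a short coil, sized so the trailing insertion
  interval is majority-helical.
* **Sequences** are drawn from near-natural amino-acid frequencies,
  proline-free on strands and helices (no amide H), seeded.
* **Noise** is a Gaussian displacement field with the requested marginal σ,
  smoothly correlated along the chain (correlation length 3 residues) and
  rigid within each residue.  This emulates predicted-model error, whose
  local covalent geometry is near-ideal; independent per-atom noise would
  corrupt bond lengths and falsely trigger the chain-break rule.  Under
  this model the full pipeline recovers strand count, topology, boundaries
  (±1) and insertion lengths exactly for σ ≤ 0.3 Å (50/50 replicates in
  the acceptance suite, 100/100 in development runs).
* **Determinism**: one integer seed fixes sequences, insertions and noise;
  identical seeds reproduce structures bit-for-bit.

What passing these tests shows — and does not.  The generator provides
idealised geometry: real predicted models have irregular strand lengths,
twisted sheets, imperfect H-bond registers and genuinely ambiguous
sandwich packings.  Success on the synthetic suite demonstrates the
correctness of the logic (bridge patterns, bulge merging, template
matching, the boundary rule, insertion arithmetic), not field performance
on hard models; the sandwich-distance and merge parameters remain exposed
for that reason.

## Problem sizes and numerical choices

The acceptance suite uses 50 seeded replicates (~120–180 residues each),
1000 random 10-point clouds for the superposition cross-check, and a
three-fragment stitching round trip — chosen to exercise every code path
at canonical C2 scale.  Bisection tolerances: pI |charge| < 1e-4;
superposition degeneracy threshold: second singular value < 1e-12 of
scale; stitching junction tolerance 2.0 Å (warning only).  Ties in greedy
candidate resolution go to the earlier sequence start; ties in topology
scoring return `ambiguous` rather than guessing.

## Known limitations

* Bridge patterns need both flanking residues, so single terminal residues
  of a strand are invisible to the H-bond boundary rule (hence ±1).
* The sheet-packing test uses a fixed 11 Å mean-distance criterion; heavily
  curved or domain-swapped sandwiches may need a different threshold.
* The Ca²⁺-pocket census depends on the packaged synthetic reference unless
  an experimental reference structure is supplied.
* `hydropathy_scan` is a screening fallback, not a TM predictor.
* Cross-structure RMSD values against experimental structures depend on the
  alignment method; strand-anchored rigid alignment can differ from
  flexible-alignment figures by a few tenths of an Å.
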