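# Methods

## The QTY substitution model

The QTY code is a fixed residue map — L→Q, I→T, V→T, F→Y, every other
residue to itself — applied to positions inside annotated transmembrane
(TM) intervals and nowhere else. Its image residues Q, T, Y are fixed
points, so the conversion is idempotent by construction; the map never
touches D, E, K, R or H, so charged-residue counts (and hence, to first
order, the isoelectric point) are conserved. TM intervals follow the
UniProt TRANSMEM convention (1-based, inclusive); user-supplied intervals
override annotation. Substitution applies to *every* L/I/V/F inside an
interval, including partially helical edges — the code is defined on the
annotated helix, with no further qualification. Variation statistics are

    TM variation %      = 100 · substituted / TM residues
    overall variation % = 100 · substituted / sequence length

kept as raw floats internally and rounded half-up to two decimals only in
reports.

## Sequence properties

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water (18.015 Da), matching how protein MW is conventionally
reported; the per-substitution deltas implied by the code are +14.97 Da
(L→Q), −12.05 Da (I→T), +1.97 Da (V→T) and +16.00 Da (F→Y), so the ledger
predicts the variant MW exactly.

Net charge at a given pH is a Henderson–Hasselbalch sum over side chains
(D, E, C, Y negative; H, K, R positive) and both termini, using the
Bjellqvist pK set including its residue-specific terminal corrections
(N-terminal pK 7.5 with overrides for A/M/S/P/T/V/E; C-terminal pK 3.55,
4.55 after Asp, 4.75 after Glu). The EMBOSS and Lehninger sets are
selectable alternatives but non-default, because the Bjellqvist constants
are what the standard web calculators report. The charge function is
strictly decreasing in pH, so the isoelectric point is found by sign
bisection on [0, 14], narrowing the bracket to 1e-6 pH — far below the
2-decimal reporting precision — and verified in tests against a brute
force 1e-4-step grid scan and against an independent implementation of
the same pK set.

An `X` ambiguity code contributes the mean residue mass (110.0 Da) and
zero charge, and passes through the QTY map unchanged.

## Structures and superposition

Coordinate files (PDB or mmCIF, parsed with gemmi) are reduced to one CA
per residue, ordered by author numbering plus insertion code. Altloc
conflicts resolve to the highest occupancy, ties to the alphabetically
first altloc — deterministic and conventional. Waters and non-amino-acid
HETATM records are dropped; common modified residues (MSE, SEP, TPO, …)
map to their parent one-letter code, unknowns to X; missing residues are
simply absent.

Sequence→structure mapping is a global pairwise alignment with identity
scoring (match +1, mismatch 0, gap −2). The deliberate choice of a flat
mismatch score lets a QTY variant — ~25% different overall, ~50% in TM
segments — align gaplessly to its native counterpart, which a
substitution matrix would not guarantee. Aligned mismatches are allowed
and counted; coverage below 0.3 aborts with a mapping error (almost
always a wrong chain or entry). A caveat of identity scoring: where a
disordered region offers several equal-scoring registers the reported
pairs are one arbitrary optimum; such pairs are geometrically wrong and
are removed by the rejection cycles below.

Superposition is the closed-form Kabsch solution: SVD of the covariance
of centred paired coordinates, with the determinant sign flip that
forbids reflections (the rotation is proper to 1e-9). Fewer than three
pairs is underdetermined and an error; collinear sets leave the rotation
non-unique and produce a warning, not an error. Refinement mimics the
widely used align protocol: up to 5 cycles of drop-pairs-above-2.0-Å,
refit, stop when stable; both the cycle-0 RMSD over all pairs and the
refined RMSD over retained pairs are reported so the protocol is
transparent. One numerical safeguard: if the initial least-squares fit
shows deviations above max(10·cutoff, 10 Å) — which happens when a few
pairs are wildly displaced (disordered loops, register errors) and drag
the fit — the rejection loop starts from a fit on the most consistent
half of the pairs instead. Without this, a handful of 100-Å outliers can
push *every* pair past the cutoff and collapse the refinement. When TM
annotations are available the pipeline trims paired residues outside the
first/last TM segment before fitting, a deterministic version of the
common practice of deleting flexible termini before comparing folds.

## Surface hydrophobicity

SASA uses a CA-coarse Shrake–Rupley scheme: one sphere per residue,
centred on the CA, with an effective radius from tabulated amino-acid
volumes (r = (3V/4π)^⅓, 2.4–3.8 Å), inflated by a 1.4 Å water probe.
Accessibility is the fraction of a deterministic golden-spiral quadrature
(default 960 points) outside all neighbouring inflated spheres, times the
sphere area. Fewer than 100 points is rejected as meaningless. This
single-sphere model is intentionally coarse — the pipeline compares
backbone-level predicted models, and the claim being quantified is
directional — so absolute values are not comparable to atomic SASA;
relative buried/exposed contrast and convergence in the point count
(<0.5% change on doubling) are what the tests pin down.

The surface hydrophobicity index is Σ(SASA·h)/Σ(SASA) over residues with
SASA ≥ 10 Å² (a conventional exposed/buried cut, configurable), with h
the Kyte–Doolittle hydropathy by default (Hopp–Woods and Eisenberg
selectable). Every QTY substitution strictly lowers h (L 3.8→−3.5,
I 4.5→−0.7, V 4.2→−0.7, F 2.8→−1.3), so on identical coordinates the
variant index is strictly below the native one whenever an exposed
residue changed — the testable form of "the QTY surface is more
hydrophilic". A structure with no exposed residue yields an explicit
null index rather than 0.

## Synthetic data: what it emulates, what it does not

The generator is the offline ground truth for every stage:

- **Sequences** alternate loops and TM segments (defaults: 12 TM × 21
  residues, 30-residue loops, 50% of TM positions drawn from {L,I,V,F}),
  chosen to match the 10–12-helix architecture, ~44–55% TM substitution
  load and ~10–25% overall load of real solute carriers. Loops draw only
  from {G,S,N,D,K,E,P} — never L/I/V/F — so any substitution outside a TM
  interval is unambiguously a bug.
- **CA traces** lie on ideal α-helices (rise 1.5 Å/residue, twist 100°,
  radius 2.3 Å), making all consecutive CA–CA distances exactly the
  analytic chord √((2r sin(twist/2))² + rise²) = 3.83 Å; bundles place
  parallel helices on an 8 Å circle to create buried and exposed faces.
- **Decoys** add isotropic Gaussian noise (per-coordinate σ) and then a
  uniform random rigid move (rotation via normalized quaternions — no
  axis bias — plus a bounded translation). After optimal superposition
  the expected RMSD is σ√3, which calibrates the whole superposition
  stack: the measured/expected ratio stays within [0.8, 1.2] for chains
  of ≥200 residues.

Every generator is a pure function of its spec and seed.

What the synthetic fixtures do **not** contain: real TM boundary noise
(UniProt annotations are model-derived and drift between releases),
helical kinks and re-entrant loops, side chains, lipid or detergent
context, and genuine prediction error, which is structured rather than
isotropic. Passing the offline suite therefore demonstrates algorithmic
correctness and calibration, not agreement with any particular published
measurement on real transporters; the two reference-data tests cover that
and require network access (UniProt) or user-supplied coordinate files
(`data/external/`: experimental entries and deposited QTY-variant models).

## Problem sizes and defaults

The test-suite and acceptance-script problem sizes — 50 synthetic
records, 100 random peptides for the pI oracle, 500- and 200-residue
decoy chains, 960 quadrature points, rotation-grid oracles on ≤8-point
sets (8° coarse scan, 0.25° local refinement) — are the package's chosen
verification sizes: large enough that every statistical band (e.g. the
σ√3 calibration) is tight, small enough that the whole suite runs in
seconds on one CPU.

## Known limitations

- TM intervals are taken as given; no hydropathy-based TM prediction.
- CA-only throughout: no side-chain building or all-atom RMSD.
- The exact terminal-trimming choices behind published RMSD comparisons
  of deposited models are not fully specified; raw and refined RMSD plus
  explicit trim counts make this package's protocol reproducible, but
  external comparisons carry a protocol tolerance.
- The surface index is this package's own operationalization of surface
  hydrophobicity; it is validated by its mathematical properties, not
  against an external standard.
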