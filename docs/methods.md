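# Methods

## Scope and model of the problem

`thermoscreen` implements the desk-side half of a rational
thermostability-engineering workflow. The physical premise is that an
enzyme loses activity at elevated temperature where its structure is
locally flexible and weakly packed; rigidifying those positions —
classically by replacing negative-φ glycines with bulky residues —
raises the melting behaviour without touching the catalytic machinery.
The package therefore screens *sites*, not physics: conformational
ensembles come from an external MD engine exported as multi-model PDB,
and mutation energies come from external calculators (a CHARMm-style
"mutation energy" or FoldX ΔΔG). Nothing in the package evaluates a
force field.

## Data model and units

Coordinates are Ångström throughout; energies kcal/mol
(negative = stabilizing); angles degrees in (−180, 180] with cis = 0
and trans = +180 (IUPAC sign convention, cross-checked against
MDAnalysis). Residues carry author numbering (1-based, inclusive
ranges like `A:238-245`); the residue count always comes from the
input file and is never hard-coded. Only multi-model PDB is accepted
as the ensemble carrier — binary trajectory formats would pull in
heavyweight dependencies and users can export frames beforehand.
Alternate locations keep altloc 'A' or blank; HETATM records are
retained as metadata but excluded from analysis.

## Ensemble analytics

Superposition is least-squares with a proper rotation enforced
(no reflections), computed via scipy's rotation machinery and verified
in tests against an independent quaternion-eigenvector implementation
to 1e-8. RMSD/RMSF use Cα atoms by default: Cα is present in every
standard residue, which keeps per-residue values comparable across
residue types; the selection is configurable (e.g. N, CA, C, O).

The **average structure** aligns window frames to the first window
frame, averages, then performs one re-averaging pass
(re-align to the mean, re-average, final alignment) — a standard
stabilizer that removes the dependence on the arbitrary initial
target. The **representative frame** is the window frame with minimal
Cα RMSD to that average, ties broken toward the lower index so runs
are reproducible. **RMSF** is the root-mean-square displacement of
each Cα from its mean position over the aligned window frames.

Analysis windows are frame-index based; frame times are carried as
metadata only (no time-unit arithmetic). A window of `None` means the
trailing 75 % of frames, mirroring the convention of discarding the
equilibration phase of a production run (e.g. analysing 5–20 ns of a
20 ns trajectory); per-frame RMSD is the exception and always covers
every frame.

**Hydrogen bonds** are geometric: donor–acceptor distance
≤ 3.5 Å *and* D–H–A angle ≥ 150°, both configurable; each
donor–acceptor residue pair counts once and same-residue pairs are
skipped. Donors are N/O atoms bearing a hydrogen; since modelled
structures usually lack hydrogens, the backbone amide H is constructed
on the bisector of the C(i−1)–N and CA–N directions at 1.01 Å —
side-chain donors participate only when explicit hydrogens exist, and
only intra-protein bonds are counted (no solvent). On an ideal
poly-alanine α helix this detector finds exactly the n−4 backbone
i→i−4 bonds, which the tests pin down by exhaustive pair enumeration.
Published per-trajectory H-bond averages for the tyrosinase case
(67 at 300 K, 58 at 400 K) depend on trajectories that are not
distributed and are context, not targets.

## The six-factor site screen

Factors run in a fixed order (RMSD regions → RMSF regions → contacts →
glycine φ → alanine scan) so provenance tags are comparable across
runs. Decisions that the source workflow made by eye are explicit
parameters here:

* **RMSD-shift regions** are supplied as ranges — judging "severe
  deformation" from superimposed snapshots is an analyst call, not a
  computation this package fakes. `per_residue_rmsd` supports that
  judgement by comparing two ensembles' average structures per residue.
* **RMSF increase**: "significant" is quantified as
  (high − low) ≥ δ over ≥ L consecutive residues, defaults
  δ = 0.5 Å, L = 3; both are mandatory config values echoed in every
  report.
* **Contacts**: residues are in contact when their representative
  atoms (Cβ; Cα for glycine) lie *strictly* below the threshold. The
  packaged default threshold is the literal 3 of the rule this screen
  reproduces; that value carries no published unit and 3 Å Cβ–Cβ is
  physically very tight, so the threshold is always echoed and should
  be reviewed per system (6–8 Å is the common contact-map choice).
  Low-contact regions are runs of ≥ 3 residues with ≤ 2 partners.
* **Glycine φ**: φ = dihedral C(i−1)–N–CA–C; sites with φ < 0 pass.
  Chain-start glycines have no φ and are skipped with a warning.
* **Alanine scan**: sites with X→Ala energy < −0.5 kcal/mol pass.
* **Exclusions** (active site, metal binding, substrate pocket) are
  user-supplied lists with reasons — the package has no catalytic-site
  detector and never infers them.

Aggregation is a set union with per-factor provenance; it is
order-independent and idempotent, and removed sites are logged with
their reason. Secondary-structure accounting takes class ranges from
external annotation (no DSSP re-implementation); percentages are
100·count/total rounded half-up to two decimals, matching the printed
precision of the tables it reproduces. On the packaged tyrosinase
inputs the five-factor union yields 56 sites; note the β-turn ranges in
the source annotation enumerate 7 residues (overlapping a coil range at
269) while the published count is 6 — turn counting is left to the
user's region input.

## Energy screens

Tables keyed by mutation sets hold all three shapes (alanine scan,
per-site saturation, combinatorial) with an engine tag. Engines use
different scales — the saturation table lists G124W at −3.82 kcal/mol
where FoldX gives −0.997 for the same mutation — so tables from
different engines are never mixed in one screen. Self-rows
(GLY→GLY = 0) are kept on parse but excluded from minima and
destabilizing counts; consequently a column described as "all
substitutions stabilizing" counts 18 negative non-self entries, with
the printed 0 self-row set aside. Classification bands are inclusive
to neutral at ±0.5 exactly. Ranking sorts ascending by energy with
lexicographic labels as tie-break, so it is a deterministic
permutation of the input.

Combinatorial rankings come either from a supplied table or, absent
one, by additivity from the saturation singles; the report states
which path produced the ranking. The additive path combines only the
sites that survive the candidate cutoff and caps the cross-product at
the four most stabilizing sites — additivity degrades with many
simultaneous substitutions and an unbounded cross-product is neither
reviewable nor trustworthy. `additive_ddg` refuses duplicated sites,
where the assumption is violated outright.

## Synthetic data

The generators exist to give every analysis a known ground truth:

* `make_helix` builds a poly-alanine backbone (N, CA, C, O, Cβ) by
  internal-coordinate chain extension with ideal bond geometry
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard angles), so the
  requested (φ, ψ) are exact by construction; sequences may plant
  glycines.
* `make_ensemble` adds iid Gaussian noise per coordinate with
  residue-wise σ. The RMSF of a residue whose only motion is such
  noise tends to σ·√3, which the tests verify within 5 % on
  2000-frame ensembles (60-residue chain, noisy residue mid-chain —
  on short chains the rigid-body fit partially chases a single noisy
  residue and biases its RMSF low).
* `make_energy_table` draws background entries uniform in
  [−0.4, +0.4] kcal/mol — inside the neutral band — and inserts
  planted entries verbatim, so default-threshold screens must return
  exactly the planted truth.

All generators are pure functions of their arguments including the
seed. What the Gaussian ensembles deliberately do **not** model:
correlated motion, anisotropy, rigid-body drift or any temperature
dependence beyond the σ values chosen. Passing the planted-recovery
suites therefore demonstrates that the screening arithmetic is
correct, not that the thresholds are well-calibrated for real
trajectories.

The end-to-end fixture runs use a 40-residue chain, 150 frames per
temperature, background σ = 0.12 Å versus 0.55 Å on a planted
5-residue stretch (ΔRMSF ≈ 0.74 Å against the 0.5 Å threshold), and
two planted stabilizing substitutions against neutral background —
sizes chosen so a 20-seed sweep of the whole pipeline completes in
seconds while leaving clear margins between signal and threshold.

## Numerical choices and degenerate inputs

Superposition requires ≥ 3 non-collinear points (collinearity checked
via singular values); rotations are validated to determinant +1 within
1e-8. Zero-RMSD assertions use a 1e-6 Å tolerance, the residual noise
floor of the underlying least-squares solver. Dihedrals reject
coincident consecutive points and collinear triples rather than return
an arbitrary angle; −180° maps to +180°. PDB output rounds to the
format's 3 decimals, and atom serials wrap above 99999. Config files
are strict: unknown keys, inverted bands and missing referenced files
are errors at validation time, and every default is echoed into the
report so a report is a complete record of its thresholds.

## Known limitations

Sites in the aggregate are residue numbers, which assumes the
single-chain case this workflow targets; multi-chain screens must run
per chain. The H-bond detector handles donors without explicit
hydrogens only for backbone amides. The contact default of 3 (see
above) reproduces its source rule but is not a recommended contact-map
threshold. Additivity of ΔΔG is an approximation that ignores
site–site coupling; supplied combinatorial tables take precedence for
exactly that reason.
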