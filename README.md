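# thermoscreen

Multi-factor rational-design screening of rigidifying mutation sites for
enzyme thermostability engineering.

Protein engineers who want a more thermostable enzyme typically (1) run
molecular-dynamics simulations of the target at a working and an elevated
temperature, (2) locate the flexible, weakly packed regions that melt
first, and (3) ask an empirical energy function which substitutions at
those positions lower the folding free energy. `thermoscreen` implements
the screening computations that sit between those external tools: it
consumes structures (PDB), exported conformational ensembles
(multi-model PDB) and mutation-energy tables (CSV/TSV or FoldX
PositionScan output), and it never runs an MD engine or a ΔΔG calculator
itself.

## What it computes

**Flexibility analytics** over an ensemble of frames
$x_1, \dots, x_T$: per-frame RMSD to a reference after optimal (Kabsch)
superposition; the average conformation and the representative frame
(the frame minimizing Cα RMSD to the average); the per-residue
fluctuation

$$\mathrm{RMSF}(i) = \sqrt{\tfrac1T \sum_t \lVert x_{i,t} - \langle x_i \rangle \rVert^2},$$

and geometric hydrogen-bond counts per frame (donor–acceptor ≤ 3.5 Å,
D–H–A ≥ 150° by default, amide H constructed when absent).

**Candidate-site factors**, each nominating residues with provenance:

1. regions with an RMSD/conformational shift at high temperature
   (supplied as ranges such as `A:238-245`);
2. regions where RMSF increases by ≥ δ (default 0.5 Å) over ≥ 3
   consecutive residues between the two temperatures;
3. residues with few contacts, where residues i and j are in contact
   when their β-carbon distance (α carbon for glycine) is strictly
   below a threshold (default literal 3, always echoed in reports);
4. glycines with backbone φ = C(i−1)–N–CA–C below 0° — positions that
   tolerate a bulkier, rigidifying side chain;
5. sites whose X→Ala mutation energy is below −0.5 kcal/mol
   (alanine scanning);

plus user-supplied exclusions (catalytic residues, metal-binding sites,
substrate pockets) with recorded reasons.

**Energy screens** on external mutation-energy tables (kcal/mol,
negative = stabilizing): classification into
stabilizing / neutral / destabilizing bands (−0.5 / +0.5), the
candidate cutoff (< −1.5) for saturation scans, per-site best
substitutions, combinatorial ranking, and additive ΔΔG
(ΔΔG of a multi-mutant ≈ Σ singles, distinct sites required).

## Worked example

The package ships the published screening inputs for the
*Streptomyces* tyrosinase case study it reproduces. Running
`python examples/energy_screens.py` prints:

```
alanine-scan hits below -0.5 kcal/mol: 12
after dropping copper-binding His:     [20, 102, 124, 135, 137, 205, 240]
site 124: best substitution TRP at -3.82 kcal/mol, 1 destabilizing option(s)
site 137: best substitution TRP at -3.58 kcal/mol, 0 destabilizing option(s)
substitutions below the -1.5 kcal/mol candidate cutoff: 24
top-ranked double mutant: G124W/G137W at -7.42 kcal/mol
additive FoldX ddG of the double mutant: -1.98166 kcal/mol
```

Twelve positions pass the alanine scan; removing the five copper-binding
histidines (which would cost catalytic activity) leaves seven. Saturating
the two key glycines shows tryptophan is the most stabilizing
substitution at both, and the double mutant G124W/G137W tops the
combinatorial ranking — the design the screen selects. The other
examples cover the glycine-φ screen (`glycine_phi_screen.py`, 22
glycines → 11 with φ < 0 → 10 after the active-site exclusion), the
flexibility analytics on synthetic ensembles
(`flexibility_analysis.py`), and the end-to-end pipeline
(`full_screen.py`).

The same screens are available from the shell:

```bash
thermoscreen screen --config config.json      # full multi-factor run
thermoscreen flex --ensemble frames.pdb --out flexout/
thermoscreen energy --table saturation.csv --out energy.json
thermoscreen fixtures helix --out helix.pdb   # synthetic inputs
```

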