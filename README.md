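# kinactive

Structural criteria for the **catalytically active conformation of protein
kinase domains**, plus the machinery to rank and benchmark predicted kinase
models by activation-loop confidence.

## The problem

A typical (PKA-like) protein kinase domain is only catalytically competent
when it can simultaneously bind ATP, Mg²⁺ and a protein substrate.  The
classic DFGin/DFGout distinction is not enough: the activation loop — the
segment running from the DFG motif to the APE motif — must be *extended*
against the C-lobe, and its C-terminal half (the P+1 loop) must form the
substrate-binding groove.  `kinactive` renders an **Active** verdict for one
kinase chain from five geometric criteria:

1. **DFGin** spatial state — the DFG-Phe ring tip Cζ is near the C-helix
   Glu4 Cα (< 11 Å) and far from the β3-Lys Cα (> 11 Å);
2. **BLAminus** dihedral state — the X, D, F residues of the XDFG motif lie
   in the B, L, A Ramachandran basins and the Phe χ1 is gauche− (~ −60°);
3. **salt bridge** — min β3-Lys Nζ to C-helix Glu Oε1/Oε2 distance < 3.6 Å
   (skipped for the lysine-less WNK kinases and for MAP3K12/13);
4. **ActLoopNT** — backbone H-bond between activation-loop residue 6
   (DFGxxX) and the residue before HRD (XHRD): min N–O / O–N < 3.6 Å;
5. **ActLoopCT** — APE9 Cα (nine residues from the loop end, XxxxxxAPE) to
   HRD-Arg carbonyl O < 6 Å in Ser/Thr kinases, < 8 Å in Tyr kinases
   (skipped for HASPIN/TP53RK/PKDCC, which lack an APE motif).

The three regulatory-spine distances (HRD-His/DFG-Phe, DFG-Phe/Glu4,
Glu4/HPN7, each the closest side-chain heavy-atom contact) are reported but
deliberately excluded from the verdict.  Missing atoms make a criterion
*unevaluable*, never failed.

For predicted models (pLDDT in the B-factor column), the package ranks
candidate models by the **minimum pLDDT over the activation loop** and
benchmarks them against reference structures by the **activation-loop
backbone RMSD (N, Cα, C, O) after Kabsch superposition of the C-terminal
domains** — fit on the C-lobe, measure on the loop, no refitting.

A curation module implements the supporting data-preparation rules:
ortholog-hit filtering (identity > 50 %, coverage > 90 %, gaps < 10 %, all
strict), greedy 90 %-identity redundancy reduction, active-template
selection (two distinct PDB entries per kinase, most ordered loop residues
first, then best resolution), and MSA-depth truncation.

Because real coordinates cannot ship with the package, a synthetic-fixture
module builds kinase-like chains from backbone torsions (ideal-geometry
chain growth) and places the criterion atoms analytically so that every
observable hits a prescribed target to 1e-6 Å — the ground truth the test
suite classifies against.

## Worked example

Generate a synthetic kinase in the active geometry and classify it:

```sh
$ kinactive fixtures make --out active.pdb --annotation-out ann.json
$ kinactive classify active.pdb --annotation ann.json
spatial=DFGin (PheCz-LysCa 12.00 Å, PheCz-Glu4Ca 9.00 Å, cutoff 11 Å)
dihedral=BLAminus (X/D/F regions B/L/A, chi1 bin minus)
saltbridge=in (3.00 Å, cutoff 3.6 Å)
actloop_nt=in (2.90 Å, cutoff 3.6 Å)
actloop_ct=in (3.50 Å, cutoff 6 Å)
spine_intact=True (max spine 4.20 Å, cutoff 5 Å; not part of the Active verdict)
Active: True
```

Each line echoes the measured observable against its cutoff: the DFG-Phe
tip sits 9 Å from Glu4 but 12 Å from the β3-Lys (DFGin), the Lys–Glu salt
bridge is formed at 3.0 Å, and both activation-loop contacts are within
hydrogen-bonding range, so all five criteria pass.

Rank a seeded model ensemble by activation-loop confidence and measure the
best model's loop RMSD against the unperturbed reference:

```sh
$ kinactive fixtures ensemble -n 4 --seed 7 --out-dir models/
$ kinactive rank models/*.pdb --annotation ann.json
model_id                 min_plddt_al  mean_plddt_al
models/model_000.pdb     91.00         91.00
models/model_002.pdb     86.38         86.38
models/model_001.pdb     76.43         76.43
models/model_003.pdb     55.00         55.00
$ kinactive rmsd models/model_000.pdb active.pdb \
    --annotation-model ann.json --annotation-ref ann.json
rmsd_al	0.343
rmsd_ctd	0.000
n_al_residues	23
```

The top-ranked model (min loop pLDDT 91.0) deviates by 0.34 Å over the 23
loop residues, while the C-terminal-domain fit is exact (the generator
perturbs only the loop).

## Library layout

| module | contents |
| --- | --- |
| `kinactive.structure` | PDB/mmCIF reading (gemmi-backed), chain/atom access, alt-loc reduction, minimal PDB writer |
| `kinactive.annotation` | anchor-residue resolution, ordinal offset arithmetic (DFG6, APE9, Glu4, HPN7, XHRD), family exception registry |
| `kinactive.geometry` | distances, IUPAC torsions, Ramachandran/χ1 binning, Kabsch superposition, RMSD |
| `kinactive.classify` | observables, per-criterion states, the Active verdict |
| `kinactive.assess` | min-pLDDT ranking, residue correspondence, fit-then-measure loop RMSD, benchmark summaries |
| `kinactive.curation` | hit filtering, greedy identity clustering, template selection, MSA truncation |
| `kinactive.fixtures` | torsion-space backbone builder, target-closing kinase fixtures, seeded perturbations and ensembles |
| `kinactive.cli` | `kinactive classify / rank / rmsd / benchmark / fixtures` |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
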