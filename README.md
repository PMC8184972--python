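# piscore

Machine-learning quality assessment of protein–protein interfaces in
macromolecular assemblies, with optional cryo-EM fit-to-map scoring.

Structures of assemblies fitted into cryo-EM maps frequently contain
subunit-interface errors that density-based validation does not catch,
especially at intermediate-to-low resolution. `piscore` scores each
pairwise chain interface of a model with the **PI-score** — the signed
decision value of a support vector machine trained on twelve interface
features — where positive means native-like and the magnitude is
confidence. For models with an accompanying density map it also computes
per-residue fit-to-map correlations, their interface average (**iCCC**),
and a **weighted combined score**

    combined = (w1 · normalized_PI + w2 · iCCC) / (w1 + w2),   w2 = 10,

with the PI-score normalized by saturation at |2.5| and w1 the 0.1-bin
index of the normalized magnitude. The combined score lies in [−1, 1],
higher is better.

The twelve features per interface: interface residue count, conserved
interface residues, charged/polar/hydrophobic residue fractions, heavy-atom
contact pairs, shape complementarity (Sc), hydrogen bonds, salt bridges,
interface solvation energy, a hydrophobic-specificity p-value, and buried
interface area. An interface is the set of residues whose Cα lies within
7 Å of the partner chain's Cαs; interfaces with fewer than 10 residues on
either side are not scored. Everything is re-implemented from first
principles (Shrake–Rupley SASA, dot-surface Sc, Kabsch superposition,
Gaussian map simulation); see `docs/methods.md` for the definitions,
defaults and design choices.

A synthetic-data module generates toy two-chain complexes and labelled
rigid-body decoys (near-native: f_Nal ≥ 0.7 ∧ iRMSD ≤ 3 Å; negative:
f_Nal < 0.3 ∨ iRMSD > 4 Å), making the whole pipeline testable without any
downloads.

## Worked example

```python
import piscore as ps

# a toy two-helix complex standing in for a real multi-chain model
structure = ps.make_toy_complex(ps.ToyComplexSpec(seed=99))
interface = ps.assign_interface(structure, "A", "B")   # 7 A Ca cutoff
features  = ps.compute_feature_vector(structure, interface, seed=0)

from piscore.classifier import load_model
import importlib.resources
model = load_model(importlib.resources.files("piscore") / "data" / "default_model.json")
print(round(ps.pi_score(model, features.as_array()), 2))   # 1.5

result = ps.combined_score(pi=-1.67, iccc=0.27)
print(result.w1, round(result.combined, 2))                # 7 -0.12
```

The native-like toy interface scores +1.5 (positive → native-like, and
|1.5| > 1 puts it in the reliable part of the score range). The second call
reproduces a published-style combined score: a PI-score of −1.67 normalizes
to −0.668 (bin index w1 = 7), and blending with iCCC 0.27 gives −0.12 — the
interface is poor even though the fit to density is passable.

The same operations are available from the shell:

```bash
piscore score model.pdb -o interface_scores.csv        # features + PI-scores
piscore train features.csv -o model.json               # CV report + SVM
piscore decoys --n-complexes 3 --outdir decoys/        # labelled decoy set
piscore combined --pi -1.67 --iccc 0.27                # prints -0.12
piscore metrics --counts 8 9 1 2                       # TPR/FPR/... table
```

`piscore score` uses a bundled default SVM trained on the synthetic decoy
generator's dataset (`scripts/make_default_model.py` regenerates it);
supply `--classifier your_model.json` to use your own.

## Layout

```
src/piscore/
  structure_io.py      PDB/mmCIF reading, PDB writing, residue classes
  interface_core.py    interface assignment, contacts, iRMSD/f_Nal, dedup
  surface_geometry.py  SASA, buried area, dot surfaces, Sc
  physchem_features.py H-bonds, salt bridges, solvation, p-value, features
  classifier.py        sklearn-style estimator, metrics, bins, ranking
  density_scoring.py   map I/O, simulated maps, CCC/per-residue/iCCC, combined
  synthetic_decoys.py  toy complexes, decoy sampling, synthetic datasets
  cli.py               the `piscore` command
  data/                radii, solvation parameters, default model
```
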