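# latentmol

Reversible SMILES latent representations with multi-objective
particle-swarm molecular optimization.

## The problem

Lead optimization in drug discovery is a multi-parameter search: improve
solubility, permeability and safety (ADMET) endpoints without losing
potency.  Chemical space is discrete and vast, so direct enumeration
fails.  `latentmol` implements the inverse-QSAR strategy: learn a
*continuous, decodable* molecular descriptor, score points of that
descriptor space with a weighted desirability function, and search it
with a particle swarm — so that optimization happens in a smooth vector
space while every candidate remains a decodable molecule.

It is a library first (the importable API plus `examples/`), with a thin
`latentmol` command-line tool over the same functions.

## The three legs

**1. A seq2seq translator** (`latentmol.translator`).  A character-level
GRU encoder reads an *enumerated* SMILES rendering and compresses it
through a fully connected bottleneck of 512 tanh units, so every latent
component lies in [−1, 1]; a GRU decoder reconstructs the *canonical*
SMILES by beam search.  Training on (enumerated → canonical) pairs
forces molecule-level rather than string-level features into the latent
vector, which doubles as a QSAR descriptor and as the optimization
variable.  The network and its training loop are implemented directly in
NumPy — no deep-learning framework required.

**2. Property evaluation and desirability scoring**
(`latentmol.properties`, `latentmol.scoring`).  SlogP, QED and synthetic
accessibility are computed from structure (RDKit); trainable endpoints
are XGBoost models over the 512-d latent features with a 75/25 diverse
split + 5-fold CV protocol.  Each objective i maps its raw value to a
desirability S_i ∈ [0, 1] (1 in the optimal range, 0 outside the
recommended range, linear between), and the final score is the weighted
mean

    F = Σ S_i·W_i / Σ W_i .

Similarity to a reference (Tanimoto on ECFP4-equivalent Morgan
fingerprints) and SMARTS substructure presence enter the same weighted
mean as constraints; the substructure constraint is hard by default.

**3. A particle swarm optimizer** (`latentmol.optimizer`).  Particles
carry position x and velocity v in the latent box; each step applies

    v ← w·v + c1·r1·(x_best_i − x) + c2·r2·(x_best − x),   x ← x + v

with per-particle uniform draws r1, r2, velocity capping and position
clipping to [−1, 1].  The swarm starts at the encoder output of the seed
molecule; every position is decoded and scored (invalid decodes score
0), the per-iteration top-k molecules are collected, and restarts merge
deduplicated by canonical SMILES.

`latentmol.fixtures` generates a synthetic homologous-family corpus and
planted property labels so the entire pipeline runs with no external
data.

## Worked example

`examples/05_optimize.py` trains the desk-scale translator on the
synthetic corpus, fits a property model for a planted heteroatom-
fraction signal, and optimizes a branched pure-carbon seed molecule
under a similarity constraint and a hard methyl-branch-motif
constraint:

```
property model test R2 = 0.641
seed CCCCC(C)C: F = 0.715
17 unique optimized molecules (all contain the motif)
  F=0.845 sim=0.33  CCCC(C)CCl
  F=0.842 sim=0.30  CCC(C)CCCN
  F=0.821 sim=0.24  CCC(C)CCl
  F=0.815 sim=0.27  CCC(C)CCCl
  F=0.806 sim=0.39  CC(C)CCCl
mean swarm-best F by iteration: [0.715, 0.715, 0.757, 0.78, 0.801, 0.801]
```

Reading the output: the seed is all-carbon, so its predicted heteroatom
fraction sits below the objective's optimal range and F = 0.715; the
swarm finds chloro- and amino-substituted homologs that keep the methyl
branch (hard constraint satisfied by every returned molecule) and
reasonable Tanimoto similarity, raising the weighted desirability to
0.845.  The rising, never-decreasing swarm-best trace is the
optimizer's defining behaviour.  (Numbers vary slightly with the
training seed; run the script to regenerate.)

The other examples each demonstrate one capability: translator round
trips (`01`), desirability scoring (`02`), swarm dynamics on an analytic
surface (`03`), and the property-model training protocol with its
permutation control (`04`).

## Command line

```bash
latentmol make-fixtures --n 200 --seed 42 --out fixtures/
latentmol train-translator --corpus fixtures/corpus.txt --out model/
latentmol encode --in mols.txt --model model/ --out vectors.csv
latentmol decode --in vectors.csv --model model/ --beam 5 --out smiles.csv
latentmol train-property --endpoint logS --data labels.csv --model model/ --task regression --out pmodel/
latentmol optimize --seed-smiles "CCCCCCCc1ccccc1" --model model/ \
    --objectives objectives.yaml --iterations 50 --restarts 100 --out run/
```

Every run writes a JSON manifest (subcommand, options, seed, version)
next to its outputs.

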