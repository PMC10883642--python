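"""Synthetic molecule corpora and planted property labels.

Every other module is testable without any external download: a small
fragment grammar (alkyl chains, ethers, amines, thioethers, halogens and
a few simple rings) assembles valid, unique molecules deterministically
from a seed, and structure-derived label rules (heteroatom fraction,
scaled size, ring presence) plant a recoverable signal for the property
training harness.  The grammar is deliberately tiny so that the
translator converges in minutes on one CPU; it is *not* chemically
representative of drug-like space.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord
from .errors import GrammarExhausted

# Valence-clean homologous families: X-(C)n(-methyl)-Y chains with an
# optional terminal phenyl.  The family is dense (a few hundred members)
# so a 200-molecule sample leaves every held-out molecule with close
# homologs in training — the property that lets a desk-scale translator
# learn the rendering-to-canonical mapping systematically.  The grammar
# trades chemical breadth for structural regularity.
_ENDS = ["", "O", "N", "F", "Cl"]
_PHENYL = "c1ccccc1"


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus."""

    n_molecules: int
    max_heavy_atoms: int = 14
    grammar: str = "default"
    seed: int = 0


def _random_smiles(rng: random.Random, max_heavy: int) -> str:
    """Assemble one candidate SMILES from the fragment grammar."""
    n = rng.randint(1, 7)
    left = rng.choice(_ENDS)
    chain = "C" * n
    if n >= 2 and rng.random() < 0.4:
        pos = rng.randint(1, n - 1)
        chain = chain[:pos] + "(C)" + chain[pos:]
    if rng.random() < 0.35:
        return left + chain + _PHENYL
    return left + chain + rng.choice(_ENDS)


def generate_corpus(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Deterministically generate ``spec.n_molecules`` unique valid
    molecules with at most ``spec.max_heavy_atoms`` heavy atoms."""
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = random.Random(spec.seed)
    seen: dict[str, None] = {}
    budget = 200 * spec.n_molecules
    for _ in range(budget):
        smi = _random_smiles(rng, spec.max_heavy_atoms)
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumHeavyAtoms() > spec.max_heavy_atoms:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen[canon] = None
            if len(seen) == spec.n_molecules:
                break
    else:
        raise GrammarExhausted(
            f"only {len(seen)} unique molecules after {budget} attempts"
        )
    return [
        MoleculeRecord(smi, smi, str(k), True) for k, smi in enumerate(seen)
    ]


_RULES = ("hetero_fraction", "size_score", "ring_flag")


def planted_property_labels(
    corpus: list[MoleculeRecord],
    rule: str = "hetero_fraction",
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Structure-derived labels plus Gaussian noise.

    Rules: ``hetero_fraction`` (non-carbon heavy atoms / heavy atoms),
    ``size_score`` (heavy-atom count / 12, the default corpus size cap),
    ``ring_flag`` (1 if any ring).  Returns a DataFrame with columns
    ``smiles`` and ``label``; the rule and noise level are recorded in
    ``DataFrame.attrs``.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {_RULES}")
    if not corpus:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in corpus:
        mol = rec.mol()
        heavy = mol.GetNumHeavyAtoms()
        if rule == "hetero_fraction":
            value = sum(
                1 for a in mol.GetAtoms() if a.GetAtomicNum() != 6
            ) / heavy
        elif rule == "size_score":
            value = heavy / 12.0
        else:
            value = float(mol.GetRingInfo().NumRings() > 0)
        rows.append((rec.canonical_smiles, value))
    df = pd.DataFrame(rows, columns=["smiles", "label"])
    df["label"] = df["label"] + rng.normal(0.0, noise_sd, size=len(df))
    df.attrs["rule"] = rule
    df.attrs["noise_sd"] = noise_sd
    df.attrs["seed"] = seed
    return df
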