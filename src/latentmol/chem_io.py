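"""Molecule and latent-vector I/O.

Parsing, canonicalization, SMILES enumeration, character-level
tokenization and file round-trips for everything the rest of the package
touches.  RDKit is the single canonicalization dialect for the whole
package: equality of molecules is always tested on the canonical SMILES
written here, never on raw input strings.
"""

from __future__ import annotations

import csv
import random
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from .errors import (
    DimensionError,
    FileFormatError,
    InvalidSmiles,
    RangeWarning,
    UnknownSymbol,
)

RDLogger.DisableLog("rdApp.*")

#: Dimension of the latent bottleneck representation.
LATENT_DIM = 512


@dataclass
class MoleculeRecord:
    """One parsed molecule.

    ``valid`` is True iff ``input_smiles`` parses under the SMILES grammar
    with satisfiable valences; ``canonical_smiles`` is then the unique
    canonical rendering (idempotent under re-canonicalization) and None
    otherwise.  Invalid records are retained, never dropped, so batch
    output aligns row-for-row with user files.
    """

    input_smiles: str
    canonical_smiles: str | None
    id: str
    valid: bool

    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumAtoms() == 0:
            return cls(smiles, None, id or "", False)
        return cls(smiles, Chem.MolToSmiles(mol), id or "", True)

    def mol(self) -> Chem.Mol:
        if not self.valid:
            raise InvalidSmiles(f"record {self.id!r} is not a valid molecule")
        return Chem.MolFromSmiles(self.canonical_smiles)


def canonicalize(smiles: str) -> str:
    """Return the unique canonical SMILES, raising :class:`InvalidSmiles`
    for unparseable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidSmiles(f"cannot parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def enumerate_smiles(smiles: str, n: int, seed: int = 0) -> list[str]:
    """Up to ``n`` syntactically distinct renderings of one molecule.

    Renderings are produced by writing the molecule with randomly permuted
    atom numbering (the standard SMILES-enumeration recipe), deduplicated,
    with an attempt budget of ``10 * n``; if the molecule admits fewer
    distinct renderings than requested, all that were found are returned.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(f"cannot parse SMILES: {smiles!r}")
    rng = random.Random(seed)
    n_atoms = mol.GetNumAtoms()
    seen: dict[str, None] = {}
    for _ in range(10 * n):
        if n_atoms > 1:
            perm = list(range(n_atoms))
            rng.shuffle(perm)
            rendered = Chem.MolToSmiles(
                Chem.RenumberAtoms(mol, perm), canonical=False
            )
        else:
            rendered = Chem.MolToSmiles(mol)
        if rendered not in seen:
            seen[rendered] = None
            if len(seen) == n:
                break
    return list(seen)


# Character-level tokenization with the standard exceptions: two-letter
# organic-subset atoms (Cl, Br) and whole bracket-atom groups are single
# tokens, as are %nn two-digit ring closures; everything else is one
# character.  Pure per-character splitting would make "Cl" ambiguous with
# C + l.
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Br|Cl|%\d{2}|.)")
_SINGLE_CHARS = set("BCNOPSFIbcnops0123456789()=#-+/\\.@%*$:~")

START = "<s>"
END = "</s>"
PAD = "<pad>"
UNK = "<unk>"


@dataclass
class TokenSequence:
    """An ordered token list bracketed by start/end markers."""

    tokens: list[str]

    @property
    def interior(self) -> list[str]:
        return self.tokens[1:-1]

    def detokenize(self) -> str:
        return "".join(self.interior)


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into tokens; exact inverse of
    :func:`detokenize` on every valid string."""
    tokens = _TOKEN_RE.findall(smiles)
    for t in tokens:
        if len(t) == 1 and t not in _SINGLE_CHARS:
            raise UnknownSymbol(f"character {t!r} is not a SMILES symbol")
        if t.startswith("[") and not t.endswith("]"):
            raise UnknownSymbol(f"unterminated bracket atom in {smiles!r}")
    return TokenSequence([START, *tokens, END])


def detokenize(seq: TokenSequence | Sequence[str]) -> str:
    """Join interior tokens back into the source SMILES string."""
    if isinstance(seq, TokenSequence):
        return seq.detokenize()
    toks = [t for t in seq if t not in (START, END, PAD)]
    return "".join(toks)


class Vocabulary:
    """Bijective symbol/index map with reserved pad/start/end/unknown slots."""

    RESERVED = (PAD, START, END, UNK)

    def __init__(self, symbols: Iterable[str]):
        self._index: dict[str, int] = {s: i for i, s in enumerate(self.RESERVED)}
        for s in sorted(set(symbols) - set(self.RESERVED)):
            self._index[s] = len(self._index)
        self._symbol = {i: s for s, i in self._index.items()}

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    @property
    def pad(self) -> int:
        return self._index[PAD]

    @property
    def start(self) -> int:
        return self._index[START]

    @property
    def end(self) -> int:
        return self._index[END]

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise UnknownSymbol(f"symbol {symbol!r} not in vocabulary") from None

    def symbol(self, index: int) -> str:
        return self._symbol[index]

    @classmethod
    def from_corpus(cls, smiles_list: Iterable[str]) -> "Vocabulary":
        symbols: set[str] = set()
        for s in smiles_list:
            symbols.update(tokenize(s).interior)
        return cls(symbols)

    def encode(self, smiles: str) -> np.ndarray:
        """Token indices of ``smiles`` including start/end markers."""
        return np.array(
            [self.index(t) for t in tokenize(smiles).tokens], dtype=np.int64
        )

    def decode(self, indices: Sequence[int]) -> str:
        """SMILES string from indices, stopping at the end marker."""
        toks = []
        for i in indices:
            s = self._symbol[int(i)]
            if s == END:
                break
            if s in (START, PAD):
                continue
            toks.append(s)
        return "".join(toks)

    def to_dict(self) -> dict:
        return dict(self._index)

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        v = cls.__new__(cls)
        v._index = {s: int(i) for s, i in d.items()}
        v._symbol = {i: s for s, i in v._index.items()}
        return v


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _records_from_txt(path: Path) -> list[MoleculeRecord]:
    records = []
    for k, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        records.append(MoleculeRecord.from_smiles(line, id=str(k)))
    return records


def _records_from_csv(path: Path) -> list[MoleculeRecord]:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise FileFormatError(f"{path}: CSV needs a 'smiles' column")
        records = []
        for k, row in enumerate(reader):
            rid = row.get("id") or str(k)
            records.append(MoleculeRecord.from_smiles(row["smiles"], id=rid))
    return records


def _records_from_sdf(path: Path) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records = []
    for k, mol in enumerate(supplier):
        if mol is None:
            records.append(MoleculeRecord("", None, str(k), False))
        else:
            smi = Chem.MolToSmiles(mol)
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            records.append(MoleculeRecord(smi, smi, rid or str(k), True))
    return records


def read_molecules(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read molecules from ``smiles_txt``, ``csv`` or ``sdf`` files.

    The format is inferred from the extension unless given.  Unparseable
    entries are flagged ``valid=False`` but kept, so the output count
    always equals the number of input entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"no such file: {path}")
    if format is None:
        format = {".txt": "smiles_txt", ".smi": "smiles_txt", ".csv": "csv",
                  ".sdf": "sdf"}.get(path.suffix.lower())
        if format is None:
            raise FileFormatError(f"cannot infer format of {path}")
    if format == "smiles_txt":
        return _records_from_txt(path)
    if format == "csv":
        return _records_from_csv(path)
    if format == "sdf":
        return _records_from_sdf(path)
    raise FileFormatError(f"unknown format {format!r}")


def write_vectors(
    path: str | Path,
    vectors: np.ndarray | Sequence[Sequence[float]],
    ids: Sequence[str] | None = None,
    smiles: Sequence[str] | None = None,
) -> None:
    """Write latent vectors as a CSV with columns id[, smiles], v_0..v_511."""
    arr = np.asarray(vectors, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != LATENT_DIM:
        raise DimensionError(
            f"expected {LATENT_DIM} components per vector, got {arr.shape[1]}"
        )
    if ids is None:
        ids = [str(i) for i in range(arr.shape[0])]
    header = ["id"] + (["smiles"] if smiles is not None else []) + [
        f"v_{i}" for i in range(LATENT_DIM)
    ]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for k in range(arr.shape[0]):
            row = [ids[k]]
            if smiles is not None:
                row.append(smiles[k])
            row.extend(repr(float(x)) for x in arr[k])
            writer.writerow(row)


def read_vectors(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a latent-vector CSV back into (ids, array of shape (n, 512)).

    A row of the wrong width raises :class:`DimensionError`; components
    outside [-1, 1] raise a :class:`RangeWarning` (the row is kept).
    """
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FileFormatError(f"{path}: empty vector file") from None
        vcols = [i for i, name in enumerate(header) if name.startswith("v_")]
        if len(vcols) != LATENT_DIM:
            raise DimensionError(
                f"{path}: expected {LATENT_DIM} vector columns, got {len(vcols)}"
            )
        ids, rows = [], []
        for row in reader:
            if len(row) != len(header):
                raise DimensionError(
                    f"{path}: row with {len(row)} fields, header has {len(header)}"
                )
            ids.append(row[0])
            rows.append([float(row[i]) for i in vcols])
    arr = np.asarray(rows, dtype=np.float64)
    if arr.size and (np.abs(arr) > 1.0 + 1e-9).any():
        warnings.warn(
            "latent components outside [-1, 1] found on read", RangeWarning
        )
    return ids, arr
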