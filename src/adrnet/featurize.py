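"""SMILES featurization into the two inputs the predictor consumes.

Each drug is represented twice:

* a heavy-atom **molecular graph** whose nodes carry (atomic number,
  chirality) and whose undirected edges carry (bond type, bond direction) —
  the input of the graph-network channel;
* a **substructure sequence**: the 1024-bit FP2 path fingerprint rendered as
  a 256-digit hexadecimal string, each digit packing four fingerprint bits —
  the input of the self-attention channel.

Graphs come from RDKit; FP2 fingerprints come from Open Babel's ``obabel``
executable, the reference implementation of the FP2 format. The hex dialect
is fixed as obabel's native fpt rendering (32 x 32-bit words, concatenated
in printed order), lowercased, so that outputs are reproducible.
"""

from __future__ import annotations

import json
import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import FeaturizationError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise is reported via exceptions

SEQUENCE_LENGTH = 256
HEX_ALPHABET = "0123456789abcdef"


class Chirality(IntEnum):
    UNSPECIFIED = 0
    CW = 1
    CCW = 2
    OTHER = 3


class BondType(IntEnum):
    SINGLE = 0
    DOUBLE = 1
    TRIPLE = 2
    AROMATIC = 3


class BondDirection(IntEnum):
    NONE = 0
    END_UP = 1
    END_DOWN = 2


# vocabulary sizes for embedding tables (atomic numbers 1..118 plus 0 pad)
NUM_ATOMIC_NUMBERS = 119
NUM_CHIRALITIES = len(Chirality)
NUM_BOND_TYPES = len(BondType)
NUM_BOND_DIRECTIONS = len(BondDirection)

_CHIRALITY_MAP = {
    Chem.ChiralType.CHI_UNSPECIFIED: Chirality.UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: Chirality.CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: Chirality.CCW,
}

_BOND_TYPE_MAP = {
    Chem.BondType.SINGLE: BondType.SINGLE,
    Chem.BondType.DOUBLE: BondType.DOUBLE,
    Chem.BondType.TRIPLE: BondType.TRIPLE,
    Chem.BondType.AROMATIC: BondType.AROMATIC,
}

_BOND_DIR_MAP = {
    Chem.BondDir.NONE: BondDirection.NONE,
    Chem.BondDir.ENDUPRIGHT: BondDirection.END_UP,
    Chem.BondDir.ENDDOWNRIGHT: BondDirection.END_DOWN,
}


@dataclass(frozen=True)
class Molecule:
    """A drug: an identifier plus its SMILES string."""

    id: str
    smiles: str


@dataclass
class MolecularGraph:
    """Heavy-atom graph with the four attributes the model consumes.

    ``node_attrs[i] = (atomic_number, Chirality)``;
    ``edges[k] = (u, v)`` unordered, each bond listed once;
    ``edge_attrs[k] = (BondType, BondDirection)``.
    """

    node_attrs: list[tuple[int, Chirality]]
    edges: list[tuple[int, int]]
    edge_attrs: list[tuple[BondType, BondDirection]]

    def __post_init__(self):
        n = len(self.node_attrs)
        if n < 1:
            raise FeaturizationError("graph must contain at least one atom")
        if len(self.edges) != len(self.edge_attrs):
            raise FeaturizationError("edges and edge_attrs lengths differ")
        seen = set()
        for u, v in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise FeaturizationError(f"edge ({u}, {v}) has out-of-range node index")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise FeaturizationError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def num_nodes(self) -> int:
        return len(self.node_attrs)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_attrs": [[a, c.name] for a, c in self.node_attrs],
                "edges": [list(e) for e in self.edges],
                "edge_attrs": [[t.name, d.name] for t, d in self.edge_attrs],
            }
        )


@dataclass(frozen=True)
class SubstructureSequence:
    """Exactly 256 lowercase hexadecimal digits (the packed FP2 fingerprint)."""

    tokens: str

    def __post_init__(self):
        if len(self.tokens) != SEQUENCE_LENGTH:
            raise FeaturizationError(
                f"sequence has {len(self.tokens)} tokens, expected {SEQUENCE_LENGTH}"
            )
        if not all(c in HEX_ALPHABET for c in self.tokens):
            raise FeaturizationError("sequence contains non-hexadecimal symbols")

    def token_ids(self) -> np.ndarray:
        """Integer token indices in [0, 16), suitable for embedding lookup."""
        return np.array([int(c, 16) for c in self.tokens], dtype=np.int64)

    def to_json(self) -> str:
        return json.dumps({"tokens": self.tokens})


def _parse_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise FeaturizationError("empty SMILES string", smiles=smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"could not parse SMILES {smiles!r}", smiles=smiles)
    if mol.GetNumAtoms() < 1:
        raise FeaturizationError(f"SMILES {smiles!r} has no heavy atoms", smiles=smiles)
    return mol


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Convert a SMILES string into the model's molecular graph.

    Heavy atoms only (implicit hydrogens are not nodes). Chirality and bond
    direction tags outside the enumerated categories collapse to
    ``OTHER``/``NONE``; bond orders outside {single, double, triple,
    aromatic} collapse to single.
    """
    mol = _parse_smiles(smiles)
    node_attrs = [
        (atom.GetAtomicNum(), _CHIRALITY_MAP.get(atom.GetChiralTag(), Chirality.OTHER))
        for atom in mol.GetAtoms()
    ]
    edges: list[tuple[int, int]] = []
    edge_attrs: list[tuple[BondType, BondDirection]] = []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        edge_attrs.append(
            (
                _BOND_TYPE_MAP.get(bond.GetBondType(), BondType.SINGLE),
                _BOND_DIR_MAP.get(bond.GetBondDir(), BondDirection.NONE),
            )
        )
    return MolecularGraph(node_attrs, edges, edge_attrs)


_HEX_WORD = re.compile(r"^[0-9a-fA-F]{8}$")


def _obabel_executable() -> str:
    exe = shutil.which("obabel")
    if exe is None:  # pragma: no cover - environment misconfiguration
        raise FeaturizationError(
            "the 'obabel' executable (Open Babel) is required for FP2 "
            "fingerprints but was not found on PATH"
        )
    return exe


def _run_fp2(smiles_list: list[str]) -> dict[int, str]:
    """Run obabel once over a batch; return index -> 256-digit hex string.

    Molecules obabel fails to parse are simply absent from the result.
    """
    exe = _obabel_executable()
    with tempfile.TemporaryDirectory() as tmp:
        smi_path = Path(tmp) / "batch.smi"
        lines = [f"{s}\tm{i}" for i, s in enumerate(smiles_list)]
        smi_path.write_text("\n".join(lines) + "\n")
        proc = subprocess.run(
            [exe, str(smi_path), "-ofpt", "-xfFP2", "-xN1024", "-xh", "-e"],
            capture_output=True,
            text=True,
        )
    result: dict[int, str] = {}
    current: int | None = None
    words: list[str] = []

    def flush():
        nonlocal current, words
        if current is not None and len(words) == 32:
            result[current] = "".join(words).lower()
        current, words = None, []

    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            flush()
            tokens = line[1:].split()
            if tokens and tokens[0].startswith("m") and tokens[0][1:].isdigit():
                current = int(tokens[0][1:])
            continue
        toks = line.split()
        if toks and all(_HEX_WORD.match(t) for t in toks):
            words.extend(toks)
    flush()
    return result


def fp2_hex_sequence(smiles: str) -> SubstructureSequence:
    """FP2 path fingerprint of a molecule as a 256-digit hexadecimal string.

    The 1024 fingerprint bits are packed four per digit; the digit order is
    Open Babel's native fpt hex rendering, lowercased. Deterministic for a
    given input.
    """
    # validate through both toolkits so graph and sequence featurization
    # agree on which molecules are usable
    _parse_smiles(smiles)
    hexes = _run_fp2([smiles])
    if 0 not in hexes:
        raise FeaturizationError(
            f"Open Babel could not fingerprint SMILES {smiles!r}", smiles=smiles
        )
    return SubstructureSequence(hexes[0])


@dataclass
class BatchResult:
    """Featurization of a batch: pairs in input order, plus skipped ids."""

    pairs: list[tuple[MolecularGraph, SubstructureSequence]]
    ids: list[str]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def featurize_batch(
    molecules: Iterable[Molecule],
    on_error: Literal["strict", "skip"] = "strict",
) -> BatchResult:
    """Featurize molecules in order, with a strict/skip failure policy.

    In ``strict`` mode the first failure raises; in ``skip`` mode failures
    are logged at WARNING and collected in ``result.skipped`` as
    ``(molecule id, reason)`` pairs.
    """
    if on_error not in ("strict", "skip"):
        raise ValueError(f"unknown on_error policy {on_error!r}")
    molecules = list(molecules)
    graphs: dict[int, MolecularGraph] = {}
    failures: dict[int, str] = {}
    for i, mol in enumerate(molecules):
        try:
            graphs[i] = smiles_to_graph(mol.smiles)
        except FeaturizationError as exc:
            if on_error == "strict":
                raise FeaturizationError(
                    f"molecule {mol.id!r}: {exc}", smiles=mol.smiles
                ) from exc
            failures[i] = str(exc)
    ok_indices = sorted(graphs)
    hexes = _run_fp2([molecules[i].smiles for i in ok_indices])
    pairs: list[tuple[MolecularGraph, SubstructureSequence]] = []
    ids: list[str] = []
    for pos, i in enumerate(ok_indices):
        mol = molecules[i]
        if pos not in hexes:
            msg = f"Open Babel could not fingerprint SMILES {mol.smiles!r}"
            if on_error == "strict":
                raise FeaturizationError(
                    f"molecule {mol.id!r}: {msg}", smiles=mol.smiles
                )
            failures[i] = msg
            continue
        pairs.append((graphs[i], SubstructureSequence(hexes[pos])))
        ids.append(mol.id)
    skipped = [(molecules[i].id, failures[i]) for i in sorted(failures)]
    for mol_id, reason in skipped:
        logger.warning("skipping molecule %s: %s", mol_id, reason)
    return BatchResult(pairs=pairs, ids=ids, skipped=skipped)
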