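"""Dataset handling: CSV loading with filtering, label statistics, splits,
and the planted-rule synthetic dataset generator.

The loader consumes already-binarized label columns (``id, smiles,
label_1..label_L``); records with a missing identifier or SMILES are
dropped and counted, mirroring the curation rules a real ADR benchmark
needs.

The synthetic generator assembles drug-like molecules by concatenating
chain-extendable SMILES fragments from a fixed pool, then plants one
substructure rule per label: label j is 1 exactly when marker pattern j
occurs in the molecule, after which each label is flipped independently
with probability ``label_noise``. With zero noise the labels are a
deterministic function of structure, so a structure-based model should
recover them; the pool is chosen so default markers have moderate,
unequal prevalences and realistic co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ValidationError

__all__ = [
    "DrugRecord",
    "LabelMatrix",
    "DatasetStats",
    "SyntheticSpec",
    "load_dataset",
    "label_stats",
    "split_train_test",
    "kfold",
    "jackknife",
    "generate_synthetic",
    "write_dataset",
    "FRAGMENT_POOL",
    "DEFAULT_MARKERS",
]


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identifier, SMILES, and its binary ADR label vector."""

    id: str
    smiles: str
    labels: tuple[int, ...]


@dataclass
class LabelMatrix:
    """N x L binary label matrix with row ids and column names."""

    values: np.ndarray
    ids: list[str]
    label_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("label matrix must be 2-D")
        if self.values.shape != (len(self.ids), len(self.label_names)):
            raise ValidationError("label matrix dimensions inconsistent with names")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("label matrix entries must be binary")

    @classmethod
    def from_records(cls, records: list[DrugRecord], label_names=None) -> "LabelMatrix":
        if not records:
            raise ValidationError("cannot build a label matrix from zero records")
        n_l = len(records[0].labels)
        if label_names is None:
            label_names = [f"label_{j}" for j in range(n_l)]
        return cls(
            values=np.array([r.labels for r in records], dtype=int),
            ids=[r.id for r in records],
            label_names=list(label_names),
        )


@dataclass
class DatasetStats:
    """Label cardinality ("base"), density, prevalence and co-occurrence."""

    n_samples: int
    n_labels: int
    label_cardinality: float
    label_density: float
    prevalence: pd.Series
    cooccurrence: pd.DataFrame

    def summary(self) -> dict[str, float]:
        return {
            "n_samples": self.n_samples,
            "n_labels": self.n_labels,
            "label_cardinality": self.label_cardinality,
            "label_density": self.label_density,
        }


def label_stats(labels: LabelMatrix) -> DatasetStats:
    """Cardinality = mean positives per sample; density = cardinality / L.

    The co-occurrence matrix counts joint positives for every label pair
    (diagonal: per-label positive counts).
    """
    values = labels.values
    if values.size == 0:
        raise ValidationError("empty label matrix")
    cardinality = float(values.sum(axis=1).mean())
    n_labels = values.shape[1]
    co = values.T @ values
    return DatasetStats(
        n_samples=values.shape[0],
        n_labels=n_labels,
        label_cardinality=cardinality,
        label_density=cardinality / n_labels,
        prevalence=pd.Series(
            values.mean(axis=0), index=labels.label_names, name="prevalence"
        ),
        cooccurrence=pd.DataFrame(
            co, index=labels.label_names, columns=labels.label_names
        ),
    )


# ---------------------------------------------------------------------------
# loading


def load_dataset(
    path: str | Path, label_columns: list[str] | None = None
) -> tuple[list[DrugRecord], int]:
    """Load a drug CSV (columns ``id, smiles, <labels...>``).

    Rows with a missing id or SMILES are dropped; the second return value
    counts them. Non-binary label cells and duplicate ids raise
    :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path} is empty") from exc
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"could not read {path}: {exc}") from exc
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ValidationError(f"{path} lacks required column {col!r}")
    if label_columns is None:
        label_columns = [c for c in df.columns if c not in ("id", "smiles")]
    if not label_columns:
        raise ValidationError(f"{path} has no label columns")
    missing = df["id"].isna() | (df["id"].astype(str).str.strip() == "")
    missing |= df["smiles"].isna() | (df["smiles"].astype(str).str.strip() == "")
    dropped = int(missing.sum())
    df = df[~missing]
    if df.empty:
        raise ValidationError(f"{path} contains no usable records")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate drug id {dup.iloc[0]!r} in {path}")
    records = []
    for row_number, (_, row) in enumerate(df.iterrows()):
        labels = []
        for col in label_columns:
            cell = row[col]
            if cell not in (0, 1, 0.0, 1.0, "0", "1"):
                raise ValidationError(
                    f"non-binary label {cell!r} in column {col!r}, row {row_number}"
                )
            labels.append(int(cell))
        records.append(
            DrugRecord(id=str(row["id"]), smiles=str(row["smiles"]), labels=tuple(labels))
        )
    return records, dropped


def write_dataset(
    records: list[DrugRecord], path: str | Path, label_names: list[str] | None = None
) -> None:
    """Write records in the same CSV dialect the loader consumes."""
    if not records:
        raise ValidationError("refusing to write an empty dataset")
    n_l = len(records[0].labels)
    if label_names is None:
        label_names = [f"label_{j}" for j in range(n_l)]
    df = pd.DataFrame(
        [
            {"id": r.id, "smiles": r.smiles, **dict(zip(label_names, r.labels))}
            for r in records
        ]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splits


def split_train_test(
    records: list[DrugRecord], fraction: float = 0.9, seed: int = 0
) -> tuple[list[DrugRecord], list[DrugRecord]]:
    """Seeded random holdout split; train size is floor(N * fraction)."""
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * fraction))
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def kfold(
    records: list[DrugRecord], k: int = 5, seed: int = 0
) -> list[tuple[list[DrugRecord], list[DrugRecord]]]:
    """Seeded k-fold partition; fold sizes differ by at most one."""
    n = len(records)
    if n < k:
        raise ValidationError(f"need at least k={k} records, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        val_idx = set(folds[i].tolist())
        train = [records[j] for j in range(n) if j not in val_idx]
        val = [records[j] for j in sorted(val_idx)]
        out.append((train, val))
    return out


def jackknife(
    records: list[DrugRecord],
) -> list[tuple[list[DrugRecord], list[DrugRecord]]]:
    """Leave-one-out pairs: each record held out exactly once."""
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records for the jackknife")
    return [
        (records[:i] + records[i + 1 :], [records[i]]) for i in range(n)
    ]


# ---------------------------------------------------------------------------
# synthetic planted-rule datasets

# Chain-extendable SMILES fragments: each is valid standalone and remains
# valid when concatenated (the next fragment bonds to the last main-chain
# atom, which always has free valence). Ring closures are self-contained.
FRAGMENT_POOL: tuple[str, ...] = (
    "CC",
    "CCC",
    "CCCC",
    "C(C)C",
    "CC(C)C",
    "CO",
    "CCO",
    "C(O)C",
    "CN",
    "CCN",
    "CNC",
    "C=CC",
    "CC=CC",
    "C(=O)C",
    "CC(=O)C",
    "C(=O)O",
    "C(=O)OC",
    "C(=O)NC",
    "c1ccccc1",
    "Cc1ccccc1",
    "c1ccc(C)cc1",
    "c1ccncc1",
    "Cc1ccncc1",
    "c1ccsc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C(Cl)C",
    "CC(Cl)C",
    "C(F)C",
    "C(F)(F)C",
    "C(Br)C",
    "CS",
    "CSC",
    "S(=O)(=O)C",
    "C(C#N)C",
    "C([N+](=O)[O-])C",
)

# One planted substructure rule per label (SMARTS): label j = 1 iff the
# molecule contains marker j. Ordered so the first four give a balanced
# default 4-label setting.
DEFAULT_MARKERS: tuple[tuple[str, str], ...] = (
    ("aromatic_ring", "c1ccccc1"),
    ("nitrogen", "[#7]"),
    ("carbonyl", "[CX3]=[OX1]"),
    ("halogen", "[F,Cl,Br,I]"),
    ("ether_oxygen", "[OX2]"),
    ("sulfur", "[#16]"),
    ("alkene", "C=C"),
    ("ring6_aliphatic", "C1CCCCC1"),
)


@dataclass
class SyntheticSpec:
    """Specification of a planted-rule synthetic multi-label drug dataset."""

    n_molecules: int = 200
    n_labels: int = 4
    label_noise: float = 0.0
    seed: int = 0
    min_fragments: int = 2
    max_fragments: int = 4
    fragment_pool: tuple[str, ...] = FRAGMENT_POOL
    markers: tuple[tuple[str, str], ...] = field(default=None)

    def __post_init__(self):
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValidationError("label_noise must be a probability")
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        if self.markers is None:
            if self.n_labels > len(DEFAULT_MARKERS):
                raise ValidationError(
                    f"only {len(DEFAULT_MARKERS)} default marker rules exist; "
                    f"supply explicit markers for n_labels={self.n_labels}"
                )
            self.markers = DEFAULT_MARKERS[: self.n_labels]
        if len(self.markers) != self.n_labels:
            raise ValidationError("need exactly one marker rule per label")


def marker_labels(smiles: str, markers) -> tuple[int, ...]:
    """Noise-free planted labels of a molecule: substructure matches."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    out = []
    for _, smarts in markers:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValidationError(f"invalid marker SMARTS {smarts!r}")
        out.append(int(mol.HasSubstructMatch(patt)))
    return tuple(out)


def generate_synthetic(spec: SyntheticSpec) -> list[DrugRecord]:
    """Deterministically generate a planted-rule synthetic dataset.

    Molecules are concatenations of ``min_fragments..max_fragments``
    fragments sampled from the pool; all SMILES parse. Labels follow the
    marker rules, then flip independently with probability
    ``spec.label_noise``.
    """
    # every marker must be realizable from the pool, else labels degenerate
    pool_hits = marker_labels("".join(spec.fragment_pool), spec.markers)
    unmatched = [
        name for (name, _), hit in zip(spec.markers, pool_hits) if hit == 0
    ]
    if unmatched:
        raise ValidationError(
            f"marker rules {unmatched} match nothing constructible from the pool"
        )
    # independent streams so the molecules drawn for a seed do not depend
    # on the noise level: only the labels change with label_noise
    struct_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(struct_ss)
    noise_rng = np.random.default_rng(noise_ss)
    records: list[DrugRecord] = []
    width = len(str(spec.n_molecules - 1))
    for i in range(spec.n_molecules):
        for _ in range(100):
            k = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
            parts = rng.choice(len(spec.fragment_pool), size=k)
            smiles = "".join(spec.fragment_pool[j] for j in parts)
            if Chem.MolFromSmiles(smiles) is not None:
                break
        else:  # pragma: no cover - pool is constructed to always compose
            raise ValidationError("could not assemble a valid molecule from the pool")
        labels = np.array(marker_labels(smiles, spec.markers))
        if spec.label_noise > 0:
            flips = noise_rng.random(spec.n_labels) < spec.label_noise
            labels = np.where(flips, 1 - labels, labels)
        records.append(
            DrugRecord(
                id=f"syn_{i:0{width}d}",
                smiles=smiles,
                labels=tuple(int(x) for x in labels),
            )
        )
    return records
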