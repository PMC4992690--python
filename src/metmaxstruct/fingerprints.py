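"""Molecule collections and MACCS166 key fingerprints.

A fingerprint here is an ordered binary vector over the 166 meaningful MACCS
structural keys.  RDKit (like most toolkits) emits a 167-position vector whose
index 0 is a permanently-unset padding slot; this module stores only keys
1..166, mapped to vector indices 0..165, so that fingerprint files written by
one run are bit-portable to any other.

Pairwise overlap is summarized by the count triple ``(a, b, c)``: the number
of keys on only in A, only in B, and in both.  Every similarity measure in
:mod:`metmaxstruct.tversky` is a function of this triple alone.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys

logger = logging.getLogger(__name__)

#: number of meaningful MACCS structural keys
MACCS_NBITS = 166

#: recognized fingerprint dialect tags
DIALECTS = ("MACCS166", "synthetic")

# RDKit parse warnings are surfaced through our own rejection accounting.
RDLogger.DisableLog("rdApp.error")


class BitCounts(NamedTuple):
    """Exact overlap counts for a fingerprint pair: on only in A / only in B / in both."""

    a: int
    b: int
    c: int


@dataclass
class MoleculeRecord:
    """One molecule: identifier, canonical structure, average molecular weight (Da), class label."""

    id: str
    structure: str
    mol_weight: float
    source_class: str = ""


@dataclass
class Fingerprint:
    """Fixed-length binary key vector for one molecule."""

    bits: np.ndarray
    key_dialect: str = "MACCS166"

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("fingerprint bits must be 0/1")
        if self.key_dialect not in DIALECTS:
            raise ValueError(f"unknown key dialect {self.key_dialect!r}")
        bits.flags.writeable = False
        self.bits = bits

    @property
    def length(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_bitstring(cls, s: str, key_dialect: str = "MACCS166") -> "Fingerprint":
        if set(s) - {"0", "1"}:
            raise ValueError("bitstring must contain only 0/1 characters")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"), key_dialect)


@dataclass
class RejectedRecord:
    """A molecule excluded from a collection, with the reason."""

    identifier: str
    reason: str


@dataclass
class Collection:
    """An ordered compound collection with one fingerprint per record.

    Fingerprints are held both per-record and as a packed ``(n, length)``
    uint8 matrix (`matrix`) so that collection-level similarity passes can
    run as dense linear algebra.  Input order is preserved everywhere; all
    downstream tie-breaks refer to it.
    """

    records: list[MoleculeRecord]
    matrix: np.ndarray
    key_dialect: str = "MACCS166"
    rejected: list[RejectedRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.records):
            raise ValueError("fingerprint matrix shape does not match record count")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids in collection: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[MoleculeRecord, Fingerprint]]:
        for i, rec in enumerate(self.records):
            yield rec, self.fingerprint(i)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def mol_weights(self) -> np.ndarray:
        return np.array([r.mol_weight for r in self.records], dtype=float)

    def fingerprint(self, i: int) -> Fingerprint:
        return Fingerprint(self.matrix[i], self.key_dialect)

    def index_of(self, mol_id: str) -> int:
        for i, rec in enumerate(self.records):
            if rec.id == mol_id:
                return i
        raise KeyError(f"id {mol_id!r} not in collection")

    def subset(self, indices: Sequence[int]) -> "Collection":
        idx = list(indices)
        return Collection(
            [self.records[i] for i in idx], self.matrix[idx], self.key_dialect
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[MoleculeRecord, Fingerprint]],
        rejected: list[RejectedRecord] | None = None,
    ) -> "Collection":
        pairs = list(pairs)
        if not pairs:
            raise ValueError("cannot build an empty collection")
        dialect = pairs[0][1].key_dialect
        length = pairs[0][1].length
        for rec, fp in pairs:
            if fp.key_dialect != dialect or fp.length != length:
                raise ValueError(f"mixed fingerprint dialects/lengths at {rec.id!r}")
        matrix = np.stack([fp.bits for _, fp in pairs])
        return cls([rec for rec, _ in pairs], matrix, dialect, rejected or [])


# ---------------------------------------------------------------------------
# structure handling


def _prepare_mol(mol: Chem.Mol, identifier: str) -> Chem.Mol:
    """Keep the largest fragment (by heavy atoms) of a multi-fragment input."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
        logger.info("kept largest fragment of multi-fragment input %s", identifier)
    return mol


def mol_from_structure(smiles: str, identifier: str = "?") -> Chem.Mol:
    """Parse a SMILES string, stripping salts/counter-ions to the parent fragment."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {identifier!r}: {smiles!r}")
    return _prepare_mol(mol, identifier)


def maccs_fingerprint(record: MoleculeRecord | str) -> Fingerprint:
    """Compute the 166-key MACCS fingerprint of a record or SMILES string.

    Deterministic: two SMILES spellings of the same molecule give identical
    bit vectors (the structure is canonicalized by the parser).
    """
    smiles = record.structure if isinstance(record, MoleculeRecord) else record
    ident = record.id if isinstance(record, MoleculeRecord) else "?"
    mol = mol_from_structure(smiles, ident)
    full = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, index 0 always unset
    bits = np.zeros(MACCS_NBITS, dtype=np.uint8)
    for b in full.GetOnBits():
        if b >= 1:  # drop the padding slot, keys 1..166 -> indices 0..165
            bits[b - 1] = 1
    return Fingerprint(bits, "MACCS166")


def record_from_smiles(
    smiles: str, mol_id: str, source_class: str = ""
) -> tuple[MoleculeRecord, Fingerprint]:
    """Build a (record, fingerprint) pair from one SMILES entry."""
    mol = mol_from_structure(smiles, mol_id)
    record = MoleculeRecord(
        id=mol_id,
        structure=Chem.MolToSmiles(mol),
        mol_weight=float(Descriptors.MolWt(mol)),
        source_class=source_class,
    )
    return record, maccs_fingerprint(record)


# ---------------------------------------------------------------------------
# bit counting


def _pack(bits: np.ndarray) -> np.ndarray:
    return np.packbits(np.asarray(bits, dtype=np.uint8))


def bit_counts(A: Fingerprint, B: Fingerprint) -> BitCounts:
    """Exact (a, b, c) overlap counts via word-packed popcounts.

    ``a + c = popcount(A)``, ``b + c = popcount(B)``; swapping the arguments
    swaps a and b and preserves c.
    """
    if A.length != B.length:
        raise ValueError(f"fingerprint length mismatch: {A.length} vs {B.length}")
    pa, pb = _pack(A.bits), _pack(B.bits)
    c = int(np.bitwise_count(pa & pb).sum())
    a = int(np.bitwise_count(pa).sum()) - c
    b = int(np.bitwise_count(pb).sum()) - c
    return BitCounts(a, b, c)


def pair_counts_matrix(
    queries: Collection, targets: Collection
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (a, b, c) for every query-target pair.

    Returns three ``(n_queries, n_targets)`` int arrays.  The shared count is
    an integer matrix product of the 0/1 fingerprint matrices; a and b follow
    from the row/column popcounts.
    """
    if queries.key_dialect != targets.key_dialect:
        raise ValueError(
            f"fingerprint dialect mismatch: {queries.key_dialect} vs {targets.key_dialect}"
        )
    if queries.length != targets.length:
        raise ValueError("fingerprint length mismatch between collections")
    Q = queries.matrix.astype(np.int32)
    T = targets.matrix.astype(np.int32)
    c = Q @ T.T
    a = Q.sum(axis=1)[:, None] - c
    b = T.sum(axis=1)[None, :] - c
    return a, b, c


# ---------------------------------------------------------------------------
# collection I/O

FPS_CSV_HEADER = ["id", "mw", "class", "bits"]


def _load_smi(path: Path, source_class: str):
    pairs, rejected = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            try:
                pairs.append(record_from_smiles(smiles, mol_id, source_class))
            except ValueError as exc:
                rejected.append(RejectedRecord(mol_id, str(exc)))
                logger.warning("rejected %s (line %d): %s", mol_id, lineno, exc)
    return pairs, rejected


def _load_sdf(path: Path, source_class: str):
    pairs, rejected = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejected.append(RejectedRecord(f"record{i + 1}", "unparseable SDF record"))
            logger.warning("rejected SDF record %d: unparseable", i + 1)
            continue
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not mol_id and mol.HasProp("ID"):
            mol_id = mol.GetProp("ID").strip()
        if not mol_id:
            mol_id = f"record{i + 1}"
        mol = _prepare_mol(mol, mol_id)
        record = MoleculeRecord(
            id=mol_id,
            structure=Chem.MolToSmiles(mol),
            mol_weight=float(Descriptors.MolWt(mol)),
            source_class=source_class,
        )
        pairs.append((record, maccs_fingerprint(record)))
    return pairs, rejected


def _load_fps_csv(path: Path, source_class: str):
    pairs, rejected = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != FPS_CSV_HEADER:
            raise ValueError(
                f"fps_csv header must be {','.join(FPS_CSV_HEADER)!r}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            bits = row["bits"].strip()
            if len(bits) != MACCS_NBITS:
                raise ValueError(
                    f"fps_csv row {row['id']!r}: bit vector length "
                    f"{len(bits)} != {MACCS_NBITS}"
                )
            record = MoleculeRecord(
                id=row["id"],
                structure="",
                mol_weight=float(row["mw"]),
                source_class=row["class"] or source_class,
            )
            pairs.append((record, Fingerprint.from_bitstring(bits)))
    return pairs, rejected


def load_collection(
    path: str | Path, format: str | None = None, source_class: str = ""
) -> Collection:
    """Load a compound collection from .smi, SDF, or fps_csv.

    For smi/sdf inputs fingerprints are computed (MACCS166); for fps_csv they
    are read bit-exact.  Unparseable entries are excluded with a logged reason
    and reported on ``Collection.rejected``; they are never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smi", ".sdf": "sdf", ".csv": "fps_csv"}.get(
            path.suffix.lower(), "smi"
        )
    loaders = {"smi": _load_smi, "sdf": _load_sdf, "fps_csv": _load_fps_csv}
    if format not in loaders:
        raise ValueError(f"unknown collection format {format!r}")
    pairs, rejected = loaders[format](path, source_class)
    if not pairs:
        raise ValueError(f"no valid molecules in {path}")
    return Collection.from_pairs(pairs, rejected)


def save_collection(collection: Collection, path: str | Path) -> None:
    """Write a collection in the bit-exact fps_csv dialect.

    Header ``id,mw,class,bits``; bits is a string of exactly 166 characters
    from {0,1}, key 1 first.  A save/load round trip preserves every bit.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FPS_CSV_HEADER)
        for rec, fp in collection:
            writer.writerow(
                [rec.id, f"{rec.mol_weight:.4f}", rec.source_class, fp.to_bitstring()]
            )
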