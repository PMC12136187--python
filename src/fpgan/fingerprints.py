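"""Binary molecular fingerprints and similarity primitives.

Molecules are encoded as fixed-length binary key vectors: MACCS structural
keys padded to 168 positions (the shape used throughout the generative
models) or a 1024-bit path-based fingerprint (linear fragments up to length
7, used for the second-round substructure screen).  Tanimoto similarity and
bit containment over these vectors drive both library search and the
two-round substructure confirmation of the compound-series workflow.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

MACCS_SCHEME = "MACCS"
FP2_SCHEME = "FP2"

#: native key count of the MACCS implementation (position 0 is unused)
_MACCS_NATIVE_BITS = 167
MACCS_LENGTH = 168
FP2_LENGTH = 1024

SCHEME_LENGTHS = {MACCS_SCHEME: MACCS_LENGTH, FP2_SCHEME: FP2_LENGTH}


class FingerprintError(ValueError):
    """Raised for unparsable molecules or incomparable fingerprints."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule identified by id with its SMILES and source library."""

    molecule_id: str
    smiles: str
    source: str = ""

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise FingerprintError(
                f"unparsable SMILES for {self.molecule_id!r}: {self.smiles!r}"
            )
        return mol


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary key vector under a named scheme.

    ``bits`` is an ordered 0/1 vector; two fingerprints are comparable only
    when scheme and length agree.  Serialized form is the unseparated 0/1
    string, position 0 first.
    """

    bits: np.ndarray
    scheme: str
    molecule_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise FingerprintError("fingerprint bits must be a 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise FingerprintError("fingerprint bits must be 0/1")
        expected = SCHEME_LENGTHS.get(self.scheme)
        if expected is not None and arr.size != expected:
            raise FingerprintError(
                f"scheme {self.scheme} expects {expected} bits, got {arr.size}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    @property
    def length(self) -> int:
        return int(self.bits.size)

    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_bitstring(
        cls, s: str, scheme: str, molecule_id: str | None = None
    ) -> "BitFingerprint":
        if set(s) - {"0", "1"}:
            raise FingerprintError("bitstring must contain only 0/1")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"),
                   scheme, molecule_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BitFingerprint):
            return NotImplemented
        return (self.scheme == other.scheme
                and self.length == other.length
                and bool(np.array_equal(self.bits, other.bits)))

    def __hash__(self) -> int:
        return hash((self.scheme, self.bits.tobytes()))


def _require_comparable(a: BitFingerprint, b: BitFingerprint) -> None:
    if a.scheme != b.scheme or a.length != b.length:
        raise FingerprintError(
            f"incomparable fingerprints: {a.scheme}/{a.length} vs {b.scheme}/{b.length}"
        )


def encode_maccs(mol: MoleculeRecord | str, length: int = MACCS_LENGTH) -> BitFingerprint:
    """Encode a molecule as MACCS structural keys, zero-padded to ``length``.

    The native key dictionary emits 167 positions; the surplus positions up
    to ``length`` (default 168) are constant zero so that every fingerprint
    matches the tensor shape used by the generative models.
    """
    rec = MoleculeRecord("", mol) if isinstance(mol, str) else mol
    if length < _MACCS_NATIVE_BITS:
        raise FingerprintError(
            f"length {length} is below the native MACCS key count {_MACCS_NATIVE_BITS}"
        )
    m = rec.to_mol()
    native = MACCSkeys.GenMACCSKeys(m)
    bits = np.zeros(length, dtype=np.uint8)
    for idx in native.GetOnBits():
        bits[idx] = 1
    scheme = MACCS_SCHEME if length == MACCS_LENGTH else f"MACCS{length}"
    return BitFingerprint(bits, scheme, rec.molecule_id or None)


def encode_fp2(mol: MoleculeRecord | str) -> BitFingerprint:
    """Encode a molecule as a 1024-bit path fingerprint.

    Linear fragments of 1..7 bonds are hashed and folded to 1024 bits — the
    FP2-style descriptor used as a pre-filter in substructure confirmation.
    """
    rec = MoleculeRecord("", mol) if isinstance(mol, str) else mol
    m = rec.to_mol()
    fp = Chem.RDKFingerprint(m, minPath=1, maxPath=7, fpSize=FP2_LENGTH)
    bits = np.zeros(FP2_LENGTH, dtype=np.uint8)
    for idx in fp.GetOnBits():
        bits[idx] = 1
    return BitFingerprint(bits, FP2_SCHEME, rec.molecule_id or None)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero vectors score 0 by convention, so an empty generated
    fingerprint never ranks as a perfect hit.
    """
    _require_comparable(a, b)
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    return inter / union if union else 0.0


def tanimoto_matrix(queries: np.ndarray, library: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between row sets of two 0/1 matrices.

    Returns shape (n_queries, n_library).  All-zero vs all-zero pairs score 0.
    """
    q = np.asarray(queries, dtype=np.int32)
    lib = np.asarray(library, dtype=np.int32)
    if q.ndim != 2 or lib.ndim != 2 or q.shape[1] != lib.shape[1]:
        raise FingerprintError("fingerprint matrices must be 2-D with equal width")
    inter = q @ lib.T
    union = q.sum(axis=1)[:, None] + lib.sum(axis=1)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return ts


def bit_containment(query: BitFingerprint, candidate: BitFingerprint) -> bool:
    """True iff every set bit of ``query`` is set in ``candidate``.

    A necessary (not sufficient, because of hash folding) condition for the
    query substructure being contained in the candidate molecule.
    """
    _require_comparable(query, candidate)
    return bool(((query.bits == 1) <= (candidate.bits == 1)).all())


def _parse_pattern(pattern: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(pattern)
    if patt is None or patt.GetNumAtoms() == 0:
        patt = Chem.MolFromSmiles(pattern)
    if patt is None:
        raise FingerprintError(f"unparsable substructure pattern: {pattern!r}")
    return patt


def confirm_substructure(mcs_smarts: str, candidate: MoleculeRecord | str) -> bool:
    """Exact subgraph-isomorphism check of a core pattern in a candidate.

    This is the authoritative second round of substructure confirmation; the
    fingerprint containment screen only pre-filters.  The pattern is parsed
    as SMARTS, falling back to SMILES.
    """
    rec = MoleculeRecord("", candidate) if isinstance(candidate, str) else candidate
    patt = _parse_pattern(mcs_smarts)
    return rec.to_mol().HasSubstructMatch(patt)


def fingerprints_to_matrix(fps: Sequence[BitFingerprint]) -> np.ndarray:
    """Stack comparable fingerprints into an (n, length) uint8 matrix."""
    if not fps:
        raise FingerprintError("empty fingerprint list")
    first = fps[0]
    for fp in fps[1:]:
        _require_comparable(first, fp)
    return np.stack([fp.bits for fp in fps]).astype(np.uint8)


def matrix_to_fingerprints(
    mat: np.ndarray, scheme: str, ids: Sequence[str] | None = None
) -> list[BitFingerprint]:
    mat = np.asarray(mat, dtype=np.uint8)
    if ids is None:
        ids = [None] * mat.shape[0]
    return [BitFingerprint(row, scheme, mid) for row, mid in zip(mat, ids)]


# ---------------------------------------------------------------------------
# molecule / fingerprint I/O

def read_molecules(path: str | Path, source: str | None = None) -> list[MoleculeRecord]:
    """Read molecules from .smi ("SMILES<tab>id"), .csv (smiles,id) or .sdf."""
    path = Path(path)
    src = source if source is not None else path.stem
    suffix = path.suffix.lower()
    records: list[MoleculeRecord] = []
    if suffix in {".smi", ".txt"}:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mid = parts[1] if len(parts) > 1 else f"{src}_{i}"
            records.append(MoleculeRecord(mid, smiles, src))
    elif suffix == ".csv":
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                mid = row.get("id") or row.get("molecule_id") or f"{src}_{i}"
                records.append(MoleculeRecord(mid, row["smiles"], src))
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{src}_{i}"
            records.append(MoleculeRecord(mid or f"{src}_{i}", Chem.MolToSmiles(mol), src))
    else:
        raise ValueError(f"unsupported molecule file format: {path.name}")
    return records


def write_fingerprints(fps: Iterable[BitFingerprint], path: str | Path) -> None:
    """Write fingerprints as CSV rows (id, scheme, bitstring)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "scheme", "bits"])
        for i, fp in enumerate(fps):
            writer.writerow([fp.molecule_id or f"fp_{i}", fp.scheme, fp.to_bitstring()])


def read_fingerprints(path: str | Path) -> list[BitFingerprint]:
    with open(path, newline="") as fh:
        return [
            BitFingerprint.from_bitstring(row["bits"], row["scheme"], row["id"])
            for row in csv.DictReader(fh)
        ]
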