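"""Training-set construction: property-matched decoys, stratified folds,
and synthetic fixture generators.

The decoy matcher reproduces the density-matched sampling used to build a
balanced active/inactive set: molecular weight and logP are jointly
z-scored, projected onto the first principal component of the active set,
and pool members are drawn with probability proportional to the active-set
kernel density at their projected score.  The synthetic generators produce
labeled fingerprint sets with planted signature bits, and toy SMILES
libraries with a planted chemical core, so every downstream stage is
testable without external databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .fingerprints import (
    MACCS_LENGTH,
    MACCS_SCHEME,
    MoleculeRecord,
    confirm_substructure,
)

ACTIVE, INACTIVE = 1, 0
LABEL_NAMES = {ACTIVE: "active", INACTIVE: "inactive"}


@dataclass
class LabeledFingerprintSet:
    """A fingerprint matrix with per-row class labels and molecule ids.

    ``fingerprints`` is (n, length) uint8; ``labels`` holds 1 for active and
    0 for inactive/decoy rows.  This is the training currency of every model.
    """

    fingerprints: np.ndarray
    labels: np.ndarray
    ids: list[str]
    scheme: str = MACCS_SCHEME

    def __post_init__(self) -> None:
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.fingerprints) == len(self.labels) == len(self.ids)):
            raise ValueError("fingerprints, labels and ids must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return int(self.fingerprints.shape[1])

    def subset(self, mask: np.ndarray) -> "LabeledFingerprintSet":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return LabeledFingerprintSet(
            self.fingerprints[idx],
            self.labels[idx],
            [self.ids[i] for i in idx],
            self.scheme,
        )

    def actives(self) -> "LabeledFingerprintSet":
        return self.subset(self.labels == ACTIVE)

    def inactives(self) -> "LabeledFingerprintSet":
        return self.subset(self.labels == INACTIVE)


@dataclass
class PropertyTable:
    """Per-molecule molecular weight (g/mol) and logP, aligned with ids."""

    ids: list[str]
    mw: np.ndarray
    logp: np.ndarray

    def __post_init__(self) -> None:
        self.mw = np.asarray(self.mw, dtype=float)
        self.logp = np.asarray(self.logp, dtype=float)
        if not (len(self.ids) == self.mw.size == self.logp.size):
            raise ValueError("ids, mw and logp must align")
        if not (np.isfinite(self.mw).all() and np.isfinite(self.logp).all()):
            raise ValueError("property values must be finite")

    @property
    def features(self) -> np.ndarray:
        return np.column_stack([self.mw, self.logp])

    @classmethod
    def from_molecules(cls, mols: Sequence[MoleculeRecord]) -> "PropertyTable":
        from rdkit.Chem import Crippen, Descriptors

        mw, logp, ids = [], [], []
        for rec in mols:
            m = rec.to_mol()
            ids.append(rec.molecule_id)
            mw.append(Descriptors.MolWt(m))
            logp.append(Crippen.MolLogP(m))
        return cls(ids, np.array(mw), np.array(logp))


@dataclass
class FoldAssignment:
    """Per-row fold index in 0..k-1 from a stratified k-fold split."""

    fold: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=np.int64)
        if self.fold.min() < 0 or self.fold.max() >= self.k:
            raise ValueError("fold indices out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold != fold)

    def to_frame(self, ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame({"id": list(ids), "fold": self.fold})


def match_decoys(
    active_props: PropertyTable,
    pool_props: PropertyTable,
    n_select: int,
    seed: int,
) -> list[str]:
    """Select property-matched decoys from a candidate pool.

    MW and logP are z-scored jointly over actives+pool and reduced to one
    dimension along the first principal component of the combined
    standardized set (the component must span the axes where pool and
    actives differ; fitting it on the actives alone can collapse onto a
    direction orthogonal to the mismatch).  ``n_select`` pool members are
    then drawn without replacement with probability proportional to the
    active-score Gaussian kernel density (Scott bandwidth) evaluated at
    each pool member's score.  Returns selected ids.
    """
    if len(pool_props.ids) < n_select:
        raise ValueError(f"pool has {len(pool_props.ids)} < n_select={n_select}")
    if not active_props.ids or not pool_props.ids:
        raise ValueError("empty property table")

    act = active_props.features
    pool = pool_props.features
    both = np.vstack([act, pool])
    mu, sd = both.mean(axis=0), both.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) property column")
    act_z, pool_z = (act - mu) / sd, (pool - mu) / sd

    pca = PCA(n_components=1).fit(np.vstack([act_z, pool_z]))
    act_score = pca.transform(act_z).ravel()
    pool_score = pca.transform(pool_z).ravel()

    if n_select == len(pool_props.ids):
        return list(pool_props.ids)

    kde = gaussian_kde(act_score)  # Scott's rule by default
    weights = np.maximum(kde(pool_score), 0.0)
    total = weights.sum()
    if total <= 0:  # actives' density vanishes over the whole pool
        weights = np.full(len(pool_score), 1.0 / len(pool_score))
    else:
        weights = weights / total
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool_score), size=n_select, replace=False, p=weights)
    return [pool_props.ids[i] for i in chosen]


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment; per-fold class counts within +/-1 of
    exact proportionality."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        fold[test_idx] = f
    return FoldAssignment(fold, k)


# ---------------------------------------------------------------------------
# synthetic fixtures

#: signature-bit defaults for the synthetic fingerprint generator
DEFAULT_SIGNATURE_BITS = tuple(range(20))
DEFAULT_P_ON_ACTIVE = 0.9
DEFAULT_P_ON_INACTIVE = 0.1
DEFAULT_BACKGROUND_P = 0.3


def make_synthetic_fpset(
    n_active: int = 2000,
    n_inactive: int = 2000,
    length: int = MACCS_LENGTH,
    signature_bits: Sequence[int] = DEFAULT_SIGNATURE_BITS,
    p_on_active: float = DEFAULT_P_ON_ACTIVE,
    p_on_inactive: float = DEFAULT_P_ON_INACTIVE,
    background_p: float = DEFAULT_BACKGROUND_P,
    seed: int = 0,
    scheme: str = MACCS_SCHEME,
) -> LabeledFingerprintSet:
    """Generate a labeled Bernoulli fingerprint set with planted signature bits.

    Actives switch each signature bit on with probability ``p_on_active``,
    inactives with ``p_on_inactive``; every other bit is Bernoulli
    ``background_p`` in both classes.  Emulates a class-separable fingerprint
    dataset at the marginal-frequency level; bit reproducible under ``seed``.
    """
    sig = np.asarray(signature_bits, dtype=np.int64)
    if sig.size and (sig.min() < 0 or sig.max() >= length):
        raise ValueError("signature_bits out of range")
    for p in (p_on_active, p_on_inactive, background_p):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_active + n_inactive
    mat = (rng.random((n, length)) < background_p).astype(np.uint8)
    mat[:n_active, sig] = (rng.random((n_active, sig.size)) < p_on_active)
    mat[n_active:, sig] = (rng.random((n_inactive, sig.size)) < p_on_inactive)
    labels = np.concatenate(
        [np.full(n_active, ACTIVE), np.full(n_inactive, INACTIVE)]
    )
    ids = [f"act_{i}" for i in range(n_active)] + [
        f"dec_{i}" for i in range(n_inactive)
    ]
    return LabeledFingerprintSet(mat, labels, ids, scheme)


def make_two_signature_fpset(
    n_per_class: int = 1000,
    length: int = MACCS_LENGTH,
    active_bits: Sequence[int] = tuple(range(0, 20)),
    inactive_bits: Sequence[int] = tuple(range(20, 40)),
    p_on: float = 0.9,
    p_off: float = 0.1,
    background_p: float = DEFAULT_BACKGROUND_P,
    seed: int = 0,
) -> LabeledFingerprintSet:
    """Two-class fixture where each class has its own signature block.

    Actives carry ``active_bits`` at ``p_on`` and ``inactive_bits`` at
    ``p_off``; inactives are mirrored.  Used to probe class conditioning:
    samples resembling one class must be distinguishably closer to it.
    """
    rng = np.random.default_rng(seed)
    a = make_synthetic_fpset(
        n_active=n_per_class, n_inactive=0, length=length,
        signature_bits=active_bits, p_on_active=p_on, p_on_inactive=p_off,
        background_p=background_p, seed=int(rng.integers(2**31)),
    )
    a.fingerprints[:, np.asarray(inactive_bits)] = (
        rng.random((n_per_class, len(inactive_bits))) < p_off
    )
    b = make_synthetic_fpset(
        n_active=0, n_inactive=n_per_class, length=length,
        signature_bits=inactive_bits, p_on_active=p_off, p_on_inactive=p_on,
        background_p=background_p, seed=int(rng.integers(2**31)),
    )
    b.fingerprints[:, np.asarray(active_bits)] = (
        rng.random((n_per_class, len(active_bits))) < p_off
    )
    return LabeledFingerprintSet(
        np.vstack([a.fingerprints, b.fingerprints]),
        np.concatenate([np.full(n_per_class, ACTIVE), np.full(n_per_class, INACTIVE)]),
        a.ids + b.ids,
        MACCS_SCHEME,
    )


#: default planted core: pyrazole carboxamide, the kind of shared scaffold a
#: compound series is built around
DEFAULT_CORE_SMILES = "O=C(N)c1cc[nH]n1"

_CORE_FREE_SCAFFOLDS = [
    "c1ccccc1",          # benzene
    "C1CCCCC1",          # cyclohexane
    "c1ccncc1",          # pyridine
    "c1ccc2ccccc2c1",    # naphthalene
    "C1CCOC1",           # tetrahydrofuran
    "c1ccsc1",           # thiophene
]

_SUBSTITUENTS = ["C", "CC", "CCC", "CC(C)C", "CCO", "CO", "N", "O", "F", "Cl",
                 "Br", "C(=O)C", "OC", "CN", "S(=O)(=O)C", "C#N"]


def _attach(base: Chem.Mol, sub_smiles: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond a substituent fragment to a random carbon of base with free valence.

    Attachment is restricted to carbons: substituting an N-H would change
    hydrogen-count-dependent structural keys of a planted core, and the
    fixture must keep the core's key environment intact so that key-based
    screening stays free of false negatives.
    """
    sub = Chem.MolFromSmiles(sub_smiles)
    if sub is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(base, sub))
    n_base = base.GetNumAtoms()
    candidates = [
        a.GetIdx()
        for a in combo.GetAtoms()
        if a.GetIdx() < n_base and a.GetTotalNumHs() > 0 and a.GetSymbol() == "C"
    ]
    if not candidates:
        return None
    anchor = int(rng.choice(candidates))
    combo.AddBond(anchor, n_base, Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def make_synthetic_library(
    n: int = 1000,
    planted_core_smarts: str = DEFAULT_CORE_SMILES,
    fraction_with_core: float = 0.3,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], np.ndarray]:
    """Generate a toy SMILES library with a planted chemical core.

    Roughly ``fraction_with_core`` of molecules are decorated copies of the
    core; the rest decorate core-free scaffolds.  Returns the records and a
    boolean ground-truth vector of actual core containment (verified by
    subgraph match at build time, so accidental core formation in the
    "without" arm is recorded truthfully).
    """
    if not 0.0 <= fraction_with_core <= 1.0:
        raise ValueError("fraction_with_core must lie in [0, 1]")
    core = Chem.MolFromSmiles(planted_core_smarts)
    if core is None:
        core = Chem.MolFromSmarts(planted_core_smarts)
    if core is None:
        raise ValueError(f"invalid core pattern: {planted_core_smarts!r}")
    core_smiles = Chem.MolToSmiles(core)

    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    truth: list[bool] = []
    for i in range(n):
        with_core = rng.random() < fraction_with_core
        base = Chem.MolFromSmiles(
            core_smiles if with_core else str(rng.choice(_CORE_FREE_SCAFFOLDS))
        )
        mol = base
        for _ in range(int(rng.integers(1, 4))):  # 1-3 decorations
            cand = _attach(mol, str(rng.choice(_SUBSTITUENTS)), rng)
            if cand is not None:
                mol = cand
        smiles = Chem.MolToSmiles(mol)
        rec = MoleculeRecord(f"lib_{i:05d}", smiles, "synthetic")
        records.append(rec)
        truth.append(confirm_substructure(planted_core_smarts, rec))
    return records, np.asarray(truth, dtype=bool)


def read_label_table(path: str | Path) -> tuple[list[MoleculeRecord], np.ndarray, PropertyTable]:
    """Read a CSV label table (id, smiles, label[, MW, logP]).

    MW/logP are computed from structure when absent.  Labels accept
    active/inactive (case-insensitive) or 1/0.
    """
    df = pd.read_csv(path)
    records = [
        MoleculeRecord(str(r["id"]), str(r["smiles"]), Path(path).stem)
        for _, r in df.iterrows()
    ]
    raw = df["label"].astype(str).str.strip().str.lower()
    labels = raw.map({"active": ACTIVE, "inactive": INACTIVE, "1": ACTIVE, "0": INACTIVE})
    if labels.isna().any():
        bad = raw[labels.isna()].unique()
        raise ValueError(f"unrecognized labels: {list(bad)}")
    if {"MW", "logP"} <= set(df.columns):
        props = PropertyTable(
            [r.molecule_id for r in records],
            df["MW"].to_numpy(float),
            df["logP"].to_numpy(float),
        )
    else:
        props = PropertyTable.from_molecules(records)
    return records, labels.to_numpy(np.int64), props
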