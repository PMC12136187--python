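"""Generation-quality metrics, classifier metrics and drug-likeness.

The four generation metrics score a sample of generated fingerprints
against itself and the training set:

* uniqueness — distinct bit-vectors / total generated;
* novelty — generated vectors absent from the training set / distinct;
* diversity — 1 minus the mean pairwise Tanimoto within the sample;
* similarity — mean Tanimoto over the generated x training cross product.

Classifier metrics (ROC-AUC, accuracy, F1, precision, recall, confusion
counts) evaluate discriminator pre-training.  Drug-likeness profiles (MW,
logP, TPSA, QED, Lipinski) characterize retrieved candidate molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from sklearn.metrics import roc_auc_score

from .fingerprints import MoleculeRecord, fingerprints_to_matrix, tanimoto_matrix


@dataclass(frozen=True)
class GenerationReport:
    """The four generation metrics for one sample of fingerprints."""

    uniqueness: float
    novelty: float
    diversity: float
    similarity: float
    n_samples: int
    subsampled: bool = False

    def __post_init__(self) -> None:
        for name in ("uniqueness", "novelty", "diversity", "similarity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "uniqueness": self.uniqueness, "novelty": self.novelty,
            "diversity": self.diversity, "similarity": self.similarity,
            "n_samples": self.n_samples,
        }])


def _as_matrix(fps) -> np.ndarray:
    if isinstance(fps, np.ndarray):
        return np.asarray(fps, dtype=np.uint8)
    return fingerprints_to_matrix(list(fps))


def _row_keys(mat: np.ndarray) -> list[bytes]:
    return [row.tobytes() for row in np.ascontiguousarray(mat, dtype=np.uint8)]


def uniqueness(fps) -> float:
    """Distinct bit-vectors over total sample size."""
    mat = _as_matrix(fps)
    if mat.shape[0] == 0:
        raise ValueError("empty fingerprint set")
    return len(set(_row_keys(mat))) / mat.shape[0]


def novelty(fps, training) -> float:
    """Fraction of *unique* generated vectors not present in the training set."""
    mat = _as_matrix(fps)
    if mat.shape[0] == 0:
        raise ValueError("empty fingerprint set")
    train_keys = set(_row_keys(_as_matrix(training)))
    uniq = set(_row_keys(mat))
    return len(uniq - train_keys) / len(uniq)


def _pair_mean_within(mat: np.ndarray, max_pairs: int | None,
                      seed: int) -> tuple[float, bool]:
    n = mat.shape[0]
    n_pairs = n * (n - 1) // 2
    if max_pairs is None or n_pairs <= max_pairs:
        ts = tanimoto_matrix(mat, mat)
        iu = np.triu_indices(n, k=1)
        return float(ts[iu].mean()), False
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)  # uniform over ordered pairs i != j
    a, b = mat[i].astype(np.int64), mat[j].astype(np.int64)
    inter = (a & b).sum(axis=1)
    union = (a | b).sum(axis=1)
    vals = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return float(vals.mean()), True


def diversity(fps, max_pairs: int | None = 2_000_000, seed: int = 0) -> float:
    """1 minus the mean pairwise Tanimoto over all unordered pairs.

    Exhaustive for pair counts up to ``max_pairs``; beyond that a seeded
    uniform subsample of pairs is used (flagged in ``generation_report``).
    """
    mat = _as_matrix(fps)
    if mat.shape[0] < 2:
        raise ValueError("diversity needs at least 2 fingerprints")
    mean_ts, _ = _pair_mean_within(mat, max_pairs, seed)
    return 1.0 - mean_ts


def similarity_to_reference(fps, reference, max_pairs: int | None = 2_000_000,
                            seed: int = 0) -> float:
    """Mean Tanimoto over the generated x reference cross product."""
    mat = _as_matrix(fps)
    ref = _as_matrix(reference)
    if mat.shape[0] == 0 or ref.shape[0] == 0:
        raise ValueError("empty input")
    n_pairs = mat.shape[0] * ref.shape[0]
    if max_pairs is None or n_pairs <= max_pairs:
        return float(tanimoto_matrix(mat, ref).mean())
    rng = np.random.default_rng(seed)
    i = rng.integers(0, mat.shape[0], size=max_pairs)
    j = rng.integers(0, ref.shape[0], size=max_pairs)
    a, b = mat[i].astype(np.int64), ref[j].astype(np.int64)
    inter = (a & b).sum(axis=1)
    union = (a | b).sum(axis=1)
    return float(np.where(union > 0, inter / np.maximum(union, 1), 0.0).mean())


def generation_report(fps, training, max_pairs: int | None = 2_000_000,
                      seed: int = 0) -> GenerationReport:
    mat = _as_matrix(fps)
    n = mat.shape[0]
    n_within = n * (n - 1) // 2
    n_cross = n * _as_matrix(training).shape[0]
    sub = max_pairs is not None and max(n_within, n_cross) > max_pairs
    return GenerationReport(
        uniqueness=uniqueness(mat),
        novelty=novelty(mat, training),
        diversity=diversity(mat, max_pairs=max_pairs, seed=seed),
        similarity=similarity_to_reference(mat, training, max_pairs=max_pairs, seed=seed),
        n_samples=n,
        subsampled=sub,
    )


@dataclass(frozen=True)
class ClassifierMetrics:
    auc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    tp: int
    tn: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "accuracy", "f1", "precision", "recall", "tp", "tn", "fp", "fn")}


def classifier_metrics(y_true: np.ndarray, scores: np.ndarray,
                       threshold: float = 0.5) -> ClassifierMetrics:
    """ROC-AUC (Mann-Whitney rank statistic, tie midranks) plus
    threshold-based confusion counts and the metrics derived from them."""
    y = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    pred = (s >= threshold).astype(np.int64)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = (tp + tn) / y.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return ClassifierMetrics(auc, accuracy, f1, precision, recall, tp, tn, fp, fn)


@dataclass(frozen=True)
class DruglikeProfile:
    """MW (g/mol), logP, TPSA (A^2), QED and the Lipinski rule-of-five flag."""

    molecule_id: str
    mw: float
    logp: float
    tpsa: float
    qed: float
    hbd: int
    hba: int
    lipinski_pass: bool


def druglike_profile(mol: MoleculeRecord | str) -> DruglikeProfile:
    """Compute the drug-likeness profile of one molecule.

    logP uses the Wildman-Crippen scheme, TPSA the Ertl fragment scheme,
    QED the Bickerton desirability aggregate; Lipinski passes when MW <= 500,
    logP <= 5, H-bond donors <= 5 and acceptors <= 10.
    """
    rec = MoleculeRecord("", mol) if isinstance(mol, str) else mol
    m = rec.to_mol()
    mw = Descriptors.MolWt(m)
    logp = Crippen.MolLogP(m)
    tpsa = rdMolDescriptors.CalcTPSA(m)
    qed = QED.qed(m)
    hbd = Lipinski.NumHDonors(m)
    hba = Lipinski.NumHAcceptors(m)
    return DruglikeProfile(
        molecule_id=rec.molecule_id,
        mw=mw, logp=logp, tpsa=tpsa, qed=qed, hbd=hbd, hba=hba,
        lipinski_pass=(mw <= 500 and logp <= 5 and hbd <= 5 and hba <= 10),
    )


def profile_table(mols: Sequence[MoleculeRecord]) -> pd.DataFrame:
    rows = [druglike_profile(m).__dict__ for m in mols]
    return pd.DataFrame(rows)


def format_metric_table(df: pd.DataFrame, value_cols: Sequence[str],
                        group_col: str | None = None) -> str:
    """Human-readable mean(std) table mirroring the report layout."""
    if group_col is None:
        stats = {c: f"{df[c].mean():.2f}({df[c].std(ddof=0):.2f})" for c in value_cols}
        return pd.DataFrame([stats]).to_string(index=False)
    rows = []
    for key, grp in df.groupby(group_col):
        row = {group_col: key}
        row.update({c: f"{grp[c].mean():.2f}({grp[c].std(ddof=0):.2f})" for c in value_cols})
        rows.append(row)
    return pd.DataFrame(rows).to_string(index=False)
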