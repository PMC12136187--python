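"""Similarity search of compound libraries against generated fingerprints,
threshold-band counting, two-round substructure confirmation, and candidate
ranking.

A library molecule's score is its *maximum* Tanimoto over all query
fingerprints ("at least X% maximum structural similarity"); band counts
report, per threshold, the number of distinct library molecules at or above
it, so counts are non-increasing as the threshold rises.  For compound-series
runs, hits are confirmed in two rounds: a 1024-bit path-fingerprint
containment screen followed by exact subgraph matching of the core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import DruglikeProfile
from .fingerprints import (
    BitFingerprint,
    FingerprintError,
    MACCS_SCHEME,
    MoleculeRecord,
    bit_containment,
    confirm_substructure,
    encode_fp2,
    encode_maccs,
    fingerprints_to_matrix,
    tanimoto_matrix,
)

DEFAULT_THRESHOLDS = (0.70, 0.75, 0.80, 0.85)


@dataclass(frozen=True)
class SearchHit:
    """One retrieved library molecule with its best-matching query."""

    query_id: str
    molecule_id: str
    ts: float
    band: float
    mcs_confirmed: bool | None = None  # None = not applicable / not yet run

    def __post_init__(self) -> None:
        if self.ts < self.band - 1e-12:
            raise ValueError("hit similarity below its threshold band")


@dataclass(frozen=True)
class BandCountTable:
    """Distinct-molecule counts per similarity threshold (cumulative)."""

    thresholds: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.counts):
            raise ValueError("thresholds and counts must align")
        for a, b in zip(self.counts, self.counts[1:]):
            if b > a:
                raise ValueError("band counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.counts],
            columns=[f"TS>={t:.2f}" for t in self.thresholds],
        )

    def as_dict(self) -> dict[float, int]:
        return dict(zip(self.thresholds, self.counts))


@dataclass
class SearchResult:
    hits: list[SearchHit]
    band_counts: BandCountTable
    n_skipped: int = 0  # library molecules that failed SMILES parsing

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame([h.__dict__ for h in self.hits])


def _encode_library(library: Sequence[MoleculeRecord], scheme: str
                    ) -> tuple[np.ndarray, list[MoleculeRecord], int]:
    encoder = encode_maccs if scheme.startswith("MACCS") else encode_fp2
    rows, kept, skipped = [], [], 0
    for rec in library:
        try:
            rows.append(encoder(rec).bits)
        except FingerprintError:
            skipped += 1
            continue
        kept.append(rec)
    if not rows:
        raise ValueError("no library molecule could be encoded")
    return np.stack(rows), kept, skipped


def search_library(
    queries: Sequence[BitFingerprint] | np.ndarray,
    library: Sequence[MoleculeRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    mw_range: tuple[float, float] | None = None,
    scheme: str = MACCS_SCHEME,
) -> SearchResult:
    """Retrieve library molecules by maximum Tanimoto over the queries.

    Library molecules are encoded with the queries' scheme; unparsable
    SMILES are skipped and counted.  A molecule becomes a hit when its max
    similarity clears the lowest threshold; its band is the highest
    threshold cleared.  ``mw_range`` filters molecules by molecular weight
    before scoring.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be a non-empty ascending list")
    if any(not 0.0 < t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if len(library) == 0:
        raise ValueError("empty library")

    if isinstance(queries, np.ndarray):
        qmat = np.asarray(queries, dtype=np.uint8)
        qids = [f"q_{i}" for i in range(qmat.shape[0])]
    else:
        queries = list(queries)
        if not queries:
            raise ValueError("no queries")
        scheme = queries[0].scheme
        qmat = fingerprints_to_matrix(queries)
        qids = [fp.molecule_id or f"q_{i}" for i, fp in enumerate(queries)]
    if qmat.shape[0] == 0:
        raise ValueError("no queries")

    if mw_range is not None:
        from rdkit.Chem import Descriptors

        lo, hi = mw_range
        filtered = []
        for rec in library:
            try:
                mw = Descriptors.MolWt(rec.to_mol())
            except FingerprintError:
                filtered.append(rec)  # parse failures counted downstream
                continue
            if lo <= mw <= hi:
                filtered.append(rec)
        library = filtered
        if not library:
            return SearchResult([], BandCountTable(thresholds,
                                                   (0,) * len(thresholds)))

    lmat, kept, skipped = _encode_library(library, scheme)
    if lmat.shape[1] != qmat.shape[1]:
        raise FingerprintError("library/query fingerprint width mismatch")

    ts = tanimoto_matrix(lmat, qmat)  # (n_lib, n_query)
    best_q = ts.argmax(axis=1)
    max_ts = ts[np.arange(ts.shape[0]), best_q]

    counts = tuple(int((max_ts >= t - 1e-12).sum()) for t in thresholds)
    hits: list[SearchHit] = []
    for i, rec in enumerate(kept):
        cleared = [t for t in thresholds if max_ts[i] >= t - 1e-12]
        if not cleared:
            continue
        hits.append(SearchHit(
            query_id=qids[best_q[i]],
            molecule_id=rec.molecule_id,
            ts=float(max_ts[i]),
            band=cleared[-1],
        ))
    hits.sort(key=lambda h: (-h.ts, h.molecule_id))
    return SearchResult(hits, BandCountTable(thresholds, counts), skipped)


def mcs_confirm_hits(
    hits: Sequence[SearchHit],
    library: Mapping[str, MoleculeRecord],
    mcs_smarts: str,
) -> list[SearchHit]:
    """Two-round substructure confirmation of search hits.

    Round one screens each hit by path-fingerprint bit containment of the
    core (cheap, no false negatives); round two decides by exact subgraph
    isomorphism.  Returns the hits with ``mcs_confirmed`` set; never adds
    hits.
    """
    confirmed: list[SearchHit] = []
    try:
        core_fp2 = encode_fp2(mcs_smarts)
    except FingerprintError:
        core_fp2 = None  # SMARTS-only pattern: skip the fingerprint screen
    for hit in hits:
        rec = library.get(hit.molecule_id)
        if rec is None:
            raise KeyError(f"no molecule record for hit {hit.molecule_id!r}")
        passed_screen = (core_fp2 is None
                         or bit_containment(core_fp2, encode_fp2(rec)))
        ok = passed_screen and confirm_substructure(mcs_smarts, rec)
        confirmed.append(replace(hit, mcs_confirmed=bool(ok)))
    return confirmed


def rank_candidates(
    hits: Sequence[SearchHit],
    profiles: Mapping[str, DruglikeProfile],
    top_n: int,
) -> pd.DataFrame:
    """Rank hits by (Tanimoto, QED) lexicographically descending.

    Ties break on molecule_id for determinism.  Requires a drug-likeness
    profile for every hit molecule.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    rows = []
    for hit in hits:
        prof = profiles.get(hit.molecule_id)
        if prof is None:
            raise KeyError(f"no profile for hit {hit.molecule_id!r}")
        rows.append({
            "molecule_id": hit.molecule_id, "query_id": hit.query_id,
            "ts": hit.ts, "qed": prof.qed, "mw": prof.mw, "logp": prof.logp,
            "tpsa": prof.tpsa, "band": hit.band,
            "mcs_confirmed": hit.mcs_confirmed,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["ts", "qed", "molecule_id"],
                        ascending=[False, False, True], kind="mergesort")
    return df.head(top_n).reset_index(drop=True)
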