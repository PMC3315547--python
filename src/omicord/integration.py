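"""Cross-platform merging of RNA and protein ratio profiles.

Platform results are keyed by platform-specific identifiers (probe ids,
protein accessions); an explicit id-to-symbol mapping table joins them to
common gene symbols.  The merged unit is the paired profile: one gene's
RNA and protein log10-ratio time courses on the shared treated-time grid.
Pairs with any missing value can be filtered out so that shape statistics
never extrapolate across holes in the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .io import time_column

__all__ = ["PairedProfiles", "cross_index", "filter_complete", "cluster_profiles"]


@dataclass
class PairedProfiles:
    """Merged RNA/protein pairs on a shared time grid.

    ``frame`` is indexed by gene symbol with columns ``rna_<t>`` and
    ``prot_<t>`` per shared treated time plus a ``complete`` flag;
    ``counts`` records the sizes at each merge step for auditability.
    """

    frame: pd.DataFrame
    shared_times: tuple[float, ...]
    counts: dict[str, int] = field(default_factory=dict)


def _ratio_times(df: pd.DataFrame) -> list[float]:
    return sorted(float(c.split("_", 1)[1]) for c in df.columns if c.startswith("ratio_"))


def _apply_id_map(df: pd.DataFrame, id_map: dict[str, str] | None) -> pd.DataFrame:
    if id_map is None:
        return df
    mapped = df.index.to_series().map(lambda i: id_map.get(i, i))
    out = df.copy()
    out.index = mapped.values
    return out


def _resolve_duplicates(df: pd.DataFrame, ratio_cols: list[str]) -> pd.DataFrame:
    """Keep, per symbol, the record with the largest mean |log10 ratio|."""
    if df.index.is_unique:
        return df
    score = df[ratio_cols].abs().mean(axis=1)
    order = np.argsort(-score.to_numpy(), kind="stable")
    picked = df.iloc[order]
    picked = picked[~picked.index.duplicated(keep="first")]
    if not picked.index.is_unique:
        raise ValueError("duplicate symbols remain after probe resolution")
    return picked.sort_index()


def cross_index(
    rna_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> PairedProfiles:
    """Merge RNA and protein ratio tables into paired profiles by symbol.

    Inputs are result frames with ``ratio_<t>`` columns indexed by
    platform identifiers; ``id_map`` maps identifiers of either platform
    to common symbols (identity where absent).  When several records map
    to one symbol (multiple probes), the one with the largest mean
    absolute log10 ratio is kept.  The shared grid is the intersection of
    the two platforms' ratio times; a pair is ``complete`` when it has no
    missing value on that grid.
    """
    rna = _apply_id_map(rna_results, id_map)
    prot = _apply_id_map(protein_results, id_map)
    rna_times = _ratio_times(rna)
    prot_times = _ratio_times(prot)
    shared = tuple(t for t in rna_times if t in set(prot_times))
    rna_cols = [time_column("ratio", t) for t in shared]
    prot_cols = [time_column("ratio", t) for t in shared]
    rna = _resolve_duplicates(rna, rna_cols)
    prot = _resolve_duplicates(prot, prot_cols)
    common = sorted(set(rna.index) & set(prot.index))
    frame = pd.DataFrame(index=pd.Index(common, name="symbol"))
    for t in shared:
        frame[time_column("rna", t)] = rna.loc[common, time_column("ratio", t)].to_numpy()
    for t in shared:
        frame[time_column("prot", t)] = prot.loc[common, time_column("ratio", t)].to_numpy()
    frame["complete"] = ~frame.isna().any(axis=1)
    counts = {
        "rna_records": int(len(rna_results)),
        "protein_records": int(len(protein_results)),
        "merged_pairs": int(len(frame)),
        "complete_pairs": int(frame["complete"].sum()),
    }
    return PairedProfiles(frame=frame, shared_times=shared, counts=counts)


def filter_complete(pairs: PairedProfiles) -> PairedProfiles:
    """Keep only pairs with a value at every shared time (idempotent)."""
    kept = pairs.frame[pairs.frame["complete"]].copy()
    counts = dict(pairs.counts)
    counts["complete_pairs"] = int(len(kept))
    return PairedProfiles(frame=kept, shared_times=pairs.shared_times, counts=counts)


def cluster_profiles(
    profiles: np.ndarray | pd.DataFrame,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
) -> np.ndarray:
    """Cluster ratio profiles (rows) into ``k`` groups.

    ``kmeans`` minimises within-cluster squared Euclidean distance with 10
    restarts; ``hierarchical`` cuts an average-linkage Euclidean tree.
    Labels are deterministic for a given seed.
    """
    X = np.asarray(profiles, dtype=float)
    if np.isnan(X).any():
        raise ValueError("profiles must not contain missing values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k ({k}) exceeds the number of profiles ({X.shape[0]})")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method == "hierarchical":
        hc = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="average")
        return hc.fit_predict(X)
    raise ValueError(f"unknown clustering method {method!r}")
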