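"""Per-platform differential-abundance calling.

Three platforms, three rule sets, one output layout:

* **RNA** (replicated array intensities): quantile normalization, per-time
  two-group comparison of log10 intensities against the 0 hr control
  replicates, Benjamini–Hochberg FDR over all entity x time tests, plus a
  fold-change gate.  Significant = some time passes the FDR *and* some
  time shows at least a ``fold``-fold change.
* **MS** (peptide-level isotopic treated:control ratios): per-protein,
  per-time aggregation of log10 peptide ratios with iterative two-sided
  Grubbs outlier removal, then a fold-change gate requiring at least
  ``min_peptides`` surviving peptides at a qualifying time.
* **Western** (triplicate treated and control intensities): the ratio per
  time is the median of the 3x3 matrix of pairwise treated/control
  ratios; a fold-change gate decides significance.

All ratios are reported as log10 vs the 0 hr control.  Result frames share
the column scheme ``symbol | platform | significant | ratio_<t> ...`` with
platform-specific extras (``p_<t>``/``q_<t>`` for RNA, ``npep_<t>`` for
MS, ``sig_<t>`` per-time qualification flags for all platforms).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import TimeDesign, fmt_time
from .io import parse_sample_column, time_column

__all__ = [
    "quantile_normalize",
    "call_differential_rna",
    "grubbs_filter",
    "aggregate_protein_ratios",
    "call_differential_ms",
    "call_differential_western",
    "significant_symbols",
]


# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (rank-mean) value distribution.

    Each column's sorted values are replaced by the across-column mean of
    the values at the same rank; ties receive the mean of the reference
    values they span (fractional average ranks are linearly interpolated).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        i, j = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite value at row {matrix.index[i]!r}, column {matrix.columns[j]!r}"
        )
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    ranks = pd.DataFrame(vals).rank(method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _sample_groups(columns) -> dict[float, list[str]]:
    groups: dict[float, list[str]] = {}
    for c in columns:
        t, _ = parse_sample_column(c)
        groups.setdefault(t, []).append(c)
    return groups


def call_differential_rna(
    matrix: pd.DataFrame,
    design: TimeDesign,
    fdr: float = 0.05,
    fold: float = 1.5,
    *,
    normalize: bool = True,
) -> pd.DataFrame:
    """Call differential RNA from replicated intensity data.

    Per entity and treated time, replicate log10 intensities are compared
    with the 0 hr control replicates by a two-sample t-test (the pairwise
    analysis-of-variance reading of time-vs-control); p-values are BH
    adjusted over the full entity x time family.  The per-time ratio is
    the difference of mean log10 intensities (log10 fold change).
    """
    groups = _sample_groups(matrix.columns)
    if 0.0 not in groups:
        raise ValueError("matrix has no 0 hr control columns")
    times = [t for t in design.rna_time_points if t > 0 and t in groups]
    if not times:
        raise ValueError("matrix has no treated time columns matching the design")
    if len(groups[0.0]) < 2:
        raise ValueError("need >= 2 control replicates")
    for t in times:
        if len(groups[t]) < 2:
            raise ValueError(f"need >= 2 replicates at time {fmt_time(t)} hr")

    data = quantile_normalize(matrix) if normalize else matrix
    log = np.log10(data.to_numpy(dtype=float))
    log = pd.DataFrame(log, index=data.index, columns=data.columns)
    ctrl = log[groups[0.0]].to_numpy()

    out = pd.DataFrame(index=matrix.index)
    out.insert(0, "platform", "rna")
    pcols = []
    for t in times:
        tr = log[groups[t]].to_numpy()
        ratio = tr.mean(axis=1) - ctrl.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-constant replicate groups trigger benign precision warnings
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat, p = stats.ttest_ind(tr, ctrl, axis=1)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties -> uninformative
        out[time_column("ratio", t)] = ratio
        out[time_column("p", t)] = p
        pcols.append(time_column("p", t))

    flat_p = out[pcols].to_numpy().ravel()
    _, q, _, _ = multipletests(flat_p, alpha=fdr, method="fdr_bh")
    qmat = q.reshape(len(out), len(times))
    thr = np.log10(fold)
    for j, t in enumerate(times):
        out[time_column("q", t)] = qmat[:, j]
    fdr_any = (qmat <= fdr).any(axis=1)
    for j, t in enumerate(times):
        ratio = out[time_column("ratio", t)].to_numpy()
        # per-time qualification: FDR pass at that time and a fold change there
        out[time_column("sig", t)] = (qmat[:, j] <= fdr) & (np.abs(ratio) >= thr)
    fold_any = np.abs(out[[time_column("ratio", t) for t in times]].to_numpy()) >= thr
    out["significant"] = fdr_any & fold_any.any(axis=1)
    out.index.name = "symbol"
    return out


# ---------------------------------------------------------------------------

def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_filter(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of values surviving iterative two-sided Grubbs removal.

    At most one point (the largest standardised deviation) is removed per
    iteration, until no point exceeds the critical value or fewer than 3
    remain (the test is undefined below n = 3).  A zero-SD sample removes
    nothing.
    """
    v = np.asarray(values, dtype=float)
    keep = np.ones(len(v), dtype=bool)
    while keep.sum() >= 3:
        cur = v[keep]
        sd = cur.std(ddof=1)
        if sd == 0:
            break
        z = np.abs(cur - cur.mean()) / sd
        imax = int(np.argmax(z))
        if z[imax] <= _grubbs_critical(len(cur), alpha):
            break
        keep[np.flatnonzero(keep)[imax]] = False
    return keep


def aggregate_protein_ratios(
    peptides: pd.DataFrame,
    grubbs_alpha: float = 0.05,
) -> pd.DataFrame:
    """Collapse peptide ratios to per-protein, per-time log10 ratios.

    Outliers among a protein-time's peptide log10 ratios are removed by
    iterative Grubbs testing; the reported ratio is the mean of the
    surviving log10 ratios (a geometric mean on the linear scale, so a
    ratio and its reciprocal aggregate symmetrically), with ``npep`` the
    survivor count.  Input columns: ``protein_symbol``, ``time_hr``,
    ``ratio`` (strictly positive linear treated:control ratios).
    """
    if (peptides["ratio"] <= 0).any():
        bad = peptides.loc[peptides["ratio"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive peptide ratio for {bad['protein_symbol']} at {bad['time_hr']} hr"
        )
    records: dict[str, dict[str, float]] = {}
    for (sym, t), grp in peptides.groupby(["protein_symbol", "time_hr"], sort=True):
        logr = np.log10(grp["ratio"].to_numpy(dtype=float))
        keep = grubbs_filter(logr, grubbs_alpha)
        rec = records.setdefault(sym, {})
        rec[time_column("ratio", t)] = float(logr[keep].mean())
        rec[time_column("npep", t)] = int(keep.sum())
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "symbol"
    return out.sort_index()


def call_differential_ms(
    aggregated: pd.DataFrame,
    fold: float = 1.5,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Fold-change + peptide-support gate on aggregated MS ratios.

    A protein qualifies at a time when its |log10 ratio| reaches the fold
    threshold with at least ``min_peptides`` surviving peptides there;
    significant proteins qualify at >= 1 time.
    """
    thr = np.log10(fold)
    times = sorted(
        float(c.split("_", 1)[1]) for c in aggregated.columns if c.startswith("ratio_")
    )
    out = aggregated.copy()
    out.insert(0, "platform", "ms")
    sig_any = np.zeros(len(out), dtype=bool)
    for t in times:
        rc, nc = time_column("ratio", t), time_column("npep", t)
        ratio = out[rc].to_numpy(dtype=float)
        npep = out[nc].fillna(0).to_numpy(dtype=float)
        sig_t = (np.abs(ratio) >= thr) & (npep >= min_peptides) & ~np.isnan(ratio)
        out[time_column("sig", t)] = sig_t
        sig_any |= sig_t
    out["significant"] = sig_any
    out["n_peptides"] = out[[time_column("npep", t) for t in times]].max(axis=1)
    return out


# ---------------------------------------------------------------------------

def call_differential_western(
    western: pd.DataFrame,
    fold: float = 1.5,
) -> pd.DataFrame:
    """Triplicate-blot calling via the 3x3 pairwise-ratio median.

    Input is long format: ``symbol, time_hr, channel (treated|control),
    rep, intensity`` (plus an optional ``phospho`` flag, propagated).  The
    control is the 0 hr sample.  For each entity and treated time, all 9
    treated/control intensity ratios are formed and their median taken as
    the ratio (a robust version of the vendor's matrix comparison).
    """
    thr = np.log10(fold)
    records: dict[str, dict] = {}
    phospho_map: dict[str, bool] = {}
    for sym, grp in western.groupby("symbol", sort=True):
        ctrl = grp[(grp["channel"] == "control")]["intensity"].to_numpy(dtype=float)
        if len(ctrl) < 3:
            raise ValueError(f"{sym}: need >= 3 control replicates, got {len(ctrl)}")
        rec: dict[str, float] = {}
        for t, tgrp in grp[grp["channel"] == "treated"].groupby("time_hr"):
            tr = tgrp["intensity"].to_numpy(dtype=float)
            if len(tr) < 3:
                raise ValueError(
                    f"{sym} at {fmt_time(t)} hr: need >= 3 treated replicates, got {len(tr)}"
                )
            ratios = (tr[:, None] / ctrl[None, :]).ravel()
            rec[time_column("ratio", t)] = float(np.log10(np.median(ratios)))
        records[sym] = rec
        if "phospho" in grp.columns:
            phospho_map[sym] = bool(grp["phospho"].iloc[0])
    out = pd.DataFrame.from_dict(records, orient="index").sort_index()
    out.index.name = "symbol"
    out.insert(0, "platform", "western")
    times = sorted(float(c.split("_", 1)[1]) for c in out.columns if c.startswith("ratio_"))
    sig_any = np.zeros(len(out), dtype=bool)
    for t in times:
        ratio = out[time_column("ratio", t)].to_numpy(dtype=float)
        sig_t = np.abs(ratio) >= thr
        sig_t &= ~np.isnan(ratio)
        out[time_column("sig", t)] = sig_t
        sig_any |= sig_t
    out["significant"] = sig_any
    if phospho_map:
        out["phospho"] = out.index.map(lambda s: phospho_map.get(s, False))
    return out


def significant_symbols(result: pd.DataFrame) -> set[str]:
    """Symbols called significant in a differential result frame."""
    return set(result.index[result["significant"].astype(bool)])
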