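"""RNA–protein temporal concordance statistics.

Given matched RNA and protein log10-ratio time profiles (one pair per
gene), this module quantifies how tightly transcript and protein dynamics
track each other:

* **Global**: classical canonical correlation analysis (CCA) across the
  shared time grid finds linear combinations of time points maximising the
  RNA/protein correlation over gene pairs; a permutation null (shuffling
  the RNA-to-protein pairing while keeping each time profile intact)
  calibrates the observed canonical correlations.

* **Per pair**: both scaled profiles are regressed on a cubic B-spline
  basis with 3 degrees of freedom.  ``F1`` tests whether the two smoothed
  profiles share one shape (equality of spline coefficients); ``F2`` tests
  the joint significance of the shared-shape regression against a flat
  profile.  A composite score ``a*F2 + b*F1`` with ``a > 0 > b`` rewards
  pairs that are both strongly time-varying and shape-concordant.  Negative
  concordance (mirror-image dynamics) is scored by repeating the fit with
  the RNA profile sign-flipped.

* **Per category**: a shared four-parameter logistic time curve measures
  within-category coherence of profiles, and a Wilcoxon rank-sum test asks
  whether a category's members are more (or less) concordant than the
  scored background.

Profiles are scaled to mean 0, SD 1 before any comparison so that the
statistics respond to profile *shape*, not amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "ScaledProfile",
    "CcaResult",
    "ConcordanceScore",
    "spline_basis",
    "scale_profile",
    "canonical_correlation",
    "permutation_test_cca",
    "concordance_f_stats",
    "composite_score",
    "score_pairs",
    "category_coherence",
    "coherence_mark",
    "category_concordance_enrichment",
]


# ---------------------------------------------------------------------------
# profile scaling

@dataclass(frozen=True)
class ScaledProfile:
    """A time profile standardised to mean 0, SD 1 (sample SD, n-1)."""

    times: tuple[float, ...]
    values: np.ndarray
    degenerate: bool = False


def scale_profile(values, times=None, *, tol: float = 1e-12) -> ScaledProfile:
    """Standardise a ratio profile to mean 0, SD 1.

    A constant profile has no shape to compare; it is returned flagged
    ``degenerate`` (values zeroed) and must be excluded from downstream
    statistics rather than crashing a batch run.
    """
    v = np.asarray(values, dtype=float)
    if times is None:
        times = tuple(range(len(v)))
    times = tuple(float(t) for t in times)
    if v.ndim != 1 or len(v) != len(times):
        raise ValueError("profile values and times must be 1-D and equal length")
    if len(v) < 3:
        raise ValueError("profile needs at least 3 time points")
    if not np.all(np.isfinite(v)):
        raise ValueError("profile contains non-finite values")
    sd = v.std(ddof=1)
    if sd <= tol:
        warnings.warn("constant profile flagged degenerate (SD = 0)", stacklevel=2)
        return ScaledProfile(times, np.zeros_like(v), degenerate=True)
    return ScaledProfile(times, (v - v.mean()) / sd, degenerate=False)


# ---------------------------------------------------------------------------
# spline basis

def spline_basis(times, df: int = 3, degree: int = 3, knot_times=None) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` columns, no intercept column.

    Mirrors the common statistical-modelling convention: interior knots (if
    ``df > degree``) at quantiles of the observation times, boundary knots
    at the extremes, and the first basis function dropped so that an
    intercept can be fit separately.  ``knot_times`` lets callers place the
    knots from one grid while evaluating the basis on another (e.g. a
    time-shifted copy of the same smooth function).
    """
    t = np.asarray(times, dtype=float)
    kt = t if knot_times is None else np.asarray(knot_times, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df < degree:
        # fewer columns than the degree would leave no valid knot vector
        raise ValueError(f"df ({df}) must be >= degree ({degree})")
    n_interior = df - degree
    lo, hi = kt.min(), kt.max()
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(kt), probs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    dm = BSpline.design_matrix(t, knots, degree, extrapolate=True).toarray()
    # full basis has df+1 functions summing to one; drop the first so the
    # span excludes the constant and an explicit intercept is identifiable
    return dm[:, 1:]


# ---------------------------------------------------------------------------
# canonical correlation

@dataclass(frozen=True)
class CcaResult:
    """Observed canonical correlations with their permutation null."""

    correlations: np.ndarray          # descending, in [0, 1]
    perm_correlations: np.ndarray     # n_perm x rank
    p_values: np.ndarray              # per-rank empirical upper-tail p
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "correlations": [float(r) for r in self.correlations],
            "p_values": [float(p) for p in self.p_values],
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
            "perm_correlations": self.perm_correlations.tolist(),
        }


def _orthonormal_basis(X: np.ndarray, name: str, on_rank_deficient: str):
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < X.shape[1]:
        if on_rank_deficient == "error":
            # name the columns most aligned with the null directions
            bad = sorted({int(np.argmax(np.abs(Vt[i]))) for i in range(rank, X.shape[1])})
            raise np.linalg.LinAlgError(
                f"{name} matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"collinear columns include indices {bad}"
            )
        if on_rank_deficient != "reduce":
            raise ValueError("on_rank_deficient must be 'error' or 'reduce'")
    return U[:, :rank], rank


def canonical_correlation(
    rna: np.ndarray,
    prot: np.ndarray,
    *,
    on_rank_deficient: str = "error",
) -> np.ndarray:
    """Classical canonical correlations between two column sets.

    Rows are observations (gene pairs), columns are variables (time
    points).  Computed by orthonormalising each centred matrix (SVD) and
    taking the singular values of the cross product — numerically
    equivalent to the textbook whitened cross-covariance eigenproblem.

    ``on_rank_deficient='reduce'`` drops null directions (as R's ``cancor``
    does via pivoted QR); the default raises, naming collinear columns.
    Mean-0-scaled profiles are always rank deficient by one, so pipeline
    callers use ``'reduce'``.
    """
    X = np.asarray(rna, dtype=float)
    Y = np.asarray(prot, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("rna and prot must be 2-D with the same number of rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not allowed in CCA input")
    if X.shape[0] < max(X.shape[1], Y.shape[1]):
        raise ValueError("need at least as many rows (pairs) as columns (times)")
    Ux, _ = _orthonormal_basis(X, "rna", on_rank_deficient)
    Uy, _ = _orthonormal_basis(Y, "prot", on_rank_deficient)
    svals = np.linalg.svd(Ux.T @ Uy, compute_uv=False)
    return np.clip(svals, 0.0, 1.0)


def permutation_test_cca(
    rna: np.ndarray,
    prot: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    on_rank_deficient: str = "reduce",
) -> CcaResult:
    """Permutation-calibrate canonical correlations.

    Each permutation shuffles which protein profile is paired with which
    RNA profile (rows of ``prot``) while leaving every individual time
    profile intact, destroying the pairing but preserving the marginal
    temporal structure.  The per-rank p-value uses the add-one empirical
    estimator ``(1 + #{perm >= obs}) / (1 + n_perm)`` so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(rna, dtype=float)
    Y = np.asarray(prot, dtype=float)
    obs = canonical_correlation(X, Y, on_rank_deficient=on_rank_deficient)
    Ux, _ = _orthonormal_basis(X, "rna", on_rank_deficient)
    Uy, _ = _orthonormal_basis(Y, "prot", on_rank_deficient)
    k = len(obs)
    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, k))
    n = X.shape[0]
    for i in range(n_perm):
        idx = rng.permutation(n)
        # row permutation of prot permutes the rows of its orthonormal basis
        s = np.linalg.svd(Ux.T @ Uy[idx], compute_uv=False)
        perm[i] = np.clip(s, 0.0, 1.0)
    p = (1 + (perm >= obs[None, :]).sum(axis=0)) / (1 + n_perm)
    return CcaResult(obs, perm, p, n_perm, seed)


# ---------------------------------------------------------------------------
# per-pair spline concordance

@dataclass(frozen=True)
class ConcordanceScore:
    """Shape-equality (F1) and joint-significance (F2) statistics for a pair.

    ``composite_pos``/``composite_neg`` are ``a*F2 + b*F1`` for the as-is
    and RNA-sign-flipped fits; higher means stronger (anti-)concordance.
    """

    F1: float
    F2: float
    F1_neg: float
    F2_neg: float
    a: float = 1.0
    b: float = -1.0

    @property
    def composite_pos(self) -> float:
        return composite_score(self.F1, self.F2, self.a, self.b)

    @property
    def composite_neg(self) -> float:
        return composite_score(self.F1_neg, self.F2_neg, self.a, self.b)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _f_pair(y_rna: np.ndarray, y_prot: np.ndarray, B: np.ndarray, df: int) -> tuple[float, float]:
    n = len(y_rna)
    y = np.concatenate([y_rna, y_prot])
    ones = np.ones(n)
    zeros = np.zeros(n)
    i_rna = np.concatenate([ones, zeros])
    i_prot = np.concatenate([zeros, ones])
    Bz = np.zeros_like(B)
    # unconstrained: separate intercept and spline coefficients per profile
    Xu = np.column_stack([i_rna, i_prot,
                          np.vstack([B, Bz]), np.vstack([Bz, B])])
    # constrained: separate intercepts, one shared spline shape
    Xc = np.column_stack([i_rna, i_prot, np.vstack([B, B])])
    X0 = np.column_stack([i_rna, i_prot])
    rss_u = _rss(y, Xu)
    rss_c = _rss(y, Xc)
    rss_0 = _rss(y, X0)
    df_u = 2 * n - (2 + 2 * df)
    df_c = 2 * n - (2 + df)
    if df_u <= 0:
        raise ValueError("not enough time points for the unconstrained spline fit")
    tol = 1e-12 * max(rss_0, 1.0)

    def f_stat(rss_small_minus_large: float, rss_large: float, df_num: int, df_den: int) -> float:
        num = max(rss_small_minus_large, 0.0) / df_num
        if rss_large <= tol:
            return 0.0 if num <= tol else float("inf")
        return num / (rss_large / df_den)

    F1 = f_stat(rss_c - rss_u, rss_u, df, df_u)
    F2 = f_stat(rss_0 - rss_c, rss_c, df, df_c)
    return F1, F2


def concordance_f_stats(
    rna: ScaledProfile,
    prot: ScaledProfile,
    df: int = 3,
) -> tuple[float, float]:
    """F1 (shape-equality) and F2 (joint regression) for one scaled pair.

    Both profiles must sit on the same time grid with at least 5 distinct
    times.  F1 compares the separate-shapes fit with the shared-shape fit;
    F2 compares the shared-shape fit with intercepts only.
    """
    if rna.times != prot.times:
        raise ValueError("RNA and protein profiles must share the same time grid")
    times = np.asarray(rna.times)
    if len(np.unique(times)) < 5:
        raise ValueError("need at least 5 distinct time points for the spline F-tests")
    if rna.degenerate or prot.degenerate:
        raise ValueError("degenerate (constant) profiles cannot be scored")
    B = spline_basis(times, df=df)
    return _f_pair(np.asarray(rna.values), np.asarray(prot.values), B, df)


def composite_score(F1: float, F2: float, a: float = 1.0, b: float = -1.0) -> float:
    """Scalar concordance ranking ``a*F2 + b*F1`` (``a > 0``, ``b < 0``)."""
    if not a > 0:
        raise ValueError("a must be > 0")
    if not b < 0:
        raise ValueError("b must be < 0")
    if F1 < 0 or F2 < 0:
        raise ValueError("F statistics must be non-negative")
    if np.isinf(F2) and np.isinf(F1):
        return 0.0  # both saturated: uninformative
    return a * F2 + b * F1


def score_pairs(
    pairs: pd.DataFrame,
    times,
    *,
    df: int = 3,
    a: float = 1.0,
    b: float = -1.0,
) -> pd.DataFrame:
    """Score every pair in a merged pairs table.

    ``pairs`` is indexed by symbol with columns ``rna_<t>`` and
    ``prot_<t>`` for every shared treated time ``t`` (log10 ratios).
    Pairs with a missing value or a constant profile are dropped with a
    warning.  Returns a frame with F1/F2 (positive and sign-flipped) and
    composite scores, ranked by ``composite_pos``.
    """
    from .io import time_column

    times = tuple(float(t) for t in times)
    rna_cols = [time_column("rna", t) for t in times]
    prot_cols = [time_column("prot", t) for t in times]
    rows = []
    for sym, row in pairs.iterrows():
        rv = row[rna_cols].to_numpy(dtype=float)
        pv = row[prot_cols].to_numpy(dtype=float)
        if np.isnan(rv).any() or np.isnan(pv).any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = scale_profile(rv, times)
            sp = scale_profile(pv, times)
        if sr.degenerate or sp.degenerate:
            warnings.warn(f"pair {sym} has a constant profile; skipped", stacklevel=2)
            continue
        F1, F2 = concordance_f_stats(sr, sp, df=df)
        sr_neg = ScaledProfile(sr.times, -sr.values)
        F1n, F2n = concordance_f_stats(sr_neg, sp, df=df)
        score = ConcordanceScore(F1, F2, F1n, F2n, a=a, b=b)
        rows.append(
            {
                "symbol": sym,
                "F1": F1,
                "F2": F2,
                "F1_neg": F1n,
                "F2_neg": F2n,
                "composite_pos": score.composite_pos,
                "composite_neg": score.composite_neg,
            }
        )
    out = pd.DataFrame(rows).set_index("symbol") if rows else pd.DataFrame(
        columns=["F1", "F2", "F1_neg", "F2_neg", "composite_pos", "composite_neg"]
    )
    out = out.sort_values("composite_pos", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# category-level statistics

def _logistic(t, lower, upper, rate, midpoint):
    return lower + (upper - lower) / (1.0 + np.exp(-rate * (t - midpoint)))


def category_coherence(profiles: np.ndarray, times) -> float:
    """Coherence p-value of one category's profiles on a shared sigmoid.

    All member profiles (rows, already scaled) are pooled and fit jointly
    to a single four-parameter logistic curve in time; the p-value is the
    F-test of that fit against the pooled constant model.  A small p means
    the members move together along one monotone time course.  Returns NaN
    (with a warning) if the curve fit fails to converge.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("category coherence needs at least 3 member profiles")
    t = np.asarray(times, dtype=float)
    if P.shape[1] != len(t):
        raise ValueError("profile length must match the time grid")
    tt = np.tile(t, P.shape[0])
    yy = P.ravel()
    n = len(yy)
    rss0 = float(np.sum((yy - yy.mean()) ** 2))
    span = yy.max() - yy.min()
    p0 = [yy.min(), yy.max(), 1.0, float(np.median(t))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _logistic, tt, yy, p0=p0, maxfev=5000,
                bounds=([yy.min() - 2 * span - 1, yy.min() - 2 * span - 1, -10.0, t.min() - 1],
                        [yy.max() + 2 * span + 1, yy.max() + 2 * span + 1, 10.0, t.max() + 1]),
            )
    except (RuntimeError, ValueError):
        warnings.warn("logistic coherence fit did not converge; p = NA", stacklevel=2)
        return float("nan")
    rss1 = float(np.sum((yy - _logistic(tt, *popt)) ** 2))
    df_num, df_den = 3, n - 4
    if df_den <= 0:
        return float("nan")
    if rss1 <= 1e-12 * max(rss0, 1.0):
        return 0.0 if rss0 > rss1 else 1.0
    F = max(rss0 - rss1, 0.0) / df_num / (rss1 / df_den)
    return float(stats.f.sf(F, df_num, df_den))


def coherence_mark(p: float) -> str:
    """Significance mark for a coherence p-value: ``XX`` p<0.01, ``X`` p<0.05."""
    if np.isnan(p):
        return "NA"
    if p < 0.01:
        return "XX"
    if p < 0.05:
        return "X"
    return ""


def category_concordance_enrichment(
    scores: pd.Series,
    categories: dict[str, set[str]],
) -> pd.DataFrame:
    """Rank-sum test of concordance scores inside vs outside each category.

    For each category, member pair scores are compared with every other
    scored pair (the full scored background provides the expected-by-chance
    frequency) with a two-sided Wilcoxon rank-sum test.  ``direction`` is
    ``+1`` when members are more concordant than the background (median
    difference positive), ``-1`` for less, ``0`` on a tie.
    """
    rows = []
    all_syms = set(scores.index)
    for name in sorted(categories):
        members = sorted(categories[name] & all_syms)
        non = sorted(all_syms - set(members))
        if not members or not non:
            raise ValueError(
                f"category {name!r} needs >=1 member and >=1 non-member among scored pairs"
            )
        ms = scores.loc[members].to_numpy(dtype=float)
        ns = scores.loc[non].to_numpy(dtype=float)
        if np.all(ms == ms[0]) and np.all(ns == ms[0]):
            p, direction = 1.0, 0
        else:
            res = stats.mannwhitneyu(ms, ns, alternative="two-sided",
                                     method="exact" if len(ms) + len(ns) <= 25 else "auto")
            p = float(res.pvalue)
            diff = float(np.median(ms) - np.median(ns))
            direction = 0 if diff == 0 else (1 if diff > 0 else -1)
        rows.append({"category": name, "n_members": len(members),
                     "wilcoxon_p": p, "direction": direction})
    return pd.DataFrame(rows)
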