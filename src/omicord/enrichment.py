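"""Hypergeometric process enrichment with time-domain staging.

Over-representation of flat category sets (GMT) among significant
entities, against the background of entities the platform could actually
detect — arrays see what is probed, MS sees what is identified, blots see
what is blotted — so that platform coverage bias does not masquerade as
biology.  Significant sets can be split into early / intermediate / late
time domains (hours after stimulation) before testing, staging the
response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import time_column
from .design import fmt_time

__all__ = ["hypergeom_enrichment", "time_domain_sets", "DEFAULT_DOMAINS"]

#: Early / intermediate / late staging of the response (hours, inclusive).
DEFAULT_DOMAINS: dict[str, tuple[float, float]] = {
    "early": (0.0, 4.0),
    "intermediate": (8.0, 13.0),
    "late": (18.0, 24.0),
}


def hypergeom_enrichment(
    significant: set[str],
    background: set[str],
    categories: dict[str, set[str]],
    *,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per category.

    For a category with ``K`` background members, ``p = P(X >= k)`` where
    ``X`` is hypergeometric with population ``N = |background|``, ``K``
    successes, and ``n = |significant|`` draws, and ``k`` the significant
    members observed.  Categories are intersected with the background
    first, so annotation entries the platform never measured are inert.
    Rows are sorted by (p, category name).  ``bh_correct`` optionally adds
    a Benjamini-Hochberg ``q`` column (off by default).
    """
    stray = significant - background
    if stray:
        raise ValueError(f"significant symbols missing from background: {sorted(stray)[:10]}")
    N = len(background)
    n = len(significant)
    rows = []
    for name in sorted(categories):
        members = categories[name] & background
        K = len(members)
        k = len(members & significant)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": name, "k": k, "n": n, "K": K, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["category", "k", "n", "K", "N", "p"])
    out = out.sort_values(["p", "category"], kind="stable").reset_index(drop=True)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def time_domain_sets(
    result: pd.DataFrame,
    domains: dict[str, tuple[float, float]] = DEFAULT_DOMAINS,
) -> dict[str, set[str]]:
    """Split a differential result into per-time-domain symbol sets.

    An entity joins every domain whose (inclusive) hour interval contains
    at least one time where the entity passes the per-time significance
    rule (``sig_<t>`` columns).  Entities may belong to several domains;
    never-significant entities belong to none.  Intervals must not
    overlap.
    """
    items = sorted(domains.items(), key=lambda kv: kv[1][0])
    for (na, (a0, a1)), (nb, (b0, b1)) in zip(items, items[1:]):
        if a1 >= b0:
            raise ValueError(f"time domains {na!r} and {nb!r} overlap")
    times = sorted(float(c.split("_", 1)[1]) for c in result.columns if c.startswith("sig_"))
    out: dict[str, set[str]] = {}
    for name, (lo, hi) in domains.items():
        cols = [time_column("sig", t) for t in times if lo <= t <= hi]
        if cols:
            mask = result[cols].astype(bool).any(axis=1)
            out[name] = set(result.index[mask])
        else:
            out[name] = set()
    return out
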