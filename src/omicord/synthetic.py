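"""Seeded synthetic multi-platform time-course generator.

Emulates the statistical structure of a growth-factor stimulation study in
which the same cell lysates feed three platforms: triplicate expression
arrays (intensities), isotopic-ratio MS proteomics (peptide-level
treated:control ratios), and triplicate antibody blots.  Every entity is
assigned one concordance class:

``concordant``
    RNA and protein share one smooth (spline-family) log10-ratio shape.
``lagged``
    Protein follows the same shape delayed by ``lag`` hours (clipped at 0),
    emulating translation delay.
``anticorrelated``
    Protein shape is the negation of the RNA shape (e.g. feedback between
    degradation and compensatory transcription).
``independent``
    RNA and protein shapes drawn independently.
``null``
    Flat truth; all observed variation is noise — the feedstock for
    false-discovery calibration.

Shapes are drawn from the same 3-df cubic B-spline family the concordance
statistics fit, so concordant pairs are exactly representable by the
shared-shape model.  Noise is additive Gaussian on the log10-ratio scale;
peptide-level rows occasionally receive a gross outlier so that robust
aggregation has something to remove.  Every function is deterministic for
a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .concordance import spline_basis
from .design import TimeDesign, DEFAULT_DESIGN, fmt_time
from .io import sample_column

__all__ = [
    "Catalog",
    "ConcordanceSpec",
    "SyntheticTruth",
    "SimulatedTimecourse",
    "PAIR_CLASSES",
    "generate_catalog",
    "generate_timecourse",
    "generate_interactions",
]

PAIR_CLASSES = ("concordant", "lagged", "anticorrelated", "independent", "null")

INTERACTION_TYPES = ("transcriptional", "protein-interaction", "phosphorylation")


@dataclass(frozen=True)
class Catalog:
    """Entity symbols plus flat category (process) memberships."""

    symbols: tuple[str, ...]
    categories: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class ConcordanceSpec:
    """Mixture and noise settings of a simulated study.

    ``fractions`` gives the proportion of entities in each pair class (must
    sum to 1).  ``noise_sd`` is the SD of additive log10 noise per
    measurement; ``effect_sd`` the SD of the true spline shape
    coefficients (log10 units); ``lag`` the protein delay for the lagged
    class (hours).  ``outlier_rate`` is the per-(protein, time) probability
    that one peptide receives a gross offset of ``outlier_scale`` x
    ``noise_sd`` (uniform in that range, random sign).  ``dropout`` is the
    per-(protein, time) probability of a missing MS value.
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "concordant": 0.2,
            "lagged": 0.2,
            "anticorrelated": 0.2,
            "independent": 0.2,
            "null": 0.2,
        }
    )
    lag: float = 4.0
    noise_sd: float = 0.1
    effect_sd: float = 0.3
    outlier_rate: float = 0.05
    outlier_scale: tuple[float, float] = (5.0, 10.0)
    dropout: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(PAIR_CLASSES)
        if unknown:
            raise ValueError(f"unknown pair classes: {sorted(unknown)}")
        vals = [self.fractions.get(c, 0.0) for c in PAIR_CLASSES]
        if any(v < 0 for v in vals):
            raise ValueError("class fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(vals)!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated time course (for recovery tests)."""

    classes: dict[str, str]
    rna_coefficients: dict[str, list[float]]
    protein_coefficients: dict[str, list[float]]
    peptide_counts: dict[str, int]
    outliers: list[dict]                 # {protein, time_hr, peptide_id, offset}
    western_entities: list[str]
    phospho_entities: list[str]
    hubs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedTimecourse:
    """Bundle of the three platform tables plus the generating truth."""

    rna: pd.DataFrame          # intensities, columns t<h>_r<rep>
    peptides: pd.DataFrame     # peptide_id, protein_symbol, time_hr, ratio
    western: pd.DataFrame      # symbol, time_hr, channel, rep, intensity, phospho
    truth: SyntheticTruth


# ---------------------------------------------------------------------------

def generate_catalog(n_entities: int, category_sizes: list[int], seed: int) -> Catalog:
    """Symbols ``SYN0001..`` plus overlapping categories of the given sizes."""
    if n_entities <= 0:
        raise ValueError("n_entities must be positive")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_entities)))
    symbols = tuple(f"SYN{i + 1:0{width}d}" for i in range(n_entities))
    categories: dict[str, tuple[str, ...]] = {}
    for j, size in enumerate(category_sizes):
        if size < 1 or size > n_entities:
            raise ValueError(f"category size {size} out of range 1..{n_entities}")
        members = rng.choice(n_entities, size=size, replace=False)
        categories[f"CAT{j + 1:02d}"] = tuple(symbols[i] for i in sorted(members))
    return Catalog(symbols=symbols, categories=categories)


def _assign_classes(n: int, spec: ConcordanceSpec, rng: np.random.Generator) -> np.ndarray:
    counts = {c: int(np.floor(spec.fractions.get(c, 0.0) * n)) for c in PAIR_CLASSES}
    short = n - sum(counts.values())
    # hand leftovers to the classes with the largest fractional remainder
    rema = sorted(
        PAIR_CLASSES,
        key=lambda c: -(spec.fractions.get(c, 0.0) * n - counts[c]),
    )
    for c in rema[:short]:
        counts[c] += 1
    labels = np.concatenate([[c] * counts[c] for c in PAIR_CLASSES])
    return rng.permutation(labels)


def _shape_fn(coef: np.ndarray, times: np.ndarray, knot_times: np.ndarray) -> np.ndarray:
    """log10 ratio vs control: one smooth spline curve anchored to 0 at t = 0.

    The curve lives on the knot vector of the full design grid, so
    evaluating it at lag-shifted times yields the *same* function delayed,
    not a re-knotted one.
    """
    query = np.concatenate([[0.0], np.asarray(times, dtype=float)])
    B = spline_basis(query, df=len(coef), knot_times=knot_times)
    vals = B @ coef
    return vals[1:] - vals[0]


def generate_timecourse(
    catalog: Catalog,
    design: TimeDesign = DEFAULT_DESIGN,
    spec: ConcordanceSpec = ConcordanceSpec(),
    seed: int = 0,
) -> SimulatedTimecourse:
    """Simulate all three platform tables for one study.

    Per entity, a true RNA shape (3 spline coefficients on the full time
    grid, anchored to 0 at the control) and a class-dependent protein
    shape are drawn; platform tables add platform-appropriate structure:
    replicate array intensities, peptide-expanded MS ratios with optional
    gross outliers and dropout, and 3+3 blot intensities for a measured
    subset.
    """
    rng = np.random.default_rng(seed)
    n = len(catalog.symbols)
    full_times = np.asarray(design.time_points)
    prot_times = np.asarray(design.treated_times)
    rna_times = np.asarray(design.rna_time_points)

    classes = _assign_classes(n, spec, rng)
    ndf = 3
    truth = SyntheticTruth(
        classes={}, rna_coefficients={}, protein_coefficients={},
        peptide_counts={}, outliers=[], western_entities=[], phospho_entities=[],
    )

    # western measures a subset (antibody availability); ~20% of catalog,
    # 10% of those phospho-specific readouts
    n_west = max(1, int(round(0.2 * n)))
    west_idx = np.sort(rng.choice(n, size=n_west, replace=False))
    west_set = {catalog.symbols[i] for i in west_idx}
    phospho = {s for s in west_set if rng.random() < 0.1}
    truth.western_entities = sorted(west_set)
    truth.phospho_entities = sorted(phospho)

    rna_rows = {}
    pep_rows = []
    west_rows = []
    pep_counter = 0

    lag_times = np.maximum(prot_times - spec.lag, 0.0)

    for i, sym in enumerate(catalog.symbols):
        cls = classes[i]
        truth.classes[sym] = cls
        if cls == "null":
            r_coef = np.zeros(ndf)
            p_coef = np.zeros(ndf)
        else:
            r_coef = rng.normal(0.0, spec.effect_sd, ndf)
            if cls in ("concordant", "lagged"):
                p_coef = r_coef.copy()
            elif cls == "anticorrelated":
                p_coef = -r_coef
            else:
                p_coef = rng.normal(0.0, spec.effect_sd, ndf)
        truth.rna_coefficients[sym] = [float(x) for x in r_coef]
        truth.protein_coefficients[sym] = [float(x) for x in p_coef]

        rna_shape = _shape_fn(r_coef, rna_times, full_times)
        if cls == "lagged":
            prot_shape = _shape_fn(p_coef, lag_times, full_times)
        else:
            prot_shape = _shape_fn(p_coef, prot_times, full_times)

        # --- RNA platform: replicate intensities around a baseline
        baseline = rng.normal(3.0, 0.5)
        row = {}
        for t, shape_val in zip(rna_times, rna_shape):
            for rep in range(1, design.replicates + 1):
                noise = rng.normal(0.0, spec.noise_sd)
                row[sample_column(t, rep)] = 10 ** (baseline + shape_val + noise)
        rna_rows[sym] = row

        # --- MS platform: peptide-expanded treated:control ratios
        n_pep = 1 + int(rng.poisson(3.0))
        truth.peptide_counts[sym] = n_pep
        pep_ids = [f"{sym}_p{j + 1}" for j in range(n_pep)]
        pep_counter += n_pep
        for t, shape_val in zip(prot_times, prot_shape):
            if spec.dropout > 0 and rng.random() < spec.dropout:
                continue
            out_j = -1
            offset = 0.0
            if spec.outlier_rate > 0 and rng.random() < spec.outlier_rate:
                out_j = int(rng.integers(n_pep))
                lo, hi = spec.outlier_scale
                offset = float(rng.uniform(lo, hi) * spec.noise_sd)
                if rng.random() < 0.5:
                    offset = -offset
                truth.outliers.append(
                    {"protein": sym, "time_hr": float(t),
                     "peptide_id": pep_ids[out_j], "offset": offset}
                )
            for j, pid in enumerate(pep_ids):
                noise = rng.normal(0.0, spec.noise_sd)
                extra = offset if j == out_j else 0.0
                pep_rows.append(
                    {"peptide_id": pid, "protein_symbol": sym,
                     "time_hr": float(t), "ratio": 10 ** (shape_val + noise + extra)}
                )

        # --- western platform: 3 treated + 3 control intensities per time
        if sym in west_set:
            wbase = rng.normal(3.0, 0.5)
            prot_shape_full = (
                _shape_fn(p_coef, lag_times, full_times) if cls == "lagged"
                else _shape_fn(p_coef, prot_times, full_times)
            )
            ph = sym in phospho
            for rep in range(1, 4):
                west_rows.append(
                    {"symbol": sym, "time_hr": 0.0, "channel": "control", "rep": rep,
                     "intensity": 10 ** (wbase + rng.normal(0.0, spec.noise_sd)),
                     "phospho": ph}
                )
            for t, shape_val in zip(prot_times, prot_shape_full):
                for rep in range(1, 4):
                    west_rows.append(
                        {"symbol": sym, "time_hr": float(t), "channel": "treated",
                         "rep": rep,
                         "intensity": 10 ** (wbase + shape_val + rng.normal(0.0, spec.noise_sd)),
                         "phospho": ph}
                    )

    rna = pd.DataFrame.from_dict(rna_rows, orient="index")
    rna.index.name = "symbol"
    peptides = pd.DataFrame(pep_rows, columns=["peptide_id", "protein_symbol", "time_hr", "ratio"])
    western = pd.DataFrame(
        west_rows, columns=["symbol", "time_hr", "channel", "rep", "intensity", "phospho"]
    )
    return SimulatedTimecourse(rna=rna, peptides=peptides, western=western, truth=truth)


def generate_interactions(
    catalog: Catalog,
    m_edges: int,
    type_mixture: dict[str, float] | None = None,
    seed: int = 0,
    n_hubs: int = 5,
    hub_weight: float = 20.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Sparse typed interaction table with preferential attachment.

    Endpoints are sampled proportionally to (1 + accumulated degree), with
    ``n_hubs`` designated symbols given ``hub_weight`` starting weight so
    the table has clear high-degree nodes, approximating the heavy-tailed
    degree distribution of curated signaling databases.  Each accepted pair
    carries one type drawn from ``type_mixture``; self-loops and repeated
    pairs are excluded.  The type is drawn only after a novel pair is
    accepted, so realized type fractions are an unbiased multinomial sample
    from the mixture even when pair rejection is frequent.  Returns the edge
    table and the hub symbols.
    """
    if m_edges < 0:
        raise ValueError("m_edges must be >= 0")
    if type_mixture is None:
        type_mixture = {"transcriptional": 0.5, "protein-interaction": 0.35,
                        "phosphorylation": 0.15}
    unknown = set(type_mixture) - set(INTERACTION_TYPES)
    if unknown:
        raise ValueError(f"unknown interaction types: {sorted(unknown)}")
    tnames = sorted(type_mixture)
    tprobs = np.array([type_mixture[t] for t in tnames], dtype=float)
    if (tprobs < 0).any() or abs(tprobs.sum() - 1.0) > 1e-9:
        raise ValueError("type mixture must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    n = len(catalog.symbols)
    weights = np.ones(n)
    hubs: list[str] = []
    if n_hubs > 0 and n > 1:
        hub_idx = rng.choice(n, size=min(n_hubs, n), replace=False)
        weights[hub_idx] = hub_weight
        hubs = sorted(catalog.symbols[i] for i in hub_idx)

    seen: set[tuple[str, str]] = set()
    rows = []
    max_tries = 50 * max(m_edges, 1) + 100
    tries = 0
    while len(rows) < m_edges and tries < max_tries:
        tries += 1
        p = weights / weights.sum()
        a, b = rng.choice(n, size=2, replace=True, p=p)
        if a == b:
            continue
        u, v = catalog.symbols[a], catalog.symbols[b]
        key = (min(u, v), max(u, v))
        if key in seen:
            continue
        seen.add(key)
        etype = tnames[int(rng.choice(len(tnames), p=tprobs))]
        rows.append({"source": u, "type": etype, "target": v})
        weights[a] += 1
        weights[b] += 1
    edges = pd.DataFrame(rows, columns=["source", "type", "target"])
    return edges, hubs
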