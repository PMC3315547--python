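"""End-to-end orchestration: simulate -> differential -> integrate ->
concordance -> network -> enrichment.

One seeded config drives the whole run; every stage writes its flat-text
outputs into the run directory and the manifest records parameters, seeds,
per-stage entity counts and output checksums so a run can be audited and
reproduced exactly.  All randomness flows from the single config seed via
fixed per-stage offsets.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import differential as dd
from . import enrichment as en
from . import integration as it
from . import network as nw
from . import synthetic as sy
from .design import TimeDesign, DEFAULT_DESIGN
from .io import (
    read_gmt,
    sample_column,
    time_column,
    write_gmt,
    write_json,
    write_matrix,
    write_sif,
    write_table,
)

logger = logging.getLogger("omicord")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated parameter set for one pipeline run."""

    seed: int
    outdir: str = "omicord_run"
    # simulation
    n_entities: int = 400
    category_sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    m_edges: int = 800
    fractions: dict[str, float] = field(
        default_factory=lambda: dict(sy.ConcordanceSpec().fractions)
    )
    lag: float = 4.0
    noise_sd: float = 0.1
    effect_sd: float = 0.3
    outlier_rate: float = 0.05
    dropout: float = 0.1
    # thresholds
    fdr: float = 0.05
    fold: float = 1.5
    grubbs_alpha: float = 0.05
    min_peptides: int = 2
    n_perm: int = 1000
    spline_df: int = 3
    composite_a: float = 1.0
    composite_b: float = -1.0
    top_k_hubs: int = 2
    k_clusters: int = 6

    def validate(self) -> None:
        """Raise one error listing every violated bound."""
        problems = []
        if not isinstance(self.seed, int):
            problems.append("seed must be an integer")
        if not 0 < self.fdr < 1:
            problems.append(f"fdr must be in (0, 1), got {self.fdr}")
        if self.fold < 1:
            problems.append(f"fold must be >= 1, got {self.fold}")
        if not 0 < self.grubbs_alpha < 1:
            problems.append(f"grubbs_alpha must be in (0, 1), got {self.grubbs_alpha}")
        if self.min_peptides < 1:
            problems.append("min_peptides must be >= 1")
        if self.n_perm < 1:
            problems.append("n_perm must be >= 1")
        if self.spline_df < 3:
            problems.append("spline_df must be >= 3")
        if not self.composite_a > 0:
            problems.append("composite_a must be > 0")
        if not self.composite_b < 0:
            problems.append("composite_b must be < 0")
        if self.top_k_hubs < 1:
            problems.append("top_k_hubs must be >= 1")
        if self.k_clusters < 1:
            problems.append("k_clusters must be >= 1")
        if self.n_entities < 10:
            problems.append("n_entities must be >= 10")
        try:
            self.concordance_spec()
        except ValueError as e:
            problems.append(str(e))
        if problems:
            raise ValueError("invalid configuration:\n- " + "\n- ".join(problems))

    def concordance_spec(self) -> sy.ConcordanceSpec:
        return sy.ConcordanceSpec(
            fractions=dict(self.fractions),
            lag=self.lag,
            noise_sd=self.noise_sd,
            effect_sd=self.effect_sd,
            outlier_rate=self.outlier_rate,
            dropout=self.dropout,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "category_sizes" in raw:
            raw["category_sizes"] = tuple(raw["category_sizes"])
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scaled_pair_matrices(pairs: it.PairedProfiles):
    """Per-profile mean-0/SD-1 RNA and protein matrices of complete pairs."""
    times = pairs.shared_times
    rna_cols = [time_column("rna", t) for t in times]
    prot_cols = [time_column("prot", t) for t in times]
    frame = pairs.frame[pairs.frame["complete"]]
    symbols, R, P = [], [], []
    for sym, row in frame.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = cc.scale_profile(row[rna_cols].to_numpy(dtype=float), times)
            sp = cc.scale_profile(row[prot_cols].to_numpy(dtype=float), times)
        if sr.degenerate or sp.degenerate:
            continue
        symbols.append(sym)
        R.append(sr.values)
        P.append(sp.values)
    return symbols, np.array(R), np.array(P)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = DEFAULT_DESIGN
    manifest: dict = {
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
        "seed": config.seed,
        "stage_seeds": {},
        "counts": {},
        "outputs": {},
    }

    # ---- stage 1: simulate -------------------------------------------------
    s0, s1, s2, s3 = (config.seed + i for i in range(4))
    manifest["stage_seeds"] = {"catalog": s0, "timecourse": s1,
                               "interactions": s2, "permutation": s3}
    catalog = sy.generate_catalog(config.n_entities, list(config.category_sizes), s0)
    sim = sy.generate_timecourse(catalog, design, config.concordance_spec(), s1)
    edges, hubs = sy.generate_interactions(catalog, config.m_edges, seed=s2)
    sim.truth.hubs = hubs
    write_gmt({k: list(v) for k, v in catalog.categories.items()}, out / "catalog.gmt")
    write_matrix(sim.rna, out / "rna_matrix.tsv")
    write_table(sim.peptides, out / "peptides.tsv")
    write_table(sim.western, out / "western.tsv")
    write_sif(edges, out / "interactions.sif")
    write_json(sim.truth.to_dict(), out / "truth.json")
    logger.info("simulated %d entities, %d peptide rows, %d interactions",
                config.n_entities, len(sim.peptides), len(edges))

    # ---- stage 2: differential --------------------------------------------
    rna_res = dd.call_differential_rna(sim.rna, design, fdr=config.fdr, fold=config.fold)
    agg = dd.aggregate_protein_ratios(sim.peptides, grubbs_alpha=config.grubbs_alpha)
    ms_res = dd.call_differential_ms(agg, fold=config.fold, min_peptides=config.min_peptides)
    west_res = dd.call_differential_western(sim.western, fold=config.fold)
    for name, res in [("rna", rna_res), ("ms", ms_res), ("western", west_res)]:
        res.to_csv(out / f"differential_{name}.tsv", sep="\t",
                   index_label="symbol", lineterminator="\n")
        manifest["counts"][f"significant_{name}"] = int(res["significant"].sum())
        manifest["counts"][f"detected_{name}"] = int(len(res))
    logger.info("significant: rna=%d ms=%d western=%d",
                *(manifest["counts"][f"significant_{p}"] for p in ("rna", "ms", "western")))

    # ---- stage 3: integrate ------------------------------------------------
    ms_sig = ms_res[ms_res["significant"]]
    pairs = it.cross_index(rna_res, ms_sig)
    complete = it.filter_complete(pairs)
    manifest["counts"].update(pairs.counts)
    pairs.frame.to_csv(out / "pairs.tsv", sep="\t", index_label="symbol",
                       lineterminator="\n")
    symbols, R, P = _scaled_pair_matrices(complete)
    if len(symbols) >= config.k_clusters and len(symbols) > 0:
        labels = it.cluster_profiles(np.hstack([R, P]), config.k_clusters,
                                     method="kmeans", seed=config.seed)
        pd.DataFrame({"symbol": symbols, "cluster": labels}).to_csv(
            out / "clusters.tsv", sep="\t", index=False, lineterminator="\n")

    # ---- stage 4: concordance ---------------------------------------------
    if len(symbols) >= len(complete.shared_times):
        cca = cc.permutation_test_cca(R, P, n_perm=config.n_perm, seed=s3)
        cca_dict = cca.to_dict()
        cca_dict.pop("perm_correlations")  # bulky; distribution summarised below
        cca_dict["perm_rank1_quantiles"] = {
            q: float(np.quantile(cca.perm_correlations[:, 0], float(q)))
            for q in ("0.5", "0.95", "0.99")
        }
        write_json(cca_dict, out / "cca.json")
        manifest["counts"]["cca_pairs"] = len(symbols)
    scores = cc.score_pairs(complete.frame, complete.shared_times,
                            df=config.spline_df, a=config.composite_a,
                            b=config.composite_b)
    scores.to_csv(out / "scores.tsv", sep="\t", index_label="symbol",
                  lineterminator="\n")

    # category-level report over scored pairs
    cat_rows = []
    scored = set(scores.index)
    tgrid = complete.shared_times
    for name, members in catalog.categories.items():
        mem = sorted(set(members) & scored)
        row: dict = {"category": name, "n_pairs": len(mem)}
        if len(mem) >= 3:
            sub = complete.frame.loc[mem]
            Rm = np.array([cc.scale_profile(
                sub.loc[s, [time_column("rna", t) for t in tgrid]].to_numpy(dtype=float),
                tgrid).values for s in mem])
            Pm = np.array([cc.scale_profile(
                sub.loc[s, [time_column("prot", t) for t in tgrid]].to_numpy(dtype=float),
                tgrid).values for s in mem])
            p_rna = cc.category_coherence(Rm, tgrid)
            p_prot = cc.category_coherence(Pm, tgrid)
            row.update(rna_coherence_p=p_rna, rna_mark=cc.coherence_mark(p_rna),
                       prot_coherence_p=p_prot, prot_mark=cc.coherence_mark(p_prot))
        if mem and len(scored - set(mem)) > 0:
            wres = cc.category_concordance_enrichment(
                scores["composite_pos"], {name: set(mem)})
            row["wilcoxon_p"] = float(wres["wilcoxon_p"].iloc[0])
            row["direction"] = {1: "+", -1: "-", 0: ""}[int(wres["direction"].iloc[0])]
        cat_rows.append(row)
    write_table(pd.DataFrame(cat_rows), out / "category_report.tsv")

    # ---- stage 5: network --------------------------------------------------
    db = nw.InteractionDatabase.from_frame(edges)
    roots = {
        "rna": dd.significant_symbols(rna_res),
        "ms": dd.significant_symbols(ms_res),
        "western": dd.significant_symbols(west_res),
    }
    roots = {k: v for k, v in roots.items() if v}
    if len(roots) >= 2:
        names = list(roots)
        unions = [tuple(names[:2])] if len(names) == 2 else [tuple(names[:2]), tuple(names)]
        net_table = nw.compare_integration(roots, db, unions=unions,
                                           top_k=config.top_k_hubs)
        write_table(net_table, out / "network_stats.tsv")

    # ---- stage 6: enrichment -----------------------------------------------
    categories = {k: set(v) for k, v in catalog.categories.items()}
    backgrounds = {
        "rna": set(rna_res.index),
        "ms": set(ms_res.index),
        "western": set(west_res.index),
    }
    for plat, res in [("rna", rna_res), ("ms", ms_res), ("western", west_res)]:
        sig = dd.significant_symbols(res)
        enr = en.hypergeom_enrichment(sig, backgrounds[plat], categories)
        write_table(enr, out / f"enrichment_{plat}.tsv")
    combined_bg = set().union(*backgrounds.values())
    domain_sets: dict[str, set[str]] = {d: set() for d in en.DEFAULT_DOMAINS}
    for res in (rna_res, ms_res, west_res):
        for dom, syms in en.time_domain_sets(res).items():
            domain_sets[dom] |= syms
    for dom, syms in domain_sets.items():
        enr = en.hypergeom_enrichment(syms, combined_bg, categories)
        write_table(enr, out / f"enrichment_domain_{dom}.tsv")
        manifest["counts"][f"domain_{dom}"] = len(syms)

    # ---- manifest ----------------------------------------------------------
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _checksum(p)
    write_json(manifest, out / "manifest.json")
    return manifest
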