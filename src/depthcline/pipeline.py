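"""Full-survey orchestration: simulate or read, then run every stage.

Stage order mirrors the field workflow: gear-selectivity correction ->
growth-cluster delineation on three-year-olds -> genotype statistics under
the delineated grouping -> gradient association tests. All randomness
derives from the single configured seed; reports record seeds and
permutation counts alongside every stochastic result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import delineation, gradient_tests, popgen_stats, selectivity, simdata
from .io import GenotypeTable, RunConfig, read_genepop, read_phenotypes

logger = logging.getLogger("depthcline")

__all__ = ["RunReport", "run_pipeline", "write_report"]


@dataclass
class RunReport:
    """Provenance plus per-stage results of one full pipeline run."""

    config: dict
    seed: int
    selectivity_table: pd.DataFrame | None = None
    class_boundaries: list[float] = field(default_factory=list)
    n_clusters: int | None = None
    cluster_medoids: list[float] = field(default_factory=list)
    mixture_aicc: dict[int, float] = field(default_factory=dict)
    mixture_selected_k: int | None = None
    shapiro: dict[str, float] = field(default_factory=dict)
    diversity: pd.DataFrame | None = None
    hwe: pd.DataFrame | None = None
    ld_summary: dict = field(default_factory=dict)
    fst_pairs: pd.DataFrame | None = None
    amova: dict[str, dict] = field(default_factory=dict)
    trends: pd.DataFrame | None = None
    mantel: pd.DataFrame | None = None
    headline: dict = field(default_factory=dict)


def _age3(pheno: pd.DataFrame) -> pd.Series:
    return pheno["age"] == 3 if "age" in pheno.columns else pd.Series(True, index=pheno.index)


def run_pipeline(
    config: RunConfig,
    genotypes: GenotypeTable | None = None,
    pheno: pd.DataFrame | None = None,
) -> RunReport:
    """Run the complete analysis; deterministic given ``config.seed``."""
    seed = config.seed
    if genotypes is None or pheno is None:
        if config.preset:
            genotypes, pheno, _ = simdata.simulate_preset(config.preset, seed=seed)
        elif config.genotypes and config.phenotypes:
            genotypes = read_genepop(config.genotypes)
            pheno = read_phenotypes(config.phenotypes)
        else:
            raise ValueError("config must name input files or a simulation preset")
    report = RunReport(config=dataclasses.asdict(config), seed=seed)

    # --- gradient trend regressions ----------------------------------------
    trend_rows = []
    for trait in ("sl", "gr"):
        for predictor in ("depth", "date_days"):
            if trait in pheno.columns and predictor in pheno.columns:
                try:
                    slope, f, (df1, df2), p = gradient_tests.linear_trend(
                        pheno[trait].to_numpy(float), pheno[predictor].to_numpy(float)
                    )
                except ValueError:
                    continue
                trend_rows.append({"trait": trait, "predictor": predictor,
                                   "slope": slope, "f": f, "df1": df1,
                                   "df2": df2, "p": p})
    report.trends = pd.DataFrame(trend_rows)

    # --- selectivity -------------------------------------------------------
    model = selectivity.fit_mesh_selectivity(pheno)
    report.selectivity_table = model.report()
    partition = selectivity.class_boundaries(model)
    report.class_boundaries = list(partition.boundaries)
    pheno = selectivity.assign_selectivity_classes(pheno, partition)

    # --- delineation on three-year-olds ------------------------------------
    age3 = _age3(pheno)
    sl3 = pheno.loc[age3, "sl"].dropna().to_numpy(float)
    w, p_norm = delineation.normality_test(sl3)
    report.shapiro = {"w": w, "p": p_norm}
    fits, k_sel = delineation.fit_gaussian_mixtures(sl3, seed=seed)
    report.mixture_aicc = {f.k: f.aicc for f in fits}
    report.mixture_selected_k = k_sel
    solution = delineation.hybrid_tree_cut(sl3)
    report.n_clusters = solution.k
    report.cluster_medoids = [float(m) for m in solution.medoids]
    cluster_col = pd.Series(np.nan, index=pheno.index)
    cluster_col.loc[pheno.index[age3][pheno.loc[age3, "sl"].notna()]] = solution.labels
    # non-age-3 fish attach to the nearest cluster by SL
    rest = pheno.index[~age3 & pheno["sl"].notna()]
    if len(rest):
        cluster_col.loc[rest] = delineation.assign_to_clusters(
            pheno.loc[rest, "sl"].to_numpy(float), solution
        )
    pheno = pheno.assign(growth_cluster=cluster_col)

    # --- genotype statistics under the delineated grouping ------------------
    g3 = genotypes.subset(age3.to_numpy() & pheno["sl"].notna().to_numpy())
    labels3 = pheno.loc[age3 & pheno["sl"].notna(), "growth_cluster"].astype(int).to_numpy()
    div = popgen_stats.diversity_summary(g3, labels3)
    report.diversity = div.summary
    report.hwe = popgen_stats.hwe_test(
        g3, labels3, chain=config.hwe_chain,
        dememorization=config.hwe_dememorization, seed=seed,
    )
    _, report.ld_summary = popgen_stats.ld_pairwise_tests(
        g3, labels3, permutations=min(config.mantel_permutations, 199), seed=seed
    )
    fst = popgen_stats.pairwise_fst(
        g3, labels3, permutations=config.fst_permutations, seed=seed, fdr_q=config.fdr_q
    )
    report.fst_pairs = fst.pairs()
    for grouping_name in ("growth_cluster", "depth", "mesh", "date_days"):
        if grouping_name not in pheno.columns:
            continue
        vals = pheno.loc[age3, grouping_name].to_numpy()
        if len(pd.unique(vals[~pd.isna(vals)])) < 2:
            continue
        res = popgen_stats.amova(
            genotypes.subset(age3.to_numpy()), vals,
            permutations=min(config.fst_permutations, 1000),
            seed=seed, grouping_name=grouping_name,
        )
        report.amova[grouping_name] = {
            "phi_st": res.phi_st, "p": res.p, "permutations": res.permutations,
        }

    # --- association tests --------------------------------------------------
    D_gen = popgen_stats.smouse_peakall_distance(g3)
    sub = pheno.loc[age3 & pheno["sl"].notna()]
    mantel_rows = []
    for trait in ("sl", "gr", "depth"):
        if trait not in sub.columns or sub[trait].isna().any():
            continue
        D_tr = gradient_tests.phenotype_distance(sub[trait].to_numpy(float))
        res = gradient_tests.mantel(
            D_gen, D_tr, permutations=config.mantel_permutations, seed=seed
        )
        mantel_rows.append({"trait": trait, "r": res.r, "p": res.p,
                            "permutations": res.permutations, "seed": seed})
    report.mantel = pd.DataFrame(mantel_rows)

    report.headline = {
        "n_fish": int(len(pheno)),
        "n_age3": int(age3.sum()),
        "k_clusters": report.n_clusters,
        "mixture_k": report.mixture_selected_k,
        "class_boundaries_mm": report.class_boundaries,
        "all_fst_significant": bool(report.fst_pairs["significant"].all()),
        "hwe_significant": int((report.hwe["p"] < 0.05).sum()),
        "ld_pct_significant": report.ld_summary.get("pct_significant"),
        "amova_phi_st": {k: v["phi_st"] for k, v in report.amova.items()},
        "mantel_r": {row["trait"]: row["r"] for row in mantel_rows},
    }
    return report


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Serialize the report: JSON summary plus delimited per-stage tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    summary = {
        "config": report.config,
        "seed": report.seed,
        "shapiro": report.shapiro,
        "mixture_aicc": {str(k): v for k, v in report.mixture_aicc.items()},
        "mixture_selected_k": report.mixture_selected_k,
        "n_clusters": report.n_clusters,
        "cluster_medoids": report.cluster_medoids,
        "class_boundaries": report.class_boundaries,
        "amova": report.amova,
        "ld_summary": report.ld_summary,
        "headline": report.headline,
    }
    path = outdir / "report.json"
    path.write_text(json.dumps(summary, indent=2, default=float))
    written.append(path)
    for name, df in (
        ("trends.tsv", report.trends),
        ("selectivity.tsv", report.selectivity_table),
        ("diversity.tsv", report.diversity),
        ("hwe.tsv", report.hwe),
        ("fst_pairs.tsv", report.fst_pairs),
        ("mantel.tsv", report.mantel),
    ):
        if df is not None:
            p = outdir / name
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
    logger.info("report written to %s", outdir)
    return written
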