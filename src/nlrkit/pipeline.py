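"""End-to-end orchestration: join per-gene tables and run the comparison battery.

The pipeline reproduces the study design on any cohort with the right inputs:

1. classify each receptor gene hv / non-hv from its clade alignment entropy;
2. per-gene population genetics (pi, S, theta_W, Tajima's D, piN/piS, and
   per-domain statistics by majority-vote column labels);
3. per-gene genomic features (log2 TPM, %CG gene-body methylation, TE
   distance, physical clusters, neighbor pairs);
4. the comparison battery: hv vs non-hv Wilcoxon tests per feature and
   domain, Fisher association with cluster membership and genic TEs,
   Kruskal-Wallis across subsets, rank-based and permutation enrichment
   against the genome background, and empirical-tail selection tests —
   with Benjamini-Hochberg correction applied within each test family.

Everything is deterministic under a fixed (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .entropy import classify_hv, entropy_profile
from .features import (
    assign_clusters,
    cluster_table,
    counts_to_tpm,
    gene_methylation,
    mean_log2_tpm,
    nearest_te_distance,
    neighbor_pairs,
)
from .io import Alignment, AnnotationSet
from .popgen import (
    balancing_selection_flags,
    diversity_stats,
    domain_columns,
    domain_stats,
    pin_pis,
    sliding_window_stats,
)
from .setstats import (
    bh_adjust,
    fisher_exact_2x2,
    kruskal_wallis,
    matched_perm_diff_test,
    perm_diff_test,
    perm_pvalue_set_score,
    significance_tier,
    tail_count_test,
    wilcoxon_rank_sum,
)
from .simulate import (
    SimConfig,
    simulate_feature_tables,
    simulate_genealogy_haplotypes,
    simulate_nlrome,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Fixed constants of the analysis, serialized into every output header."""

    entropy_threshold: float = 1.5  # bits
    min_positions: int = 10
    min_coverage: int = 5  # reads per cytosine
    cluster_max_gap: int = 50_000  # bp
    pair_max_gap: int = 2_000  # bp
    window: int = 300  # bp
    step: int = 75  # bp
    tail_q: float = 0.05
    R: int = 10_000  # permutation replicates
    n_bins: int = 10  # covariate-matching quantile bins
    seed: int = 7
    exclusion_list: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("entropy_threshold", "min_positions", "min_coverage",
                     "cluster_max_gap", "pair_max_gap", "window", "step",
                     "tail_q", "R", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Joined per-gene report, test battery results, and window tracks."""

    gene_report: pd.DataFrame
    test_results: pd.DataFrame
    window_tracks: pd.DataFrame
    truth: pd.DataFrame | None
    config: AnalysisConfig
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        gr = self.gene_report
        n_hv = int((gr["hv_label"] == "hv").sum())
        lines = [
            f"nlrkit {__version__} pipeline result (seed {self.config.seed})",
            f"genes: {len(gr)} ({n_hv} hv, {len(gr) - n_hv} non-hv)",
            f"tests: {len(self.test_results)} "
            f"({int((self.test_results['q'] < 0.05).sum())} with q < 0.05)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def _default_domain_intervals(n_codons: int) -> list[tuple[int, int, str]]:
    """Synthetic receptor architecture on protein coordinates: CC-NBARC-LRR."""
    third = n_codons // 3
    return [
        (1, third, "CC"),
        (third + 1, 2 * third, "NBARC"),
        (2 * third + 1, n_codons, "LRR"),
    ]


def run_pipeline(
    sim_config: SimConfig | None = None,
    config: AnalysisConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a synthetic cohort drawn from ``sim_config``."""
    sim_config = sim_config or SimConfig()
    config = config or AnalysisConfig()
    alignments, focal_id, truth = simulate_nlrome(sim_config)
    counts, meth_calls, genes, tes, feat_truth = simulate_feature_tables(sim_config)
    return analyze_cohort(
        alignments=alignments,
        focal_id=focal_id,
        counts=counts,
        meth_calls=meth_calls,
        genes=genes,
        tes=tes,
        config=config,
        truth=truth.join(feat_truth.drop(columns=["group"]), how="outer"),
        background_popgen=_simulate_background_popgen(sim_config),
    )


def _simulate_background_popgen(sim_config: SimConfig) -> pd.DataFrame:
    """Genome-wide empirical pi / D background from neutral coalescent genes."""
    n_bg = sim_config.n_background_genes
    rng = np.random.default_rng(np.random.SeedSequence((sim_config.seed, 2)))
    rows = []
    L = 1200
    for i in range(n_bg):
        h, _ = simulate_genealogy_haplotypes(
            sim_config.n_accessions, sim_config.theta_low, L, seed=rng
        )
        st = diversity_stats(h, L=L)
        rows.append(dict(gene_id=f"BG{i + 1:04d}", pi=st.pi_per_site,
                         tajimas_d=st.tajimas_d))
    return pd.DataFrame(rows).set_index("gene_id")


def analyze_cohort(
    alignments: Mapping[str, tuple[Alignment, Alignment]],
    focal_id: str,
    counts,
    meth_calls: pd.DataFrame,
    genes: AnnotationSet,
    tes: AnnotationSet,
    config: AnalysisConfig,
    truth: pd.DataFrame | None = None,
    background_popgen: pd.DataFrame | None = None,
) -> PipelineResult:
    """Assemble the per-gene report and run the comparison battery.

    ``alignments`` maps receptor gene id -> (codon alignment, protein
    alignment); ``genes`` must contain spans for receptor and background
    genes alike.
    """
    nlr_ids = [g for g in alignments if g not in set(config.exclusion_list)]
    excluded_rows = [
        dict(gene_id=g, reason="exclusion_list") for g in config.exclusion_list
    ]

    # --- stage 1: entropy + hv classification
    hv_rows = []
    for gid in nlr_ids:
        _, protein_aln = alignments[gid]
        prof = entropy_profile(protein_aln, focal_id, gene_id=gid)
        call = classify_hv(
            prof, threshold=config.entropy_threshold,
            min_positions=config.min_positions,
        )
        hv_rows.append(
            dict(gene_id=gid, hv_label=call.label, n_high=call.n_high,
                 mean_entropy=call.mean_entropy)
        )
    hv_df = pd.DataFrame(hv_rows).set_index("gene_id")

    # --- stage 2: population genetics per gene (+ per-domain)
    pop_rows = []
    domain_rows = []
    for gid in nlr_ids:
        codon_aln, _ = alignments[gid]
        st = diversity_stats(codon_aln)
        cd = pin_pis(codon_aln)
        pop_rows.append(
            dict(gene_id=gid, n=st.n, L=st.L, S=st.S, pi=st.pi_per_site,
                 theta_w=st.theta_w_per_site, tajimas_d=st.tajimas_d,
                 pi_n=cd.pi_n, pi_s=cd.pi_s, pin_pis=cd.ratio)
        )
        protein_intervals = _default_domain_intervals(codon_aln.length // 3)
        nuc_intervals = [
            (3 * (s - 1) + 1, 3 * e, cls) for s, e, cls in protein_intervals
        ]
        dmap = domain_columns(codon_aln, {r.id: nuc_intervals for r in codon_aln.records})
        dstats = domain_stats(codon_aln, dmap)
        dstats.insert(0, "gene_id", gid)
        domain_rows.append(dstats)
    pop_df = pd.DataFrame(pop_rows).set_index("gene_id")
    domain_df = pd.concat(domain_rows, ignore_index=True)

    # --- stage 3: genomic features
    tpm = counts_to_tpm(counts)
    log2_tpm = mean_log2_tpm(tpm)
    meth = gene_methylation(meth_calls, genes, context="CG",
                            min_coverage=config.min_coverage)
    te_dist = nearest_te_distance(genes, tes)
    nlr_ann = AnnotationSet([f for f in genes.of_kind("gene") if f.id in set(nlr_ids)])
    clusters = assign_clusters(nlr_ann, max_gap=config.cluster_max_gap)
    clu = cluster_table(clusters)
    pairs = neighbor_pairs(clusters, hv_df["hv_label"].to_dict(), nlr_ann,
                           max_pair_gap=config.pair_max_gap)

    feature_df = pd.DataFrame(
        dict(log2_tpm=log2_tpm, pct_mCG=meth["pct"], n_CG_sites=meth["n_sites"],
             te_distance=te_dist["te_distance"],
             te_within_genic=te_dist["te_within_genic"])
    )
    report = hv_df.join(pop_df).join(feature_df, how="left")
    report["cluster_id"] = clu.reindex(report.index)
    report["clustered"] = ~report["cluster_id"].str.startswith("singleton").fillna(True)

    background = feature_df.drop(index=[g for g in report.index if g in feature_df.index])

    # --- stage 4: comparison battery
    tests = compare_groups_report(
        report, background, domain_df, background_popgen, config
    )

    # --- stage 5: window tracks for the neighbor-pair case study
    track_genes = list(pairs[0]) if pairs else list(report.index[:2])
    track_frames = []
    for gid in track_genes:
        codon_aln, _ = alignments[gid]
        for stat in ("pi", "tajimas_d"):
            tr = sliding_window_stats(
                codon_aln, focal_id, stat=stat, window=config.window,
                step=config.step, gene_id=gid,
            )
            t = tr.table.copy()
            t.insert(0, "stat", stat)
            t.insert(0, "gene_id", gid)
            track_frames.append(t)
    window_tracks = (
        pd.concat(track_frames, ignore_index=True)
        if track_frames
        else pd.DataFrame(columns=["gene_id", "stat", "start", "end", "midpoint", "value"])
    )

    na_genes = report.index[report["pct_mCG"].isna()]
    excluded_rows += [
        dict(gene_id=g, reason="no covered CG site") for g in na_genes
    ]
    return PipelineResult(
        gene_report=report,
        test_results=tests,
        window_tracks=window_tracks,
        truth=truth,
        config=config,
        excluded=pd.DataFrame(excluded_rows, columns=["gene_id", "reason"]),
    )


# ---------------------------------------------------------------------------
# The battery


def compare_groups_report(
    report: pd.DataFrame,
    background_features: pd.DataFrame,
    domain_df: pd.DataFrame | None,
    background_popgen: pd.DataFrame | None,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Run the study's comparison battery on a joined per-gene report.

    Returns one row per test with raw and BH-adjusted p-values; the BH
    correction is applied within each test family (the figure-panel
    equivalents), not across the whole battery.
    """
    if "hv_label" not in report.columns:
        raise ValueError("report lacks hv_label")
    hv = report[report["hv_label"] == "hv"]
    non = report[report["hv_label"] == "non-hv"]
    rows: list[dict] = []
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(ss.generate_state(64).tolist())

    def wilcoxon_row(family: str, feature: str, frame_a, frame_b,
                     alternative: str, name: str | None = None):
        a = frame_a[feature].dropna()
        b = frame_b[feature].dropna()
        if len(a) < 2 or len(b) < 2:
            logger.warning("skipping %s/%s: too few values", family, feature)
            return
        p = wilcoxon_rank_sum(a, b, alternative=alternative)
        rows.append(dict(family=family, test=name or f"wilcoxon_{feature}",
                         feature=feature, observed=float(a.median() - b.median()),
                         p=p, seed=np.nan))

    # family: per-feature hv vs non-hv (expression higher, methylation lower,
    # TE distance lower in hv)
    wilcoxon_row("features", "log2_tpm", hv, non, "greater")
    wilcoxon_row("features", "pct_mCG", hv, non, "less")
    wilcoxon_row("features", "te_distance", hv, non, "less")

    # family: gene-wide and per-domain popgen comparisons
    for feature in ("pi", "tajimas_d", "pi_n", "pi_s", "pin_pis"):
        wilcoxon_row("popgen", feature, hv, non, "greater")
    if domain_df is not None and not domain_df.empty:
        labels = report["hv_label"]
        dd = domain_df.join(labels, on="gene_id")
        for dom in sorted(set(dd["domain"]) - {"none"}):
            sub = dd[dd["domain"] == dom]
            for feature in ("pi", "tajimas_d"):
                wilcoxon_row(
                    f"domains_{feature}", feature,
                    sub[sub["hv_label"] == "hv"], sub[sub["hv_label"] == "non-hv"],
                    "greater", name=f"wilcoxon_{dom}_{feature}",
                )

    # family: association of hv status with cluster membership / genic TEs
    for name, flag in (("clustered", report["clustered"]),
                       ("te_within_genic", report["te_within_genic"])):
        if flag.isna().all():
            continue
        f = flag.astype(bool)
        table = [
            [int((f & (report["hv_label"] == "hv")).sum()),
             int((~f & (report["hv_label"] == "hv")).sum())],
            [int((f & (report["hv_label"] == "non-hv")).sum()),
             int((~f & (report["hv_label"] == "non-hv")).sum())],
        ]
        rows.append(dict(family="association", test=f"fisher_{name}", feature=name,
                         observed=float(table[0][0]), p=fisher_exact_2x2(table),
                         seed=np.nan))

    # family: robustness across subsets (Kruskal-Wallis over cluster status)
    for feature in ("log2_tpm", "pct_mCG", "te_distance"):
        groups = [
            g[feature].dropna().to_numpy()
            for _, g in report.groupby("clustered")[[feature]]
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            rows.append(dict(family="subsets", test=f"kruskal_{feature}_by_cluster",
                             feature=feature, observed=np.nan,
                             p=kruskal_wallis(groups), seed=np.nan))

    # family: enrichment against the genome background
    if background_features is not None and not background_features.empty:
        genome = pd.concat([report[background_features.columns], background_features])
        hv_ids = list(hv.index)
        for feature, direction in (("log2_tpm", "greater"), ("pct_mCG", "less")):
            values = genome[feature].dropna()
            members = [g for g in hv_ids if g in values.index]
            seed = next(seeds)
            res = perm_pvalue_set_score(
                values, members, R=config.R, seed=seed,
                direction="greater" if direction == "greater" else "less",
            )
            rows.append(dict(family="enrichment", test=f"singscore_{feature}",
                             feature=feature, observed=res.observed,
                             p=res.p_addone, seed=seed))
            seed = next(seeds)
            bg_ids = [g for g in values.index if g not in set(members)]
            res = perm_diff_test(values, members, bg_ids, stat="mean",
                                 R=config.R, seed=seed, direction=direction)
            rows.append(dict(family="enrichment", test=f"perm_mean_{feature}",
                             feature=feature, observed=res.observed,
                             p=res.p_addone, seed=seed))
        # covariate-matched methylation enrichment (matched on CG sites/gene)
        if "n_CG_sites" in genome.columns and genome["n_CG_sites"].notna().any():
            seed = next(seeds)
            values = genome["pct_mCG"].dropna()
            cov = genome["n_CG_sites"]
            members = [g for g in hv_ids if g in values.index]
            bg_ids = [g for g in values.index if g not in set(members)]
            try:
                res = matched_perm_diff_test(
                    values, members, bg_ids, covariate=cov, n_bins=config.n_bins,
                    stat="mean", R=config.R, seed=seed, direction="less",
                )
                rows.append(dict(family="enrichment", test="matched_perm_pct_mCG",
                                 feature="pct_mCG", observed=res.observed,
                                 p=res.p_addone, seed=seed))
            except ValueError as exc:
                logger.warning("matched methylation test skipped: %s", exc)

    # family: empirical-tail selection tests
    if background_popgen is not None and not background_popgen.empty:
        pi_bg = background_popgen["pi"].dropna().to_numpy()
        d_bg = background_popgen["tajimas_d"].dropna().to_numpy()
        for label, sub in (("hv", hv), ("non-hv", non)):
            for feature, bg, tail in (("pi", pi_bg, "top5"),
                                      ("tajimas_d", d_bg, "top5"),
                                      ("tajimas_d", d_bg, "bottom5")):
                seed = next(seeds)
                res = tail_count_test(sub[feature], list(sub.index), bg, tail=tail,
                                      R=config.R, seed=seed, q=config.tail_q)
                rows.append(dict(family="tails", test=f"{label}_{feature}_{tail}",
                                 feature=feature, observed=res.observed,
                                 p=res.p_addone, seed=seed))
        joint = balancing_selection_flags(
            report["pi"], report["tajimas_d"], pi_bg, d_bg, q=config.tail_q
        )
        rows.append(dict(family="tails", test="balancing_selection_count",
                         feature="pi+tajimas_d", observed=float(joint.sum()),
                         p=np.nan, seed=np.nan))

    tests = pd.DataFrame(rows)
    tests["q"] = np.nan
    for fam, idx in tests.groupby("family").groups.items():
        sub = tests.loc[idx, "p"].dropna()
        if len(sub):
            tests.loc[sub.index, "q"] = bh_adjust(sub)
    tests["tier"] = [
        significance_tier(q) if not np.isnan(q) else ""
        for q in tests["q"]
    ]
    return tests


# ---------------------------------------------------------------------------
# Output


def write_gene_table(
    report: pd.DataFrame, path: str | Path, config: AnalysisConfig | None = None
) -> None:
    """Write the per-gene report as TSV ('.' for NA, config hash in header)."""
    if report.empty:
        raise ValueError("empty report")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# nlrkit {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        report.to_csv(fh, sep="\t", na_rep=".")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_gene_table`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["."])
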