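"""Per-gene genomic features: expression, gene-body methylation, TE distance,
physical clusters, and neighboring hv / non-hv pairs.

Gene spans are the full annotated gene (UTRs and introns included) for both
methylation averaging and TE overlap, so a TE inside an intron or UTR counts
as distance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationSet, CountMatrix, Feature

logger = logging.getLogger(__name__)

CLUSTER_MAX_GAP = 50_000  # bp between adjacent receptor genes, inclusive
NEIGHBOR_PAIR_MAX_GAP = 2_000  # bp, inclusive
METH_MIN_COVERAGE = 5  # reads per cytosine


# ---------------------------------------------------------------------------
# Expression


def counts_to_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Convert raw counts to transcripts per million (per sample).

    TPM_g = 1e6 * (count_g / length_kb_g) / sum_g'(count_g' / length_kb_g').
    Columns sum to 1e6 except for all-zero samples (left at 0 with a warning).
    """
    lengths_kb = counts.lengths / 1_000.0
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.counts.div(lengths_kb, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero samples: %s", list(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def mean_log2_tpm(tpm: pd.DataFrame, replicates: Sequence[str] | None = None) -> pd.Series:
    """Replicate-mean TPM, then log2(mean + 1) — averaging precedes the log."""
    sub = tpm[list(replicates)] if replicates is not None else tpm
    out = np.log2(sub.mean(axis=1) + 1.0)
    out.name = "log2_tpm"
    return out


# ---------------------------------------------------------------------------
# Methylation


def gene_methylation(
    calls: pd.DataFrame,
    genes: AnnotationSet,
    context: str = "CG",
    min_coverage: int = METH_MIN_COVERAGE,
) -> pd.DataFrame:
    """Weighted-by-nothing per-gene percent methylation over the gene body.

    Per cytosine, percent = 100 * methylated / total for cytosines with
    coverage >= ``min_coverage``.  Symmetric CG partners (position i on '+',
    i+1 on '-') passing the filter are averaged into one site; if only one
    strand passes, that one is used.  Site percentages are then averaged
    (unweighted) across the annotated gene span, strand-agnostic.

    Returns a DataFrame indexed by gene id with columns ``pct`` (NaN when no
    qualifying site) and ``n_sites``.
    """
    sub = calls[calls["context"] == context].copy()
    sub = sub[sub["count_total"] >= min_coverage]
    sub["pct"] = 100.0 * sub["count_methylated"] / sub["count_total"]
    if context == "CG":
        sub = _merge_symmetric_cg(sub)
    else:
        sub = sub.assign(site_pos=sub["pos"])
    rows = []
    for gene in genes.of_kind("gene"):
        mask = (
            (sub["chrom"] == gene.chrom)
            & (sub["site_pos"] >= gene.start)
            & (sub["site_pos"] <= gene.end)
        )
        pct = sub.loc[mask, "pct"]
        if len(pct) == 0:
            rows.append(dict(gene_id=gene.id, pct=np.nan, n_sites=0))
        else:
            rows.append(dict(gene_id=gene.id, pct=float(pct.mean()), n_sites=len(pct)))
    out = pd.DataFrame(rows).set_index("gene_id")
    n_excluded = int(out["pct"].isna().sum())
    if n_excluded:
        logger.info("%d genes have no covered %s site and are flagged NA", n_excluded, context)
    return out


def _merge_symmetric_cg(sub: pd.DataFrame) -> pd.DataFrame:
    """Average symmetric CG partners into one site keyed by the '+' position."""
    # canonical site position: the '+'-strand cytosine of the CG duplex
    site_pos = np.where(sub["strand"] == "-", sub["pos"] - 1, sub["pos"])
    merged = (
        sub.assign(site_pos=site_pos)
        .groupby(["chrom", "site_pos"], as_index=False)
        .agg(pct=("pct", "mean"))
    )
    return merged


def pool_replicates_weighted(per_replicate: Sequence[tuple[float, int]]) -> float:
    """Pool replicate percentages weighted by their covered-cytosine counts.

    ``per_replicate`` is a sequence of (pct, n_sites); NaN / zero-site
    replicates are ignored.  Returns NaN when nothing qualifies.
    """
    num = den = 0.0
    for pct, n_sites in per_replicate:
        if n_sites > 0 and not np.isnan(pct):
            num += pct * n_sites
            den += n_sites
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# TE distance


def nearest_te_distance(genes: AnnotationSet, tes: AnnotationSet) -> pd.DataFrame:
    """Distance (bp) from each gene span to its nearest TE on the chromosome.

    Overlap (1-based inclusive) gives distance 0 and ``within_genic`` True;
    otherwise the distance is the number of bases strictly between the two
    intervals (gene [1001, 2000] vs TE [2501, 2600] -> 500 bp).  Genes on
    chromosomes with no TE get NaN with a warning.  Strand is ignored.
    """
    te_by_chrom: dict[str, list[Feature]] = {}
    for te in tes.of_kind("transposable_element"):
        te_by_chrom.setdefault(te.chrom, []).append(te)
    rows = []
    for gene in genes.of_kind("gene"):
        cands = te_by_chrom.get(gene.chrom)
        if not cands:
            logger.warning("gene %s: no TEs on chromosome %s", gene.id, gene.chrom)
            rows.append(dict(gene_id=gene.id, te_distance=np.nan, te_within_genic=False))
            continue
        best = np.inf
        overlap = False
        for te in cands:
            gap = max(te.start - gene.end - 1, gene.start - te.end - 1, 0)
            if gap < best:
                best = gap
            if gap == 0:
                overlap = True
        rows.append(dict(gene_id=gene.id, te_distance=float(best), te_within_genic=overlap))
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Clusters and neighbor pairs


@dataclass
class ClusterAssignment:
    """A maximal chain of receptor genes with inter-gene gaps <= max_gap."""

    cluster_id: str
    members: list[str]  # gene ids ordered by position
    span: int  # bp from first start to last end

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def assign_clusters(
    nlr_genes: AnnotationSet, max_gap: int = CLUSTER_MAX_GAP
) -> list[ClusterAssignment]:
    """Single-linkage chaining of genes within ``max_gap`` bp (inclusive).

    The gap between neighbors is end-to-start; overlapping genes have gap 0.
    Every gene lands in exactly one cluster; size-1 clusters are singletons.
    """
    genes = sorted(nlr_genes.of_kind("gene"), key=lambda f: (f.chrom, f.start, f.end))
    clusters: list[ClusterAssignment] = []
    current: list[Feature] = []

    def flush() -> None:
        if current:
            cid = f"cluster_{len(clusters) + 1}"
            span = max(g.end for g in current) - min(g.start for g in current) + 1
            clusters.append(
                ClusterAssignment(cid, [g.id for g in current], span)
            )

    prev: Feature | None = None
    for g in genes:
        if prev is not None and g.chrom == prev.chrom:
            gap = max(0, g.start - max(prev.end, max(x.end for x in current)) - 1)
            if gap <= max_gap:
                current.append(g)
                prev = g
                continue
        flush()
        current = [g]
        prev = g
    flush()
    return clusters


def cluster_table(clusters: Sequence[ClusterAssignment]) -> pd.Series:
    """gene_id -> cluster_id ('singleton:<gene>' for size-1 clusters)."""
    out = {}
    for c in clusters:
        for gid in c.members:
            out[gid] = f"singleton:{gid}" if c.is_singleton else c.cluster_id
    return pd.Series(out, name="cluster_id")


def neighbor_pairs(
    clusters: Sequence[ClusterAssignment],
    hv_labels: Mapping[str, str],
    genes: AnnotationSet,
    max_pair_gap: int = NEIGHBOR_PAIR_MAX_GAP,
) -> list[tuple[str, str]]:
    """(hv gene, non-hv gene) pairs from two-member mixed clusters.

    The two genes must be within ``max_pair_gap`` bp (end-to-start gap,
    inclusive) or directly adjacent in the annotation order.
    """
    by_id = {g.id: g for g in genes.of_kind("gene")}
    ordered = sorted(by_id.values(), key=lambda f: (f.chrom, f.start))
    order_index = {g.id: i for i, g in enumerate(ordered)}
    pairs = []
    for c in clusters:
        if len(c.members) != 2:
            continue
        a, b = c.members
        la, lb = hv_labels.get(a), hv_labels.get(b)
        if {la, lb} != {"hv", "non-hv"}:
            continue
        ga, gb = by_id[a], by_id[b]
        gap = max(gb.start - ga.end - 1, ga.start - gb.end - 1, 0)
        adjacent = abs(order_index[a] - order_index[b]) == 1
        if gap <= max_pair_gap or adjacent:
            hv_gene = a if la == "hv" else b
            non_hv = b if la == "hv" else a
            pairs.append((hv_gene, non_hv))
    return pairs
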