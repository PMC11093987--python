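"""Synthetic inputs with known ground truth.

A hand-rolled standard neutral (Kingman) coalescent drives all sequence-level
simulation, using the classic ``ms`` time scaling: with k lineages the waiting
time to the next coalescence is exponential with rate k(k-1)/2 (time in 4N
generations), and mutations are Poisson with mean (theta/2) x total branch
length.  Under this scaling E[pi_total] = theta and E[S] = theta * a1, which
the test suite checks against closed forms (and cross-checks against an
independent coalescent simulator).

Three generators build on the genealogy:

* :func:`simulate_genealogy_haplotypes` — infinite-sites 0/1 haplotypes on a
  finite site grid (collisions re-drawn, bounded).
* :func:`simulate_codon_clade` — codon sequences evolved along the tree; each
  mutation proposes a random single-base change, synonymous proposals are
  always accepted, nonsynonymous ones with probability omega, stop-creating
  ones are re-drawn.  omega therefore tunes realized piN/piS monotonically.
* :func:`simulate_nlrome` / :func:`simulate_feature_tables` — a full study
  stand-in: per-gene clade alignments with hv / non-hv truth labels, plus
  negative-binomial expression counts, binomial methylation calls with Poisson
  coverage, and TE placements with group-specific distance distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Alignment,
    AnnotationSet,
    CountMatrix,
    Feature,
    HaplotypeMatrix,
    SequenceRecord,
    write_fasta,
)
from .popgen import _CODON_TABLE

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")


@dataclass
class SimConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults mirror the study's set sizes (35 hv-like and 97 non-hv-like
    receptor genes) and its reported effect directions: hv-like genes are more
    expressed (+2 log2 fold), less CG-methylated (-40 percentage points), and
    more often TE-overlapped (0.6 vs 0.1).
    """

    n_genes: int = 132
    hv_fraction: float = 35 / 132
    n_accessions: int = 32
    n_codons: int = 150
    theta_low: float = 4.0  # per-gene population mutation parameter, non-hv-like
    theta_high: float = 300.0  # hv-like (deep allelic series, near-saturated columns)
    omega_low: float = 0.15  # nonsynonymous acceptance probability, non-hv-like
    omega_high: float = 0.9  # hv-like
    expression_log2fc: float = 2.0  # hv effect on log2 expression
    expression_base_log2: float = 5.0
    expression_dispersion: float = 0.15  # NB dispersion (1/size)
    n_replicates: int = 4
    methylation_base_pct: float = 60.0  # non-hv-like gene-body CG level
    methylation_delta_pct: float = -40.0  # hv effect
    coverage_mean: float = 20.0  # Poisson read depth per cytosine
    cg_sites_mean: float = 30.0  # CG duplexes per gene body
    te_overlap_prob_hv: float = 0.6
    te_overlap_prob_nonhv: float = 0.1
    te_distance_mean: float = 3000.0  # bp, exponential, when not overlapping
    gene_length_range: tuple[int, int] = (2000, 6000)
    intergene_gap_range: tuple[int, int] = (10_000, 120_000)
    n_background_genes: int = 600  # non-receptor genes standing in for the genome
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hv_fraction <= 1.0:
            raise ValueError("hv_fraction must be in [0, 1]")
        for name in ("theta_low", "theta_high", "coverage_mean", "cg_sites_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("omega_low", "omega_high"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_hv(self) -> int:
        return round(self.n_genes * self.hv_fraction)


# ---------------------------------------------------------------------------
# Coalescent genealogy


@dataclass
class Genealogy:
    """A binary coalescent tree over ``n`` sampled leaves (ids 0..n-1)."""

    n: int
    parent: np.ndarray  # parent node id, -1 for the root
    node_time: np.ndarray  # coalescent time of each node (leaves at 0)
    leaf_sets: list[np.ndarray] = field(repr=False)  # leaves below each node

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def branch_lengths(self) -> np.ndarray:
        lengths = np.zeros(self.n_nodes)
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                lengths[v] = self.node_time[p] - self.node_time[v]
        return lengths

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])


def simulate_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Standard neutral coalescent: rate k(k-1)/2 with random pair merges."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leaf_sets: list[np.ndarray | None] = [np.array([i]) for i in range(n)] + [
        None
    ] * (n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        leaf_sets[nxt] = np.concatenate([leaf_sets[a], leaf_sets[b]])
        active.append(nxt)
        nxt += 1
    return Genealogy(n=n, parent=parent, node_time=node_time, leaf_sets=leaf_sets)


def _draw_mutation_branches(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Branch (child-node id) of each mutation; count ~ Poisson(theta/2 * T)."""
    lengths = tree.branch_lengths
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(tree.n_nodes, size=n_mut, p=lengths / total)


def simulate_genealogy_haplotypes(
    n: int,
    theta: float,
    L: int,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 100,
) -> tuple[HaplotypeMatrix, dict]:
    """Infinite-sites haplotypes on L candidate sites plus a genealogy summary.

    Each mutation lands on a distinct site (uniform over 1..L; occupied sites
    are re-drawn up to ``max_redraws`` times, then an error advises a larger L).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = simulate_genealogy(n, rng)
    branches = _draw_mutation_branches(tree, theta, rng)
    occupied: set[int] = set()
    positions: list[int] = []
    cols: list[np.ndarray] = []
    for b in branches:
        pos = int(rng.integers(1, L + 1))
        tries = 0
        while pos in occupied:
            tries += 1
            if tries > max_redraws:
                raise ValueError(
                    f"could not place {len(branches)} mutations on {L} sites; "
                    "increase L"
                )
            pos = int(rng.integers(1, L + 1))
        occupied.add(pos)
        positions.append(pos)
        col = np.zeros(n, dtype=np.int8)
        col[tree.leaf_sets[b]] = 1
        cols.append(col)
    order = np.argsort(positions)
    matrix = (
        np.stack([cols[i] for i in order], axis=1)
        if cols
        else np.zeros((n, 0), dtype=np.int8)
    )
    summary = dict(
        n_mutations=len(positions),
        total_branch_length=tree.total_branch_length,
        tmrca=tree.tmrca,
    )
    h = HaplotypeMatrix(
        matrix=matrix,
        positions=np.array(sorted(positions), dtype=np.int64),
        sample_ids=[f"acc{i:03d}" for i in range(n)],
    )
    return h, summary


# ---------------------------------------------------------------------------
# Codon clades


def _random_sense_codons(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _apply_codon_mutation(
    codons: list[str],
    omega: float,
    rng: np.random.Generator,
    hit_codons: set[int] | None = None,
    max_proposals: int = 1000,
) -> None:
    """One accepted mutation: random single-base proposal, omega-filtered.

    Synonymous proposals always accepted; nonsynonymous with probability
    omega; stop-creating proposals always re-drawn.  When ``hit_codons`` is
    given (infinite-sites mode), codons already carrying a mutation anywhere
    in the genealogy are re-drawn too, so each codon hosts at most one
    substitution and pairwise NG86 pathway counting is exact.
    """
    for _ in range(max_proposals):
        k = int(rng.integers(0, len(codons)))
        if hit_codons is not None and k in hit_codons:
            continue
        pos = int(rng.integers(0, 3))
        old = codons[k]
        base = _BASES[int(rng.integers(0, 4))]
        if base == old[pos]:
            continue
        new = old[:pos] + base + old[pos + 1 :]
        if _CODON_TABLE[new] == "*":
            continue
        if _CODON_TABLE[new] != _CODON_TABLE[old] and rng.random() > omega:
            continue
        codons[k] = new
        if hit_codons is not None:
            hit_codons.add(k)
        return
    raise RuntimeError(
        "no acceptable mutation found (all codons hit, or omega too restrictive); "
        "increase n_codons"
    )


def simulate_codon_clade(
    n: int,
    theta: float,
    omega: float,
    n_codons: int,
    seed: int | np.random.Generator = 0,
    infinite_sites: bool = True,
) -> tuple[Alignment, Alignment]:
    """Codon + protein clade alignments evolved on a neutral genealogy.

    Mutations are placed on branches proportionally to length and applied in
    root-to-tip, within-branch time order, so derived states nest correctly.

    With ``infinite_sites`` (default) each codon hosts at most one
    substitution across the whole genealogy: every pairwise codon difference
    is then a single base, so omega = 0 yields piN = 0 exactly.  Disable it
    for deeply diverged clades (theta comparable to the sequence length),
    where recurrent hits are the point — there, NG86 pathway averaging over
    multi-hit codons can report small nonzero piN even for a synonymous-only
    history.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = simulate_genealogy(n, rng)
    branches = _draw_mutation_branches(tree, theta, rng)
    # mutations per branch with a uniform time order inside the branch
    muts_per_branch: dict[int, int] = {}
    for b in branches:
        muts_per_branch[int(b)] = muts_per_branch.get(int(b), 0) + 1
    root = tree.n_nodes - 1
    sequences: dict[int, list[str]] = {root: _random_sense_codons(n_codons, rng)}
    # children lists for traversal
    children: dict[int, list[int]] = {}
    for v in range(tree.n_nodes - 1):
        children.setdefault(int(tree.parent[v]), []).append(v)
    hit_codons: set[int] | None = set() if infinite_sites else None
    stack = [root]
    while stack:
        v = stack.pop()
        for c in children.get(v, ()):  # branch above c carries its mutations
            seq = list(sequences[v])
            for _ in range(muts_per_branch.get(c, 0)):
                _apply_codon_mutation(seq, omega, rng, hit_codons)
            sequences[c] = seq
            stack.append(c)
    ids = [f"acc{i:03d}" for i in range(n)]
    codon_records = [
        SequenceRecord(ids[i], "".join(sequences[i])) for i in range(n)
    ]
    protein_records = [
        SequenceRecord(ids[i], "".join(_CODON_TABLE[c] for c in sequences[i]))
        for i in range(n)
    ]
    return (
        Alignment(codon_records, alphabet="codon"),
        Alignment(protein_records, alphabet="protein"),
    )


# ---------------------------------------------------------------------------
# Full cohort


def assign_groups(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene ids and hv-like / non-hv-like group assignment."""
    n_hv = config.n_hv
    rows = [
        dict(
            gene_id=f"NLR{i + 1:04d}",
            group="hv-like" if i < n_hv else "non-hv-like",
        )
        for i in range(config.n_genes)
    ]
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_nlrome(
    config: SimConfig,
) -> tuple[dict[str, tuple[Alignment, Alignment]], str, pd.DataFrame]:
    """Per-gene (codon, protein) clade alignments plus a truth table.

    hv-like genes evolve with (theta_high, omega_high), non-hv-like with
    (theta_low, omega_low).  The first accession (``acc000``) is the focal
    (reference) allele for every gene.  Returns (alignments, focal_id, truth).
    """
    groups = assign_groups(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_genes)
    alignments: dict[str, tuple[Alignment, Alignment]] = {}
    truth_rows = []
    for (gene_id, row), child in zip(groups.iterrows(), children):
        hv = row["group"] == "hv-like"
        theta = config.theta_high if hv else config.theta_low
        omega = config.omega_high if hv else config.omega_low
        rng = np.random.default_rng(child)
        # deep clades: recurrent hits allowed so columns can reach >2 amino acids
        codon_aln, protein_aln = simulate_codon_clade(
            config.n_accessions, theta, omega, config.n_codons, seed=rng,
            infinite_sites=False,
        )
        alignments[gene_id] = (codon_aln, protein_aln)
        truth_rows.append(
            dict(gene_id=gene_id, group=row["group"], theta=theta, omega=omega)
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return alignments, "acc000", truth


def simulate_feature_tables(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, AnnotationSet, AnnotationSet, pd.DataFrame]:
    """Counts, methylation calls, gene + TE annotations, and per-gene truth.

    Returns (counts, methylation_calls, genes, tes, truth).  Gene spans are
    laid end to end on one toy chromosome with random inter-gene gaps; TE
    placement and the expression / methylation group effects follow the
    config.  Besides the receptor genes, ``n_background_genes`` genome
    stand-ins (group ``background``) receive baseline feature distributions,
    providing the genome-wide background for enrichment and tail tests.
    """
    groups = assign_groups(config)
    if config.n_background_genes:
        bg = pd.DataFrame(
            dict(group="background"),
            index=pd.Index(
                [f"BG{i + 1:04d}" for i in range(config.n_background_genes)],
                name="gene_id",
            ),
        )
        groups = pd.concat([groups, bg])
    ss = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(ss)
    chrom = "Chr1"
    gene_feats: list[Feature] = []
    te_feats: list[Feature] = []
    truth_rows = []
    meth_rows = []
    pos = 1
    lo, hi = config.gene_length_range
    glo, ghi = config.intergene_gap_range
    for i, (gene_id, row) in enumerate(groups.iterrows()):
        hv = row["group"] == "hv-like"
        length = int(rng.integers(lo, hi + 1))
        start = pos + int(rng.integers(glo, ghi + 1))
        end = start + length - 1
        pos = end
        gene_feats.append(Feature(chrom, start, end, "+", "gene", gene_id))
        # --- TE placement
        p_overlap = config.te_overlap_prob_hv if hv else config.te_overlap_prob_nonhv
        te_id = f"TE{i + 1:04d}"
        if rng.random() < p_overlap:
            te_start = int(rng.integers(start, end - 100))
            te_end = te_start + 99
            true_te_dist = 0.0
        else:
            d = 1 + int(rng.exponential(config.te_distance_mean))
            te_end = max(100, start - d - 1)
            te_start = max(1, te_end - 99)
            true_te_dist = float(start - te_end - 1)
        te_feats.append(Feature(chrom, te_start, te_end, "+", "transposable_element", te_id))
        # --- methylation calls (CG duplexes, both strands)
        level = config.methylation_base_pct + (config.methylation_delta_pct if hv else 0.0)
        level = min(100.0, max(0.0, level)) / 100.0
        n_cg = max(1, int(rng.poisson(config.cg_sites_mean)))
        site_pos = np.sort(
            rng.choice(np.arange(start, end, 2), size=min(n_cg, (end - start) // 2), replace=False)
        )
        for p in site_pos:
            for strand_offset, strand in ((0, "+"), (1, "-")):
                cov = int(rng.poisson(config.coverage_mean))
                meth = int(rng.binomial(cov, level)) if cov > 0 else 0
                meth_rows.append(
                    dict(
                        chrom=chrom, pos=int(p) + strand_offset, strand=strand,
                        context="CG", count_methylated=meth, count_total=cov,
                    )
                )
        # --- expression
        base = config.expression_base_log2 + (config.expression_log2fc if hv else 0.0)
        mu = 2.0 ** (base + rng.normal(0.0, 0.25)) * (length / 1000.0)
        truth_rows.append(
            dict(
                gene_id=gene_id, group=row["group"], gene_length=length,
                te_distance_true=true_te_dist, meth_level_true=level * 100.0,
                expression_mu=mu,
            )
        )
    genes = AnnotationSet(gene_feats)
    tes = AnnotationSet(te_feats)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    # --- counts: NB via gamma-Poisson
    disp = config.expression_dispersion
    n_rep = config.n_replicates
    mus = truth["expression_mu"].to_numpy()
    shape = 1.0 / disp
    lam = rng.gamma(shape, scale=(mus[:, None] * disp), size=(len(mus), n_rep))
    counts = rng.poisson(lam)
    count_df = pd.DataFrame(
        counts, index=truth.index, columns=[f"rep{i + 1}" for i in range(n_rep)]
    )
    counts_matrix = CountMatrix(
        counts=count_df, lengths=truth["gene_length"].astype(float)
    )
    meth = pd.DataFrame(meth_rows)
    return counts_matrix, meth, genes, tes, truth


def write_simulated_cohort(config: SimConfig, out_dir: str | Path) -> Path:
    """Emit the full synthetic cohort to disk (FASTA, GFF3, TSVs, truth)."""
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    alignments, focal, nlrome_truth = simulate_nlrome(config)
    for gene_id, (codon_aln, protein_aln) in alignments.items():
        write_fasta(codon_aln, out / "alignments" / f"{gene_id}.codon.fasta")
        write_fasta(protein_aln, out / "alignments" / f"{gene_id}.protein.fasta")
    counts, meth, genes, tes, feat_truth = simulate_feature_tables(config)
    counts_out = counts.counts.copy()
    counts_out.insert(0, "length", counts.lengths.astype(int))
    counts_out.to_csv(out / "counts.tsv", sep="\t")
    meth.to_csv(out / "methylation_calls.tsv", sep="\t", index=False)
    _write_gff3(genes, out / "genes.gff3")
    tes.to_frame().to_csv(out / "tes.tsv", sep="\t", index=False)
    truth = nlrome_truth.join(feat_truth.drop(columns=["group"]))
    truth.to_csv(out / "truth.tsv", sep="\t")
    (out / "focal.txt").write_text(focal + "\n")
    return out


def _write_gff3(annotations: AnnotationSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotations.features:
            kind = "gene" if f.kind == "gene" else "transposable_element"
            fh.write(
                f"{f.chrom}\tnlrkit\t{kind}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.id}\n"
            )
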