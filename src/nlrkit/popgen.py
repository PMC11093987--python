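"""Population-genetic summary statistics for haplotype samples.

Implements nucleotide diversity (pi), Watterson's theta, Tajima's D with the
standard 1989 normalizing constants, Nei-Gojobori (NG86) synonymous /
nonsynonymous diversity (piN, piS), alignment-column domain labelling by
majority vote, sliding-window tracks in focal-CDS coordinates, and
empirical-distribution tail flags used for selection scans.

Conventions (documented, not inferred from any one tool):

* Per-site normalization divides by the full alignment / CDS length ``L``,
  including monomorphic and gap-containing columns.  Gaps and ``N`` reduce
  which pairs are compared at a column, never ``L`` itself.
* A column is segregating when it shows >= 2 distinct A/C/G/T states among
  non-gap sequences; indels are not variants.
* Tajima's D is undefined (NaN) when S = 0 — never coerced to 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import GAP, Alignment, HaplotypeMatrix

logger = logging.getLogger(__name__)

_VALID_NUC = np.array(list("ACGT"), dtype="U1")

DOMAIN_CLASSES = ("CC", "TIR", "NBARC", "LRR")


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent constants of Tajima's variance formula."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class DiversityStats:
    """pi, S, Watterson's theta and Tajima's D for one haplotype sample."""

    n: int
    L: int
    S: int
    pi_total: float
    theta_w_total: float
    tajimas_d: float  # NaN when undefined (S == 0)
    constants: TajimaConstants

    @property
    def pi_per_site(self) -> float:
        return self.pi_total / self.L

    @property
    def theta_w_per_site(self) -> float:
        return self.theta_w_total / self.L

    @property
    def d_defined(self) -> bool:
        return not math.isnan(self.tajimas_d)


def _alignment_char_matrix(aln: Alignment) -> np.ndarray:
    return np.char.upper(aln.to_array())


def _pairwise_diff_total(chars: np.ndarray) -> float:
    """Mean-free total: sum over pairs of per-pair differences / C(n,2).

    Columns where either member of a pair carries a non-ACGT state are skipped
    for that pair only.
    """
    n = chars.shape[0]
    valid = np.isin(chars, _VALID_NUC)
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        total += int(np.sum((chars[i] != chars[j]) & both))
    return total / (n * (n - 1) / 2)


def _segregating_sites(chars: np.ndarray) -> int:
    valid = np.isin(chars, _VALID_NUC)
    S = 0
    for j in range(chars.shape[1]):
        alleles = set(chars[valid[:, j], j])
        if len(alleles) >= 2:
            S += 1
    return S


def _stats_from_counts(
    n: int, L: int, S: int, pi_total: float
) -> DiversityStats:
    const = tajima_constants(n)
    theta_total = S / const.a1
    if S == 0 or n < 3:
        d = float("nan")
    else:
        var = const.e1 * S + const.e2 * S * (S - 1)
        num = pi_total - theta_total
        if var <= 1e-15:
            # n=3 degenerate case: e1 = e2 = 0 exactly, so D is 0/0;
            # report 0 when the numerator also vanishes, else undefined
            d = 0.0 if abs(num) < 1e-9 else float("nan")
        else:
            d = num / math.sqrt(var)
    return DiversityStats(
        n=n, L=L, S=S, pi_total=pi_total, theta_w_total=theta_total,
        tajimas_d=d, constants=const,
    )


def diversity_stats(
    data: Alignment | HaplotypeMatrix, L: int | None = None
) -> DiversityStats:
    """Compute pi, S, theta_W and Tajima's D in one pass.

    ``L`` overrides the per-site denominator (e.g. the gene's CDS length when
    the input is a SNP-only haplotype matrix; monomorphic positions then count
    toward ``L``).
    """
    if isinstance(data, HaplotypeMatrix):
        n = data.n_haplotypes
        if n < 2:
            raise ValueError("need >= 2 haplotypes")
        length = L if L is not None else max(data.n_sites, 1)
        derived = data.matrix.sum(axis=0)
        seg = (derived > 0) & (derived < n)
        S = int(seg.sum())
        c = derived[seg].astype(float)
        pi_total = float(np.sum(c * (n - c)) / (n * (n - 1) / 2))
        return _stats_from_counts(n, length, S, pi_total)
    chars = _alignment_char_matrix(data)
    n = chars.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    length = L if L is not None else chars.shape[1]
    S = _segregating_sites(chars)
    pi_total = _pairwise_diff_total(chars)
    return _stats_from_counts(n, length, S, pi_total)


def nucleotide_diversity(
    data: Alignment | HaplotypeMatrix, L: int | None = None
) -> DiversityStats:
    """Average pairwise differences (total and per site)."""
    return diversity_stats(data, L=L)


def watterson_theta(
    data: Alignment | HaplotypeMatrix, L: int | None = None
) -> DiversityStats:
    """Segregating-site count S and theta_W = S / a1."""
    return diversity_stats(data, L=L)


def tajimas_d(
    data: Alignment | HaplotypeMatrix, L: int | None = None
) -> DiversityStats:
    """Tajima's D; requires n >= 3 (the variance formula needs it)."""
    stats = diversity_stats(data, L=L)
    if stats.n < 3:
        raise ValueError("Tajima's D requires n >= 3 haplotypes")
    return stats


def stats_from_vcf_gene(h: HaplotypeMatrix, cds_length: int) -> DiversityStats:
    """Gene-level stats from a SNP matrix, normalized by the full CDS length."""
    if cds_length < 1:
        raise ValueError("cds_length must be positive")
    return diversity_stats(h, L=cds_length)


# ---------------------------------------------------------------------------
# Nei-Gojobori piN / piS

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
_BASES = "ACGT"


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon.

    Per position, the synonymous fraction is (# synonymous single-base
    changes) / (# non-stop single-base changes); stop-creating changes are
    excluded from the denominator, so syn + nonsyn sums to 3 per codon.
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = _CODON_TABLE[alt]
            if alt_aa == "*":
                continue
            n_valid += 1
            if alt_aa == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over the shortest mutational pathways, excluding pathways that
    pass through a stop codon (all pathways used if every one is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                ok = False
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (paths if ok else blocked).append((syn, nonsyn))
    pool = paths if paths else blocked
    syn = sum(p[0] for p in pool) / len(pool)
    nonsyn = sum(p[1] for p in pool) / len(pool)
    return syn, nonsyn


@dataclass
class CodonDiversity:
    """NG86 synonymous / nonsynonymous nucleotide diversity of a codon alignment."""

    pi_n: float
    pi_s: float
    syn_sites: float  # mean over pairs of pairwise-averaged potential sites
    nonsyn_sites: float
    n_pairs: int
    n_skipped_codon_pairs: int  # gap-containing codon pairs

    @property
    def ratio(self) -> float:
        """piN / piS; NaN when piS is 0."""
        if self.pi_s == 0:
            return float("nan")
        return self.pi_n / self.pi_s


_ALL_CODONS = ["".join(p) for p in itertools.product(_BASES, repeat=3)]
_NG_TABLES: dict[str, np.ndarray] = {}


def _ng_tables() -> dict[str, np.ndarray]:
    """64-codon lookup tables for NG86 (built once, lazily)."""
    if _NG_TABLES:
        return _NG_TABLES
    syn_sites = np.zeros(64)
    nonsyn_sites = np.zeros(64)
    is_stop = np.zeros(64, dtype=bool)
    for i, c in enumerate(_ALL_CODONS):
        if _CODON_TABLE[c] == "*":
            is_stop[i] = True
            continue
        syn_sites[i], nonsyn_sites[i] = _codon_site_fractions(c)
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(_ALL_CODONS):
        for j, c2 in enumerate(_ALL_CODONS):
            if is_stop[i] or is_stop[j]:
                continue
            sd[i, j], nd[i, j] = _codon_pair_differences(c1, c2)
    _NG_TABLES.update(
        syn_sites=syn_sites, nonsyn_sites=nonsyn_sites, is_stop=is_stop, sd=sd, nd=nd
    )
    return _NG_TABLES


_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _codon_indices(seq: str) -> np.ndarray:
    """Codon index 0..63 per codon; -1 where any base is gap/ambiguous."""
    idx = np.array([_BASE_INDEX.get(ch, -100) for ch in seq], dtype=np.int64)
    tri = idx.reshape(-1, 3)
    out = 16 * tri[:, 0] + 4 * tri[:, 1] + tri[:, 2]
    out[(tri < 0).any(axis=1)] = -1
    return out


def pin_pis(codon_aln: Alignment) -> CodonDiversity:
    """Nei-Gojobori (NG86, unweighted) piN and piS over all sequence pairs.

    No multiple-hit correction is applied; internal stop codons are an error;
    codon pairs where either member contains a gap or ambiguous base are
    skipped and counted.
    """
    if codon_aln.length % 3 != 0:
        raise ValueError("not a codon alignment (length % 3 != 0)")
    tables = _ng_tables()
    seqs = [r.seq.upper() for r in codon_aln.records]
    n = len(seqs)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    n_codons = codon_aln.length // 3
    indices = [_codon_indices(s) for s in seqs]
    stop_mask = []
    for sid, ci in zip(codon_aln.ids(), indices):
        stops = (ci >= 0) & tables["is_stop"][np.clip(ci, 0, 63)]
        if stops[:-1].any():
            k = int(np.flatnonzero(stops)[0])
            raise ValueError(f"{sid}: internal stop codon at codon {k + 1}")
        stop_mask.append(stops)
    tot_sd = tot_nd = tot_ss = tot_ns = 0.0
    n_pairs = 0
    n_skipped = 0
    for i, j in itertools.combinations(range(n), 2):
        ci, cj = indices[i], indices[j]
        gap = (ci < 0) | (cj < 0)
        n_skipped += int(gap.sum())
        ok = ~gap & ~stop_mask[i] & ~stop_mask[j]
        a, b = ci[ok], cj[ok]
        tot_ss += float((tables["syn_sites"][a] + tables["syn_sites"][b]).sum() / 2)
        tot_ns += float((tables["nonsyn_sites"][a] + tables["nonsyn_sites"][b]).sum() / 2)
        tot_sd += float(tables["sd"][a, b].sum())
        tot_nd += float(tables["nd"][a, b].sum())
        n_pairs += 1
    mean_ss = tot_ss / n_pairs
    mean_ns = tot_ns / n_pairs
    pi_s = (tot_sd / n_pairs) / mean_ss if mean_ss > 0 else 0.0
    pi_n = (tot_nd / n_pairs) / mean_ns if mean_ns > 0 else 0.0
    return CodonDiversity(
        pi_n=pi_n, pi_s=pi_s, syn_sites=mean_ss, nonsyn_sites=mean_ns,
        n_pairs=n_pairs, n_skipped_codon_pairs=n_skipped,
    )


# ---------------------------------------------------------------------------
# Domain labelling


@dataclass
class DomainMap:
    """Per-column domain labels of an alignment, by majority vote."""

    column_labels: list[str]  # one of DOMAIN_CLASSES or 'none' per column

    def columns_of(self, label: str) -> list[int]:
        return [j for j, lab in enumerate(self.column_labels) if lab == label]


def domain_columns(
    aln: Alignment,
    intervals: Mapping[str, Sequence[tuple[int, int, str]]],
) -> DomainMap:
    """Label each alignment column by the plurality domain class.

    ``intervals`` maps sequence id -> list of (start, end, class) on that
    sequence's ungapped 1-based coordinates.  Votes are cast by non-gap
    sequences; ties (including zero votes) give 'none'.
    """
    for sid, ivs in intervals.items():
        seq = aln[sid]
        ungapped_len = len(seq.ungapped)
        for start, end, cls in ivs:
            if cls not in DOMAIN_CLASSES:
                raise ValueError(f"unknown domain class {cls!r}")
            if start < 1 or end > ungapped_len:
                raise ValueError(
                    f"{sid}: interval [{start}, {end}] beyond ungapped length "
                    f"{ungapped_len}"
                )
    # per sequence: ungapped position at each column (0 where gapped)
    labels: list[str] = []
    per_seq_pos = {}
    for rec in aln.records:
        pos = np.cumsum([c != GAP for c in rec.seq])
        per_seq_pos[rec.id] = pos
    for j in range(aln.length):
        votes: dict[str, int] = {}
        for rec in aln.records:
            if rec.seq[j] == GAP:
                continue
            p = int(per_seq_pos[rec.id][j])
            label = "none"
            for start, end, cls in intervals.get(rec.id, ()):
                if start <= p <= end:
                    label = cls
                    break
            votes[label] = votes.get(label, 0) + 1
        real = {k: v for k, v in votes.items() if k != "none"}
        if not real:
            labels.append("none")
            continue
        best = max(real.values())
        winners = [k for k, v in real.items() if v == best]
        none_votes = votes.get("none", 0)
        if len(winners) > 1 or none_votes > best:
            labels.append("none")
        elif none_votes == best:
            labels.append("none")
        else:
            labels.append(winners[0])
    return DomainMap(column_labels=labels)


def domain_stats(
    aln: Alignment, domain_map: DomainMap
) -> pd.DataFrame:
    """DiversityStats per domain class (columns subset by majority label)."""
    chars = _alignment_char_matrix(aln)
    rows = []
    for cls in (*DOMAIN_CLASSES, "none"):
        cols = domain_map.columns_of(cls)
        if not cols:
            continue
        sub = chars[:, cols]
        n = sub.shape[0]
        S = _segregating_sites(sub)
        pi_total = _pairwise_diff_total(sub)
        st = _stats_from_counts(n, len(cols), S, pi_total)
        rows.append(
            dict(domain=cls, n=n, L=st.L, S=st.S, pi=st.pi_per_site,
                 theta_w=st.theta_w_per_site, tajimas_d=st.tajimas_d)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sliding windows


@dataclass
class WindowTrack:
    """Sliding-window statistic values in focal-CDS coordinates."""

    gene_id: str
    stat: str
    window_size: int
    step: int
    table: pd.DataFrame  # columns: start, end, midpoint, value

    def __len__(self) -> int:
        return len(self.table)


def sliding_window_stats(
    aln: Alignment,
    focal_id: str,
    stat: Literal["pi", "tajimas_d"] = "pi",
    window: int = 300,
    step: int = 75,
    gene_id: str | None = None,
) -> WindowTrack:
    """Windowed pi or D over focal-sequence CDS coordinates.

    Windows are [s, s+window-1] for s = 1, 1+step, ... while the window fits
    inside the focal ungapped CDS; incomplete tail windows are dropped.  Each
    window's statistic is computed on the alignment columns that map to the
    focal positions of the window, normalized by the window size.
    """
    focal = aln[focal_id]
    chars = _alignment_char_matrix(aln)
    focal_cols = [j for j, c in enumerate(focal.seq) if c != GAP]
    L = len(focal_cols)
    rows = []
    if L < window:
        logger.warning("%s: CDS length %d shorter than window %d", focal_id, L, window)
    else:
        for s in range(1, L - window + 2, step):
            cols = focal_cols[s - 1 : s - 1 + window]
            sub = chars[:, cols]
            st = _stats_from_counts(
                sub.shape[0], window, _segregating_sites(sub), _pairwise_diff_total(sub)
            )
            value = st.pi_per_site if stat == "pi" else st.tajimas_d
            rows.append(dict(start=s, end=s + window - 1, midpoint=s + window // 2 - 1,
                             value=value))
    table = pd.DataFrame(rows, columns=["start", "end", "midpoint", "value"])
    return WindowTrack(
        gene_id=gene_id or focal_id, stat=stat, window_size=window, step=step,
        table=table,
    )


def expected_window_count(L: int, window: int = 300, step: int = 75) -> int:
    """floor((L - window)/step) + 1 full windows (0 when L < window)."""
    if L < window:
        return 0
    return (L - window) // step + 1


# ---------------------------------------------------------------------------
# Empirical tails


@dataclass
class TailFlags:
    """Per-gene membership in the empirical top/bottom 5% of a background."""

    tail: str
    threshold: float
    flags: pd.Series  # boolean per gene


def empirical_tail_flags(
    gene_values: pd.Series,
    background: Sequence[float] | np.ndarray | pd.Series,
    tail: Literal["top5", "bottom5"] = "top5",
    q: float = 0.05,
) -> TailFlags:
    """Flag genes strictly beyond the empirical 95th (or 5th) percentile.

    The threshold is the linear-interpolation quantile of the genome-wide
    background; membership is strict inequality.
    """
    bg = np.asarray(background, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("empty background")
    if bg.size < 100:
        logger.warning("background has only %d values; tail estimate is noisy", bg.size)
    if tail == "top5":
        thr = float(np.quantile(bg, 1 - q))
        flags = gene_values > thr
    elif tail == "bottom5":
        thr = float(np.quantile(bg, q))
        flags = gene_values < thr
    else:
        raise ValueError(f"unknown tail {tail!r}")
    flags = flags & gene_values.notna()
    return TailFlags(tail=tail, threshold=thr, flags=flags)


def balancing_selection_flags(
    pi_values: pd.Series,
    d_values: pd.Series,
    pi_background: Sequence[float],
    d_background: Sequence[float],
    q: float = 0.05,
) -> pd.Series:
    """Joint criterion: gene in the top 5% of both the pi and D backgrounds."""
    top_pi = empirical_tail_flags(pi_values, pi_background, "top5", q=q).flags
    top_d = empirical_tail_flags(d_values, d_background, "top5", q=q).flags
    joint = top_pi & top_d.reindex(top_pi.index, fill_value=False)
    joint.name = "balancing_selection"
    return joint
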