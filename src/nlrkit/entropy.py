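"""Per-position Shannon entropy of clade alignments and hv/non-hv classification.

A clade alignment holds one allele per accession of a single receptor gene.
Entropy is computed column by column in the coordinate system of a designated
focal sequence (the reference accession's allele): columns where the focal
sequence carries a gap are skipped, so profile position ``k`` is the k-th
residue of the ungapped focal protein.  A gene is called highly variable (hv)
when at least ``min_positions`` profile positions exceed ``threshold`` bits.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GAP, Alignment

logger = logging.getLogger(__name__)

#: default hv rule: >= 10 positions with entropy > 1.5 bits
HV_ENTROPY_THRESHOLD = 1.5
HV_MIN_POSITIONS = 10

_AMBIGUOUS = {"X", "?", "*"}  # amino-acid alphabet: N is asparagine, not ambiguous


@dataclass
class EntropyProfile:
    """Per-position entropy (bits) in focal-sequence residue coordinates."""

    gene_id: str
    focal_id: str
    positions: np.ndarray  # 1-based residue indices of the focal sequence
    entropy: np.ndarray  # bits
    n_effective: np.ndarray  # non-gap, non-ambiguous residues per column
    low_support: np.ndarray  # columns with n_effective < 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.entropy = np.asarray(self.entropy, dtype=float)
        self.n_effective = np.asarray(self.n_effective, dtype=np.int64)
        self.low_support = np.asarray(self.low_support, dtype=bool)
        if (self.entropy < 0).any():
            raise ValueError("negative entropy")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def mean_entropy(self) -> float:
        return float(np.mean(self.entropy))


@dataclass(frozen=True)
class HvCall:
    """Classification of one gene as hv / non-hv under the entropy rule."""

    gene_id: str
    n_high: int
    threshold: float
    min_positions: int
    label: str  # 'hv' | 'non-hv'
    mean_entropy: float


def column_entropy(residue_counts: Mapping[str, int | float]) -> float:
    """Plug-in Shannon entropy (bits) of one alignment column.

    ``residue_counts`` maps residues to counts; gaps and ambiguous residues
    must already be excluded.  0*log(0) is treated as 0.
    """
    counts = np.array([c for c in residue_counts.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("all-gap column: entropy undefined")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_profile(
    aln: Alignment, focal_id: str, gene_id: str | None = None
) -> EntropyProfile:
    """Entropy of each alignment column where the focal sequence is non-gap.

    Gaps and ambiguous residues ('X') are excluded from the column counts;
    columns with fewer than two usable residues get entropy 0 and are flagged
    ``low_support``.
    """
    focal = aln[focal_id]  # raises KeyError if absent
    if set(focal.seq) == {GAP}:
        raise ValueError(f"focal sequence {focal_id!r} is all gaps")
    positions: list[int] = []
    entropies: list[float] = []
    n_eff: list[int] = []
    low: list[bool] = []
    pos = 0
    n_ambiguous = 0
    for j, focal_char in enumerate(focal.seq):
        if focal_char == GAP:
            continue
        pos += 1
        column = aln.column(j)
        counts = Counter(c for c in column.upper() if c != GAP)
        for amb in _AMBIGUOUS:
            n_ambiguous += counts.pop(amb, 0)
        total = sum(counts.values())
        positions.append(pos)
        n_eff.append(total)
        if total < 2:
            entropies.append(0.0)
            low.append(True)
        else:
            entropies.append(column_entropy(counts))
            low.append(False)
    if n_ambiguous:
        logger.debug(
            "%s: excluded %d ambiguous residues from entropy counts",
            focal_id,
            n_ambiguous,
        )
    return EntropyProfile(
        gene_id=gene_id if gene_id is not None else focal_id,
        focal_id=focal_id,
        positions=np.array(positions),
        entropy=np.array(entropies),
        n_effective=np.array(n_eff),
        low_support=np.array(low),
    )


def classify_hv(
    profile: EntropyProfile,
    threshold: float = HV_ENTROPY_THRESHOLD,
    min_positions: int = HV_MIN_POSITIONS,
) -> HvCall:
    """Label a gene hv when >= ``min_positions`` positions exceed ``threshold``.

    The entropy comparison is strict (> threshold), the position count
    inclusive (>= min_positions).
    """
    n_high = int(np.sum(profile.entropy > threshold))
    label = "hv" if n_high >= min_positions else "non-hv"
    return HvCall(
        gene_id=profile.gene_id,
        n_high=n_high,
        threshold=threshold,
        min_positions=min_positions,
        label=label,
        mean_entropy=profile.mean_entropy,
    )


def mean_entropy_per_gene(profiles: Iterable[EntropyProfile]) -> pd.Series:
    """Unweighted mean entropy per gene (one row per gene, bits)."""
    means: dict[str, float] = {}
    for p in profiles:
        if p.gene_id in means:
            raise ValueError(f"duplicate gene id {p.gene_id!r}")
        means[p.gene_id] = p.mean_entropy
    if not means:
        raise ValueError("no profiles given")
    return pd.Series(means, name="mean_entropy")


def hv_table(
    profiles: Iterable[EntropyProfile],
    threshold: float = HV_ENTROPY_THRESHOLD,
    min_positions: int = HV_MIN_POSITIONS,
) -> pd.DataFrame:
    """Tabulate hv calls for a collection of profiles."""
    rows = [
        classify_hv(p, threshold=threshold, min_positions=min_positions).__dict__
        for p in profiles
    ]
    return pd.DataFrame(rows).set_index("gene_id")
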