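"""Readers, writers, and containers for the external formats the pipeline touches.

Coordinates are 1-based inclusive throughout (GFF convention). Sequence data
lives in lightweight :class:`SequenceRecord` / :class:`Alignment` containers;
tabular data lives in pandas objects with documented column schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

Alphabet = Literal["protein", "nucleotide", "codon"]

_NUC_CHARS = set("ACGTUN-")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (protein or nucleotide), possibly gapped."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered set of equal-length gapped sequences.

    ``alphabet`` is one of ``protein``, ``nucleotide``, ``codon``; codon
    alignments must have a length divisible by 3.
    """

    records: list[SequenceRecord]
    alphabet: Alphabet = "protein"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise ValueError(f"duplicate sequence ids: {sorted(dups)}")
        if self.alphabet == "codon" and self.length % 3 != 0:
            raise ValueError(
                f"codon alignment length {self.length} is not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        """Residues of 0-based column ``j``, in record order."""
        return "".join(r.seq[j] for r in self.records)

    def to_array(self) -> np.ndarray:
        """(n, length) array of single characters."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")


class Feature(NamedTuple):
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+', '-', '.'
    kind: str  # 'gene' | 'transposable_element' | 'domain'
    id: str


@dataclass
class AnnotationSet:
    """Genomic intervals (genes, TEs, domains) with 1-based inclusive coords."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], bool] = {}
        for f in self.features:
            if f.start < 1 or f.end < f.start:
                raise ValueError(f"bad coordinates for {f.id}: [{f.start}, {f.end}]")
            key = (f.kind, f.id)
            if key in seen:
                raise ValueError(f"duplicate {f.kind} id {f.id!r}")
            seen[key] = True

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.features, columns=Feature._fields)

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class HaplotypeMatrix:
    """Haplotypes x biallelic sites over {0,1}, with 1-based site positions."""

    matrix: np.ndarray  # (n_haplotypes, n_sites) of 0/1
    positions: np.ndarray  # (n_sites,) 1-based bp
    sample_ids: list[str]
    n_dropped_missing: int = 0
    n_dropped_multiallelic: int = 0
    n_het_genotypes: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions do not match matrix columns")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("haplotype matrix must be biallelic 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CountMatrix:
    """Gene x sample read counts plus per-gene lengths in bp."""

    counts: pd.DataFrame  # index: gene ids, columns: sample labels
    lengths: pd.Series  # index: gene ids, bp

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise ValueError(f"missing gene lengths for {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


METHYLATION_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "count_methylated",
    "count_total",
]


def validate_methylation_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cytosine methylation call table (Bismark-report-like)."""
    missing = [c for c in METHYLATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"methylation table missing columns {missing}")
    bad = table["count_methylated"] > table["count_total"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"row {i}: count_methylated > count_total "
            f"({table['count_methylated'].iat[i]} > {table['count_total'].iat[i]})"
        )
    if (table["count_methylated"] < 0).any():
        raise ValueError("negative methylated counts")
    return table


# ---------------------------------------------------------------------------
# FASTA


def _detect_alphabet(seqs: Iterable[str]) -> Alphabet:
    chars = set("".join(seqs).upper())
    return "nucleotide" if chars <= _NUC_CHARS else "protein"


def read_fasta_records(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file as unaligned records (ragged lengths allowed)."""
    records = [
        SequenceRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    ids = [r.id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"duplicate ids in {path}: {dups}")
    return records


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> Alignment:
    """Read a FASTA file as an alignment; alphabet auto-detected unless given."""
    records = read_fasta_records(path)
    if alphabet is None:
        alphabet = _detect_alphabet(r.seq for r in records)
    return Alignment(records, alphabet=alphabet)


def write_fasta(records: Sequence[SequenceRecord] | Alignment, path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    if isinstance(records, Alignment):
        records = records.records
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")  # Bio wraps at 60 columns


# ---------------------------------------------------------------------------
# Annotations

_TE_TABLE_COLUMNS = {
    "Transposon_Name",
    "orientation_is_5prime",
    "Transposon_min_Start",
    "Transposon_max_End",
}


def read_annotations(
    path: str | Path, dialect: Literal["gff3", "tair_te_table"], kind: str | None = None
) -> AnnotationSet:
    """Read gene/TE intervals from GFF3 or a TAIR-style TE table.

    GFF3 rows keep their 1-based inclusive coordinates.  TE-table rows with
    start > end are swapped (strand set to '-') with a logged warning.
    """
    if dialect == "gff3":
        return _read_gff3(path, kind or "gene")
    if dialect == "tair_te_table":
        return _read_tair_te_table(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path: str | Path, default_kind: str) -> AnnotationSet:
    feats: list[Feature] = []
    kind_map = {
        "gene": "gene",
        "transposable_element": "transposable_element",
        "transposable_element_gene": "transposable_element",
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in kind_map:
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            fid = _gff_attr(attrs, "ID") or _gff_attr(attrs, "Name") or f"feat{lineno}"
            strand = strand if strand in "+-" else "."
            feats.append(Feature(chrom, s, e, strand, kind_map[ftype], fid))
    if not feats:
        logger.warning("no gene/TE features parsed from %s", path)
    return AnnotationSet(feats)


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def _read_tair_te_table(path: str | Path) -> AnnotationSet:
    table = pd.read_csv(path, sep="\t")
    if not _TE_TABLE_COLUMNS <= set(table.columns):
        raise ValueError(
            f"TE table missing columns {_TE_TABLE_COLUMNS - set(table.columns)}"
        )
    feats: list[Feature] = []
    for lineno, row in enumerate(table.itertuples(index=False), start=2):
        name = str(row.Transposon_Name)
        try:
            s = int(row.Transposon_min_Start)
            e = int(row.Transposon_max_End)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: bad TE coordinates") from exc
        strand = "+" if str(row.orientation_is_5prime).lower() in {"true", "+", "1"} else "-"
        if s > e:
            logger.warning("%s:%d: start > end for %s, swapping", path, lineno, name)
            s, e = e, s
            strand = "-"
        # TAIR TE names encode the chromosome (AT1TE52125 -> Chr1)
        chrom = f"Chr{name[2]}" if name.startswith("AT") and len(name) > 2 else "?"
        feats.append(Feature(chrom, s, e, strand, "transposable_element", name))
    return AnnotationSet(feats)


# ---------------------------------------------------------------------------
# Methylation calls and count matrices


def read_methylation_calls(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine TSV (chrom, pos, strand, context, meth, total).

    No coverage filter is applied here; filtering happens downstream.
    """
    table = pd.read_csv(path, sep="\t", na_values=["."])
    table = validate_methylation_calls(table)
    logger.info("read %d methylation calls from %s", len(table), path)
    return table


def read_counts(
    path: str | Path, lengths_path: str | Path | None = None
) -> CountMatrix:
    """Read a gene x sample count TSV with a ``length`` column (or side file)."""
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    if "length" in table.columns:
        lengths = table.pop("length")
    elif lengths_path is not None:
        side = pd.read_csv(lengths_path, sep="\t", index_col=0, na_values=["."])
        lengths = side.iloc[:, 0]
    else:
        raise ValueError("no 'length' column in counts file and no lengths file given")
    return CountMatrix(counts=table, lengths=lengths.astype(float))


# ---------------------------------------------------------------------------
# VCF


def read_vcf_region(
    path: str | Path,
    chrom: str,
    start: int,
    end: int,
    samples: Sequence[str] | None = None,
) -> HaplotypeMatrix:
    """Extract a biallelic-SNP haplotype matrix from a VCF region.

    Diploid genotypes expand to two haplotypes per sample.  Sites that are
    multiallelic, non-SNP, or carry any missing call in the sample subset are
    dropped and counted.  Heterozygous genotypes are retained (both haplotypes
    emitted) and counted in ``n_het_genotypes``.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        if chrom not in vf.header.contigs and chrom not in {
            rec.chrom for rec in _iter_contigs(path)
        }:
            raise ValueError(f"chromosome {chrom!r} absent from {path}")
        sample_list = list(samples) if samples is not None else list(vf.header.samples)
        missing_samples = set(sample_list) - set(vf.header.samples)
        if missing_samples:
            raise ValueError(f"samples absent from VCF: {sorted(missing_samples)}")
        cols: list[np.ndarray] = []
        positions: list[int] = []
        n_missing = n_multi = n_het = 0
        for rec in vf:
            if rec.chrom != chrom or rec.pos < start or rec.pos > end:
                continue
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_multi += 1
                continue
            column: list[int] = []
            ok = True
            for s in sample_list:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    ok = False
                    break
                if len(set(gt)) > 1:
                    n_het += 1
                column.extend(int(a) for a in gt)
            if not ok:
                n_missing += 1
                continue
            cols.append(np.array(column, dtype=np.int8))
            positions.append(rec.pos)
    n_hap = len(cols[0]) if cols else 0
    matrix = (
        np.stack(cols, axis=1) if cols else np.zeros((n_hap, 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        matrix=matrix,
        positions=np.array(positions, dtype=np.int64),
        sample_ids=sample_list,
        n_dropped_missing=n_missing,
        n_dropped_multiallelic=n_multi,
        n_het_genotypes=n_het,
    )


def _iter_contigs(path: str | Path):
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        yield from vf


# ---------------------------------------------------------------------------
# Protein -> codon projection (PAL2NAL-like)

STOP_CODONS = {"TAA", "TAG", "TGA"}


def project_protein_alignment_to_codons(
    protein_aln: Alignment, cds: Sequence[SequenceRecord]
) -> Alignment:
    """Thread each CDS through its gapped protein to build a codon alignment.

    Each amino-acid column becomes one codon column; a protein gap becomes
    ``---``.  Every CDS must translate (standard code) to exactly its ungapped
    protein; a single terminal stop codon is trimmed.
    """
    cds_by_id = {r.id: r for r in cds}
    out: list[SequenceRecord] = []
    for prot in protein_aln.records:
        try:
            cds_rec = cds_by_id[prot.id]
        except KeyError:
            raise ValueError(f"no CDS provided for {prot.id!r}") from None
        cds_seq = cds_rec.seq.upper().replace("U", "T")
        if len(cds_seq) % 3 != 0:
            raise ValueError(f"CDS length of {prot.id!r} is not a multiple of 3")
        codons = [cds_seq[i : i + 3] for i in range(0, len(cds_seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        ungapped = prot.ungapped
        if len(codons) != len(ungapped):
            raise ValueError(
                f"{prot.id!r}: CDS has {len(codons)} codons but protein has "
                f"{len(ungapped)} residues"
            )
        for i, (codon, aa) in enumerate(zip(codons, ungapped), start=1):
            translated = _translate_codon(codon)
            if translated is None:
                raise ValueError(f"{prot.id!r} residue {i}: untranslatable codon {codon}")
            if translated == "*":
                raise ValueError(f"{prot.id!r} residue {i}: internal stop codon {codon}")
            if translated != aa.upper():
                raise ValueError(
                    f"{prot.id!r} residue {i}: codon {codon} translates to "
                    f"{translated}, protein has {aa}"
                )
        it = iter(codons)
        projected = "".join("---" if c == GAP else next(it) for c in prot.seq)
        out.append(SequenceRecord(prot.id, projected))
    return Alignment(out, alphabet="codon")


def _translate_codon(codon: str) -> str | None:
    if set(codon) - set("ACGT"):
        return None
    return str(Seq(codon).translate())
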