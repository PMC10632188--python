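"""Reading and writing of standard genomic formats, TSS extraction, window
tiling and sequence encoding.

Coordinate conventions: 0-based half-open internally; GFF3 is read as 1-based
inclusive and BED as 0-based half-open, converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

IUPAC_LETTERS = frozenset("ACGTNRYSWKMBDHVU")
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: fixed one-hot column order
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

# byte-level lookup used by encode(): A,C,G,T -> 0..3, anything else -> 255
_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENC_TABLE[ord(_b)] = _i

#: loop-seq probe length and adapter length
PROBE_LEN = 50
ADAPTER_LEN = 25


class SequenceAlphabetError(ValueError):
    """A sequence contains a letter outside the accepted alphabet."""


class GffFormatError(ValueError):
    """A GFF3 line could not be parsed."""


@dataclass(frozen=True)
class GenomeStore:
    """Named chromosome sequences, uppercase, IUPAC alphabet only."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.records.items():
            if not cid:
                raise ValueError("empty chromosome id")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {cid!r}")
            bad = set(seq) - IUPAC_LETTERS
            if bad:
                raise SequenceAlphabetError(
                    f"chromosome {cid!r} contains non-IUPAC letter(s): "
                    f"{sorted(bad)!r}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def length(self, chrom: str) -> int:
        return len(self.records[chrom])

    @property
    def chromosomes(self) -> list[str]:
        return list(self.records)


@dataclass(frozen=True)
class TSSRecord:
    """One transcription start site: the first transcribed base of a gene."""

    gene_id: str
    chrom: str
    pos: int  # 0-based genomic index of the first transcribed base
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")


@dataclass(frozen=True)
class SequenceWindow:
    """A 50-bp (by default) genomic window with its oriented sequence."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("window span does not match sequence length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class LoopSeqRecord:
    """One loop-seq library entry: probe (possibly adapter-wrapped) + score."""

    seq: str  # length 50 (bare probe) or 100 (25-base adapters at both ends)
    c0: float

    def __post_init__(self) -> None:
        if len(self.seq) not in (PROBE_LEN, PROBE_LEN + 2 * ADAPTER_LEN):
            raise ValueError(
                f"loop-seq sequence length must be {PROBE_LEN} or "
                f"{PROBE_LEN + 2 * ADAPTER_LEN}, got {len(self.seq)}"
            )
        if not np.isfinite(self.c0):
            raise ValueError("c0 must be finite")


@dataclass(frozen=True)
class AnchoredRegion:
    """An anchor-centered, transcription-oriented slice of the genome.

    ``seq[i]`` sits at offset ``i - flank`` relative to the anchor, with
    offsets increasing 5'→3' of the anchored gene.  ``genomic_pos[i]`` is the
    0-based genomic coordinate of that base on the reference strand.
    """

    anchor: TSSRecord
    flank: int
    seq: str
    genomic_pos: np.ndarray = field(repr=False)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def window_at(self, offset: int, before: int = 24, after: int = 25) -> str:
        """Sequence of the window whose (before+1)-th base sits at ``offset``."""
        i = offset + self.flank
        lo, hi = i - before, i + after + 1
        if lo < 0 or hi > len(self.seq):
            raise IndexError(f"window at offset {offset} does not fit in region")
        return self.seq[lo:hi]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeStore:
    """Read a (multi-record) FASTA file into a :class:`GenomeStore`.

    Sequences are uppercased; duplicate ids, empty records and non-IUPAC
    letters are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise SequenceAlphabetError(
                f"record {rec.id!r}: non-IUPAC letter(s) {sorted(bad)!r}"
            )
        records[rec.id] = seq
    return GenomeStore(records)


def write_fasta(genome: GenomeStore | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        items = genome.records.items() if isinstance(genome, GenomeStore) \
            else genome.items()
        for cid, seq in items:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / TSS extraction
# ---------------------------------------------------------------------------

def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _iter_gff_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError as exc:
                raise GffFormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 1 or end < start:
                raise GffFormatError(
                    f"{path}:{lineno}: invalid coordinates {start}..{end}"
                )
            if fields[6] not in ("+", "-", ".", "?"):
                raise GffFormatError(
                    f"{path}:{lineno}: invalid strand {fields[6]!r}"
                )
            yield lineno, fields[0], fields[2], start, end, fields[6], \
                _parse_gff_attributes(fields[8])


def read_tss_from_gff(path: str | Path, genome: GenomeStore) -> list[TSSRecord]:
    """Extract one TSS per gene from a GFF3 file.

    The TSS is the first base of the 5'UTR of one chosen isoform per gene
    (the isoform whose ID ends in ".1" if present, else the lexicographically
    first).  Genes without a five_prime_UTR feature are skipped.  TSSs falling
    outside their chromosome are skipped with a warning.
    """
    parent_of: dict[str, str] = {}  # feature ID -> Parent ID
    # per (chrom): collected UTR parts keyed by their Parent (isoform) id
    utr_parts: dict[str, list[tuple[str, int, int, str]]] = {}
    for lineno, chrom, ftype, start, end, strand, attrs in _iter_gff_lines(path):
        fid = attrs.get("ID")
        parent = attrs.get("Parent")
        if fid and parent:
            parent_of[fid] = parent.split(",")[0]
        if ftype == "five_prime_UTR":
            if strand not in ("+", "-"):
                raise GffFormatError(
                    f"{path}:{lineno}: five_prime_UTR without strand"
                )
            owner = parent.split(",")[0] if parent else (fid or f"line{lineno}")
            utr_parts.setdefault(owner, []).append((chrom, start, end, strand))

    def gene_of(feature_id: str) -> str:
        seen = {feature_id}
        fid = feature_id
        while fid in parent_of:
            fid = parent_of[fid]
            if fid in seen:  # defensive: cyclic Parent chain
                break
            seen.add(fid)
        return fid

    by_gene: dict[str, dict[str, list[tuple[str, int, int, str]]]] = {}
    for isoform, parts in utr_parts.items():
        by_gene.setdefault(gene_of(isoform), {})[isoform] = parts

    out: list[TSSRecord] = []
    for gene in sorted(by_gene):
        isoforms = by_gene[gene]
        preferred = [i for i in isoforms if i.endswith(".1")]
        chosen = min(preferred) if preferred else min(isoforms)
        parts = isoforms[chosen]
        chrom = parts[0][0]
        strand = parts[0][3]
        if strand == "+":
            pos = min(p[1] for p in parts) - 1  # 1-based start -> 0-based
        else:
            pos = max(p[2] for p in parts) - 1  # 1-based inclusive end
        if chrom not in genome or not (0 <= pos < genome.length(chrom)):
            warnings.warn(
                f"TSS of gene {gene!r} at {chrom}:{pos} outside chromosome "
                "bounds; skipped"
            )
            continue
        out.append(TSSRecord(gene_id=gene, chrom=chrom, pos=pos, strand=strand))
    return out


# ---------------------------------------------------------------------------
# windows / regions
# ---------------------------------------------------------------------------

def tile_genome(genome: GenomeStore, window: int = 50,
                step: int = 50) -> list[SequenceWindow]:
    """Tile every chromosome into plus-strand windows.

    Windows containing any letter outside {A,C,G,T} are dropped; windows that
    would run past the chromosome end are never emitted.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    out: list[SequenceWindow] = []
    for chrom in genome:
        seq = genome[chrom]
        for start in range(0, len(seq) - window + 1, step):
            sub = seq[start:start + window]
            if set(sub) <= UNAMBIGUOUS:
                out.append(SequenceWindow(chrom, start, start + window, "+", sub))
    return out


def extract_anchored_region(genome: GenomeStore, anchor: TSSRecord,
                            flank: int) -> AnchoredRegion | None:
    """Extract the ±flank region around an anchor, oriented 5'→3' of the gene.

    Minus-strand regions are reverse-complemented.  Returns ``None`` (with a
    warning) for anchors too close to a chromosome edge.
    """
    if flank < 25:
        raise ValueError("flank must be >= 25")
    L = genome.length(anchor.chrom)
    lo, hi = anchor.pos - flank, anchor.pos + flank + 1
    if lo < 0 or hi > L:
        warnings.warn(
            f"anchor {anchor.gene_id!r} at {anchor.chrom}:{anchor.pos} too "
            "close to chromosome edge; skipped"
        )
        return None
    raw = genome[anchor.chrom][lo:hi]
    pos = np.arange(lo, hi)
    if anchor.strand == "-":
        raw = revcomp(raw, allow_iupac=True)
        pos = pos[::-1].copy()
    return AnchoredRegion(anchor=anchor, flank=flank, seq=raw, genomic_pos=pos)


def strip_adapters(rec: LoopSeqRecord | str) -> str:
    """Return the 50-base probe, removing 25-base terminal adapters if present."""
    seq = rec.seq if isinstance(rec, LoopSeqRecord) else rec
    if len(seq) == PROBE_LEN:
        return seq
    if len(seq) == PROBE_LEN + 2 * ADAPTER_LEN:
        return seq[ADAPTER_LEN:ADAPTER_LEN + PROBE_LEN]
    raise ValueError(
        f"loop-seq sequence length must be {PROBE_LEN} or "
        f"{PROBE_LEN + 2 * ADAPTER_LEN}, got {len(seq)}"
    )


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

_RC_IUPAC = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str, allow_iupac: bool = False) -> str:
    """Reverse complement of ``seq``.

    By default only A/C/G/T are accepted; ``allow_iupac=True`` extends the
    complement table to ambiguity codes (needed for raw genome slices).
    """
    if allow_iupac:
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise SequenceAlphabetError(f"non-IUPAC letter(s) {sorted(bad)!r}")
        return seq.translate(_RC_IUPAC)[::-1]
    bad = set(seq) - UNAMBIGUOUS
    if bad:
        raise SequenceAlphabetError(
            f"ambiguous letter(s) {sorted(bad)!r} in sequence"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Integer-encode a sequence (A,C,G,T → 0..3). Errors on other letters."""
    codes = _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(codes == 255)[0]})
        raise SequenceAlphabetError(f"ambiguous letter(s) {bad!r} in sequence")
    return codes.astype(np.int64)


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a sequence as an L×4 matrix, column order A,C,G,T."""
    codes = encode(seq)
    out = np.zeros((len(seq), 4), dtype=np.float64)
    out[np.arange(len(seq)), codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def read_loopseq_tsv(path: str | Path) -> list[LoopSeqRecord]:
    """Read a loop-seq table (TSV with header columns ``sequence``, ``c0``)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sequence", "c0"} - set(df.columns)
    if missing:
        raise ValueError(f"loop-seq TSV missing column(s) {sorted(missing)}")
    return [LoopSeqRecord(seq=str(s).upper(), c0=float(c))
            for s, c in zip(df["sequence"], df["c0"])]


def write_loopseq_tsv(records: Iterable[LoopSeqRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"sequence": [r.seq for r in records], "c0": [r.c0 for r in records]}
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[tuple]:
    """Read a BED file (3+ columns, 0-based half-open).

    Returns tuples ``(chrom, start, end, *rest)`` with extra columns kept as
    strings.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            out.append((chrom, start, end, *fields[3:]))
    return out


def write_bedgraph(path: str | Path, chrom: str, positions: np.ndarray,
                   values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for p, v in zip(positions, values):
            fh.write(f"{chrom}\t{int(p)}\t{int(p) + 1}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a bedGraph into per-chromosome (positions, values) arrays.

    Multi-base intervals are expanded to single positions.
    """
    pos: dict[str, list[int]] = {}
    val: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            for p in range(int(start), int(end)):
                pos.setdefault(chrom, []).append(p)
                val.setdefault(chrom, []).append(float(value))
    return {c: (np.asarray(pos[c]), np.asarray(val[c])) for c in pos}
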