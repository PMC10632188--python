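"""Window-set comparisons for variants, methylation contexts, TF-bound vs
unbound motif sites, and per-position track correlation.

Window registration: "the window containing a position" is the 50-bp window
whose 25th base is that position, consistent with the track convention in
:mod:`cycflex.profiles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cycflex.predictor import CyclizabilityPredictor, rc_averaged_predict_batch
from cycflex.profiles import (
    WIN_AFTER,
    WIN_BEFORE,
    WIN_LEN,
    PositionalProfile,
    anchored_mean_profile,
)
from cycflex.sequence_io import (
    UNAMBIGUOUS,
    GenomeStore,
    SequenceWindow,
    TSSRecord,
    revcomp,
)
from cycflex.stats import EffectSizeReport, cohens_d

VARIANT_TYPES = ("SNP", "INS", "DEL")
CONTEXT_CLASSES = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class VariantRecord:
    """A sequence variant anchored at a 0-based reference position."""

    chrom: str
    pos: int
    vtype: str  # SNP, INS or DEL
    ref_span: int = 1

    def __post_init__(self) -> None:
        if self.vtype not in VARIANT_TYPES:
            raise ValueError(f"vtype must be one of {VARIANT_TYPES}")
        if self.ref_span < 1:
            raise ValueError("ref_span must be >= 1")
        if self.vtype == "SNP" and self.ref_span != 1:
            raise ValueError("SNP must have ref_span 1")

    @property
    def end(self) -> int:
        return self.pos + self.ref_span


@dataclass(frozen=True)
class MethylationSiteRecord:
    """A cytosine with its 3-base context on the C's strand."""

    chrom: str
    pos: int  # 0-based position of the C on the reference
    strand: str
    context3: str  # 3 bases on the C's strand, starting with C
    context_class: str  # CG, CHG or CHH
    methylated: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.context3.startswith("C"):
            raise ValueError("context3 must start with C")
        if classify_context(self.context3) != self.context_class:
            raise ValueError(
                f"context_class {self.context_class!r} inconsistent with "
                f"context3 {self.context3!r}"
            )


def classify_context(context3: str) -> str:
    """Classify a 3-mer starting with C into CG / CHG / CHH.

    CG if the second base is G; CHG if the third base is G (second in
    {A,C,T}); CHH otherwise.  Total and unambiguous for every valid 3-mer.
    """
    if len(context3) != 3 or not context3.startswith("C"):
        raise ValueError("context must be a 3-mer starting with C")
    if context3[1] == "G":
        return "CG"
    if context3[2] == "G":
        return "CHG"
    return "CHH"


def read_variants_vcf(path) -> list[VariantRecord]:
    """Read variants from a (plain-text) VCF, typing them by REF/ALT lengths.

    Equal-length single-base REF/ALT → SNP; longer REF → DEL spanning the
    reference allele; longer ALT → INS anchored at the reference base.  One
    record is emitted per ALT allele.
    """
    out: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: VCF needs >= 5 columns")
            chrom, pos_s, _id, ref, alts = fields[:5]
            pos = int(pos_s) - 1  # VCF is 1-based
            for alt in alts.split(","):
                if alt in (".", "*"):
                    continue
                if len(ref) == 1 and len(alt) == 1:
                    out.append(VariantRecord(chrom, pos, "SNP"))
                elif len(ref) > len(alt):
                    out.append(VariantRecord(chrom, pos, "DEL",
                                             ref_span=len(ref)))
                else:
                    out.append(VariantRecord(chrom, pos, "INS"))
    return out


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def classify_variant_windows(windows: Sequence[SequenceWindow],
                             variants: Sequence[VariantRecord]) -> list[str]:
    """Label each window by the variant types overlapping it.

    A variant hits a window if ``[pos, pos+ref_span)`` overlaps
    ``[start, end)``.  Labels: none / snp_only / indel_only / snp_and_indel.
    """
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for lst in by_chrom.values():
        lst.sort(key=lambda v: v.pos)

    labels = []
    for w in windows:
        has_snp = has_indel = False
        for v in by_chrom.get(w.chrom, []):
            if v.pos >= w.end:
                break
            if v.end <= w.start:
                continue
            if v.vtype == "SNP":
                has_snp = True
            else:
                has_indel = True
        if has_snp and has_indel:
            labels.append("snp_and_indel")
        elif has_snp:
            labels.append("snp_only")
        elif has_indel:
            labels.append("indel_only")
        else:
            labels.append("none")
    return labels


def compare_feature_windows(genome: GenomeStore,
                            windows_a: Sequence[SequenceWindow],
                            windows_b: Sequence[SequenceWindow],
                            p: CyclizabilityPredictor) -> EffectSizeReport:
    """Cohen's d of rc-averaged predictions, set A vs set B.

    d > 0 means set A is, on average, more flexible.
    """
    if len(windows_a) < 2 or len(windows_b) < 2:
        raise ValueError("both window sets need at least 2 windows")
    preds_a = rc_averaged_predict_batch(p, [w.seq for w in windows_a])
    preds_b = rc_averaged_predict_batch(p, [w.seq for w in windows_b])
    return cohens_d(preds_a, preds_b)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def find_cytosine_contexts(genome: GenomeStore,
                           chrom: str) -> list[MethylationSiteRecord]:
    """All cytosines on both strands with a full 3-base context, classified.

    A minus-strand cytosine appears as a G on the reference; its context is
    read on the minus strand.  Cytosines within 2 bp of their strand's 3'
    edge, and contexts containing ambiguity codes, are skipped.
    """
    seq = genome[chrom]
    if len(seq) < 3:
        raise ValueError("chromosome shorter than 3 bp")
    out: list[MethylationSiteRecord] = []
    for i, ch in enumerate(seq):
        if ch == "C" and i + 2 < len(seq):
            ctx = seq[i:i + 3]
            if set(ctx) <= UNAMBIGUOUS:
                out.append(MethylationSiteRecord(
                    chrom=chrom, pos=i, strand="+", context3=ctx,
                    context_class=classify_context(ctx)))
        if ch == "G" and i - 2 >= 0:
            ctx_raw = seq[i - 2:i + 1]
            if set(ctx_raw) <= UNAMBIGUOUS:
                ctx = revcomp(ctx_raw)
                out.append(MethylationSiteRecord(
                    chrom=chrom, pos=i, strand="-", context3=ctx,
                    context_class=classify_context(ctx)))
    return out


def _site_window(genome: GenomeStore, chrom: str, pos: int) -> str | None:
    """50-bp reference window whose 25th base is ``pos``; None if unusable."""
    lo = pos - WIN_BEFORE
    hi = pos + WIN_AFTER + 1
    seq = genome[chrom]
    if lo < 0 or hi > len(seq):
        return None
    win = seq[lo:hi]
    return win if set(win) <= UNAMBIGUOUS else None


def _in_intervals(chrom: str, pos: int, intervals: Sequence[tuple]) -> bool:
    return any(iv[0] == chrom and iv[1] <= pos < iv[2] for iv in intervals)


def methylation_comparison(genome: GenomeStore,
                           sites: Sequence[MethylationSiteRecord],
                           promoters: Sequence[tuple],
                           p: CyclizabilityPredictor,
                           per_context3: bool = False
                           ) -> dict[str, EffectSizeReport]:
    """Methylated vs unmethylated same-context windows inside promoters.

    ``promoters`` are BED-style ``(chrom, start, end)`` tuples.  Returns one
    :class:`~cycflex.stats.EffectSizeReport` per context class (and per
    specific triplet when ``per_context3``); contexts with fewer than 2 sites
    in either group are skipped with a warning.
    """
    if not promoters:
        raise ValueError("promoter set is empty")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in promoters:
        by_chrom.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    for lst in by_chrom.values():
        lst.sort()

    def in_promoter(chrom: str, pos: int) -> bool:
        for s, e in by_chrom.get(chrom, []):
            if s > pos:
                return False
            if pos < e:
                return True
        return False

    groups: dict[str, dict[bool, list[float]]] = {}
    site_preds: dict[tuple[str, int], float] = {}
    batch_keys, batch_wins = [], []
    kept = []
    for s in sites:
        if s.methylated is None:
            raise ValueError("sites must carry methylated flags")
        if not in_promoter(s.chrom, s.pos):
            continue
        key = (s.chrom, s.pos)
        if key not in site_preds:
            win = _site_window(genome, s.chrom, s.pos)
            if win is None:
                continue
            site_preds[key] = np.nan
            batch_keys.append(key)
            batch_wins.append(win)
        kept.append(s)
    preds = rc_averaged_predict_batch(p, batch_wins)
    for key, val in zip(batch_keys, preds):
        site_preds[key] = float(val)

    for s in kept:
        val = site_preds[(s.chrom, s.pos)]
        if np.isnan(val):
            continue
        keys = [s.context_class]
        if per_context3:
            keys.append(s.context3)
        for k in keys:
            groups.setdefault(k, {True: [], False: []})[s.methylated].append(val)

    out: dict[str, EffectSizeReport] = {}
    for ctx, g in groups.items():
        if len(g[True]) < 2 or len(g[False]) < 2:
            warnings.warn(
                f"context {ctx!r}: fewer than 2 sites in one group; skipped")
            continue
        out[ctx] = cohens_d(g[True], g[False])
    return out


# ---------------------------------------------------------------------------
# TF binding
# ---------------------------------------------------------------------------

def tf_bound_vs_unbound(genome: GenomeStore, motif_sites: Sequence[tuple],
                        p: CyclizabilityPredictor, flank: int = 200,
                        min_sites: int = 100
                        ) -> tuple[PositionalProfile, PositionalProfile]:
    """Site-centered profiles for the bound subset and for all motif sites.

    ``motif_sites`` are tuples ``(chrom, start, end, bound)`` (0-based
    half-open, ``bound`` truthy for DAP-seq-supported instances).  Anchors are
    motif midpoints (rounded down for even lengths).  Sets smaller than
    ``min_sites`` raise a warning but are still profiled.
    """
    def anchors_of(sites):
        out = []
        for k, (chrom, start, end, *rest) in enumerate(sites):
            mid = (int(start) + int(end) - 1) // 2
            out.append(TSSRecord(gene_id=f"site{k}", chrom=chrom, pos=mid,
                                 strand="+"))
        return out

    bound = [s for s in motif_sites if _truthy(s[3])]
    if not bound:
        raise ValueError("no bound sites")
    for name, group in (("bound", bound), ("all", motif_sites)):
        if len(group) < min_sites:
            warnings.warn(
                f"{name} site set has {len(group)} < {min_sites} instances")
    prof_bound = anchored_mean_profile(genome, anchors_of(bound), p, flank)
    prof_all = anchored_mean_profile(genome, anchors_of(list(motif_sites)),
                                     p, flank)
    return prof_bound, prof_all


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.lower() in ("1", "true", "bound", "yes")
    return bool(v)


# ---------------------------------------------------------------------------
# per-position track correlation
# ---------------------------------------------------------------------------

def positionwise_correlation(track: dict[str, tuple[np.ndarray, np.ndarray]],
                             genome: GenomeStore, p: CyclizabilityPredictor,
                             exclude: Sequence[tuple] = ()) -> float:
    """Pearson r between non-zero track values and window predictions.

    For each non-zero track position outside the excluded intervals, the
    50-bp window whose 25th base sits at that position is predicted
    (rc-averaged); returns the correlation between track values and
    predictions.
    """
    vals, wins = [], []
    for chrom, (positions, values) in track.items():
        if chrom not in genome:
            continue
        for pos, v in zip(positions, values):
            if v == 0:
                continue
            if exclude and _in_intervals(chrom, int(pos), exclude):
                continue
            win = _site_window(genome, chrom, int(pos))
            if win is None:
                continue
            vals.append(float(v))
            wins.append(win)
    if len(vals) < 2:
        raise ValueError("fewer than 2 usable positions")
    preds = rc_averaged_predict_batch(p, wins)
    from cycflex.stats import pearson_r
    return pearson_r(np.asarray(vals), preds)
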