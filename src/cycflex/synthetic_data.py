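"""Synthetic inputs with known ground truth.

Generates genomes with planted TSS-proximal positional dinucleotide structure
(including a TATA-like subset), loop-seq-style libraries whose scores follow a
linear dinucleotide model plus Gaussian noise, and variant / methylation
annotations with planted (calibrated Cohen's d) or null associations to
window rigidity.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cycflex.predictor import LinearDinucModel, rc_averaged_predict_batch
from cycflex.randomization import PositionalBaseModel, sample_vertical
from cycflex.sequence_io import (
    BASE_ORDER,
    GenomeStore,
    LoopSeqRecord,
    SequenceWindow,
    TSSRecord,
    revcomp,
    tile_genome,
)
from cycflex.feature_compare import (
    MethylationSiteRecord,
    VariantRecord,
    find_cytosine_contexts,
)
from cycflex.stats import cohens_d

#: TATAWAWR consensus (W = A/T, R = A/G), planted at offsets -35..-28
TATA_OFFSET = -35
_TATA_CHOICES = ("TT", "AA", "TT", "AA", "AT", "AA", "AT", "AG")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chrom_lengths: tuple
    background_trans: np.ndarray  # 4x4, rows sum to 1
    n_genes: int
    promoter_model: PositionalBaseModel  # over offsets -flank..+flank
    tata_fraction: float = 0.0
    min_gene_spacing: int = 100
    utr_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        bt = np.asarray(self.background_trans, dtype=np.float64)
        object.__setattr__(self, "background_trans", bt)
        if bt.shape != (4, 4) or not np.allclose(bt.sum(axis=1), 1.0):
            raise ValueError("background_trans must be 4x4 with rows summing to 1")
        if not 0 <= self.tata_fraction <= 1:
            raise ValueError("tata_fraction must be in [0, 1]")
        if self.promoter_model.L % 2 != 1:
            raise ValueError("promoter model length must be odd (2*flank + 1)")

    @property
    def flank(self) -> int:
        return (self.promoter_model.L - 1) // 2


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    n: int
    truth: LinearDinucModel
    noise_sd: float = 0.0
    adapter5: str = "C" * 25
    adapter3: str = "G" * 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.adapter5) != 25 or len(self.adapter3) != 25:
            raise ValueError("adapters must be 25 bases")


@dataclass(frozen=True)
class PlantedAssociationSpec:
    target_d: float
    n_case: int
    n_control: int
    seed: int = 0
    tolerance: float = 0.02
    max_rounds: int = 60
    vtypes: tuple = ("SNP",)

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must be >= 2")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _sample_markov_chain(length: int, trans: np.ndarray,
                         rng: np.random.Generator) -> str:
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    codes = np.empty(length, dtype=np.int64)
    codes[0] = rng.integers(4)
    for i in range(1, length):
        row = cum[codes[i - 1]]
        ui = u[i]
        codes[i] = 0 if ui < row[0] else 1 if ui < row[1] else \
            2 if ui < row[2] else 3
    return "".join(BASE_ORDER[c] for c in codes)


def _tata_insert(rng: np.random.Generator) -> str:
    return "".join(pair[rng.integers(2)] for pair in _TATA_CHOICES)


@dataclass(frozen=True)
class SimulatedGenome:
    genome: GenomeStore
    gff_text: str
    tss: tuple  # TSSRecord per planted gene
    manifest: dict  # gene_id -> {chrom, pos, strand, tata}

    def write(self, fasta_path: str | Path, gff_path: str | Path) -> None:
        from cycflex.sequence_io import write_fasta
        write_fasta(self.genome, fasta_path)
        Path(gff_path).write_text(self.gff_text)


def simulate_genome(spec: SyntheticGenomeSpec) -> SimulatedGenome:
    """Background Markov genome with promoter-model sequences planted at TSSs.

    Promoter sequences are written in transcription orientation (roughly half
    of the genes on the minus strand); the emitted GFF3 contains
    gene/mRNA/five_prime_UTR features such that
    :func:`cycflex.sequence_io.read_tss_from_gff` recovers the planted TSSs
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    flank = spec.flank
    region_len = 2 * flank + 1

    chroms = {f"chr{i + 1}": _sample_markov_chain(L, spec.background_trans, rng)
              for i, L in enumerate(spec.chrom_lengths)}

    # deterministic slots: TSS positions spaced so regions never overlap
    slots: list[tuple[str, int]] = []
    pitch = region_len + spec.min_gene_spacing
    for cid, seq in chroms.items():
        pos = flank
        while pos + flank < len(seq):
            slots.append((cid, pos))
            pos += pitch
    if spec.n_genes > len(slots):
        raise ValueError(
            f"cannot fit {spec.n_genes} genes: only {len(slots)} slots "
            "available at the requested spacing"
        )
    chosen = [slots[i] for i in sorted(
        rng.choice(len(slots), size=spec.n_genes, replace=False))]

    mutable = {cid: list(s) for cid, s in chroms.items()}
    tss_records: list[TSSRecord] = []
    manifest: dict[str, dict] = {}
    gff_lines = ["##gff-version 3"]
    n_tata = int(round(spec.tata_fraction * spec.n_genes))
    tata_genes = set(rng.choice(spec.n_genes, size=n_tata, replace=False)
                     .tolist()) if n_tata else set()

    for g, (cid, pos) in enumerate(chosen):
        gene_id = f"gene{g + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = sample_vertical(spec.promoter_model, "dinuc", rng)
        has_tata = g in tata_genes
        if has_tata:
            ins = _tata_insert(rng)
            i0 = flank + TATA_OFFSET
            oriented = oriented[:i0] + ins + oriented[i0 + len(ins):]
        placed = oriented if strand == "+" else revcomp(oriented)
        lo = pos - flank
        mutable[cid][lo:lo + region_len] = list(placed)

        L = len(chroms[cid])
        utr = min(spec.utr_length, flank)
        if strand == "+":
            utr_start, utr_end = pos + 1, pos + utr  # 1-based inclusive
        else:
            utr_start, utr_end = pos + 2 - utr, pos + 1
        gene_start, gene_end = max(1, utr_start), min(L, utr_end)
        gff_lines.append("\t".join(
            [cid, "cycflex_sim", "gene", str(gene_start), str(gene_end), ".",
             strand, ".", f"ID={gene_id}"]))
        gff_lines.append("\t".join(
            [cid, "cycflex_sim", "mRNA", str(gene_start), str(gene_end), ".",
             strand, ".", f"ID={gene_id}.1;Parent={gene_id}"]))
        gff_lines.append("\t".join(
            [cid, "cycflex_sim", "five_prime_UTR", str(utr_start),
             str(utr_end), ".", strand, ".",
             f"ID={gene_id}.1.utr;Parent={gene_id}.1"]))
        tss_records.append(TSSRecord(gene_id=gene_id, chrom=cid, pos=pos,
                                     strand=strand))
        manifest[gene_id] = {"chrom": cid, "pos": pos, "strand": strand,
                             "tata": bool(has_tata)}

    genome = GenomeStore({cid: "".join(s) for cid, s in mutable.items()})
    return SimulatedGenome(genome=genome, gff_text="\n".join(gff_lines) + "\n",
                           tss=tuple(tss_records), manifest=manifest)


def uniform_background_trans() -> np.ndarray:
    return np.full((4, 4), 0.25)


def default_promoter_model(flank: int, ta_boost: float = 0.2,
                           center: int = -35, width: float = 12.0
                           ) -> PositionalBaseModel:
    """Positional model with a TA/AT-enriched band upstream of the anchor.

    Background transitions are uniform; within a Gaussian band around
    ``center`` the A→T and T→A transitions are boosted, taking mass from
    A→A and T→T respectively.  The perturbation is doubly stochastic, so
    base marginals stay exactly uniform: the planted structure lives purely
    in dinucleotide arrangement, invisible to single-base composition.
    ``ta_boost`` must be ≤ 0.25.
    """
    if not 0 <= ta_boost <= 0.25:
        raise ValueError("ta_boost must be in [0, 0.25]")
    L = 2 * flank + 1
    p0 = np.full((L, 4), 0.25)
    trans = np.tile(np.full((4, 4), 0.25), (L - 1, 1, 1))
    A, T = BASE_ORDER.index("A"), BASE_ORDER.index("T")
    offs = np.arange(-flank, flank)  # offset of the first base of each step
    bump = ta_boost * np.exp(-0.5 * ((offs - center) / width) ** 2)
    for i, delta in enumerate(bump):
        if delta <= 1e-6:
            continue
        trans[i, A, T] += delta
        trans[i, A, A] -= delta
        trans[i, T, A] += delta
        trans[i, T, T] -= delta
    return PositionalBaseModel(L=L, p0=p0, trans=trans)


def expected_anchored_profile(model: PositionalBaseModel,
                              truth: LinearDinucModel,
                              flank: int) -> np.ndarray:
    """Closed-form expected profile of a linear score under a positional model.

    Sequences are drawn by the dinucleotide chain (first base from p0[0],
    later bases from the conditionals), so the marginal at position i is the
    propagated chain marginal.  The expected window score at offset ``o`` is
    b + Σ_steps Σ_{a,b} P(base_i = a) · trans[i][a,b] · w[ab] over the 49
    steps of the window spanning offsets o−24 … o+25.  Returned on the same
    offset grid as :func:`cycflex.profiles.anchored_mean_profile`.
    """
    from cycflex.profiles import WIN_AFTER, WIN_BEFORE, _profile_offsets

    L = model.L
    mu = np.empty((L, 4))
    mu[0] = model.p0[0]
    for i in range(1, L):
        t = np.nan_to_num(model.trans[i - 1], nan=0.25)
        mu[i] = mu[i - 1] @ t
    w = truth.w.reshape(4, 4)
    step_exp = np.empty(L - 1)
    for i in range(L - 1):
        t = np.nan_to_num(model.trans[i], nan=0.25)
        step_exp[i] = float((mu[i][:, None] * t * w).sum())
    cum = np.concatenate([[0.0], np.cumsum(step_exp)])
    offsets = _profile_offsets(flank)
    out = np.empty(len(offsets))
    for j, o in enumerate(offsets):
        i0 = int(o) + flank - WIN_BEFORE  # first base index of the window
        out[j] = truth.b + cum[i0 + WIN_BEFORE + WIN_AFTER] - cum[i0]
    return out


# ---------------------------------------------------------------------------
# loop-seq library simulation
# ---------------------------------------------------------------------------

def simulate_loopseq_library(spec: SyntheticLibrarySpec) -> list[LoopSeqRecord]:
    """I.i.d.-uniform 50-bp probes scored by the truth model plus noise,
    wrapped in fixed 25-base adapters."""
    rng = np.random.default_rng(spec.seed)
    codes = rng.integers(0, 4, size=(spec.n, 50))
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd \
        else np.zeros(spec.n)
    scores = spec.truth.score_encoded_batch(codes) + noise
    bases = np.array(list(BASE_ORDER))
    out = []
    for i in range(spec.n):
        probe = "".join(bases[codes[i]])
        out.append(LoopSeqRecord(seq=spec.adapter5 + probe + spec.adapter3,
                                 c0=float(scores[i])))
    return out


# ---------------------------------------------------------------------------
# planted associations
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    def __init__(self, target: float, achieved: float):
        super().__init__(
            f"calibration failed: target d={target}, achieved d={achieved:.4f}")
        self.target = target
        self.achieved = achieved


def _calibrated_case_pick(scores: np.ndarray, n_case: int, n_control: int,
                          target_d: float, rng: np.random.Generator,
                          tolerance: float, max_rounds: int
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """Pick case/control index sets so that d(control, case) ≈ target_d.

    Case membership probability decreases in the standardized score
    (weight ∝ exp(−a·z)); the slope ``a`` is bisected until the realized
    Cohen's d between control and case scores is within tolerance.
    Positive target ⇒ cases sit in rigid (low-score) windows.
    """
    n = len(scores)
    if n_case + n_control > n:
        raise ValueError("not enough windows for requested case/control sizes")
    z = (scores - scores.mean()) / scores.std()
    pick_seed = int(rng.integers(2 ** 32))

    def realize(a: float):
        sub = np.random.default_rng(pick_seed)
        logw = -a * z
        logw -= logw.max()
        wts = np.exp(logw)
        case = sub.choice(n, size=n_case, replace=False, p=wts / wts.sum())
        rest = np.setdiff1d(np.arange(n), case)
        control = sub.choice(rest, size=n_control, replace=False)
        d = cohens_d(scores[control], scores[case]).d
        return case, control, d

    # d(a) is monotone increasing in a for a fixed picking stream: bracket
    # the target, then bisect
    rounds = 0
    a_lo, res_lo = 0.0, realize(0.0)
    if abs(res_lo[2] - target_d) <= tolerance:
        return res_lo
    best = res_lo
    sign = 1.0 if target_d > res_lo[2] else -1.0
    a_hi = sign * 0.25
    res_hi = realize(a_hi)
    rounds += 1
    while (res_hi[2] - target_d) * sign < 0 and rounds < max_rounds:
        a_lo, res_lo = a_hi, res_hi
        a_hi *= 2.0
        res_hi = realize(a_hi)
        rounds += 1
    for res in (res_lo, res_hi):
        if abs(res[2] - target_d) < abs(best[2] - target_d):
            best = res
    while rounds < max_rounds:
        mid = (a_lo + a_hi) / 2.0
        res = realize(mid)
        if abs(res[2] - target_d) <= tolerance:
            return res
        if (res[2] - target_d) * sign < 0:
            a_lo = mid
        else:
            a_hi = mid
        if abs(res[2] - target_d) < abs(best[2] - target_d):
            best = res
        rounds += 1
    if abs(best[2] - target_d) <= tolerance:
        return best
    raise CalibrationError(target_d, best[2])


@dataclass(frozen=True)
class VariantSimResult:
    variants: tuple  # VariantRecord
    case_windows: tuple  # SequenceWindow
    control_windows: tuple
    expected_d: float  # realized d(control, case) on truth scores


def simulate_variant_set(genome: GenomeStore, truth: LinearDinucModel,
                         spec: PlantedAssociationSpec) -> VariantSimResult:
    """Variants planted so mutation-bearing windows are rigid at the target d.

    The genome is tiled into 50-bp windows; case windows are drawn with
    probability decreasing in the standardized truth score, calibrated so
    that d(control windows, case windows) hits ``spec.target_d`` within
    ``spec.tolerance``.  One variant is emitted inside every case window.
    """
    rng = np.random.default_rng(spec.seed)
    windows = tile_genome(genome)
    if len(windows) < spec.n_case + spec.n_control:
        raise ValueError("genome too small for requested case/control sizes")
    scores = rc_averaged_predict_batch(truth, [w.seq for w in windows])
    case_idx, control_idx, realized = _calibrated_case_pick(
        scores, spec.n_case, spec.n_control, spec.target_d, rng,
        spec.tolerance, spec.max_rounds)

    variants: list[VariantRecord] = []
    for i in case_idx:
        w = windows[i]
        vtype = spec.vtypes[rng.integers(len(spec.vtypes))]
        if vtype == "SNP":
            pos = w.start + int(rng.integers(0, 50))
            span = 1
        elif vtype == "INS":
            pos = w.start + int(rng.integers(0, 50))
            span = 1
        else:  # DEL
            span = int(rng.integers(1, 4))
            pos = w.start + int(rng.integers(0, 50 - span + 1))
        variants.append(VariantRecord(chrom=w.chrom, pos=pos, vtype=vtype,
                                      ref_span=span))
    return VariantSimResult(
        variants=tuple(variants),
        case_windows=tuple(windows[i] for i in case_idx),
        control_windows=tuple(windows[i] for i in control_idx),
        expected_d=realized)


def simulate_methylation_set(genome: GenomeStore, promoters: Sequence[tuple],
                             association: str = "null",
                             target_d: float = 0.0,
                             truth: LinearDinucModel | None = None,
                             seed: int = 0,
                             methylated_fraction: float = 0.5,
                             tolerance: float = 0.02,
                             max_rounds: int = 60
                             ) -> list[MethylationSiteRecord]:
    """Context-classified cytosines in promoters with methylation flags.

    ``association='null'``: flags drawn independently of sequence.
    ``association='planted'``: per context class, flags assigned via the
    calibrated mechanism so methylated sites sit in windows offset from
    unmethylated ones by ``target_d`` (requires ``truth``).
    """
    if not promoters:
        raise ValueError("promoter set is empty")
    if association not in ("null", "planted"):
        raise ValueError(f"unknown association {association!r}")
    rng = np.random.default_rng(seed)

    prom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in promoters:
        prom_by_chrom.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    sites: list[MethylationSiteRecord] = []
    for chrom in genome:
        if chrom not in prom_by_chrom:
            continue
        for s in find_cytosine_contexts(genome, chrom):
            if any(a <= s.pos < b for a, b in prom_by_chrom[chrom]):
                sites.append(s)
    if not sites:
        raise ValueError("no cytosine-context sites inside promoters")

    if association == "null":
        flags = rng.random(len(sites)) < methylated_fraction
        return [MethylationSiteRecord(
            chrom=s.chrom, pos=s.pos, strand=s.strand, context3=s.context3,
            context_class=s.context_class, methylated=bool(f))
            for s, f in zip(sites, flags)]

    if truth is None:
        raise ValueError("planted association requires a truth model")
    from cycflex.feature_compare import _site_window
    out: list[MethylationSiteRecord] = []
    for ctx in ("CG", "CHG", "CHH"):
        grp = [s for s in sites if s.context_class == ctx]
        wins = [(s, _site_window(genome, s.chrom, s.pos)) for s in grp]
        wins = [(s, w) for s, w in wins if w is not None]
        if len(wins) < 8:
            continue
        scores = rc_averaged_predict_batch(truth, [w for _, w in wins])
        n_me = max(2, int(round(methylated_fraction * len(wins))))
        n_un = len(wins) - n_me
        if n_un < 2:
            continue
        case_idx, _, _ = _calibrated_case_pick(
            scores, n_me, n_un, -target_d, rng, tolerance, max_rounds)
        me = set(case_idx.tolist())
        for k, (s, _w) in enumerate(wins):
            out.append(MethylationSiteRecord(
                chrom=s.chrom, pos=s.pos, strand=s.strand,
                context3=s.context3, context_class=s.context_class,
                methylated=k in me))
    if not out:
        raise ValueError("no context had enough sites for planting")
    return out


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def write_variants_bed(variants: Sequence[VariantRecord],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.end}\t{v.vtype}\n")


def read_variants_bed(path: str | Path) -> list[VariantRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, vtype = line.split("\t")[:4]
            out.append(VariantRecord(chrom=chrom, pos=int(start), vtype=vtype,
                                     ref_span=int(end) - int(start)))
    return out


def write_methylation_tsv(sites: Sequence[MethylationSiteRecord],
                          path: str | Path) -> None:
    pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "strand": [s.strand for s in sites],
        "context": [s.context3 for s in sites],
        "methylated": [int(bool(s.methylated)) for s in sites],
    }).to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path) -> list[MethylationSiteRecord]:
    df = pd.read_csv(path, sep="\t")
    from cycflex.feature_compare import classify_context
    return [MethylationSiteRecord(
        chrom=str(r.chrom), pos=int(r.pos), strand=str(r.strand),
        context3=str(r.context), context_class=classify_context(str(r.context)),
        methylated=bool(int(r.methylated)))
        for r in df.itertuples()]
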