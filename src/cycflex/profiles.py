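"""Anchor-centered metaprofiles of cyclizability and composition,
randomized-profile comparisons, per-position tracks and autocorrelation.

The window registration convention throughout: the profile value at offset
``o`` averages predictions of the 50-bp window whose 25th base (1-based within
the window) sits at offset ``o``, i.e. the window spans offsets o−24 … o+25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cycflex.predictor import (
    CyclizabilityPredictor,
    rc_averaged_predict_batch,
)
from cycflex.randomization import (
    count_matches,
    fit_positional_model,
    matched_distance_shuffle,
    sample_vertical,
    shuffle_dinuc,
    shuffle_mono,
)
from cycflex.sequence_io import (
    UNAMBIGUOUS,
    GenomeStore,
    TSSRecord,
    extract_anchored_region,
)

#: bases before/after the registered 25th base of a 50-bp window
WIN_BEFORE = 24
WIN_AFTER = 25
WIN_LEN = WIN_BEFORE + WIN_AFTER + 1

RANDOMIZATION_MODES = ("mono_h", "dinuc_h", "mono_v", "dinuc_v", "matched_pair")


@dataclass(frozen=True)
class PositionalProfile:
    """Anchor-relative offsets with per-offset mean/sd/count of a statistic."""

    offsets: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        lens = {len(self.offsets), len(self.mean), len(self.sd), len(self.n)}
        if len(lens) != 1:
            raise ValueError("profile arrays must have equal lengths")
        if (np.diff(self.offsets) <= 0).any():
            raise ValueError("offsets must be strictly increasing")
        if (self.n[np.isfinite(np.asarray(self.mean, dtype=float))] < 1).any():
            raise ValueError("reported means need n >= 1")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                      "sd": self.sd, "n": self.n}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionalProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(offsets=df["offset"].to_numpy(),
                   mean=df["mean"].to_numpy(), sd=df["sd"].to_numpy(),
                   n=df["n"].to_numpy())


@dataclass(frozen=True)
class MatchedPairResult:
    """Per-window paired differences under the matched-distance protocol.

    ``diff_dinuc[i]`` / ``diff_mono[i]`` are score(shuffled) − score(actual)
    for the dinucleotide shuffle and its distance-matched single-base shuffle
    of the same parent window.
    """

    diff_dinuc: np.ndarray
    diff_mono: np.ndarray
    n_failed: int  # windows whose matched shuffle was infeasible (skipped)


@dataclass(frozen=True)
class DinucLogRatioProfile:
    """ln(observed/expected) dinucleotide composition per offset."""

    labels: tuple  # the 16 dinucleotides
    offsets: np.ndarray
    values: np.ndarray  # (16, n_offsets); NaN where undefined
    defined: np.ndarray = field(repr=False)  # boolean mask, same shape

    def value(self, dinuc: str, offset: int) -> float:
        i = self.labels.index(dinuc)
        j = int(np.searchsorted(self.offsets, offset))
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# anchored profiles
# ---------------------------------------------------------------------------

def _usable_regions(genome: GenomeStore, anchors: Sequence[TSSRecord],
                    flank: int):
    regions = []
    for a in anchors:
        reg = extract_anchored_region(genome, a, flank)
        if reg is not None:
            regions.append(reg)
    if not regions:
        raise ValueError("zero usable anchors")
    return regions


def _profile_offsets(flank: int) -> np.ndarray:
    # all offsets whose full 50-bp window fits inside [-flank, +flank]
    return np.arange(-(flank - WIN_BEFORE), flank - WIN_AFTER + 1)


def _profile_from_window_lists(seq_lists: list[list[str]],
                               offsets: np.ndarray,
                               p: CyclizabilityPredictor) -> PositionalProfile:
    """Aggregate per-offset window sequences into a mean/sd/n profile.

    ``seq_lists[j]`` holds the (unambiguous) windows observed at offset j.
    """
    flat: list[str] = []
    bounds = [0]
    for lst in seq_lists:
        flat.extend(lst)
        bounds.append(len(flat))
    preds = rc_averaged_predict_batch(p, flat)
    mean = np.full(len(offsets), np.nan)
    sd = np.full(len(offsets), np.nan)
    n = np.zeros(len(offsets), dtype=np.int64)
    for j in range(len(offsets)):
        vals = preds[bounds[j]:bounds[j + 1]]
        n[j] = len(vals)
        if len(vals):
            mean[j] = vals.mean()
            sd[j] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return PositionalProfile(offsets=offsets, mean=mean, sd=sd, n=n)


def _collect_windows(regions, offsets: np.ndarray,
                     transform=None) -> list[list[str]]:
    seq_lists: list[list[str]] = [[] for _ in offsets]
    for reg in regions:
        for j, o in enumerate(offsets):
            win = reg.window_at(int(o), WIN_BEFORE, WIN_AFTER)
            if set(win) <= UNAMBIGUOUS:
                seq_lists[j].append(win if transform is None else transform(win))
    return seq_lists


def anchored_mean_profile(genome: GenomeStore, anchors: Sequence[TSSRecord],
                          p: CyclizabilityPredictor,
                          flank: int) -> PositionalProfile:
    """Mean rc-averaged prediction per anchor-relative offset.

    For each offset ``o`` whose full 50-bp window fits in the ±flank region,
    the profile mean averages, over anchors, the prediction of the window
    whose 25th base sits at ``o``.  Anchors too close to a chromosome edge
    and windows containing ambiguity codes are skipped.
    """
    if flank < 25:
        raise ValueError("flank must be >= 25")
    regions = _usable_regions(genome, anchors, flank)
    offsets = _profile_offsets(flank)
    return _profile_from_window_lists(
        _collect_windows(regions, offsets), offsets, p)


def randomized_profile(genome: GenomeStore, anchors: Sequence[TSSRecord],
                       p: CyclizabilityPredictor, flank: int, mode: str,
                       n_reps: int, rng: np.random.Generator
                       ) -> PositionalProfile | tuple[PositionalProfile,
                                                      MatchedPairResult]:
    """Profile of randomized sequences under one of five null models.

    mono_h / dinuc_h: every 50-bp window is shuffled independently before
    prediction ("horizontal").  mono_v / dinuc_v: whole regions are resampled
    from a positional base model fit to all anchor regions ("vertical"), then
    profiled.  matched_pair: per window, one dinucleotide shuffle and one
    distance-matched single-base shuffle; returns the dinucleotide-shuffle
    profile together with both per-window difference distributions.
    """
    if mode not in RANDOMIZATION_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    regions = _usable_regions(genome, anchors, flank)
    offsets = _profile_offsets(flank)

    if mode in ("mono_h", "dinuc_h"):
        shuffler = shuffle_mono if mode == "mono_h" else shuffle_dinuc
        seq_lists: list[list[str]] = [[] for _ in offsets]
        for _ in range(n_reps):
            rep_lists = _collect_windows(regions, offsets,
                                         transform=lambda w: shuffler(w, rng))
            for j in range(len(offsets)):
                seq_lists[j].extend(rep_lists[j])
        return _profile_from_window_lists(seq_lists, offsets, p)

    if mode in ("mono_v", "dinuc_v"):
        usable = [r.seq for r in regions if set(r.seq) <= UNAMBIGUOUS]
        if not usable:
            raise ValueError("no unambiguous regions to fit positional model")
        model = fit_positional_model(usable, pseudocount=1.0)
        order = "mono" if mode == "mono_v" else "dinuc"
        seq_lists = [[] for _ in offsets]
        for _ in range(n_reps):
            for _i in range(len(usable)):
                s = sample_vertical(model, order, rng)
                for j, o in enumerate(offsets):
                    i = int(o) + flank
                    seq_lists[j].append(s[i - WIN_BEFORE:i + WIN_AFTER + 1])
        return _profile_from_window_lists(seq_lists, offsets, p)

    # matched_pair
    prof_lists: list[list[str]] = [[] for _ in offsets]
    originals: list[str] = []
    dinuc_versions: list[str] = []
    mono_versions: list[str] = []
    n_failed = 0
    for _ in range(n_reps):
        for reg in regions:
            for j, o in enumerate(offsets):
                win = reg.window_at(int(o), WIN_BEFORE, WIN_AFTER)
                if not set(win) <= UNAMBIGUOUS:
                    continue
                dshuf = shuffle_dinuc(win, rng)
                target = count_matches(win, dshuf)
                try:
                    mshuf = matched_distance_shuffle(win, target, rng)
                except RuntimeError:
                    n_failed += 1
                    continue
                originals.append(win)
                dinuc_versions.append(dshuf)
                mono_versions.append(mshuf)
                prof_lists[j].append(dshuf)
    if not originals:
        raise ValueError("no windows survived matched-pair shuffling")
    base = rc_averaged_predict_batch(p, originals)
    d_pred = rc_averaged_predict_batch(p, dinuc_versions)
    m_pred = rc_averaged_predict_batch(p, mono_versions)
    profile = _profile_from_window_lists(prof_lists, offsets, p)
    return profile, MatchedPairResult(diff_dinuc=d_pred - base,
                                      diff_mono=m_pred - base,
                                      n_failed=n_failed)


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------

_DINUCS = tuple(a + b for a in "ACGT" for b in "ACGT")


def dinuc_logratio_profile(aligned_seqs: Sequence[str],
                           expected: str | np.ndarray =
                           "pooled_mononucleotide_product"
                           ) -> DinucLogRatioProfile:
    """ln(observed / expected) frequency of each dinucleotide per offset.

    ``expected`` is 'pooled_mononucleotide_product' (product of position-pooled
    base frequencies, the default), 'pooled_dinucleotide' (position-pooled
    dinucleotide frequencies), or a user-supplied 16-vector.  Cells with zero
    observed count, or zero expected frequency, are flagged undefined (NaN).
    """
    if not aligned_seqs:
        raise ValueError("need at least one sequence")
    L = len(aligned_seqs[0])
    if any(len(s) != L for s in aligned_seqs):
        raise ValueError("sequences must have equal length")
    if L < 2:
        raise ValueError("need length >= 2")

    base_idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((16, L - 1), dtype=np.float64)
    pooled_base = np.zeros(4)
    for s in aligned_seqs:
        for ch in s:
            if ch in base_idx:
                pooled_base[base_idx[ch]] += 1
        for i in range(L - 1):
            a, b = s[i], s[i + 1]
            if a in base_idx and b in base_idx:
                counts[4 * base_idx[a] + base_idx[b], i] += 1

    col_tot = counts.sum(axis=0)
    obs = np.divide(counts, col_tot, out=np.full_like(counts, np.nan),
                    where=col_tot > 0)

    if isinstance(expected, str):
        if expected == "pooled_mononucleotide_product":
            if pooled_base.sum() == 0:
                raise ValueError("no unambiguous bases observed")
            q = pooled_base / pooled_base.sum()
            e = np.array([q[i // 4] * q[i % 4] for i in range(16)])
        elif expected == "pooled_dinucleotide":
            tot = counts.sum(axis=1)
            e = tot / tot.sum()
        else:
            raise ValueError(f"unknown expected model {expected!r}")
    else:
        e = np.asarray(expected, dtype=np.float64)
        if e.shape != (16,):
            raise ValueError("user-supplied expected must have 16 entries")

    values = np.full((16, L - 1), np.nan)
    defined = np.zeros((16, L - 1), dtype=bool)
    for d in range(16):
        if e[d] > 0:
            ok = np.isfinite(obs[d]) & (obs[d] > 0)
            values[d, ok] = np.log(obs[d, ok] / e[d])
            defined[d, ok] = True
    offsets = np.arange(L - 1)
    return DinucLogRatioProfile(labels=_DINUCS, offsets=offsets,
                                values=values, defined=defined)


# ---------------------------------------------------------------------------
# tracks and autocorrelation
# ---------------------------------------------------------------------------

def predict_track(genome: GenomeStore, chrom: str, start: int, end: int,
                  p: CyclizabilityPredictor, step: int = 1
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position rc-averaged score of sliding 50-bp windows.

    The score of each window is assigned to its 25th base; returns
    ``(positions, scores)``.  Windows containing ambiguity codes are absent.
    """
    if end - start < WIN_LEN:
        raise ValueError("region shorter than 50 bp")
    seq = genome[chrom]
    if not (0 <= start and end <= len(seq)):
        raise ValueError("region outside chromosome")
    positions, windows = [], []
    for s in range(start, end - WIN_LEN + 1, step):
        win = seq[s:s + WIN_LEN]
        if set(win) <= UNAMBIGUOUS:
            positions.append(s + WIN_BEFORE)
            windows.append(win)
    scores = rc_averaged_predict_batch(p, windows)
    return np.asarray(positions, dtype=np.int64), scores


def acf(values, max_lag: int) -> np.ndarray:
    """Mean-removed, variance-normalized sample autocorrelation function.

    Returns lags 0..max_lag; ``acf[0] == 1``.
    """
    x = np.asarray(values, dtype=np.float64)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if len(x) <= max_lag:
        raise ValueError("need more values than max_lag")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    xc = x - x.mean()
    denom = float((xc ** 2).sum())
    if denom == 0.0:
        raise ValueError("zero variance")
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = float((xc[:len(x) - k] * xc[k:]).sum()) / denom
    return out
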