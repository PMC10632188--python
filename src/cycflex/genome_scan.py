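"""Genome-wide actual-vs-shuffled cyclizability differences and
feature-stratified window sets.

Sign convention: ``D = C_actual − C_shuffled``; positive D means the genomic
sequence is more flexible than its randomized version.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cycflex.predictor import CyclizabilityPredictor, rc_averaged_predict_batch
from cycflex.randomization import shuffle_dinuc, shuffle_mono
from cycflex.sequence_io import GenomeStore, SequenceWindow, tile_genome


@dataclass(frozen=True)
class ShuffleDiffResult:
    """Per-window actual score, k shuffled scores, and their differences."""

    windows: tuple  # SequenceWindow per retained window
    c_actual: np.ndarray  # (N,)
    c_shuffled: np.ndarray  # (N, k)
    diffs: np.ndarray  # (N, k), diffs[:, j] = c_actual - c_shuffled[:, j]

    @property
    def n_shuffles(self) -> int:
        return self.c_shuffled.shape[1]

    @property
    def pooled_diffs(self) -> np.ndarray:
        return self.diffs.ravel()

    @property
    def per_window_mean_diffs(self) -> np.ndarray:
        return self.diffs.mean(axis=1)

    def summary(self) -> dict:
        pooled = self.pooled_diffs
        per_win = self.per_window_mean_diffs
        return {
            "n_windows": len(self.windows),
            "n_shuffles": self.n_shuffles,
            "pooled": {"mean": float(pooled.mean()),
                       "sd": float(pooled.std(ddof=1)),
                       "n": int(pooled.size)},
            "per_window_mean": {"mean": float(per_win.mean()),
                                "sd": float(per_win.std(ddof=1)),
                                "n": int(per_win.size)},
        }

    def to_tsv(self, path: str | Path) -> None:
        data = {"chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "c_actual": self.c_actual}
        for j in range(self.n_shuffles):
            data[f"D_{j + 1}"] = self.diffs[:, j]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def genome_shuffle_diff(genome: GenomeStore, p: CyclizabilityPredictor,
                        n_shuffles: int = 5,
                        rng: np.random.Generator | None = None,
                        window: int = 50, step: int = 50,
                        mode: str = "mono") -> ShuffleDiffResult:
    """Tile the genome and compare each window to shuffled versions of itself.

    Windows of ``window`` bp at ``step`` bp increments (ambiguous windows
    dropped) are each shuffled ``n_shuffles`` times (single-base by default)
    and ``D = C_actual − C_shuffled`` recorded per shuffle.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if mode not in ("mono", "dinuc"):
        raise ValueError(f"shuffle mode must be 'mono' or 'dinuc', got {mode!r}")
    shuffler = shuffle_mono if mode == "mono" else shuffle_dinuc

    windows = tile_genome(genome, window=window, step=step)
    if not windows:
        raise ValueError("no usable windows after tiling/ambiguity filtering")
    seqs = [w.seq for w in windows]
    c_actual = rc_averaged_predict_batch(p, seqs)
    c_shuffled = np.empty((len(seqs), n_shuffles))
    for j in range(n_shuffles):
        shuffled = [shuffler(s, rng) for s in seqs]
        c_shuffled[:, j] = rc_averaged_predict_batch(p, shuffled)
    diffs = c_actual[:, None] - c_shuffled
    return ShuffleDiffResult(windows=tuple(windows), c_actual=c_actual,
                             c_shuffled=c_shuffled, diffs=diffs)


def label_windows_by_intervals(windows: Sequence[SequenceWindow],
                               intervals: Sequence[tuple]) -> list[str]:
    """Label each window 'inside', 'outside' or 'straddling' a set of intervals.

    ``intervals`` are BED-style tuples ``(chrom, start, end, ...)`` in 0-based
    half-open coordinates.  'inside' = fully contained in at least one
    interval; 'outside' = zero overlap with all intervals; 'straddling' =
    partial overlap only.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    for ivs in by_chrom.values():
        ivs.sort()

    labels = []
    for w in windows:
        ivs = by_chrom.get(w.chrom, [])
        contained = False
        overlapped = False
        for s, e in ivs:
            if s >= w.end:
                break
            if e <= w.start:
                continue
            overlapped = True
            if s <= w.start and w.end <= e:
                contained = True
                break
        if contained:
            labels.append("inside")
        elif overlapped:
            labels.append("straddling")
        else:
            labels.append("outside")
    return labels
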