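"""Sequence null models.

Horizontal randomization: single-base shuffling, exact dinucleotide-preserving
(Eulerian / Altschul–Erickson) shuffling, and a single-base shuffle constrained
to a target number of matching positions against the original ("matched
distance").  Vertical randomization: position-specific base probabilities and
first-order conditional transition matrices fit across aligned regions, with
mono- and dinucleotide-chain samplers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cycflex.sequence_io import UNAMBIGUOUS, encode, BASE_ORDER


class MatchedShuffleError(RuntimeError):
    """matched_distance_shuffle could not reach its target match count."""

    def __init__(self, target: int, achieved: int):
        super().__init__(
            f"could not reach target match count {target}; best achieved "
            f"{achieved}"
        )
        self.target = target
        self.achieved = achieved


def _check_unambiguous(seq: str) -> None:
    bad = set(seq) - UNAMBIGUOUS
    if bad:
        raise ValueError(f"ambiguous letter(s) {sorted(bad)!r} in sequence")


def shuffle_mono(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the letters of ``seq``."""
    _check_unambiguous(seq)
    letters = list(seq)
    rng.shuffle(letters)
    return "".join(letters)


def shuffle_dinuc(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul–Erickson construction).

    All 16 dinucleotide counts and the first and last base are preserved
    exactly; the output is a uniform-ish draw over Eulerian arrangements
    (random last-edge tree, then random edge orderings).
    """
    _check_unambiguous(seq)
    if len(seq) < 2:
        raise ValueError("need length >= 2")
    if len(set(seq)) == 1:
        return seq

    # adjacency: per source base, list of target bases (edge multiset)
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = set(seq)

    # pick a random "last edge" for every vertex except the final one, until
    # the chosen edges form a tree rooted at the final vertex
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            out = adj[v]
            last_edge[v] = out[rng.integers(len(out))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    # order edges: shuffle all non-last edges, append the chosen last edge
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        out = list(adj.get(v, []))
        if v in last_edge:
            out.remove(last_edge[v])
        rng.shuffle(out)
        if v in last_edge:
            out.append(last_edge[v])
        ordered[v] = out

    # walk the Eulerian path
    result = [seq[0]]
    nxt = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        step = ordered[cur][nxt[cur]]
        nxt[cur] += 1
        result.append(step)
        cur = step
    return "".join(result)


def count_matches(a: str, b: str) -> int:
    """Number of positions where ``a`` and ``b`` carry the same letter."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x == y)


def matched_distance_shuffle(seq: str, target_matches: int,
                             rng: np.random.Generator,
                             max_iter: int | None = None) -> str:
    """Single-base shuffle with exactly ``target_matches`` positions equal to
    ``seq``.

    Repeatedly proposes swaps of two random unequal-letter positions,
    accepting a swap only if it does not push the match count below the
    target; stops when the target is hit.  Raises
    :class:`MatchedShuffleError` if the target is unreachable within
    ``max_iter`` proposals (default ``10_000 * len(seq)``).
    """
    _check_unambiguous(seq)
    L = len(seq)
    if not 0 <= target_matches <= L:
        raise ValueError("target_matches out of range")
    if target_matches == L:
        return seq
    if max_iter is None:
        max_iter = 10_000 * L
    if len(set(seq)) == 1:
        raise MatchedShuffleError(target_matches, L)

    cur = list(seq)
    matches = L
    for _ in range(max_iter):
        i, j = rng.integers(L), rng.integers(L)
        if cur[i] == cur[j]:
            continue
        delta = 0
        delta -= (cur[i] == seq[i]) + (cur[j] == seq[j])
        delta += (cur[j] == seq[i]) + (cur[i] == seq[j])
        if matches + delta < target_matches:
            continue
        cur[i], cur[j] = cur[j], cur[i]
        matches += delta
        if matches == target_matches:
            return "".join(cur)
    raise MatchedShuffleError(target_matches, matches)


# ---------------------------------------------------------------------------
# vertical (position-specific) model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionalBaseModel:
    """Per-offset base probabilities and first-order conditionals.

    ``p0[i]`` is the base distribution at offset ``i`` (rows sum to 1);
    ``trans[i, a]`` is the distribution of the base at offset ``i+1`` given
    base ``a`` at offset ``i``.  Rows with no usable observations (possible
    only with pseudocount 0) are stored as NaN and rejected at sample time.
    """

    L: int
    p0: np.ndarray  # (L, 4)
    trans: np.ndarray  # (L-1, 4, 4)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.p0.shape != (self.L, 4):
            raise ValueError("p0 must have shape (L, 4)")
        if self.trans.shape != (self.L - 1, 4, 4):
            raise ValueError("trans must have shape (L-1, 4, 4)")
        for name, arr in (("p0", self.p0), ("trans", self.trans)):
            finite = np.isfinite(arr)
            vals = arr[finite]
            if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
                raise ValueError(f"{name} has entries outside [0, 1]")
            sums = np.where(finite, arr, 0.0).sum(axis=-1)
            defined = finite.all(axis=-1)
            if not np.allclose(sums[defined], 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")


def fit_positional_model(aligned_seqs: list[str],
                         pseudocount: float = 0.0) -> PositionalBaseModel:
    """Fit per-offset base and conditional-transition frequencies.

    Ambiguous positions are excluded from the counts.  The pseudocount is
    added to every cell of both the base and the transition count tables
    before normalization.
    """
    if not aligned_seqs:
        raise ValueError("need at least one sequence")
    L = len(aligned_seqs[0])
    if any(len(s) != L for s in aligned_seqs):
        raise ValueError("sequences must have equal length")
    if L < 2:
        raise ValueError("need length >= 2")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    valid_list = []
    codes_list = []
    for s in aligned_seqs:
        raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        codes = np.full(L, -1, dtype=np.int64)
        for k, b in enumerate(BASE_ORDER):
            codes[raw == ord(b)] = k
        codes_list.append(codes)
        valid_list.append(codes >= 0)
    codes = np.stack(codes_list)  # (N, L)
    valid = np.stack(valid_list)

    counts0 = np.zeros((L, 4), dtype=np.float64)
    for k in range(4):
        counts0[:, k] = ((codes == k) & valid).sum(axis=0)
    counts0 += pseudocount
    totals = counts0.sum(axis=1)
    if pseudocount == 0 and (totals == 0).any():
        off = int(np.nonzero(totals == 0)[0][0])
        raise ValueError(f"zero usable observations at offset {off}")
    p0 = counts0 / totals[:, None]

    countsT = np.zeros((L - 1, 4, 4), dtype=np.float64)
    pair_ok = valid[:, :-1] & valid[:, 1:]
    prev = codes[:, :-1]
    nxt = codes[:, 1:]
    for a in range(4):
        sel = (prev == a) & pair_ok
        for b in range(4):
            countsT[:, a, b] = (sel & (nxt == b)).sum(axis=0)
    countsT += pseudocount
    row_tot = countsT.sum(axis=2)
    trans = np.full_like(countsT, np.nan)
    nz = row_tot > 0
    trans[nz] = countsT[nz] / row_tot[nz][:, None]
    return PositionalBaseModel(L=L, p0=p0, trans=trans, pseudocount=pseudocount)


def sample_vertical(model: PositionalBaseModel, order: str,
                    rng: np.random.Generator) -> str:
    """Draw one length-L sequence from a positional model.

    ``order='mono'``: independent per-offset draws from ``p0``;
    ``order='dinuc'``: first base from ``p0[0]``, later bases from the
    conditional transition of the previously sampled base.
    """
    if order not in ("mono", "dinuc"):
        raise ValueError(f"order must be 'mono' or 'dinuc', got {order!r}")
    out = np.empty(model.L, dtype=np.int64)
    if order == "mono":
        u = rng.random(model.L)
        cum = np.cumsum(model.p0, axis=1)
        out = (u[:, None] > cum).sum(axis=1)
    else:
        out[0] = rng.choice(4, p=model.p0[0])
        for i in range(1, model.L):
            row = model.trans[i - 1, out[i - 1]]
            if not np.isfinite(row).all():
                raise ValueError(
                    f"undefined conditional at offset {i - 1} for base "
                    f"{BASE_ORDER[out[i - 1]]} (no observations, pseudocount 0)"
                )
            out[i] = rng.choice(4, p=row)
    return "".join(BASE_ORDER[k] for k in out)
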