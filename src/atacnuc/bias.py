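"""Tn5 insertion sequence-bias model.

Tn5 contacts ~21 bp around its insertion point and prefers particular base
compositions there.  The model is a 4 x 21 position weight matrix (offsets
-10..+10 from the insertion center) trained on insertions in naked genomic
DNA, stored as log-odds against genome-wide base frequencies.  Per-base
insertion propensities derived from the PWM feed the fragment-level
background matrix B: the relative probability of observing a fragment of each
size at each midpoint offset, given that a fragment requires two independent
insertions plus a draw from the library's size distribution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .fragments import Track
from .occupancy import SizeDistribution

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PWM_WIDTH = 21
PWM_HALF = 10
PSEUDOCOUNT = 0.5

SIZE_LO, SIZE_HI = 105, 250
FLANK = 60
N_SIZES = SIZE_HI - SIZE_LO + 1
N_CENTERS = 2 * FLANK + 1
# propensity must cover the outermost insertion center of the largest fragment
PROP_PAD = FLANK + (SIZE_HI - 1) // 2 + 1  # 185


class BiasError(ValueError):
    pass


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Sequence from a dict of strings or a pyfaidx.Fasta, uppercased."""
    ref = genome[chrom]
    if isinstance(ref, str):
        return ref[start:end].upper()
    return str(ref[start:end]).upper()


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class BiasModel:
    """21-bp insertion-preference PWM as log-odds vs genomic background."""

    logodds: np.ndarray  # 4 x 21
    background: np.ndarray  # length-4 genome base frequencies

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        if self.logodds.shape != (4, PWM_WIDTH):
            raise ValueError("PWM must be 4 x 21")

    @classmethod
    def flat(cls) -> "BiasModel":
        return cls(np.zeros((4, PWM_WIDTH)), np.full(4, 0.25))

    def to_tsv(self, path: str) -> None:
        tmp = path + ".tmp"
        offsets = "\t".join(str(o) for o in range(-PWM_HALF, PWM_HALF + 1))
        with open(tmp, "w") as fh:
            fh.write(f"base\t{offsets}\n")
            for i, b in enumerate(BASES):
                row = "\t".join(f"{v:.6f}" for v in self.logodds[i])
                fh.write(f"{b}\t{row}\n")
            fh.write("# background\t" + "\t".join(f"{v:.6f}" for v in self.background) + "\n")
        os.replace(tmp, path)

    @classmethod
    def from_tsv(cls, path: str) -> "BiasModel":
        logodds = np.zeros((4, PWM_WIDTH))
        background = np.full(4, 0.25)
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "base":
                    continue
                if parts[0] == "# background":
                    background = np.array([float(v) for v in parts[1:5]])
                    continue
                if parts[0] in _BASE_INDEX:
                    logodds[_BASE_INDEX[parts[0]]] = [float(v) for v in parts[1:]]
        return cls(logodds, background)


def genome_base_frequencies(genome) -> np.ndarray:
    counts = np.zeros(4)
    for chrom in genome.keys():
        enc = _encode(fetch_seq(genome, chrom, 0, len(genome[chrom])))
        for i in range(4):
            counts[i] += int((enc == i).sum())
    total = counts.sum()
    if total == 0:
        raise BiasError("genome contains no unambiguous bases")
    return counts / total


def train_pwm(naked_insertions: Track, genome) -> BiasModel:
    """Train the 21-bp PWM from an insertion-count track on naked DNA.

    Column probabilities are pseudocounted base frequencies at each offset
    from the insertion centers; the returned matrix is their log-odds against
    genome-wide base frequencies.  Insertions too close to a contig edge are
    skipped and tallied.
    """
    chrom = naked_insertions.chrom
    positions = naked_insertions.start + np.flatnonzero(naked_insertions.values)
    counts_at = naked_insertions.values[naked_insertions.values > 0]
    if positions.size == 0:
        raise BiasError("no insertion events to train on")
    contig_len = len(genome[chrom])

    counts = np.full((4, PWM_WIDTH), PSEUDOCOUNT)
    n_skipped = 0
    enc = _encode(fetch_seq(genome, chrom, 0, contig_len))
    for pos, c in zip(positions, counts_at):
        if pos - PWM_HALF < 0 or pos + PWM_HALF >= contig_len:
            n_skipped += int(c)
            continue
        window = enc[pos - PWM_HALF : pos + PWM_HALF + 1]
        for j, b in enumerate(window):
            if b >= 0:
                counts[b, j] += c
    if counts.sum() <= 4 * PWM_WIDTH * PSEUDOCOUNT:
        raise BiasError("no usable insertion events (all near contig edges?)")

    probs = counts / counts.sum(axis=0, keepdims=True)
    bg = genome_base_frequencies(genome)
    logodds = np.log(probs) - np.log(bg)[:, None]
    model = BiasModel(logodds, bg)
    model.n_skipped = n_skipped
    return model


def insertion_propensity(model: BiasModel, genome, region) -> Track:
    """Relative per-base insertion probability over a region, mean 1.

    score(x) = exp(sum_j logodds[base(x + j - 10), j]).  Positions whose
    21-mer contains an ambiguous base get the region mean.  Requires sequence
    available 10 bp beyond both region bounds.
    """
    chrom, start, end = region
    enc = _encode(fetch_seq(genome, chrom, start - PWM_HALF, end + PWM_HALF))
    n = end - start
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(PWM_WIDTH):
        col = enc[j : j + n]
        bad = col < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, model.logodds[np.clip(col, 0, 3), j])
    prop = np.exp(scores)
    if not valid.any():
        prop = np.ones(n)
    else:
        prop[~valid] = prop[valid].mean()
        prop /= prop.mean()
    return Track(chrom, start, prop)


def _background_rows(prop: Track, size_dist: SizeDistribution) -> np.ndarray:
    """Unnormalized fragment-generation weight U[size, midpoint] over the
    propensity track's span.

    For odd sizes the midpoint is an integer and the two insertion centers
    sit at +/-(s-1)/2; even sizes have half-integer midpoints whose weight is
    split across the two flanking integer columns.
    """
    p = np.asarray(prop.values, dtype=float)
    L = len(p)
    U = np.zeros((N_SIZES, L))
    for s in range(SIZE_LO, SIZE_HI + 1):
        row = s - SIZE_LO
        ps = size_dist.prob(s)
        if ps == 0:
            continue
        if s % 2 == 1:
            h = (s - 1) // 2
            U[row, h : L - h] = ps * p[: L - 2 * h] * p[2 * h :]
        else:
            h = s // 2
            # midpoint m - 0.5: centers (m - h, m + h - 1); m + 0.5: (m - h + 1, m + h)
            left = np.zeros(L)
            right = np.zeros(L)
            left[h : L - h + 1] = p[: L - 2 * h + 1] * p[2 * h - 1 :]
            right[h - 1 : L - h] = p[: L - 2 * h + 1] * p[2 * h - 1 :]
            U[row] = 0.5 * ps * (left + right)
    return U


def background_matrix(prop: Track, size_dist: SizeDistribution, x: int) -> np.ndarray:
    """Background matrix B at position ``x``: sizes 105-250 x offsets -60..60.

    B[s, c] is proportional to prop(left) * prop(right) * P(s) for a size-s
    fragment whose midpoint is x + c, normalized so the matrix sums to 1.
    The propensity track must cover [x - 185, x + 186).
    """
    lo = x - FLANK
    hi = x + FLANK + 1
    pad = (SIZE_HI - 1) // 2 + 1
    if lo - pad < prop.start or hi + pad > prop.end:
        raise BiasError("propensity track does not cover the background window")
    U = _background_rows(prop, size_dist)
    window = U[:, lo - prop.start : hi - prop.start]
    total = window.sum()
    if total <= 0:
        return np.full((N_SIZES, N_CENTERS), 1.0 / (N_SIZES * N_CENTERS))
    return window / total


def uniform_background(size_dist: SizeDistribution) -> np.ndarray:
    """MNase-mode background: fragments placed at random given the size law.

    B[s, c] = P(s) / 121 for every center offset.
    """
    p = size_dist.restrict(SIZE_LO, SIZE_HI).probs
    return np.repeat(p[:, None], N_CENTERS, axis=1) / N_CENTERS
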