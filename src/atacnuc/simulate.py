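"""Synthetic chromatin fixtures: genome, planted architecture, fragments.

The generator emulates the fragment structure an ATAC-seq library shows over
yeast-like chromatin: a bimodal adjusted-size distribution (exponential
nucleosome-free mode plus a ~143-bp nucleosomal mode truncated at the
117-bp V apex), dyad-centered nucleosomal fragments whose midpoints sit on a
10-bp rotational lattice around each planted dyad, nucleosome-free fragments
confined to planted NFR intervals, and (optionally) insertion sites biased
through a planted 21-bp Tn5 preference matrix.  Every draw is driven by a
single seed and the planted truth is exported so tests read truth rather
than re-deriving it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import yaml

from .bias import PWM_HALF, PWM_WIDTH, BiasModel
from .fragments import OFFSET, SIZE_ADJUST, FragmentRecord

# rotational lattice: dyad-relative midpoint offsets and their weights
LATTICE_OFFSETS = (0, -10, 10, -20, 20)
LATTICE_WEIGHTS = (0.5, 0.2, 0.2, 0.05, 0.05)

NUC_SIZE_MEAN = 143.0  # nucleosomal adjusted-size mode
NUC_SIZE_SD = 15.0
NUC_SIZE_MIN = 117  # V apex: smallest fragment protected by a full wrap
FREE_SIZE_MIN = 9  # shortest adjusted size the generator emits
FREE_SIZE_MEAN = 50.0  # exponential mean of (size - FREE_SIZE_MIN)


class SimulationError(ValueError):
    pass


def make_genome(length: int, gc: float = 0.4, seed: int = 0, chrom: str = "chrS") -> dict:
    """Random genome with the requested GC content as {chrom: sequence}."""
    if not 0.0 <= gc <= 1.0:
        raise SimulationError("gc must be in [0, 1]")
    if length < 1:
        raise SimulationError("length must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return {chrom: seq}


def write_fasta(genome: dict, path: str, width: int = 70) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    os.replace(tmp, path)


@dataclass
class ArchitectureTruth:
    """Planted chromatin layout: dyads, their rotational lattice, NFRs."""

    chrom: str
    genome_length: int
    dyads: np.ndarray
    nfr_intervals: list
    alpha_true: float = 0.7
    lattice_offsets: tuple = LATTICE_OFFSETS
    lattice_weights: tuple = LATTICE_WEIGHTS
    pwm: BiasModel = None

    def __post_init__(self) -> None:
        self.dyads = np.asarray(self.dyads, dtype=int)
        if np.any(self.dyads < 0) or np.any(self.dyads >= self.genome_length):
            raise SimulationError("dyads outside the genome")

    def rotational_positions(self) -> np.ndarray:
        """All planted lattice positions (dyads plus +/-10, +/-20 satellites)."""
        offs = np.array(self.lattice_offsets)
        return np.unique((self.dyads[:, None] + offs[None, :]).ravel())

    def to_tsv(self, path: str) -> None:
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            fh.write("# record\tchrom\tfields\n")
            for d in self.dyads:
                fh.write(f"dyad\t{self.chrom}\t{d}\n")
            for s, e in self.nfr_intervals:
                fh.write(f"nfr\t{self.chrom}\t{s}\t{e}\n")
            w = ",".join(f"{x:g}" for x in self.lattice_weights)
            o = ",".join(str(x) for x in self.lattice_offsets)
            fh.write(f"lattice\t{self.chrom}\t{o}\t{w}\n")
            fh.write(f"alpha\t{self.chrom}\t{self.alpha_true:g}\n")
        os.replace(tmp, path)


def make_architecture(
    genome_length: int,
    n_dyads: int = 20,
    spacing: int = 165,
    nfr_length: int = 140,
    nucs_per_array: int = 5,
    alpha_true: float = 0.7,
    margin: int = 400,
) -> ArchitectureTruth:
    """Alternating nucleosome arrays and NFRs along a single chromosome.

    Arrays of ``nucs_per_array`` dyads at ``spacing`` bp are separated by
    ``nfr_length``-bp nucleosome-free gaps, starting ``margin`` bp from the
    left end; adjacent dyads are always >= 120 bp apart.
    """
    dyads = []
    nfrs = []
    pos = margin
    while len(dyads) < n_dyads:
        for _ in range(nucs_per_array):
            if len(dyads) >= n_dyads:
                break
            dyads.append(pos)
            pos += spacing
        gap_start = pos - spacing + 74  # just past the last array nucleosome's edge
        nfrs.append((gap_start, gap_start + nfr_length))
        pos = gap_start + nfr_length + 74
    if pos + margin > genome_length:
        raise SimulationError("genome too short for the requested architecture")
    return ArchitectureTruth(
        chrom="chrS",
        genome_length=genome_length,
        dyads=np.array(dyads),
        nfr_intervals=[iv for iv in nfrs if iv[1] + margin < genome_length],
        alpha_true=alpha_true,
    )


def _record_from_midpoint(chrom: str, midpoint: int, size: int, rng) -> FragmentRecord:
    """Integer FragmentRecord from a midpoint and adjusted size.

    Even sizes have half-integer center spans; the integer left center is
    drawn uniformly from the two consistent placements.
    """
    if size % 2 == 1:
        left = midpoint - (size - 1) // 2
    else:
        left = midpoint - size // 2 + int(rng.integers(0, 2))
    start = left - OFFSET
    return FragmentRecord(chrom, start, start + size + SIZE_ADJUST)


def simulate_fragments(
    truth: ArchitectureTruth,
    n: int,
    alpha: float | None = None,
    seed: int = 0,
    jitter: int = 1,
    nuc_size_mean: float = NUC_SIZE_MEAN,
    nuc_size_sd: float = NUC_SIZE_SD,
) -> list[FragmentRecord]:
    """Simulate ``n`` ATAC-like fragments over a planted architecture.

    A Binomial(n, alpha) share is nucleosomal: midpoint = dyad + lattice
    offset + uniform jitter in [-jitter, jitter], adjusted size from a
    discretized normal (mean 143, sd 15) truncated below 117 bp.  The rest
    are nucleosome-free: midpoint uniform over the NFR intervals, adjusted
    size 9 + floor(Exponential(mean 50)).  All records satisfy the fragment
    invariants and are returned sorted.
    """
    if alpha is None:
        alpha = truth.alpha_true
    if not 0.0 <= alpha <= 1.0:
        raise SimulationError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_nuc = int(rng.binomial(n, alpha))
    n_free = n - n_nuc
    frags: list[FragmentRecord] = []

    if n_nuc > 0:
        dyad_idx = rng.integers(0, len(truth.dyads), size=n_nuc)
        offs = rng.choice(
            truth.lattice_offsets, size=n_nuc, p=np.asarray(truth.lattice_weights)
        )
        jit = rng.integers(-jitter, jitter + 1, size=n_nuc)
        mids = truth.dyads[dyad_idx] + offs + jit
        sizes = np.rint(rng.normal(nuc_size_mean, nuc_size_sd, size=n_nuc)).astype(int)
        while np.any(sizes < NUC_SIZE_MIN):
            bad = sizes < NUC_SIZE_MIN
            sizes[bad] = np.rint(
                rng.normal(nuc_size_mean, nuc_size_sd, size=int(bad.sum()))
            ).astype(int)
        for m, s in zip(mids, sizes):
            frags.append(_record_from_midpoint(truth.chrom, int(m), int(s), rng))

    if n_free > 0:
        if not truth.nfr_intervals:
            raise SimulationError("free fragments requested but no NFR intervals")
        lengths = np.array([e - s for s, e in truth.nfr_intervals], dtype=float)
        iv_idx = rng.choice(len(lengths), size=n_free, p=lengths / lengths.sum())
        mids = np.array(
            [
                truth.nfr_intervals[i][0]
                + int(rng.integers(0, truth.nfr_intervals[i][1] - truth.nfr_intervals[i][0]))
                for i in iv_idx
            ]
        )
        sizes = FREE_SIZE_MIN + np.floor(
            rng.exponential(FREE_SIZE_MEAN, size=n_free)
        ).astype(int)
        for m, s in zip(mids, sizes):
            frags.append(_record_from_midpoint(truth.chrom, int(m), int(s), rng))

    frags = [
        f for f in frags if f.start >= 0 and f.end <= truth.genome_length
    ]
    frags.sort()
    return frags


def make_planted_pwm(strength: float = 0.6, seed: int = 7) -> BiasModel:
    """A mild but structured 21-bp insertion preference for bias tests."""
    rng = np.random.default_rng(seed)
    logodds = rng.normal(0.0, strength / 3.0, size=(4, PWM_WIDTH))
    # a few strong positions so the preference is clearly recoverable
    for j in (8, 10, 12):
        b = int(rng.integers(0, 4))
        logodds[b, j] += strength
    logodds -= logodds.mean(axis=0, keepdims=True)
    return BiasModel(logodds, np.full(4, 0.25))


def simulate_biased_insertions(
    genome: dict, chrom: str, model: BiasModel, n: int, seed: int = 0
) -> np.ndarray:
    """Sample insertion-center positions proportional to the PWM propensity."""
    from .bias import insertion_propensity

    L = len(genome[chrom])
    prop = insertion_propensity(model, genome, (chrom, PWM_HALF, L - PWM_HALF))
    p = prop.values / prop.values.sum()
    rng = np.random.default_rng(seed)
    return prop.start + rng.choice(len(p), size=n, p=p)


def write_config(path: str, params: dict) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    os.replace(tmp, path)
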