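"""V-plot templates: fragment size x midpoint-offset densities around dyads.

A nucleosome protects ~147 bp, so fragments spanning it form a "V" in the
2D histogram of fragment size (rows, 105-250 bp) versus midpoint offset from
the dyad (columns, -60..+60 bp).  A template built from fragments around
well-positioned nucleosomes is cross-correlated against per-locus fragment
matrices to score candidate dyads.  Because the template's size marginal is
library-specific, it is renormalized row-by-row to the nucleosomal
fragment-size distribution of the sample being analysed, which is what makes
a template transferable across samples and species.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .bias import FLANK, N_CENTERS, N_SIZES, SIZE_HI, SIZE_LO
from .occupancy import MixtureModel, OccupancyTrack, SizeDistribution


class VPlotError(ValueError):
    pass


@dataclass
class VPlotMatrix:
    """Nonnegative density over sizes 105..250 (rows) x offsets -60..60."""

    mat: np.ndarray

    def __post_init__(self) -> None:
        self.mat = np.asarray(self.mat, dtype=float)
        if self.mat.shape != (N_SIZES, N_CENTERS):
            raise ValueError(f"V-plot must be {N_SIZES} x {N_CENTERS}")
        if np.any(self.mat < 0):
            raise ValueError("V-plot densities must be nonnegative")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(SIZE_LO, SIZE_HI + 1)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-FLANK, FLANK + 1)

    def row_sums(self) -> np.ndarray:
        return self.mat.sum(axis=1)

    def size_marginal(self) -> SizeDistribution:
        rs = self.row_sums()
        return SizeDistribution(SIZE_LO, SIZE_HI, rs / rs.sum())

    def to_tsv(self, path: str) -> None:
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            fh.write("size\t" + "\t".join(str(o) for o in self.offsets) + "\n")
            for s, row in zip(self.sizes, self.mat):
                fh.write(str(s) + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
        os.replace(tmp, path)

    @classmethod
    def from_tsv(cls, path: str) -> "VPlotMatrix":
        mat = np.zeros((N_SIZES, N_CENTERS))
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("size"):
                raise VPlotError("malformed V-plot TSV header")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                s = int(parts[0])
                mat[s - SIZE_LO] = [float(v) for v in parts[1:]]
        return cls(mat)


def build_vplot(frags, dyads) -> VPlotMatrix:
    """Aggregate fragment (size, midpoint-offset) weights around dyads.

    Each fragment of size 105-250 bp whose (split-weighted) midpoint falls
    within 60 bp of a dyad adds its weight at (adj_size, midpoint - dyad).
    Split halves landing outside +/-60 are dropped.
    """
    dyads = np.asarray(dyads, dtype=int)
    if dyads.size == 0:
        raise VPlotError("empty dyad set")
    mat = np.zeros((N_SIZES, N_CENTERS))
    for f in frags:
        if not (SIZE_LO <= f.adj_size <= SIZE_HI):
            continue
        row = f.adj_size - SIZE_LO
        for pos, w in f.midpoint_weights():
            offs = pos - dyads
            hit = offs[np.abs(offs) <= FLANK]
            for o in hit:
                mat[row, o + FLANK] += w
    return VPlotMatrix(mat)


def select_template_dyads(
    gold_calls, occ: OccupancyTrack, score_quantile: float = 0.8, min_occ: float = 0.5
) -> np.ndarray:
    """Filter scored gold-standard dyads for template building.

    Keeps calls whose positioning score is in the top (1 - score_quantile)
    fraction and whose occupancy exceeds ``min_occ``; order preserved.
    ``gold_calls`` is a sequence of (position, score).
    """
    calls = list(gold_calls)
    if not calls:
        raise VPlotError("no gold-standard calls supplied")
    scores = np.array([s for _, s in calls], dtype=float)
    thresh = np.quantile(scores, score_quantile)
    pass_score = scores >= thresh
    occs = occ.interp([p for p, _ in calls])
    pass_occ = occs > min_occ
    kept = [p for (p, _), a, b in zip(calls, pass_score, pass_occ) if a and b]
    if not kept:
        raise VPlotError(
            f"no dyads pass both filters (score>=q{score_quantile}: "
            f"{int(pass_score.sum())}, occ>{min_occ}: {int(pass_occ.sum())})"
        )
    return np.array(kept, dtype=int)


def normalize_to_sizedist(V: VPlotMatrix, target: SizeDistribution) -> VPlotMatrix:
    """Rescale each row so row sums match the target nucleosomal size law.

    The target is restricted to 105-250 bp and renormalized first.  Rows that
    are empty in V but carry target mass are filled uniformly across columns
    so the output's row marginals equal the target law exactly; the matrix
    sums to 1.
    """
    tgt = target.restrict(SIZE_LO, SIZE_HI).probs
    rs = V.row_sums()
    out = np.zeros_like(V.mat)
    nonzero = rs > 0
    out[nonzero] = V.mat[nonzero] * (tgt[nonzero] / rs[nonzero])[:, None]
    empty = ~nonzero & (tgt > 0)
    out[empty] = tgt[empty][:, None] / N_CENTERS
    return VPlotMatrix(out)


def symmetrize_smooth(V: VPlotMatrix, sd: float = 1.0) -> VPlotMatrix:
    """Average with the mirror image, then apply a 2D Gaussian (sd 1 bp)."""
    sym = 0.5 * (V.mat + V.mat[:, ::-1])
    smoothed = gaussian_filter(sym, sigma=sd, mode="reflect")
    return VPlotMatrix(np.clip(smoothed, 0.0, None))


def refined_nuc_sizedist(
    frags,
    occ: OccupancyTrack,
    model: MixtureModel | None = None,
    min_alpha: float = 0.5,
    min_sep: int = 120,
) -> SizeDistribution:
    """Nucleosomal size law from fragments near occupancy peaks.

    Peaks are local maxima of the smoothed occupancy with alpha >= min_alpha,
    thinned to >= min_sep bp apart; the distribution pools fragments whose
    midpoints fall within 60 bp of any peak.  With no peaks, falls back to
    the mixture model's nucleosomal component (if supplied).
    """
    peaks = occ.peaks(min_alpha=min_alpha, min_sep=min_sep)
    if peaks.size == 0:
        if model is not None:
            return model.nuc.restrict(SIZE_LO, SIZE_HI)
        raise VPlotError("no occupancy peaks and no fallback model supplied")
    counts = np.zeros(N_SIZES)
    for f in frags:
        if not (SIZE_LO <= f.adj_size <= SIZE_HI):
            continue
        for pos, w in f.midpoint_weights():
            if np.min(np.abs(peaks - pos)) <= FLANK:
                counts[f.adj_size - SIZE_LO] += w
    if counts.sum() == 0:
        if model is not None:
            return model.nuc.restrict(SIZE_LO, SIZE_HI)
        raise VPlotError("no fragments near occupancy peaks")
    return SizeDistribution(SIZE_LO, SIZE_HI, counts / counts.sum())
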