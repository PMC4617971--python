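"""Nucleosome dyad calling by V-plot cross-correlation.

For every base x in an open-chromatin region, the fragment matrix F (sizes
105-250 bp, midpoints within 60 bp of x) is scored against the template V:

    Signal(x)     = F . V
    Background(x) = (B . V) * SumF
    Normalized(x) = F . V - (B . V) * SumF

where B is the per-position background matrix derived from the Tn5 bias
model and the fragment-size distribution (SumB = 1) and SumF the fragment
count in the window.  Treating the SumF fragments as a multinomial draw from
B gives the background variance

    var(Background) = SumF * (sum_k b_k (1 - b_k) v_k^2
                              - sum_{k != l} b_k b_l v_k v_l)

from which Z = Normalized / sqrt(var).  Candidate dyads are local maxima of
the normalized signal plus a 25-bp-Gaussian-smoothed copy; a greedy pass
builds the nonredundant map (no two calls within 120 bp), and calls are kept
when Z > 3 and the log-likelihood ratio of the V-plot-plus-bias model over
the bias-only model is positive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import bias as _bias
from .bias import FLANK, N_CENTERS, N_SIZES, BiasModel
from .fragments import Track, fragment_weight_matrix, insertion_track
from .occupancy import OccupancyTrack, SizeDistribution, gaussian_kernel, smooth_track
from .vplot import VPlotMatrix

LLR_EPS = 1e-9
SMOOTH_WINDOW = 25  # bp of support for the candidate-finding Gaussian
CALL_SPACING = 120  # bp exclusion radius of the nonredundant map
Z_MIN_DEFAULT = 3.0
LLR_MIN_DEFAULT = 0.0


class CallerError(ValueError):
    pass


@dataclass
class SignalTrack:
    """Raw, background, normalized and smoothed cross-correlation signal."""

    chrom: str
    start: int
    raw: np.ndarray
    background: np.ndarray
    norm: np.ndarray
    smoothed: np.ndarray
    sd: np.ndarray
    sum_f: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(len(self.raw))

    def as_track(self, which: str) -> Track:
        return Track(self.chrom, self.start, getattr(self, which))


@dataclass
class NucleosomeCall:
    chrom: str
    dyad: int
    signal: float
    z: float
    llr: float
    occ: float = np.nan
    occ_lo: float = np.nan
    occ_hi: float = np.nan
    nonredundant: bool = False


@dataclass
class NFRRegion:
    chrom: str
    start: int
    end: int
    mean_occ: float
    left_call: Optional[int] = None  # flanking dyad positions (None = region edge)
    right_call: Optional[int] = None


def raw_signal(F: np.ndarray, V: np.ndarray) -> float:
    """Cross-correlation score at one position: elementwise product sum."""
    F = np.asarray(F, dtype=float)
    V = np.asarray(V, dtype=float)
    if F.shape != V.shape:
        raise CallerError(f"shape mismatch: F {F.shape} vs V {V.shape}")
    return float((F * V).sum())


def background_and_sd(B: np.ndarray, V: np.ndarray, sum_f: float) -> tuple:
    """Expected background signal and its standard deviation.

    With n ~ Multinomial(SumF, B) fragments, the background is SumF*(B.V)
    and its variance SumF*(sum b(1-b)v^2 - sum_{k!=l} b_k b_l v_k v_l).  The
    cross term equals (sum b v)^2 - sum b^2 v^2 exactly, which is how it is
    computed here.
    """
    B = np.asarray(B, dtype=float)
    V = np.asarray(V, dtype=float)
    if B.shape != V.shape:
        raise CallerError(f"shape mismatch: B {B.shape} vs V {V.shape}")
    if sum_f <= 0:
        return 0.0, 0.0
    bv = float((B * V).sum())
    bv2 = float((B * V * V).sum())
    b2v2 = float((B * B * V * V).sum())
    var = sum_f * ((bv2 - b2v2) - (bv * bv - b2v2))
    return bv * sum_f, float(np.sqrt(max(var, 0.0)))


def zscore(raw: float, background: float, sd: float) -> float:
    if sd > 0:
        return (raw - background) / sd
    if raw == background:
        return 0.0
    return np.inf if raw > background else -np.inf


def log_likelihood_ratio(F: np.ndarray, V: np.ndarray, B: np.ndarray) -> float:
    """LLR of the template-times-bias model over the bias-only model.

    Fragment counts F are scored under p1 ~ V*B + eps and p0 ~ B + eps (each
    normalized over the matrix); the ratio is sum F * (log p1 - log p0).
    """
    F = np.asarray(F, dtype=float)
    if F.sum() <= 0:
        return 0.0
    p1 = np.asarray(V, dtype=float) * np.asarray(B, dtype=float) + LLR_EPS
    p0 = np.asarray(B, dtype=float) + LLR_EPS
    p1 = p1 / p1.sum()
    p0 = p0 / p0.sum()
    return float((F * (np.log(p1) - np.log(p0))).sum())


def _row_correlate(M: np.ndarray, V: np.ndarray) -> np.ndarray:
    """sum_s sum_c M[s, x + c] * V[s, c] for every valid x (column lag)."""
    n_out = M.shape[1] - V.shape[1] + 1
    out = np.zeros(n_out)
    for s in range(M.shape[0]):
        if M[s].any() and V[s].any():
            out += np.correlate(M[s], V[s], mode="valid")
    return out


def compute_signal(
    frags,
    region,
    V: VPlotMatrix,
    size_dist: SizeDistribution,
    bias_model: Optional[BiasModel] = None,
    genome=None,
    mnase: bool = False,
) -> SignalTrack:
    """Signal, background, normalized signal, SD and smoothed tracks.

    ``region`` is (chrom, start, end); the fragment window requires the
    region padded by 60 bp and (for the bias background) sequence padded a
    further 125 + 10 bp.  In MNase mode (or with no bias model) the
    background places fragments uniformly given the size distribution.
    """
    chrom, start, end = region
    n = end - start
    if n <= 0:
        raise CallerError("empty region")
    Vm = V.mat

    W = fragment_weight_matrix(frags, (chrom, start - FLANK, end + FLANK))
    raw = _row_correlate(W, Vm)
    sum_f = _row_correlate(W, np.ones_like(Vm))

    if mnase or bias_model is None:
        Bu = _bias.uniform_background(size_dist)
        bv = float((Bu * Vm).sum())
        bv2 = float((Bu * Vm * Vm).sum())
        b2v2 = float((Bu * Bu * Vm * Vm).sum())
        background = bv * sum_f
        var = sum_f * ((bv2 - b2v2) - (bv * bv - b2v2))
        sd = np.sqrt(np.clip(var, 0.0, None))
    else:
        if genome is None:
            raise CallerError("a genome is required when a bias model is used")
        pad = _bias.PROP_PAD
        prop = _bias.insertion_propensity(
            bias_model, genome, (chrom, start - pad, end + pad)
        )
        U = _bias._background_rows(prop, size_dist.restrict(_bias.SIZE_LO, _bias.SIZE_HI))
        # per-position window sums via correlation of U's rows
        ones = np.ones_like(Vm)
        # U spans [start - pad, end + pad); windows need [x-60, x+60] columns
        i0 = pad - FLANK
        Uw = U[:, i0 : i0 + n + 2 * FLANK]
        Z_tot = _row_correlate(Uw, ones)
        ubv = _row_correlate(Uw, Vm)
        ubv2 = _row_correlate(Uw, Vm * Vm)
        ub2v2 = _row_correlate(Uw * Uw, Vm * Vm)
        with np.errstate(divide="ignore", invalid="ignore"):
            bv = np.where(Z_tot > 0, ubv / Z_tot, 0.0)
            bv2 = np.where(Z_tot > 0, ubv2 / Z_tot, 0.0)
            b2v2 = np.where(Z_tot > 0, ub2v2 / (Z_tot * Z_tot), 0.0)
        background = bv * sum_f
        var = sum_f * ((bv2 - b2v2) - (bv * bv - b2v2))
        sd = np.sqrt(np.clip(var, 0.0, None))

    norm = raw - background
    kernel = gaussian_kernel(SMOOTH_WINDOW, SMOOTH_WINDOW / 6.0)
    smoothed = smooth_track(norm, kernel)
    return SignalTrack(chrom, start, raw, background, norm, smoothed, sd, sum_f)


def _local_maxima(y: np.ndarray) -> list[int]:
    """Strict local maxima; a flat plateau yields its (left-of-)center."""
    n = len(y)
    out: list[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def candidate_dyads(signal: SignalTrack) -> list[tuple]:
    """Candidate dyads: local maxima of (smoothed + normalized) signal where
    the normalized signal is positive.  Returns (position, norm value)."""
    combined = signal.smoothed + signal.norm
    return [
        (signal.start + i, float(signal.norm[i]))
        for i in _local_maxima(combined)
        if signal.norm[i] > 0
    ]


def nonredundant_map(candidates: Sequence[tuple], spacing: int = CALL_SPACING) -> list[int]:
    """Greedy thinning: take the highest-scoring candidate, then the next
    highest not within ``spacing`` bp (inclusive) of any kept position.
    Ties break to the leftmost position."""
    ordered = sorted(candidates, key=lambda pc: (-pc[1], pc[0]))
    kept: list[int] = []
    for pos, _ in ordered:
        if all(abs(pos - k) > spacing for k in kept):
            kept.append(pos)
    return sorted(kept)


def filter_calls(
    calls: Sequence[NucleosomeCall],
    z_min: float = Z_MIN_DEFAULT,
    llr_min: float = LLR_MIN_DEFAULT,
) -> list[NucleosomeCall]:
    """Keep calls with Z strictly above z_min and LLR strictly above llr_min."""
    return [c for c in calls if c.z > z_min and c.llr > llr_min]


def score_positions(
    positions,
    frags,
    region,
    V: VPlotMatrix,
    size_dist: SizeDistribution,
    bias_model: Optional[BiasModel] = None,
    genome=None,
    mnase: bool = False,
    occ: Optional[OccupancyTrack] = None,
) -> list[NucleosomeCall]:
    """Z-score, LLR and occupancy annotation for given dyad positions."""
    chrom, start, end = region
    Vm = V.mat
    W = fragment_weight_matrix(frags, (chrom, start - FLANK, end + FLANK))
    sd_r = size_dist.restrict(_bias.SIZE_LO, _bias.SIZE_HI)
    if not (mnase or bias_model is None):
        if genome is None:
            raise CallerError("a genome is required when a bias model is used")
        pad = _bias.PROP_PAD
        prop = _bias.insertion_propensity(
            bias_model, genome, (chrom, start - pad, end + pad)
        )
    calls = []
    for pos in positions:
        i = pos - (start - FLANK)
        F = W[:, i - FLANK : i + FLANK + 1]
        if mnase or bias_model is None:
            B = _bias.uniform_background(size_dist)
        else:
            B = _bias.background_matrix(prop, sd_r, pos)
        rs = raw_signal(F, Vm)
        bg, sd = background_and_sd(B, Vm, float(F.sum()))
        call = NucleosomeCall(
            chrom=chrom,
            dyad=int(pos),
            signal=rs - bg,
            z=zscore(rs, bg, sd),
            llr=log_likelihood_ratio(F, Vm, B),
        )
        if occ is not None:
            call.occ = float(occ.interp(pos))
            lo, hi = occ.interp_ci(pos)
            call.occ_lo, call.occ_hi = float(lo), float(hi)
        calls.append(call)
    return calls


def call_nucleosomes(
    frags,
    region,
    V: VPlotMatrix,
    size_dist: SizeDistribution,
    bias_model: Optional[BiasModel] = None,
    genome=None,
    mnase: bool = False,
    occ: Optional[OccupancyTrack] = None,
    z_min: float = Z_MIN_DEFAULT,
    llr_min: float = LLR_MIN_DEFAULT,
):
    """Full calling pass over one region.

    Returns (signal_track, filtered_calls, redundant_calls).  Redundant calls
    (all candidates passing the Z/LLR filters, before greedy thinning) retain
    rotational-positioning detail; the nonredundant flag marks members of the
    greedily thinned map.
    """
    signal = compute_signal(frags, region, V, size_dist, bias_model, genome, mnase)
    cands = candidate_dyads(signal)
    scored = score_positions(
        [p for p, _ in cands], frags, region, V, size_dist, bias_model, genome, mnase, occ
    )
    # the nonredundant map is thinned over all candidates, then thresholds apply
    nonred = set(nonredundant_map(cands))
    for c in scored:
        c.nonredundant = c.dyad in nonred
    filtered = filter_calls(scored, z_min, llr_min)
    return signal, [c for c in filtered if c.nonredundant], filtered


FOOTPRINT_HALF = 74  # bp from a dyad to the first unwrapped base (147-bp wrap)


def call_nfrs(
    occ: OccupancyTrack,
    calls: Sequence[NucleosomeCall],
    frags,
    region,
    occ_max: float = 0.1,
    min_insertion_density: float = 0.01,
    short_size: int = 100,
) -> list[NFRRegion]:
    """Nucleosome-free regions between adjacent nonredundant calls.

    The candidate NFR between two adjacent calls is the DNA outside both
    nucleosome footprints, [left_dyad + 74, right_dyad - 74) (clipped to the
    region; region edges bound terminal candidates).  A candidate is emitted
    when (a) the smoothed upper 90% CI of occupancy dips below ``occ_max``
    somewhere inside it — the interval genuinely reaches nucleosome-free
    occupancy, which a gap hiding an uncalled nucleosome never does — and
    (b) the short-fragment (< ``short_size`` bp) insertion density over it is
    at least ``min_insertion_density`` per bp, the coverage gate that
    distinguishes nucleosome depletion from missing data.
    """
    chrom, rstart, rend = region
    dyads = sorted(c.dyad for c in calls if c.nonredundant) or sorted(
        c.dyad for c in calls
    )
    short = [f for f in frags if f.chrom == chrom and f.adj_size < short_size]
    ins = insertion_track(short, (chrom, rstart, rend))

    grid = occ.positions
    out: list[NFRRegion] = []
    edges = [(None, rstart)] + [(d, d) for d in dyads] + [(None, rend)]
    for (ld, lpos), (rd, rpos) in zip(edges[:-1], edges[1:]):
        s = lpos + FOOTPRINT_HALF if ld is not None else lpos
        e = rpos - FOOTPRINT_HALF if rd is not None else rpos
        s, e = max(s, rstart), min(e, rend)
        if e - s < 1:
            continue
        inside = (grid >= s) & (grid < e)
        if not inside.any() or occ.ci_hi[inside].min() >= occ_max:
            continue
        density = ins.values[s - rstart : e - rstart].sum() / (e - s)
        if density < min_insertion_density:
            continue
        out.append(
            NFRRegion(
                chrom, s, e,
                mean_occ=float(occ.alpha[inside].mean()),
                left_call=ld, right_call=rd,
            )
        )
    return out


def write_calls_tsv(calls: Sequence[NucleosomeCall], path: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write("chrom\tdyad\tsignal\tz\tllr\tocc\tocc_lo\tocc_hi\tnonredundant\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.dyad}\t{c.signal:.6g}\t{c.z:.6g}\t{c.llr:.6g}\t"
                f"{c.occ:.4f}\t{c.occ_lo:.4f}\t{c.occ_hi:.4f}\t{int(c.nonredundant)}\n"
            )
    os.replace(tmp, path)


def write_nfrs_bed(nfrs: Sequence[NFRRegion], path: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        for r in nfrs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean_occ:.4f}\n")
    os.replace(tmp, path)
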