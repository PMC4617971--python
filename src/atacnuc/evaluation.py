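"""Concordance metrics, dinucleotide periodicity and aggregate profiles.

Positional concordance compares a test dyad set against a gold standard
(e.g. chemical-mapping calls): the distance AUC summarizes the cumulative
distribution of nearest-gold distances within 73 bp, sensitivity and
specificity count mutual nearest neighbours within 25 bp, and rotational
specificity counts test calls within 1 bp of the redundant gold set.  The
dinucleotide analysis measures the ~10.5-bp periodicity of base steps in
nucleosomal DNA via the power spectral density of normalized dinucleotide
frequency profiles 19-60 bp from the dyad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bias import fetch_seq
from .fragments import Track

DINUCS = [a + b for a in "ACGT" for b in "ACGT"]
PROFILE_LO, PROFILE_HI = 19, 60
PERIOD = 10.5

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class EvaluationError(ValueError):
    pass


@dataclass
class ConcordanceReport:
    distance_auc: float
    sensitivity: float
    specificity: float
    rotational_specificity: float
    n_test: int
    n_gold: int
    n_unmatched: int

    def to_dict(self) -> dict:
        return {
            "distance_auc": self.distance_auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "rotational_specificity": self.rotational_specificity,
            "n_test": self.n_test,
            "n_gold": self.n_gold,
            "n_unmatched": self.n_unmatched,
        }


def _nearest_distances(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref = np.sort(np.asarray(reference))
    q = np.asarray(query)
    idx = np.searchsorted(ref, q)
    left = np.abs(q - ref[np.clip(idx - 1, 0, len(ref) - 1)])
    right = np.abs(q - ref[np.clip(idx, 0, len(ref) - 1)])
    return np.minimum(left, right)


def distance_auc(test, gold, max_d: int = 73) -> float:
    """Area under the cumulative nearest-distance curve, normalized to [0,1].

    Test calls with no gold call within ``max_d`` are excluded; the AUC of
    the step CDF over [0, max_d] equals the mean of (max_d - d)/max_d over
    matched calls (exact, no discretization).  Returns NaN if no test call
    matches.
    """
    test = np.asarray(test)
    gold = np.asarray(gold)
    if test.size == 0 or gold.size == 0:
        raise EvaluationError("empty call set")
    d = _nearest_distances(test, gold)
    matched = d[d <= max_d]
    if matched.size == 0:
        return float("nan")
    return float(np.mean((max_d - matched) / max_d))


def sensitivity_specificity(test, gold, d: int = 25) -> tuple:
    """(sensitivity, specificity) at an inclusive distance threshold.

    Specificity: fraction of test calls with a gold call within d bp.
    Sensitivity: fraction of gold calls with a test call within d bp.
    """
    test = np.asarray(test)
    gold = np.asarray(gold)
    if test.size == 0 or gold.size == 0:
        raise EvaluationError("empty call set")
    spec = float(np.mean(_nearest_distances(test, gold) <= d))
    sens = float(np.mean(_nearest_distances(gold, test) <= d))
    return sens, spec


def rotational_specificity(test, redundant_gold, d: int = 1) -> float:
    """Fraction of test calls within d bp (inclusive) of the redundant gold
    set — a measure of rotational (helical-phase) positioning accuracy."""
    test = np.asarray(test)
    redundant_gold = np.asarray(redundant_gold)
    if test.size == 0 or redundant_gold.size == 0:
        return 0.0
    return float(np.mean(_nearest_distances(test, redundant_gold) <= d))


def concordance_report(test, gold, redundant_gold=None, max_d: int = 73, d: int = 25):
    test = np.asarray(test)
    gold = np.asarray(gold)
    dist = _nearest_distances(test, gold)
    sens, spec = sensitivity_specificity(test, gold, d)
    rot = (
        rotational_specificity(test, redundant_gold)
        if redundant_gold is not None
        else float("nan")
    )
    return ConcordanceReport(
        distance_auc=distance_auc(test, gold, max_d),
        sensitivity=sens,
        specificity=spec,
        rotational_specificity=rot,
        n_test=int(test.size),
        n_gold=int(gold.size),
        n_unmatched=int((dist > max_d).sum()),
    )


@dataclass
class DinucProfile:
    """Normalized dinucleotide frequencies by distance from the dyad."""

    distances: np.ndarray  # 19..60
    profiles: dict  # dinuc -> normalized frequency vector (mean 1)

    def psd_10p5(self, dinuc: str) -> float:
        return psd_at_period(self.profiles[dinuc], self.distances, PERIOD)


def dinuc_profile(dyads, genome, chrom: str, lo: int = PROFILE_LO, hi: int = PROFILE_HI):
    """Two-side-averaged dinucleotide frequency profiles around dyads.

    At distance d the downstream step is genome[dyad+d : dyad+d+2]; the
    upstream step is read outward, i.e. the reverse complement of
    genome[dyad-d-1 : dyad-d+1], since calls are unstranded.  Frequencies are
    normalized per dinucleotide by their mean over the window.  Dyads too
    close to a contig edge are skipped and tallied.
    """
    dyads = np.asarray(dyads, dtype=int)
    if dyads.size == 0:
        raise EvaluationError("empty dyad set")
    contig_len = len(genome[chrom])
    margin = hi + 1
    dists = np.arange(lo, hi + 1)
    counts = {dn: np.zeros(len(dists)) for dn in DINUCS}
    n_skipped = 0
    for dy in dyads:
        if dy - margin < 0 or dy + margin + 1 >= contig_len:
            n_skipped += 1
            continue
        seq = fetch_seq(genome, chrom, dy - margin, dy + margin + 2)
        center = margin
        for di, d in enumerate(dists):
            plus = seq[center + d : center + d + 2]
            minus = seq[center - d - 1 : center - d + 1].translate(_COMPLEMENT)[::-1]
            for step in (plus, minus):
                if step in counts:
                    counts[step][di] += 1
    total = dyads.size - n_skipped
    if total == 0:
        raise EvaluationError("all dyads fell within the contig-edge margin")
    profiles = {}
    for dn, c in counts.items():
        freq = c / (2 * total)
        mean = freq.mean()
        profiles[dn] = freq / mean if mean > 0 else np.zeros_like(freq)
    prof = DinucProfile(dists, profiles)
    prof.n_skipped = n_skipped
    return prof


def psd_at_period(vector, distances=None, period: float = PERIOD) -> float:
    """Squared modulus of the Fourier component at 1/period cycles per bp.

    The frequency does not fall on an integer DFT bin for a 42-point series,
    so the component is computed by direct complex-exponential projection of
    the mean-centered profile.
    """
    v = np.asarray(vector, dtype=float)
    if distances is None:
        distances = np.arange(PROFILE_LO, PROFILE_LO + len(v))
    d = np.asarray(distances, dtype=float)
    centered = v - v.mean()
    comp = np.sum(centered * np.exp(-2j * np.pi * d / period))
    return float(np.abs(comp) ** 2)


def aggregate_track(track: Track, anchors, flank: int) -> np.ndarray:
    """Strand-aware mean of track values around anchor positions.

    ``anchors`` is a sequence of (position, strand) with strand '+'/'-';
    minus-strand windows are reversed so the profile reads 5'->3'.  Anchors
    whose window leaves the track are dropped; all dropped -> fatal.
    """
    prof = np.zeros(2 * flank + 1)
    n = 0
    for pos, strand in anchors:
        lo, hi = pos - flank, pos + flank + 1
        if lo < track.start or hi > track.end:
            continue
        window = np.asarray(track.slice(lo, hi), dtype=float)
        if strand == "-":
            window = window[::-1]
        prof += window
        n += 1
    if n == 0:
        raise EvaluationError("no anchors with a full window inside the track")
    return prof / n
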