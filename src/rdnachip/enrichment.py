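"""Negative-binomial background model and enrichment peak calls.

Binned fragment-midpoint counts form the background; a negative binomial
(mean mu, dispersion r, variance mu + mu^2/r) is fitted by the method of
moments, falling back to Poisson when the counts are not over-dispersed.
Candidate peaks are threshold crossings of the smoothed track; each peak's
fragment count, rescaled to per-bin units, receives an upper-tail p-value
under the background model, with Benjamini-Hochberg correction across
peaks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signal import FragmentSet, SignalTrack

DEFAULT_BIN = 200


@dataclass(frozen=True)
class NBModel:
    mu: float
    size: float | None  # dispersion r; None in Poisson fallback
    fit_mode: str  # 'nb' | 'poisson_fallback'

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.fit_mode == "nb" and (self.size is None or self.size <= 0):
            raise ValueError("NB fit requires size > 0")

    def to_dict(self) -> dict:
        return {"mu": self.mu, "size": self.size, "fit_mode": self.fit_mode}


@dataclass
class Peak:
    ref_name: str
    start: int
    end: int
    summit: int
    height: float
    count: int
    p_value: float
    q_value: float = field(default=math.nan)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("peak start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak")


def bin_counts(
    fragments: FragmentSet,
    region: tuple[str, int, int] | None = None,
    bin: int = DEFAULT_BIN,
) -> np.ndarray:
    """Fragment-midpoint counts per half-open bin (boundary goes right)."""
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if region is None:
        region = (fragments.ref_name, 0, fragments.reference_length)
    _, start, end = region
    n_bins = -(-(end - start) // bin)
    mids = fragments.midpoints
    inside = (mids >= start) & (mids < end)
    idx = np.floor((mids[inside] - start) / bin).astype(np.int64)
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def fit_nb_background(counts: np.ndarray, exclude_mask: np.ndarray | None = None) -> NBModel:
    """Method-of-moments NB fit on non-excluded bins.

    mu = sample mean m; r = m^2 / (v - m) with v the unbiased sample
    variance. If v <= m (no over-dispersion) the model degrades to Poisson.
    """
    counts = np.asarray(counts, dtype=float)
    if exclude_mask is not None:
        counts = counts[~np.asarray(exclude_mask, dtype=bool)]
    if counts.size < 2:
        raise ValueError("need >= 2 non-excluded bins to fit the background")
    m = float(np.mean(counts))
    v = float(np.var(counts, ddof=1))
    if v > m and m > 0:
        return NBModel(mu=m, size=m * m / (v - m), fit_mode="nb")
    return NBModel(mu=m, size=None, fit_mode="poisson_fallback")


def nb_pvalue(observed: int, model: NBModel) -> float:
    """Upper-tail P(X >= observed) under the fitted background.

    observed = 0 covers the whole support, so p is exactly 1.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if observed == 0:
        return 1.0
    if model.fit_mode == "poisson_fallback":
        return float(stats.poisson.sf(observed - 1, model.mu))
    p_success = model.size / (model.size + model.mu)
    return float(stats.nbinom.sf(observed - 1, model.size, p_success))


def bh_qvalues(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate(([0], starts))
    if mask.size and mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return list(zip(starts.tolist(), ends.tolist()))


def call_peaks(
    track: SignalTrack,
    fragments: FragmentSet,
    model: NBModel,
    threshold_sd: float = 4.0,
    min_len: int = 100,
    merge_gap: int = 200,
    bin: int = DEFAULT_BIN,
) -> list[Peak]:
    """Threshold the track against its own background, then score peaks.

    The threshold is mean + threshold_sd * sd of the track background,
    re-estimated once after masking first-pass candidates. Runs closer
    than ``merge_gap`` are merged and runs shorter than ``min_len``
    dropped. Each peak's fragment-midpoint count, rescaled to per-``bin``
    units, is tested against the NB background; BH correction across the
    called peaks yields q-values. Summits break ties leftmost.
    """
    v = track.values
    if v.size == 0 or not np.any(v > 0):
        return []
    m1, s1 = float(np.mean(v)), float(np.std(v))
    cand = v > m1 + threshold_sd * s1
    bg = v[~cand]
    if bg.size == 0:
        bg = v
    m2, s2 = float(np.mean(bg)), float(np.std(bg))
    mask = v > m2 + threshold_sd * s2
    runs = _runs(mask)
    if not runs:
        return []

    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_len]
    if not kept:
        return []

    mids = fragments.midpoints
    peaks = []
    for s, e in kept:
        a_start, a_end = track.start + s, track.start + e
        count = int(np.count_nonzero((mids >= a_start) & (mids < a_end)))
        scaled = int(round(count * bin / (a_end - a_start)))
        seg = v[s:e]
        summit = a_start + int(np.argmax(seg))
        peaks.append(
            Peak(
                ref_name=track.ref_name,
                start=a_start,
                end=a_end,
                summit=summit,
                height=float(seg.max()),
                count=count,
                p_value=nb_pvalue(scaled, model),
            )
        )
    q = bh_qvalues([p.p_value for p in peaks])
    for pk, qv in zip(peaks, q):
        pk.q_value = float(qv)
    return peaks


def call_peaks_auto(
    track: SignalTrack,
    fragments: FragmentSet,
    threshold_sd: float = 4.0,
    min_len: int = 100,
    merge_gap: int = 200,
    bin: int = DEFAULT_BIN,
) -> tuple[list[Peak], NBModel]:
    """Fit the background with candidate bins masked, then call peaks.

    First-pass candidates (track threshold) define the exclusion mask for
    the NB fit, so planted enrichment does not inflate the null.
    """
    counts = bin_counts(fragments, (track.ref_name, track.start, track.end), bin)
    v = track.values
    m1, s1 = float(np.mean(v)), float(np.std(v))
    cand = v > m1 + threshold_sd * s1
    n_bins = counts.size
    pad = np.zeros(n_bins * bin, dtype=bool)
    pad[: v.size] = cand
    exclude = pad.reshape(n_bins, bin).any(axis=1)
    if np.count_nonzero(~exclude) < 10:
        exclude = np.zeros(n_bins, dtype=bool)
    model = fit_nb_background(counts, exclude)
    peaks = call_peaks(track, fragments, model, threshold_sd, min_len, merge_gap, bin)
    return peaks, model


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """BED6+ output: score = -10*log10(p) capped at 1000; extra columns
    summit offset, fragment count, p and q."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks, start=1):
            if pk.p_value > 0:
                score = min(1000, int(round(-10.0 * math.log10(pk.p_value))))
            else:
                score = 1000
            fh.write(
                f"{pk.ref_name}\t{pk.start}\t{pk.end}\tpeak_{i}\t{score}\t.\t"
                f"{pk.summit - pk.start}\t{pk.count}\t{pk.p_value:.6g}\t{pk.q_value:.6g}\n"
            )


def model_report(model: NBModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")
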