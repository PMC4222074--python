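"""Per-subject segmentation of log2-ratio profiles and CNA calling.

Two calling regimes coexist:

* noise-adaptive calls (:func:`call_aberrations`): a segment is called when
  its absolute mean exceeds the profile's internal noise, estimated as
  one-fourth of the median absolute difference between consecutive probes,
  with a minimum of 3 consecutive probes; amplification is a log2 ratio
  above 1.0;
* fixed-threshold calls (:func:`call_cna_dgs`): segments kept when
  |mean| >= 0.15, per-segment FDR < 1e-05, >= 10 probes and >= 1 kb, the
  conjunctive filter that feeds recurrent-region discovery.

Segmentation itself is recursive circular binary segmentation: the maximal
arc statistic is tested against a permutation null and the split is accepted
when the permutation p-value falls below ``alpha``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _cbs
from .exceptions import ConfigurationError, UndefinedNoiseError

__all__ = [
    "GenomicProfile",
    "Segment",
    "CnaCall",
    "DgsThresholds",
    "profile_noise",
    "segment_profile",
    "segment_fdrs",
    "call_aberrations",
    "call_cna_dgs",
]


def natural_chrom_key(chrom: str):
    """Sort key placing '2' before '10' and 'X' after numerals."""
    s = str(chrom)
    m = re.match(r"(?:chr)?(\d+)$", s)
    return (0, int(m.group(1)), "") if m else (1, 0, s)


@dataclass
class GenomicProfile:
    """One subject's probe-level log2(tumor/normal) profile.

    ``probes`` has columns ``chrom``, ``pos``, ``log2ratio``; positions are
    strictly increasing within each chromosome and values are finite.
    """

    subject: str
    probes: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "pos", "log2ratio"}
        if not required.issubset(self.probes.columns):
            raise ConfigurationError(
                f"profile needs columns {sorted(required)}")
        vals = self.probes["log2ratio"].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ConfigurationError("log2 ratios must be finite")
        for chrom, sub in self.probes.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    f"probe positions not strictly increasing on {chrom}")

    @property
    def chromosomes(self) -> list:
        return sorted(self.probes["chrom"].unique(), key=natural_chrom_key)

    def chrom(self, chrom) -> tuple[np.ndarray, np.ndarray]:
        sub = self.probes[self.probes["chrom"] == chrom]
        return sub["pos"].to_numpy(), sub["log2ratio"].to_numpy(float)

    def iter_chromosomes(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for c in self.chromosomes:
            pos, val = self.chrom(c)
            yield c, pos, val

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass(frozen=True)
class Segment:
    """A contiguous run of probes with common mean; closed on probe positions."""

    chrom: str
    start: int
    end: int
    n_probes: int
    mean: float

    @property
    def length(self) -> int:
        """Segment length in bases, end - start on probe coordinates."""
        return self.end - self.start

    @property
    def end_excl(self) -> int:
        """Exclusive end for half-open interval arithmetic."""
        return self.end + 1


@dataclass(frozen=True)
class CnaCall(Segment):
    """A called copy-number aberration: gain, loss or amplification."""

    state: str = "gain"
    fdr: float = float("nan")

    def __post_init__(self):
        if self.state not in ("gain", "loss", "amplification"):
            raise ConfigurationError(f"unknown CNA state {self.state!r}")

    @property
    def polarity(self) -> str:
        """'dup' for gains/amplifications, 'del' for losses."""
        return "del" if self.state == "loss" else "dup"


def profile_noise(profile: GenomicProfile) -> float:
    """Internal noise of a profile: median(|Δ consecutive log2 ratio|) / 4.

    Differences are taken within chromosomes only and pooled across them.
    Raises :class:`UndefinedNoiseError` when no consecutive pair exists.
    """
    diffs = []
    for _, _, vals in profile.iter_chromosomes():
        if vals.size >= 2:
            diffs.append(np.abs(np.diff(vals)))
    if not diffs:
        raise UndefinedNoiseError(
            f"profile {profile.subject!r} has no consecutive probe pair")
    return float(np.median(np.concatenate(diffs)) / 4.0)


def _segment_indices(values: np.ndarray, alpha: float, n_perm: int,
                     min_width: int, rng: np.random.Generator
                     ) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns (start, stop) index pairs."""
    done: list[tuple[int, int]] = []
    queue: list[tuple[int, int]] = [(0, values.size)]
    while queue:
        a, b = queue.pop(0)
        m = b - a
        # one permutation seed per split test, drawn in deterministic order
        if m < 2 * min_width or np.ptp(values[a:b]) < 1e-12:
            done.append((a, b))
            continue
        seg = values[a:b]
        t, i, j = _cbs.max_arc_stat(seg, min_width)
        seed = int(rng.integers(2**31 - 1))
        exceed = _cbs.perm_exceed_count(seg, t, n_perm, min_width, seed)
        p = (1 + exceed) / (n_perm + 1)
        if p < alpha:
            cuts = sorted({c for c in (i, j) if 0 < c < m})
            bounds = [a] + [a + c for c in cuts] + [b]
            for s, e in zip(bounds[:-1], bounds[1:]):
                queue.append((s, e))
        else:
            done.append((a, b))
    return sorted(done)


def segment_profile(profile: GenomicProfile, alpha: float = 0.01,
                    n_perm: int = 1000, min_width: int = 2,
                    seed: int = 0) -> list[Segment]:
    """Segment a profile chromosome by chromosome.

    Parameters
    ----------
    alpha
        Permutation p-value below which a split is accepted (default 0.01).
    n_perm
        Permutations per split test; the add-one rule bounds attainable
        p-values at ``1/(n_perm+1)``.
    min_width
        Minimum probes per segment (default 2).
    seed
        Seeds the permutation stream; identical seeds give identical output.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, pos, vals in profile.iter_chromosomes():
        if vals.size == 0:
            continue
        for a, b in _segment_indices(vals, alpha, n_perm, min_width, rng):
            segments.append(Segment(
                chrom=chrom, start=int(pos[a]), end=int(pos[b - 1]),
                n_probes=b - a, mean=float(vals[a:b].mean())))
    return segments


def segment_fdrs(profile: GenomicProfile,
                 segments: Sequence[Segment]) -> np.ndarray:
    """Per-segment FDR within one profile.

    A two-sided one-sample t test of the segment's member probe log2 ratios
    against zero, BH-adjusted across all segments of the profile.  Segments
    with fewer than two probes, or zero within-segment variance at nonzero
    mean, get p approximated from a z-like bound (p -> 0 for a flat nonzero
    segment, p = 1 for a flat zero segment).
    """
    pvals = np.ones(len(segments))
    for k, seg in enumerate(segments):
        pos, vals = profile.chrom(seg.chrom)
        mask = (pos >= seg.start) & (pos <= seg.end)
        x = vals[mask]
        if x.size < 2:
            pvals[k] = 1.0
            continue
        if np.ptp(x) < 1e-15:
            pvals[k] = 1.0 if abs(x[0]) < 1e-15 else np.finfo(float).tiny
            continue
        pvals[k] = stats.ttest_1samp(x, 0.0).pvalue
    if len(segments) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def call_aberrations(segments: Sequence[Segment], noise: float,
                     min_probes: int = 3,
                     amplification_threshold: float = 1.0) -> list[CnaCall]:
    """Noise-adaptive CNA calls.

    Segments with ``n_probes >= min_probes`` and ``|mean| > noise`` are
    called; gain/loss by the sign of the mean, amplification when the mean
    exceeds ``amplification_threshold`` (log2 ratio above 1.0).  Raising the
    noise never adds a call.
    """
    if noise < 0:
        raise ConfigurationError("noise must be non-negative")
    calls = []
    for seg in segments:
        if seg.n_probes < min_probes or abs(seg.mean) <= noise:
            continue
        if seg.mean > amplification_threshold:
            state = "amplification"
        elif seg.mean > 0:
            state = "gain"
        else:
            state = "loss"
        calls.append(CnaCall(seg.chrom, seg.start, seg.end, seg.n_probes,
                             seg.mean, state=state))
    return calls


@dataclass(frozen=True)
class DgsThresholds:
    """Fixed Step-1 filters: |mean| >= 0.15, FDR < 1e-05, >= 10 probes, >= 1 kb."""

    mean_threshold: float = 0.15
    max_fdr: float = 1e-5
    min_probes: int = 10
    min_length: int = 1000
    amplification_threshold: float = 1.0

    def __post_init__(self):
        if (self.mean_threshold <= 0 or self.max_fdr <= 0
                or self.min_probes <= 0 or self.min_length <= 0):
            raise ConfigurationError("DGS thresholds must be positive")


def call_cna_dgs(segments: Sequence[Segment], fdrs: Sequence[float],
                 thresholds: DgsThresholds | None = None) -> list[CnaCall]:
    """Fixed-threshold CNA calls for recurrent-region discovery.

    All four conditions are conjunctive: mean >= +0.15 (duplication) or
    <= -0.15 (deletion); FDR strictly below 1e-05; at least 10 probes
    ("less than 10 ... filtered out"); length at least 1 kb.
    """
    thr = thresholds if thresholds is not None else DgsThresholds()
    if len(fdrs) != len(segments):
        raise ConfigurationError("fdrs must align with segments")
    calls = []
    for seg, fdr in zip(segments, fdrs):
        if abs(seg.mean) < thr.mean_threshold:
            continue
        if not fdr < thr.max_fdr:
            continue
        if seg.n_probes < thr.min_probes:
            continue
        if seg.length < thr.min_length:
            continue
        if seg.mean > thr.amplification_threshold:
            state = "amplification"
        elif seg.mean > 0:
            state = "gain"
        else:
            state = "loss"
        calls.append(CnaCall(seg.chrom, seg.start, seg.end, seg.n_probes,
                             seg.mean, state=state, fdr=float(fdr)))
    return calls
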