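"""Cohort-level recurrent CNA regions, polarity and differential analysis.

A recurrent region is a maximal genomic run over which the set of altered
subjects (and their states) stays constant, altered in at least a stated
fraction of subjects (default 10%) among those carrying at least one call
anywhere.  Regions are built by atomising the genome at the union of all
per-subject call breakpoints; calls are closed on probe positions, so atoms
use half-open arithmetic with exclusive end = closed end + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .segmentation import CnaCall, natural_chrom_key

__all__ = [
    "RecurrentRegion",
    "DifferentialCluster",
    "find_recurrent_regions",
    "classify_polarity",
    "anova_differential_regions",
    "merge_into_clusters",
    "map_features_to_regions",
    "region_subject_matrix",
    "region_state_frequencies",
]


@dataclass
class RecurrentRegion:
    """A cohort-level region with per-subject states.

    ``states`` maps subject -> 'dup' | 'del' (neutral subjects are absent);
    ``recurrence`` is altered / eligible subjects; ``start``/``end_excl`` are
    half-open.
    """

    chromosome: str
    start: int
    end_excl: int
    states: dict
    recurrence: float
    polarity: str | None = None
    mixture_fraction: float = float("nan")

    @property
    def n_altered(self) -> int:
        return len(self.states)

    def subjects_with(self, state: str) -> list:
        return [s for s, st in self.states.items() if st == state]

    @property
    def majority_state(self) -> str:
        n_dup = sum(1 for v in self.states.values() if v == "dup")
        return "dup" if n_dup * 2 >= len(self.states) else "del"


def _call_state(call: CnaCall) -> str:
    return "del" if call.state == "loss" else "dup"


def find_recurrent_regions(calls: Mapping[str, Sequence[CnaCall]],
                           min_recurrence: float = 0.10
                           ) -> list[RecurrentRegion]:
    """Recurrent CNA regions from per-subject call sets.

    The genome is partitioned at the union of all call breakpoints; maximal
    runs of adjacent atoms whose (subject -> state) map stays constant are
    merged into regions.  The recurrence denominator is the number of
    subjects with at least one call anywhere.  The cut is applied on subject
    counts: a region is kept when altered in at least
    ``round(min_recurrence * denominator)`` subjects, so a cohort of 121
    eligible subjects keeps regions altered in 12 ("at least 12 (10%)") and
    drops 11.  An empty call set gives an empty result.
    """
    eligible = [s for s, cs in calls.items() if len(cs) > 0]
    if not eligible:
        return []
    denom = len(eligible)
    min_count = int(np.floor(min_recurrence * denom + 0.5))

    regions: list[RecurrentRegion] = []
    chroms = sorted({c.chrom for cs in calls.values() for c in cs},
                    key=natural_chrom_key)
    for chrom in chroms:
        events = []  # (start, end_excl, subject, state)
        bounds = set()
        for subj in sorted(calls):
            for c in calls[subj]:
                if c.chrom != chrom:
                    continue
                events.append((c.start, c.end_excl, subj, _call_state(c)))
                bounds.update((c.start, c.end_excl))
        if not events:
            continue
        cuts = sorted(bounds)
        atoms = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            state = {subj: st for s0, e0, subj, st in events
                     if s0 <= a and e0 >= b}
            atoms.append((a, b, state))
        # merge maximal runs of contiguous atoms with identical state maps
        run_start, run_end, run_state = atoms[0]
        for a, b, state in atoms[1:]:
            if a == run_end and state == run_state:
                run_end = b
            else:
                if run_state:
                    regions.append(_finish_region(chrom, run_start, run_end,
                                                  run_state, denom))
                run_start, run_end, run_state = a, b, state
        if run_state:
            regions.append(_finish_region(chrom, run_start, run_end,
                                          run_state, denom))
    return [r for r in regions if r.n_altered >= min_count]


def _finish_region(chrom, start, end_excl, states, denom):
    return RecurrentRegion(chromosome=chrom, start=start, end_excl=end_excl,
                           states=dict(states),
                           recurrence=len(states) / denom)


def classify_polarity(region: RecurrentRegion,
                      mixture_tolerance: float = 0.0) -> str:
    """Classify a region as amp_only / del_only / mixed.

    The minority-polarity fraction among altered subjects must be strictly
    below ``mixture_tolerance`` for a pure label (0 for the strict gene rule;
    0.10 for the relaxed miRNA rule).  Sets ``polarity`` and
    ``mixture_fraction`` on the region and returns the label.
    """
    if not 0 <= mixture_tolerance < 0.5:
        raise ConfigurationError("mixture_tolerance must lie in [0, 0.5)")
    if region.n_altered == 0:
        raise ConfigurationError("region has no altered subject")
    n_dup = sum(1 for v in region.states.values() if v == "dup")
    n_del = region.n_altered - n_dup
    minority = min(n_dup, n_del) / region.n_altered
    region.mixture_fraction = minority
    if minority == 0.0:
        polarity = "amp_only" if n_dup else "del_only"
    elif minority < mixture_tolerance:
        polarity = "amp_only" if n_dup > n_del else "del_only"
    else:
        polarity = "mixed"
    region.polarity = polarity
    return polarity


def region_subject_matrix(profiles, segment_sets, regions) -> pd.DataFrame:
    """Region x subject matrix of probe-weighted mean segmented log2 ratios.

    Each probe carries the mean of the segment it belongs to; a subject's
    value for a region is the mean of those segmented values over the probes
    inside the region (half-open).  Regions with no probe for a subject get
    NaN.
    """
    subjects = [p.subject for p in profiles]
    out = np.full((len(regions), len(subjects)), np.nan)
    for j, (prof, segs) in enumerate(zip(profiles, segment_sets)):
        seg_by_chrom: dict[str, list] = {}
        for s in segs:
            seg_by_chrom.setdefault(s.chrom, []).append(s)
        for i, reg in enumerate(regions):
            if reg.chromosome not in seg_by_chrom:
                continue
            pos, _ = prof.chrom(reg.chromosome)
            segmented = np.full(pos.size, np.nan)
            for s in seg_by_chrom[reg.chromosome]:
                segmented[(pos >= s.start) & (pos <= s.end)] = s.mean
            inside = (pos >= reg.start) & (pos < reg.end_excl)
            if inside.any():
                out[i, j] = np.nanmean(segmented[inside])
    index = [f"{r.chromosome}:{r.start}-{r.end_excl}" for r in regions]
    return pd.DataFrame(out, index=index, columns=subjects)


def anova_differential_regions(segmented: pd.DataFrame, labels: pd.Series,
                               fdr_threshold: float = 1e-5) -> pd.DataFrame:
    """One-way ANOVA of each region's segmented means across histologies.

    Returns a frame indexed like ``segmented`` with columns ``F``, ``p``,
    ``fdr`` and ``significant`` (fdr < ``fdr_threshold``).  Regions where
    fewer than two groups have at least two finite values get missing
    statistics and are excluded from the BH adjustment.
    """
    labels = labels.loc[segmented.columns]
    out = pd.DataFrame(index=segmented.index,
                       columns=["F", "p", "fdr"], dtype=float)
    groups_index = {h: labels.index[labels == h] for h in labels.unique()}
    for region, row in segmented.iterrows():
        samples = []
        for h, idx in groups_index.items():
            vals = row.loc[idx].dropna().to_numpy()
            if vals.size >= 2:
                samples.append(vals)
        if len(samples) < 2:
            continue
        if np.ptp(np.concatenate(samples)) < 1e-15:
            out.loc[region, ["F", "p"]] = 0.0, 1.0
            continue
        f, p = stats.f_oneway(*samples)
        out.loc[region, ["F", "p"]] = f, p
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"],
                                               method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


@dataclass
class DifferentialCluster:
    """Adjacent differential regions whose aberration frequencies agree.

    Within a cluster every (state, histology) frequency stays within the
    merge tolerance (percentage points) of the cluster's first region.
    """

    chromosome: str
    start: int
    end_excl: int
    members: list = field(default_factory=list)
    frequencies: pd.DataFrame | None = None  # anchor region's table
    anova_p: float = float("nan")
    fdr: float = float("nan")


def region_state_frequencies(regions: Sequence[RecurrentRegion],
                             labels: pd.Series) -> list[pd.DataFrame]:
    """Per-region table of aberration frequency (%) per state and histology."""
    groups = {h: (labels == h).sum() for h in sorted(labels.unique())}
    tables = []
    for reg in regions:
        tab = pd.DataFrame(0.0, index=["dup", "del"], columns=list(groups))
        for subj, st in reg.states.items():
            if subj in labels.index:
                tab.at[st, labels[subj]] += 1
        for h, n_h in groups.items():
            tab[h] = 100.0 * tab[h] / max(n_h, 1)
        tables.append(tab)
    return tables


def merge_into_clusters(regions: Sequence[RecurrentRegion],
                        frequencies: Sequence[pd.DataFrame],
                        tolerance: float = 1.0,
                        pvalues: Sequence[float] | None = None,
                        fdrs: Sequence[float] | None = None
                        ) -> list[DifferentialCluster]:
    """Greedy left-to-right merge of adjacent regions into clusters.

    Regions must be ordered by genomic position.  A region joins the running
    cluster while every (state, histology) frequency differs from the
    cluster's *first* region by at most ``tolerance`` percentage points and
    the chromosome matches; clusters never span chromosomes.
    """
    clusters: list[DifferentialCluster] = []
    current: DifferentialCluster | None = None
    anchor: pd.DataFrame | None = None
    for k, (reg, freq) in enumerate(zip(regions, frequencies)):
        p = pvalues[k] if pvalues is not None else float("nan")
        q = fdrs[k] if fdrs is not None else float("nan")
        joins = (current is not None
                 and reg.chromosome == current.chromosome
                 and (freq - anchor).abs().to_numpy().max() <= tolerance)
        if joins:
            current.members.append(reg)
            current.end_excl = max(current.end_excl, reg.end_excl)
            current.anova_p = min(current.anova_p, p) \
                if np.isfinite(current.anova_p) else p
            current.fdr = min(current.fdr, q) \
                if np.isfinite(current.fdr) else q
        else:
            current = DifferentialCluster(
                chromosome=reg.chromosome, start=reg.start,
                end_excl=reg.end_excl, members=[reg], frequencies=freq,
                anova_p=p, fdr=q)
            anchor = freq
            clusters.append(current)
    return clusters


def map_features_to_regions(regions: Sequence[RecurrentRegion],
                            annotation: pd.DataFrame,
                            warn: bool = True) -> dict[int, list]:
    """Assign features to every region their interval overlaps by >= 1 base.

    ``annotation`` is indexed by feature with columns chrom, start, end
    (0-based half-open).  Features on chromosomes absent from the region set
    are skipped (with a warning).  Returns region index -> feature id list.
    """
    import warnings

    region_chroms = {r.chromosome for r in regions}
    known = annotation["chrom"].isin(region_chroms)
    if warn and (~known).any():
        unknown = sorted(annotation.loc[~known, "chrom"].unique(),
                         key=natural_chrom_key)
        warnings.warn(f"skipping features on chromosomes without regions: "
                      f"{unknown}", stacklevel=2)
    out: dict[int, list] = {i: [] for i in range(len(regions))}
    for i, reg in enumerate(regions):
        sub = annotation[annotation["chrom"] == reg.chromosome]
        hit = (sub["start"] < reg.end_excl) & (sub["end"] > reg.start)
        out[i] = sub.index[hit].tolist()
    return out
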