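"""Seeded synthetic cohorts with planted copy-number drivers.

The generator emulates the statistical structure the driver search assumes in
a paired tumor/normal design: per-subject probe-level log2(T/N) ratios with
i.i.d. Gaussian probe noise, recurrent amplified or deleted regions carried by
a configurable fraction of subjects (optionally biased by histology), driver
genes whose expression tracks their copy state, correlated target-gene
modules induced by a shared latent factor (the scaled driver signal), a
background of independent-noise genes of which a configurable fraction carry
histology main effects, and an miRNA matrix in which miRNAs residing inside
an altered region inherit its dosage effect.

Every stage-level random stream derives deterministically from the single
``SimConfig.seed``, so identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, CoordinateError
from .segmentation import GenomicProfile

__all__ = [
    "PlantedRegion",
    "SimConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_cohort_config",
    "simulate_network",
]

HISTOLOGIES = ("AC", "SCC", "LCC")


@dataclass(frozen=True)
class PlantedRegion:
    """A planted recurrent CNA with an optional driver gene.

    ``mean_amplitude`` is the log2-ratio shift of carrier probes inside
    [start, end); its sign must match ``polarity``.  ``target_effect`` is the
    log2 expression shift per copy state applied to the driver (and to any
    miRNA inside the region), so the carrier-vs-noncarrier fold change of the
    driver is ``2**target_effect`` in expectation.
    """

    chromosome: str
    start: int
    end: int
    polarity: str  # "amplification" | "deletion"
    mean_amplitude: float
    carrier_fraction: float
    histology_bias: dict | None = None
    driver_gene: str | None = None
    n_targets: int = 0
    target_effect: float = 0.0

    def __post_init__(self):
        if self.polarity not in ("amplification", "deletion"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if not 0 < self.carrier_fraction <= 1:
            raise ConfigurationError("carrier_fraction must lie in (0, 1]")
        if self.polarity == "amplification" and self.mean_amplitude <= 0:
            raise ConfigurationError("amplification needs positive amplitude")
        if self.polarity == "deletion" and self.mean_amplitude >= 0:
            raise ConfigurationError("deletion needs negative amplitude")
        if self.end <= self.start:
            raise ConfigurationError("region end must exceed start")

    @property
    def signed_effect(self) -> float:
        return self.target_effect if self.polarity == "amplification" \
            else -self.target_effect


@dataclass
class SimConfig:
    """Cohort-generator configuration; defaults are the study conditions.

    The cohort emulated by default mirrors a ~120-subject NSCLC series with
    histology proportions AC:SCC:LCC close to 46:41:11 and three planted
    amplified driver regions; see :func:`default_cohort_config`.
    """

    n_subjects: int = 120
    n_chromosomes: int = 3
    probes_per_chromosome: int = 40
    probe_spacing: int = 50_000
    n_genes: int = 1500
    n_mirnas: int = 150
    histology_proportions: dict = field(
        default_factory=lambda: {"AC": 57 / 120, "SCC": 50 / 120,
                                 "LCC": 13 / 120})
    planted_regions: list = field(default_factory=list)
    noise_sd_probe: float = 0.15
    noise_sd_expr: float = 0.4
    module_corr: float = 0.6
    seed: int = 0
    # background structure beyond the planted modules
    frac_histology_genes: float = 0.04
    histology_effect: float = 0.5
    mirna_dosage: bool = True

    def __post_init__(self):
        if abs(sum(self.histology_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("histology_proportions must sum to 1")
        if set(self.histology_proportions) - set(HISTOLOGIES):
            raise ConfigurationError(
                f"histologies must be among {HISTOLOGIES}")
        if self.probes_per_chromosome < 30:
            raise ConfigurationError("probes_per_chromosome must be >= 30")
        if not 0 < self.module_corr < 1:
            raise ConfigurationError("module_corr must lie in (0, 1)")
        if self.noise_sd_probe < 0 or self.noise_sd_expr < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least two subjects")

    @property
    def chromosome_names(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]

    @property
    def chromosome_length(self) -> int:
        return (self.probes_per_chromosome + 1) * self.probe_spacing

    def probe_positions(self) -> np.ndarray:
        return (np.arange(self.probes_per_chromosome) + 1) * self.probe_spacing


@dataclass
class SyntheticTruth:
    """Ground truth planted in a synthetic cohort."""

    carriers: pd.DataFrame        # subjects x regions, boolean
    planted_drivers: list         # driver gene ids, one per driven region
    module_membership: dict       # target gene -> its driver
    histology: pd.Series          # subject -> label
    seed: int
    histology_genes: dict = field(default_factory=dict)  # gene -> up-label

    def to_json(self) -> str:
        payload = {
            "carriers": {r: self.carriers.index[self.carriers[r]].tolist()
                         for r in self.carriers.columns},
            "subjects": self.carriers.index.tolist(),
            "planted_drivers": list(self.planted_drivers),
            "module_membership": dict(self.module_membership),
            "histology": self.histology.to_dict(),
            "seed": int(self.seed),
            "histology_genes": dict(self.histology_genes),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        subjects = d["subjects"]
        carriers = pd.DataFrame(
            {r: [s in set(members) for s in subjects]
             for r, members in d["carriers"].items()},
            index=subjects)
        carriers = carriers[sorted(carriers.columns)]
        hist = pd.Series(d["histology"]).loc[subjects]
        hist.index.name = "subject"
        return cls(carriers=carriers, planted_drivers=d["planted_drivers"],
                   module_membership=d["module_membership"], histology=hist,
                   seed=d["seed"],
                   histology_genes=d.get("histology_genes", {}))


@dataclass
class Cohort:
    """A generated cohort bundle: profiles, matrices, annotation and truth."""

    profiles: list
    expr: pd.DataFrame          # genes x subjects, log2(T/N)
    mirna_expr: pd.DataFrame    # miRNAs x subjects, log2(T/N)
    annotation: pd.DataFrame    # feature -> chrom, start, end, feature_type
    labels: pd.Series           # subject -> histology
    truth: SyntheticTruth | None
    config: SimConfig | None = None


def default_cohort_config(seed: int = 0) -> SimConfig:
    """The default study cohort: 120 subjects, three planted amplified drivers.

    Each driver region spans 15 probes (750 kb) at amplitude +0.8 log2,
    carried by 30% of subjects; driver expression shifts by 2.5 log2 units per
    copy state (fold change ~5.7), modules of 110-130 targets at population
    correlation 0.6, probe noise SD 0.1.  The first region's carriers are
    histology-biased toward SCC, giving that driver predictive value for
    histology.
    """
    regions = [
        PlantedRegion(chromosome="1", start=500_000, end=1_250_000,
                      polarity="amplification", mean_amplitude=0.8,
                      carrier_fraction=0.30,
                      histology_bias={"SCC": 0.55, "AC": 0.12, "LCC": 0.12},
                      n_targets=110, target_effect=2.5),
        PlantedRegion(chromosome="2", start=500_000, end=1_250_000,
                      polarity="amplification", mean_amplitude=0.8,
                      carrier_fraction=0.30, n_targets=120,
                      target_effect=2.5),
        PlantedRegion(chromosome="3", start=500_000, end=1_250_000,
                      polarity="amplification", mean_amplitude=0.8,
                      carrier_fraction=0.30, n_targets=130,
                      target_effect=2.5),
    ]
    return SimConfig(planted_regions=regions, noise_sd_probe=0.1, seed=seed)


def _validate_regions(config: SimConfig) -> None:
    by_chrom: dict[str, list[PlantedRegion]] = {}
    for reg in config.planted_regions:
        if reg.chromosome not in config.chromosome_names:
            raise CoordinateError(
                f"region chromosome {reg.chromosome!r} not in genome")
        if reg.start < 0 or reg.end > config.chromosome_length:
            raise CoordinateError(
                f"region [{reg.start}, {reg.end}) outside chromosome "
                f"{reg.chromosome} (length {config.chromosome_length})")
        by_chrom.setdefault(reg.chromosome, []).append(reg)
    for chrom, regs in by_chrom.items():
        regs = sorted(regs, key=lambda r: r.start)
        for a, b in zip(regs[:-1], regs[1:]):
            if b.start < a.end:
                raise ConfigurationError(
                    f"planted regions overlap on chromosome {chrom}")


def _make_annotation(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced gene and miRNA intervals, round-robin over chromosomes."""
    rows = []
    feat_len = max(1, config.probe_spacing // 2)
    for kind, n, prefix in (("gene", config.n_genes, "G"),
                            ("mirna", config.n_mirnas, "MIR")):
        per_chrom = [n // config.n_chromosomes +
                     (1 if c < n % config.n_chromosomes else 0)
                     for c in range(config.n_chromosomes)]
        idx = 0
        for c, count in enumerate(per_chrom):
            if count == 0:
                continue
            step = config.chromosome_length / (count + 1)
            for k in range(count):
                center = (k + 1) * step
                start = int(max(0, center - feat_len / 2))
                end = min(config.chromosome_length, start + feat_len)
                rows.append((f"{prefix}{idx:05d}", config.chromosome_names[c],
                             start, end, kind))
                idx += 1
    ann = pd.DataFrame(rows, columns=["feature", "chrom", "start", "end",
                                      "feature_type"]).set_index("feature")
    return ann


def _assign_histology(config: SimConfig,
                      rng: np.random.Generator) -> pd.Series:
    """Largest-remainder allocation of subjects to histologies, shuffled."""
    n = config.n_subjects
    labels = [h for h in HISTOLOGIES if h in config.histology_proportions]
    quotas = np.array([config.histology_proportions[h] * n for h in labels])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    vec = np.repeat(labels, counts)
    rng.shuffle(vec)
    subjects = [f"S{i:03d}" for i in range(n)]
    return pd.Series(vec, index=subjects, name="histology")


def _draw_carriers(region: PlantedRegion, labels: pd.Series,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean carrier vector; counts are round(fraction x group size)."""
    n = len(labels)
    carriers = np.zeros(n, dtype=bool)
    if region.histology_bias:
        for h, grp in labels.groupby(labels):
            frac = region.histology_bias.get(h, region.carrier_fraction)
            k = int(round(frac * len(grp)))
            pos = np.flatnonzero(labels.index.isin(grp.index))
            carriers[rng.choice(pos, size=k, replace=False)] = True
    else:
        k = int(round(region.carrier_fraction * n))
        carriers[rng.choice(n, size=k, replace=False)] = True
    return carriers


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort with ground truth.

    Returns a :class:`Cohort` holding per-subject probe profiles, the gene
    and miRNA log2(T/N) expression matrices, feature annotation, histology
    labels and the :class:`SyntheticTruth`.
    """
    _validate_regions(config)
    annotation = _make_annotation(config)
    ss = np.random.SeedSequence(config.seed)
    rng_hist, rng_carrier, rng_probe, rng_expr, rng_mirna, rng_assign = (
        np.random.default_rng(s) for s in ss.spawn(6))

    labels = _assign_histology(config, rng_hist)
    subjects = labels.index.tolist()
    n = len(subjects)

    region_ids = [f"R{k:02d}" for k in range(len(config.planted_regions))]
    carriers = pd.DataFrame(
        {rid: _draw_carriers(reg, labels, rng_carrier)
         for rid, reg in zip(region_ids, config.planted_regions)},
        index=subjects, dtype=bool)
    if not region_ids:
        carriers = pd.DataFrame(index=subjects)

    genes = annotation[annotation.feature_type == "gene"]
    mirnas = annotation[annotation.feature_type == "mirna"]

    # pick driver genes and per-region gene membership
    in_any_region = pd.Series(False, index=genes.index)
    drivers: list[str] = []
    for reg in config.planted_regions:
        on_chrom = genes[genes.chrom == reg.chromosome]
        inside = on_chrom[(on_chrom.start >= reg.start)
                          & (on_chrom.end <= reg.end)]
        in_any_region.loc[on_chrom.index[
            (on_chrom.start < reg.end) & (on_chrom.end > reg.start)]] = True
        if reg.driver_gene is not None:
            g = reg.driver_gene
            if g not in inside.index:
                raise CoordinateError(
                    f"driver gene {g!r} does not lie inside "
                    f"[{reg.start}, {reg.end}) on {reg.chromosome}")
            drivers.append(g)
        elif reg.n_targets > 0 or reg.target_effect != 0:
            if inside.empty:
                raise CoordinateError(
                    f"no gene lies inside region [{reg.start}, {reg.end}) "
                    f"on chromosome {reg.chromosome}")
            mid = (reg.start + reg.end) / 2
            centers = (inside.start + inside.end) / 2
            drivers.append((centers - mid).abs().idxmin())
        else:
            drivers.append(None)

    # probe-level profiles
    positions = config.probe_positions()
    profiles = []
    for si, s in enumerate(subjects):
        frames = []
        for chrom in config.chromosome_names:
            vals = (rng_probe.normal(0.0, config.noise_sd_probe,
                                     size=positions.size)
                    if config.noise_sd_probe > 0
                    else np.zeros(positions.size))
            for rid, reg in zip(region_ids, config.planted_regions):
                if reg.chromosome == chrom and carriers.at[s, rid]:
                    inside = (positions >= reg.start) & (positions < reg.end)
                    vals[inside] += reg.mean_amplitude
            frames.append(pd.DataFrame({"chrom": chrom, "pos": positions,
                                        "log2ratio": vals}))
        profiles.append(GenomicProfile(
            subject=s, probes=pd.concat(frames, ignore_index=True)))

    # expression: background noise, then drivers, targets, histology genes
    expr = pd.DataFrame(
        rng_expr.normal(0.0, config.noise_sd_expr, size=(len(genes), n))
        if config.noise_sd_expr > 0 else np.zeros((len(genes), n)),
        index=genes.index.rename(None), columns=subjects)

    background = genes.index[~in_any_region].tolist()
    pool = list(background)
    module_membership: dict[str, str] = {}
    for rid, reg, drv in zip(region_ids, config.planted_regions, drivers):
        if drv is None:
            continue
        carrier_vec = carriers[rid].to_numpy()
        expr.loc[drv] = expr.loc[drv].to_numpy() \
            + reg.signed_effect * carrier_vec
        if reg.n_targets <= 0:
            continue
        if reg.n_targets > len(pool):
            raise ConfigurationError(
                "not enough background genes for the requested targets")
        chosen = [pool[i] for i in
                  rng_assign.choice(len(pool), size=reg.n_targets,
                                    replace=False)]
        pool = [g for g in pool if g not in set(chosen)]
        f_eff = carrier_vec.mean()
        sd_driver = np.sqrt(f_eff * (1 - f_eff) * reg.target_effect**2
                            + config.noise_sd_expr**2)
        rho = config.module_corr
        beta = (rho / np.sqrt(1 - rho**2)) * (config.noise_sd_expr / sd_driver)
        latent = expr.loc[drv].to_numpy()
        latent = latent - latent.mean()
        for g in chosen:
            expr.loc[g] = beta * latent + expr.loc[g].to_numpy()
            module_membership[g] = drv

    n_hist = int(round(config.frac_histology_genes * config.n_genes))
    histology_genes: dict[str, str] = {}
    if n_hist > 0 and pool:
        n_hist = min(n_hist, len(pool))
        chosen = [pool[i] for i in
                  rng_assign.choice(len(pool), size=n_hist, replace=False)]
        cycle = ("SCC", "AC", "LCC")
        for i, g in enumerate(chosen):
            up = cycle[i % len(cycle)]
            mask = (labels == up).to_numpy()
            expr.loc[g] = expr.loc[g].to_numpy() \
                + config.histology_effect * mask
            histology_genes[g] = up

    # miRNA matrix: noise plus dosage for miRNAs inside planted regions
    mirna_expr = pd.DataFrame(
        rng_mirna.normal(0.0, config.noise_sd_expr, size=(len(mirnas), n))
        if config.noise_sd_expr > 0 else np.zeros((len(mirnas), n)),
        index=mirnas.index.rename(None), columns=subjects)
    if config.mirna_dosage:
        for rid, reg in zip(region_ids, config.planted_regions):
            on = mirnas[(mirnas.chrom == reg.chromosome)
                        & (mirnas.start >= reg.start)
                        & (mirnas.end <= reg.end)]
            carrier_vec = carriers[rid].to_numpy()
            for m in on.index:
                mirna_expr.loc[m] = mirna_expr.loc[m].to_numpy() \
                    + reg.signed_effect * carrier_vec

    truth = SyntheticTruth(
        carriers=carriers,
        planted_drivers=[d for d in drivers if d is not None],
        module_membership=module_membership,
        histology=labels, seed=config.seed,
        histology_genes=histology_genes)
    return Cohort(profiles=profiles, expr=expr, mirna_expr=mirna_expr,
                  annotation=annotation, labels=labels, truth=truth,
                  config=config)


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write a cohort as plain-text files; round-trips through :mod:`dgsearch.io`.

    Layout: ``profiles/<subject>.seg`` (one probe per SEG row), ``expr.tsv``,
    ``mirna_expr.tsv``, ``annotation.bed`` (0-based half-open, feature type in
    column 5), ``labels.tsv`` and ``truth.json``.
    """
    from . import io as dio

    directory = Path(directory)
    (directory / "profiles").mkdir(parents=True, exist_ok=True)
    paths = {"profiles": []}
    for prof in cohort.profiles:
        p = directory / "profiles" / f"{prof.subject}.seg"
        dio.write_probe_seg(prof, p)
        paths["profiles"].append(p)
    paths["expr"] = directory / "expr.tsv"
    dio.write_matrix(cohort.expr, paths["expr"])
    paths["mirna_expr"] = directory / "mirna_expr.tsv"
    dio.write_matrix(cohort.mirna_expr, paths["mirna_expr"])
    paths["annotation"] = directory / "annotation.bed"
    dio.write_bed(cohort.annotation, paths["annotation"])
    paths["labels"] = directory / "labels.tsv"
    cohort.labels.rename("histology").to_csv(paths["labels"], sep="\t",
                                             index_label="subject")
    if cohort.truth is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(cohort.truth.to_json())
    return paths


def read_cohort(directory) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from . import io as dio

    directory = Path(directory)
    profiles = [dio.read_probe_seg(p)
                for p in sorted((directory / "profiles").glob("*.seg"))]
    expr = dio.read_matrix(directory / "expr.tsv")
    mirna = dio.read_matrix(directory / "mirna_expr.tsv")
    annotation = dio.read_bed(directory / "annotation.bed")
    labels = pd.read_csv(directory / "labels.tsv", sep="\t",
                         index_col="subject")["histology"]
    truth = None
    tpath = directory / "truth.json"
    if tpath.exists():
        truth = SyntheticTruth.from_json(tpath.read_text())
    return Cohort(profiles=profiles, expr=expr, mirna_expr=mirna,
                  annotation=annotation, labels=labels, truth=truth)


def simulate_network(genes, *, background_edge_prob: float = 0.01,
                     planted=(), seed: int = 0):
    """A gene-gene functional network with optional planted enrichment.

    Background edges are Erdos-Renyi with probability
    ``background_edge_prob``; each ``planted`` entry ``(set_a, set_b, k)``
    adds ``k`` extra distinct edges drawn uniformly between the two sets,
    creating an excess of links the enrichment test should detect.
    """
    from .nea import GeneNetwork

    genes = list(genes)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    m = len(genes)
    edges = set()
    # sparse ER sampling by expected edge count
    n_pairs = m * (m - 1) // 2
    n_bg = rng.binomial(n_pairs, background_edge_prob)
    while len(edges) < n_bg:
        i, j = rng.integers(0, m, size=2)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    for set_a, set_b, k in planted:
        a = [index[g] for g in set_a if g in index]
        b = [index[g] for g in set_b if g in index]
        added = 0
        guard = 0
        while added < k and guard < 100 * (k + 1):
            guard += 1
            i = a[rng.integers(0, len(a))]
            j = b[rng.integers(0, len(b))]
            if i != j and (min(i, j), max(i, j)) not in edges:
                edges.add((min(i, j), max(i, j)))
                added += 1
    return GeneNetwork.from_edges(
        (genes[i], genes[j]) for i, j in sorted(edges))
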