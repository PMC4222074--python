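"""End-to-end pipeline: segmentation through driver ranking, validation, NEA.

The stages mirror the three-step driver search: per-subject segmentation and
fixed-threshold CNA calling; recurrent-region discovery and polarity
classification; candidate filtering, initial correlation modules and sparse
CCA refinement; final ranking; histology-predictive validation; optional
differential-region ANOVA/cluster merging and network enrichment.  A single
seed fans out to named substreams so stages are individually reproducible,
and the report records the count surviving every filter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import drivers as drv
from . import io as dio
from . import nea as dnea
from . import predict as dpred
from . import regions as dreg
from . import segmentation as dseg
from .exceptions import ConfigurationError
from .simulate import Cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the published filter constants.

    Segment calls at |mean| >= 0.15 with FDR < 1e-05, >= 10 probes and
    >= 1 kb; recurrence >= 10%; expression SD >= 0.25; gene filters one-sided
    Welch p < 0.05 with fold change > 2 (miRNAs p < 0.01, no fold-change
    rule, < 10% polarity mixture); initial modules at p < 0.001; final
    drivers at fold change > 4 and p < 0.001; a 15-feature signature with
    1000 Monte-Carlo draws.
    """

    input_dir: str | None = None
    output_dir: str | None = None
    seed: int = 0
    # segmentation
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 500
    cbs_min_width: int = 2
    # step-1 fixed thresholds
    dgs_mean_threshold: float = 0.15
    dgs_max_fdr: float = 1e-5
    dgs_min_probes: int = 10
    dgs_min_length: int = 1000
    # cohort regions
    min_recurrence: float = 0.10
    mixture_tolerance_genes: float = 0.0
    mixture_tolerance_mirnas: float = 0.10
    anova_fdr: float = 1e-5
    cluster_tolerance: float = 1.0
    # driver filters
    sd_threshold: float = 0.25
    gene_p_max: float = 0.05
    gene_min_fold_change: float = 2.0
    mirna_p_max: float = 0.01
    min_consistency: float = 0.9
    module_p_threshold: float = 0.001
    scca_penalty: object = "auto"
    final_fold_change: float = 4.0
    final_p: float = 0.001
    # validation
    signature_size: int = 15
    cv_folds: int = 10
    mc_draws: int = 1000
    # network enrichment
    nea_n_perm: int = 1000
    nea_desired_targets: int = 100
    network_path: str | None = None
    pathways_path: str | None = None
    # stage switches
    run_anova: bool = True
    run_prediction: bool = True
    run_mirna: bool = True

    def __post_init__(self):
        for name in ("dgs_mean_threshold", "dgs_max_fdr", "min_recurrence",
                     "sd_threshold", "gene_p_max", "mirna_p_max",
                     "module_p_threshold", "final_fold_change", "final_p"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def _substream_seeds(seed: int) -> dict:
    names = ["segmentation", "scca", "montecarlo", "nea", "driver_auc"]
    ss = np.random.SeedSequence(seed)
    return {name: int(s.generate_state(1)[0] % (2**31 - 1))
            for name, s in zip(names, ss.spawn(len(names)))}


def _segment_and_call(cohort: Cohort, config: PipelineConfig, seed: int):
    thr = dseg.DgsThresholds(
        mean_threshold=config.dgs_mean_threshold,
        max_fdr=config.dgs_max_fdr, min_probes=config.dgs_min_probes,
        min_length=config.dgs_min_length)
    rng = np.random.default_rng(seed)
    segments, dgs_calls, adaptive_calls, noises = {}, {}, {}, {}
    for prof in cohort.profiles:
        sub_seed = int(rng.integers(2**31 - 1))
        segs = dseg.segment_profile(prof, alpha=config.cbs_alpha,
                                    n_perm=config.cbs_n_perm,
                                    min_width=config.cbs_min_width,
                                    seed=sub_seed)
        fdrs = dseg.segment_fdrs(prof, segs)
        noise = dseg.profile_noise(prof)
        segments[prof.subject] = segs
        noises[prof.subject] = noise
        dgs_calls[prof.subject] = dseg.call_cna_dgs(segs, fdrs, thr)
        adaptive_calls[prof.subject] = dseg.call_aberrations(segs, noise)
    return segments, dgs_calls, adaptive_calls, noises


def _driver_path(expr, annotation, regions, polarities, labels, config,
                 *, p_max, min_fc, scca_seed, feature_type):
    """Shared gene/miRNA driver search; returns (result dict, candidates,
    modules, final list).

    Candidate drivers are ``feature_type`` features inside pure-polarity
    recurrent regions; candidate targets are always variable *genes* outside
    every recurrent region.
    """
    ann = annotation[annotation.feature_type == feature_type]
    pure_idx = [i for i, pol in enumerate(polarities) if pol != "mixed"]
    pure_regions = [regions[i] for i in pure_idx]
    pure_pols = [polarities[i] for i in pure_idx]

    all_mapped = dreg.map_features_to_regions(regions, annotation,
                                              warn=False)
    in_any_region = {f for feats in all_mapped.values() for f in feats}
    mapped = dreg.map_features_to_regions(pure_regions, ann, warn=False)
    candidate_feats = sorted({f for feats in mapped.values() for f in feats})

    variable = set(drv.filter_variable_features(expr, config.sd_threshold))
    variable_candidates = [f for f in candidate_feats if f in variable]
    gene_ids = set(annotation.index[annotation.feature_type == "gene"])

    candidates = []
    best: dict[str, drv.DriverCandidate] = {}
    for ri, feats in mapped.items():
        reg = pure_regions[ri]
        pol = pure_pols[ri]
        majority = "dup" if pol == "amp_only" else "del"
        altered = reg.subjects_with(majority)
        for f in feats:
            if f not in variable or f not in expr.index:
                continue
            cand = drv.cna_expression_filter(
                expr.loc[f], altered, pol, p_max=p_max,
                min_fold_change=min_fc,
                min_consistency=config.min_consistency,
                feature=f, region_index=pure_idx[ri])
            candidates.append(cand)
            prev = best.get(f)
            if prev is None or (cand.retained, -np.nan_to_num(cand.welch_p, nan=1.0)) \
                    > (prev.retained, -np.nan_to_num(prev.welch_p, nan=1.0)):
                best[f] = cand
    retained = sorted([c for c in best.values() if c.retained],
                      key=lambda c: c.feature)

    targets = sorted((variable & set(expr.index) & gene_ids)
                     - in_any_region)
    modules: dict[str, drv.DriverModule] = {}
    corr = None
    if retained and targets:
        driver_ids = [c.feature for c in retained]
        corr, pmat = drv.pairwise_driver_correlation(expr, driver_ids,
                                                     targets)
        initial = drv.initial_modules(corr, pmat,
                                      config.module_p_threshold)
        modules = drv.refine_modules(expr, initial, corr=corr,
                                     penalty_y=config.scca_penalty,
                                     seed=scca_seed)
    final = drv.rank_and_select_drivers(
        list(best.values()), modules, fc_final=config.final_fold_change,
        p_final=config.final_p)

    counts = {
        "in_pure_recurrent_regions": len(candidate_feats),
        "variable": len(variable_candidates),
        "cna_expression_consistent": len(retained),
        "final_drivers": len(final),
    }
    result = {
        "filter_counts": counts,
        "n_candidate_targets": len(targets),
        "final_drivers": [
            {"feature": c.feature, "region_index": c.region_index,
             "polarity": c.polarity,
             "fold_change": round(c.fold_change, 6),
             "welch_p": float(c.welch_p),
             "n_targets": modules[c.feature].n_targets
             if c.feature in modules else 0}
            for c in final],
        "module_sizes": {d: m.n_targets for d, m in sorted(modules.items())},
    }
    return result, best, modules, final


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None,
                 network: dnea.GeneNetwork | None = None,
                 pathways: dict | None = None) -> dict:
    """Run every stage and return (and optionally write) the JSON report.

    ``cohort`` may be passed in memory; otherwise it is read from
    ``config.input_dir``.  The network/pathway inputs are optional; network
    enrichment runs only when both are available.  Identical seed and config
    give an identical report.
    """
    if cohort is None:
        if config.input_dir is None:
            raise ConfigurationError("need a cohort or an input_dir")
        from .simulate import read_cohort
        cohort = read_cohort(config.input_dir)
    if network is None and config.network_path:
        network = dio.read_edges(config.network_path)
    if pathways is None and config.pathways_path:
        pathways = dio.read_gmt(config.pathways_path)

    seeds = _substream_seeds(config.seed)
    report: dict = {"seed": config.seed,
                    "n_subjects": len(cohort.labels)}

    # --- segmentation and calling ---------------------------------------
    segments, dgs_calls, adaptive_calls, noises = _segment_and_call(
        cohort, config, seeds["segmentation"])
    report["segmentation"] = {
        "n_segments": int(sum(len(s) for s in segments.values())),
        "median_noise": float(np.median(list(noises.values()))),
        "n_dgs_calls": int(sum(len(c) for c in dgs_calls.values())),
        "n_subjects_with_calls": int(sum(bool(c)
                                         for c in dgs_calls.values())),
    }

    # --- recurrent regions ----------------------------------------------
    regions = dreg.find_recurrent_regions(dgs_calls, config.min_recurrence)
    gene_pols = [dreg.classify_polarity(r, config.mixture_tolerance_genes)
                 for r in regions]
    mirna_pols = [dreg.classify_polarity(r, config.mixture_tolerance_mirnas)
                  for r in regions]
    report["regions"] = {
        "n_recurrent": len(regions),
        "n_pure_gene_rule": sum(p != "mixed" for p in gene_pols),
        "n_pure_mirna_rule": sum(p != "mixed" for p in mirna_pols),
        "table": [{"chrom": r.chromosome, "start": r.start,
                   "end_excl": r.end_excl,
                   "recurrence": round(r.recurrence, 6),
                   "polarity_strict": pol}
                  for r, pol in zip(regions, gene_pols)],
    }

    # --- gene driver search ----------------------------------------------
    gene_result, gene_cands, gene_modules, gene_final = _driver_path(
        cohort.expr, cohort.annotation, regions, gene_pols, cohort.labels,
        config, p_max=config.gene_p_max,
        min_fc=config.gene_min_fold_change,
        scca_seed=seeds["scca"], feature_type="gene")
    report["genes"] = gene_result

    # --- miRNA driver search ---------------------------------------------
    if config.run_mirna and len(cohort.mirna_expr):
        mirna_expr = pd.concat([cohort.mirna_expr, cohort.expr])
        mirna_result, _, mirna_modules, mirna_final = _driver_path(
            mirna_expr, cohort.annotation, regions, mirna_pols,
            cohort.labels, config, p_max=config.mirna_p_max,
            min_fc=None, scca_seed=seeds["scca"], feature_type="mirna")
        report["mirnas"] = mirna_result
    else:
        mirna_modules, mirna_final = {}, []

    # --- histology prediction --------------------------------------------
    if config.run_prediction:
        two = cohort.labels[cohort.labels.isin(["AC", "SCC"])]
        expr2 = cohort.expr[two.index]
        clf = dpred.l1_signature(expr2, two, config.signature_size,
                                 config.cv_folds, seeds["montecarlo"])
        mc = dpred.monte_carlo_signature_pvalue(
            expr2, two, config.signature_size, config.mc_draws,
            seeds["montecarlo"], observed_auc=clf.cv_auc,
            cv_folds=config.cv_folds)
        driver_aucs = {}
        for c in gene_final:
            a, p = dpred.single_feature_auc_test(
                expr2, c.feature, two, n_draws=config.mc_draws,
                seed=seeds["driver_auc"])
            driver_aucs[c.feature] = {"auc": round(a, 6), "p": round(p, 6)}
        report["prediction"] = {
            "signature": list(map(str, clf.signature)),
            "cv_auc": round(clf.cv_auc, 6),
            "mc_p_value": round(mc.p_value, 6),
            "mc_null_median_auc": round(mc.null_median, 6),
            "driver_aucs": driver_aucs,
        }

    # --- differential-region ANOVA and clusters --------------------------
    if config.run_anova:
        atoms = dreg.find_recurrent_regions(adaptive_calls,
                                            min_recurrence=0.0)
        profiles = cohort.profiles
        seg_sets = [segments[p.subject] for p in profiles]
        mat = dreg.region_subject_matrix(profiles, seg_sets, atoms)
        anova = dreg.anova_differential_regions(mat, cohort.labels,
                                                config.anova_fdr)
        sig_mask = anova["significant"].to_numpy()
        sig_regions = [a for a, s in zip(atoms, sig_mask) if s]
        freqs = dreg.region_state_frequencies(sig_regions, cohort.labels)
        clusters = dreg.merge_into_clusters(
            sig_regions, freqs, tolerance=config.cluster_tolerance,
            pvalues=list(anova.loc[sig_mask, "p"]),
            fdrs=list(anova.loc[sig_mask, "fdr"]))
        report["anova"] = {
            "n_regions_tested": int(anova["p"].notna().sum()),
            "n_significant": int(sig_mask.sum()),
            "n_clusters": len(clusters),
        }

    # --- network enrichment ----------------------------------------------
    if network is not None and pathways is not None:
        nea_report = {}
        items = [(c.feature, gene_modules[c.feature], False)
                 for c in gene_final if c.feature in gene_modules]
        items += [(c.feature, mirna_modules[c.feature], True)
                  for c in mirna_final if c.feature in mirna_modules]
        for name, module, is_mirna in items:
            if module.n_targets == 0:
                continue
            targets, cutoff = dnea.select_targets_for_nea(
                module, desired_size=config.nea_desired_targets,
                mirna_mode=is_mirna)
            if not network.member_mask(targets).any():
                continue
            res = dnea.nea_test(targets, pathways, network,
                                n_perm=config.nea_n_perm,
                                seed=seeds["nea"])
            nea_report[name] = {
                "correlation_cutoff": cutoff,
                "n_targets_tested": len(targets),
                "pathways": [
                    {"pathway": r.pathway, "observed": r.observed_links,
                     "expected": round(r.expected_links, 4)
                     if np.isfinite(r.expected_links) else None,
                     "z": round(r.z, 4) if np.isfinite(r.z) else None,
                     "p": round(r.p, 6) if np.isfinite(r.p) else None,
                     "fdr": round(r.fdr, 6) if np.isfinite(r.fdr) else None,
                     "testable": r.testable}
                    for r in res],
            }
        report["nea"] = nea_report

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_seg(segments, out / "segments.seg")
        dio.write_seg(dgs_calls, out / "cna_calls.seg")
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    return report
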