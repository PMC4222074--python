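"""Cohort-level recurrent regions, polarity and differential clusters.

Per-subject fixed-threshold calls are atomised at the union of their
breakpoints; maximal runs with a constant altered-subject set become
regions, kept when altered in >= 10% of subjects with any call.  The
ANOVA path tests each region's segmented means across histologies and
merges significant regions into clusters whose per-state, per-histology
aberration frequencies agree within 1 percentage point.
"""

from dgsearch import (anova_differential_regions, call_cna_dgs,
                      classify_polarity, default_cohort_config,
                      find_recurrent_regions, generate_cohort,
                      merge_into_clusters, region_state_frequencies,
                      region_subject_matrix, segment_fdrs, segment_profile)

cohort = generate_cohort(default_cohort_config(seed=0))

segments, calls = {}, {}
for i, prof in enumerate(cohort.profiles):
    segs = segment_profile(prof, n_perm=300, seed=1000 + i)
    segments[prof.subject] = segs
    calls[prof.subject] = call_cna_dgs(segs, segment_fdrs(prof, segs))

regions = find_recurrent_regions(calls, min_recurrence=0.10)
print(f"{len(regions)} recurrent regions:")
for r in regions:
    pol = classify_polarity(r, mixture_tolerance=0.0)
    print(f"  chr{r.chromosome} [{r.start:,}-{r.end_excl:,}) "
          f"recurrence {r.recurrence:.2f} polarity {pol}")

seg_sets = [segments[p.subject] for p in cohort.profiles]
mat = region_subject_matrix(cohort.profiles, seg_sets, regions)
anova = anova_differential_regions(mat, cohort.labels)
print("\nANOVA across AC/SCC/LCC (BH-FDR):")
print(anova.round(6).to_string())

sig = [r for r, s in zip(regions, anova["significant"]) if s]
freqs = region_state_frequencies(sig, cohort.labels)
clusters = merge_into_clusters(sig, freqs, tolerance=1.0)
print(f"\n{len(sig)} significant regions merge into {len(clusters)} "
      "cluster(s)")
# Only the histology-biased planted region (chr1, SCC-enriched carriers)
# separates the subtypes; the unbiased regions have flat frequencies.
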