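"""Simulate a kinome-array cohort and rank the active kinases.

Builds the default study-shaped cohort (1024-substrate chip in triplicate,
six tumor-like samples with six planted active kinases), preprocesses the
arrays (QC, background correction, summarization, quantile normalization),
and prints the top of the kinase activity ranking next to the planted
ground truth. All planted kinases should appear near the top.
"""

import kinoscope as ks

cohort = ks.paper_cohort(seed=1, with_viability=False)
profiles, report = ks.preprocess_cohort(cohort.tumor_scans, cohort.layout)
print(f"{report['n_passing']}/{report['n_input']} arrays passed acquisition QC "
      f"(>= 1e6 collected hits each)")

activities = ks.infer_kinase_activity(profiles, cohort.annotation,
                                      kinase_table=cohort.kinases)
table = ks.activity_table(activities, cohort.kinases)
print("\nTop 10 kinases (rank / mean hit intensity / hits in top-100 substrates):")
print(table.head(10).to_string(index=False))

planted = sorted(cohort.truth_tumor.active_kinases)
top10 = set(table.head(10)["kinase"])
print(f"\nplanted active kinases: {planted}")
print(f"all planted recovered in top 10: {set(planted) <= top10}")
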