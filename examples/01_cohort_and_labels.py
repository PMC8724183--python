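"""Load the bundled study cohort and derive SRD responder labels.

Prints the cohort descriptives, the per-scale counts of datasets with
considerable (SRD-exceeding) improvements, and the unexpected
non-responder's changes.
"""

import rehabpredict as rp

cohort = rp.load_study_cohort()
summary = rp.summarize_cohort(cohort)
print(f"{summary['n_participants']} participants, "
      f"{summary['n_datasets']} datasets")
print(f"age  {summary['age']['mean']:.1f} +/- {summary['age']['sd']:.1f} years")
print(f"EDSS {summary['edss']['mean']:.1f} +/- {summary['edss']['sd']:.1f}")

labels = rp.label_cohort(cohort)
counts = rp.responder_counts(labels)
print("\nconsiderable improvements (change > SRD):")
for scale, srd in (("arat", 5.27), ("bbt", 8.11), ("nhpt", 5.32)):
    print(f"  {scale.upper():4s} (SRD {srd:5.2f}): {counts[scale]} of 20 datasets")

row = labels.loc["02-right"]
print("\nunexpected non-responder (participant 02, right side):")
for scale in ("arat", "bbt", "nhpt"):
    print(f"  {scale.upper():4s} change {row[f'{scale}_change']:+7.2f}"
          f"  responder: {bool(row[f'{scale}_improved'])}")
# A negative NHPT change means the timed test got slower: this participant
# had the strongest limitations at admission yet improved on no scale.
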