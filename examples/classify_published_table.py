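"""Classify the published hippocampal protein table into compensation patterns.

Loads the packaged transcription of the per-protein percent differences
(73 nuclear + 66 cytosolic instances), assigns each instance a pattern
code, and prints the pattern census plus a few named assignments.
"""

import rppatterns as rp

long = rp.table3_results()
assignments = rp.classify_all(long)

print(f"{len(assignments)} instances classified\n")
print("Pattern census (hippocampus):")
census = assignments.groupby(["fraction", "code"]).size().unstack(fill_value=0)
print(census.T.to_string())

print("\nSelected instances:")
for protein, fraction in [("CaNA", "nuclear"), ("pPKCA", "nuclear"),
                          ("BRAF", "nuclear"), ("pJNK", "nuclear")]:
    row = assignments[(assignments.protein == protein)
                      & (assignments.fraction == fraction)].iloc[0]
    print(f"  {protein:8s} {fraction:10s} -> {row.code:14s} "
          f"terms={row.terms_used:10s} residual={row.residual_pp:.1f} pp ({row.band})")

# The residual is |sum of significant terms - NL|: e.g. for BRAF the
# baseline elevation plus the failed-learning response reproduce the
# normal-learning increase to within a few percentage points, so learning
# adequacy does not depend on the drug for this protein.
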