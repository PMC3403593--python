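"""Replay of the bundled GK/WKY case-study selection tables.

Loads the published specificity TF lists and coverage tables of the
diabetic-rat (GK vs WKY) analysis that ship with the package, applies the
coverage strain-difference rule and the criterion merge, and prints the
overlap matrix and final candidates.  The 2x2 matrix counts TFs shared
between each screening-route criterion (rows) and each inference-route
criterion (columns); the final candidate set is the union of those
overlaps, with its regulated-gene pairs.
"""

from mrscreen import casestudy

report = casestudy.replay_published_selection()

print("criterion sizes:")
print(f"  screening specificity: {len(report.specificity_screening)}")
print(f"  screening coverage:    {len(report.coverage_screening)} "
      f"{sorted(report.coverage_screening)}")
print(f"  inference specificity: {len(report.specificity_inference)}")
print(f"  inference coverage:    {len(report.coverage_inference)}")
print("overlap matrix (rows: screening spec/cov; cols: inference spec/cov):")
print(f"  {report.overlap_matrix.tolist()}")
print(f"final MR candidates ({len(report.final_tfs)}):",
      ", ".join(sorted(report.final_tfs)))
print(f"regulated-gene pairs: {len(report.final_pairs)} "
      f"({len(report.final_unique_genes)} unique genes)")
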