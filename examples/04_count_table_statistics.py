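"""Proportion estimates and two-proportion z tests on in-situ count tables.

Loads the packaged in-situ tallies of lineage-labeled lung glia (cell-class
census, neuroepithelial-body contact patterns, GFAP/GFRA3 co-expression) and
recomputes each percentage with its 95% Wilson interval, plus the pairwise
pooled z tests behind the reported significance statements.
"""

from gliamine import insitu_counts, insitu_pairs, pairwise_tests, proportion_ci

counts = insitu_counts()
census = counts[counts["panel"] == "lung_glia_class_census"]
print("lung glia by class (percent of 9109 lineage-labeled cells):")
for _, row in census.iterrows():
    res = proportion_ci(int(row["k"]), int(row["n"]),
                        percent_decimals=int(row["decimals"]))
    print(f"  {row['label']:>5}: {row['k']:>5}/{row['n']} = {res.percent}% "
          f"(95% CI {res.ci_low * 100:.2f}-{res.ci_high * 100:.2f}%)")

neb = counts[counts["panel"] == "neb_contact"][["label", "k", "n"]]
tests = pairwise_tests(neb, [("basal", "intraepithelial"), ("basal", "none")])
print("\nneuroepithelial-body contact comparisons (two-proportion z):")
print(tests.to_string(index=False))
# Non-myelinating glia dominate the lung census (76%); terminal-neurosensory
# glia are rare (0.31%). Basal contact is significantly more common than
# either intra-epithelial contact or no contact (p << 0.0001).
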