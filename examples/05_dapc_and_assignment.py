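"""DAPC, diagnostic SNP ranking, and cross-validated population assignment.

DAPC reduces the genotypes with PCA and then finds the linear axes that
best discriminate the labelled populations. Held-out individuals are
assigned via Gaussian membership posteriors around the group centroids;
repeating a stratified 25% holdout ten times pools 350 test assignments
into a confusion matrix, as in marker-panel validation studies.
"""

import numpy as np

import radpop as rp

panel, truth = rp.simulate_panel(rp.study_scenario())
filtered, _ = rp.filter_panel(panel)

scan = rp.find_clusters(filtered, k_max=9, seed=1)
print(f"BIC elbow supports K = {scan.selected_k} genetic clusters")

model = rp.fit_dapc(filtered)
top = rp.rank_diagnostic_snps(model, top_n=5)
print("\nMost discriminatory SNPs (normalized contributions):")
print(top.round(4).to_string(index=False))

report = rp.crossval_assignment(filtered, seed=1)
print(f"\nPooled confusion matrix ({report.total} held-out assignments):")
print(report.confusion)
print(f"\nOverall correct-assignment rate: {100 * report.overall_rate:.1f}%")
print("Misassignments fall almost entirely inside the nearly panmictic"
      "\nlake cluster (Victoria / FETA / Igunga / Kunduchi), whose members"
      "\nare barely differentiated from one another.")
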