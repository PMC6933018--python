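"""Simulate the seven-population study design and apply the SNP filters.

The simulated panel mimics a ddRAD genotyping experiment on Nile tilapia:
140 diploid fish in 7 populations, ~2,500 candidate SNPs with a low-MAF
spectrum and 10% missing calls. Filtering keeps one SNP per ddRAD locus,
drops SNPs genotyped in under 75% of any population, and drops SNPs with
overall minor allele frequency below 5%.
"""

import radpop as rp

panel, truth = rp.simulate_panel(rp.study_scenario())
print(panel)

filtered, report = rp.filter_panel(panel)
for line in report.log_lines():
    print(" ", line)

# The removal counts always add back up to the input count:
assert (report.n_removed_multisnp + report.n_removed_missing
        + report.n_removed_maf + report.n_retained) == report.n_input
print(f"conservation holds: {report.n_input} in = {report.n_retained} kept "
      f"+ {report.n_input - report.n_retained} removed")
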