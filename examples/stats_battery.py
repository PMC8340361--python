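"""The full statistical battery on the packaged PX-domain feature table.

Five simple regressions with their matching Pearson correlations, plus the
selectivity-class and membrane-affinity tallies.  LSI-dependent analyses
drop the one domain with undetermined ligands (pairwise deletion), giving
the mixed n=50 / n=49 pattern in the output.
"""

from metstop import load_px_domain_table, run_battery

records = load_px_domain_table()
report = run_battery(records)
print(report.to_text())
# PSS~MSS is the headline relationship: domains accumulating metabolite
# modifications (MSS) in their membrane-binding sites also tend to carry
# phospho-sites there (PSS), and both indices track mRNA expression.
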