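"""Anchoring curated modification records onto sequences and site windows.

Loads the packaged metabolite-PTM table, anchors the human SNX3 records on
a membrane-binding-loop fragment, and tallies modified vs unmodified K/R
residues inside and outside the site windows.
"""

from metstop import load_ptm_site_table
from metstop.ptm_catalog import locate_in_sequence, summarize_residue_counts
from metstop.sites import SiteWindows, kr_inventory

records = load_ptm_site_table()
print(f"{len(records)} modification records across "
      f"{len({r.species for r in records})} species")
print("counting conventions:", summarize_residue_counts(records))

# A fragment spanning the SNX3 beta1-beta2 membrane-insertion loop, numbered
# from residue 39 of the full-length protein (numbering_offset = 38).
fragment = "VGVGRGRFTTYEIP"
offset = 38
human_snx3 = [r for r in records if r.protein == "SNX3" and r.species == "H. sapiens"]
for rec in human_snx3:
    loc = locate_in_sequence(rec, fragment, numbering_offset=offset)
    print(f"{rec.protein} {rec.residue} {rec.ptm_type}: fragment position "
          f"{loc.position} (verified={loc.verified})")

windows = SiteWindows((1, 10), (11, 12), (13, 14))  # loop = first window here
inv = kr_inventory(fragment, windows, human_snx3, numbering_offset=offset)
print(f"K/R inside window: {inv.inside_kr} ({inv.inside_modified} modified); "
      f"outside: {inv.outside_kr} ({inv.outside_modified} modified)")
# Both methylated arginines of the RGR motif fall inside the loop window --
# exactly the pattern the MET-stop score is designed to capture.
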