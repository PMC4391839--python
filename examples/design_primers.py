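"""Stem-loop RT-qPCR primer design and validation against the published sets.

Regenerates the stem-loop RT and forward primers for every catalogued
miRNA from its mature sequence alone and checks the 12 published assay
primer sets.
"""

import warnings

from mirscan import load_catalogue
from mirscan.primers import design_primers, validate_against_published

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    catalogue = load_catalogue()

entry = next(e for e in catalogue if e.name == "mac-miR156d")
primers = design_primers(entry.name, entry.mature)
print(f"{entry.name} mature 5'-{entry.mature}-3'")
print(f"  stem-loop RT: {primers.stemloop_rt}")
print(f"  forward:      {primers.forward}")
print(f"  universal:    {primers.universal_reverse}")

report = validate_against_published(catalogue)
exact = int(report["exact_match"].sum())
stars = report.loc[report["matches_star"], "mirna_id"].tolist()
print(f"published assays reproduced exactly: {exact}/{len(report)}")
print(f"assays matching the star strand instead: {stars}")
# the RT primer is the 37-nt backbone + reverse complement of the mature
# 3' 8 nt; the forward primer is a 14-nt tail + the mature 5' 10 nt.
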