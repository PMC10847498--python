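"""Clean a target-capture locus with the three-step filter cascade.

Builds a small alignment in memory, then applies: the 300-base absolute
minimum, the 40%-of-median relative minimum, and removal of alignment
columns where more than 95% of taxa carry no information.
"""

from saxshift.filters import (SequenceSet, drop_relative_short, drop_short,
                              strip_gappy_sites, ungapped_length)

# Aligned sequences: three good exons, one short fragment, one mid-length
# fragment; the final two columns are entirely missing data.
aln = SequenceSet([
    ("sax_alpina",   "ACGT" * 1000 + "A--"),
    ("sax_borealis", "ACGT" * 950 + "-" * 200 + "C--"),
    ("sax_montana",  "ACGT" * 900 + "N" * 400 + "T--"),
    ("fragment_1",   "ACGT" * 70 + "-" * 3720 + "---"),   # 280 bases < 300
    ("fragment_2",   "ACGT" * 300 + "-" * 2800 + "A--"),  # 1201 bases
])

step1 = drop_short(aln, min_len=300)
print(f"input sequences: {len(aln)}")
print(f"after absolute 300-base filter: {len(step1)} "
      f"({sorted(set(aln.ids()) - set(step1.ids()))} removed)")

step2 = drop_relative_short(step1, frac=0.4)
print(f"after relative 40%-of-median filter: {len(step2)} "
      f"({sorted(set(step1.ids()) - set(step2.ids()))} removed; median "
      "length among survivors of step 1 puts the threshold above "
      "fragment_2)")

site_filtered = strip_gappy_sites(step2, max_missing=0.95)
width_before = len(step2.records[0][1])
width_after = len(site_filtered.records[0][1])
print(f"alignment columns: {width_before} -> {width_after} "
      "(columns in which more than 95% of taxa are missing removed)")
print("ungapped lengths kept:",
      {rid: ungapped_length(s) for rid, s in site_filtered})
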