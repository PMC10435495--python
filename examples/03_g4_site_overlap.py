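"""Positional overlap of G-quadruplexes and protein-binding sites on L1s.

A panel of synthetic L1-like sequences is generated with canonical G4 units
planted in the 3' half; binding-site intervals are planted at the same
positions.  The co-occurrence of the two feature sets over 50 bp bins is
then tested against a hypergeometric null, with a minus-strand G4 scan as
negative control.
"""

from l1regkit import g4, synthetic as sy
from l1regkit.g4 import Interval

spec = sy.SeqSpec(
    subfamilies={"L1MdTf": sy.SubfamilySeqSpec(n_sequences=5, length=6000, n_g4=3)},
    g_freq=0.05,
)
seqs, truth_intervals, _ = sy.gen_l1_sequences(spec, seed=3)

# plant binding sites exactly at the true G4 positions (co-localized scenario)
sites = [
    Interval(iv.seq_id, iv.start, iv.end, "+", 50.0, "site")
    for iv in truth_intervals
    if iv.strand == "+"
]

g4_hits = [hit for s in seqs for hit in g4.find_g4(s)]
print(f"found {len(g4_hits)} plus-strand G4s over {len(seqs)} sequences")

profile = g4.bin_profile(g4_hits, seqs, window=50)
print(f"G4 relative positions (first 5): {profile.relative_positions[:5].round(2)}")

test = g4.overlap_test(g4_hits, sites, seqs, window=50)
control = g4.strand_control(seqs, sites, window=50)
print(f"overlap test:   {test.both_bins}/{test.a_bins} shared bins, p = {test.p:.3g}")
print(f"minus control:  {control.both_bins}/{control.a_bins} shared bins, p = {control.p:.3g}")
print("-> the planted plus-strand co-localization is highly significant,")
print("   while the reverse-strand scan shows no association.")
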