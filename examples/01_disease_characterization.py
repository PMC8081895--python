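"""Inspect the disease -> motif -> effector characterization.

Loads the packaged motif matrix for respiratory allergy (RA), allergic asthma
(AA) and non-allergic asthma (NA) and answers structural questions: how many
motifs build each disease, which motifs two diseases share, and how large the
disease-level effector sets are.
"""
from airprio import fixtures, motif_count, shared_motifs

chars = fixtures.load_disease_characterizations()
by_id = {c.disease_id: c for c in chars}

print("motifs in the catalogue:", len(chars[0].motifs))
for c in chars:
    print(f"{c.disease_id}: {motif_count(c):2d} implicated motifs, "
          f"{len(c.all_effectors):2d} distinct effector proteins")

print("shared RA/AA motifs:", sorted(shared_motifs(by_id["RA"], by_id["AA"])))
print("shared RA/NA motifs:", sorted(shared_motifs(by_id["RA"], by_id["NA"])))

# The counts mirror the characterization: allergy is built from the two
# allergy motifs (both shared with allergic asthma), non-allergic asthma from
# 12 motifs, all shared with allergic asthma's 16.
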