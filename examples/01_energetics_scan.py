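"""Score Z-DNA propensity of sequences with the thermodynamic model.

Builds a short sequence with an embedded (CG)10 repeat, scores closed-form
helices, and calls Z-prone segments.  The energies printed are kcal/mol for
flipping the helix from B- to Z-form: each dinucleotide step pays its cost
(CG 0.6, CA/TG 1.34, GG/CC 2.4, others 4.0) and the helix pays 5.0 for each
of its two BZ junctions.  Lower energy means easier Z-DNA formation.
"""

import numpy as np

from zflipon.energetics import EnergyModel, best_z_segments, segment_energy

model = EnergyModel()

print("(CG)x6 helix :", segment_energy("CG" * 6, 0, model), "kcal/mol")
print("(CA)x6 helix :", segment_energy("CA" * 6, 0, model), "kcal/mol")

rng = np.random.default_rng(0)
background = "".join(rng.choice(list("ACGT"), 400, p=[0.3, 0.2, 0.2, 0.3]))
seq = background[:180] + "CG" * 10 + background[200:]

for z in best_z_segments(seq, model):
    print(
        f"Z segment {z.interval.start}-{z.interval.end} "
        f"({z.interval.length} bp), {z.energy_per_dinuc:.2f} kcal/mol per step, "
        f"{z.energy_total:.1f} kcal/mol total"
    )
# The single call coincides with the planted (CG)10 repeat: alternating
# purine-pyrimidine steps are the cheapest to flip.
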