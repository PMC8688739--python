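"""Diversity statistics on a tiny hand-built clone table.

Builds a 4-clone repertoire dominated by one clone and prints its entropy,
clonality, R20 and top-N cumulative frequency.
"""

import pandas as pd

from clonetrace import KeyMode, Repertoire, SampleMeta, clonality, r20, \
    shannon_entropy, topn_cumulative_frequency

clones = pd.DataFrame(
    {
        "cdr3_nt": [""] * 4,
        "cdr3_aa": ["CASSDOMF", "CASSAF", "CASSBF", "CASSCF"],
        "v_gene": ["V26", "V12", "V13", "V31"],
        "d_gene": ["D1"] * 4,
        "j_gene": ["J2-7"] * 4,
        "templates": [70, 10, 10, 10],
    }
)
meta = SampleMeta("example", "m1", "allogeneic", "blood", 7)
rep = Repertoire(meta, clones, key=KeyMode.AA)

print(f"total templates:      {rep.total_templates}")
print(f"unique clones:        {rep.n_clones}")
print(f"Shannon entropy:      {shannon_entropy(rep.frequencies):.6f} bits")
print(f"clonality:            {clonality(rep):.6f}")
print(f"R20:                  {r20(rep):.6f}")
print(f"top-1 cum. frequency: {topn_cumulative_frequency(rep, 1):.2f}")

# clonality 0.32 says the repertoire is substantially skewed toward one
# clone; R20 = 0.25 means a quarter of the unique clones (here: just the
# dominant one) already carries 20% of all template mass.
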