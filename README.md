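# clonetrace

TCRβ repertoire analysis for murine bone-marrow-transplant (BMT) studies.

After allogeneic BMT, donor T cells that recognise recipient alloantigens
expand massively and drive graft-versus-host disease (GVHD) in target organs
(gut, liver, lung, skin). High-throughput sequencing of the TCRβ locus turns
this biology into clone tables — one row per rearrangement with a CDR3
sequence, V/D/J segment calls and a template count — and `clonetrace`
implements the analyses that such an experiment needs:

* **Clone-table I/O** for ImmunoSEQ-style exports and AIRR Rearrangement TSVs,
  with clonotype collapsing under three key definitions (CDR3nt+V+J,
  CDR3aa+V+J, CDR3aa) and family-level segment-label normalisation.
* **Diversity**: Shannon entropy *H = −Σ pᵢ log₂ pᵢ*, clonality
  *1 − H/log₂N* (0 = perfectly even, 1 = monoclonal), **R20** (the minimum
  clone fraction capturing 20% of template mass) and top-N cumulative
  frequencies.
* **Overlap**: shared clone counts, the averaged shared-template overlap
  metric ½(f_A + f_B), base-2 **Jensen–Shannon divergence**
  *JSD = H((x+y)/2) − (H(x)+H(y))/2* (0 = identical repertoires,
  1 = no shared clones), pairwise matrices and Venn region counts.
* **Tracking**: clone ranking with a reproducible tie policy, rank heatmaps
  of top blood/gut clones in other organs, donor trace-back with
  detectability (≥1 template in the pre-transplant graft sample), clones
  shared across replicate recipients within their top-k, and group-level
  combined top clones.
* **Gene usage**: template-weighted V/D/J segment frequencies and
  allo-vs-syn comparisons (two-tailed unpaired Student's t per segment with
  Šidák family-wise correction).
* **Simulation**: a ground-truthed generator — power-law donor pool,
  recipient-specific lognormal expansion of rare alloreactive clones,
  per-tissue Dirichlet resampling, V26-biased alloreactive labels — so every
  pipeline stage is testable without sequencing data.

## Worked example

```python
import pandas as pd
from clonetrace import KeyMode, Repertoire, SampleMeta, clonality, r20, shannon_entropy

clones = pd.DataFrame({
    "cdr3_nt": [""] * 4,
    "cdr3_aa": ["CASSDOMF", "CASSAF", "CASSBF", "CASSCF"],
    "v_gene": ["V26", "V12", "V13", "V31"],
    "d_gene": ["D1"] * 4,
    "j_gene": ["J2-7"] * 4,
    "templates": [70, 10, 10, 10],
})
rep = Repertoire(SampleMeta("example", "m1", "allogeneic", "blood", 7),
                 clones, key=KeyMode.AA)
print(f"{shannon_entropy(rep.frequencies):.6f}")  # 1.356780
print(f"{clonality(rep):.6f}")                    # 0.321610
print(f"{r20(rep):.6f}")                          # 0.250000
```

Entropy 1.36 bits out of a 2-bit maximum gives clonality 0.32: the
repertoire is substantially skewed toward one clone. R20 = 0.25 says that
25% of unique clones (here, just the dominant one) already carry 20% of all
templates.

The `examples/` directory holds one short script per capability
(diversity, overlap/JSD, clone tracking, gene usage, full report); each
builds or simulates a small input, runs the analysis and explains the
numbers it prints. A thin CLI wraps the same functions:

```sh
clonetrace simulate --out simdata --seed 7
clonetrace diversity --manifest simdata/manifest.tsv --out stats.tsv
clonetrace overlap   --manifest simdata/manifest.tsv --statistic jsd --out jsd.tsv
clonetrace report    --manifest simdata/manifest.tsv --out report/
```

Running `examples/05_full_report.py` prints the characteristic allogeneic
signature recovered from simulated data:

```
per-group means:
                     unique_clones  clonality
allogeneic                  30.500      0.662
donor_pretransplant        583.000      0.387
syngeneic                  507.312      0.377

cross-recipient clones shared within top 200: {'syngeneic': 166, 'allogeneic': 26}
```

Allogeneic recipients carry far fewer unique clones at equal depth, higher
clonality, and share almost no top clones with each other — each mouse
expands its own private alloreactive set.

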