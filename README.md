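# aptastruct

Secondary-structure pattern analysis for pools of single-stranded DNA
aptamer candidates.

Aptamer screens (SELEX-style or competition-based) return dozens of
sequences whose binding activity is widely thought to ride on secondary
structure rather than on primary-sequence motifs. `aptastruct` compares
the *predicted self-hybridized structures* of a candidate panel against a
large random-sequence background, using a pipeline of five analysis
stages:

1. **Folding** (pluggable engine) predicts the dominant (minimum free
   energy, labelled `S1`) and *suboptimal* structures — folds whose ΔG
   lies within 5% of the dominant fold's ΔG (`S2`, `S3`, …).
2. **Element decomposition** breaks each structure into seven secondary
   structure elements (SSE): single-stranded segment (S), hairpin stem
   (H), hairpin loop (L), internal loop (I), bulge (G), duplex (D) and
   multi-branched loop (M), and rewrites the molecule as a per-base
   **secondary structure string** (SS\$) over that 7-letter alphabet.
   Structures sharing the exact same count of each element — ignoring
   element position, length and base content — form a **secondary
   structure family** (SSF).
3. **Positional scoring** maps per-position element frequencies
   `f[k,j]`, their dominant-vs-dominant+suboptimal shifts (ΔSSE), and a
   position-specific score matrix against the background:

       μ[k,j] = (c_bg[k,j] + α) / (N_bg + 7α)
       θ[k,j] = (7α·μ[k,j] + c[k,j]) / (7α + N)
       W[k,j] = f[k,j] · log2(θ[k,j] / μ[k,j])
       H[j]   = max(0, log2 7 − Σ_k f[k,j] · log2(1/μ[k,j]))
       S[k,j] = H[j] · W[k,j]          (bits)

4. **MSS\$A** — multiple secondary structure string alignment: global
   progressive alignment of the SS\$ population under an identity
   substitution scheme with affine gaps, so only same-element bases ever
   "match".
5. **Consensus domains** — alignment columns are classified (≥50% one
   letter → consensus, ≥50% gaps → gap region, else non-gap), maximal
   runs become numbered domains/regions, and domains are projected back
   onto ungapped base coordinates with occupancy, distance and loss
   statistics.

The library design modelled throughout is the 69-nt screening strand
`5'-GGGACAGGGCTAGC-[40N]-GAGGCAAAGCTTCCG-3'` (fixed primer flanks at
bases 1–14 and 55–69, variable insert at 15–54), with equibase
(25/25/25/25) and A-rich (40/20/20/20) insert compositions.

## Worked example

```python
from aptastruct import (
    EQUIBASE_DESIGN, FoldingConditions, generate_library, fold,
    select_suboptimal, annotate_structure, assign_families,
    progressive_align, classify_columns, segment_regions, domain_stats,
)
from aptastruct.folding import ViennaRNAEngine

engine = ViennaRNAEngine()          # DNA parameters, 152 mM Na+/4 mM Mg2+, 23 C
cond = FoldingConditions()
library = generate_library(EQUIBASE_DESIGN, 30, seed=42)

annotations, dominant = {}, {}
for rec in library:
    structures = select_suboptimal(fold(rec, cond, engine), cond.subopt_window)
    for st in structures:
        ann = annotate_structure(st.pairs)
        annotations[st.label] = ann
        if st.rank_label == "S1":
            dominant[st.label] = ann.ss_string

catalog = assign_families(annotations)
print(f"{len(annotations)} structures -> {len(catalog.families)} families")

aln = progressive_align(dominant)
cc = classify_columns(aln)
regions = segment_regions(cc)
stats = domain_stats(aln, regions, cc)
print(f"domains per sequence: {stats.domains_per_sequence:.2f}")
print(f"% of SS$ in consensus domains: {stats.pct_ss_in_domains:.1f}")
```

prints

```
55 structures -> 10 families
domains per sequence: 10.20
% of SS$ in consensus domains: 48.8
```

meaning: the 30 library members folded into 55 dominant + suboptimal
structures, of which 22 fall into 10 element-count families (the other 33
have singleton count vectors); after aligning the 30 dominant structure
strings, the average sequence carries 10.2 consensus domains and roughly
half of its 69 letters sit in consensus-domain columns.  Small random
panels are structurally diverse, so domains here are short and numerous;
a selected aptamer panel concentrates into fewer families and broader
domains.

The same stages are scriptable from the shell:

```bash
aptastruct generate --design equibase --n 1000 --seed 17 -o lib.fasta
aptastruct fold lib.fasta --engine vienna --window 0.05 -o folded.tsv
aptastruct annotate folded.tsv -o annotated.tsv
aptastruct align annotated.tsv -o mssa.aln
aptastruct domains mssa.aln -o domains/
aptastruct run --n-background 1000 --seed 17 --engine vienna -o report/
```

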