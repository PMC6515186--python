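# Methods

## Scope and model

`aptastruct` analyses *predicted* secondary structure of short ssDNA
strands (the 69-nt screening design with fixed primer flanks). It does
not predict thermodynamics itself: folding is delegated to an engine
adapter, and everything downstream — element decomposition, family
grouping, positional scoring, structure-string alignment, consensus
domains — is the package's own implementation. Structures are
represented as pseudoknot-free base-pair sets with unique partners and
hairpin loops of at least 3 nt; engine output violating these
invariants is rejected with the offending indices named.

## Folding engines

**ViennaRNAEngine** (the mfold-compatible engine) uses the ViennaRNA
bindings with the DNA (Mathews 2004) nearest-neighbor parameters at the
requested temperature (default 23 °C). Divalent salt is folded into a
monovalent equivalent by the standard PCR-buffer rule
`[Na+]eq = [Na+] + 120·√[Mg2+]` (mM), giving 0.392 M for the 152 mM
Na+/4 mM Mg2+ screening buffer. Suboptimal folds come from the Zuker
construction (best fold through every admissible pair), filtered two
ways: (i) the free-energy window — keep folds with
`|ΔG − ΔG(S1)| ≤ w·|ΔG(S1)|`, default `w = 0.05`; (ii) the classic
suboptimal-plot distinctness filter — a fold is retained only when it
contributes more than W base pairs farther than W (in both indices)
from every pair of every already-kept fold, with the classic
length-dependent default (W = 2 for 50–119 nt). This mirrors how
mfold-style servers turn the dense suboptimal spectrum into a handful
of genuinely different foldings; W is exposed as
`distinctness_window`. Survivors are ranked S1..Sn by ascending ΔG,
ties broken by fewer pairs then lexicographic dot-bracket, so labelling
is deterministic.

**BaselineEngine** is a maximum-cardinality nested-pairing folder
(Nussinov-style dynamic program) over {A·T, G·C, G·T} with minimum
hairpin loop 3 and a deterministic traceback (a position prefers
pairing its largest admissible partner, otherwise stays unpaired). G·T
wobble is included because the 3'-flank hairpin stem of the standard
design contains a G·T pair. Its "energy" is minus the pair count,
flagged `pseudo_energy`; it exists so every stage runs with no
thermodynamic dependency, and it is *not* a substitute prediction of
real folding. **CTDirectoryEngine** replays externally computed
mfold/UNAFold CT files verbatim.

## Element decomposition

Standard loop taxonomy over the nesting tree: helices are maximal runs
of stacked pairs; the loop under a helix's innermost pair is a hairpin
loop (no inner helices), internal loop (one inner helix, unpaired on
both sides), bulge (one inner helix, unpaired on one side) or
multi-branched loop (≥2 inner helices). Only the helix directly
closing a hairpin loop is a hairpin stem (H); every other helix,
including stems separated from the loop by a bulge or internal loop,
is a duplex (D). One element is one feature: a helix counts once (both
strands), an internal loop once (both stretches), a multibranch loop
once (all stretches), and each maximal exterior unpaired run is one
single-stranded segment. A loop with zero unpaired bases (a tight
multibranch junction) still counts as an element but contributes no
letters. The unfolded structure is a single S element and participates
in family grouping. Hairpin stems and loops are counted as two
separate elements (H and L); since every hairpin loop is closed by
exactly one stem, H = L in any count vector, so merging them would
only rescale the vector and cannot change which structures share one.

## Positional scoring

The score matrix printed in the source article is typographically
garbled; the reconstruction used here keeps every recognizable
sub-expression (7α smoothing, log2 7, log2(1/μ), the indicator mean)
and yields finite, sign-interpretable bits:
μ is the additively smoothed background position frequency matrix
(α > 0 required, default α = 1 — Laplace-style, consistent with the 7α
pseudo-count structure), θ the foreground probability shrunk toward μ,
`W = f·log2(θ/μ)` the frequency-weighted log-odds, and
`H_j = max(0, log2 7 − Σ_k f·log2(1/μ))` an information-content
normalization (0 when the foreground column is no more ordered than
the background, at most log2 7). μ comes from the background
population even though the printed formula reuses the foreground's
symbols — its own caption names it the *background* frequency matrix.
`S = H·W` is 0 for an element absent from the foreground; depletion is
displayed through `Dsp = H·log2(θ/μ)`, which goes negative there.

Two consequences of the smoothing worth knowing: scores are invariant
under duplicating both populations only if α scales along, and
`S[k,j]` is not globally monotone in `c[k,j]` because `H_j` clips at 0
(enriching a background-rare element can de-order the column); the
unclipped weight `W[k,j]` is monotone in the enriched regime.

## Alignment

Pairwise alignment is global Needleman–Wunsch/Gotoh with an identity
substitution scheme (default match 10, mismatch 0 — letters never
partially match) and affine gaps costing `open + extend·L`
(default 10 + 0.2·L, ClustalW-like magnitudes; end gaps are penalized
like any other gap). Traceback prefers diagonal over up over left.
The multiple alignment is progressive: guide tree by neighbor joining
on `d = 1 − identity` distances (edit distances via edlib when
available, otherwise the package's own aligner), deterministic
tie-break to the lexicographically smallest label pair, then
profile–profile merges leaf-to-root with gap columns scoring zero;
once a gap, always a gap. The aligner is deliberately simple rather
than a ClustalW clone; externally produced Clustal alignments can be
read in when exact tool-chain reproduction matters.

## Consensus domains

Column classes use ≥ comparisons (ties count toward gap/consensus),
gaps stay in the consensus denominator, and evaluation order is gap →
consensus → non-gap; all three thresholds default to 0.5 and are
configurable. A sequence *contains* a domain when its row matches the
column consensus letter in ≥50% of the domain's columns; domain
frequency, domains-per-sequence and the membership matrix all follow
that rule. The percentage of an SS\$ occupied by consensus domains is
the fraction of a row's non-gap characters that lie in
consensus-domain columns (for ungapped 69-letter inputs the
denominator is 69). Mean ± SD domain length is taken over member rows
(all rows for gap/non-gap regions); `fraction_fixed_base` is the mean
fraction of a member row's domain characters whose ungapped base
position falls in 1–14 or 55–69. Projection maps each domain's columns
to each row's ungapped coordinates; `d_(n,n+1)` is the mean base gap
between consecutive domains, `d_prior`/`d_next` fall back to the
strand ends when no neighbor exists, and `domain_loss` counts domain
columns where a row carries a gap.

## Synthetic data

The generator emulates the screening library: verbatim flanks around
an i.i.d. insert (equibase or A-rich), seeded and bit-reproducible.
It does not emulate PCR amplification bias, synthesis errors, or any
selection pressure — so a generated "panel" behaves like the random
background, not like a screened aptamer panel. Planted structures
realize an exact element-count vector constructively (hairpin units,
bulge/internal-loop wrappers, multibranch joins, exterior runs),
which is possible exactly when H = L, D = I + G + M, multibranch joins
have enough branches (H ≥ M + 1), exterior runs fit (S ≤ H − M + 1)
and the length covers the minimum footprint; pairs are Watson–Crick.
Passing tests on planted populations therefore demonstrate the
correctness of decomposition/alignment/domain logic, not the realism
of any folding engine.

## Problem sizes and benchmark sensitivity

The acceptance computation uses a 42-sequence synthetic stand-in panel
(21 equibase + 21 A-rich draws — the screened panel is not bundled)
and the full 1000-member equibase background; the test suite's
property checks use 200–1000 random planted structures and 120–200-row
alignments. Family counts and domain statistics are sensitive to the
folding engine's suboptimal-set density and to alignment gappiness:
this package's progressive aligner spreads 1000 random 69-letter
strings over ~250 columns, which yields fewer and sparser consensus
columns than a tighter aligner would, lowering domains-per-sequence
and domain coverage for large random populations. Statistics computed
on a stand-in panel describe the screening library distribution, not
a selected panel.

## Known limitations

No pseudoknots, G-quadruplexes or base triples; no nearest-neighbor
energy tables of its own; no motif p-values (external motif tools are
out of scope); plotting is limited to the 1D region track export; the
aligner does no iterative refinement.
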