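# Methods

## Scope and data model

The package treats a mitogenome as an ordered, stranded list of features on a
circular molecule with 1-based, inclusive coordinates (GenBank convention);
a feature's size is `end − start + 1`, and the published gene tables of the
three *Gerres* genomes reproduce exactly under this convention, which is how
the packaged fixtures were validated. A feature whose end precedes its start
is interpreted as spanning the circular origin; none of the packaged genomes
needs this, but loaders and sequence extraction support it.

For consecutive features *u*, *d* the signed spacing is
`d.start − u.end − 1`: positive values are intergenic spacers (IGS), negative
values overlaps, zero abutting. The origin-spanning pair (last, first)
contributes `(L − last.end) + (first.start − 1)` on a circular molecule of
length *L*; in all three packaged genomes this wrap spacing is zero
(D-loop abuts tRNA-Phe), so it never perturbs the printed censuses. The
tiling identity `Σ sizes + Σ gaps − Σ overlaps = L` holds for all three
fixtures and for every realizable generator configuration, and is enforced
as a property test. A feature fully nested inside its predecessor is
excluded from spacing tallies with a warning, because consecutive-pair
spacing is undefined for containment.

Two transcription choices in the fixtures resolve internal inconsistencies
of the printed source table and are recorded here as the package's reading:
the *G. filamentosus* tRNA-Ser(GCT) position is 11867..11934 (the printed
run-on number lost its separator; size 68 and both flanking spacings then
agree), and the *G. decacanthus* ND2 end is 5240 (the printed 5239 would
contradict the row's own size 1047 and its zero spacing to tRNA-Trp, and
only end 5240 reproduces the published protein-coding share of 67.74%).
The *G. erythrourus* table is transcribed verbatim; its overlap census
computes to 2 sites/14 bp and its spacer count to 16, which is what the
coordinates imply even though the running text says three/15 bp and 15.

## Composition and skew

Base counts are exact and case-insensitive, U counts as T, and ambiguity
codes are excluded from counts but tallied, so reported fractions always sum
to 1. AT-skew `(A−T)/(A+T)` and GC-skew `(G−C)/(G+C)` are undefined (missing,
never zero) when the denominator vanishes. Gene-level skews are computed on
the coding-strand sequence — L-strand genes are reverse-complemented first —
while the whole-genome row uses the H-strand; the convention is stated in
output metadata. Under it, the single L-strand protein gene (ND6) shows the
sign-flipped skew that makes it the classic outlier of mitogenome skew
profiles, and this strand flip is tested as an exact identity
(`gc_skew(sense) = −gc_skew(H-projection)`).

Codon-position composition assigns bases by `index mod 3` within each gene
independently; a trailing incomplete codon contributes only the positions it
has. With the 38-feature default template (four genes ending in `T`, one in
`TA`), the pooled position totals come out 3813/3809/3808 over 11,430 bp —
the same unequal layout the published composition table prints — and the
row identity `n1 + n2 + n3 = total` is asserted.

Report percentages are rounded half-even to 2 decimals.

## Codon usage

The genetic code is NCBI translation table 2 (vertebrate mitochondrial:
AGA/AGG stops, ATA = Met, TGA = Trp), built from Biopython's table data and
carrying the synonymous-family partition of its 60 sense codons. Terminal
classification works from the coding-strand sequence alone: a complete
terminal stop when length ≡ 0 (mod 3); the incomplete stops `TA` (length ≡ 2
and last two bases TA) and `T` (length ≡ 1 and last base T), which
polyadenylation completes to TAA in the transcript.

Codon counting pools complete codons per gene; incomplete trailing codons
are never counted as codons (they are tallied, and
`3 × total + discarded bases = input length` is a tested invariant), and by
default a gene's terminal complete stop codon is excluded so usage reflects
sense codons — the flag is exposed. Internal stop codons warn rather than
fail, since mitochondrial annotations legitimately disagree about
boundaries. ND6 is included on its coding strand. RSCU follows
`k·x_c/X_F`; unused families are reported as missing, and the family-sum
normalization (Σ RSCU = k) is property-tested on random counts.

## Divergence

p-distances are computed after complete deletion of codon columns containing
gaps or ambiguity in either sequence, and partitioned as positions 1+2
pooled vs position 3 (matching the common presentation), with per-partition
site counts that sum to the overall count.

Ka/Ks uses Nei–Gojobori (1986) counting with equal-weight pathway averaging.
Sites: each of a codon's 9 single-base mutants is classified; mutants that
are stop codons are excluded with per-position renormalization, so s + n = 3
for every sense codon (verified exhaustively for all 60). Differences: for
codons differing at *d* positions, the *d*! substitution orderings are
walked; orderings passing through stop codons are dropped and the average is
over legal pathways (so sd + nd = d when any pathway is legal); when every
pathway is illegal, the direct per-position classification is used as a
flagged fallback. The implementation is checked against an independent
brute-force pathway enumerator on every ordered sense-codon pair. Columns
containing a stop codon in either sequence (including terminal stops) are
excluded from the analysis. Site totals are averaged over the two sequences,
proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected
(`d = −(3/4)·ln(1 − 4p/3)`, undefined at p ≥ 3/4 with a saturation flag),
and ω = dN/dS is undefined when Ks = 0 (zero-Ks flag).

No method is dictated for mitogenome Ka/Ks by convention alone; NG86 with
Jukes–Cantor is the default of the era's standard desktop tools and is
recorded in output metadata. Published per-gene distance and ω figures for
the real genomes are method- and software-dependent and are deliberately not
asserted anywhere; reproducing them would also require the deposited
accession sequences, which the package does not ship. When users supply
those sequences, the pipeline runs end-to-end and emits all tables without
numeric claims.

## Synthetic genomes and ground truth

The generator tiles a circular molecule from an ordered template of
(size, spacing) slots — by default the 38-feature layout with the
*G. filamentosus* sizes, spacings, strands and terminal codons, including
the duplicated Leu/Ser tRNAs — so the spacer/overlap census of the output
equals the configured totals exactly. Protein genes are drawn codon-i.i.d.
from a configurable bias over sense codons (uniform by default) with the
configured start codon and (possibly incomplete) stop; other regions are
drawn i.i.d. from a base distribution with default (A,C,G,T) =
(0.30, 0.25, 0.18, 0.27), an AT-rich, G-poor profile typical of fish
mitogenomes. One seeded NumPy generator drives each call; identical seeds
give byte-identical GenBank/FASTA/TSV artifacts.

Where the template specifies overlaps, the downstream feature's bases win in
the shared span (the molecule is a single sequence); `truth.gene_sequences`
always records what is actually in the molecule, `truth.intended_cds` the
pre-assembly draw, and exact-recovery tests use overlap-free templates or
unoverlapped genes.

Descendant sequences apply an exact plan of synonymous and nonsynonymous
single-base changes at uniformly chosen eligible codons — never creating a
stop, never touching the protected start codon, the terminal stop, or an
incomplete tail, and (in the default low-divergence mode) at most one change
per codon, so NG86 recounts Sd and Nd verbatim. The replayable ledger
(position, from, to, class) is asserted to reconstruct the descendant
exactly.

What the generator does not emulate: indels and alignment error, strand-
asymmetric mutation spectra, within-gene rate heterogeneity, selection on
codon usage, and realistic tRNA/rRNA structure. Passing recovery tests
therefore demonstrates correctness of the counting and correction machinery
under the model's assumptions, not robustness to real-data misalignment or
saturation.

## Experiment sizes and numerical choices

The ω-recovery experiment uses 2,000-codon ancestors, pS ≈ 0.15, planted
ω ∈ {0.1, 0.5}, 10 replicates per level — a per-gene problem size comparable
to the longer mitochondrial protein genes, large enough that integer
rounding of the plan perturbs ω by well under a percent. The planted ω is
defined from the integer plan as (Nd/N)/(Sd/S) with sites counted on the
ancestor. Estimates carry a small, fully explained downward bias (≈4–10%):
Jukes–Cantor inflates the larger synonymous proportion more than the
nonsynonymous one; all replicates fall within ±20% of the planted value,
and purely synonymous plans yield Ka = 0 exactly.

Ties in maximum-spacer queries resolve to the first occurrence in genome
order. PHYLIP matrices are written in relaxed (whitespace-padded) square
format with 6-decimal fixed precision. All tabular artifacts are
deterministic for fixed inputs: fixed rounding, no timestamps, and the
run manifest stores SHA-256 checksums of the inputs.
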