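# Methods

This note records the models implemented in `lrrsplice`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Gene models and coordinate conventions

Internally all genomic intervals are 0-based half-open; GTF I/O converts
to and from the standard 1-based inclusive convention. Exon index 1 is
the 5′-most exon of the mRNA (on the minus strand this is the exon with
the highest genomic coordinates). Per-exon coding lengths are the overlap
of the exon with the CDS features; the codon phase of an exon's coding
start obeys `phase(i+1) = (phase(i) + coding_length(i)) mod 3`. The stop
codon is kept inside the CDS bookkeeping and excluded from the protein
(Ensembl convention); models read from FASTA-less GTFs detect which
layout is present and record it in a flag. A transcript whose CDS is not
divisible by 3 is flagged, never dropped.

A codon split across an exon junction is assigned to the exon containing
its **first** base. This makes the intersection of protein-coordinate
domain annotations with exons deterministic; the test suite checks the
mapping against a brute-force per-codon enumeration. Whether domain
coordinates should first be clipped to CDS bounds is not settled by any
convention we know of; no clipping is performed, and the membership rule
(below) makes clipping irrelevant for in-CDS domains.

## Domain-exon extraction and frame analysis

An exon is *in-domain* when at least one codon whose first base lies in
the exon falls inside an annotated domain span ("spanning" is otherwise
ambiguous at exon borders); a stricter full-containment mode is
available. Exon length is the **full** exonic length including UTR
portions — terminal exons that run into the UTR are part of the observed
length spectrum — with a `cds_only` option for the cleaner variant.
Frame preservation is `length mod 3 == 0`.

Length spectra count exons per bp up to a 200-bp cutoff (longer records
are tallied separately). Peak-group assignment uses the four fixed
windows 69–75, 81–87, 141–147 and 168–174 bp — one 23–25-aa repeat, one
28–29-aa repeat, and their two-repeat composites. A data-driven
peak-finder (±1-bp smoothed local maxima over 2× the local median) exists
for exploration but is never used by the analyses.

Frame-preservation enrichment uses the two-tailed Fisher exact test with
the summed-small-probabilities convention: p is the sum of probabilities
of all margin-fixed tables whose hypergeometric probability does not
exceed the observed table's (within relative tolerance 1e−7, guarding
floating-point ties). This is computed directly from the hypergeometric
pmf over the margin-fixed support; alternatives such as tail doubling
would give different values and are not offered. Table orientation is
rows = (domain, non-domain), columns = (frame-shifting,
frame-preserving), so enrichment of frame preservation in the domain
appears as an odds ratio below 1. The odds ratio is the sample ratio
(a·d)/(b·c), infinite when b·c = 0, and a table with a zero margin is
degenerate with p = 1 by convention.

## LRR consensus register

The two consensus patterns are the RI class
`LxxLxLxx(N/C)xLxxxgoxxLxxoLxzxxxx` (29 positions) and the S/T class
`LxxLxLxxNxLxxLpxxoFxzxLxx` (25 positions); `(A/B)` collapses to one
position allowing either class. The residue classes behind the one-letter
codes are not standardised anywhere authoritative, so they live in a
config file (`_residue_classes.yaml`) with defaults drawn from common LRR
usage: `L`={L,I,V,M,F}, `N`={N,T,S}, `C`={C}, `F`={F,Y,W,L}, `g`={G,A,S},
`o`=nonpolar {A,V,L,I,M,F,W,C,G,P}, `p`=polar {S,T,N,Q,Y,H,K,R,D,E},
`z`=any (tracked apart from `x` so stricter tables can constrain it),
`x`=any.

Alignment is pure register tiling — no gaps or indels within a unit,
reflecting the rigid building-block structure of LRR solenoids. All
starting offsets `0..max(unit_lengths)−1` and all alternation phases are
enumerated; units cycle through the declared lengths (default 28/29).
A 28-aa unit is scored against the 29-position pattern by dropping the
pattern's final wildcard position (generalised: a unit shorter by k drops
the last k wildcard positions). The per-unit score is the matched
fraction of non-wildcard positions; `x` and `z` constrain nothing and are
excluded from the denominator. The tiling maximising the mean unit score
wins; ties go to the smallest offset, then to the phase starting with the
shorter unit. Equivalence with an independent exhaustive enumeration is
asserted in the tests.

Exon borders are reported in register coordinates for every junction
between consecutive coding exons lying inside the segmented span (both
sides contributing codons to the span), as the 0-based offset of the
downstream exon's first residue within its repeat unit. A gene with a
single domain exon therefore has no reportable border. In the canonical
architecture all offsets are 0.

## Isoform enumeration

Skip isoforms enumerate all subsets of 1..`max_skipped` internal exons
(terminal exons carry UTR/promoter roles and are excluded by default), in
lexicographic order of the skipped set. A skip is frame-preserving iff
the summed coding length of the skipped exons is divisible by 3. Products
are obtained by translating the actually spliced CDS: premature stops
introduced at new junctions are detected, never assumed absent, and
frame-shifting skips report the codon at which the frame first breaks
plus the truncated product. Amplicon lengths are summed exonic lengths
between anchor exons on the spliced transcript; anchors are parameters
because real primer positions are assay-specific. Protein properties are
limited to length and average mass (residue masses + 18.02 Da water, via
Biopython); other descriptors (pI, GRAVY, instability) are out of scope.

## Junction-based ψ

The estimator uses junction-spanning reads only. The inclusion isoform
exposes two junction positions (flank→exon, exon→flank), the skipping
isoform one (flank→flank); under uniform sampling across junction
positions a read is an inclusion read with probability `2ψ/(1+ψ)`. This
2:1 position weighting is the whole model — a deliberate simplification
of full generative read models (fragment-length distributions, exon-body
coverage), adopted because exon-body coverage is demonstrably nonuniform
in real libraries and junction counts carry the exon-centric signal.
Consequences: the MLE is `ψ̂ = r/(2−r)`; the posterior over a uniform
prior on a ψ-grid (default step 0.001, a compromise between resolution
and cost) gives the posterior-mean point estimate and an equal-tailed
credible interval from the grid CDF. The grid construction is fully
deterministic. Degenerate input (no junction reads at all) raises rather
than returning a silent 0/0. Junction tables are matched to exon
boundaries exactly; near-miss coordinates are ignored and reported, which
surfaces off-by-one convention errors instead of absorbing them. The
STAR `SJ.out.tab` column convention is accepted behind a dialect flag.

## Single-cell burst model

Per-cell molecule counts follow the stationary law of the telegraph
model: `p ~ Beta(k_on/k_deg, k_off/k_deg)`,
`m ~ Poisson(k_syn/k_deg · p)`, mean `k_syn·k_on/(k_deg(k_on+k_off))`.
Stationary sampling (rather than trajectory simulation) is sufficient for
detection-pattern statistics; a Gillespie simulator of the same kinetics
is provided for the oscillating-expression picture and is checked against
the same stationary mean. Detection is binomial capture (`capture_p`,
default 0.3 — a realistic single-cell RT efficiency scale) thresholded at
1 captured molecule (single-molecule sensitivity of nested preamp PCR).
A whole-cell technical failure (lysis/RT loss, default rate 0.05) zeroes
every target including 18S rRNA; since 18S is otherwise at saturating
copy number, its absence is the dropout sentinel, and cells without it
are excluded from pattern fractions.

Default kinetics (in units of the decay rate) put the two isoforms in the
bursty low-frequency regime — FL: k_on 0.5, k_off 5, k_syn 40 (mean ≈3.6
molecules); D5: 0.4/5/25 (mean ≈1.9); HPRT: 2/2/30; 18S: 50/1/2000 —
chosen so per-cell isoform detection sits in the tens of percent. In that
regime most informative cells show one isoform or none even though both
are transcribed from the same locus, while a minority detect both: the
qualitative signature of stochastic, non-deterministic splicing. The
independence diagnostic is the odds ratio
`(both·neither)/(FL_only·D5_only)`, ≈1 for independent detections; when a
category count is zero a Haldane +0.5 correction keeps it finite and the
result is flagged as corrected (a perfectly coupled pattern would
otherwise diverge).

## Synthetic generators

`make_lrr_gene` instantiates the consensus per repeat unit (canonical
residue at constrained positions, seeded random residues at wildcards),
so a perfect register score of 1.0 holds by construction; flank exons are
random-sequence stand-ins for the non-repeat domains, with the total
upstream coding length forced to a codon boundary so domain exons start
in phase 0, while individual flank exons remain free to be
frame-shifting. The CDS is a seeded reverse translation of the protein
plus a TAA stop; introns are 300–1500 bp. Perturbations move an exon's 3′
junction by ±bp, leaving CDS and protein intact — +1 bp makes the exon
frame-shifting, +3 bp moves exactly one border by one register position.

The default cohort plants four families matching the four peak windows
(one-unit exons of 23–25 aa and 28 aa; two-unit exons of 23+24 and
28+29 aa; 5–6 domain exons per gene, 5 genes per family, alternating
strands) plus 10 decoy genes whose exon lengths are geometric-like
(60 + Geom(0.012), so ≈1/3 frame-preserving by chance) — enough contrast
for the frame-preservation enrichment to be detectable at a few dozen
genes. Junction reads are drawn as `n_inc ~ Binomial(depth, 2ψ/(1+ψ))`
with the inclusion reads split evenly between the two inclusion
junctions.

What the generators do **not** emulate: mapping artefacts and multimapped
junction reads, nonuniform exon-body coverage, annotation errors, partial
or degenerate repeat units, paralog cross-mapping, cell-to-cell kinetic
heterogeneity beyond the telegraph law, and amplification noise in
single-cell PCR. Tests passing on these fixtures therefore validate the
estimators' correctness under their own model assumptions, not robustness
to every failure mode of real RNA-seq or single-cell data.

## Problem sizes and determinism

Analyses run at desk scale: cohorts of ~30 genes, junction depths of
10,000–50,000 reads, 1,000 posterior-coverage replicates, 5,000–10,000
simulated cells — sizes at which every Monte-Carlo check in the suite
resolves its target within three standard errors in seconds. All
stochastic components take an explicit seed (numpy `default_rng`; derived
child seeds via `SeedSequence`), and no global random state is used
anywhere.

## Known limitations

- The ψ model ignores read length, overhang filters and fragment-length
  effects; it estimates the exon-centric inclusion level, not isoform
  abundances.
- Register alignment cannot represent insertions within repeat units;
  genuinely irregular LRRs (length outliers beyond the declared
  alternation) tile with reduced scores rather than adaptive unit lengths.
- The residue-class table is a documented convention, not a fitted model;
  scores are comparable only under a fixed table.
- The telegraph defaults are plausible-regime choices, not parameters
  inferred from data; only qualitative pattern claims should be read off
  the default simulation.
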