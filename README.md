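# lrrsplice

Tools for analysing the exon-modular architecture of leucine-rich-repeat
(LRR) domains and the alternative splicing it enables, with NOD-like
receptor (NLR) genes — NLRP3 in particular — as the motivating case.

In NLR genes the LRR solenoid is not encoded by one long exon (as in
TLRs) but by a run of short exons. In the canonical NLRP3 architecture
every LRR exon is exactly 171 bp and encodes two repeats alternating
between 28 and 29 aa, with every exon–exon border at the same position in
the repeat register. Because 171 is divisible by 3, skipping any of these
exons preserves the downstream reading frame and removes an exact block of
57 aa (two repeats) — the structural precondition for generating shortened
but folded LRR variants by alternative splicing, such as the NLRP3
Δ exon 5 isoform. `lrrsplice` provides, as a tested library plus a thin
CLI:

- **gene models** (`gene_models`) — GTF-backed transcript models with
  per-exon coding lengths and codon phases, and a deterministic
  protein↔exon coordinate map (split codons assigned to the exon holding
  the codon's first base);
- **exon/domain modularity** (`exon_modularity`) — extraction of
  domain-spanning exons from protein-coordinate annotations (SMART LRR
  accessions), frame-preserving vs frame-shifting classification
  (`length mod 3`), exon-length spectra, the canonical peak windows
  (69–75, 81–87, 141–147, 168–174 bp), and a two-tailed Fisher exact test
  for frame-preservation enrichment;
- **LRR consensus register** (`lrr_consensus`) — alignment of proteins to
  the ribonuclease-inhibitor-class (`LxxLxLxx(N/C)xLxxxgoxxLxxoLxzxxxx`)
  or S/T-class (`LxxLxLxxNxLxxLpxxoFxzxLxx`) consensus by rigid unit
  tiling, and the position of each exon border within the repeat register;
- **isoform enumeration** (`isoform_enumeration`) — exon-skipping
  isoforms with frame consequences, translated products (premature stops
  detected, frameshifts located), RT-PCR amplicon lengths, protein length
  and average mass;
- **percent spliced in** (`psi_quant`) — exon-centric ψ from splice-
  junction read counts. A junction read comes from the inclusion isoform
  with probability 2ψ/(1+ψ) (two inclusion junction positions vs one skip
  position), giving the closed form ψ̂ = r/(2−r) for inclusion-read
  fraction r, plus a uniform-prior grid posterior with an equal-tailed 95%
  credible interval;
- **single-cell patterns** (`stochastic_cells`) — classification of
  per-cell isoform detection patterns (18S rRNA as the technical-dropout
  sentinel), an independence odds ratio, and a telegraph-model
  (beta-Poisson) simulator of bursty transcription with capture dropout;
- **synthetic data** (`synthetic_data`) — generators for all of the above
  with exact ground truth: repeat-modular genes and decoy cohorts written
  as GTF/FASTA/TSV, junction reads at known ψ, and single-cell calls.

## Worked example

```python
from lrrsplice import synthetic_data as sd, exon_modularity as em
from lrrsplice import lrr_consensus as lc, isoform_enumeration as ie, psi_quant as pq

gene = sd.make_lrr_gene(sd.LrrGeneSpec(), seed=42)   # canonical architecture
model = gene.model

records = em.extract_domain_exons([model], [gene.domain])
domain = [r for r in records if r.in_domain]
print(f"domain exons: {[r.exon_index for r in domain]}")
print(f"lengths (bp): {sorted({r.length_bp for r in domain})}, "
      f"all frame-preserving: {all(r.frame_preserving for r in domain)}")

seg = model.protein_seq[gene.domain.start_aa - 1 : gene.domain.end_aa]
tiling = lc.align_register(seg, segment_start_aa=gene.domain.start_aa)
borders = lc.boundary_register(model, tiling)
print(f"register score: {tiling.overall_score:.2f}, units: {len(tiling.units)}, "
      f"border offsets: {sorted({b.offset_in_unit for b in borders})}")

skip5 = [i for i in ie.enumerate_skip_isoforms(model, max_skipped=1)
         if i.skipped_exons == {5}][0]
full = ie.SpliceIsoform(model.transcript_id, frozenset(), True, model.total_exonic_length)
d = (ie.cdna_amplicon_length(model, full, 3, 13)
     - ie.cdna_amplicon_length(model, skip5, 3, 13))
print(f"amplicon difference: {d} bp, protein shortened by "
      f"{len(model.protein_seq) - skip5.protein_length_aa} aa")

reads, truth = sd.simulate_junction_reads(psi_true=0.67, depth=10_000, seed=5)
counts = pq.assign_junction_support(reads, sd.make_lrr_gene(seed=0).model,
                                    truth["target_exon"])
est = pq.psi_posterior(counts.n_inc, counts.n_skip)
print(f"psi = {est.psi_hat:.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}], "
      f"skipping = {100 * (1 - est.psi_hat):.1f}%")
```

prints

```
domain exons: [4, 5, 6, 7, 8, 9, 10, 11, 12]
lengths (bp): [171], all frame-preserving: True
register score: 1.00, units: 18, border offsets: [0]
amplicon difference: 171 bp, protein shortened by 57 aa
psi = 0.665 [0.654, 0.676], skipping = 33.5%
```

Reading it: the nine LRR exons of the synthetic canonical gene are all
171 bp and frame-preserving; the domain tiles perfectly with 18 repeat
units (two per exon) and every exon border sits at register offset 0;
skipping one LRR exon shortens the RT-PCR amplicon by exactly 171 bp and
the protein by 57 aa; and from 10,000 junction reads simulated at a true
inclusion of ψ = 0.67, the posterior recovers an exon-skipping level of
33.5% with a tight credible interval — the characteristic exon-5 skipping
level of human NLRP3.

The same stages are scriptable from the shell:

```sh
lrrsplice simulate gene --seed 1 --out-dir fixtures/
lrrsplice simulate reads --psi 0.67 --depth 10000 --seed 5 \
    --gtf fixtures/gene.gtf --gene NLRP3L --exon 5 --out junctions.tsv
lrrsplice psi --junctions junctions.tsv --gtf fixtures/gene.gtf --gene NLRP3L --exon 5
lrrsplice cells simulate --n-cells 1000 --seed 3 --out calls.csv
lrrsplice cells classify --calls calls.csv
```

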