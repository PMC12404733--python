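# wobbleseq

Quantification of wobble-inosine (I34) tRNA editing and its downstream
consequences from tRNA-seq data.

## The problem

The heterodimeric ADAT2/ADAT3 deaminase converts adenosine to inosine at the
wobble position 34 of the eight eukaryotic tRNA families whose anticodon
starts with A (the ANN tRNAs: Ala-AGC, Arg-ACG, Ile-AAU, Leu-AAG, Pro-AGG,
Ser-AGA, Thr-AGU and Val-AAC).  Because inosine pairs with U, C and A, and
because GNN anticodons are absent from the boxes these families decode, I34
is strictly required to read one C-ending codon per family.  Partial loss of
ADAT activity — as in patients carrying hypomorphic *ADAT3* variants — leaves
a fraction of each tRNA pool unedited, destabilizes the affected isodecoders,
and selectively impairs translation of transcripts enriched in
ADAT-dependent codons.

During reverse transcription inosine is read as G, so the I34 stoichiometry
of an isodecoder is directly observable in sequencing reads as the G fraction
at the wobble position.  `wobbleseq` implements the full analysis chain:

1. **reference** — load mature tRNA isodecoders (FASTA + annotation TSV),
   group them into anticodon families, derive ADAT targets and their
   dependent codons from wobble-pairing rules;
2. **simulate** — generate seeded tRNA-seq reads with a fully recorded ground
   truth (negative-binomial abundances, planted I34 stoichiometries,
   misincorporation/RT-stop signatures at other modified sites, coupled
   abundance losses, codon-enriched gene sets);
3. **assign** — modification-aware 3'-anchored read assignment with
   family-aware tie handling, pileups and library QC;
4. **modquant** — per-isodecoder and per-anticodon-pool I34 calls
   θ̂ = G/(G+A) with Wilson 95% intervals, condition deltas, modification
   profiles, and in vitro deamination curves;
5. **diffexp** — negative-binomial Wald tests of differential tRNA abundance
   (median-of-ratios normalization, trend-shrunk dispersions,
   Benjamini–Hochberg FDR);
6. **coupling** — Spearman permutation test of the ΔI34–Δabundance coupling
   and permutation tests of ADAT-dependent codon enrichment in gene sets;
7. **pipeline** — a YAML-configured end-to-end run with deterministic
   summary output (`wobbleseq run --config run.yaml`).

## Worked example

Simulate a patient-like replicate (controls fully edited, the Ala-AGC
isodecoders partially unedited), assign reads and call I34:

```python
from wobbleseq import simulate as sim, assign as asg, modquant as mq

refset = sim.demo_reference(seed=1)
cfg = sim.demo_config(refset, seed=1, reads_per_replicate=20000)
counts, truth = sim.simulate_counts(refset, cfg)
paths = sim.simulate_reads(refset, counts[["patient_1"]], cfg, "out")
result, pileup = asg.assign_reads(paths["patient_1"], refset)
calls = mq.call_i34(pileup, refset)
pools = mq.aggregate_anticodon(calls, refset)
```

Printed per-isodecoder calls for the affected family (planted
stoichiometries 0.43 and 0.13):

```
     unit  coverage    theta    ci_lo    ci_hi status
Ala-AGC-1     110.0 0.363636 0.279752 0.456723 called
Ala-AGC-2      53.0 0.188679 0.105853 0.313585 called
```

and the anticodon-pool aggregation (coverage-weighted; unaffected families
stay fully edited):

```
   unit  coverage    theta    ci_lo    ci_hi status
Ala-AGC     163.0 0.306748 0.241083 0.381313 called
Arg-ACG     952.0 1.000000 0.995981 1.000000 called
Ile-AAT     148.0 1.000000 0.974701 1.000000 called
```

`theta` is the estimated I34 proportion, `ci_lo`/`ci_hi` its Wilson 95%
interval; both planted values lie inside their intervals.  The same objects
feed the differential, coupling and enrichment stages; `wobbleseq run`
executes all of them and writes every intermediate table plus a
`summary.json`.

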