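# tailend

Resolving 3'-end length distributions of **ultrashort RNAs** (≈5–20 nt)
from RNA-seq libraries built by 3'-homonucleotide tailing.

Very short RNAs — such as the product RNAs (pRNAs) that bacterial RNA
polymerase transcribes from 6S RNA — ligate poorly to 3' adapters and are
underrepresented in standard small-RNA-seq libraries.  Enzymatic polyA/
polyC/polyU tailing captures them efficiently, but at a price: wherever an
RNA's 3' end continues with bases identical to the tailing nucleotide,
trimming the tail also removes genuine 3' bases.  Reads ending anywhere in
a maximal run of the tail base in the target sequence, or at the *anchor*
(the first non-tail base 5' of that run), collapse to the anchor and
become indistinguishable.

`tailend` implements the computational workflow around this protocol:

* **trim** — cut reads at the tail signature (a run of 5 tail bases
  followed by ≥ 3 tail bases in the next 4), or at an exact adapter seed;
* **profile** — map trimmed reads by exact anchored matching (5-nt 5'
  prefix for short targets; the first 30 nt of the 3'-proximal 40-nt
  window for long ones) and normalize per-mille:
  *f*₁₀₀₀[p] = 1000·c[p]/Σc;
* **merge** — the core algorithm: combine two libraries tailed with
  *different* bases (whose blind spots differ) into one fully resolved
  distribution, walking the target 3'→5' and classifying each position
  into case #1 (plain average), #2 (collapsed-anchor subtraction,
  total_A − total_C), #3 (negative subtraction ⇒ incongruency: clamp to
  0, average the competing totals, warn) or #4 (scaled average with
  SF = total_collapsed/total_resolved), with |x−y|/√2 error bars;
* **simulate** — the deterministic expectation of what a tailed library
  would report if an adapter-library profile were the truth;
* **synth** — a seeded generator of synthetic tailed/adapter FASTQ
  libraries with known ground truth for end-to-end testing.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Merge the published per-length count tables of the 6S-1 pRNA (target
`5'-GTTCGGTCAAAACTAGGTG`) from a polyA library (581 mapped reads, the
8–12-mer class collapsed at C8) and a polyC library (1530 reads, 7/8- and
12/13-mer classes collapsed at U7 and A12):

```python
import tailend as te

target = te.TargetSeq(id="6S1_pRNA", bases="GTTCGGTCAAAACTAGGTG")
pA = te.profile_from_count_table(
    te.read_count_table(te.example_data_path("polyA_prna_counts.tsv")), "polyA", "A")
pC = te.profile_from_count_table(
    te.read_count_table(te.example_data_path("polyC1_prna_counts.tsv")), "polyC1", "C")
result = te.merge_two_libraries(pA, pC, target)
counts = te.merged_read_counts(result)
```

which prints one incongruency warning and yields:

```
WARNING: 6S1_pRNA: incongruency at positions 12-13: polyC1 window mass
         64.05 < resolved run mass 82.62; anchor clamped to 0 (case #3)

pos base  f1000     sd  count  case
  5  G     3.44   4.87    3.6  #1
  6  G     2.70   1.05    2.9  #1
  7  T     7.32   0.61    7.7  #4
  8  C   116.09   9.73  122.5  #2
  9  A   324.84   0.00  342.9  single-source
 10  A   240.52   0.00  253.9  single-source
 11  A   165.36   0.00  174.5  single-source
 12  A     0.00   0.00    0.0  #3
 13  C    73.33   0.00   77.4  #3
 14  T    65.20   8.55   68.8  #4
 15  A     1.20   0.16    1.3  #4
```

Reading this: the 9-mer is the dominant pRNA species (*f*₁₀₀₀ = 324.84,
i.e. 32.5% of reads; merged count 324.84/1000 × (581+1530)/2 ≈ 343),
resolved from the polyC library because polyA tailing cannot distinguish
8–12-mers.  The polyA library in turn fixes the 13-mer, where the two
libraries disagree slightly (case #3: A12 clamped to 0, C13 = mean of the
competing totals ≈ 73).  Case #4 positions carry error bars from the two
per-library estimates; `single-source` positions have only one estimate.

The same pipeline is available from the shell:

```bash
tailend trim    --mode tail --tail-base A --in reads.fastq.gz \
                --out trimmed.fastq.gz --stats stats.tsv
tailend profile --targets targets.fasta --reads trimmed.fastq.gz \
                --label polyA --tail-base A --out profA.tsv
tailend merge   --profile-x profA.tsv --tail-x A \
                --profile-y profC.tsv --tail-y C \
                --targets targets.fasta --out merged.tsv --plot merged.png
tailend run-all --config run.cfg       # trim -> profile -> merge in one go
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch: it expands the packaged pRNA count tables into synthetic tailed
reads, runs the full trim → map → profile → merge pipeline (reporting the
anchor correction, the incongruency resolution, the case-#4 average and
the merged read counts), and runs the tRNA-Glu library simulation
(scaling factor and collapsed-window fractions for simulated polyA and
polyC libraries).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Selection percentages of the real sequencing runs require the raw FASTQ
downloads (BioProject PRJNA1158698) and can be checked separately with
`scripts/check_sra_selection.py`.
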