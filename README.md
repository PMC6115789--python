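# mirtarp — interspecies miRNA target prediction

`mirtarp` screens for microRNA binding sites **across species boundaries**:
host miRNAs acting on viral genomes/transcripts, and virus-encoded miRNAs
acting on host mRNAs (3′UTR FASTA is the recommended host-side input).
Mainstream target predictors lean on intra-species signals such as
conservation, which do not exist between a human miRNA and a viral genome.
This tool instead uses only the two signals that survive the species
boundary — base-pairing complementarity and hybridization thermodynamics —
so it can screen a newly sequenced virus with nothing but two FASTA files.

## Method

For a miRNA *m* (5′→3′) and a target *t*, the pipeline runs three stages:

1. **Quick match (seed scan).** Every maximal run of ≥ *b* consecutive
   Watson–Crick pairs (A:U, G:C; no G:U in the seed) between *m* and *t*
   read antiparallel is found by an exact *k*-mer index scan with *k = b*
   (default **b = 7**): each length-*b* window of the reverse complement of
   *m* is looked up in an index of *t* and extended to maximality. The scan
   is provably complete — it reports exactly the maximal runs a naive
   O(n·m) diagonal scan reports.
2. **Duplex assessment.** Each seed, extended by a ±15-nt flank (overlapping
   windows merged), is scored by an intermolecular nearest-neighbor dynamic
   program: non-crossing antiparallel pairing (WC + G:U wobble), stacks,
   bulges and internal loops (l₁+l₂ ≤ 30), no intramolecular pairs, no
   multibranch loops. The minimum free energy ΔG₃₇ of the hybrid,

   ΔG = ΔG_init + Σ stacks + Σ loop penalties + terminal AU/GU penalties,

   is computed exactly (integer 0.01 kcal/mol arithmetic) with traceback.
   Sites with **mfe ≤ e** are reported (default **e = −25 kcal/mol**,
   inclusive).
3. **Accessibility annotation.** The target window around each passing site
   (±70 nt by default) is folded with a Zuker-style MFE dynamic program
   (hairpins, stacks, bulges, internal and multibranch loops); the local
   folding MFE and the unpaired fraction of the site are reported alongside
   each hit as supplementary evidence, never used as a filter.

Energy increments are a Turner-lab-2004-style ΔG°₃₇ set shipped as a
versioned plain-text file (`mirtarp/data/turner2004_min_v1.tsv`); see
`docs/methods.md` for the exact model class and simplifications.

## Worked example

```python
from mirtarp import (MiRNARecord, NucSequence, hybridize,
                     passes_energy_cutoff, reverse_complement)

mir = MiRNARecord(id="mir-example", origin="host",
                  seq=NucSequence("mir-example", "UAGCUUAUCAGACUGAUGUUGA"))
site = reverse_complement(mir.seq.residues)
target = NucSequence("target-1", "ACGGAUUGCC" + site + "GGAUUACGGA")
dup = hybridize(mir, target, (0, len(target)))
```

prints (`python examples/duplex_energy.py`):

```
duplex MFE: -35.70 kcal/mol (site 10-32 on target-1)
miRNA  5' UAGCUUAUCAGACUGAUGUUGA 3'
          ||||||||||||||||||||||
target 3' AUCGAAUAGUCUGACUACAACU 5'
passes default cutoff (-25): True
```

The 22-bp perfect duplex scores −35.70 kcal/mol — the sum of 21 stacking
increments, the intermolecular initiation penalty (+4.10) and two AU helix-end
penalties — well below the −25 kcal/mol default, so the site is reported with
its footprint (positions 10–32 of the target, 0-based half-open).

More narrative walkthroughs live in `examples/`:
`predict_planted_sites.py` (end-to-end run against a synthetic truth table),
`accessibility_window.py` (occluded vs. accessible sites),
`negative_control.py` (dinucleotide-shuffled background).

## Command line

```bash
mirtarp make-fixture --n-mirnas 5 --n-targets 3 --n-planted 4 -o fixture/
mirtarp predict --mirna fixture/mirnas.fasta --target fixture/targets.fasta \
        -b 7 -e -25 --gff3 -o run1
```

`predict` writes `run1.sites.tsv` (one row per site: ids, strand, 0-based
half-open coordinates, seed length, duplex MFE, local fold MFE, alignment
strings), optionally `run1.sites.gff3` (1-based, score = duplex MFE), and
`run1.log` with per-stage counts. A run with zero passing sites exits 0 —
"no targets" is a result, not a failure. Flags: `--site-flank`,
`--fold-flank`, `--both-strands` (ambisense genomes), `--no-accessibility`,
`--energy-params`, `--mirna-origin`, `--config config.yaml`.

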