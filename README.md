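# grainpep

Selection of grain-discriminating gluten peptide haptens, and the
indirect-ELISA analytics used to evaluate the resulting antisera.

## What this is for

Standard gluten immunoassays report total gluten but cannot tell wheat
from barley, rye or oat — a problem both for regulations that require
declaring the gluten source and for wheat-allergic consumers who could
safely eat the other cereals. One strategy for source-specific
antibodies is to immunise with synthetic peptides taken from sequence
stretches unique to each grain's gluten proteins. `grainpep` implements
that peptide-selection workflow and the downstream serology statistics
as a reproducible pipeline for bioinformaticians and immunoassay
developers:

* **Selection** — per-GPT (gluten protein type) multiple sequence
  alignments → modal consensus sequences → grain-unique segments
  (exact length-6 window co-occurrence defines "shared") → exclusion
  screen against off-target prolamins (maize zein, soy glycinin, rice)
  → hydropathy / repeat / length filters → deterministic ranking →
  synthesis-ready strings (`Ac-C…-NH2`).
* **Serology** — endpoint titers (highest dilution reaching OD 1.000 at
  450 nm, interpolated in log2-dilution space), the Frey blank cutoff
  `mean + sd · t_{0.999,n−1}·√(1+1/n)`, serum retention at the 1:4000
  threshold, and categorical cross-reactivity bands
  (`+++`/`++`/`+`/`+/-`/`-` relative to each serum's maximum signal).

Key quantities: GRAVY (grand average of hydropathy) is the mean
Kyte–Doolittle value over a peptide — candidates must be hydrophilic
(GRAVY < 0); occurrence is the number of exact matches of a segment in
its grain's consensus set; titers are reciprocal dilutions.

Because real inputs are database snapshots with no ground truth, the
package ships a synthetic-data module that plants shared cores,
grain-unique inserts with prescribed fates, decoys and 4PL ELISA curves
with known analytic titers — every pipeline stage is verified against
that planted truth. See `docs/methods.md` for the full model
description, parameter defaults and limitations.

## Worked example

Generate a demo dataset (4 grains × 2 GPTs, 20 sequences per family,
substitution rate 0.1, with planted truth), run both pipelines:

```bash
grainpep make-fixtures --out-dir demo --seed 1
grainpep select --alignments-dir demo/alignments \
    --exclusion demo/exclusion.fasta --config demo/config.yaml \
    --out-dir demo/sel
grainpep serology --plate demo/plate.tsv --blanks demo/blanks.tsv \
    --out-dir demo/ser
```

which prints

```
8 ranked candidates -> demo/sel/candidates.tsv
cutoff OD 0.0634; 4/4 sera retained -> demo/ser
```

The top of `demo/sel/candidates.tsv`:

```
grain  gpt            start end sequence        length gravy   max_run occurrence rank_score synthesis_sequence
rye    gamma_secalin  30    44  KHDNNYYPRNSPPS  14     -2.471  2       1          1          Ac-CKHDNNYYPRNSPPS-NH2
oat    avenin         30    44  NGNQNHYHYNSKQP  14     -2.621  1       1          2          Ac-CNGNQNHYHYNSKQP-NH2
barley B_hordein      30    42  DTSRRWPDTNND    12     -2.6    2       1          3          Ac-CDTSRRWPDTNND-NH2
```

Each row is a grain-unique, hydrophilic (negative GRAVY), repeat- and
length-compliant peptide with its consensus coordinates and the string
to order from a synthesis service (cysteine prepended for carrier
coupling, acetylated/amidated termini). The run manifest records the
funnel — 14 segments found, 8 kept, 2 rejected hydrophobic, 2 with
repeat runs, 2 shared with the exclusion set — exactly matching the
planted truth in `demo/truth/planted.json`.

The serology run writes `demo/ser/bands.txt`:

```
antigen_id   barley_prolamin oat_prolamin rye_prolamin wheat_prolamin
serum_id
serum_barley             +++            +           ++              -
serum_oat                  +          +++            -              +
serum_rye                  -            +          +++              +
serum_wheat               ++            -            -            +++
```

Strong reactivity (`+++`, ≥ 75% of the serum's maximum signal) sits on
the diagonal — each synthetic serum recognises its own grain's prolamin
— with the planted weak cross-reactions off-diagonal; `-` means below
the blank-derived 99.9%-confidence cutoff (OD 0.0634 here).

## Layout

```
src/grainpep/
  seq_io.py      alignment/table/config readers and writers
  consensus.py   modal consensus with support
  uniqueness.py  shared-window mining, segment extraction, exclusion screen
  haptens.py     GRAVY, filters, ranking, synthesis strings
  elisa.py       titers, Frey cutoff, retention, banding
  synthetic.py   planted-truth generators (sequences + plates)
  pipeline.py    run_selection / run_serology orchestration + manifests
  cli.py         `grainpep select | serology | make-fixtures`
```
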