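# Methods

## The problem

Commercial gluten immunoassays quantify total gluten but cannot say which
cereal it came from. One route to grain-discriminating antibodies is to
immunise with synthetic peptide haptens chosen from stretches of gluten
protein sequence that are unique to one grain. `grainpep` implements the
in-silico half of that programme as a reusable, testable pipeline: from
per-GPT (gluten protein type) multiple sequence alignments to a ranked,
synthesis-ready peptide list, plus the serology analytics used to judge
the resulting antisera (endpoint titers, a statistical blank cutoff, and
categorical cross-reactivity bands).

## Selection pipeline

### Consensus construction

Each GPT family arrives as a precomputed alignment (computing the MSA is
out of scope; Clustal-class tools already do it). The consensus is the
modal symbol per column over the 20 residues plus the gap:

* if the mode is a residue it is kept, with support = modal votes / n;
* if the gap wins, the column is dropped, so the consensus is an ungapped
  string ready for peptide work (`consensus_gap_rule: ignore` instead
  drops a column only when no residue votes at all);
* ties are broken residue-over-gap, then alphabetically — an explicit,
  reproducible rule, since interactive alignment editors do not document
  theirs;
* ambiguity letters (X/B/Z/U/O) abstain from the vote but stay in the
  denominator: they can never win a column, and a column full of them
  shows low support rather than invented certainty.

Under the generator's noise model (i.i.d. substitutions at rate p per
position), a column errs only if some wrong residue matches or beats the
template count among n = 20 sequences. At p ≤ 0.2 the chance that the
same wrong residue recurs often enough is negligible (the 19 alternatives
split the errors), which is why the tests can demand ≥ 99% template
identity and routinely observe 100%.

### Uniqueness mining

"Shared between grains" is operationalised as exact co-occurrence of a
length-w window (default `shared_window: 6`, matching the shortest
peptide length that reliably elicits protein-binding antibodies — also
the floor for a useful hapten). A consensus position is shared iff some
window covering it occurs verbatim in the consensus of *another grain*;
GPTs of the same grain never disqualify each other, because the goal is
to discriminate between grains (`uniqueness_scope: all_vs_all` is
available). Maximal unshared runs of at least `min_segment_len: 6`
residues become candidate segments; a final screen rejects any segment
sharing a window with the exclusion set (off-target prolamins such as
maize zein, soy glycinin, rice), keeping rejected rows as an audit trail.

Exact windows instead of pairwise alignment is a deliberate design
choice: it is deterministic, oracle-checkable (the test suite compares
the k-mer-set implementation against a naive substring scan on hundreds
of random inputs), and conservative — any 6-mer in common disqualifies.
An alignment-tolerant mode (conservative substitutions, gaps) is
deliberately not implemented.

### Filtering and ranking

Candidates carry three scores: GRAVY (grand average of hydropathy, the
mean Kyte–Doolittle value per residue; negative = hydrophilic), the
longest single-residue run, and the (possibly overlapping) occurrence
count in the grain's own consensus set. Filters fire in a fixed order,
first reason wins:

1. **hydrophobic** — GRAVY ≥ `gravy_threshold` (default 0.0, i.e.
   hydrophilic means strictly negative GRAVY). Hydrophilic peptides
   conjugate well in aqueous buffers and favour surface-exposed epitopes.
2. **repeat_run** — longest run > `max_run` (default 3). Gluten's
   poly-Q/poly-P repeats recur across grains and make poor
   discriminators; 3 keeps QQQ-type motifs borderline-acceptable. The
   limit is configurable because no published number exists.
3. **too_long** — length > `max_len` (default 20). Long free peptides
   fold into conformations unlike the parent protein.

Survivors are ordered by a total lexicographic key: length ≥
`preferred_min_len` (default 9, i.e. "more than 8 residues" as a
priority flag, not a hard filter), then occurrence, GPT abundance in
gluten, and length, all descending, with ascending sequence as the final
deterministic tiebreak. GPT gluten proportions are supplied as a config
mapping; the shipped values are illustrative placeholders, not
measurements. The synthesis string prepends a cysteine when the sequence
has none (thiol handle for maleimide coupling to the carrier protein)
and marks N-terminal acetylation / C-terminal amidation: `Ac-…-NH2`.

## Serology analytics

### Endpoint titer

The titer is the highest reciprocal dilution giving OD 1.000 at 450 nm.
Reported titers are frequently not members of the 2-fold ladder, so the
default mode interpolates: scanning from the highest dilution down for
the last pair with OD_i ≥ 1.0 > OD_{i+1}, the crossing is interpolated
linearly in OD against log2(reciprocal dilution). Series entirely above
target are censored `above_range` at the top dilution; entirely below,
the titer is `none`. Noise-driven OD rises of more than 10% between
successive dilutions attach a warning; a series with no downward
crossing at all falls back to the discrete rule, flagged.

The log2-linear interpolation bias at 2-fold steps depends on curve
shape. For the generator's default reactive curve (4PL, upper asymptote
2.2, lower 0.05, Hill slope 1.8) the worst-case bias over all crossing
positions is below 2%; marginal curves whose upper asymptote barely
clears 1.0 cross in the flat tail and can err by ~4%. The stated 2%
noise-free recovery therefore applies to the default curve family.

### Blank cutoff (Frey method)

The positivity threshold is a one-sided prediction bound on a fresh
blank:

    cutoff = mean + sd · t_{conf, n−1} · √(1 + 1/n)

with the sample (n−1) standard deviation and default confidence 0.999.
Coverage is unconditional — averaged over blank samples a fresh blank
exceeds the cutoff with probability 1 − confidence — so the calibration
test draws a fresh n = 10 blank set for each of 10⁵ replicates and checks
the pooled exceedance against 0.001 within 3 binomial standard errors.
Zero blank spread collapses the cutoff to the mean and is flagged
degenerate.

### Retention and banding

The 1:4000 retention threshold is applied with a per-stage comparison
rule: `strict_greater` at the titer stage (a 1:4000 titer is discarded)
and `greater_equal` at the prolamin-sensitivity stage (a 1:4000 response
is conserved) — both behaviours are part of the contract and tested.

Cross-reactivity bands are assigned per (serum, antigen) from the
strongest signal (OD at the lowest dilution), relative to the serum's
maximum such signal: below cutoff → `-`; at most 0.050 OD → `+/-`;
then ≥ 75% of the serum maximum → `+++`, 25–75% → `++`, otherwise `+`.
The corner where an OD exceeds 0.050 but sits under 5% of the serum
maximum is not covered by the published intervals; it is assigned `+`
and flagged rather than silently guessed.

## Synthetic data with planted truth

Real inputs are database downloads with no ground truth, so every stage
is exercised on generated data where the right answer is known.

Each GPT template is `core0 + selected_insert + core1 + decoy + core2`:
the three cores (30/30/30 residues by default) are identical across all
grains and GPTs, hence shared by construction; inserts are drawn with
every window overlapping them globally novel (a rejection sampler
against a k-mer registry), hence unshared by construction. Selected
inserts are hydrophilic (drawn from the strictly-negative-GRAVY
alphabet), run-limited and 9–14 residues; decoys cycle through four
planted fates per family — hydrophobic composition, an implanted QQQQ
run, a copy planted into the exclusion set, and a 4-residue stub that
must fall below the mining threshold. Families are the template plus
i.i.d. substitutions (default rate 0.1, 20 sequences per family, 4
grains × 2 GPTs), so the alignment is exact by construction and
coordinates carry through to the consensus unchanged. The default
end-to-end scenario is expected to return exactly the planted selected
inserts and assign every decoy its planted reason, and does.

ELISA plates are 4PL curves `OD(d) = D + (A−D)/(1 + (d/C)^B)` over the
2000…256000 ladder with Gaussian OD noise (default sd 0.02) truncated at
zero, and Gaussian blanks (mean 0.045, sd 0.008, 16 wells) truncated at
zero; the analytic OD-1.0 crossing `C·((A−D)/(1−D) − 1)^{1/B}` is stored
as truth. Sequence and plate generation use independent child streams of
one seed and are byte-deterministic.

What the generator does **not** emulate: real gluten composition
(Q/P-richness beyond what the hydrophilic alphabet implies), indel-driven
alignment uncertainty (an indel mode exists but shifts coordinates and is
excluded from truth-recovery checks), plate-position effects, and
between-serum affinity variation. Passing the planted-recovery tests
therefore shows the pipeline is correct at its own contract, not that
NCBI-derived candidate counts would be reproduced — those depend on the
database snapshot and are explicitly out of scope.

## Problem sizes and numerics

Test and verification runs use: 500 random consensus sets (lengths ≤
200) for the mining oracle; 10⁵ replicates for Frey calibration; 1000
noisy plates for titer recovery; 100 replicates at substitution rate 0.2
for consensus fidelity; the default 4×2×20 grain set end to end. These
sizes give tight binomial error bars while keeping a full run in
seconds. Floating-point notes: GRAVY concatenation identity holds to
1e-12; candidate tables serialise floats with `repr` so read/write
round-trips are bit-exact; banding boundary tests use OD/maximum pairs
exactly representable in binary.

## Known limitations

* Sharedness is exact-match only; a single conservative substitution in
  another grain makes a window count as unique.
* The ranking is fully deterministic and cannot reproduce expert
  judgement applied in manual candidate selection; it is a transparent
  ordering, not a model of it.
* GPT abundance values ship as placeholders and should be replaced with
  measured gluten composition for real use.
* The interpolated titer assumes a locally monotone series around the
  crossing; strongly non-monotone data fall back to the discrete rule.
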