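# Methods

This note documents the models, defaults and numerical choices behind
`cernet`, and what the synthetic validation does and does not establish.

## Differential screen

Each feature is tested with the pooled-variance (Student's) two-sample
*t*-test on log2 values — the classical microarray choice; Welch's test is
available via `welch=True`. The signed fold change is computed from the
difference of log2 means (a geometric-mean ratio on the linear scale) and
sign-coded so |FC| ≥ 1 always: FC = +2^Δ for Δ ≥ 0, −2^(−Δ) otherwise. Calls
use strict inequalities (FC > 2, P < 0.05), so a feature exactly at either
boundary is not significant. Raw P drives the call; BH q-values are emitted
for information only, mirroring the microarray-era convention of filtering
on unadjusted P. Degenerate inputs: zero pooled variance with equal means
gives t = 0, P = 1; with unequal means the test is reported as P = 0 with a
`degenerate` flag and a warning, so that noiseless synthetic data can flow
through the pipeline instead of erroring. The design is treated as unpaired;
paired designs are out of scope.

## Target prediction

The aligner is an affine-gap Smith–Waterman (Gotoh) over the reversed miRNA
(3′→5′) versus the target (5′→3′), with complementarity as the match
criterion. Default weights follow the miRanda family: +5 Watson–Crick, +2
G:U wobble, −3 mismatch, gap open −9, gap extend −4, and substitution scores
in the miRNA seed (positions 2–8, 1-based from the 5′ end) scaled ×4. All
weights are configurable and echoed in the run summary. The seed scale of 4
was chosen so that the score of a perfect duplex sits well clear of the
acceptance floor: a perfect 22-nt duplex scores 5·15 + 20·7 = 215 > 160,
whereas a seed scale of 2 would cap every possible 22-nt alignment at 145
and make the published-style score floor unreachable. Sites are reported
greedily by descending score with non-overlapping target intervals;
tie-breaks (equal score → smaller target start; equal-score best-site →
lower energy → smaller start) make output fully deterministic. Coordinates
are 1-based inclusive on the target 5′→3′ strand. The DP kernel is JIT
compiled with numba when available, with an identical pure-Python fallback.

Duplex free energy is a nearest-neighbour stacking sum over consecutive
paired alignment columns plus a constant initiation penalty (+4.09
kcal/mol). Watson–Crick stack parameters are the standard Turner-group
RNA/RNA set (Xia et al. 1998); wobble-containing stacks use Turner-style
values of the published magnitude. Terminal-AU penalties, dangling ends and
loop terms are omitted — the estimate is a hybridisation score in the
RNAhybrid tradition, not a full secondary-structure fold, and is only used
against the fixed −30 kcal/mol ceiling. Gapped or unpaired columns break
the stack and contribute nothing.

The acceptance rule for a (miRNA, target) pair — score > 160 AND
ΔG ≤ −30 kcal/mol — reads the conventional sign of duplex energies: a
threshold of "+30" would be satisfied by every alignment and is vacuous.
Because both thresholds must hold, short accidental complements (≤ 7 nt)
cannot pass: they neither score near 160 nor stack deeply enough, which is
what keeps decoy acceptance near zero in validation.

## Coexpression filters

Pearson correlations are computed across **all samples pooled** over both
conditions. This is deliberate: the ceRNA sign pattern is driven by the
condition shift itself, and with a handful of samples per condition a
P < 0.001 cut is numerically unreachable within a single condition
(at n = 6, df = 4). P-values come from the exact t-transform
t = r√((n−2)/(1−r²)) on n−2 df, with |r| = 1 mapped to P = 0. Zero-variance
vectors raise a dedicated error; batch callers skip such pairs with a
warning. The lncRNA–mRNA filter is r > 0.90 with P < 0.001 (both strict).
The miRNA–target filter requires r < 0 with P < 0.05; the significance cut
is a package choice (configurable) since only the sign is inherent to the
model. By default **both** the miRNA–lncRNA and miRNA–mRNA anticorrelations
are required — the stricter reading of "both targets coexpressed negatively
with the same miRNA" — with `require_lnc_anticorr=False` to relax.

## Triplet assembly, networks, hubs

A stratum's triplets are exactly the (lncRNA, miRNA, mRNA) triples
satisfying: stratum sign pattern in the DE sets; passing target pairs for
both transcripts; both anticorrelations; and the lncRNA–mRNA coexpression
edge. Networks are strictly tripartite (lncRNA–miRNA and miRNA–mRNA edges
only); the lncRNA–mRNA correlation is evidence but not a drawn edge. Every
build validates tripartiteness, stratum sign consistency, provenance closure
(every edge traceable to ≥ 1 triplet) and the node set being the union of
triplet members. Node ids are namespaced by class (`lncRNA:X`) so a name
shared between classes can never collide. All outputs are ordered
lexicographically for diffable regression testing.

Hub extraction keeps lncRNAs with degree **strictly** above the threshold
(default 8, i.e. ≥ 9) and rebuilds the network from their provenance
triplets; hubs are defined on lncRNAs only. The hub rule is applied post hoc
to the finished network by default; `hub_stage="during"` instead carries the
hub subnetwork forward into enrichment, exposing both orderings of the rule.

## Enrichment

Upper-tail hypergeometric over-representation with the universe set to all
mRNAs on the expression platform — the only universe the pipeline can know,
and standard practice. Terms are intersected with the universe before
testing; empty terms are dropped. The EASE variant (k → k−1) is offered as a
flag; the exact test is the default for transparency. Reporting keeps terms
with raw P < 0.05 (BH q alongside) truncated to the top 30.

## Synthetic data

The generator emulates a two-condition microarray study:

| parameter | default | meaning |
|---|---|---|
| `n_per_condition` | 6 | samples per condition (12 pooled) |
| `de_effect` | 2.5 | log2 mean shift of planted features (FC ≈ 5.7) |
| `noise_sd` | 0.4 | per-feature within-condition sd, log2 units |
| `triplet_coupling` | 0.8 | shared fraction of within-condition variance |
| `n_planted_triplets` | 40 | per stratum |
| background features | 200/60/300 | lncRNA/miRNA/mRNA noise features |
| `seq_length_target` | 500 nt | target transcript length |
| `mirna_length` | 22 nt | planted miRNA length |
| `n_decoy_targets` | 60 | targets with no planted site |

Each planted triplet draws a shared latent factor: the signal
s = ±de·c + √ρ·σ·z (c the centred condition indicator, z ~ N(0,1) per
sample, ρ = `triplet_coupling`, σ = `noise_sd`) is added to the lncRNA and
mRNA and subtracted from the miRNA, each with independent residual noise of
sd √(1−ρ)·σ. Parametrising the coupling as a *variance fraction* keeps the
total within-condition variance at σ² regardless of ρ, so the differential
screen retains full power (t ≈ 10.8 at the defaults) while the pooled
population correlation of a planted pair is

r = (de²/4 + ρσ²) / (de²/4 + σ²) ≈ 0.981 at the defaults (≥ 0.95),

comfortably above the 0.90 filter at n = 12. An additive latent loading
large enough to reach r ≥ 0.95 would instead inflate within-condition sd to
≈ 1.3 log2 units and destroy DE recovery; the variance-fraction form is the
design that satisfies both requirements simultaneously. With 6 samples per
condition the pooled n = 12 makes P < 0.001 attainable at r > 0.9.

Sequences: each planted site is the exact reverse complement of its miRNA
spliced at a recorded 1-based position into a random backbone; decoys and
backbones are scrubbed of every ≥ 8-nt exact complement to any miRNA by
targeted point mutation (planted intervals protected). Planted miRNAs are
drawn subject to their perfect-duplex energy being ≤ −35 kcal/mol, a margin
below the −30 ceiling that emulates the GC content of real miRNAs and makes
the planted truth recoverable by construction. Gene sets: one term packed
with planted-up mRNAs (default 8 of 10 members) plus 30 uniform background
terms. All three generators draw from independent streams derived from one
seed; identical configs give byte-identical output trees.

What the simulation does **not** model: probe-level effects, background
correction, heavy-tailed noise, secondary-structure accessibility of sites,
isomiRs, or condition-specific rewiring. Passing recovery tests therefore
shows the pipeline implements its stated filters correctly and recovers
structure of the assumed form; it does not certify performance on real
arrays, where annotation quality and unmodelled correlation structure
dominate. One consequence visible in validation: all same-direction planted
features share the condition shift (population r ≈ 0.91), so occasional
cross-triplet coexpression passes the 0.90 cut and precision sits near
0.95 rather than 1 — the sequence evidence, not the correlation filter, is
what separates true triplets.

## Problem sizes used in validation

Unit and acceptance tests run the default design (40 triplets per stratum,
12 samples) across ten seeds, with oracle-equivalence suites at small sizes
(alignment ≤ 10×30 nt vs exhaustive enumeration, hypergeometric N ≤ 30 vs
exact ratios, assembly ≤ 50 features/class vs a triple loop). These sizes
give stable statistics while keeping the full suite to a few minutes on one
CPU core.

## Known limitations

* The published node counts of the motivating study cannot be regenerated:
  they require the original GEO matrices, era-specific transcript
  annotation, and a specific miRanda build with unstated parameters. The
  package's thresholds (FC > 2, P < 0.05; score > 160, ΔG ≤ −30; r > 0.90,
  P < 0.001; hub degree > 8) reproduce the *procedure*, validated on
  planted truth.
* Probe-to-gene collapsing is assumed done upstream; inputs are rejected,
  not imputed, when cells are missing or non-numeric.
* The energy model is a stacking sum, not a partition-function fold;
  absolute ΔG values should only be compared against the configured ceiling.
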