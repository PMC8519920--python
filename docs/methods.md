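# Methods

This note documents the models, numerical choices and generator defaults
behind `dnahyb`, and what the test suite's passing does and does not
establish.

## Sequence generation

Seed sequences are drawn uniformly over all A/C/G/T strings of a length
chosen uniformly in 18–26 nt with **no homopolymer run of length ≥ 3**
(the standard primer-design constraint). Uniformity over the admissible
set — not merely uniform per position — is achieved by weighting each
next-base choice with the exact count of admissible completions
(`seqops.count_admissible`); the counts follow the recurrence
`a' = 3(a+b), b' = a` over run states.

Each seed is expanded into a *family*: the seed, its reverse complement,
and a configurable number of mutants. *Minor* mutants apply one mutation
kind (insertion, deletion or substitution) once or twice; *severe*
mutants mix all three kinds 3–8 times (the count drawn uniformly — the
qualitative regime is "several, possibly many", and a bounded uniform
draw reproduces it without a long tail). Each mutant draw picks its
parent uniformly from {seed, revcomp(seed)}, so a family of
`2 + n_minor + n_severe` members spans near-perfect binders, weakly
related strands and everything between. Defaults: 6 minor + 3 severe
mutants per family. Mutants are not run-constrained (the constraint
applies to random seeds only), but members leaving the 18–26 nt window
are dropped so every sequence fits the fixed-width encodings.

Dataset assembly forms **all intra-family unordered pairings**
(self-pairs included — they are homodimers) and additionally samples
**cross-family pairings** (default: 0.35 of each round's intra-family
count, i.e. roughly a quarter of all records). The whole generated pool
is pairable in principle; quadratic all-against-all pairing is
intractable, but without a sampled cross-family mass the model would
never see truly unrelated strands — whose near-zero yields are the
bread and butter of orthogonal library screening — and systematically
overpredicts them. Pairs are deduplicated across the collection, yields
computed at 37/42/47/52/57/62 °C and labels assigned at the 57 °C
reference with the 0.2 threshold (0.2 itself is High). Rounds of new
families are added until the target size is reached *and* each of the
three yield-mass regions at 57 °C (< 0.1, ≥ 0.9, in-between) holds at
least 10 % of the records; a `max_rounds` guard turns impossible
targets into an error. With the defaults the generated distribution is
roughly 74 % low / 14 % high / 12 % mid — heavy mass at both extremes
with a populated middle, which is the regime the learning task needs.

## Built-in equilibrium oracle

The built-in yield backend is a deliberately simple **two-state**
nearest-neighbour model, not a partition-function computation:

1. the duplex geometry is the optimal semi-global alignment of `a`
   against `revcomp(b)` (match +5, mismatch −4, gap open 5, extend 2; a
   gap of length L costs `open + (L−1)·extend`; end gaps free);
2. maximal runs of consecutive Watson–Crick pairs contribute unified
   nearest-neighbour ΔH°/ΔS° stack terms plus duplex initiation terms
   that depend on the terminal pairs (A·T ends are penalised);
   every interruption between paired runs adds a fixed +0.5 kcal/mol
   to ΔH° (a documented constant, tunable in `thermo`);
3. ΔG°(T) = ΔH° − T·ΔS°/1000 and K = exp(−ΔG°/RT) with
   R = 1.9872×10⁻³ kcal/(mol·K); an entropic salt correction
   0.368·(n−1)·ln[Na⁺] cal/(mol·K) vanishes at the 1 M default;
4. the duplex concentration is the physical root of
   `K = x/((a₀−x)(b₀−x))` for heterodimers or `K = x/(a₀−2x)²` for
   homodimers (identical strands), the latter with a −1.4 cal/(mol·K)
   symmetry entropy and factor-2 stoichiometry. Homodimer yield is
   reported as the fraction of strands bound (`2x/a₀`) so both dimer
   types saturate at 1. Both quadratics are evaluated in a
   cancellation-free form (the discriminants simplify exactly to
   `K²(a₀−b₀)² + 2K(a₀+b₀) + 1` and `8Ka₀ + 1`), which keeps the root
   accurate from K → 0 to K → ∞; the test suite checks it against an
   independent bisection solver to 1e−10.

Because co-optimal alignments can tie, the pair is canonicalised over
strand swap and joint reverse complementation before alignment; yield is
therefore exactly invariant under both symmetries.

The oracle is an approximation with documented constants: it ignores
secondary-structure competition, complexes larger than 2, and loop
entropies. Parity with NUPACK is *not* asserted anywhere; the NUPACK
wrapper (v3 executables or the v4 Python API) exists behind the same
interface for users with an install. The per-strand "MFE" feature is
likewise a proxy — the nearest-neighbour ΔG° of the strand's best
alignment against its own reverse complement, capped at 0 — chosen so
the feature is computable without an external folding engine.

## Encodings and models

Pairs are encoded two ways: a 4×26×2 one-hot image (row order A,C,G,T,
left-aligned, zero right-padding; channel 0 = first strand) and a token
stream `<b> a <s> b <s>` over a 7-symbol vocabulary. Both are injective
and round-trip exactly. Because hybridisation is symmetric and the
dataset stores unordered pairs canonically (lexicographically sorted),
the predictor canonicalises input pairs the same way, which makes
predictions exactly swap-invariant.

The CNN consumes the image with one full-height 4×9 convolution
(realised as an equivalent 1-D convolution over 8 fused channels — the
4-row axis is consumed in one step, which saves millions of parameters
relative to an all-2-D stack), then 1-D convolutions of widths 9, 3, 3,
1, each followed by ReLU, batch normalisation and dropout, then dense
layers to a single sigmoid output. Default widths give ≈ 2.88 M
parameters (CNN: channels 48/64/128/128/128, head 768/256), ≈ 0.51 M
(CNN_Lite: 16/24/40/40/40, head 440/96) and ≈ 0.23 M for the
bi-directional 2-layer LSTM (embedding 32, hidden 80, first-position
readout). The ordering CNN > CNN_Lite > RNN is asserted; the exact
counts are design targets, not contracts. Dropout defaults to 0.2 for
the deep CNN and 0.1 for CNN_Lite (the small model under-fits at 0.2).

Training minimises MSE against the oracle yield at the reference
temperature with Adam (lr 1e−3, batch 512 by default; the learning-sanity
checks train CNN_Lite at batch 256, which converges slightly faster per
wall-clock here). The learning rate follows cosine annealing to 5 % of
its initial value; the best-validation-epoch weights are retained.
Batches of 8192, used in the original inference benchmarking context,
are impractical for an unrolled-LSTM autograd graph in memory, so
training defaults to 512 for both architectures; prediction accepts any
batch size and is batch-size invariant (batch normalisation uses running
statistics in eval mode, dropout is disabled).

The networks run on a small in-repo reverse-mode autograd engine over
numpy (`_autograd.py`) with im2col convolutions; all gradients are
finite-difference checked in the test suite, and runs are deterministic
given seeds under single-threaded execution.

## Evaluation

The positive class is High (yield ≥ 0.2). Precision/recall/F1 and MCC
are computed from the confusion matrix directly; AUROC uses mid-rank
tie handling on the continuous predicted yields (equivalently, the
tie-corrected Mann–Whitney statistic). Cross-temperature evaluation
freezes the model's predictions and re-derives truth labels per
temperature. Tests cross-check every metric against independent
pairwise-counting and closed-form implementations and against
scikit-learn.

## Library design

Candidate cross-hybridising pairs are those with
`LCS(a, revcomp(b)) ≥ k` (default k = 5; a direct, non-reverse-
complement mode is exposed as a flag). The builtin engine indexes all
k-mers of each reverse complement and joins on exact k-mers — sharing an
exact k-mer is *equivalent* to a common substring of length ≥ k, so the
engine equals the brute-force filter (verified exhaustively on small
libraries and on random 20-mer sets). Self-pairs and symmetric
duplicates are removed; dedup is idempotent. The optional MMseqs2 path
reproduces the documented search command (sensitivity 7.5, k-mer 5,
exact matching, ungapped alignment mode, min identity 0.25, min
alignment length 5, reverse-strand search) and applies the same dedup;
being heuristic, its hit set is reported, never asserted equal to the
exact filter. The conflict-free subset uses a greedy rule — repeatedly
drop the sequence with the highest conflict degree, ties broken by id —
chosen for determinism; it is a heuristic, not a maximum independent
set.

## Problem sizes and what passing means

The test suite and the acceptance script run at desk scale: ~50k
generated pairs for the learning checks (45 training epochs), ~4k pairs
for the classical baselines, 100–1000-sequence libraries for the design
workflow, and 100–1000 random instances per oracle-equivalence check.
These sizes were chosen so the full pipeline replays on one CPU core in
minutes while keeping every qualitative regime populated.

Passing tests establish: the fast engines equal their brute-force
oracles exactly; the thermodynamic closed forms are correct to solver
precision; the regressors can learn the *builtin oracle's* notion of
hybridisation from sequence pairs alone. They do not establish accuracy
against wet-lab data or against NUPACK's partition-function yields —
the builtin oracle is a simplified ground truth, and cross-backend
agreement is a reporting matter for users with a NUPACK install.

## Known limitations

- Two-state oracle: no intramolecular structure competition, no
  complexes beyond dimers, no kinetics.
- The LSTM is slow to train on CPU at scale; the learning-at-scale
  guarantees are stated for CNN_Lite.
- The greedy conflict-free subset is not optimal.
- Generated mutant families only emulate the published dataset's
  diversity (length window, extreme-heavy yield distribution); RNG
  streams differ, so record-level reproduction of any external dataset
  is out of scope.
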