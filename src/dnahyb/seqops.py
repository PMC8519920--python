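"""DNA sequence algebra and the mutation-driven family generator.

Sequences are plain Python strings over the alphabet ``{A, C, G, T}``,
validated and uppercased on ingestion by :func:`clean_sequence`.  Randomly
generated *seed* sequences forbid homopolymer runs of length >= 3 (a standard
primer-design constraint); mutants derived from seeds are free of that
constraint.

All randomness flows through :class:`numpy.random.Generator` objects derived
from explicit integer seeds, so every operation is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: inclusive length bounds for generator-produced seed sequences
SEED_LENGTH_RANGE = (18, 26)

#: maximum allowed homopolymer run in seed sequences (runs >= 3 forbidden)
MAX_SEED_RUN = 2

MutationKind = str
MUTATION_KINDS = ("insertion", "deletion", "substitution")


class InvalidSequenceError(ValueError):
    """A string is not a valid A/C/G/T DNA sequence."""


def clean_sequence(seq: str) -> str:
    """Validate and normalise a DNA string (uppercase A/C/G/T only).

    Raises :class:`InvalidSequenceError` naming the first offending position.
    """
    if not isinstance(seq, str):
        raise InvalidSequenceError(f"expected str, got {type(seq).__name__}")
    s = seq.upper()
    if not s:
        raise InvalidSequenceError("empty sequence")
    for i, ch in enumerate(s):
        if ch not in ALPHABET:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {i} (alphabet is A/C/G/T)"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (A<->T, C<->G, read 3'->5').

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = clean_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage of a sequence, in [0, 100]."""
    s = clean_sequence(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def max_homopolymer_run(seq: str) -> int:
    run = best = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Uniform sampling of run-constrained random sequences
# ---------------------------------------------------------------------------

def _completion_counts(length: int) -> tuple[np.ndarray, np.ndarray]:
    # a[n] / b[n]: number of admissible suffix completions of length n given the
    # current run is 1 / 2.  Recurrence: a' = 3(a+b) (switch base), b' = a
    # (extend a run of 1 by one).  Float64 is exact-enough for the ratios used
    # as sampling weights at primer lengths.
    a = np.empty(length + 1)
    b = np.empty(length + 1)
    a[0] = b[0] = 1.0
    for n in range(1, length + 1):
        a[n] = 3.0 * (a[n - 1] + b[n - 1])
        b[n] = a[n - 1]
    return a, b


def count_admissible(length: int) -> int:
    """Exact count of length-``length`` sequences with no homopolymer run >= 3."""
    if length < 1:
        raise ValueError("length must be >= 1")
    a, b = 4, 0  # ending in run of 1 / run of 2
    for _ in range(length - 1):
        a, b = 3 * (a + b), a
    return a + b


def random_sequence(length: int, rng_seed: int | np.random.Generator) -> str:
    """Draw uniformly over sequences of ``length`` with no run >= 3.

    Sequential sampling weighted by exact completion counts, so the draw is
    uniform over the admissible set (not merely uniform per position).
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    a_cnt, b_cnt = _completion_counts(length)
    out: list[str] = []
    run = 0
    for pos in range(length):
        remaining = length - pos - 1
        weights = np.empty(4)
        for k, base in enumerate(ALPHABET):
            if out and base == out[-1]:
                if run >= MAX_SEED_RUN:
                    weights[k] = 0.0  # would create a run of 3
                else:
                    weights[k] = b_cnt[remaining]  # run becomes 2
            else:
                weights[k] = a_cnt[remaining]  # run resets to 1
        weights /= weights.sum()
        choice = ALPHABET[rng.choice(4, p=weights)]
        run = run + 1 if out and choice == out[-1] else 1
        out.append(choice)
    return "".join(out)


def random_seed_sequence(rng: np.random.Generator,
                         length_range: tuple[int, int] = SEED_LENGTH_RANGE) -> str:
    """A run-constrained random sequence with length uniform in ``length_range``."""
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    return random_sequence(length, rng)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """A batch of point mutation events to apply to one sequence.

    *Minor* specs use a single mutation kind applied once or twice; *severe*
    specs mix all three kinds at least three times (default draw: uniform on
    3..8 events).
    """

    kinds: frozenset[MutationKind]
    count: int
    severity: str  # "minor" | "severe"
    rng_seed: int

    def __post_init__(self) -> None:
        if not self.kinds or not set(self.kinds) <= set(MUTATION_KINDS):
            raise ValueError(f"kinds must be a non-empty subset of {MUTATION_KINDS}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.severity == "minor":
            if len(self.kinds) != 1 or self.count not in (1, 2):
                raise ValueError("minor spec: exactly one kind, count in {1, 2}")
        elif self.severity == "severe":
            if set(self.kinds) != set(MUTATION_KINDS) or self.count < 3:
                raise ValueError("severe spec: all three kinds, count >= 3")
        else:
            raise ValueError(f"unknown severity {self.severity!r}")

    @staticmethod
    def minor(rng: np.random.Generator) -> "MutationSpec":
        kind = MUTATION_KINDS[rng.integers(3)]
        return MutationSpec(
            kinds=frozenset([kind]),
            count=int(rng.integers(1, 3)),
            severity="minor",
            rng_seed=int(rng.integers(2**31)),
        )

    @staticmethod
    def severe(rng: np.random.Generator) -> "MutationSpec":
        return MutationSpec(
            kinds=frozenset(MUTATION_KINDS),
            count=int(rng.integers(3, 9)),
            severity="severe",
            rng_seed=int(rng.integers(2**31)),
        )


def mutate(seq: str, spec: MutationSpec) -> str:
    """Apply exactly ``spec.count`` mutation events at RNG-chosen positions.

    Insertions lengthen by one base, deletions shorten by one, substitutions
    keep the length and never replace a base with itself.  Deterministic for a
    fixed ``spec.rng_seed``.  Raises if a deletion would empty the sequence.
    """
    s = list(clean_sequence(seq))
    rng = np.random.default_rng(spec.rng_seed)
    kinds = sorted(spec.kinds)
    for _ in range(spec.count):
        kind = kinds[rng.integers(len(kinds))] if len(kinds) > 1 else kinds[0]
        if kind == "deletion":
            if len(s) <= 1:
                raise ValueError("deletion would empty the sequence")
            del s[rng.integers(len(s))]
        elif kind == "insertion":
            pos = int(rng.integers(len(s) + 1))
            s.insert(pos, ALPHABET[rng.integers(4)])
        else:  # substitution
            pos = int(rng.integers(len(s)))
            alternatives = [b for b in ALPHABET if b != s[pos]]
            s[pos] = alternatives[rng.integers(3)]
    return "".join(s)


def expand_family(seed_seq: str, n_minor: int, n_severe: int,
                  rng_seed: int) -> set[str]:
    """Seed sequence, its reverse complement, and mutants of either.

    Each of the ``n_minor`` + ``n_severe`` mutant draws picks its parent
    uniformly from the seed and the seed's reverse complement, so a family
    spans both maximally-binding and unrelated partners.  Duplicates collapse.
    """
    if n_minor < 0 or n_severe < 0:
        raise ValueError("mutant counts must be >= 0")
    seed = clean_sequence(seed_seq)
    rc = reverse_complement(seed)
    rng = np.random.default_rng(rng_seed)
    family = {seed, rc}
    for severity in ["minor"] * n_minor + ["severe"] * n_severe:
        parent = seed if rng.integers(2) == 0 else rc
        spec = MutationSpec.minor(rng) if severity == "minor" else MutationSpec.severe(rng)
        family.add(mutate(parent, spec))
    return family


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping (validated)."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        out[record.id] = clean_sequence(str(record.seq))
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    """Write an ``{id: sequence}`` mapping as wrapped FASTA (ids round-trip)."""
    records = [SeqRecord(Seq(clean_sequence(s)), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
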