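"""Orthogonal-library design: exact longest-common-substring filtering,
candidate-pair generation, optional MMseqs2 orchestration, and batch yield
screening with a trained predictor.

Two strands can only anneal if one shares a consecutive stretch with the
other's reverse complement, so candidate cross-hybridisation pairs are
exactly those with ``LCS(a, reverse_complement(b)) >= k`` (default k = 5).
The builtin engine finds them by an exact k-mer join — two strings share a
common substring of length >= k iff they share an exact k-mer — which is
equivalent to the brute-force LCS filter while scaling near-linearly in the
library size.  Surviving pairs are deduplicated (no self-pairs, one
representative per unordered pair) and scored by the fast yield predictor;
pairs at or above the yield threshold are cross-hybridisation conflicts.
"""

from __future__ import annotations

import shutil
import subprocess
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqops import clean_sequence, reverse_complement

DEFAULT_MIN_LCS = 5
DEFAULT_YIELD_THRESHOLD = 0.2


@dataclass(frozen=True)
class LCSParams:
    """Threshold and comparison mode for the candidate filter.

    With ``against_revcomp`` (the default and the physically meaningful
    mode) sequence ``a`` is compared to ``reverse_complement(b)``; the
    direct mode compares the strands as written.
    """

    k: int = DEFAULT_MIN_LCS
    against_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class CandidatePairSet:
    """Deduplicated unordered id pairs that passed the LCS filter."""

    pairs: frozenset[tuple[str, str]]
    min_lcs: int
    source: str  # "builtin_kmer" | "mmseqs2"

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) survived dedup")
            if a > b:
                raise ValueError(f"pair ({a}, {b}) is not in canonical order")

    def __len__(self) -> int:
        return len(self.pairs)


def lcs_length(a: str, b: str) -> int:
    """Length of the longest *contiguous* substring common to two strings."""
    if not a or not b:
        raise ValueError("both strings must be non-empty")
    if len(b) < len(a):
        a, b = b, a
    previous = [0] * (len(a) + 1)
    best = 0
    for ch_b in b:
        current = [0] * (len(a) + 1)
        for i, ch_a in enumerate(a, start=1):
            if ch_a == ch_b:
                current[i] = previous[i - 1] + 1
                if current[i] > best:
                    best = current[i]
        previous = current
    return best


def dedup_pairs(raw: set[tuple[str, str]] | list[tuple[str, str]]
                ) -> frozenset[tuple[str, str]]:
    """Drop self-pairs and keep one representative per unordered pair.

    Idempotent: applying twice changes nothing.
    """
    out = set()
    for a, b in raw:
        if a == b:
            continue
        out.add((a, b) if a <= b else (b, a))
    return frozenset(out)


def candidate_pairs(seqs: dict[str, str],
                    params: LCSParams = LCSParams()) -> CandidatePairSet:
    """All unordered pairs whose LCS against the partner's reverse
    complement reaches the threshold, by exact k-mer join.

    Sharing an exact k-mer is equivalent to having a common substring of
    length >= k, so the output equals the brute-force filter
    ``{(a, b) : lcs_length(seq_a, reverse_complement(seq_b)) >= k}``.
    """
    seqs = {name: clean_sequence(s) for name, s in seqs.items()}
    if len(set(seqs)) != len(seqs):  # dict keys are unique by construction
        raise ValueError("duplicate sequence ids")
    k = params.k
    index: dict[str, set[str]] = defaultdict(set)
    for name, s in seqs.items():
        target = reverse_complement(s) if params.against_revcomp else s
        for i in range(len(target) - k + 1):
            index[target[i:i + k]].add(name)
    raw: set[tuple[str, str]] = set()
    for name, s in seqs.items():
        for i in range(len(s) - k + 1):
            for partner in index.get(s[i:i + k], ()):
                raw.add((name, partner))
    return CandidatePairSet(pairs=dedup_pairs(raw), min_lcs=k,
                            source="builtin_kmer")


# ---------------------------------------------------------------------------
# MMseqs2 orchestration (optional external accelerator)
# ---------------------------------------------------------------------------

class MMseqs2NotFoundError(RuntimeError):
    pass


class MMseqs2Error(RuntimeError):
    pass


def build_mmseqs_commands(fasta_path: str, workdir: str,
                          min_lcs: int = DEFAULT_MIN_LCS,
                          max_seq_len: int = 20) -> list[list[str]]:
    """The exact MMseqs2 command sequence for the reverse-complement LCS
    search: nucleotide createdb, then a maximum-sensitivity exact-k-mer
    ungapped search restricted to the reverse strand, then hit-table export.
    """
    db = f"{workdir}/db"
    aln = f"{workdir}/aln"
    tmp = f"{workdir}/tmp"
    hits = f"{workdir}/hits.tsv"
    return [
        ["mmseqs", "createdb", str(fasta_path), db, "--dbtype", "2"],
        ["mmseqs", "search", db, db, aln, tmp,
         "-s", "7.5",
         "-k", str(min_lcs),
         "--max-seqs", "10000",
         "--exact-kmer-matching", "1",
         "--spaced-kmer-mode", "0",
         "--min-seq-id", "0.25",
         "--alignment-mode", "4",
         "-e", "inf",
         "--min-aln-len", str(min_lcs),
         "--sub-mat", "nucleotide:dnafull.out,aminoacid:blosum62.out",
         "--max-seq-len", str(max_seq_len),
         "--strand", "0",
         "--search-type", "3"],
        ["mmseqs", "convertalis", db, db, aln, hits,
         "--format-output", "query,target"],
    ]


def mmseqs2_candidates(fasta_path, workdir,
                       min_lcs: int = DEFAULT_MIN_LCS,
                       max_seq_len: int = 20) -> CandidatePairSet:
    """Run the MMseqs2 reverse-complement search and dedup its hit table.

    MMseqs2 is a heuristic accelerator: its output is expected to contain
    the exact filter's pairs but is not guaranteed identical.  Raises
    :class:`MMseqs2NotFoundError` when the binary is absent.
    """
    from .seqops import read_fasta

    if not read_fasta(fasta_path):
        raise ValueError(f"empty FASTA file: {fasta_path}")
    if shutil.which("mmseqs") is None:
        raise MMseqs2NotFoundError(
            "the 'mmseqs' binary is not on PATH; install MMseqs2 or use the "
            "builtin candidate_pairs engine")
    commands = build_mmseqs_commands(str(fasta_path), str(workdir),
                                     min_lcs, max_seq_len)
    for cmd in commands:
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise MMseqs2Error(
                f"{' '.join(cmd[:2])} exited with {proc.returncode}: "
                f"{proc.stderr}")
    hit_table = pd.read_csv(f"{workdir}/hits.tsv", sep="\t", header=None,
                            names=["query", "target"], dtype=str)
    raw = set(zip(hit_table["query"], hit_table["target"]))
    return CandidatePairSet(pairs=dedup_pairs(raw), min_lcs=min_lcs,
                            source="mmseqs2")


# ---------------------------------------------------------------------------
# Yield screening and conflict report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignReport:
    """Outcome of screening candidate pairs with the yield predictor."""

    threshold: float
    pair_table: pd.DataFrame  # id_a, id_b, lcs, predicted_yield, conflict
    conflict_degree: dict[str, int]
    conflict_free: frozenset[str]

    @property
    def conflicts(self) -> pd.DataFrame:
        return self.pair_table[self.pair_table["conflict"]]

    def write_tsv(self, path) -> None:
        table = self.pair_table.copy()
        table["predicted_yield"] = table["predicted_yield"].map(
            lambda v: f"{v:.6f}")
        table.to_csv(path, sep="\t", index=False)


def design_report(candidates: CandidatePairSet, predictor,
                  seqs: dict[str, str],
                  threshold: float = DEFAULT_YIELD_THRESHOLD,
                  batch_size: int = 512) -> DesignReport:
    """Batch-predict yields for candidate pairs and flag conflicts.

    A candidate pair at or above the yield threshold is a predicted
    cross-hybridisation conflict.  The conflict-free subset is built
    greedily: while conflicts remain, drop the sequence with the highest
    conflict degree (ties broken by id for determinism).
    """
    seqs = {name: clean_sequence(s) for name, s in seqs.items()}
    pair_list = sorted(candidates.pairs)
    missing = {name for pair in pair_list for name in pair} - set(seqs)
    if missing:
        raise KeyError(f"no sequence for ids: {sorted(missing)}")
    if pair_list:
        scores = predictor.predict(
            [(seqs[a], seqs[b]) for a, b in pair_list], batch_size=batch_size)
    else:
        scores = np.empty(0)
    rows = []
    degree: dict[str, int] = {name: 0 for name in seqs}
    conflict_edges = []
    for (a, b), score in zip(pair_list, scores):
        conflict = bool(score >= threshold)
        rows.append({"id_a": a, "id_b": b,
                     "lcs": lcs_length(seqs[a], reverse_complement(seqs[b])),
                     "predicted_yield": float(score), "conflict": conflict})
        if conflict:
            degree[a] += 1
            degree[b] += 1
            conflict_edges.append((a, b))
    survivors = set(seqs)
    working = dict(degree)
    edges = list(conflict_edges)
    while edges:
        worst = max(working, key=lambda name: (working[name], name))
        survivors.discard(worst)
        kept = []
        for a, b in edges:
            if worst in (a, b):
                working[a] -= 1
                working[b] -= 1
            else:
                kept.append((a, b))
        edges = kept
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "lcs",
                                        "predicted_yield", "conflict"])
    return DesignReport(threshold=threshold, pair_table=table,
                        conflict_degree=degree,
                        conflict_free=frozenset(survivors))
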