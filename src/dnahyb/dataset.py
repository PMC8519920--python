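"""Assembly of the labelled multi-temperature hybridisation dataset.

Records are unordered sequence pairs with equilibrium yields at each
requested temperature.  The binary label at the reference temperature uses
the 0.2 cut-off: yields below 0.2 are ``Low``, 0.2 and above are ``High``.
Splits are stratified over the ten 0.1-wide yield deciles so every split
preserves the full yield distribution, and the on-disk format is a plain
TSV (gzip accepted transparently).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from . import seqops, thermo

LABEL_THRESHOLD = 0.2
SPLIT_NAMES = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)

#: default mutant draws per family (the mutation mix is a generator setting;
#: the minor:severe ratio below reproduces the heavy low/high mass with a
#: populated mid range)
DEFAULT_N_MINOR = 6
DEFAULT_N_SEVERE = 3


def label_for(yield_fraction: float, threshold: float = LABEL_THRESHOLD) -> str:
    return "Low" if yield_fraction < threshold else "High"


@dataclass(frozen=True)
class YieldRecord:
    """One unordered sequence pair with per-temperature yields and a label."""

    pair_id: str
    seq_a: str
    seq_b: str
    yields: dict[float, float]
    label: str

    def __post_init__(self) -> None:
        for t, y in self.yields.items():
            if not 0.0 <= y <= 1.0:
                raise ValueError(f"yield at {t} out of [0, 1]: {y}")
        if self.label not in ("Low", "High"):
            raise ValueError(f"label must be Low or High, got {self.label!r}")


@dataclass
class HybridisationDataset:
    """A collection of :class:`YieldRecord` with optional split assignments."""

    records: list[YieldRecord]
    reference_temperature: float = thermo.DEFAULT_TEMPERATURE
    splits: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.splits:
            ids = {r.pair_id for r in self.records}
            assigned: set[str] = set()
            for name, members in self.splits.items():
                if assigned & members:
                    raise ValueError(f"split {name!r} overlaps another split")
                assigned |= members
            if assigned != ids:
                raise ValueError("splits must partition the record ids")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.records[0].yields) if self.records else []

    def yields_at(self, temperature: float) -> np.ndarray:
        self._check_temperature(temperature)
        return np.array([r.yields[temperature] for r in self.records])

    def subset(self, split: str) -> "HybridisationDataset":
        if split not in self.splits:
            raise KeyError(f"no split {split!r}; have {sorted(self.splits)}")
        members = self.splits[split]
        return HybridisationDataset(
            records=[r for r in self.records if r.pair_id in members],
            reference_temperature=self.reference_temperature,
        )

    def _check_temperature(self, temperature: float) -> None:
        temps = self.temperatures
        if temperature not in temps:
            raise KeyError(
                f"temperature {temperature} not in dataset; available: {temps}")


@dataclass(frozen=True)
class YieldHistogram:
    """Decile binning of yields plus the three-way extreme summary."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    extreme_counts: dict[str, int]  # low: y < 0.1, high: y >= 0.9, mid: rest


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def assemble_dataset(seed_count: int, target_size: int,
                     temps=thermo.DEFAULT_TEMPERATURES,
                     backend: str = "builtin",
                     rng_seed: int = 0,
                     n_minor: int = DEFAULT_N_MINOR,
                     n_severe: int = DEFAULT_N_SEVERE,
                     reference_temperature: float = thermo.DEFAULT_TEMPERATURE,
                     initial_concentration: float = thermo.DEFAULT_CONCENTRATION,
                     variety_min: float = 0.1,
                     cross_fraction: float = 0.35,
                     max_rounds: int = 200) -> HybridisationDataset:
    """Generate families of related sequences and score all intra-family
    pairings until the target size and variety constraints are met.

    Each round draws ``seed_count`` fresh run-constrained seed sequences,
    expands every seed into a mutant family (minor and severe mutants of the
    seed and of its reverse complement), forms all unordered intra-family
    pairings (self-pairs included: they are homodimers), and samples
    cross-family pairings — the full generated set is pairable, and the
    sampled fraction (``cross_fraction`` of each round's intra-family
    count) keeps truly unrelated pairs represented without quadratic
    blow-up.  Pairs are deduplicated across the whole collection and
    yields computed at every temperature.  Rounds repeat until at least
    ``target_size`` unique pairs exist and each of the three yield-mass
    regions at the reference temperature (< 0.1, >= 0.9, in-between) holds
    at least ``variety_min`` of the records; a ``max_rounds`` guard
    prevents non-termination on impossible targets.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    temps = [float(t) for t in temps]
    if reference_temperature not in temps:
        raise ValueError("reference temperature must be among the computed temps")
    rng = np.random.default_rng(rng_seed)
    seen: set[tuple[str, str]] = set()
    records: list[YieldRecord] = []
    ref_yields: list[float] = []
    families: list[list[str]] = []

    def add_pair(a: str, b: str) -> None:
        key = _pair_key(a, b)
        if key in seen:
            return
        seen.add(key)
        results = thermo.yield_profile(
            key[0], key[1], temps, backend=backend,
            initial_concentration=initial_concentration)
        yields = {t: r.yield_fraction for t, r in zip(temps, results)}
        records.append(YieldRecord(
            pair_id=f"p{len(records):07d}",
            seq_a=key[0], seq_b=key[1],
            yields=yields,
            label=label_for(yields[reference_temperature]),
        ))
        ref_yields.append(yields[reference_temperature])

    def variety_ok() -> bool:
        y = np.asarray(ref_yields)
        if len(y) == 0:
            return False
        return (float((y < 0.1).mean()) >= variety_min
                and float((y >= 0.9).mean()) >= variety_min
                and float(((y >= 0.1) & (y < 0.9)).mean()) >= variety_min)

    for _round in range(max_rounds):
        if len(records) >= target_size and variety_ok():
            break
        intra_before = len(records)
        for _ in range(seed_count):
            seed_seq = seqops.random_seed_sequence(rng)
            family = seqops.expand_family(
                seed_seq, n_minor, n_severe, rng_seed=int(rng.integers(2**31)))
            # indel chains can leave the 18-26 nt window; the assembled
            # dataset keeps only in-range members
            lo, hi = seqops.SEED_LENGTH_RANGE
            family = {s for s in family if lo <= len(s) <= hi}
            families.append(sorted(family))
            for a, b in combinations_with_replacement(sorted(family), 2):
                add_pair(a, b)
        n_cross = int(cross_fraction * (len(records) - intra_before))
        if len(families) >= 2:
            for _ in range(n_cross):
                i, j = rng.choice(len(families), size=2, replace=False)
                a = families[i][rng.integers(len(families[i]))]
                b = families[j][rng.integers(len(families[j]))]
                add_pair(a, b)
    else:
        raise RuntimeError(
            f"variety/size targets not reached within {max_rounds} rounds "
            f"({len(records)} records)")
    return HybridisationDataset(records=records,
                                reference_temperature=reference_temperature)


def histogram(ds: HybridisationDataset, temperature: float) -> YieldHistogram:
    """Decile counts of yields at one temperature (last bin closed at 1.0).

    An empty dataset gives all-zero counts at any temperature.
    """
    edges = np.round(np.linspace(0.0, 1.0, 11), 10)
    if not ds.records:
        return YieldHistogram(bin_edges=tuple(edges), counts=(0,) * 10,
                              extreme_counts={"low": 0, "high": 0, "mid": 0})
    y = ds.yields_at(temperature)
    counts, _ = np.histogram(y, bins=edges)
    extreme = {
        "low": int((y < 0.1).sum()),
        "high": int((y >= 0.9).sum()),
        "mid": int(((y >= 0.1) & (y < 0.9)).sum()),
    }
    return YieldHistogram(bin_edges=tuple(edges), counts=tuple(int(c) for c in counts),
                          extreme_counts=extreme)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions) -> list[int]:
    exact = [n * f for f in fractions]
    floors = [int(np.floor(e)) for e in exact]
    short = n - sum(floors)
    order = np.argsort([f - e for f, e in zip(floors, exact)])  # most negative first
    for idx in order[:short]:
        floors[idx] += 1
    return floors


def stratified_split(ds: HybridisationDataset,
                     fractions=DEFAULT_FRACTIONS,
                     rng_seed: int = 0) -> HybridisationDataset:
    """Assign train/validation/test splits stratified over yield deciles.

    Strata are the ten 0.1-wide bins of the yield at the reference
    temperature; within each stratum records are allocated proportionally
    (largest-remainder rounding, so counts are within one record of the
    target per stratum) after a deterministic shuffle.
    """
    fractions = tuple(fractions)
    if len(fractions) != len(SPLIT_NAMES):
        raise ValueError(f"need {len(SPLIT_NAMES)} fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(rng_seed)
    y = ds.yields_at(ds.reference_temperature)
    bins = np.minimum((y * 10).astype(int), 9)
    splits: dict[str, set[str]] = {name: set() for name in SPLIT_NAMES}
    for b in range(10):
        idx = np.flatnonzero(bins == b)
        if idx.size == 0:
            continue
        idx = idx[rng.permutation(idx.size)]
        alloc = _largest_remainder(idx.size, fractions)
        start = 0
        for name, n in zip(SPLIT_NAMES, alloc):
            for i in idx[start:start + n]:
                splits[name].add(ds.records[i].pair_id)
            start += n
    return HybridisationDataset(records=list(ds.records),
                                reference_temperature=ds.reference_temperature,
                                splits=splits)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def _temp_col(t: float) -> str:
    return f"yield_{t:g}"


def write_dataset(ds: HybridisationDataset, path) -> None:
    """Write the dataset as TSV (``.gz`` suffix compresses transparently)."""
    temps = ds.temperatures
    split_of: dict[str, str] = {}
    for name, members in ds.splits.items():
        for pid in members:
            split_of[pid] = name
    rows = []
    for r in ds.records:
        row = {"pair_id": r.pair_id, "seq_a": r.seq_a, "seq_b": r.seq_b}
        for t in temps:
            row[_temp_col(t)] = f"{r.yields[t]:.6f}"
        row["label"] = r.label
        row["split"] = split_of.get(r.pair_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class DatasetSchemaError(ValueError):
    """A dataset TSV does not match the expected schema."""


def read_dataset(path,
                 reference_temperature: float = thermo.DEFAULT_TEMPERATURE
                 ) -> HybridisationDataset:
    """Read a dataset TSV written by :func:`write_dataset` (lossless)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pair_id", "seq_a", "seq_b", "label"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetSchemaError(f"missing columns: {sorted(missing)}")
    temp_cols = [c for c in df.columns if c.startswith("yield_")]
    if not temp_cols:
        raise DatasetSchemaError("no yield_<temperature> columns found")
    temps = {c: float(c[len("yield_"):]) for c in temp_cols}
    records: list[YieldRecord] = []
    splits: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            yields = {temps[c]: float(row[c]) for c in temp_cols}
            record = YieldRecord(pair_id=row["pair_id"],
                                 seq_a=seqops.clean_sequence(row["seq_a"]),
                                 seq_b=seqops.clean_sequence(row["seq_b"]),
                                 yields=yields, label=row["label"])
        except (ValueError, KeyError) as exc:
            raise DatasetSchemaError(f"malformed row at line {i}: {exc}") from exc
        records.append(record)
        split = row.get("split", "")
        if split:
            if split not in SPLIT_NAMES:
                raise DatasetSchemaError(
                    f"unknown split {split!r} at line {i}")
            splits.setdefault(split, set()).add(record.pair_id)
    return HybridisationDataset(records=records,
                                reference_temperature=reference_temperature,
                                splits=splits)
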