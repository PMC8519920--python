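"""Equilibrium duplex-yield oracles.

Yield is the equilibrium concentration of the two-strand duplex divided by
the initial single-strand concentration, a number in [0, 1].  Two backends
share one interface:

``builtin``
    A self-contained two-state nearest-neighbour model: the duplex geometry
    is taken from the semi-global alignment of ``a`` against
    ``reverse_complement(b)``; runs of consecutive Watson-Crick pairs are
    scored with the unified nearest-neighbour dH/dS stack parameters plus
    duplex initiation and terminal A.T terms; each interruption between
    paired runs adds a fixed destabilisation penalty.  The duplex
    equilibrium concentration then follows in closed form from
    ``K = x / ((a0 - x)(b0 - x))`` (heterodimer) or ``K = x / (a0 - 2x)^2``
    with a symmetry entropy correction (homodimer).

``nupack``
    A wrapper around the external NUPACK tool (v3 ``complexes`` +
    ``concentrations`` executables, or the v4 Python API when importable),
    enumerating complexes to size 2.  Requires a separate NUPACK install.

The builtin backend is an approximation with documented constants, not a
re-implementation of NUPACK; cross-backend agreement is reported by callers,
never asserted here.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np

from .seqops import clean_sequence, reverse_complement

#: gas constant, kcal/(mol.K)
R_KCAL = 1.9872e-3

DEFAULT_TEMPERATURES = (37.0, 42.0, 47.0, 52.0, 57.0, 62.0)
DEFAULT_TEMPERATURE = 57.0
DEFAULT_CONCENTRATION = 1e-6  # mol/L per strand

#: destabilisation added to dH (kcal/mol) per interruption between paired runs
STACK_BREAK_PENALTY = 0.5

#: entropy correction for homodimer (self-complex) formation, cal/(mol.K)
HOMODIMER_SYMMETRY_DS = -1.4

# Unified nearest-neighbour parameters for DNA/DNA stacks in 1 M NaCl:
# (dH kcal/mol, dS cal/(mol.K)) keyed by the 5'->3' dimer on one strand,
# the other strand being its Watson-Crick complement.
_NN_STACKS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# a stack read on the complementary strand has identical parameters
for _dimer in list(_NN_STACKS):
    _NN_STACKS.setdefault(reverse_complement(_dimer), _NN_STACKS[_dimer])

#: duplex initiation per terminal pair: G.C vs A.T ends
_INIT_TERMINAL = {"G": (0.1, -2.8), "C": (0.1, -2.8),
                  "A": (2.3, 4.1), "T": (2.3, 4.1)}


class ThermoError(RuntimeError):
    """Base class for thermodynamic backend failures."""


class ThermoConfigurationError(ThermoError):
    """A backend is unavailable or misconfigured."""


class ThermoBackendError(ThermoError):
    """An external backend ran but failed or produced unparseable output."""


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for a yield computation."""

    temperature_celsius: float = DEFAULT_TEMPERATURE
    initial_concentration: float = DEFAULT_CONCENTRATION
    sodium_molar: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature_celsius <= 100.0:
            raise ValueError("temperature must be within [0, 100] Celsius")
        if self.initial_concentration <= 0 or self.sodium_molar <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def temperature_kelvin(self) -> float:
        return self.temperature_celsius + 273.15


@dataclass(frozen=True)
class DuplexEnergy:
    """Two-state duplex formation thermodynamics."""

    delta_H: float      # kcal/mol
    delta_S: float      # cal/(mol.K)
    delta_G_at_T: float  # kcal/mol at the evaluation temperature
    K_eq: float         # association constant, 1/M
    structure_annotation: tuple  # paired runs: (a_start, a_end, b_start, b_end)


@dataclass(frozen=True)
class YieldResult:
    """Equilibrium outcome for one sequence pair at one condition."""

    yield_fraction: float
    duplex_concentration: float
    monomer_concentrations: tuple[float, float]
    backend: str
    temperature_celsius: float = DEFAULT_TEMPERATURE


# ---------------------------------------------------------------------------
# Builtin two-state nearest-neighbour backend
# ---------------------------------------------------------------------------

def _paired_runs(a: str, b_rc: str) -> list[tuple[int, int, int, int]]:
    # maximal runs of consecutive Watson-Crick pairs in the optimal
    # semi-global alignment of a against reverse_complement(b)
    from .features import aligned_match_positions

    matches = aligned_match_positions(a, b_rc)
    runs: list[tuple[int, int, int, int]] = []
    for i, j in matches:
        if runs and runs[-1][1] == i and runs[-1][3] == j:
            s = runs[-1]
            runs[-1] = (s[0], i + 1, s[2], j + 1)
        else:
            runs.append((i, i + 1, j, j + 1))
    return runs


def duplex_energy(a: str, b: str, cond: ThermoConditions) -> DuplexEnergy:
    """Nearest-neighbour dH/dS of the alignment-derived duplex of ``a:b``.

    The pair is first canonicalised over strand swap and joint reverse
    complementation, so co-optimal-alignment tie-breaks cannot make the
    energy depend on strand order.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    a, b = min((a, b), (b, a),
               (reverse_complement(a), reverse_complement(b)),
               (reverse_complement(b), reverse_complement(a)))
    homodimer = a == b
    runs = _paired_runs(a, reverse_complement(b))

    dH = 0.0
    dS = 0.0
    n_paired = sum(r[1] - r[0] for r in runs)
    for a_start, a_end, _, _ in runs:
        for i in range(a_start, a_end - 1):
            h, s = _NN_STACKS[a[i:i + 2]]
            dH += h
            dS += s
    if n_paired >= 2:
        # initiation depends on the duplex's two outermost pairs
        first_base = a[runs[0][0]]
        last_base = a[runs[-1][1] - 1]
        for base in (first_base, last_base):
            h, s = _INIT_TERMINAL[base]
            dH += h
            dS += s
        dH += STACK_BREAK_PENALTY * max(0, len(runs) - 1)
        if homodimer:
            dS += HOMODIMER_SYMMETRY_DS
        # entropic salt correction (vanishes at the 1 M reference)
        dS += 0.368 * (n_paired - 1) * math.log(cond.sodium_molar)
    else:
        # fewer than two pairs: no stable duplex; dG = 0 gives K = 1 /M,
        # i.e. a vanishing yield at micromolar concentrations
        dH = dS = 0.0
        runs = []

    t_k = cond.temperature_kelvin
    dG = dH - t_k * dS / 1000.0
    K = math.exp(-dG / (R_KCAL * t_k))
    return DuplexEnergy(delta_H=dH, delta_S=dS, delta_G_at_T=dG, K_eq=K,
                        structure_annotation=tuple(runs))


def _hetero_duplex_conc(K: float, a0: float, b0: float) -> float:
    # smaller root of K x^2 - (K(a0+b0)+1) x + K a0 b0 = 0, evaluated in the
    # cancellation-free form x = gamma / q with q = (|beta| + sqrt(disc)) / 2
    beta = -(K * (a0 + b0) + 1.0)
    gamma = K * a0 * b0
    # discriminant simplified analytically to avoid cancellation at large K:
    # beta^2 - 4 K gamma = K^2 (a0 - b0)^2 + 2 K (a0 + b0) + 1
    disc = (K * (a0 - b0)) ** 2 + 2.0 * K * (a0 + b0) + 1.0
    q = 0.5 * (-beta + math.sqrt(disc))
    return gamma / q


def _homo_duplex_conc(K: float, a0: float) -> float:
    # smaller root of 4K x^2 - (4K a0 + 1) x + K a0^2 = 0
    beta = -(4.0 * K * a0 + 1.0)
    gamma = K * a0 * a0
    # beta^2 - 16 K gamma = 8 K a0 + 1 exactly
    disc = 8.0 * K * a0 + 1.0
    q = 0.5 * (-beta + math.sqrt(disc))
    return gamma / q


def builtin_yield(a: str, b: str,
                  cond: ThermoConditions = ThermoConditions()) -> YieldResult:
    """Two-state nearest-neighbour equilibrium yield of a strand pair.

    Identical strands form a homodimer with factor-2 stoichiometry: the
    reported yield is then the fraction of strands bound in duplexes
    (``2x / a0``), so both dimer types saturate at 1 as K grows.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    energy = duplex_energy(a, b, cond)
    c0 = cond.initial_concentration
    if a == b:
        x = _homo_duplex_conc(energy.K_eq, c0)
        monomer = c0 - 2.0 * x
        result = YieldResult(
            yield_fraction=float(np.clip(2.0 * x / c0, 0.0, 1.0)),
            duplex_concentration=x,
            monomer_concentrations=(monomer, monomer),
            backend="builtin",
            temperature_celsius=cond.temperature_celsius,
        )
    else:
        x = _hetero_duplex_conc(energy.K_eq, c0, c0)
        result = YieldResult(
            yield_fraction=float(np.clip(x / c0, 0.0, 1.0)),
            duplex_concentration=x,
            monomer_concentrations=(c0 - x, c0 - x),
            backend="builtin",
            temperature_celsius=cond.temperature_celsius,
        )
    return result


def self_structure_mfe(seq: str, cond: ThermoConditions = ThermoConditions(),
                       backend: str = "builtin") -> float:
    """Minimum-free-energy proxy for single-strand self-structure, kcal/mol.

    The builtin estimate is the nearest-neighbour free energy of the
    strand's best alignment against its own reverse complement (its
    self-complementarity), capped at 0: unstructured strands report 0,
    strongly self-complementary strands report a negative value.
    """
    seq = clean_sequence(seq)
    if backend == "nupack":
        return _nupack_mfe(seq, cond)
    energy = duplex_energy(seq, seq, cond)
    return min(0.0, energy.delta_G_at_T)


# ---------------------------------------------------------------------------
# NUPACK wrapper (external tool; v3 executables or v4 Python API)
# ---------------------------------------------------------------------------

_NUPACK_REMEDIATION = (
    "NUPACK was not found. Install NUPACK 3 and place the 'complexes' and "
    "'concentrations' executables on PATH (and set NUPACKHOME), or install "
    "the NUPACK 4 Python package; alternatively use backend='builtin'."
)


def _have_nupack4() -> bool:
    try:
        import nupack  # noqa: F401
        return True
    except ImportError:
        return False


def _have_nupack3() -> bool:
    return bool(shutil.which("complexes") and shutil.which("concentrations"))


def _nupack4_yield(a: str, b: str, cond: ThermoConditions) -> YieldResult:
    import nupack

    model = nupack.Model(material="dna", celsius=cond.temperature_celsius,
                         sodium=cond.sodium_molar)
    sa = nupack.Strand(a, name="a")
    homodimer = a == b
    strands = {sa: cond.initial_concentration}
    if not homodimer:
        sb = nupack.Strand(b, name="b")
        strands[sb] = cond.initial_concentration
    tube = nupack.Tube(strands=strands,
                       complexes=nupack.SetSpec(max_size=2), name="t")
    result = nupack.tube_analysis(tubes=[tube], model=model)
    conc = {tuple(sorted(s.name for s in cx.strands)): c
            for cx, c in result.tubes[tube].complex_concentrations.items()}
    if homodimer:
        duplex = conc.get(("a", "a"), 0.0)
        monomer = conc.get(("a",), 0.0)
        yield_fraction = 2.0 * duplex / cond.initial_concentration
        monomers = (monomer, monomer)
    else:
        duplex = conc.get(("a", "b"), 0.0)
        yield_fraction = duplex / cond.initial_concentration
        monomers = (conc.get(("a",), 0.0), conc.get(("b",), 0.0))
    return YieldResult(yield_fraction=float(np.clip(yield_fraction, 0.0, 1.0)),
                       duplex_concentration=float(duplex),
                       monomer_concentrations=monomers,
                       backend="nupack",
                       temperature_celsius=cond.temperature_celsius)


def _run_nupack3(args: list[str], cwd: str) -> None:
    proc = subprocess.run(args, cwd=cwd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ThermoBackendError(
            f"{args[0]} exited with status {proc.returncode}: {proc.stderr}")


def _nupack3_yield(a: str, b: str, cond: ThermoConditions) -> YieldResult:
    homodimer = a == b
    n_strands = 1 if homodimer else 2
    with tempfile.TemporaryDirectory(prefix="dnahyb-nupack-") as tmp:
        prefix = "pair"
        lines = [str(n_strands), a]
        if not homodimer:
            lines.append(b)
        lines.append("2")  # max complex size
        with open(os.path.join(tmp, prefix + ".in"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
        _run_nupack3(["complexes", "-T", str(cond.temperature_celsius),
                      "-material", "dna", prefix], cwd=tmp)
        with open(os.path.join(tmp, prefix + ".con"), "w") as fh:
            for _ in range(n_strands):
                fh.write(f"{cond.initial_concentration:.6e}\n")
        _run_nupack3(["concentrations", prefix], cwd=tmp)
        eq_path = os.path.join(tmp, prefix + ".eq")
        try:
            rows = []
            with open(eq_path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("%"):
                        continue
                    rows.append(line.split())
        except OSError as exc:
            raise ThermoBackendError(f"missing NUPACK output {eq_path}") from exc
    # .eq columns: id, permutation-and-composition counts, dG, concentration
    duplex = 0.0
    monomers = [0.0] * n_strands
    for row in rows:
        try:
            counts = [int(v) for v in row[1:1 + n_strands]]
            concentration = float(row[-1])
        except (ValueError, IndexError) as exc:
            raise ThermoBackendError(
                f"unparseable NUPACK concentrations row: {row!r}") from exc
        total = sum(counts)
        if total == 2:
            duplex += concentration
        elif total == 1:
            monomers[counts.index(1)] += concentration
    if homodimer:
        yield_fraction = 2.0 * duplex / cond.initial_concentration
        monomers = [monomers[0], monomers[0]]
    else:
        yield_fraction = duplex / cond.initial_concentration
    return YieldResult(yield_fraction=float(np.clip(yield_fraction, 0.0, 1.0)),
                       duplex_concentration=duplex,
                       monomer_concentrations=(monomers[0], monomers[-1]),
                       backend="nupack",
                       temperature_celsius=cond.temperature_celsius)


def nupack_yield(a: str, b: str,
                 cond: ThermoConditions = ThermoConditions()) -> YieldResult:
    """Equilibrium duplex yield from NUPACK (complexes enumerated to size 2).

    Prefers the v4 Python API when importable, otherwise drives the v3
    ``complexes``/``concentrations`` executables through temporary ``.in``
    and ``.con`` files.  Raises :class:`ThermoConfigurationError` with
    install instructions when neither is available.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    if _have_nupack4():
        return _nupack4_yield(a, b, cond)
    if _have_nupack3():
        return _nupack3_yield(a, b, cond)
    raise ThermoConfigurationError(_NUPACK_REMEDIATION)


def _nupack_mfe(seq: str, cond: ThermoConditions) -> float:
    if _have_nupack4():
        import nupack
        model = nupack.Model(material="dna", celsius=cond.temperature_celsius,
                             sodium=cond.sodium_molar)
        result = nupack.mfe(strands=[seq], model=model)
        return float(result[0].energy) if result else 0.0
    if shutil.which("mfe"):
        with tempfile.TemporaryDirectory(prefix="dnahyb-nupack-") as tmp:
            with open(os.path.join(tmp, "s.in"), "w") as fh:
                fh.write(seq + "\n")
            _run_nupack3(["mfe", "-T", str(cond.temperature_celsius),
                          "-material", "dna", "s"], cwd=tmp)
            with open(os.path.join(tmp, "s.mfe")) as fh:
                lines = [ln.strip() for ln in fh
                         if ln.strip() and not ln.startswith("%")]
        try:
            return float(lines[1])
        except (IndexError, ValueError) as exc:
            raise ThermoBackendError("unparseable NUPACK mfe output") from exc
    raise ThermoConfigurationError(_NUPACK_REMEDIATION)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

BACKENDS = ("builtin", "nupack")


def compute_yield(a: str, b: str, cond: ThermoConditions = ThermoConditions(),
                  backend: str = "builtin") -> YieldResult:
    """Dispatch a yield computation to the selected backend."""
    if backend == "builtin":
        return builtin_yield(a, b, cond)
    if backend == "nupack":
        return nupack_yield(a, b, cond)
    raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")


def yield_profile(a: str, b: str, temps,
                  backend: str = "builtin",
                  initial_concentration: float = DEFAULT_CONCENTRATION,
                  sodium_molar: float = 1.0) -> list[YieldResult]:
    """One :class:`YieldResult` per requested temperature, same backend."""
    temps = list(temps)
    if not temps:
        raise ValueError("temperature list must be non-empty")
    return [compute_yield(a, b,
                          ThermoConditions(temperature_celsius=t,
                                           initial_concentration=initial_concentration,
                                           sodium_molar=sodium_molar),
                          backend=backend)
            for t in temps]
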