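"""Semi-global alignment scoring, per-pair feature extraction and the
classical-baseline harness.

Alignment is the Gotoh affine-gap algorithm via Biopython's
:class:`Bio.Align.PairwiseAligner`, configured semi-globally: end gaps on
either sequence are free, internal gaps cost ``open + (L - 1) * extend`` for a
gap of length L.  A high score of ``a`` against ``reverse_complement(b)``
signals that the two strands can anneal end to end.

The 9-feature baseline table per pair comprises: the annealing alignment
score, a per-strand minimum-free-energy proxy for self-structure, per-strand
equilibrium single-strand and homodimer concentrations (size-2 self-complex),
and per-strand GC percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from . import seqops
from .seqops import clean_sequence, gc_content, reverse_complement

FEATURE_NAMES = (
    "alignment_score",
    "mfe_a", "mfe_b",
    "ss_conc_a", "ss_conc_b",
    "homodimer_conc_a", "homodimer_conc_b",
    "gc_a", "gc_b",
)

BASELINE_ALGORITHMS = ("LDA", "QDA", "RF", "NN")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for semi-global DNA alignment.

    Defaults follow the standard DNA full matrix (match +5 / mismatch -4)
    with gap open 5 and gap extend 2; penalties are stored as non-negative
    magnitudes.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are non-negative magnitudes")
        if self.mismatch > self.match:
            raise ValueError("mismatch score must not exceed match score")


DEFAULT_ALIGNMENT = AlignmentParams()


@lru_cache(maxsize=16)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    # free end gaps on both sequences => semi-global
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def semi_global_align(a: str, b: str,
                      params: AlignmentParams = DEFAULT_ALIGNMENT,
                      traceback: bool = False):
    """Semi-global affine-gap alignment score of two DNA sequences.

    Returns the score, or ``(score, aligned_blocks)`` when ``traceback`` is
    requested, where ``aligned_blocks`` is a list of ``(a_start, a_end,
    b_start, b_end)`` gap-free aligned segments.
    """
    a = clean_sequence(a)
    b = clean_sequence(b)
    aligner = _aligner(params)
    if not traceback:
        return float(aligner.score(a, b))
    alignment = aligner.align(a, b)[0]
    blocks = [
        (int(ta), int(tb), int(qa), int(qb))
        for (ta, tb), (qa, qb) in zip(*[seg.tolist() for seg in alignment.aligned],
                                      strict=True)
    ]
    return float(alignment.score), blocks


def aligned_match_positions(a: str, b: str,
                            params: AlignmentParams = DEFAULT_ALIGNMENT
                            ) -> list[tuple[int, int]]:
    """Positions ``(i, j)`` where the optimal semi-global alignment pairs
    identical characters ``a[i] == b[j]``."""
    _, blocks = semi_global_align(a, b, params, traceback=True)
    matches: list[tuple[int, int]] = []
    for ta, tb, qa, _qb in blocks:
        for off in range(tb - ta):
            i, j = ta + off, qa + off
            if a[i] == b[j]:
                matches.append((i, j))
    return matches


def align_for_annealing(a: str, b: str,
                        params: AlignmentParams = DEFAULT_ALIGNMENT) -> float:
    """Annealing proxy: align ``a`` against ``reverse_complement(b)``.

    Symmetric in ``(a, b)`` because the substitution matrix is symmetric and
    reverse-complementing mirrors the alignment.
    """
    return semi_global_align(a, reverse_complement(b), params)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The 9 pre-computed baseline features for one sequence pair."""

    alignment_score: float
    mfe_a: float
    mfe_b: float
    ss_conc_a: float
    ss_conc_b: float
    homodimer_conc_a: float
    homodimer_conc_b: float
    gc_a: float
    gc_b: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def extract_features(pair: tuple[str, str], backend: str = "builtin",
                     conditions=None,
                     params: AlignmentParams = DEFAULT_ALIGNMENT
                     ) -> FeatureVector:
    """Compute the 9-feature baseline vector for a sequence pair.

    Thermodynamic features (MFE proxy, single-strand and homodimer
    equilibrium concentrations) come from the selected thermo backend's
    size-2 self-complex analysis at the given conditions; GC content and the
    alignment score need no backend.
    """
    from . import thermo  # deferred: thermo uses this module's aligner

    a, b = clean_sequence(pair[0]), clean_sequence(pair[1])
    cond = conditions or thermo.ThermoConditions()
    score = align_for_annealing(a, b, params)
    per_strand = {}
    for tag, s in (("a", a), ("b", b)):
        try:
            mfe = thermo.self_structure_mfe(s, cond, backend=backend)
            self_complex = thermo.compute_yield(s, s, cond, backend=backend)
        except thermo.ThermoConfigurationError:
            # no backend: alignment and GC stay available, the
            # thermodynamic features are flagged missing
            per_strand[tag] = (float("nan"),) * 3
            continue
        per_strand[tag] = (mfe, self_complex.monomer_concentrations[0],
                           self_complex.duplex_concentration)
    return FeatureVector(
        alignment_score=score,
        mfe_a=per_strand["a"][0], mfe_b=per_strand["b"][0],
        ss_conc_a=per_strand["a"][1], ss_conc_b=per_strand["b"][1],
        homodimer_conc_a=per_strand["a"][2], homodimer_conc_b=per_strand["b"][2],
        gc_a=gc_content(a), gc_b=gc_content(b),
    )


def feature_table(pairs: Sequence[tuple[str, str]], backend: str = "builtin",
                  conditions=None) -> np.ndarray:
    """Stack feature vectors for many pairs into an ``(n, 9)`` array."""
    return np.stack([extract_features(p, backend, conditions).as_array()
                     for p in pairs])


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

def fit_baselines(features: np.ndarray, labels: Sequence[str],
                  algorithms: Sequence[str] = BASELINE_ALGORITHMS,
                  test_features: np.ndarray | None = None,
                  test_labels: Sequence[str] | None = None,
                  rng_seed: int = 0) -> dict:
    """Fit LDA / QDA / random-forest / shallow-NN classifiers on the feature
    table and score them with the standard classification report.

    When a test split is not supplied the training data is scored (useful for
    smoke checks only).  Returns ``{algorithm: EvaluationReport}``.
    """
    from sklearn.discriminant_analysis import (
        LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis)
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    from .evaluate import classification_report

    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("baseline fitting needs both Low and High present")
    unknown = set(algorithms) - set(BASELINE_ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    y = np.array([1 if lab == "High" else 0 for lab in labels])
    if test_features is None:
        test_features, test_labels = features, labels
    y_test = np.array([1 if lab == "High" else 0 for lab in test_labels])

    factories = {
        "LDA": lambda: make_pipeline(StandardScaler(), LinearDiscriminantAnalysis()),
        "QDA": lambda: make_pipeline(StandardScaler(),
                                     QuadraticDiscriminantAnalysis(reg_param=1e-2)),
        "RF": lambda: RandomForestClassifier(n_estimators=100,
                                             random_state=rng_seed, n_jobs=1),
        "NN": lambda: make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=300,
                          random_state=rng_seed)),
    }
    reports = {}
    for name in algorithms:
        model = factories[name]()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # QDA collinearity etc. on tiny data
            model.fit(features, y)
            scores = model.predict_proba(test_features)[:, 1]
        # scores are class probabilities, so the decision point is 0.5
        reports[name] = classification_report(
            ["High" if t else "Low" for t in y_test], scores, threshold=0.5)
    return reports
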