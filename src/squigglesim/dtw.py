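"""DTW alignment, warping-path indel proxies, and ensemble comparison.

The alignment of a squiggle against its gold standard yields two warping
paths.  A gold position matched by several squiggle events must have been
time-stretched to fit the squiggle: the surplus matches are read as
*insertions* (duplicated events).  Symmetrically, a squiggle event matched
by several gold positions marks gold bases that produced no event —
*deletions*.  These proxies are exact on noiseless duplication-only mocks
built from a gold with pairwise-distinct values, and remain informative
estimators in the presence of noise.

The ensemble-level mean DTW distance to the gold standard (the Frechet
measure of consensus-averaging work) summarizes how far a whole ensemble
sits from its reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dp
from .errors import EmptyEnsembleError, LengthError
from .signal_model import Ensemble, GoldStandard, Squiggle, ensure_normalized

#: Table layout for pooled indel-count fractions: counts 0..5 for
#: insertions, 0..3 for deletions, the top bin absorbing larger counts.
DEFAULT_C_MAX_INSERTIONS = 5
DEFAULT_C_MAX_DELETIONS = 3


@dataclass(frozen=True)
class Alignment:
    """A DTW alignment: distance, warping path and per-index multiplicities.

    ``path`` is an ordered (L, 2) array of (gold_index, squiggle_index)
    pairs from (0, 0) to (n-1, m-1) with steps in {(1,0),(0,1),(1,1)}.
    """

    distance: float
    path: np.ndarray
    gold_multiplicity: np.ndarray
    squiggle_multiplicity: np.ndarray


@dataclass(frozen=True)
class IndelCounts:
    """Per-position surplus path multiplicities (multiplicity - 1)."""

    insertions_per_base: np.ndarray
    deletions_per_event: np.ndarray

    @property
    def total_insertions(self) -> int:
        return int(self.insertions_per_base.sum())

    @property
    def total_deletions(self) -> int:
        return int(self.deletions_per_event.sum())


@dataclass(frozen=True)
class IndelProfile:
    """Ensemble distribution of per-position indel counts.

    ``insertion_mean[c]`` is the mean across squiggles of the fraction of
    gold positions with insertion count c (counts above the top bin are
    pooled into it); ``insertion_std`` the population std across squiggles.
    Deletion fields likewise, over squiggle positions.
    """

    insertion_mean: np.ndarray
    insertion_std: np.ndarray
    deletion_mean: np.ndarray
    deletion_std: np.ndarray
    n_squiggles: int
    c_max_insertions: int = DEFAULT_C_MAX_INSERTIONS
    c_max_deletions: int = DEFAULT_C_MAX_DELETIONS


@dataclass(frozen=True)
class EnsembleComparison:
    """Mean +/- std of per-squiggle DTW distances to the gold standard."""

    mean_distance: float
    std_distance: float
    distances: np.ndarray

    @property
    def n_squiggles(self) -> int:
        return int(self.distances.size)


def _events(x) -> np.ndarray:
    if isinstance(x, GoldStandard):
        return x.squiggle.events
    if isinstance(x, Squiggle):
        return x.events
    return np.asarray(x, dtype=float)


def dtw_align(a, b) -> Alignment:
    """Globally optimal DTW of ``a`` (gold side) against ``b`` (squiggle side).

    Local cost |a_i - b_j| summed along an unconstrained, boundary-anchored
    monotone path; exact O(n*m) dynamic program with a deterministic
    backtrace (ties: diagonal, then squiggle-consuming, then gold-consuming
    step).
    """
    x = _events(a)
    y = _events(b)
    if x.size == 0 or y.size == 0:
        raise LengthError("cannot align empty series")
    D = _dp.accumulated_cost(x, y)
    path = _dp.backtrace(D)
    gold_mult = np.bincount(path[:, 0], minlength=x.size)
    squig_mult = np.bincount(path[:, 1], minlength=y.size)
    return Alignment(
        distance=float(D[-1, -1]),
        path=path,
        gold_multiplicity=gold_mult,
        squiggle_multiplicity=squig_mult,
    )


def indel_counts(al: Alignment) -> IndelCounts:
    """Read surplus warping-path multiplicities as insertion/deletion counts."""
    return IndelCounts(
        insertions_per_base=al.gold_multiplicity - 1,
        deletions_per_event=al.squiggle_multiplicity - 1,
    )


def _pooled_fractions(counts: np.ndarray, c_max: int) -> np.ndarray:
    pooled = np.minimum(counts, c_max)
    return np.bincount(pooled, minlength=c_max + 1) / counts.size


def indel_profile(
    ens: Ensemble,
    gold: GoldStandard,
    c_max_insertions: int = DEFAULT_C_MAX_INSERTIONS,
    c_max_deletions: int = DEFAULT_C_MAX_DELETIONS,
) -> IndelProfile:
    """Per-count indel fractions, mean +/- std across an ensemble.

    Comparisons are performed in z-normalized space: inputs not already
    flagged as normalized are z-normalized first (each squiggle on its own
    moments, the standard DTW-study convention).
    """
    if len(ens) == 0:
        raise EmptyEnsembleError("indel_profile needs a non-empty ensemble")
    g = ensure_normalized(gold.squiggle)
    ins_rows = []
    del_rows = []
    for s in ens:
        al = dtw_align(g, ensure_normalized(s))
        ic = indel_counts(al)
        ins_rows.append(_pooled_fractions(ic.insertions_per_base, c_max_insertions))
        del_rows.append(_pooled_fractions(ic.deletions_per_event, c_max_deletions))
    ins = np.vstack(ins_rows)
    dels = np.vstack(del_rows)
    return IndelProfile(
        insertion_mean=ins.mean(axis=0),
        insertion_std=ins.std(axis=0),
        deletion_mean=dels.mean(axis=0),
        deletion_std=dels.std(axis=0),
        n_squiggles=len(ens),
        c_max_insertions=c_max_insertions,
        c_max_deletions=c_max_deletions,
    )


def frechet_distance(ens: Ensemble, gold: GoldStandard) -> EnsembleComparison:
    """Mean +/- std of per-squiggle DTW distances to the gold standard."""
    if len(ens) == 0:
        raise EmptyEnsembleError("frechet_distance needs a non-empty ensemble")
    g = ensure_normalized(gold.squiggle)
    d = np.array([dtw_align(g, ensure_normalized(s)).distance for s in ens])
    return EnsembleComparison(
        mean_distance=float(d.mean()),
        std_distance=float(d.std()),
        distances=d,
    )
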