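"""Gold-standard squiggles, z-normalization and synthetic fixtures.

A *squiggle* is the series of segmented step-current levels a nanopore
sequencer produces, ideally one event per ratcheted nucleotide.  Given the
pore's k-mer current model, the noise-free ("gold standard") squiggle of a
known sequence is obtained by sliding a k-length window along the sequence
and looking up the expected current of each word.  Everything downstream —
simulation, cleaning, DTW proxies — is defined relative to that gold
standard, and comparisons are performed on z-normalized signals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyEnsembleError,
    InvalidSequenceError,
    LengthError,
    ZeroVarianceError,
)

DNA_ALPHABET = "ACGT"


@dataclass(frozen=True)
class KmerModel:
    """Lookup table mapping each k-mer over {A,C,G,T} to a mean current level.

    RNA models are stored with U mapped to T so one alphabet serves both.
    Only the mean level is kept: the gold standard is noise-free by
    definition, so per-k-mer spread columns are ignored on read.
    """

    k: int
    levels: dict[str, float]
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        expected = 4 ** self.k
        if len(self.levels) != expected:
            raise ValueError(
                f"k-mer model must contain all {expected} {self.k}-mers, "
                f"got {len(self.levels)}"
            )
        vals = np.fromiter(self.levels.values(), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("k-mer levels must all be finite")


@dataclass(frozen=True)
class Squiggle:
    """One segmented stepped-current event series.

    ``normalized`` records whether the events are in z-normalized space
    (mean 0, population standard deviation 1 at normalization time);
    ``norm_params`` keeps the original (mean, std) so the transform is
    invertible.  Noise injected *after* z-normalization intentionally leaves
    the flag set: the events live in z-space even though their realized
    moments are perturbed.
    """

    id: str
    events: np.ndarray
    normalized: bool = False
    norm_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 1 or ev.size < 1:
            raise LengthError("a squiggle needs at least one event")
        object.__setattr__(self, "events", ev)

    def __len__(self) -> int:
        return int(self.events.size)


@dataclass(frozen=True)
class GoldStandard:
    """The noise-free squiggle of a known sequence under a k-mer model."""

    squiggle: Squiggle
    source_sequence: str | None = None
    kmer_model_id: str = ""
    k: int | None = None

    def __post_init__(self) -> None:
        if self.source_sequence is not None and self.k is not None:
            expect = len(self.source_sequence) - self.k + 1
            if len(self.squiggle) != expect:
                raise LengthError(
                    f"gold length {len(self.squiggle)} != sequence length "
                    f"- k + 1 = {expect}"
                )

    def __len__(self) -> int:
        return len(self.squiggle)

    @property
    def events(self) -> np.ndarray:
        return self.squiggle.events


@dataclass
class Ensemble:
    """An ordered collection of squiggles, optionally tied to a gold standard."""

    squiggles: list[Squiggle]
    gold: GoldStandard | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.squiggles:
            raise EmptyEnsembleError("ensemble must contain at least one squiggle")
        states = {s.normalized for s in self.squiggles}
        if len(states) > 1:
            raise ValueError("ensemble mixes normalized and raw squiggles")

    def __len__(self) -> int:
        return len(self.squiggles)

    def __iter__(self):
        return iter(self.squiggles)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.squiggles], dtype=int)


def _clean_sequence(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def build_gold_squiggle(
    sequence: str, model: KmerModel, squiggle_id: str = "gold"
) -> GoldStandard:
    """Slide the k-mer model along ``sequence`` to obtain the gold squiggle.

    The result has one event per k-mer window, i.e. ``len(sequence) - k + 1``
    events; RNA input (U) is accepted and mapped to T.
    """
    seq = _clean_sequence(sequence)
    k = model.k
    if len(seq) < k:
        raise LengthError(f"sequence length {len(seq)} < k = {k}")
    bad = set(seq) - set(DNA_ALPHABET)
    if bad:
        raise InvalidSequenceError(f"sequence contains invalid characters: {sorted(bad)}")
    events = np.array(
        [model.levels[seq[i : i + k]] for i in range(len(seq) - k + 1)], dtype=float
    )
    return GoldStandard(
        squiggle=Squiggle(id=squiggle_id, events=events),
        source_sequence=seq,
        kmer_model_id=model.model_id,
        k=k,
    )


def z_normalize(s: Squiggle) -> Squiggle:
    """Remove the signal mean and scale to population standard deviation 1.

    The population (divide-by-N) convention makes the unit-variance contract
    exact for any length; the original (mean, std) are recorded in
    ``norm_params``.  Idempotent up to numerical tolerance.
    """
    if len(s) < 2:
        raise LengthError("z-normalization needs at least two events")
    mean = float(np.mean(s.events))
    std = float(np.std(s.events))  # population convention
    if std == 0.0:
        raise ZeroVarianceError(f"squiggle {s.id!r} is constant; cannot z-normalize")
    return replace(
        s,
        events=(s.events - mean) / std,
        normalized=True,
        norm_params=(mean, std),
    )


def ensure_normalized(s: Squiggle) -> Squiggle:
    """Return ``s`` unchanged if already in z-space, else z-normalize it."""
    return s if s.normalized else z_normalize(s)


def make_kmer_model(
    rng: np.random.Generator,
    k: int,
    level_mean: float = 100.0,
    level_spread: float = 15.0,
    model_id: str = "synthetic",
) -> KmerModel:
    """Draw a synthetic pore model: i.i.d. Gaussian level per k-mer.

    Continuous levels guarantee (a.s.) that gold event values are pairwise
    distinct except at repeated k-mers — the property the DTW indel proxies
    are exact under.
    """
    kmers = ["".join(p) for p in itertools.product(DNA_ALPHABET, repeat=k)]
    levels = rng.normal(level_mean, level_spread, size=len(kmers))
    return KmerModel(k=k, levels=dict(zip(kmers, levels.tolist())), model_id=model_id)


def make_fixture(
    seed: int, sequence_length: int, k: int = 5
) -> tuple[KmerModel, GoldStandard]:
    """Deterministic synthetic (pore model, gold standard) pair.

    Stands in for an OEM pore model plus a spike-in control sequence: the
    reference sequence is uniform over {A,C,G,T} and k-mer levels are i.i.d.
    Gaussian, so the gold squiggle has the pairwise-distinct values that the
    proxy-exactness results rely on.
    """
    if sequence_length < k:
        raise LengthError("sequence_length must be >= k")
    rng = np.random.default_rng(seed)
    model = make_kmer_model(rng, k, model_id=f"synthetic-seed{seed}")
    sequence = "".join(rng.choice(list(DNA_ALPHABET), size=sequence_length))
    gold = build_gold_squiggle(sequence, model)
    return model, gold
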