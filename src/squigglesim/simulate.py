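"""Generative models for mocked (distorted) squiggles.

A mocked squiggle is built from the z-normalized gold standard by walking
its positions in order: each base is either deleted (emitting nothing,
possibly skipping a run of bases) or emitted once plus a number of extra
duplicate copies, after which Gaussian white noise is added to reach a
target SNR on the z-normalized scale.

Two families of models are supported:

* **local** models apply the same per-base probabilities to every base of
  every squiggle (`chan_bernoulli`: at most one duplicate; `chan_geometric`:
  geometric repeated duplication; `local_table`: counts drawn from the
  rate-curve categorical at a fixed reference LSF).  They produce narrow
  length distributions.
* **global** models first draw a per-squiggle target LSF from a length
  model and tie the probabilities to it (`global_linear`:
  P = I0 + I1(1 - 1/LSF) with geometric duplication, and likewise for
  deletions; `global_table`: counts from the rate-curve categorical at the
  drawn LSF).  They reproduce the broad empirical length spread.

Ground truth (per-base insertion counts, deleted positions, noise std) is
retained for every mock so DTW-proxy estimates can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .characterize import (
    LengthModel,
    RateCurve,
    TailModel,
    deletion_pmf,
    insertion_pmf,
)
from .errors import ConfigError
from .signal_model import Ensemble, GoldStandard, Squiggle, ensure_normalized

LOCAL_KINDS = ("chan_bernoulli", "chan_geometric", "local_table")
GLOBAL_KINDS = ("global_linear", "global_table")
MODEL_KINDS = LOCAL_KINDS + GLOBAL_KINDS


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification of a mocked ensemble.

    For linear kinds the insertion/deletion rates are percent-scale
    P = I0 + I1(1 - 1/LSF) (chan kinds use I0 alone as the per-base
    percentage); table kinds draw counts from the clamped/renormalized
    categorical of ``rate_curve`` + ``tail``.  ``snr_target`` is the target
    z-normalized SNR (noise std = 1/snr_target); ``float("inf")`` disables
    noise.  A seed is mandatory: all randomness flows from one generator.
    """

    model_kind: str
    n_squiggles: int
    seed: int
    i0: float = 0.0
    i1: float = 0.0
    d0: float = 0.0
    d1: float = 0.0
    rate_curve: RateCurve | None = None
    tail: TailModel | None = None
    length_model: LengthModel | None = None
    local_ref_lsf: float = 1.7
    snr_target: float = float("inf")

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.model_kind!r}")
        if self.model_kind in GLOBAL_KINDS and self.length_model is None:
            raise ConfigError(f"{self.model_kind} requires a length model")
        if self.model_kind.endswith("_table") and self.rate_curve is None:
            raise ConfigError(f"{self.model_kind} requires a rate curve")
        if self.snr_target <= 0:
            raise ConfigError("snr_target must be positive (or infinite)")
        if self.n_squiggles < 1:
            raise ConfigError("n_squiggles must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass(frozen=True)
class MockRecord:
    """One mocked squiggle plus the ground truth that produced it."""

    squiggle: Squiggle
    target_lsf: float | None
    insertion_counts: np.ndarray  # per gold position; 0 at deleted positions
    deleted: np.ndarray  # boolean mask over gold positions
    noise_std: float = 0.0

    @property
    def realized_lsf(self) -> float:
        return len(self.squiggle) / float(self.insertion_counts.size)


def _linear_prob(p0: float, p1: float, lsf: float) -> float:
    p = (p0 + p1 * (1.0 - 1.0 / lsf)) / 100.0
    return float(np.clip(p, 0.0, 1.0))


def sample_length(model: LengthModel, rng: np.random.Generator) -> float:
    """Inverse-CDF draw of a target LSF, rejecting draws <= 1 (cap 1000)."""
    for _ in range(1000):
        lsf = float(model.ppf(rng.random()))
        if lsf > 1.0:
            return lsf
    raise ConfigError("length model rejected 1000 consecutive draws at LSF <= 1")


def _draw_extras(
    cfg: SimConfig, p_ins: float, lsf: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-position extra-copy counts for one squiggle."""
    if cfg.model_kind.endswith("_table"):
        pmf = insertion_pmf(cfg.rate_curve, cfg.tail, lsf)
        return rng.choice(pmf.size, size=n, p=pmf)
    if p_ins >= 1.0:
        raise ConfigError(f"insertion probability {p_ins} >= 1 after clamping")
    if cfg.model_kind == "chan_bernoulli":
        return (rng.random(n) < p_ins).astype(np.int64)
    # repeated duplication: emit-another with probability p_ins
    if p_ins == 0.0:
        return np.zeros(n, dtype=np.int64)
    return rng.geometric(1.0 - p_ins, size=n) - 1


def _deletion_law(
    cfg: SimConfig, lsf: float
) -> tuple[float, np.ndarray | None]:
    """(firing probability, run-length pmf over {1,2,3} or None for runs of 1)."""
    if cfg.model_kind.endswith("_table") and cfg.rate_curve is not None and cfg.rate_curve.deletion:
        pmf = deletion_pmf(cfg.rate_curve, lsf)
        p_del = float(1.0 - pmf[0])
        if p_del <= 0.0:
            return 0.0, None
        return p_del, pmf[1:] / pmf[1:].sum()
    return _linear_prob(cfg.d0, cfg.d1, lsf), None


def _make_mock(
    gold: GoldStandard,
    cfg: SimConfig,
    lsf: float,
    target_lsf: float | None,
    squiggle_id: str,
    rng: np.random.Generator,
) -> MockRecord:
    gvals = gold.events
    n = gvals.size
    extras = _draw_extras(cfg, _linear_prob(cfg.i0, cfg.i1, lsf), lsf, n, rng)
    p_del, run_pmf = _deletion_law(cfg, lsf)
    deleted = np.zeros(n, dtype=bool)
    if p_del > 0.0:
        u = rng.random(n)
        i = 0
        while i < n:
            if u[i] < p_del:
                run = 1 if run_pmf is None else 1 + int(rng.choice(run_pmf.size, p=run_pmf))
                hi = min(i + run, n)
                deleted[i:hi] = True
                extras[i:hi] = 0
                i = hi
            else:
                i += 1
    repeats = np.where(deleted, 0, 1 + extras)
    events = np.repeat(gvals, repeats)
    if events.size == 0:
        # pathological all-deleted draw; keep the first event so the squiggle is valid
        deleted[0] = False
        events = gvals[:1].copy()
    squiggle = Squiggle(
        id=squiggle_id,
        events=events,
        normalized=gold.squiggle.normalized,
        norm_params=gold.squiggle.norm_params,
    )
    return MockRecord(
        squiggle=squiggle,
        target_lsf=target_lsf,
        insertion_counts=np.asarray(extras, dtype=np.int64),
        deleted=deleted,
    )


def simulate_global(
    gold: GoldStandard, cfg: SimConfig, rng: np.random.Generator, squiggle_id: str = "mock"
) -> MockRecord:
    """One mock under a global (squiggle-specific) model: draw a target LSF,
    evaluate the probabilities there, then walk the gold positions."""
    if cfg.model_kind not in GLOBAL_KINDS:
        raise ConfigError(f"{cfg.model_kind} is not a global kind")
    lsf = sample_length(cfg.length_model, rng)
    return _make_mock(gold, cfg, lsf, lsf, squiggle_id, rng)


def simulate_local(
    gold: GoldStandard, cfg: SimConfig, rng: np.random.Generator, squiggle_id: str = "mock"
) -> MockRecord:
    """One mock under a local (base-specific) model: the same probabilities
    apply to every base of every squiggle (table kinds evaluate the curves
    at the fixed reference LSF)."""
    if cfg.model_kind not in LOCAL_KINDS:
        raise ConfigError(f"{cfg.model_kind} is not a local kind")
    return _make_mock(gold, cfg, cfg.local_ref_lsf, None, squiggle_id, rng)


def inject_noise(
    s: Squiggle, snr_target: float, rng: np.random.Generator
) -> Squiggle:
    """Add Gaussian white noise with std 1/snr_target in z-normalized space.

    The output is *not* re-normalized: re-normalizing would shrink the
    realized noise std and the signal would no longer sit at the target
    SNR.  An infinite target returns the squiggle unchanged.
    """
    if snr_target <= 0:
        raise ConfigError("snr_target must be positive")
    if np.isinf(snr_target):
        return s
    z = ensure_normalized(s)
    noise_std = 1.0 / snr_target
    return replace(z, events=z.events + rng.normal(0.0, noise_std, size=len(z)))


def simulate_ensemble(
    gold: GoldStandard, cfg: SimConfig
) -> tuple[Ensemble, list[MockRecord]]:
    """Generate ``cfg.n_squiggles`` mocks, reproducible from ``cfg.seed``.

    The gold standard is z-normalized first and mocks are built in that
    space, so noiseless duplication-only mocks match the gold at zero DTW
    cost and injected noise lands at the target z-normalized SNR.
    """
    rng = np.random.default_rng(cfg.seed)
    gold_z = GoldStandard(
        squiggle=ensure_normalized(gold.squiggle),
        source_sequence=gold.source_sequence,
        kmer_model_id=gold.kmer_model_id,
        k=gold.k,
    )
    make_one = simulate_global if cfg.model_kind in GLOBAL_KINDS else simulate_local
    records = []
    for i in range(cfg.n_squiggles):
        rec = make_one(gold_z, cfg, rng, squiggle_id=f"mock{i:05d}")
        if np.isfinite(cfg.snr_target):
            rec = replace(
                rec,
                squiggle=inject_noise(rec.squiggle, cfg.snr_target, rng),
                noise_std=1.0 / cfg.snr_target,
            )
        records.append(rec)
    ens = Ensemble(
        squiggles=[r.squiggle for r in records],
        gold=gold_z,
        provenance={
            "model_kind": cfg.model_kind,
            "seed": cfg.seed,
            "n_squiggles": cfg.n_squiggles,
            "snr_target": cfg.snr_target,
        },
    )
    return ens, records
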