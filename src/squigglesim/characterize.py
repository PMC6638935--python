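"""Length-scaling statistics, long-tailed fits, indel rate curves and SNR.

Squiggle lengths are summarized by the length scaling factor

    LSF = squiggle_length / gold_standard_length,

empirically ~1.7 on direct-RNA MinION data.  The LSF distribution is
long-tailed and is summarized either empirically (step CDF + kernel PDF)
or by maximum-likelihood fits of three long-tailed families (generalized
extreme value, lognormal, loglogistic).

Per-count insertion and deletion rates vary with LSF and are well
described by linear curves in (1 - 1/LSF):

    P(count | LSF) = A + B * (1 - 1/LSF)       [percent scale]

with a geometric tail for deep insertion counts,

    P(I >= 5 | LSF) = B4 * (1 - 1/LSF) / decay**(I - 4).

Because the linear curves are empirical fits rather than a probability
law, assembled categoricals are clamped to [0, 100] and renormalized.

The noise level of an ensemble is estimated from pairwise DTW residuals:
for squiggles of similar length, the difference between the two
warp-expanded series is predominantly noise, and on z-normalized signals

    SNR_znorm = K * 1 / (std(DIFF) / sqrt(2)),

where sqrt(2) accounts for comparing two noisy streams and K (mean band
length / gold length) absorbs residual indel mismatch between the pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as spo
from scipy import stats as sps

from .dtw import dtw_align, indel_profile
from .errors import ConfigError, EmptyEnsembleError
from .signal_model import Ensemble, GoldStandard, ensure_normalized

PARAMETRIC_FAMILIES = ("gev", "lognormal", "loglogistic")


# ---------------------------------------------------------------------------
# Length models


@dataclass(frozen=True)
class LengthModel:
    """A model of the LSF distribution.

    ``kind`` is "empirical" (sorted LSF values, step CDF, linear-interp
    inverse) or one of the parametric families, whose (mu, sigma, shape)
    live on the raw length scale and are divided by ``gold_length`` when
    sampling LSF values.  The GEV shape uses the convention in which a
    negative shape gives a bounded upper tail (scipy's shape is its
    negative).
    """

    kind: str
    gold_length: int = 1
    lsf_values: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None
    shape: float | None = None

    def _frozen(self):
        if self.kind == "gev":
            return sps.genextreme(c=-self.shape, loc=self.mu, scale=self.sigma)
        if self.kind == "lognormal":
            return sps.lognorm(s=self.sigma, scale=math.exp(self.mu))
        if self.kind == "loglogistic":
            return sps.fisk(c=1.0 / self.sigma, scale=math.exp(self.mu))
        raise ValueError(f"unknown parametric kind {self.kind!r}")

    def cdf(self, lsf: float) -> float:
        if self.kind == "empirical":
            return float(
                np.searchsorted(self.lsf_values, lsf, side="right")
                / self.lsf_values.size
            )
        return float(self._frozen().cdf(lsf * self.gold_length))

    def ppf(self, u) -> np.ndarray:
        """Inverse CDF on the LSF scale (vectorized over ``u``)."""
        u = np.asarray(u, dtype=float)
        if self.kind == "empirical":
            grid = np.linspace(0.0, 1.0, self.lsf_values.size)
            return np.interp(u, grid, self.lsf_values)
        return self._frozen().ppf(u) / self.gold_length


def compute_lsf(ens: Ensemble, gold: GoldStandard) -> np.ndarray:
    """One length scaling factor per squiggle."""
    if len(gold) == 0:
        raise ValueError("gold length must be positive")
    return ens.lengths / float(len(gold))


def empirical_length_model(lsf_values, gold_length: int = 1) -> LengthModel:
    """Empirical LSF model: step CDF over the sorted values.

    A Gaussian-kernel density (Silverman bandwidth) is available for
    reporting via :func:`lsf_kde`; the CDF itself is the exact step
    function.
    """
    vals = np.sort(np.asarray(lsf_values, dtype=float))
    if vals.size < 2:
        raise ValueError("empirical length model needs at least 2 values")
    return LengthModel(kind="empirical", gold_length=gold_length, lsf_values=vals)


def lsf_kde(lsf_values) -> sps.gaussian_kde:
    """Smoothed LSF density for reporting (Silverman's rule bandwidth)."""
    return sps.gaussian_kde(np.asarray(lsf_values, dtype=float), bw_method="silverman")


# ---------------------------------------------------------------------------
# Long-tailed distribution fitting


@dataclass(frozen=True)
class DistributionFit:
    family: str
    params: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    message: str = ""


def _nll(family: str, theta: np.ndarray, x: np.ndarray) -> float:
    if family == "gev":
        mu, sigma, k = theta
        if sigma <= 0:
            return np.inf
        lp = sps.genextreme.logpdf(x, c=-k, loc=mu, scale=sigma)
    elif family == "lognormal":
        mu, sigma = theta
        if sigma <= 0:
            return np.inf
        lp = sps.lognorm.logpdf(x, s=sigma, scale=math.exp(mu))
    elif family == "loglogistic":
        mu, sigma = theta
        if sigma <= 0:
            return np.inf
        lp = sps.fisk.logpdf(x, c=1.0 / sigma, scale=math.exp(mu))
    else:
        raise ValueError(f"unknown family {family!r}")
    if not np.all(np.isfinite(lp)):
        return np.inf
    return -float(lp.sum())


def _fd_hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_long_tailed(lengths, family: str) -> DistributionFit:
    """Maximum-likelihood fit of one long-tailed family to squiggle lengths.

    95% confidence intervals come from the observed-information normal
    approximation (finite-difference Hessian of the negative
    log-likelihood at the MLE).  Degenerate data or a singular information
    matrix yields ``converged=False`` with diagnostics instead of raising.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 observations to fit")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    if family not in PARAMETRIC_FAMILIES:
        raise ValueError(f"family must be one of {PARAMETRIC_FAMILIES}")

    def bad(msg: str) -> DistributionFit:
        return DistributionFit(family, {}, {}, -np.inf, False, msg)

    if np.ptp(x) == 0:
        return bad("degenerate (constant) data")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "gev":
                c, loc, scale = sps.genextreme.fit(x)
                names = ["mu", "sigma", "k"]
                theta = np.array([loc, scale, -c])
            elif family == "lognormal":
                s, _, scale = sps.lognorm.fit(x, floc=0)
                names = ["mu", "sigma"]
                theta = np.array([math.log(scale), s])
            else:
                c, _, scale = sps.fisk.fit(x, floc=0)
                names = ["mu", "sigma"]
                theta = np.array([math.log(scale), 1.0 / c])
    except Exception as exc:  # scipy fit failures on pathological data
        return bad(f"fit failed: {exc}")

    # polish: scipy's moment-started fits can stop short of a stationary
    # point, leaving the observed information indefinite
    res = spo.minimize(
        lambda t: _nll(family, t, x),
        theta,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    if np.isfinite(res.fun):
        theta = res.x

    nll = _nll(family, theta, x)
    if not np.isfinite(nll):
        return bad("non-finite likelihood at optimum")
    H = _fd_hessian(lambda t: _nll(family, t, x), theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return bad("singular observed information")
    var = np.diag(cov)
    if np.any(~np.isfinite(var)) or np.any(var <= 0):
        return bad("observed information not positive definite")
    se = np.sqrt(var)
    z = sps.norm.ppf(0.975)
    params = dict(zip(names, theta.tolist()))
    ci95 = {
        nm: (float(t - z * s_), float(t + z * s_))
        for nm, t, s_ in zip(names, theta, se)
    }
    return DistributionFit(family, params, ci95, -nll, True)


# ---------------------------------------------------------------------------
# Rate curves and tails


@dataclass(frozen=True)
class RateCurve:
    """Linear indel-rate curves A + B(1 - 1/LSF) on the percent scale.

    ``insertion`` maps counts 0..4 and ``deletion`` counts 0..3 to their
    (A, B) pairs.  Evaluations are clamped to [0, 100]: the curves are
    empirical fits, and the tabulated deep-count intercepts go slightly
    negative.
    """

    insertion: dict[int, tuple[float, float]]
    deletion: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class TailModel:
    """Geometric decay of deep insertion-count rates.

    P(count >= 5) continues the four-insertion slope ``b4`` divided by
    ``decay`` per extra insertion; decay 1.3 matches the observed ~1.3x
    fall-off of the B parameters, 2.0 is a heavier-damped variant.
    """

    b4: float = 6.2
    decay: float = 1.3

    def __post_init__(self) -> None:
        if self.decay < 1.0:
            raise ValueError("decay must be >= 1 so tail probabilities vanish")


#: Reference indel rate curves measured on MinION direct-RNA enolase
#: squiggles (percent scale, counts beyond the table treated via TailModel).
REFERENCE_RATE_CURVE = RateCurve(
    insertion={
        0: (90.2, -56.1),
        1: (11.0, 14.0),
        2: (2.1, 12.5),
        3: (-0.2, 8.8),
        4: (-0.7, 6.2),
    },
    deletion={
        0: (88.7, 17.7),
        1: (9.7, -15.0),
        2: (1.1, -1.8),
        3: (0.3, -0.4),
    },
)

REFERENCE_TAIL = TailModel(b4=6.2, decay=1.3)

#: Insertion counts beyond this are negligible (< 1e-4 for LSF <= 3.5).
I_MAX = 20


def eval_rate(curve: RateCurve, count: int, lsf: float, kind: str = "insertion") -> float:
    """Evaluate A + B(1 - 1/LSF) for one count, clamped to [0, 100] percent."""
    if lsf < 1.0:
        raise ValueError(f"LSF must be >= 1, got {lsf}")
    table = curve.insertion if kind == "insertion" else curve.deletion
    a, b = table[count]
    return float(np.clip(a + b * (1.0 - 1.0 / lsf), 0.0, 100.0))


def tail_prob(tail: TailModel, count: int, lsf: float) -> float:
    """Percent rate of ``count`` >= 5 insertions at the given LSF."""
    if count < 5:
        raise ValueError("tail model applies to counts >= 5")
    if lsf < 1.0:
        raise ValueError(f"LSF must be >= 1, got {lsf}")
    return tail.b4 * (1.0 - 1.0 / lsf) / tail.decay ** (count - 4)


def insertion_pmf(
    curve: RateCurve, tail: TailModel | None, lsf: float, i_max: int = I_MAX
) -> np.ndarray:
    """Per-base categorical over insertion counts at one LSF.

    With ``tail=None`` the support is the curve's tabulated counts alone;
    a TailModel extends it geometrically out to ``i_max`` (the deep-count
    extension that widens the simulated length distribution).  Negative
    curve evaluations are clamped to zero and the whole vector is
    renormalized to sum to 1 (the raw percent rows sum to ~96% at LSF 1.7
    before the tail).
    """
    raw = np.array(
        [eval_rate(curve, c, lsf) for c in sorted(curve.insertion)]
        + (
            []
            if tail is None
            else [tail_prob(tail, c, lsf) for c in range(max(curve.insertion) + 1, i_max + 1)]
        )
    )
    total = raw.sum()
    if total <= 0:
        raise ConfigError(f"insertion rates all zero at LSF {lsf}")
    return raw / total


def deletion_pmf(curve: RateCurve, lsf: float) -> np.ndarray:
    """Per-base categorical over deletion counts 0..3 at one LSF."""
    raw = np.array([eval_rate(curve, c, lsf, kind="deletion") for c in sorted(curve.deletion)])
    total = raw.sum()
    if total <= 0:
        raise ConfigError(f"deletion rates all zero at LSF {lsf}")
    return raw / total


def fit_rate_curves(
    ens: Ensemble, gold: GoldStandard, bin_width: int = 50
) -> RateCurve:
    """Recover (A, B) rate curves from an ensemble by length-binned regression.

    Squiggles are grouped into length bins no wider than ``bin_width``
    events; each bin contributes its DTW-proxy per-count mean fractions
    (percent) at its mean LSF, and each count's curve is fitted by weighted
    least squares of percent against (1 - 1/LSF) with bin sizes as weights.
    """
    lengths = ens.lengths
    bin_ids = lengths // bin_width
    unique_bins = np.unique(bin_ids)
    if unique_bins.size < 3:
        raise ConfigError(
            f"rate-curve fitting needs >= 3 length bins, got {unique_bins.size}"
        )
    xs, weights = [], []
    ins_rows, del_rows = [], []
    for b in unique_bins:
        members = [s for s, g in zip(ens.squiggles, bin_ids) if g == b]
        sub = Ensemble(squiggles=members, gold=gold)
        prof = indel_profile(sub, gold)
        mean_lsf = float(np.mean([len(s) for s in members])) / len(gold)
        xs.append(1.0 - 1.0 / mean_lsf)
        weights.append(len(members))
        ins_rows.append(prof.insertion_mean * 100.0)
        del_rows.append(prof.deletion_mean * 100.0)
    x = np.array(xs)
    w = np.sqrt(np.array(weights, dtype=float))
    ins_rows = np.vstack(ins_rows)
    del_rows = np.vstack(del_rows)

    def _wls(y: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(x, y, 1, w=w)
        return float(intercept), float(slope)

    insertion = {c: _wls(ins_rows[:, c]) for c in range(5)}
    deletion = {c: _wls(del_rows[:, c]) for c in range(4)}
    return RateCurve(insertion=insertion, deletion=deletion)


# ---------------------------------------------------------------------------
# Signal-to-noise estimation


@dataclass(frozen=True)
class SnrEstimate:
    snr_mean: float
    snr_std: float
    K: float
    n_pairs: int
    band: tuple[int, int] | None = None
    per_pair: np.ndarray | None = None


def range_snr(signal, noise_std: float) -> float:
    """Classical range-based SNR: max-min signal range over noise std."""
    sig = np.asarray(signal, dtype=float)
    return float(np.ptp(sig) / noise_std)


def estimate_snr(
    ens: Ensemble,
    gold_length: int,
    band: tuple[int, int] | None = None,
    K: float | None = None,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> SnrEstimate:
    """Estimate SNR_znorm from pairwise DTW residuals within a length band.

    For every unordered pair (P, Q) of band members the two warp-expanded
    series are subtracted along the optimal path; assuming similar-length
    squiggles share indel structure, the residual is predominantly noise
    and each pair yields K * sqrt(2) / std(DIFF).  By default
    K = mean band length / gold_length; pass ``K=1`` to disable the indel
    correction.  ``max_pairs`` subsamples pairs for large bands.
    """
    members = list(ens)
    if band is not None:
        lo, hi = band
        members = [s for s in members if lo <= len(s) <= hi]
    if len(members) < 2:
        raise EmptyEnsembleError("need at least 2 squiggles in the band")
    members = [ensure_normalized(s) for s in members]
    mean_len = float(np.mean([len(s) for s in members]))
    k_factor = mean_len / gold_length if K is None else float(K)
    pairs = list(itertools.combinations(range(len(members)), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    vals = []
    for i, j in pairs:
        al = dtw_align(members[i], members[j])
        diff = members[i].events[al.path[:, 0]] - members[j].events[al.path[:, 1]]
        sd = float(np.std(diff))
        if sd == 0.0:
            warnings.warn("estimate_snr: identical pair skipped", stacklevel=2)
            continue
        vals.append(k_factor * math.sqrt(2.0) / sd)
    if not vals:
        raise EmptyEnsembleError("no informative pairs (all identical)")
    arr = np.array(vals)
    return SnrEstimate(
        snr_mean=float(arr.mean()),
        snr_std=float(arr.std()),
        K=k_factor,
        n_pairs=arr.size,
        band=band,
        per_pair=arr,
    )
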