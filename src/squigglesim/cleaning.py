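"""Ensemble cleaning cascade for raw squiggle ensembles.

Real squiggle ensembles carry several classes of non-biological artefact:
reads shorter than the gold standard (gross truncations — squiggles run
~1.7x *longer* than gold, so anything shorter is broken), the enzyme
leader prefix, streams whose summary statistics are extreme outliers, and
in-silico chimeric reads whose intensity spread is inhomogeneous along the
stream.  The cascade removes them in a fixed order:

    short -> leader stripping -> 5-sigma outlier pruning -> chimera test

and reports a per-squiggle disposition.  The cascade is idempotent on
homogeneous ensembles: a second pass removes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import LengthError
from .signal_model import Ensemble, GoldStandard, Squiggle

DEFAULT_LEADER_WINDOW = 50
DEFAULT_N_SECTIONS = 10


@dataclass
class CleaningReport:
    n_input: int = 0
    n_removed_short: int = 0
    n_removed_outlier: int = 0
    n_removed_chimera: int = 0
    n_retained: int = 0
    #: squiggle id -> ("retained" | "short" | "outlier" | "chimera", reason)
    dispositions: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: squiggle id -> leader boundary (retained squiggles only)
    leader_boundaries: dict[str, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        removed = self.n_removed_short + self.n_removed_outlier + self.n_removed_chimera
        return self.n_retained == self.n_input - removed


def remove_short(
    ens: Ensemble, gold: GoldStandard, report: CleaningReport | None = None
) -> list[Squiggle]:
    """Drop every squiggle shorter than the gold standard.

    Returns the retained list (possibly empty, with a warning) so the
    cascade can proceed; callers wanting an Ensemble should rewrap.
    """
    kept = []
    for s in ens:
        if len(s) >= len(gold):
            kept.append(s)
        elif report is not None:
            report.n_removed_short += 1
            report.dispositions[s.id] = (
                "short",
                f"length {len(s)} < gold length {len(gold)}",
            )
    if not kept:
        warnings.warn("remove_short: all squiggles shorter than gold", stacklevel=2)
    return kept


def strip_leader(
    s: Squiggle, window: int = DEFAULT_LEADER_WINDOW
) -> tuple[Squiggle, int]:
    """Locate and remove the enzyme-leader prefix of a squiggle.

    The leader is identified by its local mean and standard deviation not
    matching those of the remaining stream: scanning boundaries from the
    start, the first index whose following ``window`` events have a mean
    within 2 standard deviations of the downstream stream mean, and a
    standard deviation within a factor of 2 of the downstream one, is taken
    as the leader boundary.  Boundary 0 means no leader was detected.

    Two guards keep the heuristic honest: boundaries shorter than half the
    window are reported as 0 (indistinguishable from local fluctuation),
    and the scan stops a quarter of the way into the stream — enzyme
    leaders are short relative to the read, and without the cap a strongly
    inhomogeneous (e.g. chimeric) stream would have its entire first
    segment declared a leader.
    """
    n = len(s)
    if n <= 2 * window:
        raise LengthError(f"squiggle length {n} too short for leader window {window}")
    ev = s.events
    # suffix moments via reverse cumulative sums
    csum = np.concatenate(([0.0], np.cumsum(ev)))
    csum2 = np.concatenate(([0.0], np.cumsum(ev**2)))

    def _moments(lo: int, hi: int) -> tuple[float, float]:
        cnt = hi - lo
        m = (csum[hi] - csum[lo]) / cnt
        var = max((csum2[hi] - csum2[lo]) / cnt - m * m, 0.0)
        return m, float(np.sqrt(var))

    max_scan = min(n - 2 * window, max(n // 4, window))
    for t in range(0, max_scan + 1):
        w_mean, w_std = _moments(t, t + window)
        p_mean, p_std = _moments(t + window, n)
        mean_ok = abs(w_mean - p_mean) <= 2.0 * p_std
        if p_std == 0.0 or w_std == 0.0:
            std_ok = p_std == w_std
        else:
            ratio = w_std / p_std
            std_ok = 0.5 <= ratio <= 2.0
        if mean_ok and std_ok:
            if t < window // 2:
                # a leader this short cannot be distinguished from local
                # fluctuation at this window size; report none
                return s, 0
            return replace(s, events=ev[t:].copy()), t
    return s, 0


def prune_outliers(
    ens_or_list, report: CleaningReport | None = None, n_sigma: float = 5.0
) -> list[Squiggle]:
    """Remove squiggles whose mean, std or length deviates by > 5 ensemble sigma.

    Squiggle lengths are not normally distributed, so the usual 2-sigma rule
    would over-prune; only gross outliers beyond ``n_sigma`` on any of the
    three per-squiggle statistics are removed.  Ensembles of fewer than 3
    squiggles pass through unchanged (ensemble statistics need support).
    """
    squiggles = list(ens_or_list)
    if len(squiggles) < 3:
        warnings.warn("prune_outliers: ensemble too small, passing through", stacklevel=2)
        return squiggles
    stats = np.array(
        [[float(np.mean(s.events)), float(np.std(s.events)), len(s)] for s in squiggles]
    )
    mu = stats.mean(axis=0)
    sd = stats.std(axis=0)
    kept = []
    for s, row in zip(squiggles, stats):
        dev = np.abs(row - mu)
        ok = np.all((sd == 0) | (dev <= n_sigma * sd))
        if ok:
            kept.append(s)
        elif report is not None:
            report.n_removed_outlier += 1
            which = ["mean", "std", "length"][int(np.argmax(np.where(sd > 0, dev / np.where(sd == 0, 1, sd), 0)))]
            report.dispositions[s.id] = ("outlier", f"{which} beyond {n_sigma} sigma")
    return kept


def section_spread_statistic(s: Squiggle, n_sections: int) -> float:
    """Mean over contiguous equal sections of the section intensity std.

    The remainder goes to the last section; with ``n_sections = 1`` this is
    the whole-squiggle std.  Chimeric reads concatenate signal from more
    than one molecule and show inhomogeneous section spreads.
    """
    n = len(s)
    if n < n_sections:
        raise LengthError(f"squiggle length {n} < n_sections {n_sections}")
    base = n // n_sections
    stds = []
    for i in range(n_sections):
        lo = i * base
        hi = (i + 1) * base if i < n_sections - 1 else n
        stds.append(float(np.std(s.events[lo:hi])))
    return float(np.mean(stds))


def reject_chimeras(
    ens_or_list,
    n_sections: int = DEFAULT_N_SECTIONS,
    report: CleaningReport | None = None,
) -> list[Squiggle]:
    """Reject squiggles whose sectioned-spread statistic is > 2 sigma from the ensemble mean."""
    squiggles = list(ens_or_list)
    stats = []
    valid = []
    kept = []
    for s in squiggles:
        try:
            stats.append(section_spread_statistic(s, n_sections))
            valid.append(s)
        except LengthError:
            if report is not None:
                report.n_removed_chimera += 1
                report.dispositions[s.id] = ("chimera", f"shorter than {n_sections} sections")
    arr = np.array(stats)
    if arr.size == 0:
        return kept
    mu = arr.mean()
    sd = arr.std()
    for s, stat in zip(valid, arr):
        if sd == 0 or abs(stat - mu) <= 2.0 * sd:
            kept.append(s)
        elif report is not None:
            report.n_removed_chimera += 1
            report.dispositions[s.id] = (
                "chimera",
                f"section spread {stat:.4g} vs ensemble {mu:.4g} +/- {sd:.4g}",
            )
    return kept


def clean_ensemble(
    ens: Ensemble,
    gold: GoldStandard,
    window: int = DEFAULT_LEADER_WINDOW,
    n_sections: int = DEFAULT_N_SECTIONS,
) -> tuple[Ensemble | None, CleaningReport]:
    """Run the full cascade: short -> leader -> 5-sigma outliers -> chimeras.

    Leaders are stripped before ensemble statistics are computed, since the
    leader segment is non-biological and would bias the means.  Returns
    (cleaned ensemble or None if everything was removed, report).
    """
    report = CleaningReport(n_input=len(ens))
    kept = remove_short(ens, gold, report)
    stripped = []
    for s in kept:
        try:
            t, boundary = strip_leader(s, window)
        except LengthError:
            t, boundary = s, 0
        report.leader_boundaries[s.id] = boundary
        stripped.append(t)
    kept = prune_outliers(stripped, report)
    kept = reject_chimeras(kept, n_sections, report)
    for s in kept:
        report.dispositions[s.id] = ("retained", "")
    report.n_retained = len(kept)
    if not kept:
        return None, report
    out = Ensemble(
        squiggles=kept,
        gold=gold,
        provenance=dict(ens.provenance, cleaned=True),
    )
    return out, report
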