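import numpy as np
import pytest

import squigglesim as sq
from squigglesim.cleaning import section_spread_statistic
from squigglesim.errors import LengthError


def _noisy_copies(gold, n, noise, rng, prefix="s"):
    gz = sq.ensure_normalized(gold.squiggle)
    return [
        sq.Squiggle(
            id=f"{prefix}{i}",
            events=gz.events + rng.normal(0, noise, size=len(gz)),
            normalized=True,
        )
        for i in range(n)
    ]


@pytest.fixture()
def gold400():
    return sq.make_fixture(5, 404, 5)[1]


class TestRemoveShort:
    def test_threshold_at_gold_length(self, gold400):
        rng = np.random.default_rng(0)
        lens = [399, 400, 600]
        ens = sq.Ensemble(
            squiggles=[sq.Squiggle(id=f"s{n}", events=rng.normal(size=n)) for n in lens]
        )
        kept = sq.remove_short(ens, gold400)
        assert sorted(len(s) for s in kept) == [400, 600]

    def test_all_longer_unchanged(self, gold400):
        rng = np.random.default_rng(1)
        ens = sq.Ensemble(
            squiggles=[sq.Squiggle(id=f"s{i}", events=rng.normal(size=500)) for i in range(3)]
        )
        assert len(sq.remove_short(ens, gold400)) == 3

    def test_all_shorter_warns_and_empties(self, gold400):
        rng = np.random.default_rng(2)
        ens = sq.Ensemble(squiggles=[sq.Squiggle(id="s", events=rng.normal(size=10))])
        with pytest.warns(UserWarning):
            assert sq.remove_short(ens, gold400) == []


class TestStripLeader:
    def test_no_leader(self, gold400):
        s = sq.ensure_normalized(gold400.squiggle)
        out, boundary = sq.strip_leader(s, window=50)
        assert boundary == 0
        np.testing.assert_array_equal(out.events, s.events)

    def test_offset_leader_found_within_window(self, gold400):
        rng = np.random.default_rng(3)
        s = sq.ensure_normalized(gold400.squiggle)
        leader = rng.normal(8.0, 1.0, size=100)  # +8 global std offset
        spiked = sq.Squiggle(id="lead", events=np.concatenate([leader, s.events]))
        out, boundary = sq.strip_leader(spiked, window=50)
        assert 50 <= boundary <= 150
        assert len(out) == len(spiked) - boundary

    def test_leader_shorter_than_half_window_undetectable(self, gold400):
        rng = np.random.default_rng(4)
        s = sq.ensure_normalized(gold400.squiggle)
        leader = rng.normal(8.0, 1.0, size=20)
        spiked = sq.Squiggle(id="lead", events=np.concatenate([leader, s.events]))
        _, boundary = sq.strip_leader(spiked, window=50)
        assert boundary == 0

    def test_too_short_rejected(self):
        with pytest.raises(LengthError):
            sq.strip_leader(sq.Squiggle(id="s", events=np.zeros(10) + np.arange(10)), window=50)


class TestPruneOutliers:
    def test_homogeneous_ensemble_mostly_retained(self, gold400):
        rng = np.random.default_rng(5)
        squiggles = _noisy_copies(gold400, 100, 0.25, rng)
        kept = sq.prune_outliers(squiggles)
        assert len(kept) >= 99

    def test_shifted_mean_removed(self, gold400):
        rng = np.random.default_rng(6)
        squiggles = _noisy_copies(gold400, 100, 0.25, rng)
        means = [float(np.mean(s.events)) for s in squiggles]
        shift = 10 * np.std(means)
        bad = sq.Squiggle(id="bad", events=squiggles[0].events + shift, normalized=True)
        kept = sq.prune_outliers(squiggles + [bad])
        assert all(s.id != "bad" for s in kept)

    def test_identical_squiggles_all_retained(self, gold400):
        gz = sq.ensure_normalized(gold400.squiggle)
        squiggles = [
            sq.Squiggle(id=f"s{i}", events=gz.events.copy(), normalized=True) for i in range(5)
        ]
        assert len(sq.prune_outliers(squiggles)) == 5

    def test_tiny_ensemble_passes_through(self, gold400):
        squiggles = _noisy_copies(gold400, 2, 0.25, np.random.default_rng(7))
        with pytest.warns(UserWarning):
            assert len(sq.prune_outliers(squiggles)) == 2


class TestRejectChimeras:
    def test_homogeneous_retention_near_95pct(self, gold400):
        rng = np.random.default_rng(8)
        squiggles = _noisy_copies(gold400, 100, 0.25, rng)
        kept = sq.reject_chimeras(squiggles, n_sections=10)
        assert 85 <= len(kept) <= 100

    def test_inflated_second_half_rejected(self, gold400):
        rng = np.random.default_rng(9)
        squiggles = _noisy_copies(gold400, 30, 0.25, rng)
        ev = squiggles[0].events.copy()
        ev[len(ev) // 2 :] *= 10.0
        chimera = sq.Squiggle(id="chimera", events=ev, normalized=True)
        kept = sq.reject_chimeras(squiggles + [chimera], n_sections=10)
        assert all(s.id != "chimera" for s in kept)

    def test_single_section_is_whole_std(self, gold400):
        s = sq.ensure_normalized(gold400.squiggle)
        assert section_spread_statistic(s, 1) == pytest.approx(float(np.std(s.events)))

    def test_short_squiggle_auto_rejected(self):
        short = sq.Squiggle(id="short", events=np.arange(5.0))
        report = sq.CleaningReport(n_input=1)
        kept = sq.reject_chimeras([short], n_sections=10, report=report)
        assert kept == []
        assert report.dispositions["short"][0] == "chimera"


class TestCascade:
    def _planted_ensemble(self, gold400, with_leader=True):
        gz = sq.ensure_normalized(gold400.squiggle)
        rng = np.random.default_rng(10)
        good = [
            sq.Squiggle(id=f"good{i}", events=gz.events.copy(), normalized=True)
            for i in range(20)
        ]
        short = sq.Squiggle(id="short", events=gz.events[:100].copy(), normalized=True)
        leader = sq.Squiggle(
            id="leader",
            events=np.concatenate([rng.normal(8.0, 1.0, 100), gz.events]),
            normalized=True,
        )
        ch_ev = gz.events.copy()
        ch_ev[200:] *= 10.0
        chimera = sq.Squiggle(id="chimera", events=ch_ev, normalized=True)
        planted = [short, chimera] + ([leader] if with_leader else [])
        return sq.Ensemble(squiggles=good + planted)

    def test_cascade_removes_planted_artifacts_and_reconciles(self, gold400):
        ens = self._planted_ensemble(gold400)
        cleaned, report = sq.clean_ensemble(ens, gold400)
        assert report.n_input == 23
        assert report.n_removed_short == 1
        assert report.n_removed_chimera >= 1
        assert report.reconciles()
        assert report.leader_boundaries["leader"] > 0
        ids = {s.id for s in cleaned}
        assert "short" not in ids and "chimera" not in ids
        assert "leader" in ids  # retained after stripping

    def test_cascade_idempotent(self, gold400):
        # leader residues can legitimately shift section statistics, so
        # idempotence is checked on the leader-free planted ensemble
        ens = self._planted_ensemble(gold400, with_leader=False)
        cleaned, _ = sq.clean_ensemble(ens, gold400)
        cleaned2, report2 = sq.clean_ensemble(cleaned, gold400)
        assert report2.n_retained == report2.n_input
        assert len(cleaned2) == len(cleaned)
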