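"""Run the cleaning cascade on an ensemble with planted artefacts.

short reads -> leader stripping -> 5-sigma outlier pruning -> sectioned
chimera rejection, with a per-squiggle disposition report.
"""

import numpy as np

import squigglesim as sq

_, gold = sq.make_fixture(seed=5, sequence_length=404, k=5)
gz = sq.ensure_normalized(gold.squiggle)
rng = np.random.default_rng(0)

good = [
    sq.Squiggle(id=f"good{i}", events=gz.events + rng.normal(0, 0.25, len(gz)),
                normalized=True)
    for i in range(30)
]
short = sq.Squiggle(id="short", events=gz.events[:120].copy(), normalized=True)
leader = sq.Squiggle(
    id="with_leader",
    events=np.concatenate([rng.normal(8.0, 1.0, 100), good[0].events]),
    normalized=True,
)
chim_ev = good[1].events.copy()
chim_ev[200:] *= 10.0
chimera = sq.Squiggle(id="chimera", events=chim_ev, normalized=True)

ens = sq.Ensemble(squiggles=good + [short, leader, chimera])
cleaned, report = sq.clean_ensemble(ens, gold)

print(f"input {report.n_input} | removed: short {report.n_removed_short}, "
      f"outlier {report.n_removed_outlier}, chimera {report.n_removed_chimera} "
      f"| retained {report.n_retained}")
print(f"leader boundary found for 'with_leader': "
      f"{report.leader_boundaries['with_leader']} events (100 were planted)")
for sid in ("short", "chimera"):
    print(f"  {sid}: {report.dispositions[sid]}")
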