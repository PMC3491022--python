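"""Recover hidden mRNA levels in a dividing colony from protein counts.

A transcription-translation circuit (DNA -> mRNA -> protein) runs in a
colony whose cells divide every 20 minutes, molecules partitioning
binomially between daughters.  Only the protein copy number is observed,
once a minute.  The colony smoother fuses every cell's observations through
the division kernel and returns, for each cell, the posterior of its hidden
mRNA count given the entire lineage's data.
"""

import numpy as np

import crnobserver as co
from crnobserver.io import attach_observations

net = co.builtin("tvo_m1")
space = net.state_space()
A = co.build_generator(net, space)
sensor = co.count_partition("P")  # noise-free protein read-out
rho0 = net.initial_distribution(space)  # M = 0, P = 0

tree, trajs = co.simulate_colony(net, 1200.0, 3500.0, seed=11,
                                 x0={"M": 0, "P": 0})
obs = {cid: co.observe(t, sensor, ("periodic", 60.0), space)
       for cid, t in trajs.items()}
attach_observations(tree, obs)
print(f"colony: {len(tree)} cells over {3500/60:.0f} minutes "
      f"(divisions every 20 min)")

post = co.colony_smooth(tree, A, sensor, rho0, space, network=net, n_interior=0)

print("\n  cell   window (min)    mean |mRNA error|   mean posterior sd")
for cid in sorted(tree.cells):
    cell = tree.cells[cid]
    times, mean, sd = co.mmse(post[cid], space, "M")
    true = trajs[cid].state_at(times)[:, 0]
    print(f"  {cid:<5}  {cell.birth/60:5.0f}-{cell.end/60:4.0f}      "
          f"{np.abs(mean - true).mean():11.2f}        {sd.mean():8.2f}")

err = np.concatenate([
    co.mmse(post[cid], space, "M")[1] - trajs[cid].state_at(
        co.mmse(post[cid], space, "M")[0])[:, 0]
    for cid in tree.cells
])
print(f"\ncolony-wide RMS error of the smoothed mRNA estimate: "
      f"{np.sqrt((err**2).mean()):.2f} molecules")
print("(the stationary mRNA sd is sqrt(5) ~ 2.24, so the protein record "
      "roughly halves the uncertainty)")
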