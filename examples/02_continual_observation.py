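"""Filter a continually observed, noise-free output path.

When the coarse output is watched at every instant, the data are the exact
times at which the symbol changes.  Between changes the conditional state
distribution evolves under the within-class generator block (staying put is
itself informative); at each change it is pushed through the cross-class
block.  This script checks the continual filter against very finely sampled
discrete observations of the same trajectory.
"""

import numpy as np

import crnobserver as co

net = co.builtin("birth_death")
space = net.state_space()
A = co.build_generator(net, space)
sensor = co.three_band_partition("X")
split = co.split_generator(A, sensor, space)

traj = co.ssa(net, {"X": 10}, 2.0, seed=3, space=space)
path = co.observe(traj, sensor, "continual", space)
print(f"output path: starts {path.y0!r}, {len(path.jump_times)} symbol "
      f"changes in 2 time units")

rho0 = np.zeros(space.n)
rho0[10] = 1.0
fc = co.forward_continual(split, path, rho0)

# reference: noise-free snapshots every millisecond
times = np.arange(1e-3, 2.0 + 1e-12, 1e-3)
seq = co.observe(traj, sensor, times, space)
fd = co.forward_discrete(A, sensor, seq, rho0, space, n_interior=0)

tv = 0.5 * np.abs(fc.final - fd.final).sum()
print(f"continual filter vs 1 ms discrete sampling, final TV distance: {tv:.2e}")
print(f"path log-density accumulated by the continual observer: "
      f"{fc.log_evidence:.3f}")
print("holding a symbol carries information: the filter sharpens even "
      "between output changes.")
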