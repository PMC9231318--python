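"""Counting complete water traversals of a membrane-spanning channel.

Builds a scripted trajectory of 12 water particles: some cross the channel
slab (z = 2.32 to 6.55 nm) completely, one enters and retreats, some never
enter.  A permeation event requires entering through one face and exiting
through the opposite face while staying inside the 1 nm sampling cylinder,
so only the complete crossings are counted.
"""

import numpy as np

import poreform as pf

n, nf = 12, 16
z = np.empty((nf, n))
z[:, :5] = np.linspace(1.0, 8.0, nf)[:, None]          # 5 cross upward
z[:, 5:8] = np.linspace(8.0, 1.0, nf)[:, None]         # 3 cross downward
half = np.linspace(1.0, 5.0, nf // 2)
z[:, 8] = np.concatenate([half, half[::-1]])           # 1 aborts mid-slab
z[:, 9:] = 1.0                                         # 3 stay in the bulk

box = np.array([4.0, 4.0, 11.0])
topo = pf.Topology(roles=np.array(["water"] * n, dtype=object),
                   chain_ids=np.full(n, -1), masses=np.full(n, 72.0),
                   vdw_radii=np.full(n, 0.235), backbone=np.zeros(n, bool))
frames = [pf.Frame(time=float(k), box=box,
                   coordinates=np.column_stack(
                       [np.full(n, 2.0), np.full(n, 2.0), z[k]]))
          for k in range(nf)]
traj = pf.Trajectory(topology=topo, frames=frames)

events = pf.count_permeation_events(traj, "water", z_lo=2.32, z_hi=6.55,
                                    cylinder_radius=1.0)
print(f"{len(events)} permeation events (scripted: 8)")
for e in events:
    print(f"  particle {e.particle:2d}: {e.direction} crossing, "
          f"entered t={e.entry_time:.0f} ns, exited t={e.exit_time:.0f} ns")
print("the aborted and bulk-only particles produce no events; "
      "re-crossings out the entry face never count")
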