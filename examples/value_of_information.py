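"""Where does sharing prey locations pay off? The value-of-information map.

For a two-predator system, computes the fractional change of consumption
rate between full information sharing and none over a grid of environments
(handling time and patch lifetime, both in units of the search time). Red
corner: long handling and fleeting patches -- a tip-off is valuable and the
shared patch would have vanished anyway. Blue corner: short handling and
persistent patches -- sharing only splits prey that the finder could have
kept.
"""

import numpy as np

from forageshare.experiments import SweepGrid, voi_map

grid = SweepGrid(axis1="tau_h", axis2="tau_l", resolution=9)
vm = voi_map(grid, n_predators=2)
r1, r2 = grid.ratios()

print("value of information (%), rows = tau_h/tau_s, cols = tau_l/tau_s\n")
header = "        " + " ".join(f"{r:7.2f}" for r in r2)
print(header)
for i, rh in enumerate(r1):
    row = " ".join(f"{100 * vm.values[i, j]:+7.1f}" for j in range(len(r2)))
    print(f"{rh:7.2f} {row}")

print(f"\nmost favorable cell : {100 * np.nanmax(vm.values):+.1f}% "
      "(long handling, fleeting patches)")
print(f"least favorable cell: {100 * np.nanmin(vm.values):+.1f}% "
      "(short handling, persistent patches)")
print(f"cells touching the zero contour: {int(vm.zero_contour.sum())}")
print("\nThe zero contour separates environments where predators should"
      "\nbroadcast their finds from those where secrecy pays.")
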