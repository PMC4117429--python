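"""Canalizing inputs and locally redundant links versus the dynamical
decomposition.

A canalizing input forces the output by itself at one of its values; a
redundant input never affects the output at all (two-level minimization
eliminates it). Redundancy is purely local — it looks at one truth table —
whereas the robust neighbor is a global, dynamical notion, so the two need
not coincide.
"""

from boolcarve import (canalizing_inputs, compare_redundant_vs_decomposition,
                       decompose, redundant_links)
from boolcarve.synth import fixture

net = fixture("REDUNDANT4")
print("model: A (input) -> D, with B<->C feedback driving D via f_D(A,C)=C")

for v, t in sorted(net.tables.items()):
    if t.k >= 1:
        print(f"  {v}: canalizing {canalizing_inputs(t)}")

red = redundant_links(net)
print(f"locally redundant links: {sorted(red)}")

dec = decompose(net, n_samples=50, seed_init=0, seed_order=0)
res = compare_redundant_vs_decomposition(net, dec)
print(f"core = {sorted(dec.core_edges)}")
print(f"neighbor = {sorted(dec.neighbor_edges)}")
print(f"overlap counts: {res}")
# (A,D) is redundant and lands in the neighbor; (C,D) is locally essential
# yet its dynamical importance only shows through the full-dimensional
# primary cycle - local and global dispensability are different concepts.
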