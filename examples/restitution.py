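"""APD restitution with and without the constitutively active K+ current.

A dynamic (descending cycle length) protocol in the tissue ("constitutive")
mode versus full block of the constitutive current (the tertiapin-Q
condition).  Blocking roughly triples APD80 at long cycle lengths and
raises the shortest cycle length the cell can follow 1:1 — the mechanism
by which the drug suppresses reentry in monolayers.
"""

from nram import CellParams, dynamic_restitution

params = CellParams()
bcls = [1000, 600, 400, 300, 200, 150, 125, 100, 80]

print(f"{'BCL (ms)':>9} {'control APD80':>14} {'blocked APD80':>14}")
control = dynamic_restitution(params, bcl_list=bcls, beats_per_bcl=8,
                              mode="constitutive")
blocked = dynamic_restitution(params, bcl_list=bcls, beats_per_bcl=8,
                              mode="blocked")
for i, bcl in enumerate(bcls):
    c = f"{control.apd80[i]:10.1f}" if control.captured[i] else "  no 1:1"
    b = f"{blocked.apd80[i]:10.1f}" if blocked.captured[i] else "  no 1:1"
    print(f"{bcl:9.0f} {c:>14} {b:>14}")
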