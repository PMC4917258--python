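"""Pace a single atrial myocyte at 1 Hz and report its AP characteristics.

The cell is paced with the standard 7 pA(/pF), 5 ms stimulus for 12 beats;
the final beat is measured.  Expect a resting potential near -73 mV, an
amplitude near 133 mV, APD50/APD80 near 25/59 ms, and mean SR Ca content
in the high-700 uM range — the electrophysiological signature of a
cultured neonatal rat atrial cardiomyocyte.
"""

from nram import CellParams, ap_metrics, pace_to_steady_state

params = CellParams()
rec = pace_to_steady_state(params, bcl=1000.0, n_beats=12,
                           mode="single_cell")
t0 = 11000.0
m = ap_metrics(rec.window(t0, t0 + 1000.0), stim_time=t0)
sel = rec.t >= t0

print(f"resting potential : {m.rmp:8.1f} mV")
print(f"AP amplitude      : {m.amplitude:8.1f} mV")
print(f"max upstroke rate : {m.dvdt_max:8.0f} mV/ms")
print(f"APD50 / APD80     : {m.apd50:5.1f} / {m.apd80:5.1f} ms")
print(f"mean [Ca]_i       : {rec.ca_i[sel].mean() * 1e3:8.2f} uM")
print(f"mean [Ca]_NSR     : {rec.ca_nsr[sel].mean() * 1e3:8.0f} uM")
print(f"mean [Ca]_JSR     : {rec.ca_jsr[sel].mean() * 1e3:8.0f} uM")
rec.to_csv("single_cell_1hz.csv")
print("full trace written to single_cell_1hz.csv")
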