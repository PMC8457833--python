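"""Distal-dominant effect of a hyperosmotic challenge on calcium influx.

Doubling the dendritic leak conductance (the generator's model of a
hyperosmotic stimulus) shortens the effective length constant, so the same
somatic train produces a much smaller calcium response at 125 um than at
25 um.  The script measures delta Peak dF/F (% of baseline response) at
both sites and tests the proximal/distal difference.
"""

import numpy as np

import dendrocalc as dc

base = dc.CellGroundTruth(seed=2)
rng = np.random.default_rng(base.seed)
n_cells = 8

deltas = {25.0: [], 125.0: []}
for _ in range(n_cells):
    for distance in deltas:
        peaks = {}
        for leak in (1.0, 2.0):  # control vs hyperosmotic
            rec = dc.simulate_linescan(base.with_(osmotic_leak_factor=leak),
                                       distance, rng=rng)
            peaks[leak] = dc.analyze_recording(rec).peak_dff
        deltas[distance].append(
            dc.delta_peak_percent([peaks[1.0]], [peaks[2.0]]))

prox, dist = np.asarray(deltas[25.0]), np.asarray(deltas[125.0])
print(f"proximal (25 um): delta Peak dF/F = {prox.mean():6.1f} +/- "
      f"{prox.std(ddof=1)/np.sqrt(n_cells):4.1f} %")
print(f"distal (125 um):  delta Peak dF/F = {dist.mean():6.1f} +/- "
      f"{dist.std(ddof=1)/np.sqrt(n_cells):4.1f} %")

res = dc.paired_t(prox, dist)
print(f"paired t({res.df:.0f}) = {res.statistic:.2f}, p = {res.p:.2g}")
print("A negative delta means the challenge reduced the response; the")
print("distal site loses proportionally more because attenuation compounds")
print("with distance when the membrane gets leakier.")
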