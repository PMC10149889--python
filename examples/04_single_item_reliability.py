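"""Retest reliability of a single item from three measurement occasions.

Simulates a quasi-simplex panel (reliability .75, wave-to-wave true-score
stability .90, retention 100/67/67 percent as in a typical online panel)
and estimates the item's reliability from the three observed
autocorrelations: rxx = (r12 * r23) / r13.  The formula removes true
change, so it isolates measurement error from instability.
"""

from psyvalid import SimplexSpec, heise_with_bounds, sample_three_wave

spec = SimplexSpec(n_subjects=411, reliability=0.75, stability=0.9,
                   attrition_rates=(1.0, 0.67, 0.67), seed=42)
wide = sample_three_wave(spec)

for sample in ("full", "panel"):
    est = heise_with_bounds(wide, sample=sample)
    print(f"{sample:5s}  r12 = {est.r12:.2f}  r23 = {est.r23:.2f}  r13 = {est.r13:.2f}"
          f"   rxx = {est.rxx:.2f}  [{est.lower:.2f}, {est.upper:.2f}]"
          f"   n = {est.n12}/{est.n23}/{est.n13}")

# Both samples should recover rxx near the generating reliability of .75;
# the full sample uses all available pairs per lag (pairwise deletion),
# the panel sample only subjects observed at all three waves.  The bounds
# apply the formula to the per-lag 95% confidence limits.
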