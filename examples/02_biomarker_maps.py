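"""Compute ADC, PDFF and MTR maps from a synthetic study.

Runs the full map pipeline — DWI exclusions + log-ratio ADC, 12-echo
merge + graph-cut field map + water/fat least squares, SNR-gated MTR —
on a noise-free phantom and prints recovered section means against the
generator truth.  Noise-free, the recovery is exact to numerical
precision; the printed deltas show it.
"""

from marrowqib import phantom, pipeline

study = phantom.simulate_study(
    {q: phantom.WT_SECTION_MEANS[q] for q in phantom.QIB_NAMES},
    field_amplitude_hz=20.0,
)
maps, stats, _ = pipeline.process_study(study, pipeline.MapConfig(mtr_noise_sd=1e-6))

print(f"{'QIB':5s} {'sec':3s} {'recovered':>12s} {'truth':>8s} {'delta':>10s}")
for st in stats:
    idx = {"S1": 0, "S2": 1, "S3": 2}[st.section]
    truth = study.truth.section_values[st.qib_kind][idx]
    print(f"{st.qib_kind:5s} {st.section:3s} {st.mean:12.6f} {truth:8.3f} "
          f"{st.mean - truth:10.2e}")
# delta ~ 1e-10 or below: the three inverse problems are solved exactly
# on noise-free data (field-map refinement removes the psi grid bias).
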