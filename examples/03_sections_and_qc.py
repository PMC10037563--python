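"""Section parsing and the automatic section-level quality control.

Parses a VOI into the S1/S2/S3 z-spans (1.8-9.0, 9.8-11.7, 12.6-13.5 mm
from the widest axial slice), then shows the QC rules eliminating
implausible section means: ADC < 0.05 um^2/ms and MTR < 0.1 (strict).
"""

from marrowqib import phantom
from marrowqib.sections import SectionStat, apply_section_qc, parse_sections

voi = phantom.make_voi_mask()
ss = parse_sections(voi, phantom.PhantomGeometry().spacing)
print(f"origin slice (widest): {ss.origin_slice_index}")
for name, mask in ss.masks.items():
    lo, hi = ss.spans_mm[name]
    print(f"{name}: z {lo:4.1f}-{hi:4.1f} mm -> {int(mask.sum()):4d} voxels")

stats = [
    SectionStat("ADC", "S3", mean=0.04, n_valid_pixels=50),   # too low -> drop
    SectionStat("ADC", "S1", mean=0.32, n_valid_pixels=700),
    SectionStat("MTR", "S3", mean=0.10, n_valid_pixels=50),   # boundary -> keep
    SectionStat("MTR", "S2", mean=0.08, n_valid_pixels=90),   # below -> drop
]
for st in apply_section_qc(stats):
    verdict = "pass" if st.qc_pass else f"FAIL ({st.exclusion_reason})"
    print(f"{st.qib_kind} {st.section} mean={st.mean:5.2f}: {verdict}")
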