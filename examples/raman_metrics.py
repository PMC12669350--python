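"""Compute the five Raman bone-quality metrics from synthetic spectra.

Renders spectra with a dominant fluorescence background and 1% noise at five
microanatomical positions of a forming osteon (Os → TA1 → TA2 → TA3 → In),
with the mineral bands growing along tissue age.  The pipeline trims to
350–1800 cm⁻¹, removes the background with the rubber-band method, computes
the band-ratio metrics, and averages ROIs into statistical units.  The
mineral/matrix ratio should rise monotonically with tissue age and match the
closed-form values of the generating bands to a few percent.
"""

import pandas as pd

import osteomat as om

rows = []
seed = 0
for position, mineral_scale in [("Os", 0.55), ("TA1", 0.75), ("TA2", 0.95),
                                ("TA3", 1.15), ("In", 1.35)]:
    for roi in range(3):
        spec = om.SpectrumSpec(
            bands=om.default_bone_bands(mineral_scale=mineral_scale),
            noise_sd=0.01, seed=seed)
        spectrum, truth = om.render_spectrum(spec)
        params = om.process_spectrum(spectrum)  # trim + rubber band + metrics
        rows.append(dict(subject="S001", compartment="osteonal",
                         position=position, roi_id=roi, label_quality="ok",
                         truth_mm=truth.mineral_matrix, **params.as_dict()))
        seed += 1

units = om.aggregate_statistical_units(pd.DataFrame(rows))
print("statistical units (one row per subject x compartment x position):")
print(units[["position", "mineral_matrix", "gag_ratio", "nanoporosity",
             "pyd", "mmc"]].round(4).to_string(index=False))

per_roi = pd.DataFrame(rows)
err = (per_roi.mineral_matrix - per_roi.truth_mm).abs() / per_roi.truth_mm
print(f"\nMM median |error| vs closed-form band truth: {err.median():.2%}")
print("MM rises Os -> In:", units.sort_values('position')
      .mineral_matrix.is_monotonic_increasing)
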