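"""Published summary statistics used for calibration and validation.

The original 44-fish market-weight Senegalese sole trial that this package
emulates deposited no raw data; its printed per-trait summaries (mean, sd,
min, max, CV) and simple-regression coefficients are therefore the only
real-data surface available. They are embedded here as plain constants and
used in two ways: to calibrate the synthetic-population defaults, and as
inputs to the internal-arithmetic validation suite
(:func:`filletvol.pipeline.validate_reference`), which recomputes derivable
quantities (trait sums, regression predictions at the means, CVs, critical
correlation values) through the package's own operations.

All areas are cm^2, volumes cm^3, weights g, lengths mm, CVs %.
"""

from __future__ import annotations

N_FISH = 44

#: Mean slice length between consecutive ultrasound sections at the mean
#: printed fish length (203.11 mm / 10), in cm.
SECTION_LENGTH_CM = 2.0311

#: Fish-level traits: name -> (mean, sd, min, max, cv_pct).
FISH_SUMMARIES: dict[str, tuple[float, float, float, float, float]] = {
    "body_weight_g": (298.54, 87.30, 178.77, 456.32, 29.2),
    "total_volume_cm3": (283.27, 80.59, 172.10, 412.70, 28.4),
    "length_mm": (203.11, 36.52, 162.30, 299.60, 18.0),
    "fillet_weight_g": (49.31, 17.28, 26.90, 85.00, 35.0),
    "fillet_volume_cm3": (49.12, 17.51, 28.20, 88.20, 35.6),
    "fillet_yield_pct": (16.32, 1.57, 12.08, 20.13, 9.6),
}

#: Mean measured slice areas A1..A10 (cm^2), cranial to caudal.
SLICE_AREA_MEANS: dict[str, float] = {
    "A1": 3.40, "A2": 3.68, "A3": 3.60, "A4": 2.75, "A5": 2.61,
    "A6": 2.62, "A7": 1.96, "A8": 1.40, "A9": 1.02, "A10": 0.81,
}

#: Mean single-section volumes V1..V9 (cm^3).
SINGLE_VOLUME_MEANS: dict[str, float] = {
    "V1": 7.12, "V2": 7.80, "V3": 7.43, "V4": 5.64, "V5": 5.41,
    "V6": 5.48, "V7": 4.05, "V8": 2.86, "V9": 2.13,
}

#: Mean spanning and combined volumes (cm^3) as printed.
VOLUME_TRAIT_MEANS: dict[str, float] = {
    "V1-5": 33.39,
    "V6-9": 14.52,
    "V1+2": 14.92,
    "V3+4": 13.07,
    "V5+6": 10.89,
    "V7+8": 6.91,
    "V1+2+3": 22.35,
    "V4+5+6": 16.53,
    "V7+8+9": 9.03,
    "V1+3+5+7+9": 26.12,
    "V2+4+6+8": 21.79,
    "V1-3+4-6+7-9": 51.98,
    "V1+()+9": 47.91,
}

#: Simple-regression coefficients of actual fillet volume on a trait:
#: name -> (intercept, slope, r_squared, rmse). Only the rows the
#: validation suite and the worked examples use.
SIMPLE_FITS: dict[str, tuple[float, float, float, float]] = {
    "A1": (-2.53, 15.20, 0.613, 11.02),
    "A2": (-1.63, 13.79, 0.820, 7.51),
    "V1-5": (0.13, 1.47, 0.970, 3.08),
    "V6-9": (7.49, 2.87, 0.802, 7.88),
    "V1+()+9": (0.23, 1.02, 0.960, 3.55),
}

#: Printed significance bands for Pearson correlations at n = 44:
#: below 0.298 not significant; 0.299-0.387 significant at p < 0.05;
#: above 0.388 at p < 0.01. The exact df = n-2 t computation gives
#: critical values 0.297 (alpha = 0.05) and 0.384 (alpha = 0.01); both are
#: reported, classification always uses the exact test.
PRINTED_CRITICAL_R_05 = 0.298
PRINTED_CRITICAL_R_01 = 0.388
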