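# Tissue -> epidermis conversion coefficients (SYNTHETIC PLACEHOLDERS).
#
# The pipeline converts red-blood-cell and unhatched-egg isotope values
# to epidermis equivalents with linear regressions of the form
#     epidermis = slope * tissue + intercept      (per element)
# The authoritative coefficients come from published tissue-comparison
# regressions and must be supplied by the analyst; the values below are
# synthetic stand-ins of plausible magnitude, intended only for demos
# and tests. Do NOT use them for real data.
tissue_conversion:
  red_blood_cells:
    d13C: {slope: 1.0, intercept: 1.7}
    d15N: {slope: 1.0, intercept: 0.9}
  unhatched_egg:
    d13C: {slope: 1.0, intercept: 0.6}
    d15N: {slope: 1.0, intercept: -0.4}
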