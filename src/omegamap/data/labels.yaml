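# Stable-isotope-label (SIL) registry for fatty-acyl chains.
#
# Each entry maps a single-capital-letter prefix code (prepended to the
# chain shorthand, e.g. "A18:1") to the isotope label it encodes:
#   code    - unique capital letter; "O" and "P" are reserved for the
#             ether/vinyl-ether linkage prefixes and may not be used
#   element - "D" (deuterium) or "13C" (carbon-13)
#   count   - number of heavy atoms introduced by the label
#   omega   - the n-x double-bond position the label implies (labels sit at
#             the methyl terminus, so they survive elongation/desaturation
#             and pin the omega position), or null if none
labels:
  - {code: A, element: D,   count: 17, omega: 9}
  - {code: B, element: D,   count: 11, omega: 6}
  - {code: C, element: D,   count: 5,  omega: 3}
  - {code: D, element: 13C, count: 16, omega: 7}
  - {code: E, element: D,   count: 19, omega: 10}
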