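"""Published reference values used in worked examples and validation.

``TEHRAN_CLUSTERS`` holds the cluster summary table of a neighbourhood-level
female breast-cancer incidence study of Tehran (374 neighbourhoods, 3,080
geocoded cases, March 2008 – March 2011) as printed: per cluster the at-risk
population, observed (O) and expected (E) cases, and the published O/E and
relative-risk columns. The printed O, E and the study total C = 3,080 are
sufficient inputs to recompute the O/E and RR arithmetic exactly, which the
test suite and the acceptance script do.

Note: in the published table the low-rate primary row prints O/E = 0.05
although 6/106.75 = 0.056 rounds to 0.06; the published RR for that row
(0.05) does agree with the footnote formula. Recomputation therefore matches
every printed value to within one unit in the last printed digit.
"""

from __future__ import annotations

import pandas as pd

#: Total geocoded cases in the reference study.
TEHRAN_TOTAL_CASES = 3080

#: Published optimal Gini coefficient and maximum-size-cluster fraction.
TEHRAN_OPTIMAL_GINI = 0.47
TEHRAN_MSC_FRACTION = 0.04

TEHRAN_CLUSTERS = pd.DataFrame(
    [
        # direction, rank, districts, pop, observed, expected, printed O/E, printed RR
        ("high", 1, "3;6", 58039, 217, 55.37, 3.92, 4.14),
        ("high", 2, "3;4", 29134, 145, 27.79, 5.22, 5.43),
        ("high", 3, "4;8", 45449, 161, 43.36, 3.71, 3.86),
        ("low", 1, "17;18;19", 111902, 6, 106.75, 0.05, 0.05),
        ("low", 2, "16;20", 124216, 27, 118.50, 0.23, 0.22),
        ("low", 3, "14", 113341, 23, 108.12, 0.21, 0.21),
    ],
    columns=[
        "direction",
        "rank",
        "districts",
        "pop",
        "observed",
        "expected",
        "oe_published",
        "rr_published",
    ],
)
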