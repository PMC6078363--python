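"""Published worked example: reclassification after adding GRS quartiles.

Reference counts from a 31-variant coronary-artery-disease genetic risk
score study (1,566 cases, 1,322 controls) in which a baseline
traditional-risk-factor model was compared with the same model plus GRS
quartiles.  They let the reclassification arithmetic be verified
end-to-end with exact integer inputs, independent of any simulation.

``RECLASS_EVENTS`` / ``RECLASS_NONEVENTS`` are 4x4 reclassification
tables over the risk categories < 25%, 25-50%, 50-75%, 75-100% (rows =
baseline-model category, columns = with-GRS category).  The category-free
counts record how many subjects in each group moved to higher or lower
predicted risk when the GRS was added.
"""

from __future__ import annotations

import numpy as np

from .reclassification import DEFAULT_CUTPOINTS, ReclassTable

RECLASS_EVENTS = np.array([
    [6, 11, 0, 0],
    [44, 335, 123, 0],
    [0, 59, 471, 305],
    [0, 0, 9, 203],
])

RECLASS_NONEVENTS = np.array([
    [65, 36, 0, 0],
    [186, 504, 88, 0],
    [0, 60, 268, 79],
    [0, 0, 1, 35],
])

#: category-free up/down mover counts: (n, up, down) per group
CFNRI_EVENTS = (1566, 897, 669)
CFNRI_NONEVENTS = (1322, 553, 769)


def reference_reclass_table() -> ReclassTable:
    return ReclassTable(RECLASS_EVENTS.copy(), RECLASS_NONEVENTS.copy(),
                        DEFAULT_CUTPOINTS)
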