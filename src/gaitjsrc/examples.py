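"""Worked-example confusion counts for a nine-activity wearable-gait study.

The counts below come from a reference nine-activity classification
experiment on 20 subjects wearing five inertial sensor nodes (200-sample
windows, compressed-domain classification at 50% compression with 40
neighboring atoms per class); each class contributed 200 test windows.
They are used as input data by the documentation, the test suite and the
acceptance script to exercise the confusion-table metrics on realistic
numbers.

Two rows of the table as printed are internally inconsistent: "upstairs"
sums to 206 and "jog" to 205 against the stated 200 windows per class (and
the "sitting" column total disagrees with the printed one).
``CONSISTENT_ROWS`` indexes the seven rows whose counts do add up; recall
checks are restricted to those.
"""

import numpy as np

ACTIVITY_CLASSES = [
    "standing",
    "sitting",
    "walk_forward",
    "turn_left",
    "turn_right",
    "upstairs",
    "downstairs",
    "jog",
    "jump",
]

#: Rows = true class, columns = predicted class, order as ACTIVITY_CLASSES.
NINE_ACTIVITY_CONFUSION = np.array(
    [
        [186, 14, 0, 0, 0, 0, 0, 0, 0],
        [6, 184, 10, 0, 0, 0, 0, 0, 0],
        [4, 0, 194, 0, 0, 2, 0, 0, 0],
        [4, 0, 6, 188, 2, 0, 0, 0, 0],
        [6, 4, 0, 0, 190, 0, 0, 0, 0],
        [0, 6, 0, 0, 0, 196, 0, 4, 0],
        [4, 2, 0, 0, 0, 0, 194, 0, 0],
        [0, 0, 0, 0, 0, 4, 1, 200, 0],
        [0, 0, 6, 0, 0, 4, 6, 4, 180],
    ],
    dtype=int,
)

#: Test windows per class in the source experiment.
WINDOWS_PER_CLASS = 200

#: Indices of rows whose printed counts sum to WINDOWS_PER_CLASS.
CONSISTENT_ROWS = [0, 1, 2, 3, 4, 6, 8]

#: Recalls (percent) implied by the consistent rows: diagonal / 200 x 100.
CONSISTENT_ROW_RECALLS = [93.0, 92.0, 97.0, 94.0, 95.0, 97.0, 90.0]
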