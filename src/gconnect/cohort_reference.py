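"""Published cohort summary statistics used as reference inputs.

Group-level means and standard deviations (patients n=110, controls n=79)
for the general factor g, the LDA discriminant score and the 11 battery
tests, as printed in the source cohort's effect-size table, together with
the printed pooled-SD Cohen's d. These are inputs for recomputation and
cross-checks, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

N_PATIENTS = 110
N_CONTROLS = 79

#: measure -> (patient mean, patient SD, control mean, control SD, printed |d|)
EFFECT_TABLE_ROWS: list[tuple[str, float, float, float, float, float]] = [
    ("g", -0.307, 0.876, 0.427, 0.846, 0.850),
    ("lda", -0.407, 0.841, 0.567, 0.929, 1.109),
    ("block_design", -0.185, 0.938, 0.257, 1.033, 0.452),
    ("vocabulary", -0.269, 0.913, 0.375, 1.000, 0.677),
    ("line_orientation", -0.210, 1.110, 0.292, 0.735, 0.516),
    ("motor_speed", -0.280, 0.917, 0.390, 0.985, 0.709),
    ("letter_fluency", -0.079, 1.042, 0.110, 0.934, 0.190),
    ("semantic_fluency", -0.107, 1.017, 0.148, 0.963, 0.256),
    ("verbal_learning", -0.310, 0.955, 0.432, 0.901, 0.796),
    ("delayed_recall", -0.277, 0.999, 0.386, 0.870, 0.700),
    ("naming", -0.165, 1.012, 0.230, 0.942, 0.401),
    ("attention_inhibition", -0.189, 0.872, 0.263, 1.108, 0.463),
    ("working_memory", -0.125, 1.045, 0.174, 0.912, 0.301),
]


def effect_table() -> pd.DataFrame:
    """The printed effect-size table as a DataFrame indexed by measure."""
    return pd.DataFrame(
        EFFECT_TABLE_ROWS,
        columns=["measure", "mean_patient", "sd_patient", "mean_control",
                 "sd_control", "printed_d"],
    ).set_index("measure")
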