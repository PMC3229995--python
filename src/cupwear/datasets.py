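"""Reference tables from a published hip-simulator validation experiment.

Twelve commercial UHMWPE acetabular cups (28 mm inner diameter, outer
diameters 48–64 mm, titanium mesh backing) were wear-tested in a hip
simulator; linear wear of each cup was measured both with the 3D CT
method and with a coordinate measurement machine (CMM) as reference,
and cup/head diameters were measured by CT before and after wear. Four
cups served as unloaded soak controls. These printed summary values are
the inputs for the agreement and creep computations; the underlying
per-scan raw measurements were not published.

All linear values are millimetres.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "linear_wear_by_cup",
    "linear_wear_long",
    "diameters_by_ct",
    "SOAK_CONTROL_CUPS",
    "soak_control_cmm_penetration",
]

#: Per-cup mean (SD over replicate measurements) linear wear, mm.
#: Columns: CT mean/SD, CMM mean/SD for cups 1-12.
_LINEAR_WEAR = [
    # cup, ct_mean, ct_sd, cmm_mean, cmm_sd
    (1, 0.65, 0.14, 1.55, 0.21),
    (2, 0.89, 0.15, 1.23, 0.06),
    (3, 0.81, 0.11, 1.15, 0.16),
    (4, 0.20, 0.16, 0.08, 0.14),
    (5, 2.22, 0.12, 2.54, 0.27),
    (6, 2.18, 0.13, 1.69, 0.25),
    (7, 0.01, 0.14, 0.02, 0.23),
    (8, 0.17, 0.07, 0.02, 0.24),
    (9, 1.00, 0.12, 1.26, 0.09),
    (10, -0.01, 0.10, 0.05, 0.08),
    (11, 0.46, 0.12, 0.60, 0.08),
    (12, 1.04, 0.14, 0.91, 0.13),
]

#: Printed per-cup difference column (CT minus CMM) of the same table;
#: computed by the original authors from unrounded means, so cup 7 reads
#: -0.00 while the rounded means give -0.01.
PRINTED_DIFFERENCES = [
    -0.90, -0.34, -0.34, 0.12, -0.32, 0.49, -0.00, 0.15, -0.26, -0.06, -0.14, 0.13,
]

#: Cups used as unloaded soak controls (creep estimation).
SOAK_CONTROL_CUPS = (4, 7, 8, 10)

#: CT measurements of outer cup and femoral head diameters, mm:
#: mean over all 48 measurements (SD) before and after wear.
_DIAMETERS_CT = [
    # object, state, mean, sd
    ("cup", "unworn", 54.37, 5.14),
    ("cup", "worn", 54.77, 5.12),
    ("head", "unworn", 28.04, 0.06),
    ("head", "worn", 27.86, 0.05),
]


def linear_wear_by_cup() -> pd.DataFrame:
    """Per-cup linear wear summary, indexed by cup number.

    Columns: ``ct_mean``, ``ct_sd``, ``cmm_mean``, ``cmm_sd``,
    ``printed_difference`` (the difference column as originally
    printed).
    """
    df = pd.DataFrame(
        _LINEAR_WEAR, columns=["cup", "ct_mean", "ct_sd", "cmm_mean", "cmm_sd"]
    ).set_index("cup")
    df["printed_difference"] = PRINTED_DIFFERENCES
    return df


def linear_wear_long() -> pd.DataFrame:
    """Per-cup wear in long format: ``unit_id``, ``method``, ``value``.

    One row per cup and method (the published per-cup means), shaped for
    :func:`cupwear.stats.summarize_wear_table`.
    """
    wide = linear_wear_by_cup()
    rows = []
    for cup, row in wide.iterrows():
        rows.append({"unit_id": cup, "method": "CT", "value": row["ct_mean"]})
        rows.append({"unit_id": cup, "method": "CMM", "value": row["cmm_mean"]})
    return pd.DataFrame(rows)


def diameters_by_ct() -> pd.DataFrame:
    """CT diameter measurements, indexed by (object, state)."""
    return pd.DataFrame(
        _DIAMETERS_CT, columns=["object", "state", "mean", "sd"]
    ).set_index(["object", "state"])


def soak_control_cmm_penetration() -> pd.Series:
    """CMM penetration readings of the four soak-control cups (mm)."""
    wide = linear_wear_by_cup()
    return wide.loc[list(SOAK_CONTROL_CUPS), "cmm_mean"]
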