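"""Fixed feature-table schema shared across extraction, statistics and evaluation.

A feature table is a pandas DataFrame with one row per subject:
``subject_id``, ``gender`` ("F"/"M"), ``group`` ("HC"/"MCI"/"AD"), then 25
acoustic columns and 10 linguistic columns in a fixed order.
"""

from __future__ import annotations

import pandas as pd

ID_COLUMNS = ["subject_id", "gender", "group"]

F0_COLUMNS = [f"f0_{i}" for i in range(1, 8)]
MFCC_MEAN_COLUMNS = [f"mfcc{i}_mean" for i in range(1, 7)]
MFCC_STD_COLUMNS = [f"mfcc{i}_std" for i in range(1, 7)]
FORMANT_COLUMNS = [f"formant{i}_med" for i in range(1, 5)]

ACOUSTIC_COLUMNS = (
    F0_COLUMNS + ["jitter", "shimmer"] + MFCC_MEAN_COLUMNS + MFCC_STD_COLUMNS + FORMANT_COLUMNS
)

LINGUISTIC_COLUMNS = [
    "noun_ratio",
    "verb_ratio",
    "pronoun_ratio",
    "ttr_words",
    "ttr_chars",
    "info_word_ratio",
    "iu_people",
    "iu_objects",
    "iu_places",
    "iu_actions",
]

ALL_FEATURE_COLUMNS = ACOUSTIC_COLUMNS + LINGUISTIC_COLUMNS

FEATURE_SETS = {
    "acoustic": ACOUSTIC_COLUMNS,
    "linguistic": LINGUISTIC_COLUMNS,
    "all": ALL_FEATURE_COLUMNS,
}

GROUPS = ("HC", "MCI", "AD")

#: Classification tasks: positive (impaired) groups vs the HC reference.
TASKS = {
    "HC_vs_AD": ("AD",),
    "HC_vs_CI": ("AD", "MCI"),  # CI = cognitively impaired = AD plus MCI
}


def validate_feature_table(table: pd.DataFrame, feature_set: str = "all") -> None:
    """Check schema, id uniqueness and completeness for the chosen feature set."""
    cols = FEATURE_SETS[feature_set]
    missing = [c for c in ID_COLUMNS + cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in feature table")
    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if table[cols].isna().any().any():
        na_cols = table[cols].columns[table[cols].isna().any()].tolist()
        raise ValueError(f"incomplete feature columns: {na_cols}")
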