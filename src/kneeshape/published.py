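"""Published summary values from the reference adolescent knee-cohort study.

The raw MRI data behind the reference study are not publicly deposited; what
is public are summary tables. The values below are inputs for bookkeeping
checks (explained-variance accounting, mode selection, Bonferroni
thresholds, cohort proportions) — they are never used to fit anything.
"""

#: per-mode explained variance (%) of the patellar shape model, printed for
#: the modes that met the >= 1% inclusion rule
PATELLA_EXPLAINED_PCT = (44.4, 16.1, 7.0, 5.0, 3.5, 3.1, 2.2, 1.8, 1.5, 1.3, 1.1)

#: per-mode explained variance (%) of the femoral shape model
FEMUR_EXPLAINED_PCT = (48.1, 7.6, 5.2, 4.8, 3.5, 2.7, 2.3, 2.0, 1.9, 1.7,
                       1.5, 1.3, 1.1, 1.0)

#: cohort size and the two most common sports
N_PARTICIPANTS = 1912
N_FOOTBALL = 321
N_FIELD_HOCKEY = 277
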