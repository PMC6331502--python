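"""Published group-level summary statistics used as verification anchors.

These constants are the per-group descriptive statistics and printed test
statistics of the matched-pair vocal-emotion / vocal-pitch study design this
package models (16 adults with ASD, 16 matched typically-developing
comparison participants).  They serve two roles: defaults for the synthetic
cohort generator, and inputs to :func:`voxpitch.pipeline.reproduce_printed_statistics`,
which recomputes every derivable statistic (pooled t, Cohen's d, partial eta
squared, Fisher's Z, correlation p-values) from them and reports
computed-vs-printed deltas.
"""

from __future__ import annotations

N_PER_GROUP = 16

# ----- emotion recognition test: percent correct, mean and SD per group -----
# (ASD group first, comparison group second)
EMOTION_ACCURACY = {
    "happiness": {"asd": (64.10, 30.93), "comparison": (80.54, 9.93)},
    "sadness":   {"asd": (51.45, 32.05), "comparison": (81.64, 10.76)},
    "fear":      {"asd": (68.37, 27.82), "comparison": (89.85, 6.71)},
    "anger":     {"asd": (84.98, 13.15), "comparison": (92.48, 6.58)},
    "disgust":   {"asd": (50.18, 22.77), "comparison": (65.97, 21.78)},
    "neutral":   {"asd": (90.63, 9.11),  "comparison": (93.13, 5.43)},
}
EMOTION_TOTAL = {"asd": (68.33, 17.41), "comparison": (83.95, 5.86)}

# Printed post-hoc statistics for single emotions (t(30), Cohen's d).
PRINTED_POSTHOC = {
    "sadness": {"t": 3.573, "d": 1.263, "p": 0.001},
    "fear":    {"t": 3.002, "d": 1.061, "p": 0.005},
    "neutral": {"t": 0.943, "d": 0.333, "p": 0.353},
}

# Printed 2 (group) x 6 (emotion) ANOVA effects (multivariate approach).
PRINTED_ANOVA = {
    "group":       {"F": 11.594, "df1": 1, "df2": 30, "p": 0.002, "eta_p2": 0.279},
    "within":      {"F": 15.062, "df1": 5, "df2": 26, "p": 0.001, "eta_p2": 0.743},
    "interaction": {"F": 2.346,  "df1": 5, "df2": 26, "p": 0.069, "eta_p2": 0.311},
}

# ----- discrimination thresholds and control tests (mean, SD per group) -----
PITCH_JND = {"asd": (65.18, 47.69), "comparison": (36.02, 21.39)}      # cents
TIMBRE_JND = {"asd": (4.28, 2.17), "comparison": (3.45, 1.62)}         # SER-%
NONVOCAL_PITCH = {"asd": (82.27, 8.03), "comparison": (85.56, 7.57)}   # MBEA %

# ----- questionnaire / diagnostic scores -----
AQ = {"asd": (39.81, 6.61), "comparison": (14.13, 4.77)}
AQ_CLINICAL_CUTOFF = 32
ADOS_COMMUNICATION = {"asd": (3.80, 1.27)}

# ----- matched-pair demographics -----
AGE = {"asd": (33.75, 10.12), "comparison": (33.69, 9.58)}
FULLSCALE_IQ = {"asd": (110.31, 13.79), "comparison": (111.50, 10.97)}
AGE_MATCH_TOLERANCE_YEARS = 3.0
IQ_MATCH_TOLERANCE_POINTS = 15.0
GENDER_COUNTS = {"male": 13, "female": 3}      # per group of 16
HANDEDNESS_COUNTS = {"right": 14, "left": 2}   # per group of 16

# ----- printed within-group correlations (variable pair -> r, n, tails) -----
CORRELATIONS = {
    ("emotion_total", "pitch_jnd", "comparison"):
        {"r": -0.489, "n": 16, "p": 0.027, "tails": 1, "method": "spearman"},
    ("emotion_total", "pitch_jnd", "comparison", "pearson"):
        {"r": -0.554, "n": 16},
    ("emotion_total", "pitch_jnd", "asd"):
        {"r": -0.346, "n": 15, "p": 0.207, "tails": 2},
    ("emotion_total", "aq", "comparison"):
        {"r": -0.501, "n": 16, "p": 0.048, "tails": 2},
    ("emotion_total", "aq", "asd"):
        {"r": -0.197, "n": 16, "p": 0.465, "tails": 2},
    ("emotion_total", "ados_comm", "asd"):
        {"r": -0.672, "n": 15, "p": 0.006, "tails": 2},
}

# Printed comparisons of correlation coefficients.
PRINTED_FISHER_Z = {  # emotion-pitch r, comparison (Pearson) vs ASD group
    "r1": -0.554, "n1": 16, "r2": -0.346, "n2": 15, "z": -0.66,
}
PRINTED_STEIGER_Z = {  # vocal-pitch vs non-vocal-pitch correlation, comparison
    "z": 0.55,  # the inter-correlation r23 needed to recompute it is unpublished
}

# ----- stimulus-level 4-level ANOVAs (intensity / frequency range) -----
PRINTED_LEVEL_ANOVA = {
    "intensity":  {"F": 53.529, "df1": 3, "df2": 28},
    "freq_range": {"F": 14.720, "df1": 3, "df2": 28},
}
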