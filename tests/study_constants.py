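"""Printed reference numbers of the tetrahydroquinoline LSD1 study used as
test inputs: the 40-row activity table, the published model statistics and
the external-validation table."""

# (compound number, IC50 in μM, printed pIC50, in external test set)
ACTIVITY_TABLE = [
    (1, 0.00825, 8.08355, False),
    (2, 0.01726, 7.76296, True),
    (3, 0.03126, 7.50501, False),
    (4, 0.03626, 7.44057, False),
    (5, 0.03637, 7.43926, False),
    (6, 0.03658, 7.43676, False),
    (7, 0.03768, 7.42389, False),
    (8, 0.03825, 7.41737, True),
    (9, 0.03834, 7.41635, False),
    (10, 0.04678, 7.32994, False),
    (11, 0.04736, 7.32459, True),
    (12, 0.05349, 7.27173, False),
    (13, 0.06000, 7.22185, False),
    (14, 0.08035, 7.09501, True),
    (15, 0.14856, 6.82810, False),
    (16, 0.15000, 6.82391, False),
    (17, 0.15000, 6.82391, True),
    (18, 0.18000, 6.74473, False),
    (19, 0.39000, 6.40894, False),
    (20, 0.53000, 6.27572, False),
    (21, 0.54000, 6.26761, False),
    (22, 0.54000, 6.26761, False),
    (23, 0.73232, 6.13530, True),
    (24, 0.78000, 6.10791, True),
    (25, 0.92000, 6.03621, False),
    (26, 0.93000, 6.03152, False),
    (27, 0.97000, 6.01323, False),
    (28, 1.13000, 5.94692, False),
    (29, 1.56000, 5.80688, True),
    (30, 1.82000, 5.73993, False),
    (31, 2.31000, 5.63639, False),
    (32, 2.81000, 5.55129, False),
    (33, 3.92000, 5.40671, True),
    (34, 4.44000, 5.35262, False),
    (35, 4.55000, 5.34199, False),
    (36, 4.58000, 5.33914, False),
    (37, 5.12000, 5.29073, False),
    (38, 13.0900, 4.88306, False),
    (39, 18.8000, 4.72584, True),
    (40, 25.6400, 4.59108, False),
]

# published external-validation inputs (test-set regression statistics)
EXTERNAL_COMFA = {"r2": 0.754, "k": 0.971, "k_prime": 1.025, "r02": 0.752, "r02_prime": 0.650}
EXTERNAL_COMSIA = {"r2": 0.749, "k": 0.975, "k_prime": 1.021, "r02": 0.745, "r02_prime": 0.706}

# published fit statistics of the two selected models: (n_train, ONC, r2, F)
FIT_STATS_COMFA_S = (30, 2, 0.877, 96.151)
FIT_STATS_COMSIA_SHDA = (30, 7, 0.965, 86.831)

# field-kind combination of the study's selected similarity model
STUDY_KINDS = ("steric", "hydrophobic", "donor", "acceptor")
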