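"""Reference cluster cross-tabulations from a published multi-cohort PD study.

Demographic and clinical count tables for two published sMRI-based PD
cluster solutions — a 3-cluster solution obtained without global-atrophy
adjustment and an 8-cluster (of 10, two excluded as too small) solution
obtained with it — together with the chi-square statistics reported for
them.  Rows are clusters, columns are variable categories.  These serve as
fixed worked-example inputs for the categorical test machinery and the
minimum-cluster-size filter.
"""

# 3-cluster (global-atrophy-unadjusted) solution, N = 633
UNADJUSTED_TABLES = {
    # variable: (counts rows=cl1..cl3, reported chi-square)
    "sex_men_women": ([[190, 112], [88, 60], [123, 60]], 2.166),
    "hoehn_yahr": ([[85, 2, 174, 5, 22, 6],
                    [57, 2, 73, 2, 7, 2],
                    [48, 1, 102, 5, 19, 2]], 12.013),
    "medicated": ([[117, 184], [60, 88], [81, 102]], 1.376),
    "mci": ([[47, 184], [13, 96], [38, 99]], 9.307),
    "depression": ([[47, 185], [26, 85], [32, 110]], 0.536),
    "rbd": ([[55, 99], [27, 44], [37, 52]], 0.823),
    "cohort": ([[46, 40, 61, 155], [26, 15, 36, 71], [35, 20, 39, 89]], 3.148),
}

# 8-cluster (global-atrophy-adjusted) solution, N = 624 retained
ADJUSTED_TABLES = {
    "sex_men_women": ([[51, 5], [145, 44], [40, 22], [75, 92],
                       [37, 14], [19, 27], [15, 4], [18, 16]], 73.143),
    "hoehn_yahr": ([[19, 0, 32, 1, 2, 1], [58, 2, 99, 2, 19, 2],
                    [12, 1, 40, 2, 5, 1], [45, 0, 90, 6, 13, 5],
                    [15, 1, 33, 0, 2, 0], [14, 1, 26, 0, 4, 1],
                    [11, 0, 7, 0, 1, 0], [14, 0, 15, 1, 2, 0]], 32.097),
    "medicated": ([[28, 28], [79, 110], [26, 36], [74, 93],
                   [17, 34], [21, 25], [5, 14], [7, 26]], 11.353),
    "mci": ([[8, 40], [33, 105], [12, 31], [23, 96],
             [11, 33], [6, 32], [2, 12], [3, 21]], 5.168),
    "depression": ([[7, 40], [23, 114], [12, 35], [36, 88],
                    [9, 35], [10, 28], [1, 13], [5, 20]], 9.881),
    "rbd": ([[12, 14], [40, 51], [10, 20], [34, 41],
             [6, 26], [5, 15], [2, 10], [7, 13]], 12.966),
    "cohort": ([[16, 8, 6, 26], [24, 25, 49, 91], [13, 5, 14, 30],
                [31, 21, 39, 76], [8, 5, 6, 32], [10, 8, 8, 20],
                [2, 0, 5, 12], [2, 3, 9, 20]], 28.416),
}

#: sizes of the published 10-cluster solution before the >= 10 filter
TEN_CLUSTER_SIZES = [56, 189, 62, 167, 51, 46, 19, 34, 8, 1]

#: sizes of the published 3-cluster solution (no exclusions)
THREE_CLUSTER_SIZES = [302, 148, 183]

ALL_TABLES = {("unadjusted", k): v for k, v in UNADJUSTED_TABLES.items()} | \
             {("adjusted", k): v for k, v in ADJUSTED_TABLES.items()}
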