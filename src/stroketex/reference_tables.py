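"""Reference 10-fold confusion counts for the four SVM kernels.

Each kernel maps to ten per-fold ``(TP, TN, FP, FN)`` tuples; the metric
arithmetic of :mod:`stroketex.model_eval` must reproduce the associated
reported per-fold metrics and fold averages exactly at 2-decimal rounding.
``REPORTED_FOLD_METRICS`` and ``REPORTED_SUMMARY`` hold those reported
values ``(ACC, PPV, SEN, SPE, Dice)`` for cross-checking.
"""

REFERENCE_FOLD_COUNTS = {
    "linear": [
        (37, 21, 1, 6), (41, 19, 4, 2), (38, 17, 5, 6), (40, 21, 1, 4),
        (39, 17, 5, 5), (39, 18, 4, 5), (40, 19, 3, 4), (36, 20, 2, 8),
        (38, 20, 2, 6), (36, 21, 1, 7),
    ],
    "poly2": [
        (37, 22, 0, 6), (39, 23, 0, 4), (40, 20, 2, 4), (39, 22, 0, 5),
        (43, 21, 1, 1), (40, 22, 0, 4), (41, 21, 1, 3), (36, 22, 0, 8),
        (40, 22, 0, 4), (40, 22, 0, 3),
    ],
    "poly3": [
        (38, 22, 0, 5), (38, 23, 0, 5), (40, 21, 1, 4), (39, 22, 0, 5),
        (42, 21, 1, 2), (41, 22, 0, 3), (38, 20, 2, 6), (37, 22, 0, 7),
        (37, 22, 0, 7), (41, 22, 0, 2),
    ],
    "rbf": [
        (38, 21, 1, 5), (40, 23, 0, 3), (41, 18, 4, 3), (40, 22, 0, 4),
        (43, 20, 2, 1), (40, 21, 1, 4), (42, 21, 1, 2), (39, 22, 0, 5),
        (41, 22, 0, 3), (40, 22, 0, 3),
    ],
}

REPORTED_FOLD_METRICS = {
    "linear": [
        (89.23, 97.37, 86.05, 95.45, 0.91), (90.91, 91.11, 95.35, 82.61, 0.93),
        (83.33, 88.37, 86.36, 77.27, 0.87), (92.42, 97.56, 90.91, 95.45, 0.94),
        (84.85, 88.64, 88.64, 77.27, 0.89), (86.36, 90.70, 88.64, 81.82, 0.90),
        (89.39, 93.02, 90.91, 86.36, 0.92), (84.85, 94.74, 81.82, 90.91, 0.88),
        (87.88, 95.00, 86.36, 90.91, 0.90), (87.69, 97.30, 83.72, 95.45, 0.90),
    ],
    "poly2": [
        (90.77, 100.00, 86.05, 100.00, 0.93), (93.94, 100.00, 90.70, 100.00, 0.95),
        (90.91, 95.24, 90.91, 90.91, 0.93), (92.42, 100.00, 88.64, 100.00, 0.94),
        (96.97, 97.73, 97.73, 95.45, 0.98), (93.94, 100.00, 90.91, 100.00, 0.95),
        (93.94, 97.62, 93.18, 95.45, 0.95), (87.88, 100.00, 81.82, 100.00, 0.90),
        (93.94, 100.00, 90.91, 100.00, 0.95), (95.38, 100.00, 93.02, 100.00, 0.96),
    ],
    "poly3": [
        (92.31, 100.00, 88.37, 100.00, 0.94), (92.42, 100.00, 88.37, 100.00, 0.94),
        (92.42, 97.56, 90.91, 95.45, 0.94), (92.42, 100.00, 88.64, 100.00, 0.94),
        (95.45, 97.67, 95.45, 95.45, 0.97), (95.45, 100.00, 93.18, 100.00, 0.96),
        (87.88, 95.00, 86.36, 90.91, 0.90), (89.39, 100.00, 84.09, 100.00, 0.91),
        (89.39, 100.00, 84.09, 100.00, 0.91), (96.92, 100.00, 95.35, 100.00, 0.98),
    ],
    "rbf": [
        (90.77, 97.44, 88.37, 95.45, 0.93), (95.45, 100.00, 93.02, 100.00, 0.96),
        (89.39, 91.11, 93.18, 81.82, 0.92), (93.94, 100.00, 90.91, 100.00, 0.95),
        (95.45, 95.56, 97.73, 90.91, 0.97), (92.42, 97.56, 90.91, 95.45, 0.94),
        (95.45, 97.67, 95.45, 95.45, 0.97), (92.42, 100.00, 88.64, 100.00, 0.94),
        (95.45, 100.00, 93.18, 100.00, 0.96), (95.38, 100.00, 93.02, 100.00, 0.96),
    ],
}

# fold-averaged (ACC, PPV, SEN, SPE, Dice) per kernel
REPORTED_SUMMARY = {
    "linear": (87.69, 93.38, 87.88, 87.35, 0.90),
    "poly2": (93.01, 99.06, 90.39, 98.18, 0.94),
    "poly3": (92.41, 99.02, 89.48, 98.18, 0.94),
    "rbf": (93.62, 97.93, 92.44, 95.91, 0.95),
}

# summed confusion counts per kernel, as reported in the averaged rows
REPORTED_TOTAL_COUNTS = {
    "linear": (384, 193, 28, 53),
    "poly2": (395, 217, 4, 42),
    "poly3": (391, 217, 4, 46),
    "rbf": (404, 212, 9, 33),
}
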