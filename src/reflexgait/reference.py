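"""Published reference parameter sets for the motor transfer functions.

Twelve transfer-function sets (1A–6B) were derived from human treadmill
walking: the letter distinguishes the two treadmill sequences (A = 25
strides per speed setting, B = 100 strides per speed setting) and the
number the aggregation policy over subjects (mean of all, per-sex means,
minimum-MSE selection, single subjects).  Each set provides the fitted
critically-damped twitch parameters (tau1, tau2 rise/fall time constants
and T0 trigger-to-onset delay, all in milliseconds) for the hip and knee
flexor/extensor activation curves, plus the measured curve characteristics
(ΔT50 width at half peak and time-to-peak) and the stability outcome
observed when the set drove the physical walker.
"""

from __future__ import annotations

SET_IDS = ("1A", "1B", "2A", "2B", "3A", "3B", "4A", "4B", "5A", "5B", "6A", "6B")

SET_DESCRIPTIONS = {
    "1": "mean average of all subjects",
    "2": "mean average of male subjects only",
    "3": "mean average of female subjects only",
    "4": "per-function subject with minimum final adaptive-filter MSE",
    "5": "single male subject (subject C)",
    "6": "single female subject (subject H)",
}

# Hip curve-fit parameters: set -> {"flexion"/"extension": (tau1_ms, tau2_ms, T0_ms)}
HIP_CURVE_PARAMS = {
    "1A": {"flexion": (76.97, 76.96, 75), "extension": (73.22, 73.22, 75)},
    "1B": {"flexion": (86.91, 86.91, 80), "extension": (128.24, 81.73, 85)},
    "2A": {"flexion": (88.31, 88.31, 30), "extension": (72.47, 72.47, 80)},
    "2B": {"flexion": (83.80, 83.80, 60), "extension": (71.82, 71.82, 80)},
    "3A": {"flexion": (78.53, 78.52, 90), "extension": (72.31, 72.31, 100)},
    "3B": {"flexion": (93.71, 93.71, 80), "extension": (133.76, 133.76, 80)},
    "4A": {"flexion": (91.96, 91.96, 125), "extension": (95.88, 34.27, 80)},
    "4B": {"flexion": (77.52, 77.52, 70), "extension": (100.46, 100.46, 50)},
    "5A": {"flexion": (113.28, 113.28, 5), "extension": (91.43, 91.43, 15)},
    "5B": {"flexion": (76.18, 76.18, 75), "extension": (74.65, 74.65, 100)},
    "6A": {"flexion": (93.08, 93.08, 110), "extension": (112.16, 112.16, 100)},
    "6B": {"flexion": (78.41, 78.41, 120), "extension": (110.89, 110.89, 100)},
}

# Knee curve-fit parameters, same layout.  The printed T0 values are the
# measured trigger-to-onset delays; when the sets are deployed on the walker
# the knee delays are zeroed (the knee's series springs already provide an
# equivalent mechanical latency), which `finalize_motor_tf` applies.
KNEE_CURVE_PARAMS = {
    "1A": {"flexion": (83.11, 83.11, 115), "extension": (103.84, 103.84, 425)},
    "1B": {"flexion": (105.02, 105.02, 115), "extension": (134.63, 134.59, 440)},
    "2A": {"flexion": (94.47, 94.47, 110), "extension": (107.71, 107.71, 430)},
    "2B": {"flexion": (76.58, 76.58, 120), "extension": (139.47, 139.47, 435)},
    "3A": {"flexion": (69.09, 69.09, 140), "extension": (77.13, 77.12, 460)},
    "3B": {"flexion": (113.76, 113.76, 125), "extension": (94.56, 94.56, 495)},
    "4A": {"flexion": (108.96, 108.96, 90), "extension": (136.61, 136.54, 450)},
    "4B": {"flexion": (82.99, 82.85, 105), "extension": (150.33, 150.33, 415)},
    "5A": {"flexion": (95.95, 95.95, 110), "extension": (131.17, 131.17, 410)},
    "5B": {"flexion": (82.99, 82.85, 105), "extension": (148.99, 148.99, 420)},
    "6A": {"flexion": (78.37, 78.37, 150), "extension": (151.75, 151.75, 425)},
    "6B": {"flexion": (97.24, 97.22, 130), "extension": (123.34, 123.34, 495)},
}

# Measured hip activation-curve characteristics per set:
# (flexor dT50_ms, flexor Tpeak_ms, extensor dT50_ms, extensor Tpeak_ms).
HIP_CHARACTERISTICS = {
    "1B": (175, 215, 190, 255),
    "3B": (190, 230, 220, 330),
    "4B": (155, 190, 165, 245),
    "5A": (140, 275, 125, 225),
    "6A": (220, 230, 230, 275),
    "6B": (215, 195, 225, 270),
    "1A": (160, 190, 160, 180),
    "2A": (135, 215, 130, 175),
    "2B": (155, 205, 165, 175),
    "3A": (280, 195, 185, 180),
    "4A": (225, 225, 130, 145),
    "5B": (155, 185, 185, 185),
}

# Observed gait outcome on the physical walker.
STABLE_SETS = frozenset({"1B", "3B", "4B", "5A", "6A", "6B"})
UNSTABLE_SETS = frozenset({"1A", "2A", "2B", "3A", "4A", "5B"})

# Sets where the "extensor dT50 > flexor dT50" heuristic disagrees with the
# observed outcome: 5A walked although the rule says no; 2B and 5B fell
# although the rule says yes.  The rule is a tendency, not a theorem.
HEURISTIC_EXCEPTIONS = frozenset({"5A", "2B", "5B"})

DEFAULT_SET = "1B"
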