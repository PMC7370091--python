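"""Published summary statistics of the motivating crossover trial.

The package's default simulation conditions emulate a randomized crossover
trial in which 18 men with moderate-to-severe COPD walked twice for 10 min at
50% of peak oxygen uptake, once breathing freely through mouth and nose (ONB)
and once through a nasal airflow-restriction device (FB).  The trial's raw
breath-by-breath series are not publicly deposited; what is available are
per-condition summary statistics (mean +/- SD of per-subject test means) and
the responder counts per variable, reproduced here as plain data.

These summaries serve two roles: they parameterize the default synthetic
generator (baselines, condition effects, noise scales), and they are the
inputs to the summary-level checks (breathing-pattern ratio, responder
proportion tests, paired effect sizes).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Number of participants who completed both conditions.
N_SUBJECTS = 18


@dataclass(frozen=True)
class ConditionSummary:
    """Per-variable trial summary: condition means/SDs and responder count."""

    fb_mean: float
    fb_sd: float
    onb_mean: float
    onb_sd: float
    responders: int


#: Per-variable condition summaries, ordered by descending responder count
#: as reported.  Note: the Tex/Tot SDs were reported in fractional units
#: (0.07, 0.06) while the means are percentages; values are kept as printed.
TABLE2: dict[str, ConditionSummary] = {
    "Tin": ConditionSummary(1.4, 0.6, 1.0, 0.3, 13),
    "RER": ConditionSummary(0.8, 0.1, 0.9, 0.1, 12),
    "Tin/Tot": ConditionSummary(44.7, 7.2, 41.3, 5.0, 10),
    "Tex": ConditionSummary(1.7, 0.6, 1.5, 0.3, 9),
    "BF": ConditionSummary(21.2, 6.7, 25.1, 5.2, 9),
    "EqO2": ConditionSummary(26.5, 4.2, 28.4, 4.0, 9),
    "FEO2": ConditionSummary(16.6, 0.7, 17.0, 0.5, 9),
    "Tex/Tot": ConditionSummary(55.3, 0.07, 58.7, 0.06, 9),
    "VTex": ConditionSummary(1.6, 0.5, 1.4, 0.4, 8),
    "VTin": ConditionSummary(1.5, 0.5, 1.4, 0.4, 8),
    "FECO2": ConditionSummary(3.2, 0.6, 3.0, 0.5, 7),
    "PETCO2": ConditionSummary(4.7, 0.5, 4.6, 0.5, 7),
    "VO2": ConditionSummary(1130.0, 300.0, 1110.0, 360.0, 7),
    "PETO2": ConditionSummary(14.4, 0.8, 14.6, 0.6, 7),
    "VE": ConditionSummary(32.1, 9.0, 34.5, 10.2, 7),
    "EqCO2": ConditionSummary(31.7, 4.5, 33.4, 4.5, 6),
    "HR": ConditionSummary(109.2, 17.0, 108.9, 15.4, 5),
    "VD/VT": ConditionSummary(24.5, 8.8, 26.9, 8.4, 5),
    "VCO2": ConditionSummary(900.2, 343.0, 895.6, 364.0, 2),
}

#: Borg rating of perceived exertion after each test: (mean, sd) per condition.
RPE_POST = {"ONB": (10.2, 2.9), "FB": (11.9, 2.6)}

#: Maximal inspiratory pressure (cmH2O): (mean, sd) at baseline and post-test.
PIMAX = {"Pre": (102.3, 25.2), "ONB": (100.5, 27.6), "FB": (95.2, 27.3)}


def breathing_pattern_ratio(condition: str) -> float:
    """Ratio of breathing frequency to minute ventilation (BF / VE).

    A lower ratio indicates a slower, deeper breathing pattern.  Computed
    from the trial's per-condition summary means.
    """
    bf = TABLE2["BF"]
    ve = TABLE2["VE"]
    if condition == "FB":
        return bf.fb_mean / ve.fb_mean
    if condition == "ONB":
        return bf.onb_mean / ve.onb_mean
    raise KeyError(f"unknown condition {condition!r}")
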