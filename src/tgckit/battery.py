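"""Neuropsychological test battery: domain map and scoring directions.

The battery covers six cognitive domains. Each test is scored against the
non-psychiatric control group (z-scores), averaged into domain composites,
and the six domain composites are averaged into a global cognition composite.

``HIGHER_IS_BETTER`` is False for timed/ratio measures where a larger raw
value means worse performance (Trail Making Test A time per connection and
the TMT B/A ratio); their z-scores are sign-flipped so that larger z always
means better performance.
"""

from __future__ import annotations

DOMAINS: tuple[str, ...] = (
    "verbal_memory",
    "visuospatial_memory",
    "processing_speed",
    "working_memory",
    "language",
    "executive_function",
)

#: test name -> cognitive domain
DOMAIN_MAP: dict[str, str] = {
    "cvlt_total_recall": "verbal_memory",
    "cvlt_dprime": "verbal_memory",
    "cvlt_pct_retained": "verbal_memory",
    "bvmt_total_recall": "visuospatial_memory",
    "bvmt_pct_retained": "visuospatial_memory",
    "dsc_correct": "processing_speed",
    "tmt_a_time_per_connection": "processing_speed",
    "pasat_correct": "working_memory",
    "cpt_ip_dprime": "working_memory",
    "bnt_correct": "language",
    "semantic_fluency": "language",
    "letter_fluency": "language",
    "tmt_b_a_ratio": "executive_function",
    "stroop_correct": "executive_function",
    "clock_drawing": "executive_function",
}

#: test name -> True if a larger raw score means better performance
HIGHER_IS_BETTER: dict[str, bool] = {
    name: name not in ("tmt_a_time_per_connection", "tmt_b_a_ratio")
    for name in DOMAIN_MAP
}

#: plausible control-population raw-score calibration: test -> (mean, SD)
#: used only by the synthetic generator; real data carries its own norms
CONTROL_CALIBRATION: dict[str, tuple[float, float]] = {
    "cvlt_total_recall": (45.0, 10.0),
    "cvlt_dprime": (2.5, 0.8),
    "cvlt_pct_retained": (85.0, 12.0),
    "bvmt_total_recall": (20.0, 6.0),
    "bvmt_pct_retained": (85.0, 15.0),
    "dsc_correct": (55.0, 12.0),
    "tmt_a_time_per_connection": (1.4, 0.4),
    "pasat_correct": (75.0, 18.0),
    "cpt_ip_dprime": (2.2, 0.7),
    "bnt_correct": (55.0, 4.0),
    "semantic_fluency": (20.0, 5.0),
    "letter_fluency": (40.0, 11.0),
    "tmt_b_a_ratio": (2.3, 0.8),
    "stroop_correct": (45.0, 10.0),
    "clock_drawing": (9.0, 1.5),
}

TESTS: tuple[str, ...] = tuple(DOMAIN_MAP)


def tests_in_domain(domain: str) -> list[str]:
    return [t for t, d in DOMAIN_MAP.items() if d == domain]
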