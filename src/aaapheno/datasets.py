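"""Bundled worked-example data.

Small transcribed summary tables from the multi-site chart-review validation
of this AAA algorithm (three eMERGE Network biobanks — GHS, the primary
development site, plus Mayo Clinic and Marshfield Clinic as validation
sites — and Aurora Health System, a non-network site).  They exist so the
documentation examples and regression checks can exercise the validation
statistics end to end without any clinical data: per-stratum review counts
for the PPV report, and per-site case-type counts for the case-mix table.
"""

from __future__ import annotations

import pandas as pd

from .validation import ConfusionCounts

__all__ = [
    "example_chart_review_counts",
    "example_chart_review_frame",
    "example_case_type_counts",
    "EMERGE_SITES",
]

#: The three network sites whose review counts are pooled for the headline
#: estimate; the external site is reported separately.
EMERGE_SITES = ("GHS", "Mayo", "Marshfield")

_CHART_REVIEW = (
    # site, cases reviewed, cases confirmed, controls reviewed, confirmed
    ("GHS", 50, 47, 50, 50),
    ("Mayo", 50, 44, 50, 50),
    ("Marshfield", 25, 25, 22, 22),
    ("Aurora", 50, 48, 50, 50),
)

_CASE_TYPES = {
    "GHS": {1: 295, 2: 16, 3: 388},
    "Aurora": {1: 0, 2: 7, 3: 249},
    "Mayo": {1: 72, 2: 0, 3: 106},
}


def example_chart_review_counts() -> list[ConfusionCounts]:
    """Chart-review confusion counts for the four example sites."""
    return [
        ConfusionCounts(
            site=site,
            predicted_case_reviewed=cr,
            true_case_among_predicted_cases=cc,
            predicted_control_reviewed=kr,
            true_control_among_predicted_controls=kc,
        )
        for site, cr, cc, kr, kc in _CHART_REVIEW
    ]


def example_chart_review_frame() -> pd.DataFrame:
    """Same counts as a DataFrame (the CSV dialect ``aaapheno report`` reads)."""
    rows = [
        {
            "site": site,
            "cases_reviewed": cr,
            "cases_confirmed": cc,
            "controls_reviewed": kr,
            "controls_confirmed": kc,
            "emerge": site in EMERGE_SITES,
        }
        for site, cr, cc, kr, kc in _CHART_REVIEW
    ]
    return pd.DataFrame(rows)


def example_case_type_counts(site: str) -> dict[int, int]:
    """Case counts by type for one of the three large example sites."""
    try:
        return dict(_CASE_TYPES[site])
    except KeyError:
        raise KeyError(
            f"no case-type counts for {site!r}; available: {sorted(_CASE_TYPES)}"
        ) from None
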