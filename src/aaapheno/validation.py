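"""Blinded-review sampling and algorithm-performance statistics.

An ePhenotyping algorithm is judged by its positive predictive value (PPV)
against blinded expert chart review: equal numbers of predicted cases and
predicted controls are sampled at random, reviewed without knowledge of the
algorithm's call, and PPV = confirmed / reviewed is computed per stratum.
Because the review samples are small, uncertainty is reported as the exact
(Clopper–Pearson) binomial interval, obtained from beta quantiles; at 100%
observed PPV the interval still has an informative lower bound (e.g.
122/122 → 97.0%).  Multi-site results are pooled by summing counts per
stratum across sites — not by averaging site PPVs — so the pooled estimate
is the review-size-weighted one.

Sensitivity and NPV are not computable from this design (the review samples
only the algorithm's own predictions, so missed cases are never observed).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ReviewSample",
    "StratumEstimate",
    "PPVReport",
    "ppv",
    "clopper_pearson_ci",
    "wilson_ci",
    "binomial_ci",
    "pooled_ppv_report",
    "sample_for_review",
    "false_positive_breakdown",
    "JUDGMENTS",
]

JUDGMENTS = ("case", "control", "unsure")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Chart-review confusion counts for one site (per-stratum totals)."""

    site: str
    predicted_case_reviewed: int
    true_case_among_predicted_cases: int
    predicted_control_reviewed: int
    true_control_among_predicted_controls: int

    def __post_init__(self) -> None:
        for true, reviewed in (
            (self.true_case_among_predicted_cases, self.predicted_case_reviewed),
            (self.true_control_among_predicted_controls,
             self.predicted_control_reviewed),
        ):
            if not 0 <= true <= reviewed:
                raise ValueError(
                    f"{self.site}: confirmed count {true} outside [0, {reviewed}]"
                )


def ppv(true_positive: int, predicted_positive: int) -> float:
    """Positive predictive value in percent: 100 × TP / predicted positives."""
    if predicted_positive < 1:
        raise ValueError("PPV undefined: no predicted positives reviewed")
    if not 0 <= true_positive <= predicted_positive:
        raise ValueError(
            f"true_positive {true_positive} outside [0, {predicted_positive}]"
        )
    return 100.0 * true_positive / predicted_positive


def clopper_pearson_ci(successes: int, n: int,
                       alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta-quantile form).

    lower = Beta^{-1}(α/2; x, n−x+1) (0 when x = 0);
    upper = Beta^{-1}(1−α/2; x+1, n−x) (1 when x = n).
    """
    _check_binomial_args(successes, n, alpha)
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lo, hi


def wilson_ci(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval (offered as an alternative to the exact one)."""
    _check_binomial_args(successes, n, alpha)
    z = stats.norm.ppf(1 - alpha / 2)
    p = successes / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def binomial_ci(successes: int, n: int, alpha: float = 0.05,
                method: str = "clopper-pearson") -> tuple[float, float]:
    if method == "clopper-pearson":
        return clopper_pearson_ci(successes, n, alpha)
    if method == "wilson":
        return wilson_ci(successes, n, alpha)
    raise ValueError(f"unknown CI method {method!r}")


def _check_binomial_args(successes: int, n: int, alpha: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


# --------------------------------------------------------------------------
# pooled PPV report
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StratumEstimate:
    """PPV point estimate + CI for one stratum (cases or controls)."""

    reviewed: int
    confirmed: int
    ppv_pct: float
    ci_low_pct: float
    ci_high_pct: float

    def to_dict(self) -> dict[str, float]:
        return {
            "reviewed": self.reviewed,
            "confirmed": self.confirmed,
            "ppv_pct": round(self.ppv_pct, 1),
            "ci_low_pct": round(self.ci_low_pct, 1),
            "ci_high_pct": round(self.ci_high_pct, 1),
        }


@dataclasses.dataclass(frozen=True)
class PPVReport:
    """Per-site and pooled PPV estimates with exact CIs."""

    alpha: float
    method: str
    sites: tuple[str, ...]
    per_site: dict[str, dict[str, StratumEstimate]]
    pooled: dict[str, StratumEstimate]

    def to_dict(self) -> dict[str, object]:
        return {
            "alpha": self.alpha,
            "ci_method": self.method,
            "sites": list(self.sites),
            "per_site": {
                site: {k: v.to_dict() for k, v in strata.items()}
                for site, strata in self.per_site.items()
            },
            "pooled": {k: v.to_dict() for k, v in self.pooled.items()},
        }

    def to_text(self) -> str:
        """Human-readable table (one column pair per site, pooled last)."""
        lines = []
        header = f"{'':14s}" + "".join(
            f"{s[:16]:>18s}" for s in (*self.sites, "Pooled")
        )
        lines.append(header)
        cols = [*(self.per_site[s] for s in self.sites), self.pooled]
        for stratum, label in (("case", "Case PPV"), ("control", "Control PPV")):
            row = f"{label:14s}"
            for col in cols:
                e = col[stratum]
                row += f"{e.ppv_pct:7.1f} ({e.confirmed}/{e.reviewed})".rjust(18)
            lines.append(row)
            row = f"{'  95% CI':14s}" if self.alpha == 0.05 else f"{'  CI':14s}"
            for col in cols:
                e = col[stratum]
                row += f"{e.ci_low_pct:.1f}-{e.ci_high_pct:.1f}".rjust(18)
            lines.append(row)
        return "\n".join(lines)


def _estimate(confirmed: int, reviewed: int, alpha: float,
              method: str) -> StratumEstimate:
    lo, hi = binomial_ci(confirmed, reviewed, alpha, method)
    return StratumEstimate(
        reviewed=reviewed, confirmed=confirmed,
        ppv_pct=ppv(confirmed, reviewed),
        ci_low_pct=100 * lo, ci_high_pct=100 * hi,
    )


def pooled_ppv_report(
    site_counts: Sequence[ConfusionCounts],
    alpha: float = 0.05,
    sites: Iterable[str] | None = None,
    method: str = "clopper-pearson",
) -> PPVReport:
    """Per-site PPVs plus the pooled estimate (summed counts per stratum).

    ``sites`` subsets the input by site name (e.g. pooling only the network
    validation sites while a non-network site is reported separately).
    """
    if not site_counts:
        raise ValueError("site_counts is empty")
    if sites is not None:
        wanted = list(sites)
        available = [c.site for c in site_counts]
        missing = [s for s in wanted if s not in available]
        if missing:
            raise ValueError(f"unknown site(s): {missing}; available: {available}")
        site_counts = [c for c in site_counts if c.site in wanted]
    if not site_counts:
        raise ValueError("no sites left after subsetting")

    per_site = {}
    for c in site_counts:
        per_site[c.site] = {
            "case": _estimate(c.true_case_among_predicted_cases,
                              c.predicted_case_reviewed, alpha, method),
            "control": _estimate(c.true_control_among_predicted_controls,
                                 c.predicted_control_reviewed, alpha, method),
        }
    pooled = {
        "case": _estimate(
            sum(c.true_case_among_predicted_cases for c in site_counts),
            sum(c.predicted_case_reviewed for c in site_counts), alpha, method,
        ),
        "control": _estimate(
            sum(c.true_control_among_predicted_controls for c in site_counts),
            sum(c.predicted_control_reviewed for c in site_counts), alpha, method,
        ),
    }
    return PPVReport(
        alpha=alpha, method=method,
        sites=tuple(c.site for c in site_counts),
        per_site=per_site, pooled=pooled,
    )


# --------------------------------------------------------------------------
# review sampling
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ReviewSample:
    """A blinded chart-review sample: equal strata of predicted cases and
    controls, drawn without replacement, reproducible from the seed."""

    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    seed: int
    n_requested: int

    @property
    def capped(self) -> dict[str, bool]:
        return {
            "case": len(self.case_ids) < self.n_requested,
            "control": len(self.control_ids) < self.n_requested,
        }

    def blinded_frame(self) -> pd.DataFrame:
        """Subject ids only, shuffled so order does not leak the stratum."""
        ids = list(self.case_ids) + list(self.control_ids)
        rng = np.random.default_rng(self.seed + 1)
        rng.shuffle(ids)
        return pd.DataFrame({"subject_id": ids})

    def key_frame(self) -> pd.DataFrame:
        """The sealed key: subject id -> predicted label (not for reviewers)."""
        return pd.DataFrame(
            {
                "subject_id": list(self.case_ids) + list(self.control_ids),
                "predicted_label": ["case"] * len(self.case_ids)
                + ["control"] * len(self.control_ids),
            }
        )


def sample_for_review(results, n_per_stratum: int, seed: int) -> ReviewSample:
    """Draw the blinded validation sample from a classification output.

    ``results`` may be a list of ``ClassificationResult`` or a results frame
    with ``subject_id``/``label`` columns.  When a stratum holds fewer than
    ``n_per_stratum`` subjects the whole stratum is taken (with a logged
    warning), mirroring small-site practice.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in results],
                "label": [r.label.value for r in results],
            }
        )
    strata = {}
    for label in ("case", "control"):
        pool = sorted(frame.loc[frame["label"] == label, "subject_id"].astype(str))
        if not pool:
            raise ValueError(f"no predicted {label}s to sample from")
        strata[label] = pool
    rng = np.random.default_rng(seed)
    drawn = {}
    for label, pool in strata.items():
        k = min(n_per_stratum, len(pool))
        if k < n_per_stratum:
            logger.warning(
                "%s stratum capped at %d (requested %d)", label, k, n_per_stratum
            )
        drawn[label] = tuple(rng.choice(pool, size=k, replace=False))
    return ReviewSample(
        case_ids=drawn["case"], control_ids=drawn["control"],
        seed=seed, n_requested=n_per_stratum,
    )


# --------------------------------------------------------------------------
# false-positive breakdown
# --------------------------------------------------------------------------


def false_positive_breakdown(review_outcomes: pd.DataFrame,
                             results) -> pd.DataFrame:
    """False-positive counts per assigned case type per site.

    ``review_outcomes`` needs ``subject_id`` and ``reviewer_judgment``
    (∈ {case, control, unsure}) columns, plus an optional ``site`` column.
    A reviewed predicted case whose judgment is not "case" counts as a false
    positive.  Rows are case types 1–3 plus "All"; columns are sites plus
    "Total".
    """
    from .engine import results_to_frame

    if not isinstance(results, pd.DataFrame):
        results = results_to_frame(results)
    res = results.set_index(results["subject_id"].astype(str))

    outcomes = review_outcomes.copy()
    outcomes["subject_id"] = outcomes["subject_id"].astype(str)
    bad = sorted(set(outcomes["subject_id"]) - set(res.index))
    if bad:
        raise ValueError(
            f"review outcome(s) for unknown subject id(s): {bad[:5]}"
        )
    invalid = sorted(set(outcomes["reviewer_judgment"]) - set(JUDGMENTS))
    if invalid:
        raise ValueError(
            f"invalid reviewer judgment(s) {invalid}; expected one of {JUDGMENTS}"
        )
    if "site" not in outcomes.columns:
        outcomes["site"] = "all"

    joined = outcomes.join(res[["label", "case_type"]], on="subject_id")
    fp = joined[(joined["label"] == "case")
                & (joined["reviewer_judgment"] != "case")]

    sites = sorted(outcomes["site"].unique())
    table = pd.DataFrame(0, index=["1", "2", "3"], columns=sites, dtype=int)
    for _, row in fp.iterrows():
        table.loc[str(int(row["case_type"])), row["site"]] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["All"] = table.sum(axis=0)
    table.index.name = "case_type"
    return table
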