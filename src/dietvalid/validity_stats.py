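"""Paired-method comparison battery for relative-validity studies.

Two dietary assessment methods measured the same participants on the same
day.  Intake distributions are right-skewed, so location is compared with
the Wilcoxon signed rank test (normal approximation, zeros dropped, tied
absolute differences sharing average ranks, tie-corrected variance, no
continuity correction by default), being-a-consumer with the McNemar test on
discordant pairs, monotone association with tie-aware Spearman rank
correlation, and individual-level agreement with Bland–Altman 95% limits of
agreement (mean difference ± 1.96 × SD).

A difference in medians is *relevant* when it is statistically significant
at two-sided p < 0.05 AND exceeds 10% of the reference-method median.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intake_engine import DailyIntake
from .records_io import FoodRecordEntry, IdentificationMode, Participant

__all__ = [
    "wilcoxon_signed_rank",
    "mcnemar",
    "spearman_rho",
    "bland_altman",
    "BlandAltmanResult",
    "relevance_flag",
    "RelevanceFlag",
    "Direction",
    "compare_tables",
    "ValidityReport",
    "intakes_to_frame",
    "median_of_correlations",
    "recording_mode_tally",
    "ModeTally",
    "sus_score",
    "sus_summary",
    "SusSummary",
    "ALPHA",
    "RELEVANCE_THRESHOLD",
]

ALPHA = 0.05
RELEVANCE_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    differences: Sequence[float],
    zero_method: str = "wilcox",
    continuity: bool = False,
) -> float:
    """Two-sided signed-rank p-value from the normal approximation.

    ``zero_method="wilcox"`` drops zero differences before ranking (the
    classic convention); ``"pratt"`` ranks zeros with the rest and then drops
    them.  Tied absolute differences share average ranks and the variance is
    tie-corrected.  All-zero input yields p = 1 with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("wilcoxon_signed_rank requires >= 1 difference")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    if np.all(d == 0):
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0

    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: rank with zeros, then discard the zero ranks
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]

    n = d.size
    w_plus = float(ranks[d > 0].sum())
    if zero_method == "wilcox":
        mu = n * (n + 1) / 4.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    else:
        # Pratt: moments use the full rank set minus the zero block
        m = len(differences) - n  # number of zeros
        big_n = n + m
        mu = (big_n * (big_n + 1) - m * (m + 1)) / 4.0
        sigma2 = (
            big_n * (big_n + 1) * (2 * big_n + 1)
            - m * (m + 1) * (2 * m + 1)
        ) / 24.0
    # average-rank tie correction: group sizes of equal |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if sigma2 <= 0:
        warnings.warn("degenerate variance in signed-rank test; p = 1", stacklevel=2)
        return 1.0

    z = w_plus - mu
    if continuity:
        z -= 0.5 * np.sign(z)
    z /= np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def mcnemar(
    consumer_a: Sequence[bool],
    consumer_b: Sequence[bool],
    correction: bool = False,
    exact_threshold: int = 10,
) -> float:
    """McNemar p-value for paired consumer indicators.

    Uses the chi-squared statistic (b − c)² / (b + c) on the discordant pair
    counts, with an exact two-sided binomial fallback when b + c is below
    ``exact_threshold`` (the chi-squared approximation is unreliable there).
    ``correction=True`` applies the continuity correction (|b − c| − 1)².
    """
    a = np.asarray(consumer_a, dtype=bool)
    b = np.asarray(consumer_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n_ab = int(np.sum(a & ~b))  # discordant: consumer in A only
    n_ba = int(np.sum(~a & b))  # discordant: consumer in B only
    n_disc = n_ab + n_ba
    if n_disc == 0:
        warnings.warn("no discordant pairs; p = 1", stacklevel=2)
        return 1.0
    if n_disc < exact_threshold:
        p = 2.0 * sps.binom.cdf(min(n_ab, n_ba), n_disc, 0.5)
        return float(min(1.0, p))
    delta = abs(n_ab - n_ba)
    if correction:
        delta = max(0.0, delta - 1.0)
    chi2 = delta**2 / n_disc
    return float(sps.chi2.sf(chi2, df=1))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman correlation: Pearson correlation of average ranks.

    Returns NaN (with a warning) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho requires paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(
    x: Sequence[float], y: Sequence[float], z: float = 1.96
) -> BlandAltmanResult:
    """Mean difference (x − y) and 95% limits of agreement (mean ± 1.96 SD).

    SD uses the n − 1 denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("bland_altman requires paired vectors with n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - z * sd,
        loa_high=mean + z * sd,
        n=d.size,
    )


# ---------------------------------------------------------------------------
# Relevance rule
# ---------------------------------------------------------------------------

class Direction(str, enum.Enum):
    METHOD_A_LOWER = "method_a_lower"
    METHOD_A_HIGHER = "method_a_higher"
    NONE = "none"


@dataclass(frozen=True)
class RelevanceFlag:
    relevant: Optional[bool]  # None when the reference median is 0
    direction: Direction


def relevance_flag(
    median_a: float,
    median_b: float,
    p: float,
    alpha: float = ALPHA,
    threshold: float = RELEVANCE_THRESHOLD,
) -> RelevanceFlag:
    """Flag a relevant method difference.

    Relevant iff p < alpha AND |median_a − median_b| > threshold × median_b,
    with median_b the reference-method median.  When the reference median is
    zero the rule is not evaluable and ``relevant`` is None.  Direction is
    reported regardless of relevance.
    """
    diff = median_a - median_b
    if diff < 0:
        direction = Direction.METHOD_A_LOWER
    elif diff > 0:
        direction = Direction.METHOD_A_HIGHER
    else:
        direction = Direction.NONE
    if median_b == 0:
        return RelevanceFlag(relevant=None, direction=direction)
    relevant = (p < alpha) and (abs(diff) > threshold * abs(median_b))
    return RelevanceFlag(relevant=relevant, direction=direction)


def median_of_correlations(rhos: Sequence[float]) -> float:
    """Standard median of correlation coefficients (mean of the central pair
    for even n)."""
    arr = np.asarray(rhos, dtype=float)
    if arr.size == 0:
        raise ValueError("median_of_correlations requires >= 1 value")
    return float(np.median(arr))


# ---------------------------------------------------------------------------
# Table-shaped comparisons
# ---------------------------------------------------------------------------

def intakes_to_frame(
    dailies: Iterable[DailyIntake],
    group_vars: Sequence[str],
    nutrient_vars: Sequence[str] = (),
) -> pd.DataFrame:
    """Wide per-participant frame: one row per participant-day, one column
    per food group (g/d) and nutrient."""
    rows = {}
    for d in dailies:
        row = {g: d.grams_by_group.get(g, 0.0) for g in group_vars}
        row.update({n: d.nutrients.get(n, 0.0) for n in nutrient_vars})
        rows[d.participant_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "participant_id"
    return frame.sort_index()


@dataclass
class ValidityReport:
    """Main paired table, consumer table, and stratified variants."""

    paired: pd.DataFrame
    consumers: pd.DataFrame
    stratified: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)


def _paired_row(name: str, a: np.ndarray, b: np.ndarray) -> dict:
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if np.array_equal(a, b):
        # identical columns: no information for the signed-rank test
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_signed_rank(a - b) if np.any(a != b) else 1.0
    else:
        p = wilcoxon_signed_rank(a - b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearman_rho(a, b)
    flag = relevance_flag(med_a, med_b, p)
    return {
        "variable": name,
        "n": len(a),
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "median_a": med_a,
        "q1_a": float(np.percentile(a, 25)),
        "q3_a": float(np.percentile(a, 75)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "median_b": med_b,
        "q1_b": float(np.percentile(b, 25)),
        "q3_b": float(np.percentile(b, 75)),
        "wilcoxon_p": p,
        "spearman_rho": rho,
        "relevant": flag.relevant,
        "direction": flag.direction.value,
    }


def _consumer_row(name: str, a: np.ndarray, b: np.ndarray) -> dict:
    cons_a, cons_b = a > 0, b > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mc_p = mcnemar(cons_a, cons_b)
    both = cons_a & cons_b
    if both.sum() >= 1 and np.any(a[both] != b[both]):
        cons_w_p = wilcoxon_signed_rank(a[both] - b[both])
    else:
        cons_w_p = np.nan if both.sum() == 0 else 1.0
    return {
        "variable": name,
        "consumers_a": int(cons_a.sum()),
        "consumers_b": int(cons_b.sum()),
        "mcnemar_p": mc_p,
        "consumers_median_a": float(np.median(a[cons_a])) if cons_a.any() else np.nan,
        "consumers_median_b": float(np.median(b[cons_b])) if cons_b.any() else np.nan,
        "consumers_wilcoxon_p": cons_w_p,
    }


def _compare_frame(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    group_vars: Sequence[str],
    nutrient_vars: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    paired_rows = []
    consumer_rows = []
    for name in group_vars:
        a = frame_a[name].to_numpy(float)
        b = frame_b[name].to_numpy(float)
        consumer_rows.append(_consumer_row(name, a, b))
        # food groups whose 75th percentile is 0 under both methods stay out
        # of the main table but remain in the consumer table
        if np.percentile(a, 75) == 0 and np.percentile(b, 75) == 0:
            continue
        paired_rows.append(_paired_row(name, a, b))
    for name in nutrient_vars:
        a = frame_a[name].to_numpy(float)
        b = frame_b[name].to_numpy(float)
        paired_rows.append(_paired_row(name, a, b))
    return pd.DataFrame(paired_rows), pd.DataFrame(consumer_rows)


def compare_tables(
    intake_a: pd.DataFrame,
    intake_b: pd.DataFrame,
    group_vars: Sequence[str],
    nutrient_vars: Sequence[str] = (),
    participants: Optional[Sequence[Participant]] = None,
    strata: Sequence[str] = (),
) -> ValidityReport:
    """Build the main paired table, the consumer table and stratified variants.

    ``intake_a`` and ``intake_b`` are wide per-participant frames (see
    :func:`intakes_to_frame`) for the test and reference method; they must
    cover the same participants on the same day.  ``strata`` may contain
    ``"education"`` and/or ``"bmi"`` (3 classes each), which requires
    ``participants``.  Output is invariant to participant ordering; a stratum
    with fewer than 2 participants is suppressed with a warning.
    """
    if set(intake_a.index) != set(intake_b.index):
        raise ValueError("methods cover different participants")
    frame_a = intake_a.sort_index()
    frame_b = intake_b.sort_index()

    paired, consumers = _compare_frame(frame_a, frame_b, group_vars, nutrient_vars)
    report = ValidityReport(paired=paired, consumers=consumers)

    if strata:
        if participants is None:
            raise ValueError("stratified analysis requires participants")
        by_id = {p.participant_id: p for p in participants}
        classifiers = {
            "education": lambda p: p.education.value,
            "bmi": lambda p: p.bmi_class,
        }
        for stratum_var in strata:
            classify = classifiers[stratum_var]
            labels = pd.Series(
                {pid: classify(by_id[pid]) for pid in frame_a.index}
            )
            report.stratified[stratum_var] = {}
            for label in sorted(labels.unique()):
                ids = labels.index[labels == label]
                if len(ids) < 2:
                    warnings.warn(
                        f"stratum {stratum_var}={label} has n={len(ids)} < 2; "
                        "suppressed",
                        stacklevel=2,
                    )
                    continue
                sub_paired, _ = _compare_frame(
                    frame_a.loc[ids], frame_b.loc[ids], group_vars, nutrient_vars
                )
                report.stratified[stratum_var][label] = sub_paired
    return report


# ---------------------------------------------------------------------------
# Descriptive tallies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeTally:
    counts: Mapping[IdentificationMode, int]
    total: int

    def share(self, mode: IdentificationMode) -> float:
        return self.counts.get(mode, 0) / self.total

    @property
    def branded_share_excluding_previous(self) -> float:
        """(branded search + barcode scans) / (total − previously selected)."""
        branded = self.counts.get(
            IdentificationMode.BRANDED_SEARCH, 0
        ) + self.counts.get(IdentificationMode.BARCODE_SCAN, 0)
        denom = self.total - self.counts.get(
            IdentificationMode.PREVIOUSLY_SELECTED, 0
        )
        if denom == 0:
            return float("nan")
        return branded / denom


def recording_mode_tally(
    entries: Iterable[FoodRecordEntry] | Mapping[IdentificationMode, int],
) -> ModeTally:
    """Counts and shares per food-identification mode.

    Accepts either parsed entries or a precomputed mode → count mapping.
    """
    if isinstance(entries, Mapping):
        counts = {IdentificationMode(k): int(v) for k, v in entries.items()}
    else:
        counts = {}
        for e in entries:
            counts[e.identification_mode] = counts.get(e.identification_mode, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no entries to tally")
    return ModeTally(counts=counts, total=total)


# ---------------------------------------------------------------------------
# System Usability Scale
# ---------------------------------------------------------------------------

def sus_score(responses: Sequence[Optional[int]]) -> Optional[float]:
    """Standard 10-item usability score on the 0–100 scale.

    Odd-numbered (positively worded) items contribute response − 1 and
    even-numbered (negatively worded) items 5 − response; the sum is scaled
    by 2.5.  Returns None when any item is missing (such respondents are
    excluded from the total score but still counted in per-item means).
    """
    if len(responses) != 10:
        raise ValueError("exactly 10 responses required")
    total = 0
    for i, r in enumerate(responses, start=1):
        if r is None:
            return None
        if not 1 <= r <= 5:
            raise ValueError(f"item {i}: response {r} outside 1-5")
        total += (r - 1) if i % 2 == 1 else (5 - r)
    return total * 2.5


@dataclass(frozen=True)
class SusSummary:
    n_respondents: int
    n_complete: int
    mean_score: float
    sd_score: float
    item_means: tuple[float, ...]


def sus_summary(
    response_matrix: Sequence[Sequence[Optional[int]]],
) -> SusSummary:
    """Cohort usability summary: mean/SD of complete total scores plus
    per-item means over answered items."""
    scores = [s for s in (sus_score(r) for r in response_matrix) if s is not None]
    if not scores:
        raise ValueError("no complete questionnaires")
    item_means = []
    for i in range(10):
        vals = [r[i] for r in response_matrix if r[i] is not None]
        item_means.append(sum(vals) / len(vals))
    arr = np.asarray(scores, dtype=float)
    return SusSummary(
        n_respondents=len(response_matrix),
        n_complete=len(scores),
        mean_score=float(arr.mean()),
        sd_score=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        item_means=tuple(item_means),
    )
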