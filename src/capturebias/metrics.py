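"""Population-level disease metrics: fitness cost, relative risk, allele change.

Three quantities that field studies of host-parasite selection estimate:

1. the reproductive-success difference between uninfected and infected
   parents, raw (offspring units) and corrected (divided by the mean
   offspring count of uninfected parents, which removes pure detection
   thinning);
2. the relative risk of infection of the high-risk genotype class over
   the low-risk class;
3. the focal-allele frequency change from the parent to the offspring
   generation.

Each is computed either on the full population ("truth") or on the
distinct individuals detected in a capture-history set ("sampled").
Undefined values (empty classes, zero denominators) come back as NaN and
are flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import allele_frequency
from .sampling import CaptureHistory

__all__ = [
    "MetricSet",
    "offspring_counts",
    "reproductive_success_difference",
    "relative_risk",
    "allele_frequency_change",
    "compute_metric_set",
    "high_risk_mask",
]


@dataclass
class MetricSet:
    """The three outcome metrics for one variant of one run."""

    repro_diff_raw: float
    repro_diff_corrected: float
    relative_risk: float
    allele_freq_change: float
    variant: str  # full | control | increased | decreased


def offspring_counts(
    parents: pd.DataFrame,
    offspring: pd.DataFrame,
    detected_ids: np.ndarray | set | None = None,
) -> pd.Series:
    """Offspring count per parent, optionally restricted to detected offspring.

    Every offspring credits both of its parents (parent-level means, not
    pair-level).  ``detected_ids`` restricts the count to offspring
    captured in at least one bout; an offspring captured in several bouts
    still counts once.
    """
    off = offspring
    if len(off):
        parent_ids = set(parents["id"].to_numpy().tolist())
        links = set(off["mother_id"].tolist()) | set(off["father_id"].tolist())
        orphans = links - parent_ids
        if orphans:
            raise ValueError(f"offspring reference unknown parents: {sorted(orphans)[:5]}")
    if detected_ids is not None:
        keep = off["id"].isin(np.asarray(list(detected_ids)))
        off = off.loc[keep]
    counts = pd.Series(0, index=parents["id"].to_numpy(), dtype=np.int64)
    if len(off):
        tallies = pd.concat([off["mother_id"], off["father_id"]]).value_counts()
        counts.loc[tallies.index] += tallies.astype(np.int64)
    return counts


def reproductive_success_difference(
    counts: pd.Series, infected: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Mean-offspring difference, uninfected minus infected parents.

    Returns ``(raw, corrected)`` where ``corrected = raw / mean count of
    uninfected parents``.  NaN (flagged) when a class is empty or the
    uninfected mean is zero.
    """
    infected = np.asarray(infected, dtype=bool)
    vals = counts.to_numpy(dtype=float)
    if not infected.any() or infected.all():
        return float("nan"), float("nan")
    mean_unf = float(vals[~infected].mean())
    raw = mean_unf - float(vals[infected].mean())
    corrected = raw / mean_unf if mean_unf > 0 else float("nan")
    return raw, corrected


def high_risk_mask(geno: np.ndarray, scheme: str) -> np.ndarray:
    """Boolean mask of the high-risk genotype class under a scheme."""
    g = np.asarray(geno)
    if scheme == "heterozygote_advantage":
        return g != 1  # both homozygotes
    if scheme == "resistance_allele":
        return g == 0  # non-carriers
    raise ValueError(f"unknown scheme {scheme!r}")


def relative_risk(
    geno: np.ndarray, infected: np.ndarray, scheme: str
) -> float:
    """Proportion infected in the high-risk class over the low-risk class.

    NaN (flagged) when either class is empty or no low-risk individual is
    infected (zero denominator).
    """
    geno = np.asarray(geno)
    infected = np.asarray(infected, dtype=bool)
    high = high_risk_mask(geno, scheme)
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        return float("nan")
    prop_high = infected[high].mean()
    prop_low = infected[~high].mean()
    if prop_low == 0:
        return float("nan")
    return float(prop_high / prop_low)


def allele_frequency_change(parents: pd.DataFrame, offspring: pd.DataFrame) -> float:
    """Focal-allele frequency, offspring minus parents.

    NaN (flagged) when either generation is absent from the evaluated set.
    """
    if len(parents) == 0 or len(offspring) == 0:
        return float("nan")
    return allele_frequency(offspring) - allele_frequency(parents)


def compute_metric_set(
    parents: pd.DataFrame,
    offspring: pd.DataFrame,
    pooled: pd.DataFrame,
    scheme: str,
    variant: str,
    history: CaptureHistory | None = None,
    require_parent_detected: bool = False,
    parent_roster: set | None = None,
) -> MetricSet:
    """All three metrics for one variant.

    ``variant="full"`` (``history=None``) evaluates the truth on the
    complete population.  Sampled variants evaluate relative risk and
    allele-frequency change on the distinct individuals detected in at
    least one bout, and reproductive success on detected offspring counts
    (all parents enumerable unless ``require_parent_detected``).

    ``parent_roster`` fixes the set of parent ids admitted to the
    reproductive-success comparison; by default the variant's own
    detections are used.  In paired designs the roster from the unbiased
    reference sample is passed here for the biased variants, so that the
    roster's composition does not itself depend on the capture bias.
    """
    if history is None:
        counts = offspring_counts(parents, offspring)
        par_inf = parents["infected"]
        raw, corrected = reproductive_success_difference(counts, par_inf)
        rr = relative_risk(pooled["geno"].to_numpy(), pooled["infected"].to_numpy(), scheme)
        dfreq = allele_frequency_change(parents, offspring)
        return MetricSet(raw, corrected, rr, dfreq, variant)

    detected = set(history.detected_ids().tolist())
    counts = offspring_counts(parents, offspring, detected_ids=detected)
    par_inf = parents["infected"].to_numpy()
    if require_parent_detected:
        roster = detected if parent_roster is None else parent_roster
        seen = parents["id"].isin(list(roster)).to_numpy()
        raw, corrected = reproductive_success_difference(counts[seen], par_inf[seen])
    else:
        raw, corrected = reproductive_success_difference(counts, par_inf)

    seen_pool = pooled.loc[pooled["id"].isin(list(detected))]
    rr = relative_risk(
        seen_pool["geno"].to_numpy(), seen_pool["infected"].to_numpy(), scheme
    )
    dfreq = allele_frequency_change(
        seen_pool.loc[seen_pool["generation"] == "parent"],
        seen_pool.loc[seen_pool["generation"] == "offspring"],
    )
    return MetricSet(raw, corrected, rr, dfreq, variant)
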