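"""Robust-design capture histories with infection-dependent capture bias.

Each sampling bout captures exactly ``sample_size`` distinct individuals
from the pooled population.  The bias multiplier ``c`` is the ratio of
the per-capita capture rates of infected and uninfected hosts: the
infected share of the population is weighted by ``c`` and the class
composition of the bout renormalised, so the expected infected capture
count is ``round(sample_size * prevalence*c / (prevalence*c + 1 -
prevalence))``.  A bias of 1 reproduces simple uniform sampling, values
below 1 under-sample infected hosts (e.g. lethargic animals hiding) and
values above 1 over-sample them (e.g. infection-driven risk taking).
Bouts are independent — being captured once neither helps nor hinders
later capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .population import GENOTYPE_CODES, _CODE_TO_COUNT

__all__ = ["CaptureHistory", "draw_bout", "build_capture_histories",
           "write_histories", "read_histories"]

logger = logging.getLogger(__name__)


@dataclass
class CaptureHistory:
    """Detection matrix over bouts plus per-individual covariates.

    ``detections[i, t]`` is 1 iff individual ``i`` (row ``i`` of
    ``individuals``) was captured in bout ``t``.  Rows cover the whole
    population; never-detected individuals keep an all-zero row.
    """

    individuals: pd.DataFrame  # columns: id, geno, infected, generation
    detections: np.ndarray     # shape (n_individuals, n_bouts), int8
    bias_value: float

    @property
    def n_bouts(self) -> int:
        return self.detections.shape[1]

    def detected_any(self) -> np.ndarray:
        """Boolean mask of individuals captured in at least one bout."""
        return self.detections.any(axis=1)

    def detected_ids(self) -> np.ndarray:
        """Ids of the distinct individuals captured in at least one bout."""
        return self.individuals.loc[self.detected_any(), "id"].to_numpy()


def draw_bout(
    pop: pd.DataFrame,
    sample_size: int,
    bias_value: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One capture bout: ids of the ``sample_size`` captured individuals.

    The infected capture target ``k = round(sample_size * prevalence*bias
    / (prevalence*bias + 1 - prevalence))`` — the infected class weighted
    by the capture-rate ratio ``bias``, renormalised — is clamped to what
    either class can supply; any shortfall is back-filled from the other
    class so the bout total is exact.  Within each class individuals are
    drawn uniformly without replacement.
    """
    n_pop = len(pop)
    if sample_size > n_pop:
        raise ValueError(f"sample_size {sample_size} exceeds population {n_pop}")
    if bias_value <= 0:
        raise ValueError("bias_value must be positive")

    infected = pop["infected"].to_numpy()
    inf_ids = pop.loc[infected, "id"].to_numpy()
    unf_ids = pop.loc[~infected, "id"].to_numpy()
    prevalence = len(inf_ids) / n_pop

    weighted = prevalence * bias_value
    k = int(np.rint(sample_size * weighted / (weighted + 1.0 - prevalence)))
    k_clamped = min(k, sample_size, len(inf_ids))
    n_unf = sample_size - k_clamped
    if n_unf > len(unf_ids):
        # uninfected pool too small: take them all, back-fill infected
        n_unf = len(unf_ids)
        k_clamped = sample_size - n_unf
    if k_clamped != k:
        logger.warning(
            "infected capture target %d clamped to %d (attenuates realised bias %.3f)",
            k, k_clamped, bias_value,
        )

    take_inf = rng.choice(inf_ids, size=k_clamped, replace=False)
    take_unf = rng.choice(unf_ids, size=n_unf, replace=False)
    return np.concatenate([take_inf, take_unf])


def build_capture_histories(
    pop: pd.DataFrame,
    config: ScenarioConfig,
    bias_value: float,
    rng: np.random.Generator,
) -> CaptureHistory:
    """Run ``n_bouts`` independent bouts and assemble the detection matrix."""
    n = len(pop)
    id_to_row = pd.Series(np.arange(n), index=pop["id"].to_numpy())
    det = np.zeros((n, config.n_bouts), dtype=np.int8)
    for t in range(config.n_bouts):
        ids = draw_bout(pop, config.sample_size, bias_value, rng)
        det[id_to_row.loc[ids].to_numpy(), t] = 1
    cov = pop[["id", "geno", "infected", "generation"]].reset_index(drop=True)
    return CaptureHistory(individuals=cov, detections=det, bias_value=bias_value)


def write_histories(history: CaptureHistory, path: str | Path) -> None:
    """Export as delimited text: covariates then one 0/1 column per bout."""
    out = history.individuals.copy()
    out.insert(1, "genotype", out.pop("geno").map(GENOTYPE_CODES))
    out = out[["id", "generation", "genotype", "infected"]]
    for t in range(history.n_bouts):
        out[f"bout_{t + 1}"] = history.detections[:, t]
    out.to_csv(path, index=False)


def read_histories(path: str | Path, bias_value: float = 1.0) -> CaptureHistory:
    """Read the text format written by :func:`write_histories`.

    This is also the entry point of re-analysis mode: any table with one
    row per individual and 0/1 bout columns can be fed to the CJS fitter.
    """
    raw = pd.read_csv(path)
    bout_cols = [c for c in raw.columns if c.startswith("bout_")]
    fixed = ["id", "generation", "genotype", "infected"]
    if list(raw.columns[: len(fixed)]) != fixed or not bout_cols:
        raise ValueError(f"capture-history header mismatch: {list(raw.columns)}")
    det = raw[bout_cols].to_numpy(dtype=np.int8)
    if not np.isin(det, (0, 1)).all():
        raise ValueError("detection entries must be 0/1")
    cov = pd.DataFrame(
        {
            "id": raw["id"].astype(np.int64),
            "geno": raw["genotype"].map(_CODE_TO_COUNT).astype(np.int8),
            "infected": raw["infected"].astype(bool),
            "generation": raw["generation"],
        }
    )
    return CaptureHistory(individuals=cov, detections=det, bias_value=bias_value)
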