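"""Core individual-based simulation: founders, infection, reproduction.

Individuals live in a columnar :class:`pandas.DataFrame` (the
"population table") with columns

``id``         unique integer
``geno``       count of the focal allele ``a`` (0 = AA, 1 = Aa, 2 = aa);
               ``a`` is the resistance allele in the resistance-allele
               scheme
``infected``   bool
``generation`` ``"parent"`` or ``"offspring"``
``mother_id``  parent link, -1 for founders
``father_id``  parent link, -1 for founders

The life cycle of one run is: founders -> infection -> random monogamous
pairing -> Poisson reproduction with an infection penalty on each
infected parent's half of the pair's expected fecundity -> Mendelian
gamete transmission -> infection of the offspring pool -> pooling of both
generations for sampling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig, ConfigError

__all__ = [
    "GENOTYPE_CODES",
    "make_founders",
    "genotype_risk",
    "infection_probability",
    "apply_infection",
    "pair_parents",
    "offspring_lambda",
    "reproduce",
    "pool_generations",
    "allele_frequency",
    "write_population",
    "read_population",
]

#: Mapping between focal-allele counts and the conventional codes.
GENOTYPE_CODES = {0: "AA", 1: "Aa", 2: "aa"}
_CODE_TO_COUNT = {v: k for k, v in GENOTYPE_CODES.items()}

_COLUMNS = ["id", "geno", "infected", "generation", "mother_id", "father_id"]


def _empty_like() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": pd.Series(dtype=np.int64),
            "geno": pd.Series(dtype=np.int8),
            "infected": pd.Series(dtype=bool),
            "generation": pd.Series(dtype=object),
            "mother_id": pd.Series(dtype=np.int64),
            "father_id": pd.Series(dtype=np.int64),
        }
    )


def make_founders(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate the founder generation.

    Each founder's two alleles are independent fair Bernoulli draws, so
    the focal-allele count is Binomial(2, 0.5) and the expected genotype
    proportions are 0.25 / 0.50 / 0.25.  Founders start uninfected.
    """
    n = config.population_size
    geno = rng.binomial(2, 0.5, size=n).astype(np.int8)
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "geno": geno,
            "infected": np.zeros(n, dtype=bool),
            "generation": "parent",
            "mother_id": np.full(n, -1, dtype=np.int64),
            "father_id": np.full(n, -1, dtype=np.int64),
        }
    )


def genotype_risk(
    geno: np.ndarray | int,
    scheme: str,
    high_risk_prob: float,
    low_risk_prob: float,
) -> np.ndarray | float:
    """Genotype-determined infection risk.

    heterozygote_advantage
        heterozygotes (Aa) take the low risk, both homozygotes the high.
    resistance_allele
        any carrier of the focal allele ``a`` (Aa or aa) takes the low
        risk, non-carriers (AA) the high.
    """
    g = np.asarray(geno)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype codes must be allele counts in {0, 1, 2}")
    if scheme == "heterozygote_advantage":
        low = g == 1
    elif scheme == "resistance_allele":
        low = g >= 1
    else:
        raise ConfigError(f"unknown scheme {scheme!r}")
    out = np.where(low, low_risk_prob, high_risk_prob)
    return float(out) if np.isscalar(geno) else out


def infection_probability(
    g_risk: np.ndarray | float,
    w: float,
    r_i: np.ndarray | float,
) -> np.ndarray | float:
    """Per-individual infection probability.

    ``clamp(w * g_risk + (1 - w) * r_i, 0, 1)``: the genotype risk
    weighted by the genotype prediction value ``w``, plus the individual
    random risk component weighted by its complement, truncated to [0, 1].
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"genotype prediction value w={w} outside [0, 1]")
    p = np.clip(w * np.asarray(g_risk, dtype=float) + (1.0 - w) * np.asarray(r_i, dtype=float), 0.0, 1.0)
    return float(p) if np.isscalar(g_risk) and np.isscalar(r_i) else p


def apply_infection(
    pop: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign infection states by independent Bernoulli trials.

    Each individual receives a fresh random risk component
    ``r_i ~ Normal(noise_mean, noise_sd)`` and is infected with
    probability :func:`infection_probability`.  Genotypes are unchanged.
    """
    if len(pop) == 0:
        raise ValueError("population is empty")
    g_risk = genotype_risk(
        pop["geno"].to_numpy(), config.scheme, config.high_risk_prob, config.low_risk_prob
    )
    r = rng.normal(config.noise_mean, config.noise_sd, size=len(pop))
    p = infection_probability(g_risk, config.genotype_prediction_value, r)
    out = pop.copy()
    out["infected"] = rng.random(len(pop)) < p
    return out


def pair_parents(pop: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random perfect matching of the parents.

    Every parent appears in exactly one pair (monogamy; all founders
    breed once), giving ``len(pop) / 2`` breeding pairs.  Returns an
    (n_pairs, 2) array of ids.
    """
    ids = pop["id"].to_numpy()
    if len(ids) % 2:
        raise ValueError("cannot pair an odd number of parents")
    perm = rng.permutation(ids)
    return perm.reshape(-1, 2)


def _round_half_up(x: float) -> float:
    return float(np.floor(x + 0.5))


def offspring_lambda(
    infected_a: bool,
    infected_b: bool,
    base_lambda: float,
    penalty: float,
    rounding: str = "half_up",
) -> float:
    """Expected Poisson offspring for one breeding pair.

    Neither parent infected: ``base_lambda``.  Exactly one infected: the
    uninfected parent's half is kept and the infected half is multiplied
    by the penalty and rounded (``base_lambda/2 + round(penalty *
    base_lambda/2)``).  Both infected: ``penalty * base_lambda``
    (unrounded; the Poisson rate need not be an integer).
    """
    if not 0.0 <= penalty <= 1.0:
        raise ValueError(f"infection penalty {penalty} outside [0, 1]")
    half = base_lambda / 2.0
    rounder = _round_half_up if rounding == "half_up" else lambda v: float(np.round(v))
    if infected_a and infected_b:
        return penalty * base_lambda
    if infected_a or infected_b:
        return half + rounder(penalty * half)
    return base_lambda


def reproduce(
    pop: pd.DataFrame,
    pairs: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the offspring generation from breeding pairs.

    Per pair, the offspring count is Poisson with rate
    :func:`offspring_lambda` evaluated on the parents' infection states.
    Each offspring draws one uniformly chosen allele from each parent,
    independently per offspring (Mendelian transmission).  Offspring are
    returned uninfected; infect them afterwards with
    :func:`apply_infection`.
    """
    pairs = np.asarray(pairs)
    idx = pop.set_index("id")
    inf = idx["infected"]
    geno = idx["geno"]
    inf_a = inf.loc[pairs[:, 0]].to_numpy()
    inf_b = inf.loc[pairs[:, 1]].to_numpy()
    penalty = config.effective_penalty

    # vectorised offspring_lambda over the three infection configurations
    half = config.base_lambda / 2.0
    scaled = penalty * half
    rounded = _round_half_up(scaled) if config.rounding == "half_up" else float(np.round(scaled))
    n_inf = inf_a.astype(int) + inf_b.astype(int)
    lam = np.select(
        [n_inf == 0, n_inf == 1],
        [config.base_lambda, half + rounded],
        default=penalty * config.base_lambda,
    )

    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return _empty_like()

    mother = np.repeat(pairs[:, 0], counts)
    father = np.repeat(pairs[:, 1], counts)
    geno_m = geno.loc[mother].to_numpy()
    geno_f = geno.loc[father].to_numpy()
    # a gamete carries the focal allele with probability geno/2
    allele_m = rng.random(total) < geno_m / 2.0
    allele_f = rng.random(total) < geno_f / 2.0
    child_geno = (allele_m.astype(np.int8) + allele_f.astype(np.int8))

    start = int(pop["id"].max()) + 1
    return pd.DataFrame(
        {
            "id": np.arange(start, start + total, dtype=np.int64),
            "geno": child_geno,
            "infected": np.zeros(total, dtype=bool),
            "generation": "offspring",
            "mother_id": mother.astype(np.int64),
            "father_id": father.astype(np.int64),
        }
    )


def pool_generations(parents: pd.DataFrame, offspring: pd.DataFrame) -> pd.DataFrame:
    """Concatenate both generations into the full sampled population."""
    if len(offspring) == 0:
        return parents.reset_index(drop=True)
    return pd.concat([parents, offspring], ignore_index=True)


def allele_frequency(pop: pd.DataFrame) -> float:
    """Frequency of the focal allele ``a`` in a population table."""
    if len(pop) == 0:
        raise ValueError("cannot compute an allele frequency on an empty set")
    return float(pop["geno"].sum() / (2 * len(pop)))


def write_population(pop: pd.DataFrame, path: str | Path) -> None:
    """Dump a population table as delimited text with genotype codes."""
    out = pop.copy()
    out["genotype"] = out["geno"].map(GENOTYPE_CODES)
    out[["id", "genotype", "infected", "generation", "mother_id", "father_id"]].to_csv(
        path, index=False
    )


def read_population(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_population`."""
    raw = pd.read_csv(path)
    expected = ["id", "genotype", "infected", "generation", "mother_id", "father_id"]
    if list(raw.columns) != expected:
        raise ValueError(f"population file header mismatch: {list(raw.columns)}")
    bad = set(raw["genotype"]) - set(_CODE_TO_COUNT)
    if bad:
        raise ValueError(f"unknown genotype codes: {sorted(bad)}")
    return pd.DataFrame(
        {
            "id": raw["id"].astype(np.int64),
            "geno": raw["genotype"].map(_CODE_TO_COUNT).astype(np.int8),
            "infected": raw["infected"].astype(bool),
            "generation": raw["generation"],
            "mother_id": raw["mother_id"].astype(np.int64),
            "father_id": raw["father_id"].astype(np.int64),
        }
    )
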