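"""Incidence-based species richness: matrices, estimators, accumulation curves.

Sampling units are publications (or individual records); a species' incidence
frequency m_i is the number of units that cite it.  Uniques (Q1) and
duplicates (Q2) — species in exactly one / two units — drive the Chao2
estimator; the bootstrap estimator uses the full incidence-frequency vector.
The exact (Mao Tau) accumulation curve gives the expected species count at
every sub-effort k without resampling.

Also here: the Hawksworth extrapolation, which converts a region's vascular
plant richness P into an expected fungal richness E = R * P (working ratio
R = 6 fungal species per plant species) and expresses the known species
count as a percentage of E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .checklist import Checklist
from .errors import EmptySelectionError, InsufficientSamplesError, MycocheckError
from .util import round_half_up


@dataclass
class IncidenceMatrix:
    """Species x sampling-unit presence structure.

    ``presence[i, j]`` is True when species i occurs in sampling unit j.
    """

    species_ids: list[str]
    sample_ids: list[str]
    presence: np.ndarray  # bool, shape (S, m)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValueError("presence shape does not match labels")

    @property
    def m(self) -> int:
        """Number of sampling units."""
        return self.presence.shape[1]

    @property
    def incidence_freq(self) -> np.ndarray:
        """m_i: per-species number of units containing the species."""
        return self.presence.sum(axis=1)

    @property
    def S_obs(self) -> int:
        return int((self.incidence_freq >= 1).sum())

    @property
    def Q1(self) -> int:
        """Uniques: species found in exactly one sampling unit."""
        return int((self.incidence_freq == 1).sum())

    @property
    def Q2(self) -> int:
        """Duplicates: species found in exactly two sampling units."""
        return int((self.incidence_freq == 2).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int),
                            index=self.species_ids, columns=self.sample_ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    def write_triplets(self, path: str | Path) -> None:
        """Sparse export: one (species, sample) row per presence."""
        ii, jj = np.nonzero(self.presence)
        pd.DataFrame({
            "species": [self.species_ids[i] for i in ii],
            "sample": [self.sample_ids[j] for j in jj],
        }).to_csv(path, index=False)


def build_incidence(
    cl: Checklist,
    sample_unit: str = "publication",
    scope: Iterable[str] | None = None,
) -> IncidenceMatrix:
    """Build a presence matrix from a checklist.

    ``sample_unit="publication"`` makes one column per distinct publication;
    ``"record"`` makes one column per record row (each column then contains
    exactly one species).  ``scope`` restricts to a country subset (default:
    every country configured for the checklist).
    """
    if sample_unit not in ("publication", "record"):
        raise ValueError(f"unknown sample_unit {sample_unit!r}")
    records = cl.records
    if scope is not None:
        scope = set(scope)
        records = [r for r in records if r.country in scope]
    if not records:
        raise EmptySelectionError(f"no records in scope {sorted(scope or [])}")

    species = sorted({r.species_name for r in records})
    s_index = {s: i for i, s in enumerate(species)}
    if sample_unit == "publication":
        samples = sorted({r.publication_id for r in records})
        p_index = {p: j for j, p in enumerate(samples)}
        presence = np.zeros((len(species), len(samples)), dtype=bool)
        for r in records:
            presence[s_index[r.species_name], p_index[r.publication_id]] = True
    else:
        samples = [f"record_{k}" for k in range(len(records))]
        presence = np.zeros((len(species), len(records)), dtype=bool)
        for k, r in enumerate(records):
            presence[s_index[r.species_name], k] = True
    return IncidenceMatrix(species, list(samples), presence)


@dataclass
class RichnessEstimate:
    """A nonparametric richness estimate with its standard error."""

    estimator: str  # {"chao2", "bootstrap"}
    value: float
    se: float
    S_obs: int
    m: int
    variant: str = "classic"

    def display(self) -> str:
        """Table-style "estimate ± se" with integer rounding."""
        return f"{round_half_up(self.value, 0):.0f} ± {round_half_up(self.se, 0):.0f}"


def chao2(im: IncidenceMatrix) -> RichnessEstimate:
    """Chao2 incidence-based richness estimate with analytic standard error.

    With A = (m-1)/m and Q1, Q2 the uniques/duplicates counts:

    * Q2 > 0 (classic): S = S_obs + A * Q1^2 / (2 Q2), with
      var = Q2 * (A^2 r^4 / 4 + A^2 r^3 + A r^2 / 2), r = Q1/Q2.
    * Q2 = 0 (bias-corrected): S = S_obs + A * Q1 (Q1 - 1) / 2, with
      var = A Q1(Q1-1)/2 + A^2 Q1 (2 Q1 - 1)^2 / 4 - A^2 Q1^4 / (4 S).

    The estimate never falls below S_obs; Q1 = 0 returns S_obs with se 0.
    """
    if im.m < 2:
        raise InsufficientSamplesError(f"chao2 needs m >= 2 sampling units, got {im.m}")
    m, s_obs, q1, q2 = im.m, im.S_obs, im.Q1, im.Q2
    a = (m - 1) / m
    if q1 == 0:
        return RichnessEstimate("chao2", float(s_obs), 0.0, s_obs, m, "classic")
    if q2 > 0:
        value = s_obs + a * q1 * q1 / (2 * q2)
        r = q1 / q2
        var = q2 * (a * a * r**4 / 4 + a * a * r**3 + a * r * r / 2)
        variant = "classic"
    else:
        value = s_obs + a * q1 * (q1 - 1) / 2
        var = (a * q1 * (q1 - 1) / 2
               + a * a * q1 * (2 * q1 - 1) ** 2 / 4
               - a * a * q1**4 / (4 * value))
        variant = "bias-corrected"
    return RichnessEstimate("chao2", float(value), float(np.sqrt(max(var, 0.0))),
                            s_obs, m, variant)


def _bootstrap_value(presence: np.ndarray) -> float:
    """S_obs + sum_i (1 - p_i)^m over species present in the matrix."""
    m = presence.shape[1]
    freq = presence.sum(axis=1)
    freq = freq[freq > 0]
    p = freq / m
    return float(len(freq) + ((1.0 - p) ** m).sum())


def bootstrap_richness(
    im: IncidenceMatrix, n_boot: int = 1000, seed: int | None = None
) -> RichnessEstimate:
    """Smith–van Belle bootstrap richness estimate.

    Point value S_obs + sum_i (1 - m_i/m)^m.  The standard error is the SD of
    the re-estimates over ``n_boot`` resamples of the sampling units (columns)
    with replacement, seeded for reproducibility.
    """
    if im.m < 2:
        raise InsufficientSamplesError(
            f"bootstrap needs m >= 2 sampling units, got {im.m}")
    value = _bootstrap_value(im.presence)
    rng = np.random.default_rng(seed)
    m = im.m
    reps = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.integers(0, m, size=m)
        reps[b] = _bootstrap_value(im.presence[:, cols])
    return RichnessEstimate("bootstrap", value, float(reps.std(ddof=1)),
                            im.S_obs, m, "resampled-se")


@dataclass
class AccumulationCurve:
    """Expected species count as sampling effort grows from 1 to m units."""

    k: np.ndarray
    expected_S: np.ndarray
    sd: np.ndarray
    method: str  # {"exact", "random"}
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "expected_S": self.expected_S, "sd": self.sd})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def accumulation_curve(
    im: IncidenceMatrix,
    method: str = "exact",
    n_perm: int = 100,
    seed: int | None = None,
) -> AccumulationCurve:
    """Sample-based species accumulation curve.

    ``exact`` (Mao Tau) evaluates, for each k in 1..m,

        E[S(k)] = S_obs - sum_i C(m - m_i, k) / C(m, k)

    via log-gamma (stable at m in the tens of thousands of record-columns);
    its sd column is 0.  ``random`` averages distinct-species counts over
    ``n_perm`` seeded random orderings of the sampling units and reports the
    per-k mean and SD.  Both end at S_obs exactly at k = m.
    """
    m = im.m
    if m < 1:
        raise InsufficientSamplesError("need at least one sampling unit")
    ks = np.arange(1, m + 1)
    freq = im.incidence_freq
    freq = freq[freq > 0]
    s_obs = len(freq)
    if method == "exact":
        # term(i, k) = C(m - m_i, k) / C(m, k); zero once k > m - m_i
        rem = (m - freq)[:, None].astype(float)  # (S, 1)
        kk = ks[None, :].astype(float)
        with np.errstate(invalid="ignore"):
            logterm = _log_choose(rem, kk) - _log_choose(float(m), kk)
        term = np.where(kk <= rem, np.exp(logterm), 0.0)
        expected = s_obs - term.sum(axis=0)
        # monotone guard against last-digit float noise
        expected = np.maximum.accumulate(expected)
        expected[-1] = s_obs
        return AccumulationCurve(ks, expected, np.zeros(m), "exact")
    if method == "random":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        counts = np.empty((n_perm, m))
        for p in range(n_perm):
            order = rng.permutation(m)
            seen = np.cumsum(im.presence[:, order], axis=1) > 0
            counts[p] = seen.sum(axis=0)
        sd = counts.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(m)
        return AccumulationCurve(ks, counts.mean(axis=0), sd, "random", n_perm, seed)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class HawksworthEstimate:
    """Plant-ratio extrapolation of expected fungal richness for an area.

    E = R * P expected fungal species from P vascular plant species at ratio
    R (default 6:1); pct_known = 100 * S_obs / E.  A known richness above E
    is flagged rather than rejected — the ratio is a working hypothesis.
    """

    P: int
    R: float
    S_obs: int
    E: float = field(init=False)
    pct_known: float = field(init=False)
    exceeds_expectation: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError(f"plant richness P must be positive, got {self.P}")
        if self.R <= 0 or self.S_obs < 0:
            raise ValueError("require R > 0 and S_obs >= 0")
        self.E = self.R * self.P
        if float(self.R).is_integer():
            self.E = int(round(self.E))
        self.pct_known = 100.0 * self.S_obs / self.E
        self.exceeds_expectation = self.S_obs > self.E

    @property
    def pct_known_display(self) -> float:
        """Half-up 1-decimal rounding, as printed in summary tables."""
        return round_half_up(self.pct_known, 1)


def hawksworth_estimate(S_obs: int, P: int, R: float = 6.0) -> HawksworthEstimate:
    """Expected fungal richness from plant richness via the Hawksworth ratio."""
    return HawksworthEstimate(P=P, R=R, S_obs=S_obs)


def hawksworth_table(df: pd.DataFrame, R: float = 6.0) -> pd.DataFrame:
    """Apply the ratio extrapolation to a per-area summary table.

    ``df`` needs columns ``area``, ``plant_species``, ``fungal_species``;
    returns the table with ``hawksworth_E`` and ``pct_known`` columns added.
    """
    required = {"area", "plant_species", "fungal_species"}
    if not required.issubset(df.columns):
        raise MycocheckError(f"summary table needs columns {sorted(required)}")
    out = df.copy()
    ests = [hawksworth_estimate(int(s), int(p), R)
            for s, p in zip(df["fungal_species"], df["plant_species"])]
    out["hawksworth_E"] = [e.E for e in ests]
    out["pct_known"] = [e.pct_known_display for e in ests]
    return out
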