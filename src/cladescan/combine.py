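"""Combining the independent sub-test p-values.

The three sub-tests (single-marker, clade distillation, quadratic form) emit
mutually independent p-values under the null, so any combiner of independent
p-values applies. Plain Fisher combination treats every subset of non-null
alternatives as equally interesting; here the interesting alternatives are
only those in which the single-marker signal is non-null (the locus' core
marker should tag a causal allele), so the combined statistic is the minimum
over the SMT-anchored subset family

    S = min( G_1(F(p_smt)), G_2(F(p_smt, p_sd)),
             G_2(F(p_smt, p_q)), G_3(F(p_smt, p_sd, p_q)) )

where ``F`` is the Fisher statistic (sum of -log p) and ``G_p`` the survival
function of its Gamma(p, 1) null — i.e. the minimum of the four subset
Fisher p-values, the reading under which all four terms are commensurate.
``S`` is not itself a p-value; its null distribution is precalculated by
simulation, with a monotone spline for the body and a fitted exponential
right tail for ``-log S`` beyond a quantile threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import gammaincc

__all__ = ["fisher", "min_subset_statistic", "SubsetFisherNull", "build_subset_null", "combine_pvalues"]


def fisher(p_vec: np.ndarray) -> tuple[float, float]:
    """Fisher combination: ``F = sum -log p`` and its Gamma(p, 1) survival p-value.

    Zero p-values are clamped at the smallest positive normal double with a
    warning (a literal zero upstream is a bug, not evidence).
    """
    p = np.atleast_1d(np.asarray(p_vec, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-value clamped at machine tiny")
        p = np.maximum(p, np.finfo(float).tiny)
    F = float(-np.log(p).sum())
    return F, float(gammaincc(p.size, F))


def _subset_pvalues(
    p_smt: np.ndarray, p_sd: np.ndarray | None, p_q: np.ndarray | None
) -> np.ndarray:
    """Stacked Fisher p-values of the SMT-anchored subsets (vectorized).

    Rows: the available subsets in the fixed order {SMT}, {SMT,SD},
    {SMT,Q}, {SMT,SD,Q} (rows for missing sub-tests dropped).
    """
    l_smt = -np.log(np.maximum(p_smt, np.finfo(float).tiny))
    rows = [np.exp(-l_smt)]  # G_1(F) = exp(-F)
    if p_sd is not None:
        F = l_smt - np.log(np.maximum(p_sd, np.finfo(float).tiny))
        rows.append((1.0 + F) * np.exp(-F))  # G_2
    if p_q is not None:
        F = l_smt - np.log(np.maximum(p_q, np.finfo(float).tiny))
        rows.append((1.0 + F) * np.exp(-F))
    if p_sd is not None and p_q is not None:
        F = (
            l_smt
            - np.log(np.maximum(p_sd, np.finfo(float).tiny))
            - np.log(np.maximum(p_q, np.finfo(float).tiny))
        )
        rows.append((1.0 + F + 0.5 * F**2) * np.exp(-F))  # G_3
    return np.vstack(rows)


def min_subset_statistic(
    p_smt: np.ndarray | float,
    p_sd: np.ndarray | float | None = None,
    p_q: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Minimum over the SMT-anchored subset Fisher p-values."""
    scalar = np.ndim(p_smt) == 0
    p_smt_a = np.atleast_1d(np.asarray(p_smt, dtype=float))
    sd = None if p_sd is None else np.atleast_1d(np.asarray(p_sd, dtype=float))
    q = None if p_q is None else np.atleast_1d(np.asarray(p_q, dtype=float))
    S = _subset_pvalues(p_smt_a, sd, q).min(axis=0)
    return float(S[0]) if scalar else S


@dataclass
class SubsetFisherNull:
    """Simulated null distribution of the min-subset statistic.

    Stores the survival function of ``W = -log S`` under independent uniform
    inputs: a monotone cubic (PCHIP) spline of ``log SF(W)`` over quantile
    knots for the body, and a maximum-likelihood exponential tail for
    exceedances above the ``tail_q`` empirical quantile. ``family`` records
    which sub-tests were present (has_sd, has_q).
    """

    family: tuple[bool, bool]
    sims: int
    seed: int
    knots_w: np.ndarray
    knots_logsf: np.ndarray
    tail_w0: float
    tail_rate: float
    tail_sf0: float

    def __post_init__(self):
        self._spline = PchipInterpolator(self.knots_w, self.knots_logsf)

    def pvalue(self, S: np.ndarray | float) -> np.ndarray | float:
        """Null probability of a min-subset statistic at most ``S``."""
        scalar = np.ndim(S) == 0
        s = np.atleast_1d(np.asarray(S, dtype=float))
        w = -np.log(np.maximum(s, np.finfo(float).tiny))
        out = np.empty_like(w)
        body = w <= self.tail_w0
        wb = np.clip(w[body], self.knots_w[0], self.tail_w0)
        out[body] = np.exp(self._spline(wb))
        out[~body] = self.tail_sf0 * np.exp(-self.tail_rate * (w[~body] - self.tail_w0))
        out[w <= self.knots_w[0]] = 1.0
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": list(self.family),
                "sims": self.sims,
                "seed": self.seed,
                "knots_w": self.knots_w.tolist(),
                "knots_logsf": self.knots_logsf.tolist(),
                "tail_w0": self.tail_w0,
                "tail_rate": self.tail_rate,
                "tail_sf0": self.tail_sf0,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SubsetFisherNull":
        o = json.loads(text)
        return cls(
            tuple(o["family"]),
            o["sims"],
            o["seed"],
            np.asarray(o["knots_w"]),
            np.asarray(o["knots_logsf"]),
            o["tail_w0"],
            o["tail_rate"],
            o["tail_sf0"],
        )


def build_subset_null(
    sims: int = 10_000_000,
    seed: int = 0,
    *,
    family: tuple[bool, bool] = (True, True),
    n_knots: int = 2048,
    tail_q: float = 0.999,
) -> SubsetFisherNull:
    """Simulate the null table of the min-subset statistic.

    Draws ``sims`` i.i.d. uniform sub-test p-value tuples, computes the
    statistic, and summarizes ``W = -log S``: PCHIP spline of ``log SF`` on
    quantile knots for the body, exponential MLE on exceedances above the
    ``tail_q`` quantile for the tail. Deterministic given ``seed``.
    """
    if sims < 100_000:
        raise ValueError("need at least 1e5 simulations")
    rng = np.random.default_rng(seed)
    has_sd, has_q = family
    chunk = 2_000_000
    ws = []
    done = 0
    while done < sims:
        m = min(chunk, sims - done)
        p_smt = rng.random(m)
        p_sd = rng.random(m) if has_sd else None
        p_q = rng.random(m) if has_q else None
        S = _subset_pvalues(p_smt, p_sd, p_q).min(axis=0)
        ws.append(-np.log(np.maximum(S, np.finfo(float).tiny)))
        done += m
    w = np.sort(np.concatenate(ws))
    n = w.size
    w0 = float(np.quantile(w, tail_q))
    exceed = w[w > w0] - w0
    rate = 1.0 / float(exceed.mean())
    sf0 = exceed.size / n
    # body knots: evenly spaced quantiles up to the tail threshold
    qs = np.linspace(0.0, tail_q, n_knots)
    knots_w = np.quantile(w, qs)
    knots_sf = 1.0 - qs
    knots_sf[-1] = sf0  # splice body and tail exactly at the threshold
    knots_w, idx = np.unique(knots_w, return_index=True)
    knots_logsf = np.log(np.maximum(knots_sf[idx], 1.0 / n))
    knots_logsf = np.minimum.accumulate(knots_logsf)  # enforce monotone SF
    return SubsetFisherNull(
        family=family,
        sims=sims,
        seed=seed,
        knots_w=knots_w,
        knots_logsf=knots_logsf,
        tail_w0=float(knots_w[-1]),
        tail_rate=rate,
        tail_sf0=float(np.exp(knots_logsf[-1])),
    )


def combine_pvalues(
    p_smt: np.ndarray | float,
    p_sd: np.ndarray | float | None,
    p_q: np.ndarray | float | None,
    null: SubsetFisherNull | None,
) -> np.ndarray | float:
    """Combined p-value ``p_C`` of the SMT-anchored min-subset statistic.

    Missing sub-tests (e.g. no sprigs at the locus) restrict the subset
    family; the supplied null table must have been built for the matching
    family. With only the single-marker test present the statistic *is*
    ``p_smt`` and no table is needed.
    """
    family = (p_sd is not None, p_q is not None)
    if family == (False, False):
        return p_smt
    if null is None:
        raise ValueError("a simulated null table is required for this family")
    if null.family != family:
        raise ValueError(f"null table family {null.family} != required {family}")
    return null.pvalue(min_subset_statistic(p_smt, p_sd, p_q))
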