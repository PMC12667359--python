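"""Synthetic haplotype panels and phenotypes with calibrated signal strength.

The panel generator emulates a sequenced cohort: founder haplotypes drawn
from (optionally stratified) allele-frequency pools, descendant haplotypes
built as recombination mosaics of the founders, and Poisson-placed mutations
private to each haplotype. A "planted" clade copies one template segment
into a chosen subset of haplotypes and gives them a private derived allele
at a focal variant — ground truth for sprig-recovery tests. The
founder-pool stratification is a stand-in for explicit multi-population
demography: it produces realistic block-sharing and rare-variant structure,
not a calibrated population-genetic model.

The phenotype generator plants a *total association signal strength* ``s``:
the -log10 p-value that an oracle ANOVA targeting exactly the causal
variants would obtain. Writing ``X_A`` for the causal genotype columns,
``X~_A = P_A^perp X_A`` with length-normalized columns and ``QR = X~_A``,
the oracle's sufficient statistic is ``||Q'Y||^2`` with expectation
``||R beta||^2``; solving ``R beta = sqrt(q_chi2 / |A|) 1`` with ``q_chi2``
the ``1 - 10^-s`` chi-square quantile on ``|A|`` df splits the observed
signal evenly across causal variants, and simulating

    Y = A alpha + X~_A beta + P_{X_A}^perp eps,    eps ~ N(0, I)

pins ``||Q'Y||^2 = q_chi2`` in *every* replicate, so the oracle -log10 p
equals ``s`` exactly — power curves can then be indexed by ``s`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import HaplotypePanel

__all__ = [
    "PlantedClade",
    "PhenotypeSpec",
    "InfeasibleSpec",
    "simulate_panel",
    "select_causal_variants",
    "simulate_phenotype",
    "oracle_anova_neglog10",
    "rank_match",
]


class InfeasibleSpec(ValueError):
    """The panel cannot satisfy the requested spec; reject and resample."""


@dataclass
class PlantedClade:
    """A haplotype subset sharing one identical segment and a private allele.

    ``haplotypes`` lists the member haplotype indices; they are overwritten
    with a common template over ``span`` (variant index window, inclusive)
    and given derived allele 1 at ``focal`` while all others carry 0 there.
    """

    haplotypes: tuple[int, ...]
    focal: int
    span: tuple[int, int]


@dataclass
class PhenotypeSpec:
    """Design of one simulated phenotype draw.

    ``s``: total association signal strength (oracle ANOVA -log10 p).
    ``n_causal``: causal variants drawn in ``causal_window`` subject to
    ``count_class`` — "any", "doubleton" (derived count exactly 2) or an
    inclusive-exclusive count interval like ``(150, 750)``. Explicit
    ``causal_variants`` bypass selection. ``observed`` records whether the
    causal columns are meant to stay in the analysis panel (the generator
    returns their indices either way; hiding is the caller's slicing).
    """

    s: float
    n_causal: int = 1
    count_class: str | tuple[int, int] = "any"
    causal_window: tuple[int, int] | None = None
    causal_variants: tuple[int, ...] | None = None
    observed: bool = True


def simulate_panel(
    n_samples: int,
    V: int,
    seed: int,
    *,
    planted: PlantedClade | None = None,
    n_founders: int | None = None,
    n_populations: int = 1,
    switch_prob: float = 0.05,
    mutation_rate: float = 0.3,
    rho: float = 1e-2,
    mu: float = 1e-4,
    bp_spacing: int = 500,
) -> HaplotypePanel:
    """Mosaic haplotype panel with optional planted clade, deterministic in ``seed``.

    ``n_founders`` defaults to ``max(4, N // 5)``; descendants switch founder
    templates with probability ``switch_prob`` per variant interval and carry
    ``Poisson(mutation_rate)`` private flips each. ``rho``/``mu`` are the
    copying-model parameters stored in the variant map, not the generative
    rates. With ``n_populations > 1`` the founder pool is stratified into
    groups with distinct allele-frequency draws.
    """
    if V < 10:
        raise ValueError("V must be >= 10")
    rng = np.random.default_rng(seed)
    N = 2 * n_samples
    if n_founders is None:
        n_founders = max(4, N // 5)
    founders = np.empty((n_founders, V), dtype=np.int8)
    pop_of_founder = rng.integers(0, n_populations, size=n_founders)
    for pop in range(n_populations):
        freqs = rng.beta(0.2, 0.8, size=V)
        rows = pop_of_founder == pop
        founders[rows] = rng.random((int(rows.sum()), V)) < freqs
    H = np.empty((N, V), dtype=np.int8)
    for h in range(N):
        cur = rng.integers(n_founders)
        switches = rng.random(V) < switch_prob
        row = np.empty(V, dtype=np.int8)
        for v in range(V):
            if v and switches[v]:
                cur = rng.integers(n_founders)
            row[v] = founders[cur, v]
        n_mut = rng.poisson(mutation_rate)
        if n_mut:
            sites = rng.integers(0, V, size=n_mut)
            row[sites] = 1 - row[sites]
        H[h] = row
    if planted is not None:
        members = np.asarray(planted.haplotypes)
        lo, hi = planted.span
        if not (0 <= lo <= planted.focal <= hi < V):
            raise InfeasibleSpec("planted focal variant outside its span")
        if members.max() >= N or len(set(members.tolist())) < 2:
            raise InfeasibleSpec("planted clade needs >= 2 distinct haplotypes in range")
        template = H[members[0], lo : hi + 1].copy()
        H[members, lo : hi + 1] = template
        H[:, planted.focal] = 0
        H[members, planted.focal] = 1
    positions = (1 + np.arange(V)) * bp_spacing
    return HaplotypePanel(
        H=H,
        positions=positions,
        rho=np.full(V - 1, rho),
        mu=np.full(V, mu),
        ancestral=np.zeros(V, dtype=np.int8),
    )


def select_causal_variants(
    panel: HaplotypePanel, spec: PhenotypeSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw the causal set uniformly from the window subject to the count class.

    Raises :class:`InfeasibleSpec` when the window lacks enough qualifying
    variants — the caller's contract is to reject the panel and simulate a
    new one rather than silently relax the class.
    """
    if spec.causal_variants is not None:
        return np.asarray(spec.causal_variants, dtype=int)
    lo, hi = spec.causal_window if spec.causal_window else (0, panel.n_variants - 1)
    cand = np.arange(lo, hi + 1)
    counts = panel.H[:, cand].sum(axis=0)
    if spec.count_class == "any":
        ok = counts > 0
    elif spec.count_class == "doubleton":
        ok = counts == 2
    else:
        lo_c, hi_c = spec.count_class
        ok = (counts >= lo_c) & (counts < hi_c)
    cand = cand[ok]
    if cand.size < spec.n_causal:
        raise InfeasibleSpec(
            f"only {cand.size} variants of class {spec.count_class!r} in window, "
            f"need {spec.n_causal}"
        )
    return np.sort(rng.choice(cand, size=spec.n_causal, replace=False))


def simulate_phenotype(
    panel: HaplotypePanel,
    spec: PhenotypeSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One phenotype draw with oracle signal strength pinned at ``spec.s``.

    Returns ``(Y, A, truth)``: the phenotype vector, the background
    covariates (column 0 standard Gaussian, column 1 Rademacher, fixed
    effects 1 each) and a truth record (causal indices, beta, s, seed).
    With ``s = 0`` (or no causal set) the phenotype is a pure null draw
    ``Y ~ N(a1 + a2, I)``.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    a1 = rng.standard_normal(n)
    a2 = rng.choice([-1.0, 1.0], size=n)
    A = np.column_stack([a1, a2])
    alpha = np.ones(2)
    eps = rng.standard_normal(n)
    if spec.s == 0 or spec.n_causal == 0:
        Y = A @ alpha + eps
        return Y, A, {"causal": [], "beta": [], "s": 0.0, "seed": seed}
    causal = select_causal_variants(panel, spec, rng)
    X_A = np.column_stack([panel.genotypes(v).astype(float) for v in causal])
    Qa, _ = np.linalg.qr(A)
    Xt = X_A - Qa @ (Qa.T @ X_A)
    norms = np.linalg.norm(Xt, axis=0)
    if (norms <= 1e-10).any():
        raise InfeasibleSpec("causal variant collinear with covariates")
    Xt = Xt / norms
    Q, R = np.linalg.qr(Xt)
    if np.abs(np.diag(R)).min() <= 1e-8:
        raise InfeasibleSpec("causal genotype columns are linearly dependent")
    k = causal.size
    q_chi2 = stats.chi2.ppf(1.0 - 10.0 ** (-spec.s), df=k)
    rb = np.full(k, np.sqrt(q_chi2 / k))
    beta = np.linalg.solve(R, rb)
    eps_perp = eps - Q @ (Q.T @ eps)
    Y = A @ alpha + Xt @ beta + eps_perp
    truth = {
        "causal": causal.tolist(),
        "beta": beta.tolist(),
        "s": float(spec.s),
        "seed": seed,
        "midpoint_bp": float(
            0.5 * (panel.positions[causal[0]] + panel.positions[causal[-1]])
        ),
    }
    return Y, A, truth


def oracle_anova_neglog10(Y: np.ndarray, A: np.ndarray, X_A: np.ndarray) -> float:
    """Oracle ANOVA -log10 p: chi-square test of the causal span, known variance.

    The likelihood-ratio statistic of ``Y ~ A alpha + X_A beta + eps`` versus
    ``Y ~ A alpha + eps`` with unit noise variance is ``||Q'Y||^2`` on
    ``rank(X~_A)`` degrees of freedom.
    """
    Qa, _ = np.linalg.qr(np.asarray(A, dtype=float))
    Xt = np.asarray(X_A, dtype=float)
    Xt = Xt - Qa @ (Qa.T @ Xt)
    Q, R = np.linalg.qr(Xt)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    stat = float(np.sum((Q.T @ Y) ** 2))
    return float(-stats.chi2.logsf(stat, df=Q.shape[1]) / np.log(10.0))


def rank_match(
    Y: np.ndarray,
    A: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Match covariate-residual ranks to a fresh null residual; re-add the fit.

    Residuals of ``Y`` on ``(1, A)`` are replaced by a fresh draw from the
    *null residual law* — a standard normal vector projected off ``(1, A)``
    — rearranged to carry the data's ranks (the k-th smallest residual
    becomes the k-th smallest fresh value). Under H0 this reproduces the
    null residual distribution up to the coupling between a residual's
    sorted values and its rank pattern, so every downstream test sees (near)
    unit-variance Gaussian residuals whatever the raw trait's distribution.

    Two cruder variants fail measurably: deterministic quantile scores fix
    the residual norm across replicates, and matching to *unprojected*
    i.i.d. draws ignores that covariate leverage makes the residual ranks a
    non-uniform permutation; both visibly distort quadratic-form nulls.

    Ties are flagged when heavy and share the average of their matched
    scores. ``rng`` (int seed or Generator; default seed 0) pins the draws.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    Y2 = Y[:, None] if squeeze else Y.copy()
    n = Y2.shape[0]
    if n < 10:
        raise ValueError("rank matching needs n >= 10")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(0 if rng is None else rng)
    ones = np.ones((n, 1))
    D = ones if A is None else np.column_stack([ones, A])
    Qd, _ = np.linalg.qr(D)
    fitted = Qd @ (Qd.T @ Y2)
    resid = Y2 - fitted
    out = np.empty_like(Y2)
    for t in range(Y2.shape[1]):
        col = resid[:, t]
        if np.unique(col).size < 0.5 * n:
            import warnings

            warnings.warn("heavy ties in rank matching; tied scores averaged")
        eps = rng.standard_normal(n)
        draws = np.sort(eps - Qd @ (Qd.T @ eps))  # fresh null residual, sorted
        order = np.argsort(col, kind="stable")
        scores = np.empty(n)
        scores[order] = draws
        # average matched scores within tie groups so ties stay exchangeable
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=scores)
            scores = (sums / counts)[inv]
        out[:, t] = fitted[:, t] + scores
    return out[:, 0] if squeeze else out
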