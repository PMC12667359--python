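"""End-to-end screen: single-marker pass, target selection, ancestry testing.

The screen mirrors how genealogy-boosted testing slots into a GWAS: a cheap
single-marker pass over every variant picks target loci (e.g. p < 1e-4);
the copying model is then decoded at the targets right-to-left under an
optimal checkpoint schedule, and at each target the local distances are
turned into sprig genotypes ``X`` and a relatedness matrix ``Omega``, tested
with stable distillation and the quadratic form on the distilled residuals,
and the three independent p-values are combined. Nothing of size
``N x N``/``n x n`` is persisted between targets ("test it and forget it").
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .checkpoint import iterate_targets, solve_schedule
from .combine import SubsetFisherNull, build_subset_null, combine_pvalues
from .egrm import build_psi_omega, remove_sprig_structure, threshold_from_mu
from .panel import HaplotypePanel
from .qform import qform_test
from .sdtest import DEFAULT_C_MAX, distill
from .simulate import rank_match
from .smt import smt_screen, smt_test
from .sprigs import call_sprigs

logger = logging.getLogger("cladescan")

__all__ = [
    "ScreenConfig",
    "run_screen",
    "write_results",
    "lead_variant_distance",
    "interval_width_80",
]

#: Fixed, documented column order of the results table.
RESULT_COLUMNS = [
    "locus",
    "position",
    "phenotype",
    "p_smt",
    "p_sd",
    "p_q",
    "p_c",
    "n_sprigs",
    "k_eigen",
    "eta1",
    "eta2",
]


@dataclass
class ScreenConfig:
    """Tunable knobs of :func:`run_screen` (defaults follow the methods note)."""

    smt_threshold: float = 1e-4
    max_targets: int | None = None
    targets: tuple[int, ...] | None = None  # explicit 0-based loci, skips selection
    checkpoints: int = 2
    c_threshold: float | None = None  # None: -0.2 log(mu) at each target
    c_max: int = DEFAULT_C_MAX
    null_table_sims: int = 1_000_000
    seed: int = 0
    rank_match: bool = True
    ancestral_mode: bool = False
    full_spectrum: bool | None = None  # None: dense when n <= 800
    qform_p_threshold: float = 1e-3


def run_screen(
    panel: HaplotypePanel,
    Y: np.ndarray,
    A: np.ndarray | None = None,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full screen; returns (results table, diagnostics).

    ``Y`` may hold many phenotypes (columns); every stage is batched across
    them. Reruns with the same inputs and config are identical.
    """
    cfg = config or ScreenConfig()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, T = Y.shape
    if panel.n_samples != n:
        raise ValueError("phenotype length does not match panel samples")
    if cfg.rank_match:
        Y = rank_match(Y, A, rng=cfg.seed)
    # every stage adjusts for an explicit intercept, matching the (1, A)
    # projection inside rank_match — without it the re-added fitted part
    # carries null noise that downstream tests would not remove
    ones = np.ones((n, 1))
    A = ones if A is None else np.column_stack([ones, A])
    t0 = time.perf_counter()
    scan = smt_screen(panel.H, Y, A, positions=panel.positions)
    p_cols = [c for c in scan.columns if c.startswith("p_smt")]
    p_min = scan[p_cols].min(axis=1).to_numpy()
    t_smt = time.perf_counter() - t0

    if cfg.targets is not None:
        targets = np.unique(np.asarray(cfg.targets, dtype=int))
    else:
        targets = np.flatnonzero(p_min < cfg.smt_threshold)
        if cfg.max_targets is not None and targets.size > cfg.max_targets:
            targets = targets[np.argsort(p_min[targets])[: cfg.max_targets]]
            targets = np.sort(targets)
    diagnostics: dict = {"smt_seconds": t_smt, "n_targets": int(targets.size)}
    if targets.size == 0:
        logger.info("no locus passed the single-marker threshold; SMT-only output")
        diagnostics["notice"] = "empty target set: SMT-only output"
        return scan, diagnostics

    schedule = solve_schedule(len(targets), cfg.checkpoints)
    diagnostics["schedule_cost"] = schedule.total_cost
    logger.info(
        "screen: %d targets, C=%d, scheduled forward cost %d",
        len(targets), cfg.checkpoints, schedule.total_cost,
    )

    full_spec = cfg.full_spectrum if cfg.full_spectrum is not None else n <= 800
    null_tables: dict[tuple[bool, bool], SubsetFisherNull] = {}

    def null_for(family: tuple[bool, bool]) -> SubsetFisherNull:
        if family not in null_tables:
            null_tables[family] = build_subset_null(
                cfg.null_table_sims, seed=cfg.seed + 7919, family=family
            )
        return null_tables[family]

    rows: list[dict] = []

    def test_locus(dec) -> None:
        v = dec.locus
        G = panel.genotypes(v).astype(float)
        c = cfg.c_threshold or threshold_from_mu(panel.mu[v])
        rel, eta = build_psi_omega(dec.d, c)
        sprigs = call_sprigs(eta)
        if sprigs.n_sprigs:
            rel = remove_sprig_structure(rel, sprigs)
        reg = smt_test(Y, A, G)
        if sprigs.n_sprigs:
            sd = distill(Y, sprigs.X, A, G, c_max=cfg.c_max)
            Y_out, basis, p_sd = sd.Y_out, sd.basis, sd.p_sd
        else:
            sd, Y_out, basis, p_sd = None, Y, None, None
        p_q, kern = qform_test(
            Y_out,
            rel.Omega,
            A,
            G,
            extra_basis=basis,
            p_threshold=cfg.qform_p_threshold,
            full_spectrum=full_spec,
        )
        p_q = np.atleast_1d(p_q)
        p_c = combine_pvalues(
            reg.p_smt,
            p_sd,
            p_q,
            null_for((p_sd is not None, True)),
        )
        p_c = np.atleast_1d(p_c)
        for t in range(T):
            rows.append(
                {
                    "locus": v + 1,  # 1-based in output
                    "position": int(panel.positions[v]),
                    "phenotype": t,
                    "p_smt": reg.p_smt[t],
                    "p_sd": np.nan if p_sd is None else p_sd[t],
                    "p_q": p_q[t],
                    "p_c": p_c[t],
                    "n_sprigs": sprigs.n_sprigs,
                    "k_eigen": kern.k,
                    "eta1": kern.eta1,
                    "eta2": kern.eta2,
                }
            )

    t1 = time.perf_counter()
    accounting = iterate_targets(
        panel,
        targets[::-1].tolist(),
        cfg.checkpoints,
        test_locus,
        ancestral_mode=cfg.ancestral_mode,
        schedule=schedule,
    )
    diagnostics.update(accounting)
    diagnostics["testing_seconds"] = time.perf_counter() - t1
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values(
        ["locus", "phenotype"], ignore_index=True
    )
    return results, diagnostics


def write_results(results: pd.DataFrame, path) -> None:
    """Write the results table as TSV in the fixed column order."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    results.to_csv(path, sep="\t", index=False, columns=cols)


def lead_variant_distance(
    positions: np.ndarray, pvalues: np.ndarray, causal_midpoint_bp: float
) -> float:
    """Distance (bp) from the lead variant to the causal-region midpoint.

    Ties on the minimal p-value are resolved by averaging the tied variants'
    distances.
    """
    positions = np.asarray(positions, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    lead = pvalues == pvalues.min()
    return float(np.abs(positions[lead] - causal_midpoint_bp).mean())


def interval_width_80(distances: np.ndarray) -> float:
    """Width of the 80% localization interval from replicate lead distances.

    The window centered on the lead variant must extend the 80th percentile
    of lead-to-midpoint distances each way to capture the causal midpoint in
    80% of replicates, so the width is twice that percentile.
    """
    return float(2.0 * np.quantile(np.asarray(distances, dtype=float), 0.8))
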