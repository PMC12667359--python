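"""Phased haplotype panel container and plain-text I/O.

A panel holds ``N = 2n`` phased haplotypes over ``V`` variants together with
the per-variant parameters of the Li & Stephens copying model: the
recombination switch probability ``rho`` for each of the ``V - 1`` inter-variant
intervals and the mutation (miscopy) probability ``mu`` at each variant.
Haplotypes ``2s`` and ``2s + 1`` (0-based) belong to diploid sample ``s``; this
layout is relied on when haplotype-level relatedness is collapsed to samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["HaplotypePanel", "read_panel", "write_panel", "read_vcf", "write_vcf"]


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes plus the variant map driving the copying model.

    Parameters
    ----------
    H
        ``(N, V)`` binary matrix; row ``i`` is haplotype ``i``. ``N`` must be
        even (diploid samples).
    positions
        Physical coordinate (bp, 1-based) per variant, strictly increasing.
    rho
        Per-interval recombination switch probability, length ``V - 1``,
        entries in ``[0, 1]``.
    mu
        Per-variant miscopy probability, entries in ``(0, 0.5)``. A scalar is
        broadcast to all variants.
    ancestral
        Optional per-variant ancestral allele (0 or 1). When present, the
        ancestral-aware emission mode of the copying model can be used.
    """

    H: np.ndarray
    positions: np.ndarray
    rho: np.ndarray
    mu: np.ndarray
    ancestral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.ascontiguousarray(self.H, dtype=np.int8)
        if self.H.ndim != 2:
            raise ValueError("H must be a 2-D matrix of shape (N, V)")
        N, V = self.H.shape
        # odd N is allowed for pure haplotype-level work (toy HMM panels);
        # anything that collapses to diploid samples checks evenness itself
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("H entries must be 0/1")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (V,):
            raise ValueError("positions must have one entry per variant")
        if V > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (max(V - 1, 0),):
            raise ValueError(f"rho must have length V-1 = {V - 1}")
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("rho entries must lie in [0, 1]")
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim == 0:
            mu = np.full(V, float(mu))
        if mu.shape != (V,):
            raise ValueError("mu must be scalar or length V")
        if ((mu <= 0) | (mu >= 0.5)).any():
            raise ValueError("mu entries must lie in (0, 0.5)")
        self.mu = mu
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
            if self.ancestral.shape != (V,):
                raise ValueError("ancestral must have one entry per variant")
            if not np.isin(self.ancestral, (0, 1)).all():
                raise ValueError("ancestral entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_samples(self) -> int:
        if self.H.shape[0] % 2:
            raise ValueError("odd haplotype count: no diploid sample layout")
        return self.H.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.H.shape[1]

    def genotypes(self, v: int) -> np.ndarray:
        """Diploid 0/1/2 genotype vector at variant ``v`` (0-based)."""
        self.n_samples  # validates the diploid layout
        col = self.H[:, v]
        return (col[0::2] + col[1::2]).astype(np.int8)


def write_panel(panel: HaplotypePanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel as ``<prefix>.haps.tsv`` + ``<prefix>.map.tsv``.

    The haplotype file is a headered TSV with one row per haplotype; the map
    file has columns ``pos``, ``rho``, ``mu`` and optionally ``ancestral``.
    ``rho`` for variant ``v`` is the switch probability of the interval
    *preceding* ``v`` (first entry 0 by convention).
    """
    prefix = Path(prefix)
    haps_path = prefix.with_suffix(".haps.tsv")
    map_path = prefix.with_suffix(".map.tsv")
    hap_df = pd.DataFrame(
        panel.H, index=[f"hap{i}" for i in range(panel.n_haplotypes)]
    )
    hap_df.columns = [f"v{j}" for j in range(panel.n_variants)]
    hap_df.to_csv(haps_path, sep="\t", index_label="haplotype")
    map_df = pd.DataFrame(
        {
            "pos": panel.positions,
            "rho": np.concatenate([[0.0], panel.rho]),
            "mu": panel.mu,
        }
    )
    if panel.ancestral is not None:
        map_df["ancestral"] = panel.ancestral
    map_df.to_csv(map_path, sep="\t", index=False)
    return haps_path, map_path


def read_panel(prefix: str | Path) -> HaplotypePanel:
    """Read a panel written by :func:`write_panel`."""
    prefix = Path(prefix)
    hap_df = pd.read_csv(prefix.with_suffix(".haps.tsv"), sep="\t", index_col=0)
    map_df = pd.read_csv(prefix.with_suffix(".map.tsv"), sep="\t")
    ancestral = map_df["ancestral"].to_numpy() if "ancestral" in map_df else None
    return HaplotypePanel(
        H=hap_df.to_numpy(),
        positions=map_df["pos"].to_numpy(),
        rho=map_df["rho"].to_numpy()[1:],
        mu=map_df["mu"].to_numpy(),
        ancestral=ancestral,
    )


def write_vcf(panel: HaplotypePanel, path: str | Path, chrom: str = "1") -> Path:
    """Write the panel's haplotypes as an uncompressed phased VCF.

    ``rho``/``mu`` are not representable in VCF; pair the file with the
    variant map from :func:`write_panel` to round-trip a full panel.
    """
    path = Path(path)
    n = panel.n_samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if panel.ancestral is not None:
            fh.write(
                '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
            )
        samples = "\t".join(f"s{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for v in range(panel.n_variants):
            if panel.ancestral is not None:
                info = f"AA={'A' if panel.ancestral[v] == 0 else 'C'}"
            else:
                info = "."
            gts = "\t".join(
                f"{panel.H[2 * s, v]}|{panel.H[2 * s + 1, v]}" for s in range(n)
            )
            fh.write(
                f"{chrom}\t{panel.positions[v]}\tv{v}\tA\tC\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
    return path


def read_vcf(
    path: str | Path,
    rho: np.ndarray | float,
    mu: np.ndarray | float,
) -> HaplotypePanel:
    """Read phased GT fields from a VCF into a panel.

    The copying-model parameters ``rho``/``mu`` are not part of VCF and must be
    supplied (scalars are broadcast). Unphased genotypes raise.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    haps: list[np.ndarray] = []
    positions: list[int] = []
    ancestral: list[int] = []
    has_aa = True
    for rec in VCF(str(path)):
        gt = np.asarray(rec.genotype.array())
        if not gt[:, 2].all():
            raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        haps.append(gt[:, :2].reshape(-1))
        positions.append(rec.POS)
        aa = rec.INFO.get("AA")
        if aa is None:
            has_aa = False
        else:
            ancestral.append(0 if aa == rec.REF else 1)
    H = np.asarray(haps).T
    V = H.shape[1]
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:
        rho = np.full(max(V - 1, 0), float(rho))
    return HaplotypePanel(
        H=H,
        positions=np.asarray(positions),
        rho=rho,
        mu=mu,
        ancestral=np.asarray(ancestral) if has_aa else None,
    )
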