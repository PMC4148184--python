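"""Phased reference haplotype panels.

A panel is a binary haplotype-by-marker matrix (0 = A allele, 1 = B allele)
with a marker map giving chromosome and physical position.  Panels supply the
population linkage-disequilibrium information from which the haplotype-cluster
model is fitted; a few hundred phased haplotypes of matched ancestry (e.g. a
HapMap-style reference) is the intended scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAP_COLUMNS = ("marker_id", "chrom", "pos")


def _check_marker_map(marker_map: pd.DataFrame) -> None:
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map is missing columns {missing}")
    for _, block in marker_map.groupby("chrom", sort=False):
        pos = block["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing within a chromosome")
    # chromosome blocks must be contiguous
    chrom = marker_map["chrom"].to_numpy()
    seen: set = set()
    prev = None
    for c in chrom:
        if c != prev:
            if c in seen:
                raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
            seen.add(c)
            prev = c


def chrom_bounds(chrom: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of consecutive chromosome blocks, in file order."""
    bounds = []
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            bounds.append((start, i))
            start = i
    return bounds


@dataclass
class ReferencePanel:
    """Phased haplotypes (rows) over biallelic markers (columns)."""

    alleles: np.ndarray  # (n_haplotypes, n_markers) with entries in {0, 1}
    marker_map: pd.DataFrame  # columns: marker_id, chrom, pos (1-based bp)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x marker matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be binary (0 = A, 1 = B)")
        self.alleles = self.alleles.astype(np.int8)
        self.marker_map = self.marker_map.reset_index(drop=True)
        _check_marker_map(self.marker_map)
        if len(self.marker_map) != self.alleles.shape[1]:
            raise ValueError("marker map length does not match allele matrix")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_map["marker_id"].to_numpy()

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker B-allele frequency across panel haplotypes."""
        return self.alleles.mean(axis=0)

    def chrom_bounds(self) -> list[tuple[int, int]]:
        return chrom_bounds(self.marker_map["chrom"].to_numpy())

    @classmethod
    def from_haplotype_matrix(cls, hap_path, map_path) -> "ReferencePanel":
        """Read a whitespace-delimited 0/1 matrix plus a 3-column marker map.

        The map file has columns ``marker_id chrom pos`` (1-based position),
        one row per marker, in the same order as the matrix columns.
        """
        alleles = np.loadtxt(hap_path, dtype=np.int8, ndmin=2)
        marker_map = pd.read_csv(
            map_path, sep=r"\s+", header=None, names=list(MAP_COLUMNS),
            dtype={"marker_id": str, "chrom": str, "pos": np.int64},
        )
        return cls(alleles=alleles, marker_map=marker_map)

    @classmethod
    def from_vcf(cls, path) -> "ReferencePanel":
        """Read phased GT fields ('|'-separated) from a biallelic VCF."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        n_samples = len(vcf.samples)
        cols: list[np.ndarray] = []
        rows: list[tuple] = []
        for variant in vcf:
            if len(variant.ALT) != 1:
                continue
            hap = np.empty(2 * n_samples, dtype=np.int8)
            for i, gt in enumerate(variant.genotypes):
                a0, a1, phased = gt[0], gt[1], gt[2]
                if not phased:
                    raise ValueError(
                        f"unphased genotype at {variant.CHROM}:{variant.POS}; "
                        "panel VCFs must use '|' separators"
                    )
                if a0 < 0 or a1 < 0:
                    raise ValueError("missing genotypes are not supported in panels")
                hap[2 * i] = a0
                hap[2 * i + 1] = a1
            cols.append(hap)
            rows.append((variant.ID or f"{variant.CHROM}:{variant.POS}",
                         str(variant.CHROM), int(variant.POS)))
        if not rows:
            raise ValueError(f"no usable biallelic records in {path}")
        alleles = np.stack(cols, axis=1)
        marker_map = pd.DataFrame(rows, columns=list(MAP_COLUMNS))
        return cls(alleles=alleles, marker_map=marker_map)

    def write_haplotype_matrix(self, hap_path, map_path) -> None:
        np.savetxt(hap_path, self.alleles, fmt="%d")
        self.marker_map.to_csv(map_path, sep="\t", header=False, index=False)
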