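"""Variant records, marker identifiers and the genotype matrix container.

Markers follow the scaffold-anchored naming convention ``C{scaffold}_{position}``
(e.g. ``C29_6721563``), so physical distances between markers on the same
scaffold can be recovered from the identifiers alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

MISSING = -1
_MARKER_RE = re.compile(r"^C(\d+)_(\d+)$")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant anchored to a scaffold position (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    @property
    def vtype(self) -> str:
        return "InDel" if len(self.ref) != len(self.alt) else "SNP"


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """Split ``C{scaffold}_{pos}`` into (scaffold name, 1-based position)."""
    m = _MARKER_RE.match(marker_id)
    if m is None:
        raise ValueError(f"malformed marker id {marker_id!r}; expected C<scaffold>_<pos>")
    return f"C{m.group(1)}", int(m.group(2))


def marker_distance(id_a: str, id_b: str) -> int:
    """Physical distance in bp between two markers on the same scaffold."""
    chrom_a, pos_a = parse_marker_id(id_a)
    chrom_b, pos_b = parse_marker_id(id_b)
    if chrom_a != chrom_b:
        raise ValueError(
            f"markers {id_a} and {id_b} lie on different scaffolds ({chrom_a} vs {chrom_b})"
        )
    return abs(pos_a - pos_b)


@dataclass
class GenotypeMatrix:
    """Samples x variants genotype codes.

    Codes: 0 = homozygous for the wild-parent (reference) allele, 1 =
    heterozygous, 2 = homozygous for the mutant-parent (alternate) allele,
    -1 = missing call.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in index],
            codes=self.codes[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=list(self.variants),
            codes=self.codes[index, :],
        )
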