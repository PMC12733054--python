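"""Digital coding of backcross genotypes against the recurrent parent.

Loci where both parents are homozygous for different alleles are the only
informative markers in a backcross.  At each such locus a progeny call is
coded

* ``1`` — homozygous and identical to the recurrent parent (RP),
* ``2`` — heterozygous carrying exactly the two parental alleles,
* ``0`` — everything else (missing, donor-homozygous, off-type allele).

The SNP-level background recovery rate is then

    PRPG = A / B x 100%

with A = number of code-1 loci and B = number of non-zero codes (missing
loci excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, LocusTable


class NoPolymorphicLociError(ValueError):
    """The two parents share genotypes everywhere usable."""


class UndefinedRateError(ValueError):
    """A recovery rate was requested on an all-missing vector."""


@dataclass
class PolymorphicSet:
    """Loci where RP and DP are both homozygous with different alleles."""

    index: np.ndarray  # row indices into the LocusTable (sorted order)
    chrom: np.ndarray  # chromosome per retained locus
    pos: np.ndarray  # 1-based bp per retained locus
    rp_allele: np.ndarray  # single-character RP allele
    dp_allele: np.ndarray  # single-character DP allele

    def __post_init__(self) -> None:
        if np.any(self.rp_allele == self.dp_allele):
            raise ValueError("rp_allele == dp_allele at a claimed polymorphic locus")

    @property
    def n(self) -> int:
        return len(self.index)


def _hom_allele(calls: np.ndarray) -> np.ndarray:
    """First allele where the call is homozygous, else '' (missing/het)."""
    first = np.array([c[0] if c != MISSING else "" for c in calls], dtype=object)
    second = np.array([c[1] if c != MISSING else "?" for c in calls], dtype=object)
    return np.where(first == second, first, "")


def find_polymorphic_loci(
    genotypes: LocusTable, rp_sample: str, dp_sample: str
) -> PolymorphicSet:
    """Identify parental polymorphic loci.

    Retains exactly the loci where both parents are non-missing, homozygous
    and carry different alleles; parents with a missing call cannot certify
    polymorphism and the locus is dropped.
    """
    rp = _hom_allele(genotypes.calls(rp_sample))
    dp = _hom_allele(genotypes.calls(dp_sample))
    keep = (rp != "") & (dp != "") & (rp != dp)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise NoPolymorphicLociError(
            f"no polymorphic loci between {rp_sample!r} and {dp_sample!r}"
        )
    return PolymorphicSet(
        index=idx,
        chrom=genotypes.chrom[idx],
        pos=genotypes.pos[idx],
        rp_allele=rp[idx],
        dp_allele=dp[idx],
    )


def code_individual(
    genotypes: LocusTable, sample: str, poly: PolymorphicSet
) -> np.ndarray:
    """Code one individual's calls at the polymorphic loci into {0, 1, 2}."""
    calls = genotypes.calls(sample)[poly.index]
    rp2 = poly.rp_allele + poly.rp_allele  # RP-homozygous call
    swap = poly.rp_allele > poly.dp_allele
    lo = np.where(swap, poly.dp_allele, poly.rp_allele)
    hi = np.where(swap, poly.rp_allele, poly.dp_allele)
    het = lo + hi  # parental heterozygote, normalised order
    codes = np.zeros(poly.n, dtype=np.uint8)
    codes[calls == rp2] = 1
    codes[calls == het] = 2
    return codes


def code_matrix(
    genotypes: LocusTable, samples: list[str], poly: PolymorphicSet
) -> np.ndarray:
    """Stack :func:`code_individual` over samples -> (n_samples, n_loci) uint8."""
    return np.stack([code_individual(genotypes, s, poly) for s in samples])


def code_diagnostics(
    genotypes: LocusTable, sample: str, poly: PolymorphicSet
) -> dict[str, int]:
    """QC breakdown of the code-0 class (missing vs donor-homozygous vs off-type).

    The pipeline treats all three identically; this is reporting only.
    """
    calls = genotypes.calls(sample)[poly.index]
    codes = code_individual(genotypes, sample, poly)
    zero = codes == 0
    missing = zero & (calls == MISSING)
    dp2 = poly.dp_allele + poly.dp_allele
    donor_hom = zero & (calls == dp2)
    return {
        "missing": int(missing.sum()),
        "donor_homozygous": int(donor_hom.sum()),
        "off_type": int((zero & ~missing & ~donor_hom).sum()),
    }


def prpg(coded: np.ndarray) -> float:
    """SNP-level recovery rate A/B x 100 (percent).

    Raises :class:`UndefinedRateError` if every code is 0.
    """
    coded = np.asarray(coded)
    b = int(np.count_nonzero(coded))
    if b == 0:
        raise UndefinedRateError("PRPG undefined: all loci missing (code 0)")
    a = int(np.count_nonzero(coded == 1))
    return a / b * 100.0
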