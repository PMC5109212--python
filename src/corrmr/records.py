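"""Core record types for GWAS summary statistics.

A two-sample Mendelian randomization analysis consumes nothing but summary
associations: per-SNP effect sizes with standard errors, one table per trait,
plus a SNP-by-SNP correlation (linkage disequilibrium) matrix.  These types
are deliberately thin and validated at construction so that every downstream
module can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .exceptions import DuplicateRecordError, FormatError, LdRangeError

VALID_ALLELES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``: cups/day
    for the coffee exposure, log-odds for a binary outcome, trait units (often
    SD after inverse-normal transformation) for a continuous outcome.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    p: Optional[float] = None
    n: Optional[int] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    locus_label: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise FormatError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise FormatError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.rsid}: effect and other allele are identical")
        if self.beta is not None and not (self.se > 0):
            raise FormatError(f"{self.rsid}: se must be positive when beta is present")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise FormatError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise FormatError(f"{self.rsid}: p-value {self.p} outside (0, 1]")
        for name in ("n", "n_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise FormatError(f"{self.rsid}: {name} must be nonnegative")
        if (
            self.n is not None
            and self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n
        ):
            raise FormatError(f"{self.rsid}: n_cases + n_controls != n")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G SNPs, whose strand cannot be read off the alleles."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def with_(self, **changes) -> "SnpAssociation":
        return replace(self, **changes)


class AssociationSet:
    """Summary associations of many SNPs with a single trait.

    Records are keyed by rsid (unique within a set) and preserve insertion
    order.  ``trait_type`` is ``"binary"`` (betas are log odds ratios) or
    ``"continuous"`` (betas are trait units).
    """

    def __init__(
        self,
        trait_name: str,
        trait_type: str,
        records: Sequence[SnpAssociation] = (),
        provenance: str = "",
    ) -> None:
        if trait_type not in ("binary", "continuous"):
            raise FormatError(f"trait_type must be binary or continuous, got {trait_type!r}")
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.provenance = provenance
        self._records: dict[str, SnpAssociation] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SnpAssociation) -> None:
        if rec.rsid in self._records:
            raise DuplicateRecordError(f"duplicate rsid {rec.rsid} in {self.trait_name!r}")
        self._records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._records

    def __getitem__(self, rsid: str) -> SnpAssociation:
        return self._records[rsid]

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self._records.values())

    @property
    def rsids(self) -> list[str]:
        return list(self._records)

    def __repr__(self) -> str:
        return (
            f"AssociationSet({self.trait_name!r}, {self.trait_type!r}, "
            f"{len(self)} records)"
        )


class LdMatrix:
    """Signed SNP-by-SNP correlation matrix keyed by rsid.

    Stores signed r in the exposure effect-allele orientation; r**2 is derived.
    Symmetry (tolerance 1e-8), a unit diagonal and entries within [-1, 1]
    are enforced at construction.
    """

    def __init__(self, rsids: Sequence[str], r: np.ndarray) -> None:
        r = np.asarray(r, dtype=float)
        rsids = list(rsids)
        if len(set(rsids)) != len(rsids):
            raise FormatError("duplicate rsids in LD matrix")
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(rsids):
            raise FormatError("LD matrix must be square and match its labels")
        if not np.allclose(r, r.T, atol=1e-8, rtol=0.0):
            raise FormatError("LD matrix is not symmetric (tolerance 1e-8)")
        r = (r + r.T) / 2.0
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise LdRangeError("LD entries must lie in [-1, 1]")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise LdRangeError("LD matrix diagonal must equal 1")
        np.fill_diagonal(r, 1.0)
        self.rsids = rsids
        self.r = np.clip(r, -1.0, 1.0)
        self._index = {s: i for i, s in enumerate(rsids)}

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def submatrix(self, rsids: Sequence[str]) -> "LdMatrix":
        """Restrict and reorder to ``rsids`` (all must be present)."""
        missing = [s for s in rsids if s not in self._index]
        if missing:
            raise KeyError(f"rsids absent from LD matrix: {missing}")
        idx = [self._index[s] for s in rsids]
        return LdMatrix(list(rsids), self.r[np.ix_(idx, idx)])

    def __repr__(self) -> str:
        return f"LdMatrix({len(self.rsids)} SNPs)"


@dataclass(frozen=True)
class ProxyCandidate:
    """A substitute SNP in high LD with an instrument missing from an outcome."""

    rsid: str
    r2: float
    distance_kb: float
    allele_map: tuple[str, str]  # (index SNP effect allele, proxy effect allele)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise FormatError(f"proxy {self.rsid}: r2 {self.r2} outside [0, 1]")


@dataclass(frozen=True)
class InstrumentAnnotation:
    """Curated knowledge about one instrument: pleiotropy, function, proxies."""

    rsid: str
    pleiotropy_terms: tuple[str, ...] = ()
    functional: bool = False
    proxy_candidates: tuple[ProxyCandidate, ...] = field(default_factory=tuple)
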