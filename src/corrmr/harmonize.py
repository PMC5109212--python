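"""Allele harmonization of outcome associations to the exposure orientation.

Before any causal estimate, every outcome beta must be expressed per copy of
the same effect allele the exposure beta refers to.  Four letter-level
configurations arise (same order, swapped order, and either of those on the
opposite strand); palindromic SNPs (A/T or C/G) are strand-ambiguous and are
resolved by allele-frequency agreement or excluded.

The signed LD matrix is stored in the exposure effect-allele orientation,
which harmonization never changes, so correlations are passed through
untouched (restricted and reordered to the harmonized pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import AlleleMismatchError
from .instruments import InstrumentSet
from .records import COMPLEMENT, AssociationSet, LdMatrix, SnpAssociation

ACTIONS = ("none", "swap", "strand_flip", "swap_and_flip", "excluded_palindromic")


@dataclass(frozen=True)
class PalindromicPolicy:
    """How to treat strand-ambiguous (A/T, C/G) SNPs.

    A palindromic SNP is kept only when both allele frequencies are known and
    both are further than ``freq_margin`` from 0.5, so that frequency matching
    identifies the strand; otherwise it is excluded.
    """

    freq_margin: float = 0.08


@dataclass(frozen=True)
class HarmonizedPair:
    """Per-SNP exposure and outcome effects on a common effect allele."""

    rsid: str
    bx: float
    sx: float
    by: float
    sy: float
    action: str

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown harmonization action {self.action!r}")
        if self.action != "excluded_palindromic" and not (self.sx > 0 and self.sy > 0):
            raise ValueError(f"{self.rsid}: standard errors must be positive")


@dataclass
class HarmonizedSet:
    """Harmonized pairs plus the LD matrix restricted to them, in order."""

    pairs: list[HarmonizedPair]
    ld: LdMatrix
    excluded: list[HarmonizedPair]

    def __post_init__(self) -> None:
        if self.ld.rsids != [p.rsid for p in self.pairs]:
            raise ValueError("LD matrix order must match pair order")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([p.bx for p in self.pairs])
        sx = np.array([p.sx for p in self.pairs])
        by = np.array([p.by for p in self.pairs])
        sy = np.array([p.sy for p in self.pairs])
        return bx, sx, by, sy


def _orient(exp: SnpAssociation, out: SnpAssociation, policy: PalindromicPolicy):
    """Return (sign, action) aligning the outcome record to the exposure alleles.

    sign is +1/-1 multiplying the outcome beta; action 'excluded_palindromic'
    signals an unresolvable strand-ambiguous SNP.
    """
    e1, o1 = exp.effect_allele, exp.other_allele
    e2, o2 = out.effect_allele, out.other_allele

    if exp.is_palindromic:
        if {e2, o2} != {e1, o1}:
            raise AlleleMismatchError(
                f"{exp.rsid}: outcome alleles {e2}/{o2} irreconcilable with {e1}/{o1}"
            )
        f1, f2 = exp.eaf, out.eaf
        if (
            f1 is None
            or f2 is None
            or abs(f1 - 0.5) <= policy.freq_margin
            or abs(f2 - 0.5) <= policy.freq_margin
        ):
            return 0, "excluded_palindromic"
        # frequency of the exposure effect allele as the outcome reports it
        f2_for_e1 = f2 if e2 == e1 else 1.0 - f2
        nominal_sign = 1.0 if e2 == e1 else -1.0
        if (f1 - 0.5) * (f2_for_e1 - 0.5) > 0:
            return nominal_sign, ("none" if nominal_sign > 0 else "swap")
        # frequencies disagree: the outcome record is on the opposite strand
        return -nominal_sign, ("swap_and_flip" if nominal_sign > 0 else "strand_flip")

    if (e2, o2) == (e1, o1):
        return 1.0, "none"
    if (e2, o2) == (o1, e1):
        return -1.0, "swap"
    ce2, co2 = COMPLEMENT[e2], COMPLEMENT[o2]
    if (ce2, co2) == (e1, o1):
        return 1.0, "strand_flip"
    if (ce2, co2) == (o1, e1):
        return -1.0, "swap_and_flip"
    raise AlleleMismatchError(
        f"{exp.rsid}: outcome alleles {e2}/{o2} irreconcilable with {e1}/{o1}"
    )


def harmonize(
    inst: InstrumentSet,
    outcome: AssociationSet,
    ld: Optional[LdMatrix] = None,
    policy: PalindromicPolicy = PalindromicPolicy(),
) -> HarmonizedSet:
    """Align outcome betas to the exposure effect alleles, SNP by SNP.

    Every instrument (post proxy substitution) must be present in ``outcome``.
    If ``ld`` is omitted, instruments are treated as uncorrelated (identity).
    """
    missing = [m.rsid for m in inst.members if m.rsid not in outcome]
    if missing:
        raise KeyError(f"instruments absent from outcome {outcome.trait_name!r}: {missing}")
    pairs: list[HarmonizedPair] = []
    excluded: list[HarmonizedPair] = []
    for rec in inst.members:
        out = outcome[rec.rsid]
        sign, action = _orient(rec, out, policy)
        pair = HarmonizedPair(
            rsid=rec.rsid,
            bx=rec.beta,
            sx=rec.se,
            by=sign * out.beta,
            sy=out.se,
            action=action,
        )
        (excluded if action == "excluded_palindromic" else pairs).append(pair)
    rsids = [p.rsid for p in pairs]
    if ld is None:
        sub = LdMatrix(rsids, np.eye(len(rsids)))
    else:
        sub = ld.submatrix(rsids)
    return HarmonizedSet(pairs=pairs, ld=sub, excluded=excluded)
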