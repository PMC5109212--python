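"""Instrument curation: significance filtering, LD pruning, pleiotropy
subsets and proxy substitution.

The curation flow mirrors standard two-sample MR practice: start from the
genome-wide significant hits for the exposure, discard one SNP of each pair in
high linkage disequilibrium (keeping the smaller p-value), optionally restrict
to variants without known pleiotropy or to functionally characterised
variants, and substitute a high-LD proxy for any instrument missing from the
outcome dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .exceptions import (
    AnnotationGapError,
    DomainError,
    EmptyInstrumentError,
    MissingCorrelationError,
)
from .records import (
    COMPLEMENT,
    AssociationSet,
    InstrumentAnnotation,
    LdMatrix,
    SnpAssociation,
)

logger = logging.getLogger(__name__)

SUBSET_MODES = ("all", "no_known_pleiotropy", "functional")


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    ``p_threshold`` approximates the Bayesian genome-wide cutoff
    (log10 Bayes factor > 5.64 corresponds to p < 5e-8 in the source GWAS).
    ``proxy_r2_min`` defaults below the conventional 0.8 because published
    analyses admit proxies somewhat under it; substitutions with r2 < 0.8 are
    logged as notices.
    """

    p_threshold: float = 5e-8
    log10_bf_threshold: float = 5.64
    r2_prune: float = 0.8
    proxy_r2_min: float = 0.65
    proxy_freq_tol: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise DomainError("p_threshold must be in (0, 1]")
        for name in ("r2_prune", "proxy_r2_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.proxy_freq_tol <= 0.5):
            raise DomainError("proxy_freq_tol must be in [0, 0.5]")


@dataclass(frozen=True)
class Status:
    """Provenance of one rsid along the curation pipeline."""

    state: str  # selected | dropped_ld | dropped_pleiotropy | dropped_no_proxy | substituted_by_proxy
    original_rsid: Optional[str] = None
    proxy_r2: Optional[float] = None
    reason: str = ""


@dataclass
class InstrumentSet:
    """An ordered, curated set of exposure associations with provenance."""

    members: list[SnpAssociation]
    provenance: dict[str, Status] = field(default_factory=dict)
    subset_label: str = "all"

    def __post_init__(self) -> None:
        rsids = [m.rsid for m in self.members]
        if len(set(rsids)) != len(rsids):
            raise DomainError("instrument members must be pairwise distinct")

    @property
    def rsids(self) -> list[str]:
        return [m.rsid for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def _p_key(rec: SnpAssociation) -> tuple[float, str]:
    # Equal p ties break on the lexicographically smaller rsid.
    p = rec.p if rec.p is not None else 1.0
    return (p, rec.rsid)


def select_genomewide(assoc: AssociationSet, cfg: SelectionConfig = SelectionConfig()) -> InstrumentSet:
    """Keep records with p below the genome-wide threshold, ordered by ascending p."""
    hits = sorted((r for r in assoc if r.p is not None and r.p < cfg.p_threshold), key=_p_key)
    if not hits:
        raise EmptyInstrumentError(
            f"no record in {assoc.trait_name!r} passes p < {cfg.p_threshold:g}"
        )
    prov = {r.rsid: Status("selected") for r in hits}
    return InstrumentSet(members=hits, provenance=prov)


def ld_prune(inst: InstrumentSet, ld: LdMatrix, r2_max: float = 0.8) -> InstrumentSet:
    """Greedy LD pruning in ascending-p order (clumping-style).

    Members are visited from smallest to largest p; each is kept unless it has
    r2 > ``r2_max`` with an already-kept member, in which case it is dropped
    (the larger-p member of every violating pair loses).  Idempotent.
    """
    missing = [m.rsid for m in inst.members if m.rsid not in ld]
    if missing:
        raise MissingCorrelationError(f"instruments absent from LD matrix: {missing}")
    kept: list[SnpAssociation] = []
    prov = dict(inst.provenance)
    for rec in sorted(inst.members, key=_p_key):
        clash = next(
            (k for k in kept if ld.get(rec.rsid, k.rsid) ** 2 > r2_max), None
        )
        if clash is None:
            kept.append(rec)
        else:
            prov[rec.rsid] = Status(
                "dropped_ld",
                reason=f"r2 {ld.get(rec.rsid, clash.rsid)**2:.3f} with {clash.rsid} "
                f"(larger p {rec.p:g} > {clash.p:g})",
            )
            logger.info("LD prune: dropped %s (high LD with %s)", rec.rsid, clash.rsid)
    return InstrumentSet(members=kept, provenance=prov, subset_label=inst.subset_label)


def subset_instruments(
    inst: InstrumentSet,
    annotations: Mapping[str, InstrumentAnnotation],
    mode: str = "all",
) -> InstrumentSet:
    """Restrict to a pleiotropy-defined subset of the instruments.

    ``no_known_pleiotropy`` keeps members with no recorded pleiotropic trait;
    ``functional`` keeps members flagged as functionally relevant to the
    exposure's metabolism.
    """
    if mode not in SUBSET_MODES:
        raise DomainError(f"unknown subset mode {mode!r}; expected one of {SUBSET_MODES}")
    unannotated = [m.rsid for m in inst.members if m.rsid not in annotations]
    if unannotated:
        raise AnnotationGapError(f"instruments without annotation: {unannotated}")
    if mode == "all":
        return InstrumentSet(list(inst.members), dict(inst.provenance), subset_label="all")
    kept = []
    prov = dict(inst.provenance)
    for rec in inst.members:
        ann = annotations[rec.rsid]
        keep = (not ann.pleiotropy_terms) if mode == "no_known_pleiotropy" else ann.functional
        if keep:
            kept.append(rec)
        else:
            prov[rec.rsid] = Status(
                "dropped_pleiotropy",
                reason="; ".join(ann.pleiotropy_terms) or "not functionally characterised",
            )
    return InstrumentSet(members=kept, provenance=prov, subset_label=mode)


def _proxy_record(
    original: SnpAssociation, cand, outcome_rec: SnpAssociation
) -> SnpAssociation:
    """Build the proxy's exposure record: the index SNP's effect re-keyed.

    The proxy inherits the index SNP's exposure beta/SE/frequency (the two are
    near-interchangeable by the r2 admission rule) but takes the proxy rsid and
    an allele pair consistent with the outcome file's orientation.
    """
    a_from, a_to = cand.allele_map
    pair = {outcome_rec.effect_allele, outcome_rec.other_allele}
    if a_to in pair:
        other = (pair - {a_to}).pop()
    elif COMPLEMENT[a_to] in pair:
        # outcome reports the opposite strand; keep our orientation
        other = COMPLEMENT[(pair - {COMPLEMENT[a_to]}).pop()]
    else:
        other = COMPLEMENT[a_to]
    return original.with_(rsid=cand.rsid, effect_allele=a_to, other_allele=other)


def substitute_proxies(
    inst: InstrumentSet,
    outcome: AssociationSet,
    annotations: Mapping[str, InstrumentAnnotation],
    cfg: SelectionConfig = SelectionConfig(),
) -> InstrumentSet:
    """Replace instruments absent from ``outcome`` by their best proxy.

    Candidates must meet ``cfg.proxy_r2_min``, be present in the outcome set,
    and (when both frequencies are known) agree in allele frequency within
    ``cfg.proxy_freq_tol``.  Ranking: highest r2, then smallest distance, then
    closest frequency.  Members with no admissible proxy are dropped with a
    logged warning; nothing raises.
    """
    members: list[SnpAssociation] = []
    prov = dict(inst.provenance)
    for rec in inst.members:
        if rec.rsid in outcome:
            members.append(rec)
            continue
        ann = annotations.get(rec.rsid)
        candidates = []
        for cand in (ann.proxy_candidates if ann else ()):
            if cand.r2 < cfg.proxy_r2_min or cand.rsid not in outcome:
                continue
            out_rec = outcome[cand.rsid]
            fdiff = 0.0
            if rec.eaf is not None and out_rec.eaf is not None:
                fdiff = min(abs(out_rec.eaf - rec.eaf), abs(1.0 - out_rec.eaf - rec.eaf))
                if fdiff > cfg.proxy_freq_tol:
                    continue
            candidates.append((-cand.r2, cand.distance_kb, fdiff, cand))
        if not candidates:
            prov[rec.rsid] = Status(
                "dropped_no_proxy", reason=f"absent from {outcome.trait_name!r}, no admissible proxy"
            )
            logger.warning(
                "%s absent from outcome %r and no admissible proxy; instrument dropped",
                rec.rsid,
                outcome.trait_name,
            )
            continue
        candidates.sort(key=lambda t: t[:3])
        best = candidates[0][3]
        if best.r2 < 0.8:
            logger.info(
                "proxy %s for %s admitted at r2=%.3f, below the conventional 0.8",
                best.rsid,
                rec.rsid,
                best.r2,
            )
        members.append(_proxy_record(rec, best, outcome[best.rsid]))
        prov[best.rsid] = Status(
            "substituted_by_proxy", original_rsid=rec.rsid, proxy_r2=best.r2
        )
    return InstrumentSet(members=members, provenance=prov, subset_label=inst.subset_label)
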