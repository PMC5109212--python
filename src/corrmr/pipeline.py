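"""Orchestration of the full analysis and assembly of the results table.

``run_analysis`` drives, for every configured outcome and instrument subset:
significance selection, LD pruning, pleiotropy subsetting, proxy substitution,
allele harmonization and correlated-instrument IVW estimation; outcomes
observed by two partially overlapping studies are additionally pooled with the
overlap-adjusted correlation.  Every row failure is recorded in place (NA with
a reason) and never aborts other rows; the whole path is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import fixtures
from .exceptions import CorrMrError, DomainError
from .estimators import ivw_correlated
from .harmonize import PalindromicPolicy, harmonize
from .instruments import (
    SUBSET_MODES,
    SelectionConfig,
    ld_prune,
    select_genomewide,
    subset_instruments,
    substitute_proxies,
)
from .io import read_association_table
from .pooling import OverlapSpec, overlap_correlation, pool_correlated
from .records import AssociationSet, InstrumentAnnotation, LdMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    consortium: str
    path: Optional[str] = None
    dialect: Optional[dict] = None


@dataclass(frozen=True)
class OutcomeConfig:
    """One association test: an outcome observed by one or two studies."""

    name: str
    trait_type: str
    studies: tuple[StudyConfig, ...]
    overlap: Optional[OverlapSpec] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise DomainError(f"{self.name}: trait_type must be binary or continuous")
        if not (1 <= len(self.studies) <= 2):
            raise DomainError(f"{self.name}: one or two studies per outcome")


@dataclass(frozen=True)
class AnalysisConfig:
    outcomes: tuple[OutcomeConfig, ...]
    subsets: tuple[str, ...] = ("all", "no_known_pleiotropy", "functional")
    alpha: float = 0.05
    n_tests: Optional[int] = None  # defaults to the number of outcomes
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    exposure_path: Optional[str] = None
    ld_path: Optional[str] = None
    annotation_path: Optional[str] = None
    exposure_trait_name: str = "exposure"

    def __post_init__(self) -> None:
        bad = [s for s in self.subsets if s not in SUBSET_MODES]
        if bad:
            raise DomainError(f"unknown subset labels: {bad}")
        if self.n_tests is not None and self.n_tests < 1:
            raise DomainError("n_tests must be >= 1")

    @property
    def effective_n_tests(self) -> int:
        return self.n_tests if self.n_tests is not None else len(self.outcomes)


def enumerate_tests(cfg: AnalysisConfig) -> list[str]:
    """The association tests the configuration defines (one per outcome)."""
    return [o.name for o in cfg.outcomes]


def load_config(path) -> AnalysisConfig:
    """Parse a YAML analysis configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        sel = SelectionConfig(**raw.get("selection", {}))
        outcomes = []
        for o in raw["outcomes"]:
            overlap = OverlapSpec(**o["overlap"]) if o.get("overlap") else None
            studies = tuple(
                StudyConfig(
                    consortium=s["consortium"],
                    path=s.get("path"),
                    dialect=s.get("dialect"),
                )
                for s in o["studies"]
            )
            outcomes.append(
                OutcomeConfig(
                    name=o["name"],
                    trait_type=o["trait_type"],
                    studies=studies,
                    overlap=overlap,
                )
            )
        return AnalysisConfig(
            outcomes=tuple(outcomes),
            subsets=tuple(raw.get("subsets", SUBSET_MODES)),
            alpha=float(raw.get("alpha", 0.05)),
            n_tests=raw.get("n_tests"),
            selection=sel,
            exposure_path=(raw.get("exposure") or {}).get("path"),
            ld_path=(raw.get("ld") or {}).get("path"),
            annotation_path=(raw.get("annotations") or {}).get("path"),
            exposure_trait_name=(raw.get("exposure") or {}).get("trait_name", "exposure"),
        )
    except (KeyError, TypeError) as exc:
        raise DomainError(f"malformed analysis config {path}: {exc}") from exc


def default_analysis_config() -> AnalysisConfig:
    """The packaged study layout: 18 association tests, three subsets."""
    with fixtures.default_config_path() as p:
        return load_config(p)


@dataclass
class ResultRow:
    """One outcome x subset x study cell of the results table."""

    outcome: str
    consortium: str
    subset: str
    trait_type: str
    n_snps: Optional[int] = None
    theta: Optional[float] = None
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p: Optional[float] = None
    nominal_significant: Optional[bool] = None
    bonferroni_significant: Optional[bool] = None
    note: str = ""

    @property
    def is_na(self) -> bool:
        return self.theta is None

    def estimate_str(self) -> str:
        """Odds ratio (binary) or mean difference, rounded to two decimals."""
        if self.is_na:
            return "NA"
        v = math.exp(self.theta) if self.trait_type == "binary" else self.theta
        return f"{v:.2f}"

    def ci_str(self) -> str:
        if self.is_na:
            return "NA"
        lo, hi = self.ci_low, self.ci_high
        if self.trait_type == "binary":
            lo, hi = math.exp(lo), math.exp(hi)
        return f"{lo:.2f}, {hi:.2f}"


@dataclass
class ResultsTable:
    rows: list[ResultRow]
    alpha: float = 0.05
    n_tests: int = 1

    @property
    def corrected_threshold(self) -> float:
        return self.alpha / self.n_tests

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "outcome": r.outcome,
                    "consortium": r.consortium,
                    "subset": r.subset,
                    "n_snps": r.n_snps,
                    "estimate": r.estimate_str(),
                    "ci_95": r.ci_str(),
                    "theta": r.theta,
                    "se": r.se,
                    "p": r.p,
                    "nominal_significant": r.nominal_significant,
                    "bonferroni_significant": r.bonferroni_significant,
                    "note": r.note,
                }
                for r in self.rows
            ]
        )


def bonferroni_flag(table: ResultsTable, alpha: float = 0.05, n_tests: int = 1) -> ResultsTable:
    """Set nominal (p < alpha) and corrected (p < alpha/n_tests) flags in place.

    The corrected threshold is the exact quotient alpha/n_tests, not its
    presentation rounding.
    """
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    for row in table.rows:
        if row.p is None:
            row.nominal_significant = None
            row.bonferroni_significant = None
        else:
            row.nominal_significant = row.p < alpha
            row.bonferroni_significant = row.p < alpha / n_tests
    table.alpha = alpha
    table.n_tests = n_tests
    return table


def _load_exposure_inputs(cfg: AnalysisConfig):
    if cfg.exposure_path:
        exposure = read_association_table(
            cfg.exposure_path, trait_name=cfg.exposure_trait_name, trait_type="continuous"
        )
    else:
        exposure = fixtures.coffee_instruments()
    from .io import read_annotation_table, read_ld_matrix

    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else fixtures.coffee_ld()
    annotations = (
        read_annotation_table(cfg.annotation_path)
        if cfg.annotation_path
        else fixtures.coffee_annotations()
    )
    return exposure, ld, annotations


def run_analysis(
    cfg: AnalysisConfig,
    data: Optional[Mapping[tuple[str, str], AssociationSet]] = None,
    exposure: Optional[AssociationSet] = None,
    ld: Optional[LdMatrix] = None,
    annotations: Optional[Mapping[str, InstrumentAnnotation]] = None,
    policy: PalindromicPolicy = PalindromicPolicy(),
) -> ResultsTable:
    """Run the full analysis over all outcomes and subsets.

    ``data`` maps ``(outcome name, consortium)`` to in-memory association sets
    and takes precedence over configured paths (used for simulated outcomes).
    Stage failures are recorded per row as NA-with-reason.
    """
    if exposure is None or ld is None or annotations is None:
        fx_exposure, fx_ld, fx_ann = _load_exposure_inputs(cfg)
        exposure = exposure or fx_exposure
        ld = ld or fx_ld
        annotations = annotations or fx_ann

    base = ld_prune(select_genomewide(exposure, cfg.selection), ld, cfg.selection.r2_prune)
    logger.info("instruments after selection + LD pruning: %d", len(base))

    rows: list[ResultRow] = []
    for outcome in cfg.outcomes:
        for subset in cfg.subsets:
            rows.extend(
                _analyse_cell(outcome, subset, base, annotations, ld, cfg, data, policy)
            )
    table = ResultsTable(rows)
    return bonferroni_flag(table, cfg.alpha, cfg.effective_n_tests)


def _study_data(
    outcome: OutcomeConfig,
    study: StudyConfig,
    data: Optional[Mapping[tuple[str, str], AssociationSet]],
) -> Optional[AssociationSet]:
    if data and (outcome.name, study.consortium) in data:
        return data[(outcome.name, study.consortium)]
    if study.path and Path(study.path).exists():
        return read_association_table(
            study.path,
            trait_name=outcome.name,
            trait_type=outcome.trait_type,
            dialect=study.dialect,
            provenance=study.consortium,
        )
    return None


def _analyse_cell(
    outcome: OutcomeConfig,
    subset: str,
    base,
    annotations,
    ld: LdMatrix,
    cfg: AnalysisConfig,
    data,
    policy: PalindromicPolicy,
) -> list[ResultRow]:
    scale = "log_odds" if outcome.trait_type == "binary" else "trait_units"
    try:
        sub = subset_instruments(base, annotations, subset)
    except CorrMrError as exc:
        return [
            ResultRow(outcome.name, s.consortium, subset, outcome.trait_type, note=str(exc))
            for s in outcome.studies
        ]

    rows: list[ResultRow] = []
    estimates = []
    for study in outcome.studies:
        row = ResultRow(outcome.name, study.consortium, subset, outcome.trait_type)
        aset = _study_data(outcome, study, data)
        if aset is None:
            row.note = "no data available"
            rows.append(row)
            estimates.append(None)
            continue
        try:
            inst = substitute_proxies(sub, aset, annotations, cfg.selection)
            if not inst.members:
                raise DomainError("no admissible instruments for this outcome")
            hset = harmonize(inst, aset, ld, policy)
            est = ivw_correlated(hset, scale=scale)
        except CorrMrError as exc:
            row.note = str(exc)
            rows.append(row)
            estimates.append(None)
            continue
        row.n_snps = est.n_snps
        row.theta, row.se = est.theta, est.se
        row.ci_low, row.ci_high, row.p = est.ci_low, est.ci_high, est.p
        rows.append(row)
        estimates.append(est)

    if len(outcome.studies) == 2:
        pooled_row = ResultRow(outcome.name, "Pooled", subset, outcome.trait_type)
        if all(e is not None for e in estimates):
            r = overlap_correlation(outcome.overlap) if outcome.overlap else 0.0
            pooled = pool_correlated(estimates[0], estimates[1], r)
            pooled_row.n_snps = max(e.n_snps for e in estimates)
            pooled_row.theta, pooled_row.se = pooled.theta, pooled.se
            pooled_row.ci_low, pooled_row.ci_high = pooled.ci_low, pooled.ci_high
            pooled_row.p = pooled.p
            pooled_row.note = f"overlap correlation {pooled.r_used:.3f}"
        else:
            pooled_row.note = "pooling skipped: missing component estimate"
        rows.append(pooled_row)
    return rows
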