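"""Packaged study fixtures for the habitual-coffee-consumption analysis.

The instrument table transcribes the published genome-wide significant coffee
SNPs (effect per allele in cups/day, SE 0.01), their pleiotropy annotations
and their documented proxies.  The LD matrix is synthetic by construction:
only the proxy r-squared values and the one above-threshold pair are published,
so those entries carry the published magnitudes (positive sign assumed) and
all unpublished pairs are set to zero.

Also packaged: the two ischemic-heart-disease consortium results (odds ratios
with 95% CIs per instrument subset) and their sample-overlap specification,
which drive the overlap-adjusted pooling.
"""

from __future__ import annotations

from importlib import resources

from .io import read_annotation_table, read_association_table, read_ld_matrix
from .pooling import OverlapSpec
from .records import AssociationSet, InstrumentAnnotation, LdMatrix

_DATA = resources.files("corrmr.data")


def _path(name: str):
    return resources.as_file(_DATA / name)


def coffee_instruments() -> AssociationSet:
    """The transcribed coffee-GWAS instrument table (10 SNPs, cups/day)."""
    with _path("coffee_instruments.tsv") as p:
        return read_association_table(
            p,
            trait_name="habitual coffee consumption (cups/day)",
            trait_type="continuous",
            provenance="coffee-consumption GWAS, 129,788 drinkers",
        )


def coffee_ld() -> LdMatrix:
    """Signed LD among the instruments and their proxies (synthetic fill-in)."""
    with _path("coffee_ld.tsv") as p:
        return read_ld_matrix(p)


def coffee_annotations() -> dict[str, InstrumentAnnotation]:
    """Pleiotropy terms, functional flags and proxy candidates per instrument."""
    with _path("instrument_annotations.tsv") as p:
        return read_annotation_table(p)


def default_config_path():
    """Context manager yielding the packaged default analysis config path."""
    return _path("default_config.yaml")


#: Published per-consortium ischemic heart disease results: odds ratio with
#: 95% CI per instrument subset (all 9 SNPs / 5 without known pleiotropy /
#: 3 functionally relevant).
IHD_GWAS_OR = {
    "all": (1.06, 0.94, 1.20),
    "no_known_pleiotropy": (1.07, 0.91, 1.26),
    "functional": (1.12, 0.84, 1.49),
}
IHD_METABOCHIP_OR = {
    "all": (0.96, 0.84, 1.10),
    "no_known_pleiotropy": (0.96, 0.80, 1.14),
    "functional": (0.97, 0.73, 1.30),
}

#: Sample overlap of the two IHD consortia: 57.5% of cases and 40.1% of
#: controls are shared.  Shared counts are taken as those fractions of the
#: smaller study's cases and of the first-listed study's controls.
IHD_OVERLAP = OverlapSpec(
    n_cases_1=60_801,
    n_controls_1=123_504,
    n_cases_2=63_746,
    n_controls_2=130_681,
    shared_cases=round(0.575 * 60_801),
    shared_controls=round(0.401 * 123_504),
)
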