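"""Instrument curation: significance filter, LD pruning, pleiotropy subsets,
proxy substitution, and the 10 -> 9 -> 5 -> 3 selection flow."""

import itertools
import logging

import numpy as np
import pytest

from corrmr.exceptions import (
    AnnotationGapError,
    EmptyInstrumentError,
    MissingCorrelationError,
)
from corrmr.instruments import (
    SelectionConfig,
    ld_prune,
    select_genomewide,
    subset_instruments,
    substitute_proxies,
)
from corrmr.records import InstrumentAnnotation, LdMatrix

from conftest import association_set, identity_ld, snp

VACUOUS = SelectionConfig(p_threshold=1.0)


class TestSelect:
    def test_packaged_table_is_fully_certified(self, coffee_exposure):
        """The transcribed instrument list passes selection in its entirety
        (it is the discovery GWAS's certified genome-wide significant set)."""
        inst = select_genomewide(coffee_exposure, VACUOUS)
        assert len(inst) == 10

    def test_filters_on_p_and_orders_ascending(self):
        aset = association_set(
            [snp("rs_a", p=0.5), snp("rs_b", p=1e-9), snp("rs_c", p=1e-12)]
        )
        inst = select_genomewide(aset, SelectionConfig(p_threshold=5e-8))
        assert inst.rsids == ["rs_c", "rs_b"]

    def test_vacuous_threshold_retains_all(self):
        aset = association_set([snp("rs_a", p=0.5), snp("rs_b", p=0.99)])
        assert len(select_genomewide(aset, VACUOUS)) == 2

    def test_no_survivor_is_an_error(self):
        aset = association_set([snp("rs_a", p=0.5)])
        with pytest.raises(EmptyInstrumentError):
            select_genomewide(aset, SelectionConfig(p_threshold=5e-8))


def _brute_force_optimal_sets(rsids, pvals, r2, r2_max):
    """All maximal conflict-free subsets, by enumeration."""
    ok = []
    n = len(rsids)
    for k in range(n, 0, -1):
        for keep in itertools.combinations(range(n), k):
            if all(r2[i][j] <= r2_max for i, j in itertools.combinations(keep, 2)):
                ok.append(set(keep))
        if ok:
            return ok
    return [set()]


class TestLdPrune:
    def test_packaged_flow_drops_the_high_ld_twin(self, coffee_exposure, coffee_ld):
        inst = ld_prune(select_genomewide(coffee_exposure, VACUOUS), coffee_ld, 0.8)
        assert len(inst) == 9
        assert "rs6968554" not in inst.rsids  # p 5.23e-17 > 3.08e-17 of rs4410790
        assert "rs4410790" in inst.rsids
        assert inst.provenance["rs6968554"].state == "dropped_ld"

    def test_no_ld_leaves_set_unchanged(self):
        inst = select_genomewide(
            association_set([snp("rs_a", p=1e-10), snp("rs_b", p=1e-9)]), VACUOUS
        )
        pruned = ld_prune(inst, identity_ld(["rs_a", "rs_b"]), 0.8)
        assert pruned.rsids == inst.rsids

    def test_chain_keeps_endpoints_matching_enumeration_oracle(self):
        """A r2 0.9 with B, B 0.9 with C, A 0.1 with C, p_A < p_B < p_C: the
        greedy sweep must return a maximal conflict-free set containing the
        smallest-p member -- here {A, C}."""
        rsids = ["rs_a", "rs_b", "rs_c"]
        pvals = [1e-12, 1e-10, 1e-8]
        r = np.array([[1.0, 0.9487, 0.3162], [0.9487, 1.0, 0.9487], [0.3162, 0.9487, 1.0]])
        ld = LdMatrix(rsids, r)
        inst = select_genomewide(
            association_set([snp(s, p=p) for s, p in zip(rsids, pvals)]), VACUOUS
        )
        pruned = ld_prune(inst, ld, 0.8)
        assert set(pruned.rsids) == {"rs_a", "rs_c"}
        optimal = _brute_force_optimal_sets(rsids, pvals, (r**2).tolist(), 0.8)
        kept_idx = {rsids.index(s) for s in pruned.rsids}
        assert kept_idx in optimal
        assert 0 in kept_idx  # smallest-p member always survives

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        rsids = [f"rs{i}" for i in range(n)]
        a = rng.uniform(-1, 1, (n, n))
        r = np.clip((a + a.T) / 2, -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        ld = LdMatrix(rsids, r)
        inst = select_genomewide(
            association_set([snp(s, p=float(p)) for s, p in zip(rsids, rng.uniform(1e-20, 1e-8, n))]),
            VACUOUS,
        )
        once = ld_prune(inst, ld, 0.5)
        twice = ld_prune(once, ld, 0.5)
        assert twice.rsids == once.rsids

    def test_member_absent_from_ld_is_an_error(self):
        inst = select_genomewide(association_set([snp("rs_a", p=1e-10)]), VACUOUS)
        with pytest.raises(MissingCorrelationError, match="rs_a"):
            ld_prune(inst, identity_ld(["rs_other"]), 0.8)


class TestSubsets:
    @pytest.fixture()
    def pruned(self, coffee_exposure, coffee_ld):
        return ld_prune(select_genomewide(coffee_exposure, VACUOUS), coffee_ld, 0.8)

    def test_no_known_pleiotropy_keeps_five(self, pruned, coffee_annotations):
        sub = subset_instruments(pruned, coffee_annotations, "no_known_pleiotropy")
        assert sorted(sub.rsids) == [
            "rs17685",
            "rs2470893",
            "rs2472297",
            "rs4410790",
            "rs9902453",
        ]

    def test_functional_keeps_three(self, pruned, coffee_annotations):
        sub = subset_instruments(pruned, coffee_annotations, "functional")
        assert sorted(sub.rsids) == ["rs2470893", "rs2472297", "rs4410790"]

    def test_functional_subset_nested_in_no_pleiotropy(self, pruned, coffee_annotations):
        nk = set(subset_instruments(pruned, coffee_annotations, "no_known_pleiotropy").rsids)
        fn = set(subset_instruments(pruned, coffee_annotations, "functional").rsids)
        assert fn <= nk

    def test_pipeline_counts_shrink_monotonically(self, coffee_exposure, coffee_ld, coffee_annotations):
        sel = select_genomewide(coffee_exposure, VACUOUS)
        pr = ld_prune(sel, coffee_ld, 0.8)
        counts = [len(sel), len(pr)] + [
            len(subset_instruments(pr, coffee_annotations, m))
            for m in ("all", "no_known_pleiotropy", "functional")
        ]
        assert counts == [10, 9, 9, 5, 3]

    def test_empty_annotations_leave_set_unchanged(self, pruned):
        blank = {s: InstrumentAnnotation(rsid=s) for s in pruned.rsids}
        sub = subset_instruments(pruned, blank, "no_known_pleiotropy")
        assert sub.rsids == pruned.rsids

    def test_unannotated_member_is_an_error(self, pruned, coffee_annotations):
        partial = {k: v for k, v in coffee_annotations.items() if k != "rs17685"}
        with pytest.raises(AnnotationGapError, match="rs17685"):
            subset_instruments(pruned, partial, "no_known_pleiotropy")


class TestProxies:
    @pytest.fixture()
    def pruned(self, coffee_exposure, coffee_ld):
        return ld_prune(select_genomewide(coffee_exposure, VACUOUS), coffee_ld, 0.8)

    def _outcome_missing(self, pruned, missing, extra=()):
        recs = [
            snp(m.rsid, m.effect_allele, m.other_allele, beta=0.01, se=0.02, eaf=m.eaf)
            for m in pruned.members
            if m.rsid != missing
        ]
        recs += list(extra)
        return association_set(recs, trait_name="outcome", trait_type="binary")

    def test_documented_proxy_substitution(self, pruned, coffee_annotations):
        outcome = self._outcome_missing(
            pruned, "rs17685", extra=[snp("rs8565", "A", "G", beta=0.01, se=0.02, eaf=0.29)]
        )
        inst = substitute_proxies(pruned, outcome, coffee_annotations)
        assert "rs8565" in inst.rsids and "rs17685" not in inst.rsids
        status = inst.provenance["rs8565"]
        assert status.state == "substituted_by_proxy"
        assert status.original_rsid == "rs17685"
        assert status.proxy_r2 == 0.845
        # the proxy inherits the index SNP's exposure effect
        proxy = next(m for m in inst.members if m.rsid == "rs8565")
        assert proxy.beta == 0.07 and proxy.se == 0.01

    def test_all_present_is_a_no_op(self, pruned, coffee_annotations):
        outcome = self._outcome_missing(pruned, missing=None)
        inst = substitute_proxies(pruned, outcome, coffee_annotations)
        assert inst.rsids == pruned.rsids

    def test_below_threshold_candidate_drops_with_warning(self, pruned, coffee_annotations, caplog):
        outcome = self._outcome_missing(
            pruned, "rs17685", extra=[snp("rs8565", "A", "G", beta=0.01, se=0.02, eaf=0.29)]
        )
        strict = SelectionConfig(proxy_r2_min=0.9)
        with caplog.at_level(logging.WARNING):
            inst = substitute_proxies(pruned, outcome, coffee_annotations, strict)
        assert "rs17685" not in inst.rsids and "rs8565" not in inst.rsids
        assert len(inst) == 8
        assert inst.provenance["rs17685"].state == "dropped_no_proxy"
        assert any("rs17685" in rec.message for rec in caplog.records)

    def test_frequency_tolerance_gates_candidates(self, pruned, coffee_annotations):
        # rs8565 with a discordant allele frequency is not admissible
        outcome = self._outcome_missing(
            pruned, "rs17685", extra=[snp("rs8565", "A", "G", beta=0.01, se=0.02, eaf=0.60)]
        )
        inst = substitute_proxies(pruned, outcome, coffee_annotations)
        assert "rs8565" not in inst.rsids
        assert len(inst) == 8
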